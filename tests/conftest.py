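import numpy as np
import pytest

from phageflex.alignments import compute_coverage
from phageflex.islands import detect_mgis
from phageflex.simulate import (CommunityConfig, emit_ideal_alignments,
                                simulate_community, simulate_reads,
                                to_alignment_records)


@pytest.fixture(scope="session")
def small_community():
    """A two-location community with two divergent variable modules."""
    cfg = CommunityConfig(
        genome_length=14_000, n_modules=2, module_length_range=(600, 1400),
        variants_per_module=(2, 3), inter_variant_identity_range=(0.50, 0.70),
        n_locations=2, depth_per_location=20.0, sequencing_error_rate=0.001,
        seed=9)
    references, truth = simulate_community(cfg)
    return cfg, references, truth


@pytest.fixture(scope="session")
def cross_recruitment(small_community):
    """Location-0 reads recruited to the location-1 reference, with
    coverage track and detected islands."""
    cfg, references, truth = small_community
    pairs, read_truth = simulate_reads(truth, 0, cfg)
    alns = emit_ideal_alignments(pairs, read_truth, truth, 1)
    records = to_alignment_records(alns, "ref")
    track = compute_coverage(records, "ref", len(references[1]))
    mgis = detect_mgis(track)
    return dict(cfg=cfg, references=references, truth=truth, pairs=pairs,
                read_truth=read_truth, records=records, track=track, mgis=mgis)


def brute_force_islands(depth, mean, regime, frac_of_mean=0.25,
                        min_len_high=100, min_len_low=200):
    """Independent per-position scan for qualifying dropout runs."""
    if regime == "high_regime":
        def below(d):
            return d < frac_of_mean * mean
        min_len = min_len_high
    else:
        def below(d):
            return d == 0
        min_len = min_len_low
    out = []
    i = 0
    n = len(depth)
    while i < n:
        if below(depth[i]):
            j = i
            while j < n and below(depth[j]):
                j += 1
            if j - i >= min_len:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


def random_track(rng, length=None):
    """A random piecewise-constant coverage track with planted dropouts."""
    length = length or int(rng.integers(5_000, 100_001))
    base = int(rng.integers(1, 40))
    depth = rng.poisson(base, size=length).astype(np.int32)
    for _ in range(int(rng.integers(0, 6))):
        start = int(rng.integers(0, max(1, length - 500)))
        span = int(rng.integers(30, 500))
        level = int(rng.integers(0, max(1, base // 3)))
        depth[start:start + span] = level
    return depth
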