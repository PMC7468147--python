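"""Island detection: regime rules, worked examples, oracle equivalence."""

import numpy as np
import pytest

from phageflex.alignments import CoverageTrack
from phageflex.islands import (DetectionConfig, Eligibility,
                               detect_mgis, eligible_for_detection, read_bed,
                               summarize_mgis, write_bed)

from conftest import brute_force_islands, random_track


def track_of(depth):
    return CoverageTrack("c", np.asarray(depth, dtype=np.int32))


class TestEligibility:
    def test_low_breadth_excluded_despite_high_depth(self):
        depth = np.zeros(1000, dtype=np.int32)
        depth[:650] = 46  # breadth 0.65, mean ~30x
        track = track_of(depth)
        assert track.breadth < 0.70 and track.mean_depth > 5
        assert eligible_for_detection(track) is Eligibility.EXCLUDED_LOW_BREADTH

    def test_mean_below_two_excluded(self):
        depth = np.ones(1000, dtype=np.int32)
        assert eligible_for_detection(track_of(depth)) is Eligibility.EXCLUDED_LOW_DEPTH

    def test_low_regime_between_two_and_five(self):
        depth = np.full(1000, 3, dtype=np.int32)
        assert eligible_for_detection(track_of(depth)) is Eligibility.LOW_REGIME

    def test_exactly_five_is_high_regime(self):
        depth = np.full(1000, 5, dtype=np.int32)
        assert eligible_for_detection(track_of(depth)) is Eligibility.HIGH_REGIME

    def test_zero_length_contig_errors(self):
        with pytest.raises(ValueError):
            eligible_for_detection(track_of([]))


class TestDetection:
    def test_high_regime_dropout_with_extension(self):
        # 1000 bp at 20x except a 150 bp stretch at 4x:
        # mean 17.6, threshold 4.4, island [400, 550), extended clamped
        depth = np.full(1000, 20, dtype=np.int32)
        depth[400:550] = 4
        track = track_of(depth)
        assert track.mean_depth == pytest.approx(17.6)
        mgis = detect_mgis(track)
        assert len(mgis) == 1
        mgi = mgis[0]
        assert (mgi.start, mgi.end) == (400, 550)
        assert mgi.rule == "high_regime"
        assert (mgi.ext_start, mgi.ext_end) == (100, 850)

    def test_uniform_coverage_has_no_islands(self):
        assert detect_mgis(track_of(np.full(1000, 20))) == []

    def test_low_regime_requires_zero_coverage_run(self):
        depth = np.full(1000, 4, dtype=np.int32)
        depth[100:350] = 0
        track = track_of(depth)
        assert track.mean_depth == pytest.approx(3.0)
        mgis = detect_mgis(track)
        assert len(mgis) == 1
        assert (mgis[0].start, mgis[0].end) == (100, 350)
        assert mgis[0].rule == "low_regime"

    def test_dropout_below_min_length_ignored(self):
        depth = np.full(2000, 20, dtype=np.int32)
        depth[500:590] = 0  # 90 bp < 100 bp minimum
        assert detect_mgis(track_of(depth)) == []

    def test_matches_brute_force_oracle_on_random_tracks(self):
        rng = np.random.default_rng(33)
        checked = 0
        for _ in range(150):
            depth = random_track(rng, length=int(rng.integers(2000, 20_000)))
            track = track_of(depth)
            regime = eligible_for_detection(track)
            if regime not in (Eligibility.HIGH_REGIME, Eligibility.LOW_REGIME):
                continue
            got = [(m.start, m.end) for m in detect_mgis(track)]
            expected = brute_force_islands(depth.tolist(), track.mean_depth,
                                           regime.value)
            assert got == expected
            checked += 1
        assert checked > 50

    def test_lower_frac_of_mean_never_creates_new_islands(self):
        rng = np.random.default_rng(44)
        for _ in range(20):
            depth = random_track(rng, length=5000) + 6  # force high regime
            track = track_of(depth)
            if eligible_for_detection(track) is not Eligibility.HIGH_REGIME:
                continue
            loose = {(m.start, m.end) for m in detect_mgis(
                track, DetectionConfig(frac_of_mean=0.25))}
            strict_cfg = DetectionConfig(frac_of_mean=0.10)
            strict = detect_mgis(track, strict_cfg)
            covered = np.zeros(track.length, dtype=bool)
            for s, e in loose:
                covered[s:e] = True
            for m in strict:
                assert covered[m.start:m.end].all()


class TestSummary:
    def test_mean_and_range(self):
        depth = np.full(5000, 20, dtype=np.int32)
        depth[100:200] = 0
        depth[1000:1200] = 0
        depth[2000:2300] = 0
        mgis = detect_mgis(track_of(depth))
        summary = summarize_mgis(mgis, {"c": 5000})
        assert summary["count"] == 3
        assert summary["mean_length"] == pytest.approx(200.0)
        assert (summary["min_length"], summary["max_length"]) == (100, 300)

    def test_no_islands_reports_absent_mean(self):
        summary = summarize_mgis([], {"c": 1000})
        assert summary["count"] == 0 and summary["mean_length"] is None

    def test_bp_per_kb(self):
        depth = np.full(15_000, 20, dtype=np.int32)
        depth[1000:1500] = 0
        depth[5000:5500] = 0
        depth[9000:9500] = 0
        mgis = detect_mgis(track_of(depth))
        summary = summarize_mgis(mgis, {"c": 15_000})
        assert summary["mgi_bp_per_kb"] == pytest.approx(100.0)


def test_bed_round_trip(tmp_path):
    depth = np.full(3000, 20, dtype=np.int32)
    depth[500:800] = 0
    mgis = detect_mgis(track_of(depth))
    path = tmp_path / "islands.bed"
    write_bed(mgis, path, seed=1)
    back = read_bed(path, {"c": 3000})
    assert [(m.contig_id, m.start, m.end, m.rule) for m in back] == \
           [(m.contig_id, m.start, m.end, m.rule) for m in mgis]


from hypothesis import given, settings, strategies as st


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=40), min_size=300,
                max_size=1200))
def test_detection_equals_oracle_on_arbitrary_tracks(depths):
    """Property: on any depth profile the run-length scan and the
    per-position oracle agree (islands, coordinates, rule)."""
    track = track_of(depths)
    regime = eligible_for_detection(track)
    if regime in (Eligibility.EXCLUDED_LOW_BREADTH,
                  Eligibility.EXCLUDED_LOW_DEPTH):
        return
    got = [(m.start, m.end) for m in detect_mgis(track)]
    expected = brute_force_islands(list(depths), track.mean_depth, regime.value)
    assert got == expected
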