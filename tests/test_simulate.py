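"""Community generator: invariants, determinism, depth and identity targets."""

import numpy as np
import pytest

from phageflex.identity import fast_identity, pairwise_identity
from phageflex.simulate import (CommunityConfig, SimulationError,
                                emit_ideal_alignments, simulate_community,
                                simulate_reads)


class TestConfigValidation:
    def test_insert_shorter_than_two_reads_rejected(self):
        with pytest.raises(SimulationError, match="insert"):
            CommunityConfig(insert_mean=150, read_length=100).validate()

    def test_bad_mixture_simplex_rejected(self):
        cfg = CommunityConfig(n_modules=1, n_locations=1,
                              mixture_proportions=(((0.5, 0.4),),))
        with pytest.raises(SimulationError, match="simplex"):
            cfg.validate()

    def test_deletion_index_out_of_range_rejected(self):
        with pytest.raises(SimulationError):
            CommunityConfig(n_modules=2, deletion_modules=frozenset({5})).validate()

    def test_modules_that_cannot_fit_raise_placement_error(self):
        cfg = CommunityConfig(genome_length=8_000, n_modules=4,
                              module_length_range=(3000, 3000), n_locations=1)
        with pytest.raises(SimulationError, match="fit"):
            simulate_community(cfg)


def test_no_modules_gives_core_only_drift():
    cfg = CommunityConfig(genome_length=8_000, n_modules=0, n_locations=2, seed=2)
    references, truth = simulate_community(cfg)
    ident = fast_identity(references[0], references[1])
    assert ident == pytest.approx(cfg.core_identity_between_locations, abs=0.005)


def test_variant_count_and_byte_determinism():
    cfg = CommunityConfig(genome_length=12_000, n_modules=2,
                          module_length_range=(600, 900),
                          variants_per_module=(2, 2), n_locations=2, seed=1)
    refs_a, truth_a = simulate_community(cfg)
    refs_b, truth_b = simulate_community(cfg)
    assert sum(m.n_variants for m in truth_a.modules) == 4
    assert refs_a == refs_b
    for mod_a, mod_b in zip(truth_a.modules, truth_b.modules):
        assert mod_a.variants == mod_b.variants
    pairs_a, rt_a = simulate_reads(truth_a, 0, cfg)
    pairs_b, rt_b = simulate_reads(truth_b, 0, cfg)
    assert pairs_a == pairs_b
    assert rt_a == rt_b


def test_module_intervals_disjoint_and_in_bounds(small_community):
    cfg, _, truth = small_community
    prev_end = 0
    for mod in truth.modules:
        assert 0 <= mod.anc_start < mod.anc_end <= cfg.genome_length
        assert mod.anc_start >= prev_end
        prev_end = mod.anc_end


def test_realized_identity_near_target_and_below_distinctness():
    cfg = CommunityConfig(genome_length=9_000, n_modules=1,
                          module_length_range=(900, 900),
                          variants_per_module=(3, 3),
                          inter_variant_identity_range=(0.45, 0.55),
                          n_locations=1, seed=4)
    _, truth = simulate_community(cfg)
    mod = truth.modules[0]
    for i in range(mod.n_variants):
        for j in range(i + 1, mod.n_variants):
            # verify with the reference affine-gap aligner, not the
            # generator's internal metric
            ident = pairwise_identity(mod.variants[i], mod.variants[j])
            assert ident < 0.90
            assert 0.40 <= ident <= 0.62  # target band +- tolerance


def test_mixture_simplexes_sum_to_one(small_community):
    cfg, _, truth = small_community
    for loc_mix in truth.mixtures:
        for simplex in loc_mix:
            assert np.sum(simplex) == pytest.approx(1.0, abs=1e-9)


class TestReads:
    def test_mean_core_depth_within_sampling_error(self):
        cfg = CommunityConfig(genome_length=76_000, n_modules=0, n_locations=1,
                              depth_per_location=20.0,
                              sequencing_error_rate=0.0, seed=6)
        _, truth = simulate_community(cfg)
        pairs, read_truth = simulate_reads(truth, 0, cfg)
        alns = emit_ideal_alignments(pairs, read_truth, truth, 0)
        total_bp = sum(len(a.seq_fwd) for a in alns if a.mapped)
        assert 18.0 <= total_bp / truth.genome(0).length <= 22.0

    def test_zero_depth_gives_no_reads(self):
        cfg = CommunityConfig(genome_length=8_000, n_modules=0, n_locations=1,
                              depth_per_location=0.0, seed=6)
        _, truth = simulate_community(cfg)
        pairs, read_truth = simulate_reads(truth, 0, cfg)
        assert pairs == [] and read_truth == []

    def test_mixture_proportions_drive_read_origins(self):
        mix = (((0.7, 0.3),),)
        cfg = CommunityConfig(genome_length=10_000, n_modules=1,
                              module_length_range=(1500, 1500),
                              variants_per_module=(2, 2), n_locations=1,
                              depth_per_location=20.0,
                              mixture_proportions=mix, seed=8)
        _, truth = simulate_community(cfg)
        _, read_truth = simulate_reads(truth, 0, cfg)
        module_reads = [r for r in read_truth if r.module == 0]
        frac_a = np.mean([r.variant == 0 for r in module_reads])
        assert frac_a == pytest.approx(0.70, abs=0.05)

    def test_every_read_traceable(self, small_community):
        cfg, _, truth = small_community
        pairs, read_truth = simulate_reads(truth, 0, cfg)
        assert len(pairs) == len(read_truth)
        assert len({r.read_id for r in read_truth}) == len(read_truth)


class TestIdealAlignments:
    def test_own_variant_error_free_maps_with_zero_mismatches(self):
        cfg = CommunityConfig(genome_length=8_000, n_modules=0, n_locations=1,
                              depth_per_location=5.0,
                              sequencing_error_rate=0.0,
                              core_identity_between_locations=1.0, seed=10)
        _, truth = simulate_community(cfg)
        pairs, read_truth = simulate_reads(truth, 0, cfg)
        alns = emit_ideal_alignments(pairs, read_truth, truth, 0)
        assert alns and all(a.mapped and a.mismatches == 0 for a in alns)

    def test_reads_inside_foreign_variant_are_unmapped(self, cross_recruitment):
        truth = cross_recruitment["truth"]
        read_truth = cross_recruitment["read_truth"]
        mapped_ids = {r.read_id for r in cross_recruitment["records"]}
        for rec in read_truth:
            if rec.module < 0:
                continue
            if rec.variant != truth.dominants[1][rec.module]:
                src = truth.genome(0, rec.module, rec.variant)
                ms, me = int(src.module_starts[rec.module]), int(src.module_ends[rec.module])
                # fragment entirely inside the divergent module: both
                # mates must be unmapped, hence absent from the SAM
                if ms <= rec.template_start and rec.template_start + rec.insert <= me:
                    assert rec.read_id not in mapped_ids

    def test_pair_over_deletion_is_discordant_with_stretched_template(self):
        cfg = CommunityConfig(genome_length=10_000, n_modules=1,
                              module_length_range=(700, 700), n_locations=2,
                              deletion_modules=frozenset({0}),
                              depth_per_location=20.0, seed=12)
        refs, truth = simulate_community(cfg)
        read_loc = next(l for l in range(2) if truth.dominants[l][0] == 1)
        ref_loc = 1 - read_loc
        pairs, read_truth = simulate_reads(truth, read_loc, cfg)
        alns = emit_ideal_alignments(pairs, read_truth, truth, ref_loc)
        discordant = [a for a in alns
                      if a.mapped and a.mate_mapped and not a.proper_pair]
        assert discordant
        tlens = {abs(a.template_length) for a in discordant}
        # template ~ insert + deleted module length (700)
        assert all(700 < t <= cfg.max_insert + 700 + 100 for t in tlens)
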