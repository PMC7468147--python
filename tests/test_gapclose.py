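"""Consensus contracts, read recruitment, patching, closure, validation."""

import numpy as np
import pytest

from phageflex.alignments import AlignmentRecord
from phageflex.assemble import Contig
from phageflex.gapclose import (Pileup, ReadStore,
                                call_consensus, close_locus, patch_consensus,
                                recruit_gap_reads, validate_by_reassembly)
from phageflex.identity import fast_identity
from phageflex.islands import MGIInterval
from phageflex.simulate import simulate_reads


def pileup_of(columns, reference):
    """columns: list of dicts base->count."""
    counts = np.zeros((4, len(columns)), dtype=np.int32)
    for pos, col in enumerate(columns):
        for base, count in col.items():
            counts["ACGT".index(base), pos] = count
    return Pileup(counts, reference)


class TestConsensus:
    def test_plurality_wins_regardless_of_fraction(self):
        pile = pileup_of([{"A": 3, "G": 1}], "T")
        assert call_consensus(pile, "reference_fill") == "A"

    def test_zero_depth_takes_reference_base(self):
        pile = pileup_of([{}], "C")
        assert call_consensus(pile, "reference_fill") == "C"

    def test_zero_depth_takes_n_in_n_fill(self):
        pile = pileup_of([{}], "C")
        assert call_consensus(pile, "n_fill") == "N"

    def test_tie_resolves_by_fixed_base_priority(self):
        pile = pileup_of([{"G": 2, "C": 2}, {"T": 1, "A": 1}], "NN")
        assert call_consensus(pile, "n_fill") == "CA"

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            call_consensus(pileup_of([{"A": 1}], "A"), "majority_50")


class TestRecruitment:
    def rec(self, read_id, start, mapped=True):
        return AlignmentRecord(read_id, "c", start, 100, 0, 400, mapped,
                               True, True)

    def island(self):
        return MGIInterval("c", 5000, 6000, 4700, 6300, "high_regime", 20.0)

    def test_flank_anchored_read_and_mate_recruited(self):
        # the mate itself is unmapped, but its anchor is 100 bp left of
        # the island: the whole template joins the pool
        records = [self.rec("p1", 4900), self.rec("p1", 0, mapped=False)]
        assert recruit_gap_reads(records, self.island()) == {"p1"}

    def test_distant_pair_excluded(self):
        records = [self.rec("far", 15_000)]
        assert recruit_gap_reads(records, self.island()) == set()

    def test_pool_size_scales_with_depth(self, cross_recruitment):
        cfg = cross_recruitment["cfg"]
        mgi = cross_recruitment["mgis"][0]
        ids = recruit_gap_reads(cross_recruitment["records"], mgi, flank=500)
        expected = (mgi.length + 2 * 500) * cfg.depth_per_location \
            / (2 * cfg.read_length)
        # divergent-module interiors recruit nothing, so the pool holds
        # roughly the flank-anchored half of the expected templates
        assert 0.3 * expected <= len(ids) <= 1.5 * expected


class TestPatching:
    def build_case(self, gap=500, flank=300):
        rng = np.random.default_rng(60)
        left = "".join(rng.choice(list("ACGT"), flank))
        interior = "".join(rng.choice(list("ACGT"), gap))
        right = "".join(rng.choice(list("ACGT"), flank))
        consensus = left + "N" * gap + right
        contig = Contig(left + interior + right, 10.0)
        return consensus, interior, contig, left, right

    def test_matching_contig_replaces_n_run(self):
        consensus, interior, contig, left, right = self.build_case()
        patched, n = patch_consensus(consensus, [contig])
        assert n == 1
        assert patched == left + interior + right

    def test_no_matching_contig_leaves_ns(self):
        consensus, *_ = self.build_case()
        rng = np.random.default_rng(61)
        decoy = Contig("".join(rng.choice(list("ACGT"), 800)), 5.0)
        patched, n = patch_consensus(consensus, [decoy])
        assert n == 0 and patched == consensus

    def test_gap_beyond_cap_not_patched(self):
        consensus, interior, contig, left, right = self.build_case(gap=3500)
        patched, n = patch_consensus(consensus, [contig])
        assert n == 0 and "N" in patched

    def test_reverse_complement_contig_accepted(self):
        from phageflex.identity import reverse_complement
        consensus, interior, contig, left, right = self.build_case()
        patched, n = patch_consensus(
            consensus, [Contig(reverse_complement(contig.seq), 10.0)])
        assert n == 1 and patched == left + interior + right

    def test_inconsistent_anchor_orientation_rejected(self):
        consensus, interior, contig, left, right = self.build_case()
        # contig with the two flanks in swapped order: no valid patch
        swapped = Contig(right + interior + left, 10.0)
        patched, n = patch_consensus(consensus, [swapped])
        assert n == 0


class TestClosure:
    def island_for(self, truth, ref_loc, module, mean=20.0):
        layout = truth.genome(ref_loc)
        start = int(layout.module_starts[module])
        end = int(layout.module_ends[module])
        return MGIInterval("ref", start, end, max(0, start - 300), end + 300,
                           "high_regime", mean)

    def test_identical_variant_converges_to_reference(self, small_community):
        cfg, references, truth = small_community
        pairs, read_truth = simulate_reads(truth, 0, cfg)
        store = ReadStore(pairs, read_truth)
        mgi = self.island_for(truth, 0, 0)  # own reference: same variant
        result = close_locus(references[0], mgi, store)
        assert result.closed
        window = references[0][result.window_start:
                               result.window_start + len(result.sequence)]
        assert fast_identity(result.sequence, window) >= 0.999

    def test_divergent_variant_reconstructed_to_truth(self, cross_recruitment):
        truth = cross_recruitment["truth"]
        refs = cross_recruitment["references"]
        store = ReadStore(cross_recruitment["pairs"],
                          cross_recruitment["read_truth"])
        mgi = cross_recruitment["mgis"][0]
        layout = truth.genome(1)
        module = int(np.argmin(np.abs(layout.module_starts - mgi.start)))
        result = close_locus(refs[1], mgi, store)
        assert result.closed and result.validated
        expected = truth.query_window(
            0, 1, module, result.window_start,
            min(len(refs[1]), mgi.end + 500))
        assert fast_identity(result.sequence, expected) >= 0.99

    def test_idempotent_on_closed_locus(self, cross_recruitment):
        refs = cross_recruitment["references"]
        store = ReadStore(cross_recruitment["pairs"],
                          cross_recruitment["read_truth"])
        mgi = cross_recruitment["mgis"][0]
        first = close_locus(refs[1], mgi, store)
        again = close_locus(first.sequence, MGIInterval(
            "ref", mgi.start - first.window_start, mgi.end - first.window_start,
            0, len(first.sequence), mgi.rule, mgi.contig_mean_depth), store)
        # the re-closure window may be narrower (patching can lengthen
        # the locus) but its content must be reproduced byte-for-byte
        assert again.closed
        assert again.sequence == first.sequence[
            again.window_start:again.window_start + len(again.sequence)]

    def test_low_depth_non_closure_is_recorded(self, small_community):
        import dataclasses
        cfg, references, truth = small_community
        low_cfg = dataclasses.replace(cfg, depth_per_location=2.0)
        pairs, read_truth = simulate_reads(truth, 0, low_cfg)
        store = ReadStore(pairs, read_truth)
        mgi = self.island_for(truth, 1, 0, mean=2.0)
        result = close_locus(references[1], mgi, store)
        assert not result.closed
        assert result.remaining_n_runs


class TestValidation:
    def test_empty_read_set_is_invalid(self):
        assert validate_by_reassembly([], "ACGT" * 100) is False

    def test_chimeric_reconstruction_rejected(self):
        rng = np.random.default_rng(70)
        hap_a = "".join(rng.choice(list("ACGT"), 1200))
        hap_b = "".join(rng.choice(list("ACGT"), 1200))
        reads = [hap_a[i:i + 100] for i in range(0, 1101, 8)] \
            + [hap_b[i:i + 100] for i in range(0, 1101, 8)]
        chimera = hap_a[:600] + hap_b[600:]
        assert validate_by_reassembly(reads, chimera) is False

    def test_faithful_reconstruction_validates(self):
        rng = np.random.default_rng(71)
        hap = "".join(rng.choice(list("ACGT"), 1200))
        reads = [hap[i:i + 100] for i in range(0, 1101, 8)]
        assert validate_by_reassembly(reads, hap) is True
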