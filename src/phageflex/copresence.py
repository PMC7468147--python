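"""Variant panels and co-presence quantification.

All reconstructed variants of a flexible locus are clustered at the
90% identity distinctness threshold (single linkage on the pairwise
global-identity matrix): members of different clusters share <90%
identity and count as distinct variants.  Each metagenome's reads are
then recruited against the whole panel, every read mapping at most
once to its closest match (highest alignment identity, >=90% cutoff).
A variant is *co-present* in a metagenome when reads cover more than
70% of its positions at >=1x, and its abundance is expressed as its
mean recruitment depth as a percentage of the core-genome mean depth
(the core mean is computed with island regions +- extension excluded,
so flexible loci do not bias the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .alignments import CoverageTrack
from .identity import pairwise_identity, reverse_complement
from .islands import MGIInterval


@dataclass
class VariantPanel:
    locus_id: str
    labels: list[str]  # ordered by first appearance
    sequences: list[str]
    identity: np.ndarray  # pairwise identity matrix
    clusters: list[int]  # cluster index per variant, at the 0.90 threshold

    @property
    def n_clusters(self) -> int:
        return len(set(self.clusters))

    def representatives(self) -> dict[int, str]:
        """Longest member per cluster (ties: first appearance)."""
        best: dict[int, tuple[int, str]] = {}
        for label, seq, cl in zip(self.labels, self.sequences, self.clusters):
            if cl not in best or len(seq) > best[cl][0]:
                best[cl] = (len(seq), label)
        return {cl: label for cl, (_, label) in best.items()}


def build_panel(variants: Sequence[tuple[str, str]], locus_id: str = "locus",
                distinct_threshold: float = 0.90,
                identity_fn: Callable[[str, str], float] = pairwise_identity
                ) -> VariantPanel:
    """Single-linkage clustering of (label, sequence) variants at 90%."""
    if not variants:
        raise ValueError("a panel needs at least one variant sequence")
    labels = [label for label, _ in variants]
    seqs = [seq for _, seq in variants]
    n = len(seqs)
    ident = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = identity_fn(seqs[i], seqs[j])
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if ident[i, j] >= distinct_threshold:
                parent[max(find(i), find(j))] = min(find(i), find(j))
    roots: dict[int, int] = {}
    clusters = []
    for i in range(n):
        root = find(i)
        if root not in roots:
            roots[root] = len(roots)
        clusters.append(roots[root])
    return VariantPanel(locus_id, labels, seqs, ident, clusters)


def recruit_to_panel(reads: Iterable[str],
                     panel_seqs: Sequence[tuple[str, str]],
                     min_identity: float = 0.90
                     ) -> dict[str, CoverageTrack]:
    """Best-single-placement recruitment of reads to labelled sequences.

    Each read is aligned infix-wise (both strands) against every panel
    sequence; it contributes coverage only to the sequence with the
    highest alignment identity (ties: earlier panel order), and only
    if that identity passes the >=90% cutoff.  The panel normally
    includes the core reference as the final entry so core reads are
    not forced onto variants.
    """
    tracks = {label: np.zeros(len(seq), dtype=np.int32)
              for label, seq in panel_seqs}
    for read in reads:
        best = None  # (identity, -panel_index, location)
        for idx, (label, seq) in enumerate(panel_seqs):
            for oriented in (read, reverse_complement(read)):
                result = edlib.align(oriented, seq, mode="HW", task="locations")
                if result["editDistance"] < 0:
                    continue
                identity = 1.0 - result["editDistance"] / len(read)
                key = (identity, -idx)
                if best is None or key > best[0]:
                    loc = result["locations"][0]
                    best = (key, label, (loc[0], loc[1] + 1))
        if best is not None and best[0][0] >= min_identity:
            _, label, (start, end) = best
            tracks[label][max(0, start):end] += 1
    return {label: CoverageTrack(label, depth) for label, depth in tracks.items()}


@dataclass(frozen=True)
class CopresenceRecord:
    locus_id: str
    variant: str
    metagenome: str
    breadth: float
    mean_depth: float
    pct_of_core: float | None  # reported only for co-present variants
    co_present: bool


def core_mean_depth(track: CoverageTrack, mgis: Sequence[MGIInterval] = (),
                    use_extended: bool = True) -> float:
    """Mean depth over the core genome (island intervals excluded)."""
    mask = np.ones(track.length, dtype=bool)
    for mgi in mgis:
        s, e = (mgi.ext_start, mgi.ext_end) if use_extended else (mgi.start, mgi.end)
        mask[s:e] = False
    if not mask.any():
        raise ValueError("no core positions left after excluding islands")
    return float(track.depth[mask].mean())


def copresence_table(variant_tracks: dict[str, CoverageTrack],
                     core_mean: float, locus_id: str, metagenome: str,
                     breadth_threshold: float = 0.70) -> list[CopresenceRecord]:
    """Flag co-present variants (>70% breadth at >=1x) and express their
    mean depth as a percentage of the core mean."""
    if core_mean <= 0:
        raise ValueError("core genome recruited no reads: cannot normalize")
    records = []
    for variant, track in variant_tracks.items():
        breadth = track.breadth
        mean = track.mean_depth
        present = breadth > breadth_threshold
        records.append(CopresenceRecord(
            locus_id=locus_id, variant=variant, metagenome=metagenome,
            breadth=breadth, mean_depth=mean,
            pct_of_core=(100.0 * mean / core_mean) if present else None,
            co_present=present))
    records.sort(key=lambda r: (r.metagenome, -(r.pct_of_core or -1.0)))
    return records


def records_to_frame(records: Sequence[CopresenceRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus": r.locus_id, "variant": r.variant, "metagenome": r.metagenome,
        "breadth": r.breadth, "mean_depth": r.mean_depth,
        "pct_of_core": r.pct_of_core, "co_present": r.co_present,
    } for r in records])
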