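"""Alignment records, identity filtering and per-base coverage tracks.

Read recruitment to a reference is only meaningful above a minimum
nucleotide identity; the pipeline applies an explicit, aligner-
independent >=90% cutoff computed from the NM (mismatch) tag over the
aligned length rather than relying on aligner scoring settings.
Coverage is per-base read depth (the bedtools-genomecov convention:
every aligned base of every record counts, not the template span).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from . import __version__


@dataclass(frozen=True, slots=True)
class AlignmentRecord:
    read_id: str
    contig_id: str
    start: int  # 0-based leftmost
    aligned_length: int
    mismatches: int | None
    template_length: int  # signed TLEN
    mapped: bool
    mate_mapped: bool
    proper_pair: bool
    is_read2: bool = False

    @property
    def end(self) -> int:
        return self.start + self.aligned_length

    @property
    def percent_identity(self) -> float | None:
        if not self.mapped or self.mismatches is None or self.aligned_length == 0:
            return None
        return 1.0 - self.mismatches / self.aligned_length


def read_sam(path, include_unmapped: bool = True,
             include_secondary: bool = False) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM/BAM file.

    Secondary and supplementary alignments are excluded by default
    ("map once" semantics).  Unmapped records are retained (they carry
    mate information needed for gap-closing read recruitment) unless
    ``include_unmapped=False``.
    """
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if (seg.is_secondary or seg.is_supplementary) and not include_secondary:
                continue
            if seg.is_unmapped and not include_unmapped:
                continue
            nm = seg.get_tag("NM") if seg.has_tag("NM") else None
            yield AlignmentRecord(
                read_id=seg.query_name,
                contig_id=seg.reference_name or "",
                start=seg.reference_start if seg.reference_start is not None else -1,
                aligned_length=seg.query_alignment_length if not seg.is_unmapped else 0,
                mismatches=nm,
                template_length=seg.template_length,
                mapped=not seg.is_unmapped,
                mate_mapped=not seg.mate_is_unmapped if seg.is_paired else False,
                proper_pair=seg.is_proper_pair,
                is_read2=seg.is_read2,
            )


def filter_by_identity(records: Iterable[AlignmentRecord],
                       min_identity: float = 0.90,
                       on_missing: str = "skip") -> Iterator[AlignmentRecord]:
    """Keep mapped records with percent identity >= min_identity.

    Unmapped records are dropped.  Records without mismatch information
    are skipped with a warning (``on_missing="skip"``, default) or
    raise (``on_missing="error"``).
    """
    warned = False
    for rec in records:
        if not rec.mapped:
            continue
        identity = rec.percent_identity
        if identity is None:
            if on_missing == "error":
                raise ValueError(f"record {rec.read_id} lacks a mismatch count")
            if not warned:
                warnings.warn("records without mismatch counts were skipped")
                warned = True
            continue
        if identity >= min_identity:
            yield rec


@dataclass
class CoverageTrack:
    """Per-base read depth along one reference contig."""

    contig_id: str
    depth: np.ndarray  # non-negative ints, len == contig length

    @property
    def length(self) -> int:
        return int(self.depth.size)

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if self.depth.size else 0.0

    @property
    def breadth(self) -> float:
        return float((self.depth > 0).mean()) if self.depth.size else 0.0

    def to_bedgraph(self, path, seed: int | None = None) -> None:
        """4-column bedGraph (0-based half-open), runs collapsed exactly."""
        with open(path, "w") as fh:
            fh.write(f"# phageflex {__version__} coverage"
                     + (f" seed={seed}" if seed is not None else "") + "\n")
            depth = self.depth
            if depth.size:
                boundaries = np.flatnonzero(np.diff(depth)) + 1
                starts = np.concatenate([[0], boundaries])
                ends = np.concatenate([boundaries, [depth.size]])
                for s, e in zip(starts, ends):
                    fh.write(f"{self.contig_id}\t{s}\t{e}\t{int(depth[s])}\n")

    @classmethod
    def from_bedgraph(cls, path, contig_id: str | None = None,
                      length: int | None = None) -> "CoverageTrack":
        rows = []
        name = contig_id
        with open(path) as fh:
            for line in fh:
                if line.startswith(("#", "track", "browser")) or not line.strip():
                    continue
                chrom, start, end, value = line.split()[:4]
                if name is None:
                    name = chrom
                if chrom != name:
                    continue
                rows.append((int(start), int(end), int(float(value))))
        total = length or (max(e for _, e, _ in rows) if rows else 0)
        depth = np.zeros(total, dtype=np.int32)
        for s, e, v in rows:
            depth[s:e] = v
        return cls(name or "", depth)


def compute_coverage(records: Iterable[AlignmentRecord], contig_id: str,
                     contig_length: int) -> CoverageTrack:
    """Per-base depth: depth[i] = number of aligned spans covering i."""
    delta = np.zeros(contig_length + 1, dtype=np.int64)
    for rec in records:
        if not rec.mapped or rec.contig_id != contig_id:
            continue
        if rec.start < 0 or rec.end > contig_length:
            raise ValueError(
                f"alignment {rec.read_id} [{rec.start},{rec.end}) exceeds "
                f"contig {contig_id} of length {contig_length}")
        delta[rec.start] += 1
        delta[rec.end] -= 1
    return CoverageTrack(contig_id, np.cumsum(delta[:-1]).astype(np.int32))


def detect_coverage_spikes(track: CoverageTrack, spike_factor: float = 10.0,
                           min_len: int = 100) -> list[tuple[int, int]]:
    """Maximal runs of >= min_len positions above spike_factor x mean depth.

    A contig with any spike is excluded from island detection (spikes
    indicate error-prone reads or unresolved repeats, which would both
    depress the mean-relative dropout threshold and fake islands).
    """
    mean = track.mean_depth
    if mean <= 0:
        return []
    mask = track.depth > spike_factor * mean
    return [(s, e) for s, e in _bool_runs(mask) if e - s >= min_len]


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as 0-based half-open intervals."""
    padded = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))
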