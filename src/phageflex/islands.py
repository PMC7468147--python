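"""Metagenomic-island (MGI) detection on coverage tracks.

An MGI is a region of a reference genome that sharply under-recruits
reads relative to the rest of the genome.  Two coverage regimes use
different rules:

* high regime (contig mean depth >= 5x): coverage below 25% of the
  contig mean over a run of >= 100 bp;
* low regime (mean in [2, 5)): coverage exactly zero over >= 200 bp.

Contigs with breadth < 70% or mean depth < 2x are excluded.  Detected
intervals are extended 300 bp on each side (clamped to the contig) for
gene identification only; all statistics are computed on the raw
intervals.  Boundary conventions: ">=5x" inclusive, "<25%" strict,
length thresholds inclusive.  The contig mean includes island
positions themselves (a single global mean per contig); nearby
dropouts separated by above-threshold positions are not merged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .alignments import CoverageTrack, _bool_runs


class Eligibility(enum.Enum):
    EXCLUDED_LOW_BREADTH = "excluded_low_breadth"
    EXCLUDED_LOW_DEPTH = "excluded_low_depth"
    LOW_REGIME = "low_regime"
    HIGH_REGIME = "high_regime"


@dataclass(frozen=True)
class DetectionConfig:
    high_regime_min_mean: float = 5.0
    low_regime_min_mean: float = 2.0
    frac_of_mean: float = 0.25
    min_len_high: int = 100
    min_len_low: int = 200
    extension: int = 300
    min_contig_breadth: float = 0.70

    def validate(self) -> None:
        values = (self.high_regime_min_mean, self.low_regime_min_mean,
                  self.frac_of_mean, self.min_len_high, self.min_len_low,
                  self.extension, self.min_contig_breadth)
        if any(v <= 0 for v in values[:-1]) or self.extension < 0:
            raise ValueError("detection thresholds must be positive")
        if not self.frac_of_mean < 1:
            raise ValueError("frac_of_mean must be < 1")


@dataclass(frozen=True)
class MGIInterval:
    contig_id: str
    start: int  # raw coordinates, 0-based half-open
    end: int
    ext_start: int  # extended, clamped to the contig
    ext_end: int
    rule: str  # "high_regime" | "low_regime"
    contig_mean_depth: float

    @property
    def length(self) -> int:
        return self.end - self.start


def eligible_for_detection(track: CoverageTrack,
                           config: DetectionConfig = DetectionConfig()) -> Eligibility:
    if track.length == 0:
        raise ValueError(f"contig {track.contig_id} has zero length")
    if track.breadth < config.min_contig_breadth:
        return Eligibility.EXCLUDED_LOW_BREADTH
    mean = track.mean_depth
    if mean < config.low_regime_min_mean:
        return Eligibility.EXCLUDED_LOW_DEPTH
    if mean < config.high_regime_min_mean:
        return Eligibility.LOW_REGIME
    return Eligibility.HIGH_REGIME


def detect_mgis(track: CoverageTrack,
                config: DetectionConfig = DetectionConfig()) -> list[MGIInterval]:
    """Maximal qualifying dropout runs on an eligible track, sorted."""
    config.validate()
    regime = eligible_for_detection(track, config)
    if regime in (Eligibility.EXCLUDED_LOW_BREADTH, Eligibility.EXCLUDED_LOW_DEPTH):
        return []
    mean = track.mean_depth
    if regime is Eligibility.HIGH_REGIME:
        mask = track.depth < config.frac_of_mean * mean
        min_len = config.min_len_high
        rule = "high_regime"
    else:
        mask = track.depth == 0
        min_len = config.min_len_low
        rule = "low_regime"
    out = []
    for start, end in _bool_runs(mask):
        if end - start >= min_len:
            out.append(MGIInterval(
                contig_id=track.contig_id, start=start, end=end,
                ext_start=max(0, start - config.extension),
                ext_end=min(track.length, end + config.extension),
                rule=rule, contig_mean_depth=mean))
    return out


def summarize_mgis(mgis: list[MGIInterval],
                   reference_lengths: dict[str, int]) -> dict:
    """Count/length summary plus MGI bp per kb of reference.

    ``reference_lengths`` maps every screened contig (with or without
    islands) to its length; the fraction of genomes carrying at least
    one island and the bp-per-kb statistic use all of them.
    """
    lengths = np.array([m.length for m in mgis], dtype=float)
    total_ref = sum(reference_lengths.values())
    with_mgi = {m.contig_id for m in mgis}
    summary = {
        "count": len(mgis),
        "total_mgi_bp": int(lengths.sum()) if len(mgis) else 0,
        "mean_length": float(lengths.mean()) if len(mgis) else None,
        "min_length": int(lengths.min()) if len(mgis) else None,
        "max_length": int(lengths.max()) if len(mgis) else None,
        "mgi_bp_per_kb": (1000.0 * lengths.sum() / total_ref) if total_ref else None,
        "frac_genomes_with_mgi": (len(with_mgi & set(reference_lengths)) /
                                  len(reference_lengths)) if reference_lengths else None,
    }
    return summary


def read_bed(path, contig_lengths: dict[str, int] | None = None,
             extension: int = 300) -> list[MGIInterval]:
    """Read raw-interval BED written by :func:`write_bed` back into MGIs."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            mean = float(fields[4]) if len(fields) > 4 else 0.0
            rule = fields[6] if len(fields) > 6 else "high_regime"
            length = (contig_lengths or {}).get(contig)
            out.append(MGIInterval(
                contig_id=contig, start=start, end=end,
                ext_start=max(0, start - extension),
                ext_end=min(length, end + extension) if length else end + extension,
                rule=rule, contig_mean_depth=mean))
    return out


def write_bed(mgis: list[MGIInterval], path, extended: bool = False,
              seed: int | None = None) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# phageflex {__version__} mgi "
                 f"{'extended' if extended else 'raw'}"
                 + (f" seed={seed}" if seed is not None else "") + "\n")
        for i, m in enumerate(mgis):
            s, e = (m.ext_start, m.ext_end) if extended else (m.start, m.end)
            fh.write(f"{m.contig_id}\t{s}\t{e}\tMGI_{i:04d}\t"
                     f"{m.contig_mean_depth:.2f}\t.\t{m.rule}\n")
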