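"""Deterministic ungapped seed-and-extend read mapper.

Used inside the gap-closing loop, where reads must be re-mapped to an
evolving consensus that may contain stretches of ``N``.  Exact k-mer
seeds (k=21 by default) vote for a diagonal; the best diagonal is
verified by an ungapped comparison.  ``N`` positions in the target are
uninformative rather than mismatching, so reads anchored in known
sequence can extend into an N-run and fill it -- the "iterative
read-fill" behaviour gap closing depends on.  Short reads against a
locally correct consensus do not need gapped alignment; reads from a
diverged variant are meant to fail the identity cutoff, which is the
signal the pipeline uses.

Fully deterministic: ties are broken by leftmost position, then
forward strand.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .identity import reverse_complement

_N = ord("N")


@dataclass(frozen=True, slots=True)
class Placement:
    start: int  # 0-based on the target (start of the aligned part)
    strand: int  # +1 forward, -1 reverse
    mismatches: int
    compared: int  # non-N target positions compared
    query_start: int = 0  # offset of the aligned part in the oriented read
    query_length: int = 0  # aligned length (reads clipped at target ends)

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.compared if self.compared else 0.0


class ReadMapper:
    def __init__(self, target: str, k: int = 21, min_identity: float = 0.90,
                 min_compared: int = 30, max_seed_hits: int = 50):
        self.target = target
        self.k = k
        self.min_identity = min_identity
        self.min_compared = min_compared
        self._bytes = np.frombuffer(target.encode(), dtype=np.uint8)
        self._index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(target) - k + 1):
            kmer = target[i:i + k]
            if "N" not in kmer:
                hits = self._index[kmer]
                if len(hits) < max_seed_hits:
                    hits.append(i)

    def _best_diagonal(self, read: str) -> tuple[int, int] | None:
        k = self.k
        votes: Counter[int] = Counter()
        step = max(1, (len(read) - k) // 8) if len(read) > k else 1
        offsets = list(range(0, max(1, len(read) - k + 1), step))
        if offsets and offsets[-1] != len(read) - k and len(read) >= k:
            offsets.append(len(read) - k)
        for off in offsets:
            for pos in self._index.get(read[off:off + k], ()):
                votes[pos - off] += 1
        if not votes:
            return None
        best = max(votes.items(), key=lambda item: (item[1], -item[0]))
        return best[0], best[1]

    def _evaluate(self, read: str, start: int) -> Placement | None:
        tgt = self._bytes
        L = len(read)
        if start < 0 or start + L > tgt.size:
            # clip to target bounds; at least half the read must be on-target
            lo = max(start, 0)
            hi = min(start + L, tgt.size)
            if hi - lo < max(self.min_compared, L // 2):
                return None
            window = tgt[lo:hi]
            rbytes = np.frombuffer(read.encode(), dtype=np.uint8)[lo - start:hi - start]
            offset, qstart = lo, lo - start
        else:
            window = tgt[start:start + L]
            rbytes = np.frombuffer(read.encode(), dtype=np.uint8)
            offset, qstart = start, 0
        informative = window != _N
        compared = int(informative.sum())
        if compared < self.min_compared:
            return None
        mismatches = int(np.count_nonzero((rbytes != window) & informative))
        return Placement(offset, +1, mismatches, compared, qstart, int(window.size))

    def map_read(self, read: str) -> Placement | None:
        """Best placement of the read on either strand, or None."""
        best: Placement | None = None
        best_votes = -1
        for strand, seq in ((+1, read), (-1, reverse_complement(read))):
            hit = self._best_diagonal(seq)
            if hit is None:
                continue
            start, votes = hit
            placement = self._evaluate(seq, start)
            if placement is None or placement.identity < self.min_identity:
                continue
            placement = Placement(placement.start, strand,
                                  placement.mismatches, placement.compared,
                                  placement.query_start, placement.query_length)
            key = (votes, -placement.mismatches, -placement.start, strand)
            if best is None or key > (best_votes, -best.mismatches, -best.start, best.strand):
                best, best_votes = placement, votes
        return best

    def oriented(self, read: str, placement: Placement) -> str:
        return read if placement.strand > 0 else reverse_complement(read)
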