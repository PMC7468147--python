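"""A small de Bruijn graph assembler for targeted local assembly.

Re-specifies the assembly step of the gap-closing protocol by its
declared contract: k-mers of 23 or 33, k-mers seen fewer than
``min_kmer_count`` times discarded (this removes almost all sequencing
errors at the depths of interest), simple bubbles whose arms diverge
over at most ``bubble_size`` bp popped in favour of the
higher-coverage arm, and contigs reported as maximal non-branching
paths.  Both strands of every read are inserted, so each contig arises
twice; duplicates are collapsed to the lexicographically smaller of a
contig and its reverse complement.  All tie-breaks are lexicographic,
making the output independent of read order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .identity import reverse_complement

_BASES = "ACGT"


@dataclass(frozen=True)
class AssemblyParams:
    kmer: int = 23  # 23 or 33
    bubble_size: int = 2000
    min_kmer_count: int = 2
    tip_len: int = 100  # dead-end branches up to this length are clipped
    max_patch_gap: int = 3000
    max_iterations: int = 10
    flank: int = 500
    anchor_len: int = 100
    anchor_min_identity: float = 0.95
    anchor_min_len: int = 50

    def validate(self, read_length: int | None = None) -> None:
        if self.kmer not in (23, 33):
            raise ValueError("kmer must be 23 or 33")
        if read_length is not None and self.flank < read_length:
            raise ValueError("flank must be >= read length")


@dataclass
class Contig:
    seq: str
    coverage: float  # mean count of constituent k-mers

    def __len__(self) -> int:
        return len(self.seq)


def _count_kmers(reads: Iterable[str], k: int) -> Counter:
    counts: Counter[str] = Counter()
    for read in reads:
        for seq in (read, reverse_complement(read)):
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" not in kmer:
                    counts[kmer] += 1
    return counts


class _Graph:
    def __init__(self, counts: Counter):
        self.counts = counts

    def succs(self, km: str) -> list[str]:
        suffix = km[1:]
        return [suffix + b for b in _BASES if suffix + b in self.counts]

    def preds(self, km: str) -> list[str]:
        prefix = km[:-1]
        return [b + prefix for b in _BASES if b + prefix in self.counts]


def _walk_arm(graph: _Graph, start: str, limit: int) -> tuple[str | None, list[str]]:
    """Follow unique successors from `start`; stop at a merge node or limit."""
    path = [start]
    cur = start
    for _ in range(limit):
        if len(graph.preds(cur)) > 1 and len(path) > 1:
            return cur, path[:-1]
        nxt = graph.succs(cur)
        if len(nxt) != 1:
            return None, path
        cur = nxt[0]
        path.append(cur)
    if len(graph.preds(cur)) > 1:
        return cur, path[:-1]
    return None, path


def _walk_tip(graph: _Graph, start: str, limit: int) -> list[str] | None:
    """Unique-successor path from `start`; the path if it dead-ends
    within `limit` k-mers, else None."""
    path = [start]
    cur = start
    for _ in range(limit):
        succs = graph.succs(cur)
        if not succs:
            return path
        if len(succs) != 1 or len(graph.preds(succs[0])) != 1:
            return None  # rejoins the graph: not a tip
        cur = succs[0]
        path.append(cur)
    return None


def _clip_tips_once(graph: _Graph, tip_len: int) -> bool:
    """Remove short, low-coverage dead-end branches (error spurs).

    At each fork, an arm that dead-ends within `tip_len` k-mers is
    clipped when a sibling arm continues, or when it carries less than
    half the sibling's mean coverage.
    """
    changed = False
    for km in sorted(graph.counts):
        if km not in graph.counts:
            continue
        succs = graph.succs(km)
        if len(succs) < 2:
            continue
        arms = [(s, _walk_tip(graph, s, tip_len)) for s in sorted(succs)]
        tips = [(s, p) for s, p in arms if p is not None]
        through = [s for s, p in arms if p is None]
        for s, path in tips:
            if not all(x in graph.counts for x in path):
                continue
            cov = sum(graph.counts[x] for x in path) / len(path)
            sib_cov = max((graph.counts[t] for t in through), default=0)
            other_tips = [(s2, p2) for s2, p2 in tips if s2 != s]
            if through:
                drop = cov < sib_cov  # spurs run below the through-arm
            elif other_tips:
                best_cov = max(sum(graph.counts[x] for x in p2) / len(p2)
                               for _, p2 in other_tips)
                drop = cov < 0.5 * best_cov
            else:
                drop = False
            if drop:
                for x in path:
                    graph.counts.pop(x, None)
                    graph.counts.pop(reverse_complement(x), None)
                changed = True
    return changed


def _prune_weak_branches_once(graph: _Graph) -> bool:
    """Drop fork arms whose entry k-mer carries <=25% of the strongest
    sibling's count.

    Interleaved error bubbles can deadlock pairwise bubble popping (each
    arm's walk stops at the other's fork); relative pruning resolves
    them the way production assemblers do.  Balanced arms -- genuine
    haplotypes at comparable coverage -- are never pruned.
    """
    changed = False
    for km in sorted(graph.counts):
        if km not in graph.counts:
            continue
        succs = sorted(graph.succs(km))
        if len(succs) < 2:
            continue
        cmax = max(graph.counts[s] for s in succs)
        for s in succs:
            count = graph.counts.get(s, 0)
            if 0 < count < cmax and count <= 0.25 * cmax:
                graph.counts.pop(s, None)
                graph.counts.pop(reverse_complement(s), None)
                changed = True
    return changed


def _pop_bubbles_once(graph: _Graph, bubble_size: int) -> bool:
    changed = False
    for km in sorted(graph.counts):
        if km not in graph.counts:
            continue
        succs = sorted(graph.succs(km))
        if len(succs) < 2:
            continue
        arms = [(s, *_walk_arm(graph, s, bubble_size)) for s in succs]
        # pop the weaker of any two arms converging on the same node;
        # ties keep the lexicographically smaller entry arm
        for i in range(len(arms)):
            for j in range(i + 1, len(arms)):
                _, end_a, path_a = arms[i]
                _, end_b, path_b = arms[j]
                if end_a is None or end_a != end_b:
                    continue
                if not all(x in graph.counts for x in path_a + path_b):
                    continue
                cov_a = sum(graph.counts[x] for x in path_a) / max(len(path_a), 1)
                cov_b = sum(graph.counts[x] for x in path_b) / max(len(path_b), 1)
                drop = path_b if cov_a >= cov_b else path_a
                for x in drop:
                    graph.counts.pop(x, None)
                    graph.counts.pop(reverse_complement(x), None)
                changed = True
    return changed


def _unitigs(graph: _Graph) -> list[tuple[str, float]]:
    out = []
    visited: set[str] = set()

    def is_path_start(km: str) -> bool:
        preds = graph.preds(km)
        if len(preds) != 1:
            return True
        return len(graph.succs(preds[0])) != 1

    for km in sorted(graph.counts):
        if km in visited or not is_path_start(km):
            continue
        path = [km]
        visited.add(km)
        cur = km
        while True:
            succs = graph.succs(cur)
            if len(succs) != 1:
                break
            nxt = succs[0]
            if len(graph.preds(nxt)) != 1 or nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        seq = path[0] + "".join(p[-1] for p in path[1:])
        cov = sum(graph.counts[p] for p in path) / len(path)
        out.append((seq, cov))
    # isolated cycles (rare): emit each once
    for km in sorted(graph.counts):
        if km in visited:
            continue
        path = [km]
        visited.add(km)
        cur = km
        while True:
            succs = graph.succs(cur)
            if len(succs) != 1:
                break
            nxt = succs[0]
            if nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        seq = path[0] + "".join(p[-1] for p in path[1:])
        cov = sum(graph.counts[p] for p in path) / len(path)
        out.append((seq, cov))
    return out


def assemble_local(reads: Sequence[str],
                   params: AssemblyParams = AssemblyParams()) -> list[Contig]:
    """Assemble reads into contigs; empty input or over-filtering gives []."""
    if not reads:
        return []
    counts = _count_kmers(reads, params.kmer)
    counts = Counter({km: c for km, c in counts.items()
                      if c >= params.min_kmer_count})
    if not counts:
        return []
    graph = _Graph(counts)
    # interleave spur clipping and bubble popping until the graph is
    # stable: popping one artifact frequently exposes another
    # relative branch pruning only when the absolute count floor is off:
    # with the count-2 floor most error k-mers are already gone and
    # pruning could cut genuine low-coverage path at dips
    prune = params.min_kmer_count < 2
    for _ in range(10):
        tips_changed = _clip_tips_once(graph, params.tip_len)
        pruned = prune and _prune_weak_branches_once(graph)
        bubbles_changed = _pop_bubbles_once(graph, params.bubble_size)
        if not (tips_changed or pruned or bubbles_changed):
            break
    seen: set[str] = set()
    contigs = []
    for seq, cov in _unitigs(graph):
        canonical = min(seq, reverse_complement(seq))
        if canonical in seen:
            continue
        seen.add(canonical)
        contigs.append(Contig(canonical, cov))
    contigs.sort(key=lambda c: (-len(c.seq), c.seq))
    return contigs
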