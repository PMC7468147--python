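"""Targeted gap closing: reconstruct the sequence occupying an island.

The flexible sequence present in a query metagenome at a detected
island is rebuilt by a reference-guided loop that mirrors the
six-step closure protocol:

1. map the metagenome's reads to the locus window (island +- flank);
2. call a plurality ("0% majority") consensus, writing ``N`` where no
   read covers a position -- reads from a diverged variant do not map,
   so the island interior turns into an N-run;
3. recruit the mapped reads plus their mates (mates reach ~one insert
   length beyond the mapped frontier) and assemble them de novo with a
   small de Bruijn assembler;
4. patch each N-run whose two non-N flanks both match the ends of one
   assembled contig (>=95% identity anchors), replacing the run by the
   contig interior (gap capped at 3 kb);
5. iterate: remapping to the patched consensus recruits deeper into
   the locus, and reads anchored next to an N-run extend into it
   ("read-fill"), until no N remains or no progress is made;
6. validate the closed locus by reassembling the recruited reads with
   the reference removed and checking a contig reproduces it.

Non-closure is a recorded outcome, not an error: at low depth the
assembler cannot pass the k-mer count filter and N-runs persist.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib
import numpy as np

from .alignments import AlignmentRecord, _bool_runs
from .assemble import AssemblyParams, Contig, assemble_local
from .identity import reverse_complement
from .islands import MGIInterval
from .mapping import Placement, ReadMapper

_BASE_ORDER = "ACGT"  # plurality ties resolve in this priority order
_BASE_IDX = {b: i for i, b in enumerate(_BASE_ORDER)}


@dataclass
class Pileup:
    """Per-position base counts over a window, plus the window reference."""

    counts: np.ndarray  # shape (4, L), rows in A,C,G,T order
    reference: str

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def pileup_from_placements(window_len: int,
                           placements: list[tuple[Placement, str]],
                           reference: str) -> Pileup:
    """Accumulate oriented read sequences into per-position base counts."""
    counts = np.zeros((4, window_len), dtype=np.int32)
    for placement, oriented in placements:
        start = placement.start
        qstart = placement.query_start
        qlen = placement.query_length or len(oriented)
        for offset, base in enumerate(oriented[qstart:qstart + qlen]):
            pos = start + offset
            if 0 <= pos < window_len and base in _BASE_IDX:
                counts[_BASE_IDX[base], pos] += 1
    return Pileup(counts, reference)


def call_consensus(pileup: Pileup, mode: str = "reference_fill") -> str:
    """Plurality consensus ("0% majority": the most counted base wins
    regardless of its fraction).  Zero-depth positions take the
    reference base (``reference_fill``) or ``N`` (``n_fill``).
    Plurality ties resolve by fixed priority A>C>G>T.
    """
    if mode not in ("reference_fill", "n_fill"):
        raise ValueError(f"unknown consensus mode: {mode}")
    counts = pileup.counts
    best = np.argmax(counts, axis=0)  # argmax takes the first max: A>C>G>T
    depth = counts.sum(axis=0)
    out = [_BASE_ORDER[b] for b in best]
    for pos in np.flatnonzero(depth == 0):
        out[pos] = pileup.reference[pos] if mode == "reference_fill" else "N"
    return "".join(out)


def recruit_gap_reads(records: list[AlignmentRecord], mgi: MGIInterval,
                      flank: int = 500) -> set[str]:
    """Read ids anchored within `flank` of the island, plus their mates.

    A read whose mapped span overlaps [start-flank, end+flank) anchors
    its template; both mates of an anchored template are recruited,
    including mates that are themselves unmapped (they often originate
    from the unknown island sequence).  Returns the (possibly empty)
    set of read ids; an empty pool marks the locus unreconstructable.
    """
    lo, hi = mgi.start - flank, mgi.end + flank
    ids = set()
    for rec in records:
        if rec.mapped and rec.contig_id == mgi.contig_id \
                and rec.start < hi and rec.end > lo:
            ids.add(rec.read_id)
    return ids


@dataclass
class GapClosureResult:
    locus_id: str
    metagenome: str
    sequence: str
    remaining_n_runs: list[tuple[int, int]]
    iterations: int
    validated: bool
    window_start: int = 0  # reference coordinate of the window's first base
    recruited_reads: int = 0

    @property
    def closed(self) -> bool:
        return not self.remaining_n_runs


def _locate_anchor(anchor: str, contig: str, min_identity: float
                   ) -> tuple[int, int, float] | None:
    """Best infix match of `anchor` in `contig`: (start, end, identity)."""
    result = edlib.align(anchor, contig, mode="HW", task="locations")
    if result["editDistance"] < 0:
        return None
    identity = 1.0 - result["editDistance"] / len(anchor)
    if identity < min_identity:
        return None
    start, end = result["locations"][0]
    return start, end + 1, identity


def _n_runs(seq: str) -> list[tuple[int, int]]:
    mask = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")
    return _bool_runs(mask)


def _anchor_window(seq: str, pos: int, length: int, left: bool) -> str:
    """Up to `length` bp of non-N sequence adjacent to position `pos`."""
    if left:
        chunk = seq[max(0, pos - length):pos]
        cut = chunk.rfind("N")
        return chunk[cut + 1:]
    chunk = seq[pos:pos + length]
    cut = chunk.find("N")
    return chunk if cut < 0 else chunk[:cut]


def patch_consensus(consensus: str, contigs: list[Contig],
                    params: AssemblyParams = AssemblyParams()) -> tuple[str, int]:
    """Replace N-runs bracketed by contig-matching flank anchors.

    For each N-run, the non-N anchors on both sides (up to
    ``anchor_len`` bp, at least ``anchor_min_len``) are searched in
    every contig on both strands; a contig matching both anchors at
    >=``anchor_min_identity`` in consistent orientation and order, with
    an implied gap of at most ``max_patch_gap``, replaces the run with
    its interior.  The best candidate wins by summed anchor identity,
    ties by longer contig.  Returns (new sequence, number patched).
    """
    runs = _n_runs(consensus)
    if not runs or not contigs:
        return consensus, 0
    pieces: list[str] = []
    cursor = 0
    n_patched = 0
    for run_start, run_end in runs:
        left = _anchor_window(consensus, run_start, params.anchor_len, left=True)
        right = _anchor_window(consensus, run_end, params.anchor_len, left=False)
        replacement = None
        if len(left) >= params.anchor_min_len and len(right) >= params.anchor_min_len:
            best_key = None
            for contig in contigs:
                for seq in (contig.seq, reverse_complement(contig.seq)):
                    hit_l = _locate_anchor(left, seq, params.anchor_min_identity)
                    hit_r = _locate_anchor(right, seq, params.anchor_min_identity)
                    if hit_l is None or hit_r is None:
                        continue
                    if hit_l[1] > hit_r[0]:
                        continue  # inconsistent order/orientation: no patch
                    interior = seq[hit_l[1]:hit_r[0]]
                    if len(interior) > params.max_patch_gap:
                        continue
                    key = (hit_l[2] + hit_r[2], len(seq), seq)
                    if best_key is None or key > best_key:
                        best_key = key
                        replacement = interior
        pieces.append(consensus[cursor:run_start])
        if replacement is not None:
            pieces.append(replacement)
            n_patched += 1
        else:
            pieces.append(consensus[run_start:run_end])
        cursor = run_end
    pieces.append(consensus[cursor:])
    return "".join(pieces), n_patched


class ReadStore:
    """Paired read sequences for one metagenome, keyed by read id."""

    def __init__(self, pairs, records=None):
        # pairs: list[(seq1, seq2)] with parallel truth records, or
        # dict[id] -> (seq1, seq2)
        if records is not None:
            self._pairs = {rec.read_id: pair for pair, rec in zip(pairs, records)}
        else:
            self._pairs = dict(pairs)

    @classmethod
    def from_fastq(cls, path1, path2) -> "ReadStore":
        from Bio import SeqIO

        def strip(name: str) -> str:
            return name[:-2] if name.endswith(("/1", "/2")) else name

        first = {strip(r.id): str(r.seq) for r in SeqIO.parse(str(path1), "fastq")}
        second = {strip(r.id): str(r.seq) for r in SeqIO.parse(str(path2), "fastq")}
        return cls({rid: (seq, second[rid]) for rid, seq in first.items()
                    if rid in second})

    def __len__(self) -> int:
        return len(self._pairs)

    def items(self):
        return self._pairs.items()

    def sequences(self, ids=None) -> list[str]:
        if ids is None:
            out = []
            for seq1, seq2 in self._pairs.values():
                out.extend((seq1, seq2))
            return out
        out = []
        for rid in sorted(ids):
            pair = self._pairs.get(rid)
            if pair:
                out.extend(pair)
        return out


def _map_store(mapper: ReadMapper, store: ReadStore
               ) -> tuple[list[tuple[Placement, str]], set[str]]:
    placements = []
    mapped_ids = set()
    for rid, (seq1, seq2) in store.items():
        for seq in (seq1, seq2):
            hit = mapper.map_read(seq)
            if hit is not None:
                placements.append((hit, mapper.oriented(seq, hit)))
                mapped_ids.add(rid)
    return placements, mapped_ids


def close_locus(reference: str, mgi: MGIInterval, store: ReadStore,
                params: AssemblyParams = AssemblyParams(),
                locus_id: str = "locus", metagenome: str = "query",
                mapper_k: int = 21, min_identity: float = 0.90
                ) -> GapClosureResult:
    """Run the map/consensus/assemble/patch loop for one island."""
    window_start = max(0, mgi.start - params.flank)
    window_end = min(len(reference), mgi.end + params.flank)
    consensus = reference[window_start:window_end]
    prev_n = None
    iterations = 0
    pool_ids: set[str] = set()
    for iterations in range(1, params.max_iterations + 1):
        mapper = ReadMapper(consensus, k=mapper_k, min_identity=min_identity)
        placements, mapped_ids = _map_store(mapper, store)
        pool_ids |= mapped_ids
        pileup = pileup_from_placements(len(consensus), placements, consensus)
        consensus = call_consensus(pileup, mode="n_fill")
        pool_reads = store.sequences(pool_ids)
        contigs = assemble_local(pool_reads, params)
        consensus, _ = patch_consensus(consensus, contigs, params)
        if "N" in consensus:
            # count-1 fallback assembly (with relative branch pruning)
            # spans coverage dips the count-2 floor breaks at
            sensitive = assemble_local(pool_reads,
                                       replace(params, min_kmer_count=1))
            consensus, _ = patch_consensus(consensus, sensitive, params)
        n_count = consensus.count("N")
        if n_count == 0:
            break
        if prev_n is not None and n_count >= prev_n:
            break
        prev_n = n_count
    # zero-coverage overhangs at the window boundaries are outside the
    # locus proper; trim them rather than reporting them as open gaps
    trimmed = consensus.strip("N")
    offset = consensus.find(trimmed) if trimmed else 0
    window_start += offset
    consensus = trimmed
    runs = _n_runs(consensus)
    validated = False
    if not runs and pool_ids:
        validated = validate_by_reassembly(store.sequences(pool_ids),
                                           consensus, params)
    return GapClosureResult(
        locus_id=locus_id, metagenome=metagenome, sequence=consensus,
        remaining_n_runs=runs, iterations=iterations, validated=validated,
        window_start=window_start, recruited_reads=len(pool_ids))


def iterate_closure(reference: str, mgis: list[MGIInterval], store: ReadStore,
                    params: AssemblyParams = AssemblyParams(),
                    metagenome: str = "query") -> list[GapClosureResult]:
    """Close every detected island of one reference against one metagenome."""
    results = []
    for i, mgi in enumerate(mgis):
        results.append(close_locus(
            reference, mgi, store, params,
            locus_id=f"{mgi.contig_id}_mgi{i:03d}", metagenome=metagenome))
    return results


def validate_by_reassembly(read_seqs: list[str], sequence: str,
                           params: AssemblyParams = AssemblyParams(),
                           min_identity: float = 0.99,
                           min_span: float = 0.95) -> bool:
    """Reference-free reassembly check of a reconstructed locus.

    The recruited reads are assembled de novo (no reference involved);
    the locus is validated when some contig reproduces >=``min_span``
    of it at >=``min_identity``.  The central ``min_span`` fraction of
    the locus is aligned infix-wise against each contig on both
    strands.

    A small parameter ladder is swept (mirroring the protocol's own
    k-value sweep): the standard count-2 assembly first, then a
    count-1 assembly, which rescues loci at moderate depth where the
    count-2 floor fragments contigs at single-coverage dips.  A
    chimeric reconstruction matches no contig under either setting.
    """
    if not read_seqs or not sequence:
        return False
    trim = int(len(sequence) * (1.0 - min_span) / 2.0)
    core = sequence[trim:len(sequence) - trim]
    if not core:
        return False
    tried = []
    for min_count in (params.min_kmer_count, 1):
        if min_count in tried:
            continue
        tried.append(min_count)
        contigs = assemble_local(read_seqs, replace(params, min_kmer_count=min_count))
        for contig in contigs:
            if len(contig.seq) < len(core):
                continue
            for seq in (contig.seq, reverse_complement(contig.seq)):
                result = edlib.align(core, seq, mode="HW", task="distance")
                if result["editDistance"] < 0:
                    continue
                if 1.0 - result["editDistance"] / len(core) >= min_identity:
                    return True
    return False
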