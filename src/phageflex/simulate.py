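"""Synthetic phage pan-genome communities with full ground truth.

The generator emulates the statistical structure a metagenomic-island
(MGI) analysis assumes: a set of geographic locations each dominated by
a phage whose *core* genome is near-identical everywhere (~99%
nucleotide identity, substitution-only drift) while a handful of
*flexible modules* -- disjoint intervals of the genome -- are occupied
by interchangeable homologous variants.  Variants of one module share
40-90% global-alignment identity and are therefore "distinct" under
the <90% rule; a module may instead be simulated as a clean
presence/absence (deletion) polymorphism.  Paired-end reads (100 bp,
~400 bp inserts) are sampled per location at a configurable depth with
per-module mixture proportions over the variant pool, and every read
is traceable to its (location, module, variant) origin.

Because the module architecture is shared and core drift is
substitution-only, coordinates transfer exactly between any two
community genomes.  :func:`emit_ideal_alignments` exploits this to
produce the alignments a >=90%-identity read recruiter would report,
without an external aligner: reads are placed at their true
coordinates with exact mismatch counts, reads from a foreign variant
fail the identity cutoff and are reported unmapped, and pairs whose
template spans a deletion come out with an oversized template length
and a discordant flag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .identity import fast_identity, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Empirical per-variant divergence -> expected pairwise identity curve
# (matches/columns of a global alignment, both variants evolved at the
# given substitution rate from one ancestor).  Used only as the initial
# guess of the rejection sampler; the realized identity is always
# measured.
_DIVERGENCE_CURVE = np.array(
    [
        (0.00, 1.000),
        (0.025, 0.951),
        (0.05, 0.906),
        (0.10, 0.810),
        (0.20, 0.688),
        (0.30, 0.584),
        (0.40, 0.544),
        (0.50, 0.532),
        (0.80, 0.528),
    ]
)

# Identity of unrelated random DNA under global alignment; requested
# targets below this saturate at the floor.
IDENTITY_FLOOR = 0.54


class SimulationError(ValueError):
    """Raised for invalid community configurations or impossible layouts."""


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of a synthetic phage community.

    Defaults mirror the reference study system: a 76 kb phage genome
    with nine flexible modules of 2-5 variants each at 40-88% mutual
    identity, ~99% core identity between locations, and 100 bp
    paired-end reads with 400 bp inserts.
    """

    genome_length: int = 76_000
    n_modules: int = 9
    module_length_range: tuple[int, int] = (500, 7_000)
    variants_per_module: tuple[int, int] = (2, 5)
    inter_variant_identity_range: tuple[float, float] = (0.40, 0.88)
    core_identity_between_locations: float = 0.99
    n_locations: int = 5
    read_length: int = 100
    insert_mean: int = 400
    insert_sd: int = 60
    max_insert: int = 800
    depth_per_location: float = 20.0
    sequencing_error_rate: float = 0.001
    mixture_proportions: tuple | None = None  # [loc][module] -> proportions
    deletion_modules: frozenset[int] = frozenset()
    indel_fraction: float = 0.05  # indel events per substitution event
    min_module_gap: int = 1_200
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise SimulationError("genome_length must be positive")
        if self.n_modules < 0:
            raise SimulationError("n_modules must be >= 0")
        lo, hi = self.module_length_range
        if not (0 < lo <= hi):
            raise SimulationError("invalid module_length_range")
        klo, khi = self.variants_per_module
        if not (1 <= klo <= khi):
            raise SimulationError("invalid variants_per_module")
        ilo, ihi = self.inter_variant_identity_range
        if not (0.0 <= ilo <= ihi <= 0.90):
            raise SimulationError(
                "inter_variant_identity_range must lie within [0, 0.90]: "
                "distinct variants must share <90% identity (realized "
                "identities are capped just below the threshold)"
            )
        if self.insert_mean < 2 * self.read_length:
            raise SimulationError(
                f"insert_mean ({self.insert_mean}) shorter than two read "
                f"lengths ({2 * self.read_length}): mates would overlap the "
                "whole fragment"
            )
        if self.min_module_gap < self.max_insert:
            raise SimulationError(
                "min_module_gap must be >= max_insert so one fragment "
                "never spans two modules"
            )
        if self.n_locations < 1:
            raise SimulationError("need at least one location")
        if not (0.0 <= self.sequencing_error_rate < 0.5):
            raise SimulationError("sequencing_error_rate out of range")
        if any(m < 0 or m >= self.n_modules for m in self.deletion_modules):
            raise SimulationError("deletion_modules indices out of range")
        if self.mixture_proportions is not None:
            if len(self.mixture_proportions) != self.n_locations:
                raise SimulationError("mixture_proportions: one entry per location")
            for loc_mix in self.mixture_proportions:
                if len(loc_mix) != self.n_modules:
                    raise SimulationError("mixture_proportions: one simplex per module")
                for simplex in loc_mix:
                    total = float(np.sum(simplex))
                    if abs(total - 1.0) > 1e-9 or np.min(simplex) < 0:
                        raise SimulationError(
                            f"mixture proportions must be a simplex (sum {total})"
                        )


@dataclass
class ModuleTruth:
    index: int
    anc_start: int  # interval in ancestor/core coordinates
    anc_end: int
    variants: list[str]  # variant 'absent' of a deletion module is ""
    identity: np.ndarray  # realized pairwise identity matrix
    is_deletion: bool

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class GenomeLayout:
    """One concrete genome: sequence plus module coordinates within it."""

    seq: str
    module_starts: np.ndarray
    module_ends: np.ndarray
    variants: tuple[int, ...]  # variant index per module
    location: int

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ReadTruth:
    read_id: str
    location: int
    module: int  # -1 for pure-core fragments
    variant: int  # -1 for pure-core fragments
    template_start: int  # 0-based start on the template genome
    insert: int


@dataclass
class TruthTable:
    config: CommunityConfig
    location_cores: list[str]  # ancestor-length core per location
    modules: list[ModuleTruth]
    dominants: list[list[int]]  # [location][module] -> variant index
    mixtures: list[list[np.ndarray]]  # [location][module] -> simplex
    _genomes: dict = field(default_factory=dict, repr=False)

    def dominant_assignment(self, location: int) -> tuple[int, ...]:
        return tuple(self.dominants[location])

    def genome(self, location: int, module: int | None = None,
               variant: int | None = None) -> GenomeLayout:
        """The location's dominant genome, optionally with one module swapped."""
        assignment = list(self.dominants[location])
        if module is not None:
            assignment[module] = variant
        key = (location, tuple(assignment))
        if key not in self._genomes:
            self._genomes[key] = self._build(location, tuple(assignment))
        return self._genomes[key]

    def query_window(self, read_loc: int, ref_loc: int, module: int,
                     ref_start: int, ref_end: int) -> str:
        """True query-side sequence for a reference window over one module.

        The window [ref_start, ref_end) on the reference location's
        dominant genome must span module `module`; core flanks map 1:1
        (core drift is substitution-only), so the corresponding window
        of the read location's dominant genome is returned -- the
        ground truth a gap-closure of that window should reproduce.
        """
        qg = self.genome(read_loc)
        rg = self.genome(ref_loc)
        msr, mer = int(rg.module_starts[module]), int(rg.module_ends[module])
        msq, meq = int(qg.module_starts[module]), int(qg.module_ends[module])
        # anchor both window edges on the module boundaries: core flank
        # offsets are preserved, while absolute coordinates may shift
        # when earlier modules differ in length between the genomes
        q_start = msq - (msr - ref_start) if ref_start <= msr else meq + (ref_start - mer)
        q_end = meq + (ref_end - mer) if ref_end >= mer else msq - (msr - ref_end)
        return qg.seq[max(0, q_start):max(0, q_end)]

    def _build(self, location: int, assignment: tuple[int, ...]) -> GenomeLayout:
        core = self.location_cores[location]
        pieces = []
        starts = []
        ends = []
        cursor = 0  # ancestor coordinate
        built = 0
        for mod, v in zip(self.modules, assignment):
            pieces.append(core[cursor:mod.anc_start])
            built += mod.anc_start - cursor
            starts.append(built)
            var_seq = mod.variants[v]
            pieces.append(var_seq)
            built += len(var_seq)
            ends.append(built)
            cursor = mod.anc_end
        pieces.append(core[cursor:])
        return GenomeLayout(
            seq="".join(pieces),
            module_starts=np.asarray(starts, dtype=np.int64),
            module_ends=np.asarray(ends, dtype=np.int64),
            variants=assignment,
            location=location,
        )


# ---------------------------------------------------------------------------
# sequence evolution helpers


def random_dna(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    n = int(mask.sum())
    if n:
        # shift by 1-3 positions in the base alphabet: always a different base
        idx = np.searchsorted(_BASES, arr[mask])
        arr[mask] = _BASES[(idx + rng.integers(1, 4, size=n)) % 4]
    return arr.tobytes().decode()


def _evolve(seq: str, rate: float, rng: np.random.Generator,
            indel_fraction: float, max_indel: int = 8) -> str:
    """Point substitutions plus occasional small indels at `rate`."""
    out = _substitute(seq, rate, rng)
    n_indels = rng.binomial(len(out), rate * indel_fraction)
    if n_indels == 0:
        return out
    chars = list(out)
    positions = sorted(rng.integers(0, len(chars), size=n_indels), reverse=True)
    for pos in positions:
        size = int(rng.integers(1, max_indel + 1))
        if rng.random() < 0.5:
            del chars[pos:pos + size]
        else:
            chars[pos:pos] = list(random_dna(size, rng))
    return "".join(chars)


def _generate_variant_pool(ancestor: str, k: int, target: float,
                           rng: np.random.Generator, indel_fraction: float,
                           max_rounds: int = 25) -> tuple[list[str], np.ndarray]:
    """k variants of one module with pairwise identity near `target`.

    Rejection sampling: all variants drift from the module ancestor at a
    common rate, the realized identity matrix is measured, and the rate
    is adjusted until every pair falls in the acceptance band
    [target-0.05, min(target+0.05, 0.895)].  Targets below the
    random-alignment identity floor saturate there; the band's lower
    edge is relaxed accordingly (the <0.90 distinctness invariant is
    always enforced).
    """
    saturated = target - 0.05 <= IDENTITY_FLOOR
    hi_cap = min(target + 0.05, 0.895)
    if saturated:
        # targets at/below the random-alignment floor realize at the floor
        hi_cap = min(max(hi_cap, IDENTITY_FLOOR + 0.05), 0.895)
    lo_cap = max(min(target - 0.05, hi_cap - 0.02), 0.0)
    rate = float(np.interp(target, _DIVERGENCE_CURVE[::-1, 1], _DIVERGENCE_CURVE[::-1, 0]))
    rate = min(max(rate, 0.005), 0.8)
    for _ in range(max_rounds):
        variants = [_evolve(ancestor, rate, rng, indel_fraction) for _ in range(k)]
        ident = np.ones((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                ident[i, j] = ident[j, i] = fast_identity(variants[i], variants[j])
        off = ident[np.triu_indices(k, 1)]
        if off.max() <= hi_cap and (saturated or off.min() >= lo_cap):
            return variants, ident
        if off.max() > hi_cap:
            rate = min(rate * 1.3, 0.8)
        else:
            rate = max(rate * 0.75, 0.003)
    raise SimulationError(
        f"could not realize inter-variant identity near {target:.2f} "
        f"after {max_rounds} rounds"
    )


def _place_modules(cfg: CommunityConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Disjoint module intervals with >= min_module_gap of core between/around.

    Module lengths are drawn right-skewed over the configured range
    (log-quadratic: most modules are short, a few approach the upper
    bound), emulating the strongly skewed island-size distributions of
    real phage genomes and keeping the total flexible load a modest
    fraction of the genome -- a genome that is mostly flexible sequence
    would fail the 70% recruitment-breadth rule by construction.
    """
    lo, hi = cfg.module_length_range
    u = rng.random(cfg.n_modules)
    lengths = np.round(lo * (hi / lo) ** (u ** 4)).astype(np.int64)
    required = int(lengths.sum()) + (cfg.n_modules + 1) * cfg.min_module_gap
    slack = cfg.genome_length - required
    if slack < 0:
        raise SimulationError(
            f"{cfg.n_modules} modules totalling {int(lengths.sum())} bp do not "
            f"fit disjointly in a {cfg.genome_length} bp genome with "
            f"{cfg.min_module_gap} bp gaps"
        )
    # distribute the slack across the n_modules+1 gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=cfg.n_modules))
    extra = np.diff(np.concatenate([[0], cuts, [slack]]))
    intervals = []
    cursor = 0
    for length, pad in zip(lengths, extra[:-1]):
        cursor += cfg.min_module_gap + int(pad)
        intervals.append((cursor, cursor + int(length)))
        cursor += int(length)
    return intervals


def _default_mixtures(cfg: CommunityConfig,
                      modules: list[ModuleTruth]) -> tuple[list[list[np.ndarray]], list[list[int]]]:
    """Point-mass mixtures; the dominant variant rotates with location."""
    mixtures: list[list[np.ndarray]] = []
    dominants: list[list[int]] = []
    for loc in range(cfg.n_locations):
        row_mix, row_dom = [], []
        for mod in modules:
            k = mod.n_variants
            dom = (loc + mod.index) % k
            simplex = np.zeros(k)
            simplex[dom] = 1.0
            row_mix.append(simplex)
            row_dom.append(dom)
        mixtures.append(row_mix)
        dominants.append(row_dom)
    return mixtures, dominants


def simulate_community(cfg: CommunityConfig) -> tuple[dict[int, str], TruthTable]:
    """Build the community: one reference genome per location plus truth.

    Returns ``(references, truth)`` where ``references[loc]`` is the
    location's dominant genome sequence (the natural read-recruitment
    reference for that location).
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    ancestor = random_dna(cfg.genome_length, rng)
    intervals = _place_modules(cfg, rng) if cfg.n_modules else []

    ident_lo, ident_hi = cfg.inter_variant_identity_range
    modules: list[ModuleTruth] = []
    for idx, (start, end) in enumerate(intervals):
        anc_module = ancestor[start:end]
        if idx in cfg.deletion_modules:
            variants = [anc_module, ""]
            ident = np.array([[1.0, 0.0], [0.0, 1.0]])
            modules.append(ModuleTruth(idx, start, end, variants, ident, True))
        else:
            k = int(rng.integers(cfg.variants_per_module[0],
                                 cfg.variants_per_module[1] + 1))
            target = float(rng.uniform(ident_lo, ident_hi))
            variants, ident = _generate_variant_pool(
                anc_module, k, target, rng, cfg.indel_fraction)
            modules.append(ModuleTruth(idx, start, end, variants, ident, False))

    # per-location core drift, substitution-only so coordinates stay shared
    per_loc_rate = (1.0 - cfg.core_identity_between_locations) / 2.0
    location_cores = [_substitute(ancestor, per_loc_rate, rng)
                      for _ in range(cfg.n_locations)]

    mixtures, dominants = _default_mixtures(cfg, modules)
    if cfg.mixture_proportions is not None:
        mixtures = [[np.asarray(simplex, dtype=float) for simplex in loc_mix]
                    for loc_mix in cfg.mixture_proportions]
        for loc in range(cfg.n_locations):
            for m, mod in enumerate(modules):
                if mixtures[loc][m].size != mod.n_variants:
                    raise SimulationError(
                        f"mixture for location {loc} module {m} has "
                        f"{mixtures[loc][m].size} entries, expected {mod.n_variants}")
                dominants[loc][m] = int(np.argmax(mixtures[loc][m]))

    truth = TruthTable(cfg, location_cores, modules, dominants, mixtures)
    references = {loc: truth.genome(loc).seq for loc in range(cfg.n_locations)}
    return references, truth


# ---------------------------------------------------------------------------
# read simulation


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    return _substitute(seq, rate, rng)


def simulate_reads(truth: TruthTable, location: int,
                   cfg: CommunityConfig | None = None
                   ) -> tuple[list[tuple[str, str]], list[ReadTruth]]:
    """Sample paired-end reads for one location's community.

    Fragment starts are uniform along the dominant genome; a fragment
    overlapping a module re-draws its haplotype from the module's
    mixture simplex (the remainder of the genome is identical across
    haplotypes, so only the overlapped module matters).  Read 1 is the
    forward end of the fragment, read 2 the reverse complement of the
    other end.  Substitution errors are applied i.i.d. per base.

    Returns ``(pairs, read_truth)`` with ``pairs[i] = (seq1, seq2)``.
    """
    cfg = cfg or truth.config
    if cfg.depth_per_location < 0:
        raise SimulationError("depth must be >= 0")
    rng = np.random.default_rng([cfg.seed, 1, location])
    dom = truth.genome(location)
    r = cfg.read_length
    n_frag = int(round(cfg.depth_per_location * dom.length / (2 * r)))
    pairs: list[tuple[str, str]] = []
    records: list[ReadTruth] = []
    starts_all = rng.integers(0, max(1, dom.length), size=n_frag)
    inserts_all = np.clip(
        np.round(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_frag)),
        2 * r, cfg.max_insert).astype(np.int64)
    doubled_cache: dict[int, str] = {}
    for i in range(n_frag):
        insert = int(inserts_all[i])
        # circular genome: fragment starts are uniform over the whole
        # circle and fragments may wrap the origin (module placement
        # keeps >= min_module_gap of core on both sides of the origin,
        # so wrapped fragments are always pure core)
        x = int(starts_all[i])
        j = int(np.searchsorted(dom.module_ends, x, side="right"))
        module = variant = -1
        template = dom
        if x + insert <= dom.length \
                and j < len(truth.modules) and dom.module_starts[j] < x + insert:
            module = j
            simplex = truth.mixtures[location][j]
            variant = int(rng.choice(simplex.size, p=simplex))
            if variant != truth.dominants[location][j]:
                template = truth.genome(location, j, variant)
                m_start = int(dom.module_starts[j])
                if x > m_start:
                    dom_len = int(dom.module_ends[j]) - m_start
                    var_len = int(template.module_ends[j]) - m_start
                    x = m_start + int((x - m_start) * max(var_len, 1) / max(dom_len, 1))
                x = min(x, max(0, template.length - insert))
        read_id = f"L{location}_{i:07d}"
        doubled = doubled_cache.get(id(template))
        if doubled is None:
            doubled = template.seq + template.seq[:cfg.max_insert]
            doubled_cache[id(template)] = doubled
        seq1 = doubled[x:x + r]
        seq2 = reverse_complement(doubled[x + insert - r:x + insert])
        pairs.append((_apply_errors(seq1, cfg.sequencing_error_rate, rng),
                      _apply_errors(seq2, cfg.sequencing_error_rate, rng)))
        records.append(ReadTruth(read_id, location, module, variant, x, insert))
    return pairs, records


def write_fastq_pair(pairs: Sequence[tuple[str, str]],
                     records: Sequence[ReadTruth],
                     path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for (seq1, seq2), rec in zip(pairs, records):
            qual1 = "I" * len(seq1)
            qual2 = "I" * len(seq2)
            f1.write(f"@{rec.read_id}/1\n{seq1}\n+\n{qual1}\n")
            f2.write(f"@{rec.read_id}/2\n{seq2}\n+\n{qual2}\n")


def read_truth_rows(records: Iterable[ReadTruth]) -> list[dict]:
    return [dataclasses.asdict(rec) for rec in records]


# ---------------------------------------------------------------------------
# ideal alignment emission


def _transfer_point(y: int, src: GenomeLayout, ref: GenomeLayout) -> int | None:
    """Map a coordinate of `src` onto `ref`; None inside a non-shared module."""
    n = src.module_starts.size
    j = int(np.searchsorted(src.module_ends, y, side="right"))
    if j < n and y >= src.module_starts[j]:
        if src.variants[j] == ref.variants[j]:
            return int(ref.module_starts[j]) + (y - int(src.module_starts[j]))
        return None
    if j == 0:
        return y
    return int(ref.module_ends[j - 1]) + (y - int(src.module_ends[j - 1]))


def _hamming(a: bytes, b: bytes) -> int:
    return int(np.count_nonzero(
        np.frombuffer(a, dtype=np.uint8) != np.frombuffer(b, dtype=np.uint8)))


@dataclass
class IdealAlignment:
    """One mate's placement against a reference genome (SAM-ready)."""

    read_id: str
    is_read2: bool
    mapped: bool
    start: int  # 0-based leftmost, valid if mapped
    mismatches: int
    seq_fwd: str  # reference-strand orientation
    template_length: int  # signed, 0 if unresolvable
    mate_mapped: bool
    mate_start: int
    proper_pair: bool


def emit_ideal_alignments(pairs: Sequence[tuple[str, str]],
                          records: Sequence[ReadTruth],
                          truth: TruthTable,
                          ref_location: int,
                          min_identity: float = 0.90,
                          max_insert: int | None = None
                          ) -> list[IdealAlignment]:
    """Place simulated reads on another location's reference genome.

    Each mate that shares >=`min_identity` with the reference window at
    its transferred coordinate is emitted as mapped with an exact
    mismatch count; mates from foreign (<90% identity) variants come
    out unmapped.  Pairs whose mapped template exceeds `max_insert`
    (default: the community config's insert cap, the recruiter's -X)
    are flagged discordant (``proper_pair=False``).  Pairs with both
    mates unmapped are omitted, as a read recruiter discards them.
    """
    cfg = truth.config
    max_insert = max_insert or cfg.max_insert
    ref = truth.genome(ref_location)
    ref_bytes = ref.seq.encode()
    r = cfg.read_length
    out: list[IdealAlignment] = []
    for (seq1, seq2), rec in zip(pairs, records):
        if rec.module >= 0 and rec.variant != truth.dominants[rec.location][rec.module]:
            src = truth.genome(rec.location, rec.module, rec.variant)
        else:
            src = truth.genome(rec.location)
        wrapped_pair = rec.template_start + rec.insert > src.length
        mates = []
        for is_read2, seq in ((False, seq1), (True, seq2)):
            y = rec.template_start if not is_read2 else rec.template_start + rec.insert - r
            if wrapped_pair:
                # fragment spans the circular origin; a mate lying past
                # the origin is placed at its wrapped coordinate, a mate
                # straddling the origin itself cannot map end-to-end
                y = y % src.length
                if y + r > src.length:
                    mates.append((is_read2, False, -1, 0,
                                  seq if not is_read2 else reverse_complement(seq)))
                    continue
            seq_fwd = seq if not is_read2 else reverse_complement(seq)
            # segment rule: a mate overlapping a module whose source
            # variant differs from the reference's (variants are <90%
            # identical by construction) is unmapped, like a recruiter
            # rejecting reads from a foreign variant
            foreign = False
            j = int(np.searchsorted(src.module_ends, y, side="right"))
            if j < src.module_starts.size and src.module_starts[j] < y + r \
                    and src.variants[j] != ref.variants[j]:
                foreign = True
            s = _transfer_point(y, src, ref)
            if s is None:
                e = _transfer_point(y + r - 1, src, ref)
                if e is not None:
                    s = e - (r - 1)
            mapped = False
            mm = 0
            if not foreign and s is not None and 0 <= s and s + r <= ref.length:
                mm = _hamming(seq_fwd.encode(), ref_bytes[s:s + r])
                mapped = (1.0 - mm / r) >= min_identity
            mates.append((is_read2, mapped, s if s is not None else -1, mm, seq_fwd))
        both = mates[0][1] and mates[1][1] and not wrapped_pair
        if not (mates[0][1] or mates[1][1]):
            continue
        if wrapped_pair:
            # emit mapped mates of an origin-spanning fragment unpaired:
            # their reference-coordinate "template" would fake a
            # genome-length bridging insert
            for is_read2, mapped, s, mm, seq_fwd in mates:
                if mapped:
                    out.append(IdealAlignment(
                        read_id=rec.read_id, is_read2=is_read2, mapped=True,
                        start=s, mismatches=mm, seq_fwd=seq_fwd,
                        template_length=0, mate_mapped=False,
                        mate_start=s, proper_pair=False))
            continue
        tlen = 0
        proper = False
        if both:
            left = min(mates[0][2], mates[1][2])
            right = max(mates[0][2], mates[1][2]) + r
            tlen = right - left
            proper = tlen <= max_insert
        for (is_read2, mapped, s, mm, seq_fwd), (_, mate_mapped, mate_s, _, _) in (
                (mates[0], mates[1]), (mates[1], mates[0])):
            signed = 0
            if both:
                signed = tlen if s <= mate_s else -tlen
            out.append(IdealAlignment(
                read_id=rec.read_id, is_read2=is_read2, mapped=mapped,
                start=s if mapped else (mate_s if mate_mapped else 0),
                mismatches=mm if mapped else 0,
                seq_fwd=seq_fwd, template_length=signed,
                mate_mapped=mate_mapped,
                mate_start=mate_s if mate_mapped else max(s, 0),
                proper_pair=proper))
    return out


def to_alignment_records(alignments: Iterable[IdealAlignment], contig_id: str):
    """Mapped ideal alignments as :class:`~phageflex.alignments.AlignmentRecord`s."""
    from .alignments import AlignmentRecord

    return [AlignmentRecord(
        read_id=a.read_id, contig_id=contig_id, start=a.start,
        aligned_length=len(a.seq_fwd), mismatches=a.mismatches,
        template_length=a.template_length, mapped=True,
        mate_mapped=a.mate_mapped, proper_pair=a.proper_pair,
        is_read2=a.is_read2) for a in alignments if a.mapped]


def write_sam(alignments: Iterable[IdealAlignment], path,
              ref_name: str, ref_length: int, seed: int | None = None) -> None:
    """Write ideal alignments as plain SAM with NM tags and TLEN."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": ref_name, "LN": ref_length}],
              "PG": [{"ID": "phageflex", "PN": "phageflex",
                      "CL": f"emit_ideal_alignments seed={seed}"}]}
    with pysam.AlignmentFile(str(path), "w", header=pysam.AlignmentHeader.from_dict(header)) as fh:
        for aln in alignments:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = aln.read_id
            flag = 0x1  # paired
            flag |= 0x80 if aln.is_read2 else 0x40
            if not aln.mapped:
                flag |= 0x4
            if not aln.mate_mapped:
                flag |= 0x8
            if aln.proper_pair:
                flag |= 0x2
            if aln.is_read2 and aln.mapped:
                flag |= 0x10
            if (not aln.is_read2) and aln.mate_mapped:
                flag |= 0x20
            a.flag = flag
            a.reference_id = 0
            a.reference_start = max(aln.start, 0)
            a.mapping_quality = 42 if aln.mapped else 0
            if aln.mapped:
                a.cigarstring = f"{len(aln.seq_fwd)}M"
            a.next_reference_id = 0
            a.next_reference_start = max(aln.mate_start, 0)
            a.template_length = aln.template_length
            a.query_sequence = aln.seq_fwd
            a.query_qualities = pysam.qualitystring_to_array("I" * len(aln.seq_fwd))
            if aln.mapped:
                a.set_tag("NM", aln.mismatches)
            fh.write(a)
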