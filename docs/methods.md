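# Methods

`phageflex` analyses phage pan-genome structure from read recruitment:
regions of a reference phage genome that sharply under-recruit
metagenomic reads ("metagenomic islands", MGIs) mark loci where the
sampled population carries a different — or no — sequence.  The
package detects these islands from per-base coverage, classifies the
cause (deletion polymorphism, intein insertion, or a divergent
variable gene), reconstructs the flexible sequence actually present
in a query metagenome by targeted gap closing, and quantifies how many
distinct variants of each flexible module co-occur in a metagenome.
A synthetic community generator with complete ground truth makes every
stage testable end to end.

## Synthetic communities

The generator emulates a community of near-identical phage genomes
that differ at a small number of interchangeable flexible modules:

* **Core genome.** A random ancestor of `genome_length` bp (default
  76 kb, circular).  Each location's core drifts from the ancestor by
  substitution only, at a rate chosen so that pairwise core identity
  between locations matches `core_identity_between_locations`
  (default 0.99).  Keeping core drift substitution-only means core
  coordinates are directly alignable across all genomes, which the
  idealized read placer exploits; indels occur only inside module
  variants.
* **Flexible modules.** `n_modules` (default 9) disjoint intervals
  with at least `min_module_gap` (1.2 kb) of core between them and
  around the circular origin.  Module lengths are drawn right-skewed
  over `module_length_range` (default 500–7000 bp; log-power sampling
  with exponent 4, median ≈ 0.8 kb), reflecting the strongly skewed
  island-size distributions of real phage genomes and keeping the
  total flexible load near 10–20% of the genome — a genome that is
  mostly flexible sequence would fail the 70% recruitment-breadth
  inclusion rule by construction.
* **Variant pools.** Each variable module carries 2–5 homologous
  variants evolved from the module ancestor by substitutions plus
  occasional short indels.  A per-module target identity is drawn
  from `inter_variant_identity_range` (default 0.40–0.88) and the
  drift rate is adjusted by rejection sampling until every measured
  pairwise identity falls within ±0.05 of the target and strictly
  below 0.895 (so all variants are "distinct" under the <90% rule).
  Note that global-alignment identity (matches over alignment
  columns) of *unrelated* DNA is already ≈ 0.53–0.54, because a
  global aligner pairs up chance matches; requested targets below
  that floor saturate there, and realized identities near the floor
  mean "no detectable homology".  Modules listed in
  `deletion_modules` instead carry a present/absent pool.
* **Mixtures and dominants.** Per location and module, variant
  frequencies form a simplex.  The default is a point mass whose
  dominant variant rotates with location (dominants shuffle
  independently per module, as observed in real communities); explicit
  mixtures enable co-presence experiments.
* **Reads.** 100 bp paired-end reads, insert length truncated-normal
  (mean 400 bp, sd 60, clamped to [200, 800]), substitution errors
  i.i.d. at `sequencing_error_rate` (default 0.1%).  Fragments start
  uniformly on the circle; a fragment overlapping a module redraws its
  haplotype from the module's mixture.  When a chosen variant's length
  differs from the dominant's, the fragment start is rescaled
  proportionally into the variant — per-base depth inside
  length-changing variants is therefore approximate (exact in
  expectation for equal-length variants).  Every read records its
  (location, module, variant, coordinate) origin.

**Idealized recruitment.** `emit_ideal_alignments` reproduces what a
read recruiter with a >90% identity cutoff would report, without an
external aligner: each mate is placed at its exactly transferred
coordinate with a true mismatch count (NM) and signed template length.
A mate overlapping a module whose source variant differs from the
reference's is reported unmapped (variants are <90% identical by
construction), as is any mate whose window identity to the reference
falls below 90% — the latter catches reads spanning deletion
junctions.  Pairs whose mapped template exceeds the 800 bp insert cap
are flagged discordant; mates of origin-spanning (wrapped) fragments
are emitted unpaired so that their genome-length "templates" cannot
masquerade as bridging evidence.

What the generator does **not** model: quality-score profiles, GC or
position bias, chimeric fragments, indel sequencing errors (optional
substitution-only errors keep the identity-filter analysis exact), and
real variant architectures with conserved sub-domains.  Passing tests
therefore demonstrate the pipeline's correctness under the stated
statistical structure, not performance on any particular real
metagenome.

## Island detection

Coverage is per-base read depth (every aligned base counts) computed
from identity-filtered alignments; the ≥90% identity filter is
computed explicitly from NM over the aligned length, making it
aligner-independent.  Contigs with breadth < 70% or mean depth < 2×
are excluded; contigs with a coverage spike (≥100 bp above 10× the
contig mean — error-prone reads or unresolved repeats) are flagged
and excluded by default (an automated, documented stand-in for manual
curation).  On eligible contigs:

* mean depth ≥ 5× ("high regime"): an island is any maximal run of
  ≥100 bp with depth strictly below 25% of the contig mean;
* mean depth in [2, 5) ("low regime"): any maximal run of ≥200 bp with
  zero coverage.

Boundary conventions are explicit: "≥5×" inclusive, "<25%" strict,
length thresholds inclusive.  The contig mean includes island
positions (a single global mean per contig); nearby dropouts are not
merged.  Detected intervals are extended 300 bp per side (clamped)
for gene identification only — counts and length statistics always
use raw intervals.

## Classification

A read pair whose template (leftmost mate start to rightmost mate
end) fully contains an island, exceeds 300 bp, and keeps both mates
outside the island is a *bridging template*: the island's flanks are
contiguous in the sampled genome, i.e. the island sequence is deleted
there.  If bridging templates exceed 10% of the contig mean depth the
island is a **deletion**; otherwise, if an overlapping gene or domain
carries an intein / homing-endonuclease-intein annotation (explicit
`intein=true` GFF3 attribute or a keyword match), it is an
**intein**; otherwise it is a **variable** gene — the default.  Mate
extents are approximated from the record's own aligned length (mates
of equal length).  Genes are assigned to islands when the gene covers
≥10% of the raw island (extended coordinates only widen the candidate
search).

## Gap closing

The flexible sequence occupying an island is rebuilt by an iterative
reference-guided loop over a window of island ± 500 bp:

1. map the metagenome's reads to the window with a deterministic
   seed-and-extend ungapped mapper (21-mer seeds, ≥90% identity over
   non-N columns; `N` positions are uninformative rather than
   mismatching, so anchored reads extend into unknown sequence);
2. call a plurality consensus ("0% majority": the most counted base
   wins at any fraction; ties resolve A>C>G>T), writing `N` where no
   read covers a position;
3. recruit the mapped reads plus their mates and assemble them with a
   small de Bruijn assembler (k = 23 or 33, k-mers below count 2
   dropped, tips ≤100 bp clipped, bubbles ≤2000 bp popped in favour of
   the higher-coverage arm; a count-1 fallback pass with relative
   branch pruning — arms at ≤25% of the strongest sibling — spans the
   single-coverage dips the count-2 floor breaks at);
4. patch each N-run whose two flank anchors (up to 100 bp, ≥95%
   identity over ≥50 bp) both match one contig in consistent
   orientation, replacing the run by the contig interior (gap capped
   at 3 kb); and
5. iterate until no `N` remains, progress stalls, or 10 iterations.
   Zero-coverage overhangs of a few bp at the window boundaries (no
   read can anchor there) are trimmed rather than reported as gaps.

Closed loci are **validated** reference-free: the recruited reads are
reassembled with no reference involved, and the locus passes when a
single contig reproduces ≥95% of it at ≥99% identity (the same
count-2 / count-1 ladder is swept).  At 20× depth closure and
validation both succeed routinely; at 10× closure succeeds and
validation usually does; at 5× a spanning error-free contig is
statistically unattainable (single-read columns have no plurality
correction), so 5× closures are legitimately reported unvalidated.

Sequence identities are reported from an end-to-end alignment under
an affine gap model (match +1, mismatch −1, gap open −2, extend −1),
identity = identical columns / alignment columns, best of both
strands.  A unit-cost (edit-distance) global alignment with the same
identity definition serves as the fast internal metric where
thousands of comparisons are needed; the two agree within the
tolerances used anywhere they are interchanged.

## Co-presence

All reconstructed variants of a locus are clustered by single linkage
at 90% identity; members of different clusters are distinct variants,
and the longest member represents each cluster.  Reads are recruited
against the panel plus the core reference, each read counting once
toward its highest-identity match (≥90% cutoff, ties to earlier panel
order).  A variant is co-present when reads cover >70% of its
positions at ≥1×; its abundance is its mean recruitment depth as a
percentage of the core-genome mean, where the core mean excludes
island intervals (± extension) so flexible loci do not bias the
denominator (switchable to the whole-genome mean).

## Numerical and design choices

* Coordinates are 0-based half-open internally; GFF3 (1-based) is
  converted at the boundary.
* All randomness flows from numpy `default_rng` seeded from the
  community seed; every tie-break (consensus bases, assembly arms,
  panel order, read mapping) is deterministic, so identical
  configurations give byte-identical outputs, including SAM/bedGraph/
  BED/FASTA files and their headers.
* The bridging-fraction denominator is the contig mean depth — the
  only coverage baseline the detection stage defines.
* The ">300 bp insert" bridging rule is deliberately below the 400 bp
  insert mean: for islands shorter than the insert, an ordinary pair
  bridging the island already demonstrates that the flanks are
  adjacent in the sampled genome.
* Secondary/supplementary alignments are dropped on input ("map
  once" semantics); recruitment to a panel enforces single placement
  explicitly.
* Scale of the shipped analyses: the end-to-end study-shaped run uses
  the full default community (76 kb × 5 locations × 20×, ≈ 7,600 read
  pairs per location, 20 cross-location recruitments); reconstruction
  grids use a 12 kb genome with one 1.2 kb module per cell; detection
  is verified against an independent per-position oracle on 1,000
  random tracks of 5–100 kb.  These sizes are the package's default
  desk-scale experiment and complete in a few minutes on one CPU.

## Known limitations

* The ungapped internal mapper relies on exact 21-mer seeds: reads
  with dense errors or spanning long indels are unmapped rather than
  split-aligned; the assembly/patching path carries length changes
  instead.
* The assembler is a minimal DBG: no paired-end scaffolding, no
  repeat resolution beyond 23/33-mers.  Loci embedded in long exact
  repeats would not reconstruct uniquely.
* Mixture abundance estimates are read-count ratios, not an EM
  deconvolution; strongly shared sub-regions between co-present
  variants bias assignment toward the earlier panel entry.
* Bridging detection assumes equal mate lengths when reconstructing
  the far mate's extent from TLEN.
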