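"""File-level orchestration of the analysis stages.

Each stage reads standard formats (FASTA/FASTQ/SAM/bedGraph/BED/GFF3),
runs the corresponding library module, and writes plain-text outputs
whose headers record the tool version, the resolved parameters and the
seed, so a rerun with identical inputs is byte-identical.  Stages are
independently re-runnable; the command-line interface in
:mod:`phageflex.cli` is a thin wrapper over these functions.

By default reads are never recruited to the reference that originates
from their own location (metagenomically assembled references are
biased toward their own sample's dominant variants); pass
``include_self=True`` to override.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import __version__
from .alignments import CoverageTrack, compute_coverage, detect_coverage_spikes, \
    filter_by_identity, read_sam
from .assemble import AssemblyParams
from .classify import assign_genes, bridging_fraction, classify_mgi, read_gff3, \
    tabulate_mgi_gene_categories
from .copresence import build_panel, copresence_table, core_mean_depth, \
    records_to_frame, recruit_to_panel
from .gapclose import ReadStore, iterate_closure
from .identity import fast_identity
from .islands import DetectionConfig, Eligibility, detect_mgis, \
    eligible_for_detection, read_bed, summarize_mgis, write_bed
from .simulate import CommunityConfig, emit_ideal_alignments, simulate_community, \
    simulate_reads, write_fastq_pair, write_sam


def _header(seed=None, **params) -> str:
    blob = json.dumps(params, sort_keys=True, default=str)
    return f"# phageflex {__version__} seed={seed} params={blob}\n"


def write_fasta(path, entries: list[tuple[str, str]], seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed=seed).replace("#", ";", 1))
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    # fasta-pearson tolerates the provenance comment line our writer emits
    return {rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(path), "fasta-pearson")}


def run_simulate(cfg: CommunityConfig, outdir, emit_sams: bool = True,
                 include_self: bool = False) -> dict:
    """Generate a community: references, reads, truth, ideal alignments."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    references, truth = simulate_community(cfg)
    with open(outdir / "config.json", "w") as fh:
        json.dump({**dataclasses.asdict(cfg),
                   "deletion_modules": sorted(cfg.deletion_modules),
                   "phageflex": __version__},
                  fh, sort_keys=True, indent=1, default=str)
        fh.write("\n")
    write_fasta(outdir / "references.fasta",
                [(f"ref_L{loc}", seq) for loc, seq in sorted(references.items())],
                seed=cfg.seed)
    variant_entries = []
    module_rows = ["module\tanc_start\tanc_end\tn_variants\tis_deletion"]
    for mod in truth.modules:
        module_rows.append(f"{mod.index}\t{mod.anc_start}\t{mod.anc_end}"
                           f"\t{mod.n_variants}\t{int(mod.is_deletion)}")
        for v, seq in enumerate(mod.variants):
            if seq:
                variant_entries.append((f"module{mod.index}__variant{v}", seq))
    write_fasta(outdir / "truth_variants.fasta", variant_entries, seed=cfg.seed)
    (outdir / "truth_modules.tsv").write_text(
        _header(seed=cfg.seed) + "\n".join(module_rows) + "\n")
    dom_rows = ["location\tmodule\tdominant\tmixture"]
    for loc in range(cfg.n_locations):
        for m, mod in enumerate(truth.modules):
            mix = ",".join(f"{p:.6g}" for p in truth.mixtures[loc][m])
            dom_rows.append(f"{loc}\t{m}\t{truth.dominants[loc][m]}\t{mix}")
    (outdir / "truth_dominants.tsv").write_text(
        _header(seed=cfg.seed) + "\n".join(dom_rows) + "\n")

    all_pairs = {}
    for loc in range(cfg.n_locations):
        pairs, records = simulate_reads(truth, loc, cfg)
        all_pairs[loc] = (pairs, records)
        write_fastq_pair(pairs, records,
                         outdir / f"reads_L{loc}_R1.fastq",
                         outdir / f"reads_L{loc}_R2.fastq")
    if emit_sams:
        samdir = outdir / "sam"
        samdir.mkdir(exist_ok=True)
        for read_loc, (pairs, records) in all_pairs.items():
            for ref_loc in range(cfg.n_locations):
                if ref_loc == read_loc and not include_self:
                    continue
                alns = emit_ideal_alignments(pairs, records, truth, ref_loc)
                write_sam(alns, samdir / f"reads-L{read_loc}_ref-L{ref_loc}.sam",
                          f"ref_L{ref_loc}", len(references[ref_loc]),
                          seed=cfg.seed)
    return {"references": references, "truth": truth}


def _length_from_sam(sam_path, contig_id: str) -> int:
    import pysam

    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        return int(fh.header.to_dict()["SQ"][
            [sq["SN"] for sq in fh.header.to_dict()["SQ"]].index(contig_id)]["LN"])


def run_detect(sam_path, contig_id: str, contig_length: int | None, outdir,
               detection: DetectionConfig = DetectionConfig(),
               min_identity: float = 0.90, seed=None,
               bedgraph_path=None, exclude_spiked: bool = True) -> dict:
    """Coverage + MGI detection for one (reference, metagenome) pair."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if contig_length is None and sam_path is not None:
        contig_length = _length_from_sam(sam_path, contig_id)
    if bedgraph_path is not None:
        track = CoverageTrack.from_bedgraph(bedgraph_path, contig_id, contig_length)
    else:
        records = filter_by_identity(read_sam(sam_path), min_identity=min_identity)
        track = compute_coverage(records, contig_id, contig_length)
    stem = Path(sam_path or bedgraph_path).stem
    track.to_bedgraph(outdir / f"{stem}.coverage.bedgraph", seed=seed)
    spikes = detect_coverage_spikes(track)
    eligibility = eligible_for_detection(track, detection)
    mgis = []
    if not (spikes and exclude_spiked) and eligibility in (
            Eligibility.HIGH_REGIME, Eligibility.LOW_REGIME):
        mgis = detect_mgis(track, detection)
    write_bed(mgis, outdir / f"{stem}.mgi.bed", extended=False, seed=seed)
    write_bed(mgis, outdir / f"{stem}.mgi.extended.bed", extended=True, seed=seed)
    summary = summarize_mgis(mgis, {contig_id: contig_length})
    with open(outdir / f"{stem}.summary.tsv", "w") as fh:
        fh.write(_header(seed=seed, eligibility=eligibility.value,
                         n_spikes=len(spikes)))
        fh.write("metric\tvalue\n")
        for key, value in summary.items():
            fh.write(f"{key}\t{value}\n")
    return {"track": track, "mgis": mgis, "summary": summary,
            "eligibility": eligibility, "spikes": spikes}


def run_classify(sam_path, mgi_bed, gff_path, outdir, contig_id: str,
                 contig_length: int | None = None, min_identity: float = 0.90,
                 category_map: dict[str, str] | None = None, seed=None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if contig_length is None:
        contig_length = _length_from_sam(sam_path, contig_id)
    mgis = read_bed(mgi_bed, {contig_id: contig_length})
    records = list(filter_by_identity(read_sam(sam_path),
                                      min_identity=min_identity))
    track = compute_coverage(records, contig_id, contig_length)
    genes = read_gff3(gff_path) if gff_path else []
    assignments = assign_genes(mgis, genes)
    hits_by_mgi = {}
    for mgi, gene, frac in assignments:
        hits_by_mgi.setdefault(id(mgi), []).append(gene)
    classifications = []
    stem = Path(sam_path).stem
    with open(outdir / f"{stem}.classification.tsv", "w") as fh:
        fh.write(_header(seed=seed))
        fh.write("contig\tstart\tend\tlabel\tbridging_fraction\tintein_evidence\n")
        for mgi in mgis:
            frac = bridging_fraction(mgi, records, track.mean_depth)
            cls = classify_mgi(mgi, frac, hits_by_mgi.get(id(mgi), []))
            classifications.append(cls)
            fh.write(f"{mgi.contig_id}\t{mgi.start}\t{mgi.end}\t{cls.label}"
                     f"\t{cls.bridging_fraction:.4f}\t{cls.intein_evidence or '.'}\n")
    table = tabulate_mgi_gene_categories(assignments, classifications, category_map)
    with open(outdir / f"{stem}.categories.tsv", "w") as fh:
        fh.write(_header(seed=seed))
        table.to_csv(fh, sep="\t", index=False)
    return {"classifications": classifications, "assignments": assignments,
            "table": table}


def run_reconstruct(ref_fasta, contig_id: str, mgi_bed, fastq1, fastq2, outdir,
                    params: AssemblyParams = AssemblyParams(),
                    metagenome: str = "query", seed=None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = read_fasta(ref_fasta)[contig_id]
    mgis = read_bed(mgi_bed, {contig_id: len(reference)})
    store = ReadStore.from_fastq(fastq1, fastq2)
    results = iterate_closure(reference, mgis, store, params, metagenome=metagenome)
    write_fasta(outdir / f"{metagenome}.reconstructed.fasta",
                [(f"{res.locus_id}__{metagenome}", res.sequence)
                 for res in results if res.sequence],
                seed=seed)
    with open(outdir / f"{metagenome}.closure.tsv", "w") as fh:
        fh.write(_header(seed=seed))
        fh.write("locus\tmetagenome\titerations\tn_remaining\tclosed\t"
                 "validated\trecruited_reads\n")
        for res in results:
            n_left = sum(e - s for s, e in res.remaining_n_runs)
            fh.write(f"{res.locus_id}\t{res.metagenome}\t{res.iterations}"
                     f"\t{n_left}\t{int(res.closed)}\t{int(res.validated)}"
                     f"\t{res.recruited_reads}\n")
    return {"results": results}


def run_copresence(variant_fasta, fastq1, fastq2, outdir,
                   core_fasta=None, core_contig: str | None = None,
                   mgi_bed=None, locus_prefix_sep: str = "__",
                   seed=None, min_identity: float = 0.90,
                   identity_fn=fast_identity) -> dict:
    """Panel building + best-single-placement recruitment + co-presence table.

    Variant FASTA entries are named ``<locus>__<metagenome>``; entries
    sharing a locus prefix form one panel.  If a core reference is
    supplied its mean depth (islands excluded) is the normalizing
    denominator; otherwise the panel's own best track is used.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants = read_fasta(variant_fasta)
    store = ReadStore.from_fastq(fastq1, fastq2)
    reads = store.sequences()
    loci: dict[str, list[tuple[str, str]]] = {}
    for name, seq in variants.items():
        locus = name.split(locus_prefix_sep)[0]
        loci.setdefault(locus, []).append((name, seq))

    core_mean = None
    if core_fasta is not None:
        core_seq = read_fasta(core_fasta)[core_contig]
        core_tracks = recruit_to_panel(reads, [("__core__", core_seq)],
                                       min_identity=min_identity)
        mgis = read_bed(mgi_bed, {core_contig: len(core_seq)}) if mgi_bed else []
        core_mean = core_mean_depth(core_tracks["__core__"], mgis)

    all_records = []
    metagenome = Path(fastq1).stem.replace("_R1", "")
    for locus in sorted(loci):
        panel = build_panel(loci[locus], locus_id=locus, identity_fn=identity_fn)
        reps = panel.representatives()
        panel_seqs = [(label, dict(loci[locus])[label])
                      for label in reps.values()]
        tracks = recruit_to_panel(reads, panel_seqs, min_identity=min_identity)
        norm = core_mean if core_mean is not None else max(
            (t.mean_depth for t in tracks.values()), default=0.0)
        all_records.extend(copresence_table(tracks, norm, locus, metagenome))
        np.savetxt(outdir / f"{locus}.identity.tsv", panel.identity,
                   fmt="%.4f", delimiter="\t",
                   header=" ".join(panel.labels), comments="# ")
    frame = records_to_frame(all_records)
    with open(outdir / "copresence.tsv", "w") as fh:
        fh.write(_header(seed=seed, core_mean=core_mean))
        frame.to_csv(fh, sep="\t", index=False, float_format="%.4f")
    return {"records": all_records, "frame": frame, "core_mean": core_mean}


def run_report(stage_dir, outdir, seed=None) -> dict:
    """Aggregate per-pair detection summaries into one report."""
    import pandas as pd

    stage_dir, outdir = Path(stage_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for summary in sorted(stage_dir.glob("**/*.summary.tsv")):
        frame = pd.read_csv(summary, sep="\t", comment="#")
        row = dict(zip(frame["metric"], frame["value"]))
        row["pair"] = summary.stem.replace(".summary", "")
        rows.append(row)
    report = pd.DataFrame(rows)
    with open(outdir / "report.tsv", "w") as fh:
        fh.write(_header(seed=seed))
        report.to_csv(fh, sep="\t", index=False)
    return {"report": report}
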