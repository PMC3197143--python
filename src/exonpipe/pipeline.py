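"""End-to-end orchestration of the paired tumor/normal analysis.

Two alignment pipelines feed quantification, mirroring the hierarchical
design the analysis assumes:

* gene level — reads align to the spliced transcriptome only; multireads
  are assigned to the most abundant transcript and gene RPKM uses the
  per-sample major transcript's length;
* exon level — reads align to the genome (both strands) first, unaligned
  reads to the known exon-exon junction references, and still-unaligned
  reads to the phase-compatible novel junction references; exon counts
  fan out over overlapped exons and junctional exons.

Differential calls at both levels use the paired t + exact Wilcoxon
conjunction with a BH-FDR ceiling, DEE-containing genes receive pattern
labels, and planted-truth recovery metrics are computed when the input is
the synthetic cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from exonpipe import align as al
from exonpipe import diffexpr as dx
from exonpipe import junctions as jx
from exonpipe import quantify as qt
from exonpipe.annotation import GenomeAnnotation
from exonpipe.patterns import classify_patterns, venn_gene_exon
from exonpipe.report import RunSummary, summarize_run
from exonpipe.simulate import (
    SimulationConfig,
    TruthTable,
    generate_expression_profiles,
    generate_genome_annotation,
    simulate_reads,
)

logger = logging.getLogger(__name__)


@dataclass
class SampleAlignment:
    """Per-sample stage tallies and count vectors."""

    sample_id: str
    total_reads: int
    transcriptome_aligned: int
    exon_pipeline_aligned: int
    tx_counts: pd.Series
    gene_counts: pd.Series
    exon_counts: pd.Series
    novel_junction_counts: dict[str, int]
    stage_tally: dict[str, int]


@dataclass
class PipelineResult:
    config: SimulationConfig
    annotation: GenomeAnnotation
    truth: TruthTable | None
    gene_counts: pd.DataFrame
    tx_counts: pd.DataFrame
    gene_rpkm: pd.DataFrame
    exon_counts: pd.DataFrame
    exon_rpkm: pd.DataFrame
    junction_counts: pd.DataFrame
    junction_tpm: pd.DataFrame
    known_db: jx.JunctionReference
    novel_db: jx.JunctionReference
    gene_calls: pd.DataFrame
    exon_calls: pd.DataFrame
    pattern_calls: pd.DataFrame
    venn: tuple[int, int, int]
    run_summary: RunSummary
    pcc: pd.DataFrame
    pcc_groups: dict[str, float]
    design: dx.PairedDesign
    metrics: dict[str, float] = field(default_factory=dict)


def _align_sample(
    sample_id: str,
    fastq_text: str,
    tx_index: al.ReferenceIndex,
    genome_index: al.ReferenceIndex,
    known_index: al.ReferenceIndex | None,
    novel_index: al.ReferenceIndex | None,
    known_db: jx.JunctionReference,
    novel_db: jx.JunctionReference,
    locator: qt.ExonLocator,
    tx2gene: dict[str, str],
    read_length: int,
    min_overhang: int,
) -> SampleAlignment:
    batch = al.load_fastq(StringIO(fastq_text), read_length)
    total = len(batch) + batch.n_discarded

    # gene-level pipeline: transcriptome only, sense strand
    gene_stage = al.align_hierarchical(batch, [("transcriptome", tx_index, False)])
    tx_hits = gene_stage.stages[0].hits
    tx_counts, gene_counts = qt.assign_reads_gene_level(
        tx_hits, list(tx_index.ids), tx2gene
    )

    # exon-level pipeline: genome -> known junctions -> novel junctions
    stages: list[tuple[str, al.ReferenceIndex, bool]] = [("genome", genome_index, True)]
    if known_index is not None:
        stages.append(("known_junction", known_index, False))
    if novel_index is not None:
        stages.append(("novel_junction", novel_index, False))
    exon_stage = al.align_hierarchical(batch, stages)
    tally = exon_stage.tally()

    junction_pairs = None
    novel_counts: dict[str, int] = {r.junction_id: 0 for r in novel_db.records}
    for stage in exon_stage.stages[1:]:
        db = known_db if stage.name == "known_junction" else novel_db
        counts, valid = jx.detect_junction_reads(
            stage.hits, stage.reference_ids, db, read_length, min_overhang
        )
        if stage.name == "known_junction" and len(stage.hits):
            rank = {e: i for i, e in enumerate(locator.exon_ids)}
            reads, exons = [], []
            for row in np.nonzero(valid)[0]:
                rec = db[stage.reference_ids[int(stage.hits.ref_idx[row])]]
                for exon_id in (rec.donor_exon, rec.acceptor_exon):
                    reads.append(int(stage.hits.read_idx[row]))
                    exons.append(rank[exon_id])
            junction_pairs = (np.array(reads, np.int64), np.array(exons, np.int64))
        if stage.name == "novel_junction":
            novel_counts = counts

    exon_result = qt.assign_reads_exon_level(
        exon_stage.stages[0].hits, list(genome_index.ids), junction_pairs,
        locator, read_length,
    )
    exon_aligned = sum(v for k, v in tally.items() if k not in ("unaligned", "total"))

    return SampleAlignment(
        sample_id=sample_id,
        total_reads=total,
        transcriptome_aligned=gene_stage.stages[0].n_aligned,
        exon_pipeline_aligned=exon_aligned,
        tx_counts=tx_counts,
        gene_counts=gene_counts,
        exon_counts=exon_result.counts,
        novel_junction_counts=novel_counts,
        stage_tally=tally,
    )


def run_synthetic_study(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    alpha: float = dx.DEFAULT_ALPHA,
    fdr_ceiling: float = dx.DEFAULT_FDR_CEILING,
) -> PipelineResult:
    """Generate the synthetic cohort and run the full analysis on it."""
    fasta, gtf, ann = generate_genome_annotation(config)
    abund, truth = generate_expression_profiles(ann, config)
    fastqs = simulate_reads(ann, abund, config, truth.novel_transcripts)
    result = run_cohort(ann, fastqs, config, truth, alpha, fdr_ceiling)
    if outdir is not None:
        save_artifacts(result, Path(outdir), fasta=fasta, gtf=gtf, fastqs=fastqs)
    return result


def run_cohort(
    ann: GenomeAnnotation,
    fastqs: dict[str, str],
    config: SimulationConfig,
    truth: TruthTable | None = None,
    alpha: float = dx.DEFAULT_ALPHA,
    fdr_ceiling: float = dx.DEFAULT_FDR_CEILING,
) -> PipelineResult:
    """Run both pipelines plus downstream statistics on per-sample FASTQ text."""
    L = config.read_length
    tx_refs = [(tid, ann.transcript_cdna(tid)) for tid in sorted(ann.transcripts)]
    tx2gene = {tid: ann.transcripts[tid].gene_id for tid in ann.transcripts}
    tx_index = al.build_index(tx_refs)
    genome_index = al.build_index(sorted(ann.genome.items()))
    known_db = jx.build_known_junction_db(ann, L, config.min_overhang)
    novel_db = jx.build_novel_junction_db(ann, known_db, L, config.min_overhang)
    known_index = al.build_index(known_db.as_references()) if len(known_db) else None
    novel_index = al.build_index(novel_db.as_references()) if len(novel_db) else None
    locator = qt.ExonLocator(ann)

    samples: list[SampleAlignment] = []
    for sample_id in config.sample_ids:
        sa = _align_sample(
            sample_id, fastqs[sample_id], tx_index, genome_index, known_index,
            novel_index, known_db, novel_db, locator, tx2gene, L, config.min_overhang,
        )
        logger.info("sample %s: %d/%d transcriptome-aligned", sample_id,
                    sa.transcriptome_aligned, sa.total_reads)
        samples.append(sa)

    sample_ids = [s.sample_id for s in samples]
    gene_counts = pd.DataFrame({s.sample_id: s.gene_counts for s in samples})
    tx_counts = pd.DataFrame({s.sample_id: s.tx_counts for s in samples})
    exon_counts = pd.DataFrame({s.sample_id: s.exon_counts for s in samples})
    junction_counts = pd.DataFrame(
        {s.sample_id: pd.Series(s.novel_junction_counts, dtype=np.int64) for s in samples}
    ) if len(novel_db) else pd.DataFrame(index=pd.Index([], name="junction_id"),
                                         columns=sample_ids)

    gene_totals = pd.Series({s.sample_id: s.transcriptome_aligned for s in samples})
    exon_totals = pd.Series({s.sample_id: s.exon_pipeline_aligned for s in samples})
    tx_lengths = pd.Series({tid: ann.transcripts[tid].cdna_length
                            for tid in ann.transcripts})
    exon_lengths = pd.Series({eid: ann.exons[eid].length for eid in ann.exons})

    gene_rpkm = qt.compute_gene_rpkm(gene_counts, tx_counts, tx_lengths, tx2gene,
                                     gene_totals)
    exon_rpkm = qt.compute_rpkm(exon_counts, exon_lengths.reindex(exon_counts.index),
                                exon_totals)
    junction_tpm = (qt.compute_tpm_junction(junction_counts, exon_totals)
                    if len(junction_counts) else junction_counts.copy())

    design = dx.PairedDesign.from_sample_sheet(config.sample_sheet())
    gene_calls = dx.call_features(gene_rpkm, gene_counts, design, alpha, fdr_ceiling)
    exon_calls = dx.call_features(exon_rpkm, exon_counts, design, alpha, fdr_ceiling)

    deg_genes = set(gene_calls.index[gene_calls["significant"]])
    exon2gene = {eid: ann.exons[eid].gene_id for eid in ann.exons}
    pattern_calls = classify_patterns(exon_calls, exon2gene, deg_genes=deg_genes)
    dee_genes = set(pattern_calls.index)
    venn = venn_gene_exon(deg_genes, dee_genes)

    pcc, pcc_groups = dx.sample_correlation_matrix(np.log2(gene_rpkm + 1.0), design)

    sample_stats = pd.DataFrame({
        "total_reads": {s.sample_id: s.total_reads for s in samples},
        "aligned_reads": {s.sample_id: s.transcriptome_aligned for s in samples},
    })
    detected_genes = {s.sample_id: set(s.gene_counts.index[s.gene_counts > 0])
                      for s in samples}
    detected_tx = {s.sample_id: set(s.tx_counts.index[s.tx_counts > 0])
                   for s in samples}
    detected_exons = {s.sample_id: set(s.exon_counts.index[s.exon_counts > 0])
                      for s in samples}
    mean_rpkm = gene_rpkm.mean(axis=1)
    mean_rate = (gene_counts.mean(axis=1) * 1000.0
                 / tx_lengths.groupby(pd.Series(tx2gene)).max().reindex(gene_counts.index))
    rate_counts = {
        "gene_over_10_tags_per_kb": int((mean_rate > 10).sum()),
        "gene_over_3_rpkm": int((mean_rpkm > 3).sum()),
    }
    summary = summarize_run(
        sample_stats, detected_genes, detected_tx, detected_exons,
        ann.summary(), rate_counts,
    )

    result = PipelineResult(
        config=config, annotation=ann, truth=truth,
        gene_counts=gene_counts, tx_counts=tx_counts, gene_rpkm=gene_rpkm,
        exon_counts=exon_counts, exon_rpkm=exon_rpkm,
        junction_counts=junction_counts, junction_tpm=junction_tpm,
        known_db=known_db, novel_db=novel_db,
        gene_calls=gene_calls, exon_calls=exon_calls,
        pattern_calls=pattern_calls, venn=venn, run_summary=summary,
        pcc=pcc, pcc_groups=pcc_groups, design=design,
    )
    if truth is not None:
        result.metrics = recovery_metrics(result, truth)
    return result


def recovery_metrics(result: PipelineResult, truth: TruthTable) -> dict[str, float]:
    """Planted-truth recovery: DEG sensitivity/FDR, pattern accuracy, junctions."""
    metrics: dict[str, float] = {}
    called = set(result.gene_calls.index[result.gene_calls["significant"]])
    genes = truth.genes.set_index("gene_id")
    planted = set(genes.index[genes["is_DEG"]])
    null_genes = set(genes.index[genes["true_log2fc"].abs() < 1e-9])
    if planted:
        metrics["deg_sensitivity"] = len(called & planted) / len(planted)
    metrics["deg_calls"] = float(len(called))
    if called:
        metrics["deg_empirical_fdr"] = len(called & null_genes) / len(called)
    else:
        metrics["deg_empirical_fdr"] = 0.0

    truth_patterns = genes[genes["pattern"].isin(["1", "2", "3"])]["pattern"]
    if len(truth_patterns):
        predicted = result.pattern_calls["pattern"] if len(result.pattern_calls) else pd.Series(dtype=object)
        correct = sum(
            1 for g, pat in truth_patterns.items()
            if g in predicted.index and predicted[g] == pat
        )
        metrics["pattern_accuracy"] = correct / len(truth_patterns)

    if len(truth.junctions):
        db_pairs = result.novel_db.pairs()
        in_db = [
            (row.donor_exon, row.acceptor_exon) in db_pairs
            for row in truth.junctions.itertuples()
        ]
        metrics["novel_junction_db_recall"] = float(np.mean(in_db))
        tumor_samples = result.design.tumor_samples
        detected = []
        for row in truth.junctions.itertuples():
            jid = f"NJ:{row.gene_id}:{row.donor_exon}|{row.acceptor_exon}"
            if jid not in result.junction_counts.index:
                detected.append(0.0)
                continue
            per_sample = result.junction_counts.loc[jid, tumor_samples]
            detected.append(float((per_sample >= 1).mean()))
        metrics["novel_junction_tumor_detection"] = float(np.mean(detected))
    return metrics


def save_artifacts(
    result: PipelineResult,
    outdir: Path,
    fasta: str | None = None,
    gtf: str | None = None,
    fastqs: dict[str, str] | None = None,
) -> dict[str, str]:
    """Write the deterministic artifact tree plus a manifest of content hashes."""
    outdir = Path(outdir)
    layout = ["alignments", "counts", "expression", "diffexpr", "junctions",
              "patterns", "reports"]
    for sub in layout:
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    if fasta is not None:
        (outdir / "genome.fa").write_text(fasta)
    if gtf is not None:
        (outdir / "annotation.gtf").write_text(gtf)
    if fastqs is not None:
        reads_dir = outdir / "reads"
        reads_dir.mkdir(exist_ok=True)
        for sample, text in fastqs.items():
            (reads_dir / f"{sample}.fastq").write_text(text)

    result.gene_counts.to_csv(outdir / "counts" / "gene_counts.tsv", sep="\t")
    result.tx_counts.to_csv(outdir / "counts" / "transcript_counts.tsv", sep="\t")
    result.exon_counts.to_csv(outdir / "counts" / "exon_counts.tsv", sep="\t")
    result.junction_counts.to_csv(outdir / "counts" / "novel_junction_counts.tsv", sep="\t")
    result.gene_rpkm.to_csv(outdir / "expression" / "gene_rpkm.tsv", sep="\t")
    result.exon_rpkm.to_csv(outdir / "expression" / "exon_rpkm.tsv", sep="\t")
    result.junction_tpm.to_csv(outdir / "expression" / "novel_junction_tpm.tsv", sep="\t")
    result.gene_calls.to_csv(outdir / "diffexpr" / "gene_calls.tsv", sep="\t")
    result.exon_calls.to_csv(outdir / "diffexpr" / "exon_calls.tsv", sep="\t")
    with open(outdir / "diffexpr" / "pcc_matrix.tsv", "w") as fh:
        result.pcc.to_csv(fh, sep="\t")
    with open(outdir / "junctions" / "known_junctions.fa", "w") as fh:
        result.known_db.to_fasta(fh)
    with open(outdir / "junctions" / "novel_junctions.fa", "w") as fh:
        result.novel_db.to_fasta(fh)
    with open(outdir / "junctions" / "novel_junctions.tsv", "w") as fh:
        result.novel_db.to_tsv(fh)
    result.pattern_calls.to_csv(outdir / "patterns" / "pattern_calls.tsv", sep="\t")
    with open(outdir / "reports" / "run_summary.tsv", "w") as fh:
        result.run_summary.to_tsv(fh)
    with open(outdir / "reports" / "metrics.json", "w") as fh:
        json.dump(result.metrics, fh, indent=2, sort_keys=True)

    manifest: dict[str, str] = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest[str(path.relative_to(outdir))] = digest
    payload = {
        "seed": result.config.seed,
        "config": {k: v for k, v in vars(result.config).items()},
        "files": manifest,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=list)
    return manifest


def run_saturation(
    ann: GenomeAnnotation,
    fastq_text: str,
    config: SimulationConfig,
    bins: list[int],
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Raw-read subsampling saturation on one sample's read pool.

    The full pool is aligned to the transcriptome once; each bin of raw
    reads is then drawn from the pool (unaligned reads included) and the
    genes hit by the sampled reads are counted.  Returns the Monte-Carlo
    curve plus the closed-form occupancy expectation for the same bins.
    """
    batch = al.load_fastq(StringIO(fastq_text), config.read_length)
    tx_refs = [(tid, ann.transcript_cdna(tid)) for tid in sorted(ann.transcripts)]
    index = al.build_index(tx_refs)
    hits = al.align_batch(batch.codes, index)
    gene_ids = sorted(ann.genes)
    gene_rank = {g: i for i, g in enumerate(gene_ids)}
    tx_gene_rank = np.array(
        [gene_rank[ann.transcripts[t].gene_id] for t in index.ids], dtype=np.int64
    )
    pair = np.unique(hits.read_idx * len(gene_ids) + tx_gene_rank[hits.ref_idx])
    hit_read = pair // len(gene_ids)
    hit_gene = pair % len(gene_ids)
    pool = len(batch)
    curve = qt.saturation_curve(pool, hit_read, hit_gene, bins, n_replicates, seed)
    expected = qt.occupancy_expectation(pool, hit_read, hit_gene, bins)
    return curve, expected
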