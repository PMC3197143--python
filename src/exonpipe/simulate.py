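"""Synthetic mini-cohort generator with planted ground truth.

The generator emulates a paired tumor/adjacent-tissue study design:
``n_pairs`` patients, each contributing one tumor and one non-tumor sample
of single-end 36-nt reads.  It produces

* a mini genome (one chromosome, random sequence) and a phase-consistent
  GTF annotation in which every transcript's CDS length is a multiple of 3;
* per-sample transcript abundances with log-normal patient effects shared
  within a pair (an overdispersed, negative-binomial-like marginal once
  reads are drawn multinomially), extra tumor-side heterogeneity, and
  planted effects:

  - **DEG genes** — the whole gene shifted by ``deg_log2fc`` in tumor
    (exon pattern 1: every exon moves concordantly);
  - **pattern-2 genes** — two annotated isoforms, one lacking a block of
    exons; only the skip isoform is shifted in tumor, so shared exons move
    in one direction while the skipped block stays flat;
  - **pattern-3 genes** — two annotated isoforms with mutually exclusive
    exon blocks; their shares switch between conditions at constant gene
    output, so one block goes up and the other down;
  - **novel-skip genes** — an *unannotated* in-frame skip isoform (the
    exon 6-8 skip archetype) expressed only in tumor, whose skipped block
    sums to a multiple of 3 so the flanking exons are phase-compatible;

* per-sample FASTQ with reads drawn uniformly along transcripts and
  independent per-base substitution errors; headers encode the source
  transcript and offset for oracle checks.

All outputs are deterministic functions of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from exonpipe.annotation import GenomeAnnotation, annotation_from_string

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the paired design the pipeline targets: 10 patient
    pairs, 36-nt single-end reads, planted |log2FC| = 2 differential genes,
    and a tumor-only in-frame exon-skip isoform at full inclusion.
    """

    seed: int = 0
    n_pairs: int = 10
    n_genes: int = 150
    exons_per_gene: tuple[int, int] = (4, 10)
    exon_length: tuple[int, int] = (90, 240)
    intron_length: tuple[int, int] = (60, 150)
    intergenic_gap: int = 300
    read_length: int = 36
    min_overhang: int = 8
    reads_per_sample: int = 200_000
    error_rate: float = 0.005
    # expression model (log2 scale)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    patient_log2_sd: float = 0.5
    sample_log2_sd: float = 0.15
    tumor_extra_log2_sd: float = 0.2
    # planted effects
    deg_fraction: float = 0.08
    deg_log2fc: float = 2.0
    n_pattern2: int = 4
    pattern2_log2fc: float = 2.0
    pattern2_shares: tuple[float, float] = (0.7, 0.3)  # (full, skip) isoform
    n_pattern3: int = 4
    pattern3_shares_normal: tuple[float, float] = (0.7, 0.3)
    pattern3_shares_tumor: tuple[float, float] = (0.3, 0.7)
    n_novel_skip: int = 3
    novel_skip_span: int = 3  # number of consecutive exons skipped
    novel_skip_inclusion_tumor: float = 1.0
    novel_skip_inclusion_normal: float = 0.0

    def __post_init__(self) -> None:
        for name in ("deg_fraction", "error_rate",
                     "novel_skip_inclusion_tumor", "novel_skip_inclusion_normal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not np.isfinite([self.deg_log2fc, self.pattern2_log2fc]).all():
            raise ValueError("effect sizes must be finite")
        flank = self.read_length - self.min_overhang
        if self.exon_length[0] < flank:
            raise ValueError(
                f"minimum exon length {self.exon_length[0]} is below the junction "
                f"flank requirement read_length - min_overhang = {flank}"
            )
        n_special = self.n_pattern2 + self.n_pattern3 + self.n_novel_skip
        if self.n_genes and n_special > self.n_genes:
            raise ValueError(
                f"{n_special} pattern/skip genes requested but only {self.n_genes} genes"
            )

    @property
    def sample_ids(self) -> list[str]:
        out = []
        for p in range(1, self.n_pairs + 1):
            out.append(f"P{p:02d}T")
            out.append(f"P{p:02d}N")
        return out

    @property
    def patient_ids(self) -> list[str]:
        return [f"P{p:02d}" for p in range(1, self.n_pairs + 1)]

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for p in self.patient_ids:
            rows.append({"sample_id": f"{p}T", "patient_id": p, "condition": "tumor"})
            rows.append({"sample_id": f"{p}N", "patient_id": p, "condition": "non-tumor"})
        return pd.DataFrame(rows)


@dataclass
class TruthTable:
    """Planted ground truth for recovery tests.

    ``genes``: gene_id, role, is_DEG, direction, true_log2fc (expected
    gene-level shift), pattern label in {"1","2","3","none"}.
    ``exons``: exon_id, gene_id, is_DEE, direction.
    ``junctions``: planted novel junctions (gene, donor/acceptor exon,
    tumor_enriched).  ``novel_transcripts`` maps each unannotated skip
    isoform id to its exon-id chain in transcription order.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    junctions: pd.DataFrame
    novel_transcripts: dict[str, list[str]] = field(default_factory=dict)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(directory / "truth_genes.tsv", sep="\t", index=False)
        self.exons.to_csv(directory / "truth_exons.tsv", sep="\t", index=False)
        self.junctions.to_csv(directory / "truth_junctions.tsv", sep="\t", index=False)


@dataclass
class _Isoform:
    transcript_id: str
    exon_indices: list[int]  # transcription-order indices into the gene's exon list
    annotated: bool
    share_normal: float
    share_tumor: float


@dataclass
class _GenePlan:
    gene_id: str
    role: str  # null | deg | pattern2 | pattern3 | novel_skip
    strand: str
    exon_lengths: list[int]  # transcription order
    intron_lengths: list[int]
    isoforms: list[_Isoform]
    deg_direction: int = 0  # +1 / -1 for DEG genes
    blocks: dict[str, tuple[int, int]] = field(default_factory=dict)  # [start, end) indices

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    def exon_id(self, idx: int) -> str:
        return f"{self.gene_id}.E{idx + 1:02d}"


def _round_to_frame(total: int) -> int:
    """Adjustment (0-2 nt) making ``total`` a multiple of 3."""
    return (3 - total % 3) % 3


def _plan_cohort(config: SimulationConfig) -> list[_GenePlan]:
    """Deterministic gene-structure plan shared by all generator stages."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    plans: list[_GenePlan] = []
    roles = (
        ["novel_skip"] * config.n_novel_skip
        + ["pattern2"] * config.n_pattern2
        + ["pattern3"] * config.n_pattern3
    )
    n_deg = int(round(config.deg_fraction * config.n_genes))
    n_deg = min(n_deg, max(config.n_genes - len(roles), 0))
    roles += ["deg"] * n_deg
    roles += ["null"] * (config.n_genes - len(roles))

    lo, hi = config.exons_per_gene
    span = config.novel_skip_span
    for g, role in enumerate(roles):
        gene_id = f"G{g + 1:03d}"
        if role == "novel_skip":
            n_exons = max(hi, span + 7)  # archetype: 10 exons, skip 6-8
        elif role in ("pattern2", "pattern3"):
            n_exons = max(int(rng.integers(lo, hi + 1)), 2 * span + 5)
        else:
            n_exons = int(rng.integers(lo, hi + 1))
        lengths = rng.integers(config.exon_length[0], config.exon_length[1] + 1,
                               size=n_exons).tolist()
        introns = rng.integers(config.intron_length[0], config.intron_length[1] + 1,
                               size=max(n_exons - 1, 0)).tolist()
        strand = "+" if rng.random() < 0.5 else "-"
        plan = _GenePlan(gene_id, role, strand, lengths, introns, [])

        def _frame_block(start: int, end: int) -> tuple[int, int]:
            # pad the block's last exon so the block length is a multiple of 3
            lengths[end - 1] += _round_to_frame(sum(lengths[start:end]))
            return (start, end)

        all_idx = list(range(n_exons))
        if role == "novel_skip":
            block = _frame_block(5, 5 + span)  # skip exons 6..8 (1-based)
            plan.blocks["skip"] = block
            plan.isoforms = [
                _Isoform(f"{gene_id}.T1", all_idx, True, 1.0, 1.0),
            ]
        elif role == "pattern2":
            block = _frame_block(4, 4 + span)
            plan.blocks["skip"] = block
            keep = [i for i in all_idx if not block[0] <= i < block[1]]
            a, b = config.pattern2_shares
            plan.isoforms = [
                _Isoform(f"{gene_id}.T1", all_idx, True, a, a),
                _Isoform(f"{gene_id}.T2", keep, True, b,
                         b * 2.0 ** config.pattern2_log2fc),
            ]
        elif role == "pattern3":
            b1 = _frame_block(2, 2 + span)
            b2 = _frame_block(3 + span, 3 + 2 * span)
            plan.blocks["block1"] = b1
            plan.blocks["block2"] = b2
            exons_a = [i for i in all_idx if not b2[0] <= i < b2[1]]  # A keeps block1
            exons_b = [i for i in all_idx if not b1[0] <= i < b1[1]]  # B keeps block2
            (an, bn) = config.pattern3_shares_normal
            (at, bt) = config.pattern3_shares_tumor
            plan.isoforms = [
                _Isoform(f"{gene_id}.T1", exons_a, True, an, at),
                _Isoform(f"{gene_id}.T2", exons_b, True, bn, bt),
            ]
        else:
            plan.isoforms = [_Isoform(f"{gene_id}.T1", all_idx, True, 1.0, 1.0)]

        # whole-transcript CDS must close the frame: total length % 3 == 0;
        # adjust the last exon, which never belongs to a planted block
        lengths[-1] += _round_to_frame(sum(lengths))
        for iso in plan.isoforms:
            iso_len = sum(lengths[i] for i in iso.exon_indices)
            assert iso_len % 3 == 0, f"{iso.transcript_id}: frame not closed"
        plans.append(plan)

    # DEG directions alternate deterministically: half up, half down, so the
    # planted shifts can be output-balanced at the expression step
    deg_serial = 0
    for plan in plans:
        if plan.role == "deg":
            plan.deg_direction = 1 if deg_serial % 2 == 0 else -1
            deg_serial += 1
    return plans


def _novel_skip_isoform(plan: _GenePlan) -> tuple[str, list[int]]:
    block = plan.blocks["skip"]
    keep = [i for i in range(plan.n_exons) if not block[0] <= i < block[1]]
    return f"{plan.gene_id}.S1", keep


def generate_genome_annotation(
    config: SimulationConfig,
) -> tuple[str, str, GenomeAnnotation]:
    """Emit (genome FASTA text, GTF text, loaded GenomeAnnotation).

    Every transcript is fully coding with CDS length a multiple of 3; for
    every planted novel-skip gene the skipped block also sums to a multiple
    of 3, so the flanking exons end up phase-compatible.
    """
    plans = _plan_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    if not plans:
        return "", "", annotation_from_string("", None)

    chrom = "chr1"
    chunks: list[np.ndarray] = []
    cursor = 0
    gtf = StringIO()
    for plan in plans:
        cursor += config.intergenic_gap
        chunks.append(rng.integers(0, 4, size=config.intergenic_gap).astype(np.uint8))
        # genomic order of exons: transcription order on +, reversed on -
        order = list(range(plan.n_exons))
        if plan.strand == "-":
            order = order[::-1]
        exon_coords: dict[int, tuple[int, int]] = {}
        for j, tx_idx in enumerate(order):
            length = plan.exon_lengths[tx_idx]
            exon_coords[tx_idx] = (cursor, cursor + length)
            chunks.append(rng.integers(0, 4, size=length).astype(np.uint8))
            cursor += length
            if j < plan.n_exons - 1:
                intron = plan.intron_lengths[j]
                chunks.append(rng.integers(0, 4, size=intron).astype(np.uint8))
                cursor += intron
        for iso in plan.isoforms:
            if not iso.annotated:
                continue
            genomic_order = sorted(iso.exon_indices, key=lambda i: exon_coords[i][0])
            for tx_idx in genomic_order:
                start, end = exon_coords[tx_idx]
                attrs = (
                    f'gene_id "{plan.gene_id}"; transcript_id "{iso.transcript_id}"; '
                    f'exon_id "{plan.exon_id(tx_idx)}";'
                )
                for feature in ("exon", "CDS"):
                    gtf.write(
                        f"{chrom}\texonpipe\t{feature}\t{start + 1}\t{end}\t.\t"
                        f"{plan.strand}\t.\t{attrs}\n"
                    )
    chunks.append(rng.integers(0, 4, size=config.intergenic_gap).astype(np.uint8))

    genome_codes = np.concatenate(chunks)
    genome_seq = _BASES[genome_codes].tobytes().decode("ascii")
    fasta = f">{chrom}\n" + "\n".join(
        genome_seq[i : i + 80] for i in range(0, len(genome_seq), 80)
    ) + "\n"
    gtf_text = gtf.getvalue()
    ann = annotation_from_string(gtf_text, fasta)
    return fasta, gtf_text, ann


def generate_expression_profiles(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthTable]:
    """Per-sample transcript abundances (transcripts x samples) plus truth.

    Rows include the unannotated tumor skip isoforms; their exon chains are
    listed in ``TruthTable.novel_transcripts``.
    """
    plans = _plan_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    samples = config.sample_ids
    n_pairs = config.n_pairs

    tx_rows: list[str] = []
    abund: list[np.ndarray] = []
    gene_truth: list[dict] = []
    exon_truth: list[dict] = []
    junction_truth: list[dict] = []
    novel_transcripts: dict[str, list[str]] = {}

    # Effective isoform sets: for novel-skip genes the unannotated skip
    # isoform enters here with its tumor/normal inclusion shares.
    eff_isoforms: list[list[_Isoform]] = []
    for plan in plans:
        isoforms = list(plan.isoforms)
        if plan.role == "novel_skip":
            skip_id, keep = _novel_skip_isoform(plan)
            inc_t = config.novel_skip_inclusion_tumor
            inc_n = config.novel_skip_inclusion_normal
            isoforms = [
                _Isoform(isoforms[0].transcript_id, isoforms[0].exon_indices, True,
                         1.0 - inc_n, 1.0 - inc_t),
                _Isoform(skip_id, keep, False, inc_n, inc_t),
            ]
        eff_isoforms.append(isoforms)

    # Baselines, then an exact output balance on the *read-yield* scale:
    # reads are drawn with weight abundance x (transcript length - L + 1),
    # so expected read totals per condition involve length-weighted shares.
    # Down-shifted genes' baselines are scaled so planted up- and
    # down-shifts cancel in expected total read yield; read sampling is
    # compositional (fixed reads per sample), and without the balance every
    # null gene's count expectation would shift, violating the generator's
    # contract that non-planted genes share expectation across conditions.
    # Biologically this casts tumor-down genes as highly expressed
    # normal-tissue genes (the liver-enzyme archetype).
    L = config.read_length

    def _yield_weight(plan: _GenePlan, iso: _Isoform) -> float:
        length = sum(plan.exon_lengths[j] for j in iso.exon_indices)
        return float(max(length - L + 1, 1))

    bases = np.empty(len(plans))
    s_normal = np.empty(len(plans))
    s_tumor = np.empty(len(plans))
    for i, plan in enumerate(plans):
        if plan.role == "novel_skip":
            # planted skip genes sit 1.5 log2 units above the cohort mean so
            # the junction event is well covered in every tumor sample
            bases[i] = 2.0 ** (config.baseline_log2_mean + 1.5)
        elif plan.role in ("deg", "pattern2", "pattern3"):
            # planted-effect genes sit at mid-range expression (narrow
            # spread): recovery should measure the effect, not the draw of
            # an extreme baseline, and no single gene may dominate output
            bases[i] = 2.0 ** rng.normal(
                config.baseline_log2_mean, min(0.5, config.baseline_log2_sd)
            )
        else:
            bases[i] = 2.0 ** rng.normal(config.baseline_log2_mean,
                                         config.baseline_log2_sd)
        deg_factor = (
            2.0 ** (plan.deg_direction * config.deg_log2fc)
            if plan.role == "deg" else 1.0
        )
        s_normal[i] = sum(
            iso.share_normal * _yield_weight(plan, iso) for iso in eff_isoforms[i]
        )
        s_tumor[i] = deg_factor * sum(
            iso.share_tumor * _yield_weight(plan, iso) for iso in eff_isoforms[i]
        )
    up = s_tumor > s_normal
    down = s_tumor < s_normal
    up_excess = float((bases[up] * (s_tumor[up] - s_normal[up])).sum())
    down_deficit = float((bases[down] * (s_normal[down] - s_tumor[down])).sum())
    if up_excess > 0 and down_deficit > 0:
        bases[down] *= up_excess / down_deficit
        s_tumor[down] *= up_excess / down_deficit  # keep s arrays consistent
        s_normal[down] *= up_excess / down_deficit
    elif up_excess != down_deficit:
        logger.warning(
            "planted shifts cannot be output-balanced (up excess %.1f, "
            "down deficit %.1f); null genes will carry a compositional shift",
            up_excess, down_deficit,
        )

    for plan_idx, plan in enumerate(plans):
        base = bases[plan_idx]
        patient = 2.0 ** rng.normal(0.0, config.patient_log2_sd, size=n_pairs)
        tumor_noise = 2.0 ** (
            rng.normal(0.0, config.sample_log2_sd, size=n_pairs)
            + rng.normal(0.0, config.tumor_extra_log2_sd, size=n_pairs)
        )
        normal_noise = 2.0 ** rng.normal(0.0, config.sample_log2_sd, size=n_pairs)
        deg_factor = (
            2.0 ** (plan.deg_direction * config.deg_log2fc) if plan.role == "deg" else 1.0
        )
        gene_tumor = base * patient * tumor_noise * deg_factor
        gene_normal = base * patient * normal_noise

        isoforms = eff_isoforms[plan_idx]
        if plan.role == "novel_skip":
            skip_iso = isoforms[1]
            novel_transcripts[skip_iso.transcript_id] = [
                plan.exon_id(j) for j in skip_iso.exon_indices
            ]
            block = plan.blocks["skip"]
            junction_truth.append({
                "gene_id": plan.gene_id,
                "donor_exon": plan.exon_id(block[0] - 1),
                "acceptor_exon": plan.exon_id(block[1]),
                "skip_isoform": skip_iso.transcript_id,
                "tumor_enriched": skip_iso.share_tumor > skip_iso.share_normal,
            })

        # per-exon expected (share-weighted) output in each condition
        exon_out_n = np.zeros(plan.n_exons)
        exon_out_t = np.zeros(plan.n_exons)
        for iso in isoforms:
            tx_rows.append(iso.transcript_id)
            profile = np.empty(len(samples))
            profile[0::2] = gene_tumor * iso.share_tumor
            profile[1::2] = gene_normal * iso.share_normal
            abund.append(profile)
            for j in iso.exon_indices:
                exon_out_n[j] += iso.share_normal
                exon_out_t[j] += iso.share_tumor

        # expected gene-level read-yield shift (what counts actually do)
        gene_lfc = float(np.log2(s_tumor[plan_idx] / s_normal[plan_idx]))
        pattern = {"deg": "1", "pattern2": "2", "pattern3": "3"}.get(plan.role, "none")
        gene_truth.append({
            "gene_id": plan.gene_id, "role": plan.role,
            "is_DEG": plan.role == "deg",
            "direction": {1: "up", -1: "down"}.get(plan.deg_direction, ""),
            "true_log2fc": gene_lfc, "pattern": pattern,
        })
        deg_dir = {1: "up", -1: "down"}.get(plan.deg_direction, "")
        for i in range(plan.n_exons):
            if plan.role == "deg":
                is_dee, direction = True, deg_dir
            elif exon_out_n[i] == 0 and exon_out_t[i] == 0:
                is_dee, direction = False, ""
            else:
                # expected log2 shift of this exon's output between conditions
                with np.errstate(divide="ignore"):
                    shift = np.log2(exon_out_t[i]) - np.log2(exon_out_n[i])
                if abs(shift) > 0.25:  # planted structural shifts are all >= ~0.9
                    is_dee = True
                    direction = "up" if shift > 0 else "down"
                else:
                    is_dee, direction = False, ""
            exon_truth.append({
                "exon_id": plan.exon_id(i), "gene_id": plan.gene_id,
                "is_DEE": is_dee, "direction": direction,
            })

    abund_df = pd.DataFrame(
        np.array(abund) if abund else np.empty((0, len(samples))),
        index=pd.Index(tx_rows, name="transcript_id"),
        columns=samples,
    )
    truth = TruthTable(
        genes=pd.DataFrame(gene_truth, columns=[
            "gene_id", "role", "is_DEG", "direction", "true_log2fc", "pattern"]),
        exons=pd.DataFrame(exon_truth, columns=["exon_id", "gene_id", "is_DEE", "direction"]),
        junctions=pd.DataFrame(junction_truth, columns=[
            "gene_id", "donor_exon", "acceptor_exon", "skip_isoform", "tumor_enriched"]),
        novel_transcripts=novel_transcripts,
    )
    return abund_df, truth


def _transcript_sequence(
    annotation: GenomeAnnotation, transcript_id: str,
    novel_transcripts: dict[str, list[str]],
) -> str:
    if transcript_id in annotation.transcripts:
        return annotation.transcript_cdna(transcript_id)
    chain = novel_transcripts[transcript_id]
    return "".join(
        annotation.extract_sequence(e.chrom, e.start, e.end, e.strand)
        for e in (annotation.exons[eid] for eid in chain)
    )


def simulate_reads(
    annotation: GenomeAnnotation,
    abundances: pd.DataFrame,
    config: SimulationConfig,
    novel_transcripts: dict[str, list[str]] | None = None,
) -> dict[str, str]:
    """Simulate per-sample FASTQ text from transcript abundances.

    Reads start uniformly along each transcript; a transcript's sampling
    weight is abundance times its number of valid start positions, so
    junction-spanning windows of skip isoforms are covered.  Per-base
    substitution errors occur independently at ``config.error_rate``.
    Headers are ``sample:transcript:start:serial`` for oracle checks.
    """
    novel_transcripts = novel_transcripts or {}
    L = config.read_length
    seqs: dict[str, np.ndarray] = {}
    for tid in abundances.index:
        s = _transcript_sequence(annotation, tid, novel_transcripts)
        if len(s) < L:
            logger.warning("transcript %s shorter than read length; excluded", tid)
            continue
        from exonpipe.align import encode

        seqs[tid] = encode(s)

    out: dict[str, str] = {}
    for s_idx, sample in enumerate(abundances.columns):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404, s_idx]))
        tids = [t for t in abundances.index if t in seqs]
        weights = np.array([
            abundances.at[t, sample] * (len(seqs[t]) - L + 1) for t in tids
        ])
        lines: list[str] = []
        if weights.sum() > 0 and config.reads_per_sample > 0:
            counts = rng.multinomial(config.reads_per_sample, weights / weights.sum())
            serial = 0
            for t, c in zip(tids, counts):
                if c == 0:
                    continue
                codes = seqs[t]
                starts = rng.integers(0, len(codes) - L + 1, size=c)
                windows = np.lib.stride_tricks.sliding_window_view(codes, L)[starts].copy()
                if config.error_rate > 0:
                    err = rng.random(windows.shape) < config.error_rate
                    n_err = int(err.sum())
                    if n_err:
                        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                        windows[err] = (windows[err] + shift) % 4
                qual = "I" * L
                for i in range(c):
                    lines.append(
                        f"@{sample}:{t}:{int(starts[i])}:{serial}\n"
                        f"{_BASES[windows[i]].tobytes().decode('ascii')}\n+\n{qual}\n"
                    )
                    serial += 1
        out[sample] = "".join(lines)
    return out


def write_cohort(
    config: SimulationConfig, directory: str | Path
) -> tuple[GenomeAnnotation, pd.DataFrame, TruthTable]:
    """Generate and write the full synthetic cohort to ``directory``.

    Writes genome.fa, annotation.gtf, per-sample FASTQ, the sample sheet,
    abundance matrix and truth tables; returns the in-memory objects.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta, gtf, ann = generate_genome_annotation(config)
    (directory / "genome.fa").write_text(fasta)
    (directory / "annotation.gtf").write_text(gtf)
    abund, truth = generate_expression_profiles(ann, config)
    abund.to_csv(directory / "abundances.tsv", sep="\t")
    truth.write(directory)
    config.sample_sheet().to_csv(directory / "samples.tsv", sep="\t", index=False)
    fastqs = simulate_reads(ann, abund, config, truth.novel_transcripts)
    fastq_dir = directory / "reads"
    fastq_dir.mkdir(exist_ok=True)
    for sample, text in fastqs.items():
        (fastq_dir / f"{sample}.fastq").write_text(text)
    return ann, abund, truth
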