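"""Counting, RPKM/TPM normalization and saturation analysis.

Multiread rules
---------------
Gene level: a read hitting several transcripts is assigned to the hit
transcript with the highest count of *uniquely* mapped reads (two-pass;
ties break to the lexicographically smallest transcript id), so every
aligned read contributes exactly once and gene counts are the sum over the
gene's transcripts.

Exon level: a genome-stage read adds one count to every exon it overlaps
(>= 1 nt) provided its total number of alignment hits is at most 30;
beyond 30 hits the read is discarded as repeat-derived.  A read mapped to
an exon-exon junction adds one count to each of the two junctional exons.

Units
-----
RPKM = count * 1e9 / (feature length in nt * total mapped reads in the
sample).  Junction expression uses tags per million: count * 1e6 / total
mapped reads.  Gene length for RPKM is the length of the gene's most
abundant ("major") transcript in that sample by default, consistent with
the assign-to-most-abundant multiread rule; a union-exon mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from exonpipe.align import HitTable
from exonpipe.annotation import GenomeAnnotation

logger = logging.getLogger(__name__)

MAX_EXON_LEVEL_HITS = 30


# ---------------------------------------------------------------------------
# gene-level assignment


def assign_reads_gene_level(
    hits: HitTable,
    reference_ids: list[str],
    tx2gene: dict[str, str],
) -> tuple[pd.Series, pd.Series]:
    """Two-pass multiread assignment; returns (transcript counts, gene counts).

    Pass 1 counts uniquely mapping reads per transcript; pass 2 assigns each
    multiread to its hit transcript with the highest pass-1 count, ties
    resolved to the lexicographically smallest transcript id.
    """
    n_refs = len(reference_ids)
    tx_counts = np.zeros(n_refs, dtype=np.int64)
    if len(hits):
        # distinct (read, transcript) pairs: multiple offsets in one
        # transcript still leave the read unique to that transcript
        pair = hits.read_idx * n_refs + hits.ref_idx
        pair = np.unique(pair)
        read = pair // n_refs
        ref = pair % n_refs
        _, first, degree = np.unique(read, return_index=True, return_counts=True)
        is_unique = np.repeat(degree == 1, degree)
        tx_counts += np.bincount(ref[is_unique], minlength=n_refs)

        multi = ~is_unique
        if multi.any():
            lexrank = np.argsort(np.argsort(reference_ids))
            m_read, m_ref = read[multi], ref[multi]
            order = np.lexsort((lexrank[m_ref], -tx_counts[m_ref], m_read))
            m_read, m_ref = m_read[order], m_ref[order]
            _, first = np.unique(m_read, return_index=True)
            tx_counts += np.bincount(m_ref[first], minlength=n_refs)

    tx_series = pd.Series(tx_counts, index=pd.Index(reference_ids, name="transcript_id"),
                          name="count")
    genes = pd.Index(sorted({tx2gene[t] for t in reference_ids}), name="gene_id")
    gene_series = (
        tx_series.groupby([tx2gene[t] for t in reference_ids]).sum()
        .reindex(genes, fill_value=0).rename("count")
    )
    return tx_series, gene_series


# ---------------------------------------------------------------------------
# exon-level assignment


class ExonLocator:
    """Overlap queries of read windows against genomic exon intervals.

    Uses a vectorized double-binary-search when the per-chromosome exon
    intervals are non-overlapping (always true for the synthetic genomes);
    falls back to a linear candidate scan otherwise.
    """

    def __init__(self, annotation: GenomeAnnotation):
        self.exon_ids: list[str] = sorted(annotation.exons)
        self._exon_rank = {e: i for i, e in enumerate(self.exon_ids)}
        self.chroms: dict[str, dict[str, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for eid in self.exon_ids:
            rec = annotation.exons[eid]
            by_chrom.setdefault(rec.chrom, []).append(
                (rec.start, rec.end, self._exon_rank[eid])
            )
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            idx = np.array([r[2] for r in rows], dtype=np.int64)
            disjoint = bool((ends[:-1] <= starts[1:]).all()) if len(rows) > 1 else True
            self.chroms[chrom] = {
                "starts": starts, "ends": ends, "idx": idx,
                "cummax_end": np.maximum.accumulate(ends),
                "disjoint": np.array([disjoint]),
            }

    def overlaps(self, chrom: str, pos: np.ndarray, length: int) -> tuple[np.ndarray, np.ndarray]:
        """(query row, exon rank) pairs for windows [pos, pos+length)."""
        tab = self.chroms.get(chrom)
        if tab is None or len(pos) == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        starts, ends, idx = tab["starts"], tab["ends"], tab["idx"]
        if tab["disjoint"][0]:
            lo = np.searchsorted(ends, pos, side="right")
            hi = np.searchsorted(starts, pos + length, side="left")
            cnt = np.maximum(hi - lo, 0)
            total = int(cnt.sum())
            rows = np.repeat(np.arange(len(pos)), cnt)
            base = np.repeat(np.cumsum(cnt) - cnt, cnt)
            cand = np.repeat(lo, cnt) + (np.arange(total) - base)
            return rows, idx[cand]
        rows_out, exon_out = [], []
        cummax = tab["cummax_end"]
        for q, p in enumerate(pos):
            hi = np.searchsorted(starts, p + length, side="left")
            j = hi - 1
            while j >= 0 and cummax[j] > p:
                if ends[j] > p:
                    rows_out.append(q)
                    exon_out.append(idx[j])
                j -= 1
        return np.array(rows_out, np.int64), np.array(exon_out, np.int64)


@dataclass
class ExonCountResult:
    counts: pd.Series  # indexed by exon_id
    n_discarded_multireads: int


def assign_reads_exon_level(
    genome_hits: HitTable,
    genome_reference_ids: list[str],
    junction_exon_pairs: tuple[np.ndarray, np.ndarray] | None,
    locator: ExonLocator,
    read_length: int,
    max_hits: int = MAX_EXON_LEVEL_HITS,
) -> ExonCountResult:
    """Fan-out exon counting from genome- and junction-stage alignments.

    ``junction_exon_pairs`` is (read indices, exon ranks) contributed by
    junction-stage reads — one entry per (read, junctional exon), built by
    the caller from overhang-valid junction hits.
    """
    contrib_read: list[np.ndarray] = []
    contrib_exon: list[np.ndarray] = []
    n_discarded = 0

    if len(genome_hits):
        hit_counts = np.bincount(genome_hits.read_idx)
        discard = hit_counts[genome_hits.read_idx] > max_hits
        n_discarded = int(len(np.unique(genome_hits.read_idx[discard])))
        keep = ~discard
        for chrom_idx, chrom in enumerate(genome_reference_ids):
            sel = keep & (genome_hits.ref_idx == chrom_idx)
            if not sel.any():
                continue
            pos = genome_hits.offset[sel]
            rows, exon_rank = locator.overlaps(chrom, pos, read_length)
            if len(rows):
                contrib_read.append(genome_hits.read_idx[sel][rows])
                contrib_exon.append(exon_rank)

    if junction_exon_pairs is not None and len(junction_exon_pairs[0]):
        contrib_read.append(junction_exon_pairs[0])
        contrib_exon.append(junction_exon_pairs[1])

    n_exons = len(locator.exon_ids)
    if contrib_read:
        read = np.concatenate(contrib_read)
        exon = np.concatenate(contrib_exon)
        # one count per distinct (read, exon) pair
        pair = np.unique(read * n_exons + exon)
        counts = np.bincount(pair % n_exons, minlength=n_exons)
    else:
        counts = np.zeros(n_exons, dtype=np.int64)
    series = pd.Series(counts, index=pd.Index(locator.exon_ids, name="exon_id"),
                       name="count")
    return ExonCountResult(series, n_discarded)


# ---------------------------------------------------------------------------
# normalization


def compute_rpkm(
    counts: pd.DataFrame, lengths: pd.Series, totals: pd.Series
) -> pd.DataFrame:
    """RPKM = count * 1e9 / (length_nt * total mapped reads per sample)."""
    lengths = lengths.reindex(counts.index)
    totals = totals.reindex(counts.columns)
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero total mapped reads in sample(s) {bad}")
    return counts * 1e9 / np.outer(lengths.to_numpy(), totals.to_numpy())


def gene_lengths_major_transcript(
    tx_counts: pd.DataFrame, tx_lengths: pd.Series, tx2gene: dict[str, str]
) -> pd.DataFrame:
    """Per-sample gene length = length of the gene's highest-count transcript.

    Ties break to the lexicographically smallest transcript id (the same
    tie-break used by multiread assignment).
    """
    df = tx_counts.copy()
    df.index.name = "transcript_id"
    genes = pd.Series({t: tx2gene[t] for t in df.index}, name="gene_id")
    out = {}
    order = np.argsort(df.index)  # lexicographic tie-break via stable sort
    for sample in df.columns:
        col = df[sample].to_numpy()
        tmp = pd.DataFrame({
            "gene_id": genes.to_numpy(),
            "count": col,
            "length": tx_lengths.reindex(df.index).to_numpy(),
            "tid": df.index,
        }).sort_values(["gene_id", "count", "tid"], ascending=[True, False, True])
        major = tmp.groupby("gene_id", sort=True).first()
        out[sample] = major["length"]
    return pd.DataFrame(out)


def compute_gene_rpkm(
    gene_counts: pd.DataFrame,
    tx_counts: pd.DataFrame,
    tx_lengths: pd.Series,
    tx2gene: dict[str, str],
    totals: pd.Series,
    length_mode: str = "major",
    union_lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Gene RPKM with per-sample major-transcript length (or union-exon)."""
    if length_mode == "union":
        if union_lengths is None:
            raise ValueError("union_lengths required for length_mode='union'")
        return compute_rpkm(gene_counts, union_lengths, totals)
    if length_mode != "major":
        raise ValueError(f"unknown length_mode {length_mode!r}")
    lengths = gene_lengths_major_transcript(tx_counts, tx_lengths, tx2gene)
    lengths = lengths.reindex(index=gene_counts.index, columns=gene_counts.columns)
    totals = totals.reindex(gene_counts.columns)
    if (totals <= 0).any():
        raise ValueError("zero total mapped reads")
    return gene_counts * 1e9 / (lengths * totals)


def compute_tpm_junction(counts: pd.DataFrame, totals: pd.Series) -> pd.DataFrame:
    """Tags per million: count * 1e6 / total mapped reads of the sample."""
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any():
        raise ValueError("zero total mapped reads")
    return counts * 1e6 / totals


# ---------------------------------------------------------------------------
# saturation analysis


def saturation_curve(
    pool_size: int,
    hit_read_idx: np.ndarray,
    hit_gene_idx: np.ndarray,
    bins: list[int],
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Genes detected (>= 1 mapped read) versus randomly sampled raw-read depth.

    Sampling draws ``bin`` raw reads from the pool of ``pool_size`` without
    replacement; detection is evaluated on the pre-computed alignment of the
    full pool (``hit_read_idx``/``hit_gene_idx`` pairs), which is equivalent
    to aligning the sampled reads since alignment is per-read deterministic.
    Returns long-format (bin, replicate, genes_detected) plus per-bin means.
    """
    for b in bins:
        if b > pool_size:
            raise ValueError(f"bin {b} exceeds pool size {pool_size}")
        if b < 0:
            raise ValueError("bin sizes must be nonnegative")
    rows = []
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed + r, 77]))
        for b in bins:
            if b == 0:
                rows.append({"bin": 0, "replicate": r, "genes_detected": 0})
                continue
            if b == pool_size:
                sampled_mask = np.ones(pool_size, dtype=bool)
            else:
                chosen = rng.choice(pool_size, size=b, replace=False)
                sampled_mask = np.zeros(pool_size, dtype=bool)
                sampled_mask[chosen] = True
            genes = np.unique(hit_gene_idx[sampled_mask[hit_read_idx]])
            rows.append({"bin": b, "replicate": r, "genes_detected": len(genes)})
    return pd.DataFrame(rows)


def occupancy_expectation(
    pool_size: int,
    hit_read_idx: np.ndarray,
    hit_gene_idx: np.ndarray,
    bins: list[int],
) -> pd.Series:
    """Closed-form expected detection: E[detected] = sum_g 1 - (1 - p_g)^n.

    ``p_g`` is each gene's per-read detection probability estimated from the
    full pool.  Used as an independent check on the Monte-Carlo curve.
    """
    pairs = np.unique(hit_read_idx * (hit_gene_idx.max() + 1 if len(hit_gene_idx) else 1)
                      + hit_gene_idx) if len(hit_read_idx) else np.empty(0, np.int64)
    if len(pairs):
        gene_of_pair = pairs % (hit_gene_idx.max() + 1)
        m_g = np.bincount(gene_of_pair)
        m_g = m_g[m_g > 0]
    else:
        m_g = np.empty(0, np.int64)
    p_g = m_g / pool_size
    return pd.Series(
        {b: float(np.sum(1.0 - (1.0 - p_g) ** b)) for b in bins}, name="expected_genes"
    )
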