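"""Run summaries and derived percentage statistics.

Printed percentages use half-up decimal rounding so that recomputing any
published-style figure from its numerator and denominator reproduces the
printed value exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import IO

import pandas as pd


def pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator, half-up rounded to ``decimals``."""
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class RunSummary:
    """Per-sample alignment/detection tallies plus cohort-level fractions."""

    per_sample: pd.DataFrame  # index sample_id; columns total_reads, aligned_reads,
    #                           mapped_genes, mapped_transcripts, mapped_exons
    annotation_totals: dict[str, int]
    cohort: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        bad = self.per_sample[
            self.per_sample["aligned_reads"] > self.per_sample["total_reads"]
        ]
        if len(bad):
            raise ValueError(f"aligned > total for samples {list(bad.index)}")

    def to_tsv(self, handle: IO[str]) -> None:
        self.per_sample.to_csv(handle, sep="\t")
        handle.write("\n")
        for key, value in self.cohort.items():
            handle.write(f"{key}\t{value}\n")

    def consistency_table(self) -> pd.DataFrame:
        """Audit: every reported percentage recomputed from its num/den."""
        rows = []
        for key, value in self.cohort.items():
            if not key.endswith("_pct"):
                continue
            stem = key[:-4]
            num = self.cohort.get(f"{stem}_count")
            den = self.annotation_totals.get(stem.split("_")[0] + "s")
            if num is None or den in (None, 0):
                continue
            rows.append({
                "statistic": key, "numerator": num, "denominator": den,
                "printed": value, "recomputed": pct(num, den, 1),
            })
        return pd.DataFrame(rows)


def summarize_run(
    sample_stats: pd.DataFrame,
    detected_genes: dict[str, set[str]],
    detected_transcripts: dict[str, set[str]],
    detected_exons: dict[str, set[str]],
    annotation_totals: dict[str, int],
    gene_rate_counts: dict[str, int] | None = None,
) -> RunSummary:
    """Assemble the per-sample table and cohort detection fractions.

    ``sample_stats`` needs columns total_reads and aligned_reads per sample;
    detection sets are per sample.  ``gene_rate_counts`` may carry
    threshold-passing counts (e.g. genes over 10 tags/kb or over 3 RPKM)
    to be reported alongside their percentages.
    """
    samples = list(sample_stats.index)
    per_sample = sample_stats.copy()
    per_sample["mapped_genes"] = [len(detected_genes[s]) for s in samples]
    per_sample["mapped_transcripts"] = [len(detected_transcripts[s]) for s in samples]
    per_sample["mapped_exons"] = [len(detected_exons[s]) for s in samples]

    union_genes = set().union(*detected_genes.values()) if detected_genes else set()
    union_tx = set().union(*detected_transcripts.values()) if detected_transcripts else set()
    union_exons = set().union(*detected_exons.values()) if detected_exons else set()

    cohort: dict[str, float] = {
        "gene_detected_count": len(union_genes),
        "transcript_detected_count": len(union_tx),
        "exon_detected_count": len(union_exons),
    }
    for kind, detected in (("gene", union_genes), ("transcript", union_tx),
                           ("exon", union_exons)):
        total = annotation_totals.get(f"{kind}s", 0)
        if total:
            cohort[f"{kind}_detected_pct"] = pct(len(detected), total, 1)
    for key, count in (gene_rate_counts or {}).items():
        cohort[f"{key}_count"] = count
        total = annotation_totals.get("genes", 0)
        if total:
            cohort[f"{key}_pct"] = pct(count, total, 1)

    summary = RunSummary(per_sample, annotation_totals, cohort)
    summary.validate()
    return summary
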