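"""Gene-versus-exon regulation patterns and the gene/exon Venn decomposition.

Genes containing at least one differentially expressed exon (DEE) fall
into three classes:

* **pattern 1** — every expressed exon of the gene is a DEE and all move
  in the same direction (the whole gene is shifted);
* **pattern 2** — a proper subset of expressed exons are DEEs, all in one
  direction, while the remaining expressed exons are unchanged;
* **pattern 3** — DEEs in both directions within one gene, the signature
  of an isoform switch.

The classifier formalizes what is usually judged from per-exon coverage
plots: an exon counts as expressed when its mean RPKM exceeds a
configurable floor in at least one condition (default 1), and pattern 1
optionally relaxes "every exon" to a fraction for noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from exonpipe.diffexpr import PairedDesign, paired_t_test

DEFAULT_EXPRESSION_FLOOR = 1.0


@dataclass
class PatternCall:
    gene_id: str
    pattern: str  # "1" | "2" | "3"
    expressed_exons: list[str] = field(default_factory=list)
    dee_exons: list[str] = field(default_factory=list)
    dee_directions: list[str] = field(default_factory=list)
    also_deg: bool = False


def classify_pattern(
    gene_id: str,
    exon_calls: pd.DataFrame,
    expression_floor: float = DEFAULT_EXPRESSION_FLOOR,
    pattern1_fraction: float = 1.0,
    deg_genes: set[str] | None = None,
) -> PatternCall | None:
    """Classify one gene from its exon-level differential calls.

    ``exon_calls`` is the per-exon call table restricted to this gene
    (columns ``significant``, ``direction``, ``mean_expr_tumor``,
    ``mean_expr_normal``).  Returns None when the gene has no expressed
    exon or no DEE among them.
    """
    expressed = exon_calls[
        (exon_calls["mean_expr_tumor"] > expression_floor)
        | (exon_calls["mean_expr_normal"] > expression_floor)
    ]
    if len(expressed) == 0:
        return None
    dee = expressed[expressed["significant"].astype(bool)]
    if len(dee) == 0:
        return None
    directions = set(dee["direction"])
    if {"up", "down"} <= directions:
        pattern = "3"
    elif len(dee) >= pattern1_fraction * len(expressed):
        pattern = "1"
    else:
        pattern = "2"
    return PatternCall(
        gene_id=gene_id,
        pattern=pattern,
        expressed_exons=list(expressed.index),
        dee_exons=list(dee.index),
        dee_directions=list(dee["direction"]),
        also_deg=gene_id in (deg_genes or set()),
    )


def classify_patterns(
    exon_calls: pd.DataFrame,
    exon2gene: dict[str, str],
    expression_floor: float = DEFAULT_EXPRESSION_FLOOR,
    pattern1_fraction: float = 1.0,
    deg_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Pattern labels for every DEE-containing gene (one row per gene)."""
    df = exon_calls.copy()
    df["gene_id"] = [exon2gene[e] for e in df.index]
    rows = []
    for gene_id, sub in df.groupby("gene_id", sort=True):
        call = classify_pattern(
            gene_id, sub.drop(columns="gene_id"), expression_floor,
            pattern1_fraction, deg_genes,
        )
        if call is None:
            continue
        rows.append({
            "gene_id": call.gene_id,
            "pattern": call.pattern,
            "n_expressed_exons": len(call.expressed_exons),
            "n_dee": len(call.dee_exons),
            "n_up": call.dee_directions.count("up"),
            "n_down": call.dee_directions.count("down"),
            "also_DEG": call.also_deg,
        })
    return pd.DataFrame(
        rows, columns=["gene_id", "pattern", "n_expressed_exons", "n_dee",
                       "n_up", "n_down", "also_DEG"],
    ).set_index("gene_id") if rows else pd.DataFrame(
        columns=["pattern", "n_expressed_exons", "n_dee", "n_up", "n_down", "also_DEG"],
        index=pd.Index([], name="gene_id"),
    )


def exon_ratio_contrast(
    exon_a: str,
    exon_b: str,
    expression: pd.DataFrame,
    design: PairedDesign,
) -> dict:
    """Per-sample log2 ratio of two exons' expression, contrasted by condition.

    The ratio cancels gene-level shifts, so pattern-1 genes show no
    condition difference while isoform switches (patterns 2 and 3) do.
    Samples where the denominator exon has zero expression are excluded and
    counted.  Returns the two ratio vectors plus a paired test on patients
    retaining both conditions.
    """
    ratios: dict[str, list[float]] = {"tumor": [], "non-tumor": []}
    excluded = 0
    keep_patients = []
    for patient, ts, ns in zip(design.patients, design.tumor_samples,
                               design.normal_samples):
        vals = {}
        for cond, sample in (("tumor", ts), ("non-tumor", ns)):
            a = expression.at[exon_a, sample]
            b = expression.at[exon_b, sample]
            if b == 0 or a == 0:  # log-ratio undefined; sample dropped and counted
                excluded += 1
                vals = {}
                break
            vals[cond] = float(np.log2(a) - np.log2(b))
        if vals:
            ratios["tumor"].append(vals["tumor"])
            ratios["non-tumor"].append(vals["non-tumor"])
            keep_patients.append(patient)
    if len(keep_patients) >= 2:
        t, p = paired_t_test(np.array(ratios["tumor"]), np.array(ratios["non-tumor"]))
    else:
        t, p = float("nan"), float("nan")
    return {
        "patients": keep_patients,
        "ratio_tumor": ratios["tumor"],
        "ratio_normal": ratios["non-tumor"],
        "n_excluded_samples": excluded,
        "t": t,
        "p": p,
        "mean_shift": (
            float(np.mean(ratios["tumor"]) - np.mean(ratios["non-tumor"]))
            if keep_patients else float("nan")
        ),
    }


def venn_gene_exon(deg_genes: set[str], dee_genes: set[str]) -> tuple[int, int, int]:
    """(|DEG only|, |intersection|, |DEE-gene only|); parts sum to |union|."""
    inter = deg_genes & dee_genes
    return len(deg_genes - inter), len(inter), len(dee_genes - inter)
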