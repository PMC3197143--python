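"""Paired differential testing and expression-quality statistics.

Significance at both gene and exon level uses the conjunction of a paired
t-test and an exact paired Wilcoxon signed-rank test (two-sided P < 0.05
for both), plus a Benjamini-Hochberg FDR ceiling on the t-test p-values
(default 0.05).  Tests run on log2(RPKM + 1) by default; the log transform
stabilizes variances across the expression range (a raw-RPKM mode is
available).  An optional external per-feature p/q table can be supplied to
reproduce a three-way conjunction with a count-model package.

The Wilcoxon test is exact for n <= 25: zero differences are dropped, tied
absolute differences receive average ranks, and the null distribution of
W+ over all 2^n sign assignments is built by dynamic programming over
(doubled, hence integer) rank sums.  Two-sided p is
min(1, 2 * min(P(W+ <= w), P(W+ >= w))).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_FDR_CEILING = 0.05
MA_PSEUDOCOUNT = 0.5
EXACT_WILCOXON_MAX_N = 25


def paired_t_test(values_t: np.ndarray, values_nt: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on per-patient differences.

    t = mean(d) / (sd(d)/sqrt(n)) with df = n - 1.  Degenerate inputs:
    zero-variance differences give (0, 1) when the mean is zero and
    (signed inf, 0) with a warning otherwise.
    """
    d = np.asarray(values_t, dtype=float) - np.asarray(values_nt, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        logger.warning("zero-variance nonzero-mean differences: p -> 0")
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of subset sums of ``doubled_ranks`` (the exact W+ null, x2 scale)."""
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        dist[r:] += dist[: total + 1 - r].copy()
    return dist


def wilcoxon_signed_rank(
    values_t: np.ndarray, values_nt: np.ndarray
) -> tuple[float, float]:
    """Exact two-sided paired Wilcoxon signed-rank test; returns (W+, p)."""
    d = np.asarray(values_t, dtype=float) - np.asarray(values_nt, dtype=float)
    d = d[d != 0.0]  # zero differences dropped, reducing effective n
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    if n > EXACT_WILCOXON_MAX_N:
        raise ValueError(
            f"exact enumeration limited to n <= {EXACT_WILCOXON_MAX_N}, got {n}"
        )
    ranks = stats.rankdata(np.abs(d))  # average ranks for ties -> multiples of 0.5
    w_plus = float(ranks[d > 0].sum())
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    dist = _signed_rank_distribution(doubled)
    n_total = dist.sum()  # == 2^n
    w2 = int(round(2.0 * w_plus))
    p_le = dist[: w2 + 1].sum() / n_total
    p_ge = dist[w2:].sum() / n_total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return w_plus, float(p)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PairedDesign:
    """Tumor/non-tumor sample columns matched by patient."""

    patients: list[str]
    tumor_samples: list[str]
    normal_samples: list[str]

    @classmethod
    def from_sample_sheet(cls, sheet: pd.DataFrame) -> "PairedDesign":
        tumor = sheet[sheet["condition"] == "tumor"].set_index("patient_id")["sample_id"]
        normal = sheet[sheet["condition"] == "non-tumor"].set_index("patient_id")["sample_id"]
        patients = sorted(set(tumor.index) & set(normal.index))
        if len(patients) < len(sheet) / 2:
            logger.warning("some patients lack a complete tumor/non-tumor pair")
        return cls(patients, [tumor[p] for p in patients], [normal[p] for p in patients])

    @property
    def n_pairs(self) -> int:
        return len(self.patients)


def call_features(
    expression: pd.DataFrame,
    counts: pd.DataFrame,
    design: PairedDesign,
    alpha: float = DEFAULT_ALPHA,
    fdr_ceiling: float = DEFAULT_FDR_CEILING,
    log_transform: bool = True,
    min_mean_expression: float = 0.0,
    external_fdr: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature paired differential calls (one row per tested feature).

    A feature is tested when its mean expression exceeds
    ``min_mean_expression`` in at least one condition (features expressed
    nowhere are excluded).  Significance requires paired-t p < alpha AND
    Wilcoxon p < alpha AND BH q <= fdr_ceiling on the t p-values; when an
    ``external_fdr`` table is given (e.g. from a count-model package) its
    q-values replace the built-in BH criterion, reproducing a three-way
    conjunction.  Direction follows the sign of the mean paired difference.
    """
    if design.n_pairs < 3:
        raise ValueError("paired design needs at least 3 pairs")
    t_mat = expression[design.tumor_samples].to_numpy(dtype=float)
    n_mat = expression[design.normal_samples].to_numpy(dtype=float)

    mean_t_raw = t_mat.mean(axis=1)
    mean_n_raw = n_mat.mean(axis=1)
    tested = (mean_t_raw > min_mean_expression) | (mean_n_raw > min_mean_expression)

    if log_transform:
        t_mat = np.log2(t_mat + 1.0)
        n_mat = np.log2(n_mat + 1.0)

    rows = []
    for i in np.nonzero(tested)[0]:
        t_stat, t_p = paired_t_test(t_mat[i], n_mat[i])
        w_stat, w_p = wilcoxon_signed_rank(t_mat[i], n_mat[i])
        rows.append((expression.index[i], t_stat, t_p, w_stat, w_p,
                     float(t_mat[i].mean() - n_mat[i].mean()),
                     mean_t_raw[i], mean_n_raw[i]))
    calls = pd.DataFrame(
        rows,
        columns=["feature_id", "t", "t_p", "W", "w_p", "mean_diff",
                 "mean_expr_tumor", "mean_expr_normal"],
    ).set_index("feature_id")

    if len(calls) == 0:
        for col, dtype in (("q", float), ("log2fc", float),
                           ("significant", bool), ("direction", object)):
            calls[col] = pd.Series(dtype=dtype)
        return calls

    calls["q"] = bh_fdr(calls["t_p"].to_numpy())
    c = MA_PSEUDOCOUNT
    pooled_t = counts[design.tumor_samples].sum(axis=1).reindex(calls.index)
    pooled_n = counts[design.normal_samples].sum(axis=1).reindex(calls.index)
    # pseudocount only protects zeros; nonzero pools keep the plain ratio
    calls["log2fc"] = np.log2(np.maximum(pooled_t, c) / np.maximum(pooled_n, c))

    fdr_crit = (
        external_fdr.reindex(calls.index) <= fdr_ceiling
        if external_fdr is not None
        else calls["q"] <= fdr_ceiling
    )
    calls["significant"] = (
        (calls["t_p"] < alpha) & (calls["w_p"] < alpha) & fdr_crit
    )
    calls["direction"] = np.where(calls["mean_diff"] > 0, "up", "down")
    calls.loc[calls["mean_diff"] == 0, "direction"] = ""
    return calls


def ma_values(
    counts_tumor: pd.Series,
    counts_normal: pd.Series,
    total_tumor: float,
    total_normal: float,
    pseudocount: float = MA_PSEUDOCOUNT,
) -> pd.DataFrame:
    """MA-plot quantities from condition-pooled counts.

    M = log2(count_T / count_NT), with the pseudocount substituted only for
    zero counts so nonzero ratios are exact; the concentration axis is the
    sum of the gene's count fractions in the two pooled conditions (raw
    counts, no pseudocount).  Features with a zero raw count on either side
    carry ``zero_flag`` and are conventionally plotted as a separate class.
    """
    ct = counts_tumor.astype(float)
    cn = counts_normal.reindex(ct.index).astype(float)
    m = np.log2(np.maximum(ct, pseudocount) / np.maximum(cn, pseudocount))
    concentration = ct / total_tumor + cn / total_normal
    return pd.DataFrame({
        "M": m,
        "concentration": concentration,
        "zero_flag": (ct == 0) | (cn == 0),
    })


def sample_correlation_matrix(
    log_expression: pd.DataFrame, design: PairedDesign | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pairwise Pearson correlations across samples plus group means.

    Constant-expression samples have undefined correlations, reported as
    NaN.  With a design, mean off-diagonal PCC is summarized for the
    (NT,NT), (T,T) and (T,NT) pair classes.
    """
    if log_expression.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(log_expression.to_numpy(dtype=float).T)
    pcc = pd.DataFrame(mat, index=log_expression.columns, columns=log_expression.columns)
    groups: dict[str, float] = {}
    if design is not None:
        t_set = [s for s in design.tumor_samples if s in pcc.index]
        n_set = [s for s in design.normal_samples if s in pcc.index]

        def mean_off_diag(rows: list[str], cols: list[str], same: bool) -> float:
            vals = []
            for a in rows:
                for b in cols:
                    if same and b <= a:
                        continue
                    vals.append(pcc.at[a, b])
            return float(np.nanmean(vals)) if vals else float("nan")

        groups["NT-NT"] = mean_off_diag(n_set, n_set, True)
        groups["T-T"] = mean_off_diag(t_set, t_set, True)
        groups["T-NT"] = mean_off_diag(t_set, n_set, False)
    return pcc, groups


def platform_comparison(
    platform_a: pd.Series, platform_b: pd.Series,
    id_mapping: dict[str, str] | None = None,
) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Pearson correlation of mean log2 expression between two platforms.

    ``id_mapping`` translates platform-B feature ids onto platform-A ids
    before joining on the shared set.  Also reports each platform's dynamic
    range (min, max) over the common features.
    """
    b = platform_b.copy()
    if id_mapping is not None:
        b = b.rename(index=id_mapping)
        b = b[~b.index.duplicated()]
    common = platform_a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common features; need at least 3")
    x = platform_a[common].astype(float)
    y = b[common].astype(float)
    pcc = float(np.corrcoef(x, y)[0, 1])
    return pcc, (float(x.min()), float(x.max())), (float(y.min()), float(y.max()))
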