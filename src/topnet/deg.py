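"""Differential expression between two sample groups on a count matrix.

A deliberately transparent negative-binomial Wald pipeline: median-of-ratios
size factors, method-of-moments dispersion pooled within the two compared
groups, a delta-method standard error for the log2 ratio of group means, and
a two-sided normal tail probability. It emulates the (log2fc, p) interface
of the heavyweight RNA-seq tools without their shrinkage machinery, which
downstream network mining does not consume.

Conventions
-----------
* NB parameterization: mean mu, dispersion alpha with Var = mu + alpha*mu**2
  (alpha = 1/size in the classical size/prob convention).
* ``log2fc`` is test over reference, computed on normalized group means with
  a pseudocount so zero-count groups stay finite.
* DEG call: |log2fc| >= log2(fold_threshold) (inclusive) and p < alpha
  (strict).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8

RESULT_COLUMNS = [
    "gene", "base_mean", "log2fc", "se", "wald_stat",
    "p", "p_bh", "p_bonf", "is_deg", "direction",
]


@dataclass
class CountMatrix:
    """Integer gene x sample counts with a group label per sample.

    Parameters
    ----------
    counts : DataFrame
        Genes as the index, samples as columns, non-negative integer cells.
    groups : Series
        Maps sample id -> group name; must cover every column of ``counts``.
    """

    counts: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.reindex(self.counts.columns)
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_groups(self, *names: str) -> "CountMatrix":
        keep = [s for s in self.samples if self.groups[s] in names]
        if not keep:
            raise ValueError(f"no samples in groups {names}")
        return CountMatrix(self.counts[keep], self.groups[keep])


def estimate_size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j, s_j is the median over genes (restricted to genes with
    a strictly positive geometric mean across samples) of
    counts[g, j] / geomean_g. If no gene is expressed in every sample the
    estimator falls back to total-count ratios (logged).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.mean(np.log(arr), axis=1)  # -inf where any zero
    usable = np.isfinite(loggeo)
    if usable.any():
        ratios = arr[usable] / np.exp(loggeo[usable])[:, None]
        factors = np.median(ratios, axis=0)
    else:
        logger.warning(
            "no gene expressed in all samples; falling back to total-count size factors"
        )
        totals = arr.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total count; cannot normalize")
        factors = totals / totals.mean()
    if (factors <= 0).any():
        raise ValueError("non-positive size factor estimated")
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def estimate_dispersion(norm_counts: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Per-gene NB dispersion by pooled within-group method of moments.

    alpha_g = max((s2_pooled - mu_pooled) / mu_pooled**2, floor) where the
    variance is pooled across groups with (n_k - 1) weights and the mean is
    the sample-size-weighted group mean. Genes with zero pooled mean (all-zero
    counts) sit at the floor and are logged.
    """
    groups = groups.reindex(norm_counts.columns)
    arr = norm_counts.to_numpy(dtype=float)
    n_total = 0
    ss = np.zeros(arr.shape[0])
    mu = np.zeros(arr.shape[0])
    df_sum = 0
    for g in pd.unique(groups):
        cols = (groups == g).to_numpy()
        n_k = int(cols.sum())
        sub = arr[:, cols]
        mu += n_k * sub.mean(axis=1)
        n_total += n_k
        if n_k >= 2:
            ss += (n_k - 1) * sub.var(axis=1, ddof=1)
            df_sum += n_k - 1
    mu /= n_total
    if df_sum == 0:
        logger.warning("no group with >= 2 samples; dispersion fixed at floor")
        return pd.Series(DISPERSION_FLOOR, index=norm_counts.index, name="dispersion")
    s2 = ss / df_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    zero_mean = mu <= 0
    if zero_mean.any():
        logger.info("%d all-zero genes set to dispersion floor", int(zero_mean.sum()))
        alpha[zero_mean] = DISPERSION_FLOOR
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=norm_counts.index, name="dispersion")


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg (``BH``) or ``bonferroni`` adjustment."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method: {method!r}")
    return multipletests(p, method=key)[1]


def wald_test(
    cm: CountMatrix,
    test_group: str,
    reference_group: str,
    *,
    pseudocount: float = 0.5,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene Wald test of ``test_group`` against ``reference_group``.

    The two groups are subset out of the matrix, size factors and dispersion
    are estimated on that subset, and for each gene

        log2fc = log2((mean_test + c) / (mean_ref + c))
        Var(mean_k) = (mu_k + alpha * mu_k**2) / n_k
        SE = sqrt(Var_t / (mean_t + c)**2 + Var_r / (mean_r + c)**2) / ln 2
        wald_stat = log2fc / SE,  p = 2 * Phi(-|wald_stat|)

    Single-sample groups are allowed; their mean variance is the model
    variance of the lone observation and the result is flagged in the
    ``low_confidence`` column.
    """
    if test_group == reference_group:
        raise ValueError("test and reference group must differ")
    sub = cm.subset_groups(test_group, reference_group)
    sf = estimate_size_factors(sub.counts)
    norm = sub.counts / sf
    alpha = (dispersion.reindex(norm.index) if dispersion is not None
             else estimate_dispersion(norm, sub.groups))

    t_cols = (sub.groups == test_group).to_numpy()
    r_cols = (sub.groups == reference_group).to_numpy()
    n_t, n_r = int(t_cols.sum()), int(r_cols.sum())
    if n_t == 0 or n_r == 0:
        raise ValueError("both groups must be non-empty")
    if min(n_t, n_r) == 1:
        logger.warning(
            "group with a single sample (%s); Wald SE uses its model variance only",
            test_group if n_t == 1 else reference_group,
        )

    arr = norm.to_numpy(dtype=float)
    mu_t = arr[:, t_cols].mean(axis=1)
    mu_r = arr[:, r_cols].mean(axis=1)
    a = alpha.to_numpy(dtype=float)
    c = float(pseudocount)

    log2fc = np.log2(mu_t + c) - np.log2(mu_r + c)
    var_t = (mu_t + a * mu_t**2) / n_t
    var_r = (mu_r + a * mu_r**2) / n_r
    ln2 = math.log(2.0)
    se = np.sqrt(var_t / (mu_t + c) ** 2 + var_r / (mu_r + c) ** 2) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, np.where(log2fc == 0, 0.0, np.inf * np.sign(log2fc)))
    p = 2.0 * stats.norm.sf(np.abs(wald))

    res = pd.DataFrame({
        "gene": norm.index,
        "base_mean": arr.mean(axis=1),
        "log2fc": log2fc,
        "se": se,
        "wald_stat": wald,
        "p": p,
        "p_bh": adjust_pvalues(p, "BH"),
        "p_bonf": adjust_pvalues(p, "bonferroni"),
        "low_confidence": min(n_t, n_r) == 1,
    })
    return res.reset_index(drop=True)


def call_degs(
    results: pd.DataFrame,
    *,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    use_adjusted: bool = False,
    adjusted_column: str = "p_bonf",
) -> pd.DataFrame:
    """Annotate a Wald result table with DEG calls and directions.

    DEG iff |log2fc| >= log2(fold_threshold) and the (raw or adjusted)
    p-value is strictly below ``alpha``. Direction is the sign of log2fc.
    """
    lfc_min = math.log2(fold_threshold)
    pcol = adjusted_column if use_adjusted else "p"
    out = results.copy()
    out["is_deg"] = (out["log2fc"].abs() >= lfc_min) & (out[pcol] < alpha)
    out["direction"] = np.where(
        ~out["is_deg"], "none", np.where(out["log2fc"] > 0, "up", "down")
    )
    return out


def deg_table(results: pd.DataFrame) -> pd.DataFrame:
    """Project a called result table onto the canonical output columns."""
    return results[RESULT_COLUMNS].copy()
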