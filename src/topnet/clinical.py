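"""Clinical blood-count statistics: NLR and group summaries/comparisons.

The neutrophil-to-lymphocyte ratio (NLR) is computed per patient and then
summarized per group as mean +/- SD (sample SD, n-1 denominator), so a
dispersion accompanies every group mean. Pairwise group comparisons use
Welch's t by default, with Mann-Whitney available for small or non-normal
groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

PARAMETERS = ["neutrophil_pct", "lymphocyte_pct", "nlr", "esr", "crp", "aso"]


def compute_nlr(neutrophil_pct, lymphocyte_pct):
    """Neutrophil % over lymphocyte %; scalar or elementwise on arrays.

    Scale-invariant: absolute counts give the same ratio as percentages as
    long as both share a denominator.
    """
    n = np.asarray(neutrophil_pct, dtype=float)
    l = np.asarray(lymphocyte_pct, dtype=float)
    if np.any(l <= 0):
        raise ValueError("lymphocyte percentage must be strictly positive")
    out = n / l
    return float(out) if out.ndim == 0 else out


def add_nlr(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["nlr"] = compute_nlr(out["neutrophil_pct"], out["lymphocyte_pct"])
    return out


def summarize_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean, sample SD and n for every clinical parameter present.

    Missing values are excluded parameter-wise with the remaining n
    reported; a single observation yields mean with SD = NaN (undefined).
    """
    if "group" not in table.columns:
        raise ValueError("clinical table needs a 'group' column")
    tab = add_nlr(table) if "nlr" not in table.columns else table
    params = [p for p in PARAMETERS if p in tab.columns]
    rows = []
    for grp, sub in tab.groupby("group", sort=True):
        for p in params:
            vals = sub[p].dropna().to_numpy(dtype=float)
            n = len(vals)
            rows.append({
                "group": grp,
                "parameter": p,
                "n": n,
                "mean": float(np.mean(vals)) if n else np.nan,
                "sd": float(np.std(vals, ddof=1)) if n >= 2 else np.nan,
            })
    return pd.DataFrame(rows)


def compare_groups(values_a, values_b, test: str = "welch_t") -> tuple[float, float]:
    """Two-sided comparison of two samples; returns (statistic, p).

    ``welch_t``: unequal-variance t test (needs >= 2 values per group).
    ``mann_whitney``: rank-sum with mid-rank tie handling.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "welch_t":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("welch_t needs at least 2 values per group")
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mann_whitney":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("mann_whitney needs non-empty groups")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                 use_continuity=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def pairwise_tests(
    table: pd.DataFrame,
    parameter: str = "nlr",
    test: str = "welch_t",
) -> pd.DataFrame:
    """All pairwise group comparisons of one parameter."""
    tab = add_nlr(table) if parameter == "nlr" and "nlr" not in table.columns else table
    groups = sorted(tab["group"].unique())
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            va = tab.loc[tab["group"] == ga, parameter].dropna()
            vb = tab.loc[tab["group"] == gb, parameter].dropna()
            stat, p = compare_groups(va, vb, test=test)
            rows.append({"group_a": ga, "group_b": gb, "parameter": parameter,
                         "test": test, "statistic": stat, "p": p})
    return pd.DataFrame(rows)
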