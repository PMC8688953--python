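"""Group-comparison statistics for morphometric parameters.

Two groups of per-sample parameter values are compared the standard way
for small-animal bone studies: a Shapiro-Wilk normality gate on each
group; Welch's two-sided t-test when both groups look normal, otherwise a
two-sided Mann-Whitney U; significance at p < 0.05.  Group differences
are expressed as a percentage of the control mean.  No multiple-testing
correction is applied by default (a Bonferroni/Benjamini-Hochberg switch
exists for users who want one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "percent_difference", "compare_groups", "spearman_assoc",
    "ComparisonResult", "compare_table",
]


def percent_difference(control_mean: float, flight_mean: float) -> float:
    """100 * (flight - control) / control, control taken as 100%.

    Full precision; round to one decimal only for display.
    """
    if control_mean == 0:
        raise ZeroDivisionError("control mean is zero; percent difference undefined")
    return 100.0 * (flight_mean - control_mean) / control_mean


@dataclass
class ComparisonResult:
    test_used: str  # 'welch_t' or 'mann_whitney_u'
    statistic: float
    p_value: float
    significant: bool


def _shapiro_ok(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        warnings.warn("constant group: Shapiro-Wilk undefined, "
                      "falling through to Mann-Whitney U")
        return False
    return sps.shapiro(x).pvalue > alpha


def _mann_whitney(x: np.ndarray, y: np.ndarray):
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if min(len(x), len(y)) <= 8 and not has_ties:
        return sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    return sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")


def compare_groups(control, flight, alpha: float = 0.05) -> ComparisonResult:
    """Normality-gated two-group comparison.

    Welch's t if both groups pass Shapiro-Wilk at ``alpha``, else
    Mann-Whitney U (exact enumeration for tie-free samples with
    min(n) <= 8, normal approximation with tie correction otherwise).
    """
    x = np.asarray(control, dtype=np.float64)
    y = np.asarray(flight, dtype=np.float64)
    if len(x) < 3 or len(y) < 3:
        raise ValueError(f"each group needs n >= 3 (got {len(x)}, {len(y)})")
    if _shapiro_ok(x, alpha) and _shapiro_ok(y, alpha):
        res = sps.ttest_ind(x, y, equal_var=False)
        return ComparisonResult("welch_t", float(res.statistic),
                                float(res.pvalue), bool(res.pvalue < alpha))
    res = _mann_whitney(x, y)
    return ComparisonResult("mann_whitney_u", float(res.statistic),
                            float(res.pvalue), bool(res.pvalue < alpha))


def spearman_assoc(weights, parameter_values) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p-value."""
    x = np.asarray(weights, dtype=np.float64)
    y = np.asarray(parameter_values, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def compare_table(control: pd.DataFrame, flight: pd.DataFrame,
                  parameters=None, alpha: float = 0.05,
                  correction: str | None = None) -> pd.DataFrame:
    """Comparison table: one row per parameter, shaped like a standard
    bone-morphometry results table (mean/SD per group, difference in % of
    control, test used, p-value, significance marker).

    ``correction`` may be 'bonferroni' or 'bh' to adjust p-values across
    parameters; default is none.
    """
    if parameters is None:
        parameters = [c for c in control.columns
                      if c in flight.columns
                      and pd.api.types.is_numeric_dtype(control[c])]
    rows = []
    for p in parameters:
        x = control[p].dropna().to_numpy(dtype=float)
        y = flight[p].dropna().to_numpy(dtype=float)
        cm, fm = float(x.mean()), float(y.mean())
        res = compare_groups(x, y, alpha=alpha)
        rows.append({
            "Index": p,
            "Control mean": cm, "Control SD": float(x.std(ddof=1)),
            "Flight mean": fm, "Flight SD": float(y.std(ddof=1)),
            "Difference (%)": round(percent_difference(cm, fm), 1),
            "Test": res.test_used, "p-value": res.p_value,
            "n control": len(x), "n flight": len(y),
        })
    df = pd.DataFrame(rows)
    pvals = df["p-value"].to_numpy()
    if correction == "bonferroni":
        pvals = np.minimum(pvals * len(pvals), 1.0)
    elif correction == "bh":
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty_like(pvals)
        adj[order] = np.minimum(ranked, 1.0)
        pvals = adj
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    df["p adjusted"] = pvals
    df["Significant"] = pvals < alpha
    return df
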