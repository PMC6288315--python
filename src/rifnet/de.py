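"""Two-group differential-expression screen.

The screen combines a Welch unequal-variance test on log2(FPKM +
pseudocount) — a stand-in for the upstream quantification tool's test —
with the study's exact filter chain: a feature is DE when

* max(mean_H, mean_L) >= 0.5 FPKM        (expression filter)
* |log2FC| >= 1.2                        (fold-change filter)
* p <= 0.05 and Storey q <= 0.10         (significance filter)

The filters, not the test, are the reproduced methodology; thresholds
are configurable via :class:`DEThresholds`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix

__all__ = ["DEThresholds", "group_stats", "welch_test", "storey_pi0",
           "storey_qvalues", "apply_de_filters", "de_screen"]


@dataclass(frozen=True)
class DEThresholds:
    min_group_fpkm: float = 0.5
    min_abs_log2fc: float = 1.2
    max_p: float = 0.05
    max_q: float = 0.10
    pseudocount: float = 0.01
    # 'max' keeps features expressed in at least one group; 'min'
    # requires both groups to clear the floor
    expression_rule: str = "max"

    def __post_init__(self) -> None:
        for name in ("min_group_fpkm", "min_abs_log2fc", "max_p", "max_q",
                     "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.expression_rule not in ("max", "min"):
            raise ValueError("expression_rule must be 'max' or 'min'")


def group_stats(matrix: ExpressionMatrix,
                pseudocount: float = 0.01) -> pd.DataFrame:
    """Per-feature group means (FPKM) and pseudocount-stabilised log2FC.

    log2fc = log2((mean_H + pc) / (mean_L + pc)), H over L.
    """
    matrix.require_min_group_size(2)
    mean_h = matrix.group_values("H").mean(axis=1)
    mean_l = matrix.group_values("L").mean(axis=1)
    log2fc = np.log2((mean_h + pseudocount) / (mean_l + pseudocount))
    return pd.DataFrame({"mean_H": mean_h, "mean_L": mean_l,
                         "log2fc": log2fc})


def welch_test(matrix: ExpressionMatrix,
               pseudocount: float = 0.01) -> pd.Series:
    """Two-sided Welch p-values on log2(FPKM + pseudocount).

    Degenerate rule: a feature with zero variance in both groups gets
    p = 1 when the group means agree and p = 0 when they differ (the
    separation limit of the statistic).
    """
    matrix.require_min_group_size(2)
    h = np.log2(matrix.group_values("H").to_numpy() + pseudocount)
    l = np.log2(matrix.group_values("L").to_numpy() + pseudocount)
    with warnings.catch_warnings():
        # constant rows trigger a precision warning; handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(h, l, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    var_h = h.var(axis=1, ddof=1)
    var_l = l.var(axis=1, ddof=1)
    degenerate = (var_h == 0) & (var_l == 0)
    if degenerate.any():
        equal_means = np.isclose(h.mean(axis=1), l.mean(axis=1),
                                 rtol=0.0, atol=0.0)
        p[degenerate] = np.where(equal_means[degenerate], 1.0, 0.0)
    return pd.Series(p, index=matrix.feature_ids, name="p")


_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def storey_pi0(pvals: np.ndarray,
               lambdas: np.ndarray = _LAMBDA_GRID) -> float:
    """Estimate the null proportion pi0 with the cubic-smoother method.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is fit with a cubic
    polynomial over the lambda grid and evaluated at the largest lambda,
    then clipped to [1/m, 1].
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam))
                           for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def storey_qvalues(pvals, pi0: float | None = None) -> np.ndarray:
    """Storey q-values (step-up over ordered p, scaled by pi0).

    q_(i) = min_{p_(j) >= p_(i)} pi0 * m * p_(j) / j.  With ``pi0=1``
    this reduces exactly to Benjamini-Hochberg adjusted p-values.
    Output order matches input order; ties keep input order (stable sort).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    if pi0 is None:
        pi0 = storey_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def apply_de_filters(records: pd.DataFrame,
                     thresholds: DEThresholds = DEThresholds()) -> pd.DataFrame:
    """Attach the four filter verdicts and the DE call.

    ``records`` must carry columns mean_H, mean_L, log2fc, p, q.
    All threshold comparisons are inclusive.
    """
    out = records.copy()
    if thresholds.expression_rule == "max":
        expr = np.maximum(out["mean_H"], out["mean_L"])
    else:
        expr = np.minimum(out["mean_H"], out["mean_L"])
    out["pass_expression"] = expr >= thresholds.min_group_fpkm
    out["pass_fc"] = out["log2fc"].abs() >= thresholds.min_abs_log2fc
    out["pass_significance"] = ((out["p"] <= thresholds.max_p)
                                & (out["q"] <= thresholds.max_q))
    out["is_DE"] = (out["pass_expression"] & out["pass_fc"]
                    & out["pass_significance"])
    return out


def de_screen(matrix: ExpressionMatrix,
              thresholds: DEThresholds = DEThresholds()) -> pd.DataFrame:
    """Full screen: stats + Welch p + Storey q + filter verdicts."""
    records = group_stats(matrix, thresholds.pseudocount)
    records["p"] = welch_test(matrix, thresholds.pseudocount)
    records["q"] = storey_qvalues(records["p"].to_numpy())
    return apply_de_filters(records, thresholds)
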