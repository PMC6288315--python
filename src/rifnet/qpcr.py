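"""qPCR-side computations and cross-platform agreement statistics.

Covers the technical-validation arm of the pipeline: converting mean
Cp values to efficiency-corrected relative quantities, geometric-mean
normalisation factors from reference genes, the geNorm pairwise
stability statistic M, per-gene Pearson correlation between platforms,
and Lin's concordance correlation coefficient (CCC) for fold-change
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QPCRTable", "CCCResult", "relative_quantities",
           "normalization_factors", "genorm_stability", "lin_ccc",
           "per_gene_platform_correlation"]


@dataclass
class QPCRTable:
    """Mean Cp values (gene x sample) with per-gene efficiencies.

    Cp is the quantification cycle (mean of 3 technical replicates);
    efficiency E is from the standard curve (E = 2 is perfect doubling).
    """

    cp: pd.DataFrame
    efficiency: pd.Series
    reference_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.cp.to_numpy() <= 0).any():
            raise ValueError("Cp values must be positive")
        self.efficiency = self.efficiency.reindex(self.cp.index)
        if self.efficiency.isna().any():
            raise ValueError("every gene needs an efficiency")
        if ((self.efficiency <= 1) | (self.efficiency > 2.5)).any():
            raise ValueError("efficiencies must lie in (1, 2.5]")
        missing = set(self.reference_genes) - set(self.cp.index)
        if missing:
            raise ValueError(f"reference genes not in table: {sorted(missing)}")


def relative_quantities(qpcr: QPCRTable) -> pd.DataFrame:
    """Q_gs = E_g^(Cp_min,g - Cp_gs).

    The sample with the lowest Cp (highest expression) of each gene is
    the calibrator, where Q = 1.
    """
    cp = qpcr.cp
    e = qpcr.efficiency.to_numpy()[:, None]
    delta = cp.min(axis=1).to_numpy()[:, None] - cp.to_numpy()
    return pd.DataFrame(e ** delta, index=cp.index, columns=cp.columns)


def normalization_factors(quantities: pd.DataFrame,
                          reference_genes) -> pd.Series:
    """Per-sample normalisation factor: geometric mean of the reference
    gene quantities."""
    refs = list(reference_genes)
    if len(refs) < 2:
        raise ValueError("need at least 2 reference genes")
    q = quantities.loc[refs]
    if (q.to_numpy() <= 0).any():
        raise ValueError("reference quantities must be positive")
    return pd.Series(np.exp(np.log(q.to_numpy()).mean(axis=0)),
                     index=quantities.columns, name="NF")


def genorm_stability(quantities: pd.DataFrame, candidate_refs) -> pd.Series:
    """geNorm stability M for each candidate reference gene.

    M_g = mean over the other candidates h of the SD (n-1 denominator)
    across samples of log2(Q_g / Q_h); lower M means more stable.
    """
    refs = list(candidate_refs)
    if len(refs) < 2:
        raise ValueError("need at least 2 candidate reference genes")
    q = quantities.loc[refs].to_numpy(dtype=float)
    if (q <= 0).any():
        raise ValueError("quantities must be positive")
    logq = np.log2(q)
    m = {}
    for i, g in enumerate(refs):
        sds = [np.std(logq[i] - logq[j], ddof=1)
               for j in range(len(refs)) if j != i]
        m[g] = float(np.mean(sds))
    return pd.Series(m, name="M")


@dataclass(frozen=True)
class CCCResult:
    ccc: float
    pearson: float
    n: int


def lin_ccc(x, y) -> CCCResult:
    """Lin's concordance correlation coefficient.

    ccc = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2) with
    n-denominator moments (the original estimator's convention);
    the Pearson r is reported alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sx2, sy2 = x.var(), y.var()
    if sx2 == 0 or sy2 == 0:
        raise ValueError("zero variance input")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    ccc = 2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)
    return CCCResult(ccc=float(ccc),
                     pearson=float(sxy / np.sqrt(sx2 * sy2)),
                     n=int(x.size))


def per_gene_platform_correlation(fpkm: pd.DataFrame,
                                  normalized_qpcr: pd.DataFrame
                                  ) -> pd.DataFrame:
    """Per-gene Pearson r (and t-transform p, n-2 df) between RNA-seq
    FPKM and normalised qPCR quantities across the shared samples."""
    genes = fpkm.index.intersection(normalized_qpcr.index)
    samples = fpkm.columns.intersection(normalized_qpcr.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples")
    rows = {}
    for g in genes:
        a = fpkm.loc[g, samples].to_numpy(dtype=float)
        b = normalized_qpcr.loc[g, samples].to_numpy(dtype=float)
        if a.std() == 0 or b.std() == 0:
            rows[g] = {"r": np.nan, "p": np.nan}
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        n = len(samples)
        r_c = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
        t = r_c * np.sqrt((n - 2) / (1.0 - r_c ** 2))
        rows[g] = {"r": r, "p": float(2.0 * stats.t.sf(abs(t), df=n - 2))}
    return pd.DataFrame.from_dict(rows, orient="index")
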