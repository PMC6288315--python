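"""Regulatory Impact Factor (RIF) scoring with bootstrap calibration.

For a panel of candidate transcription regulators (TRFs) and a set of
n_DE differentially expressed genes, the two metrics for TRF *i* are

    RIF1_i = (1/n_DE) * sum_j a_j * d_j * (r1_ij - r2_ij)^2
    RIF2_i = (1/n_DE) * sum_j [(e1_j * r1_ij)^2 - (e2_j * r2_ij)^2]

where a_j and d_j are the average and differential expression of DE
gene *j*, e1_j/e2_j its group-mean expression in H and L, and
r1_ij/r2_ij the within-group Pearson correlations between TRF and gene.
RIF1 rewards differential co-expression with abundant, strongly DE
genes; RIF2 rewards a change in the TRF's ability to predict the DE
genes' abundance.  Scores are z-scored across the panel and calibrated
against a bootstrap null in which the DE set is replaced by random
expressed transcripts (10,000 iterations, 99% CI in the original
design); TRFs with z-scores outside the null bounds are called extreme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionMatrix

__all__ = ["RIFInput", "BootstrapNull", "build_rif_input", "rif_scores",
           "zscore_panel", "rif_bootstrap_null", "call_extreme_trfs",
           "expressed_features", "rif_analysis"]

log = logging.getLogger(__name__)


@dataclass
class RIFInput:
    """Pre-computed quantities the two RIF formulas consume.

    All expression values are on the configured scale (default
    log2(FPKM+1)).  Correlation entries for zero-variance pairs are 0
    and flagged in ``r1_defined``/``r2_defined``.
    """

    trf_ids: list[str]
    de_ids: list[str]
    a: np.ndarray          # (n_DE,) average expression
    d: np.ndarray          # (n_DE,) differential expression, H - L
    e1: np.ndarray         # (n_DE,) group-mean expression in H
    e2: np.ndarray         # (n_DE,) group-mean expression in L
    r1: np.ndarray         # (n_TRF, n_DE) within-H correlations
    r2: np.ndarray         # (n_TRF, n_DE) within-L correlations
    r1_defined: np.ndarray
    r2_defined: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.d, self.e1 - self.e2):
            raise ValueError("d must equal e1 - e2")
        for r in (self.r1, self.r2):
            if np.nanmax(np.abs(r), initial=0.0) > 1.0 + 1e-9:
                raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class BootstrapNull:
    """Empirical null distribution summary for one metric.

    ``lower``/``upper`` are scalars in pooled mode and per-TRF arrays in
    per-TRF mode.
    """

    metric: str
    n_iterations: int
    level: float
    lower: float | np.ndarray
    upper: float | np.ndarray
    null_values: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")
        if np.any(np.asarray(self.lower) > np.asarray(self.upper)):
            raise ValueError("lower bound exceeds upper bound")

    def is_extreme(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v < self.lower) | (v > self.upper)

    def to_jsonable(self) -> dict:
        lo, hi = self.lower, self.upper
        return {"metric": self.metric, "n_iterations": self.n_iterations,
                "level": self.level,
                "lower": lo if np.isscalar(lo) else list(map(float, lo)),
                "upper": hi if np.isscalar(hi) else list(map(float, hi)),
                "seed": self.seed}


def _transform(values: np.ndarray, scale: str) -> np.ndarray:
    if scale == "log2p1":
        return np.log2(values + 1.0)
    if scale == "raw":
        return values
    raise ValueError(f"unknown expression scale {scale!r}")


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled to mean 0, unit SS; zero-variance rows become 0 (flagged).

    With both factors standardised this way, a matrix product gives the
    Pearson correlation.
    """
    centred = x - x.mean(axis=1, keepdims=True)
    ss = np.sqrt((centred ** 2).sum(axis=1))
    defined = ss > 0
    ss_safe = np.where(defined, ss, 1.0)
    return centred / ss_safe[:, None], defined


def expressed_features(matrix: ExpressionMatrix,
                       min_fpkm: float = 0.5) -> pd.Index:
    """Features whose group-mean FPKM exceeds ``min_fpkm`` in >= 1 group."""
    mean_h = matrix.group_values("H").mean(axis=1)
    mean_l = matrix.group_values("L").mean(axis=1)
    keep = (mean_h > min_fpkm) | (mean_l > min_fpkm)
    return matrix.feature_ids[keep]


def build_rif_input(matrix: ExpressionMatrix, de_ids, trf_ids,
                    min_fpkm: float = 0.5,
                    scale: str = "log2p1") -> RIFInput:
    """Assemble the RIF input quantities from an expression matrix.

    The TRF panel is restricted to members expressed above ``min_fpkm``
    in at least one group.  Zero-variance correlations are set to 0 and
    flagged rather than dropping the gene, so n_DE stays fixed.
    """
    de_ids = list(de_ids)
    trf_ids = list(trf_ids)
    if not de_ids or not trf_ids:
        raise ValueError("DE set and TRF panel must be non-empty")
    matrix.require_min_group_size(2)
    expressed = set(expressed_features(matrix, min_fpkm))
    trf_ids = [t for t in trf_ids if t in expressed]
    if not trf_ids:
        raise ValueError("no TRF passes the expression floor")

    x = _transform(matrix.subset(de_ids + trf_ids).values.to_numpy(), scale)
    n_de = len(de_ids)
    h_cols = matrix.groups.to_numpy() == "H"
    xh, xl = x[:, h_cols], x[:, ~h_cols]
    e1, e2 = xh[:n_de].mean(axis=1), xl[:n_de].mean(axis=1)
    zh, def_h = _standardize_rows(xh)
    zl, def_l = _standardize_rows(xl)
    r1 = zh[n_de:] @ zh[:n_de].T
    r2 = zl[n_de:] @ zl[:n_de].T
    r1_defined = np.outer(def_h[n_de:], def_h[:n_de])
    r2_defined = np.outer(def_l[n_de:], def_l[:n_de])
    np.clip(r1, -1.0, 1.0, out=r1)
    np.clip(r2, -1.0, 1.0, out=r2)
    return RIFInput(trf_ids=trf_ids, de_ids=de_ids,
                    a=(e1 + e2) / 2.0, d=e1 - e2, e1=e1, e2=e2,
                    r1=r1, r2=r2,
                    r1_defined=r1_defined, r2_defined=r2_defined)


def rif_scores(rif_input: RIFInput) -> pd.DataFrame:
    """Evaluate both RIF sums exactly for every TRF in the panel."""
    a, d, e1, e2 = (rif_input.a, rif_input.d, rif_input.e1, rif_input.e2)
    r1, r2 = rif_input.r1, rif_input.r2
    rif1 = ((a * d)[None, :] * (r1 - r2) ** 2).mean(axis=1)
    rif2 = ((e1[None, :] * r1) ** 2 - (e2[None, :] * r2) ** 2).mean(axis=1)
    return pd.DataFrame({"rif1": rif1, "rif2": rif2},
                        index=pd.Index(rif_input.trf_ids, name="trf_id"))


def zscore_panel(values) -> np.ndarray:
    """(x - mean) / SD with the n-1 denominator; errors on zero spread."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to z-score")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation in panel")
    return (v - v.mean()) / sd


def rif_bootstrap_null(matrix: ExpressionMatrix, trf_ids, pool_ids,
                       n_DE: int, n_iter: int = 10_000, level: float = 0.99,
                       seed: int | None = None, scale: str = "log2p1",
                       min_fpkm: float = 0.5, per_trf: bool = False,
                       max_stored: int = 100_000,
                       ) -> tuple[BootstrapNull, BootstrapNull]:
    """Bootstrap null for the RIF z-scores.

    Each iteration samples ``n_DE`` pool features without replacement as
    a pseudo-DE set, recomputes both metrics for the whole TRF panel and
    z-scores them within the iteration.  By default z-scores are pooled
    across TRFs and iterations into one distribution per metric whose
    (1-level)/2 and 1-(1-level)/2 empirical quantiles form the bounds;
    with ``per_trf=True`` every TRF is instead flagged against its own
    row-wise quantile interval.

    Deterministic given ``seed``.
    """
    if n_iter < 100:
        log.warning("rif_bootstrap_null: n_iter=%d is very small", n_iter)
    pool_ids = list(pool_ids)
    trf_ids = list(trf_ids)
    if n_DE > len(pool_ids):
        raise ValueError("n_DE exceeds the bootstrap pool size")
    matrix.require_min_group_size(2)
    expressed = set(expressed_features(matrix, min_fpkm))
    trf_ids = [t for t in trf_ids if t in expressed]

    x = _transform(matrix.subset(pool_ids + trf_ids).values.to_numpy(), scale)
    n_pool = len(pool_ids)
    h_cols = matrix.groups.to_numpy() == "H"
    xh, xl = x[:, h_cols], x[:, ~h_cols]
    e1_all, e2_all = xh.mean(axis=1), xl.mean(axis=1)
    zh, _ = _standardize_rows(xh)
    zl, _ = _standardize_rows(xl)
    zh_trf, zl_trf = zh[n_pool:], zl[n_pool:]

    rng = np.random.default_rng(seed)
    z1_all = np.empty((n_iter, len(trf_ids)))
    z2_all = np.empty((n_iter, len(trf_ids)))
    for it in range(n_iter):
        pick = rng.choice(n_pool, size=n_DE, replace=False)
        e1, e2 = e1_all[pick], e2_all[pick]
        a, d = (e1 + e2) / 2.0, e1 - e2
        r1 = zh_trf @ zh[pick].T
        r2 = zl_trf @ zl[pick].T
        rif1 = ((a * d)[None, :] * (r1 - r2) ** 2).mean(axis=1)
        rif2 = ((e1[None, :] * r1) ** 2 - (e2[None, :] * r2) ** 2).mean(axis=1)
        z1_all[it] = zscore_panel(rif1)
        z2_all[it] = zscore_panel(rif2)

    alpha = (1.0 - level) / 2.0
    nulls = []
    for name, z in (("RIF1-z", z1_all), ("RIF2-z", z2_all)):
        if per_trf:
            lower = np.quantile(z, alpha, axis=0)
            upper = np.quantile(z, 1.0 - alpha, axis=0)
        else:
            flat = z.ravel()
            lower = float(np.quantile(flat, alpha))
            upper = float(np.quantile(flat, 1.0 - alpha))
        flat = z.ravel()
        if flat.size > max_stored:
            step = int(np.ceil(flat.size / max_stored))
            flat = flat[::step]
        nulls.append(BootstrapNull(metric=name, n_iterations=n_iter,
                                   level=level, lower=lower, upper=upper,
                                   null_values=flat, seed=seed))
    return nulls[0], nulls[1]


def call_extreme_trfs(results: pd.DataFrame, null1: BootstrapNull,
                      null2: BootstrapNull) -> pd.DataFrame:
    """Flag TRFs whose z-scores fall outside the null bounds.

    ``results`` must carry columns z1 and z2; returns a copy with
    extreme1/extreme2/extreme (union) flags.
    """
    out = results.copy()
    out["extreme1"] = null1.is_extreme(out["z1"].to_numpy())
    out["extreme2"] = null2.is_extreme(out["z2"].to_numpy())
    out["extreme"] = out["extreme1"] | out["extreme2"]
    return out


def extreme_counts(results: pd.DataFrame) -> dict[str, int]:
    """RIF1-only / RIF2-only / both / union counts, as usually reported."""
    e1, e2 = results["extreme1"], results["extreme2"]
    return {"rif1_only": int((e1 & ~e2).sum()),
            "rif2_only": int((e2 & ~e1).sum()),
            "both": int((e1 & e2).sum()),
            "union": int((e1 | e2).sum())}


def rif_analysis(matrix: ExpressionMatrix, de_ids, trf_ids,
                 pool_ids=None, n_iter: int = 10_000, level: float = 0.99,
                 seed: int | None = None, scale: str = "log2p1",
                 min_fpkm: float = 0.5,
                 ) -> tuple[pd.DataFrame, BootstrapNull, BootstrapNull]:
    """End-to-end RIF stage: scores, z-scores, bootstrap null, calls.

    The default bootstrap pool is the expressed features minus the TRF
    panel and minus the observed DE set; including the DE genes
    themselves would let pseudo-DE draws carry the very signal being
    calibrated (negligible at genome scale, severe on small panels).
    """
    if pool_ids is None:
        excluded = set(trf_ids) | set(de_ids)
        pool_ids = [f for f in expressed_features(matrix, min_fpkm)
                    if f not in excluded]
    rin = build_rif_input(matrix, de_ids, trf_ids, min_fpkm, scale)
    res = rif_scores(rin)
    res["z1"] = zscore_panel(res["rif1"].to_numpy())
    res["z2"] = zscore_panel(res["rif2"].to_numpy())
    null1, null2 = rif_bootstrap_null(
        matrix, rin.trf_ids, pool_ids, n_DE=len(rin.de_ids), n_iter=n_iter,
        level=level, seed=seed, scale=scale, min_fpkm=min_fpkm)
    return call_extreme_trfs(res, null1, null2), null1, null2
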