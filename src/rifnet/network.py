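"""Weighted co-expression network, modules, eigengenes and hubs.

A compact re-implementation of the weighted-network workflow: unsigned
soft-threshold adjacency a_ij = |cor|^beta (beta = 6 by default, the
study's scale-free choice), the unsigned topological overlap matrix

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu,

average-linkage hierarchical clustering on 1 - TOM with a deterministic
modularity-selected cut height standing in for dynamic tree cutting,
module
eigengenes (first principal component of the standardised member
profiles), module-trait (IMF) correlations, intramodular connectivity
kIM, and the top-20% hub-lncRNA rule.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data import ExpressionMatrix

__all__ = ["CoexprNetwork", "soft_adjacency", "topological_overlap",
           "detect_modules", "module_eigengene", "module_trait_correlation",
           "intramodular_connectivity", "hub_lncrnas", "build_network"]

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class CoexprNetwork:
    feature_ids: list[str]
    beta: int
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    module_labels: pd.Series


def soft_adjacency(matrix: ExpressionMatrix, ids, beta: int = 6,
                   signed: bool = False) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor(x_i, x_j)|^beta.

    ``signed=True`` uses the signed-hybrid variant (negative
    correlations get adjacency 0).  Zero-variance features are dropped
    with a log entry; the diagonal is 1.
    """
    ids = list(ids)
    if len(matrix.sample_ids) < 3:
        raise ValueError("need at least 3 samples for a co-expression network")
    values = matrix.subset(ids).values
    sd = values.std(axis=1, ddof=1)
    kept = [i for i, s in zip(ids, sd) if s > 0]
    dropped = sorted(set(ids) - set(kept))
    if dropped:
        log.info("dropping %d zero-variance feature(s) from network: %s",
                 len(dropped), dropped[:5])
    if len(kept) < 2:
        raise ValueError("fewer than 2 features with non-zero variance")
    cor = np.corrcoef(values.loc[kept].to_numpy())
    cor = np.clip(cor, -1.0, 1.0)
    if signed:
        adj = np.where(cor > 0, cor, 0.0) ** beta
    else:
        adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=kept, columns=kept)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned TOM from an adjacency matrix (diagonal 1)."""
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # l_ij + a_ii*a_ij terms; diagonal of a is 0 so exact
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(tom: pd.DataFrame, min_size: int = 3,
                   cut: str | float = "modularity",
                   adjacency: pd.DataFrame | None = None,
                   cut_quantile: float = 0.95) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a deterministic cut.

    The default ``cut="modularity"`` finds, by exact dynamic programming
    over the dendrogram, the tree-respecting partition (every cluster a
    complete subtree) that maximizes Newman modularity on the weighted
    network (``adjacency`` if given, else the TOM itself).  Modularity
    is additive over clusters, so the optimum over all branch cuts is
    found bottom-up: each subtree either stays one module or splits into
    its children's best partitions (ties prefer the finer partition).
    This is a deterministic counterpart of dynamic tree cutting: the
    effective cut height adapts per branch to the observed block
    structure.  ``cut="quantile"`` instead cuts at the ``cut_quantile``
    of merge heights, and a float ``cut`` is used as an absolute height.

    Clusters smaller than ``min_size`` become "unassigned"; surviving
    modules are labelled by size rank ("module-1" = largest).  A
    degenerate all-equal TOM yields a single module.
    """
    n = len(tom)
    if n < 2:
        return pd.Series([UNASSIGNED] * n, index=tom.index, name="module")
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    if cut == "modularity":
        weights = (adjacency.to_numpy(dtype=float) if adjacency is not None
                   else tom.to_numpy(dtype=float)).copy()
        np.fill_diagonal(weights, 0.0)
        two_m = weights.sum()
        if two_m == 0:
            raw = np.arange(n)  # no edges: every feature on its own
        else:
            deg = weights.sum(axis=1)
            root = hierarchy.to_tree(z)

            def solve(node):
                """(best modularity, best partition as leaf-lists, leaves)."""
                if node.is_leaf():
                    leaves = [node.id]
                    return -((deg[node.id] / two_m) ** 2), [leaves], leaves
                ql, pl, ll = solve(node.left)
                qr, pr, lr = solve(node.right)
                leaves = ll + lr
                idx = np.asarray(leaves)
                q_whole = (weights[np.ix_(idx, idx)].sum() / two_m
                           - (deg[idx].sum() / two_m) ** 2)
                if q_whole > ql + qr:
                    return q_whole, [leaves], leaves
                return ql + qr, pl + pr, leaves

            old_limit = sys.getrecursionlimit()
            sys.setrecursionlimit(max(old_limit, 10 * n + 100))
            try:
                _, partition, _ = solve(root)
            finally:
                sys.setrecursionlimit(old_limit)
            raw = np.empty(n, dtype=int)
            for ci, cluster in enumerate(partition):
                raw[cluster] = ci
    else:
        height = (float(np.quantile(z[:, 2], cut_quantile))
                  if cut == "quantile" else float(cut))
        raw = hierarchy.fcluster(z, t=height, criterion="distance")
    labels = pd.Series(raw, index=tom.index)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_size]
    # size-rank labels; ties broken by raw cluster id for determinism
    rank = {c: f"module-{i + 1}"
            for i, c in enumerate(sorted(keep.index,
                                         key=lambda c: (-sizes[c], c)))}
    return labels.map(lambda c: rank.get(c, UNASSIGNED)).rename("module")


def module_eigengene(matrix: ExpressionMatrix,
                     member_ids) -> tuple[pd.Series, float]:
    """First principal component of the standardised member profiles.

    Returns the unit-norm per-sample eigengene (sign fixed so the mean
    correlation with member profiles is >= 0) and the fraction of
    variance it explains.
    """
    member_ids = list(member_ids)
    if len(member_ids) < 2:
        raise ValueError("module must have at least 2 members")
    x = matrix.subset(member_ids).values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mean) / sd  # features x samples
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    member_cor = z @ eig / np.linalg.norm(z, axis=1).clip(min=1e-300)
    if member_cor.mean() < 0:
        eig = -eig
    return pd.Series(eig, index=matrix.subset(member_ids).sample_ids,
                     name="eigengene"), var_explained


def module_trait_correlation(eigengenes: dict[str, pd.Series],
                             phenotype: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each eigengene with IMF, p from the t
    transform with n-2 degrees of freedom."""
    if phenotype["imf"].isna().any():
        raise ValueError("phenotype has missing IMF values")
    rows = {}
    for label, eig in eigengenes.items():
        imf = phenotype["imf"].reindex(eig.index)
        if imf.isna().any():
            raise ValueError(f"missing phenotype for samples of {label}")
        n = len(eig)
        r = float(np.corrcoef(eig.to_numpy(), imf.to_numpy())[0, 1])
        r_c = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
        t = r_c * np.sqrt((n - 2) / (1.0 - r_c ** 2))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        rows[label] = {"trait_cor": r, "trait_p": float(p)}
    return pd.DataFrame.from_dict(rows, orient="index")


def intramodular_connectivity(adjacency: pd.DataFrame,
                              module_labels: pd.Series) -> pd.Series:
    """kIM_i = sum of adjacencies to co-members; unassigned -> 0."""
    labels = module_labels.reindex(adjacency.index)
    kim = pd.Series(0.0, index=adjacency.index, name="kIM")
    for label, members in labels.groupby(labels).groups.items():
        if label == UNASSIGNED:
            continue
        sub = adjacency.loc[members, members].to_numpy(dtype=float).copy()
        np.fill_diagonal(sub, 0.0)
        kim.loc[members] = sub.sum(axis=1)
    return kim


def hub_lncrnas(kim: pd.Series, module_labels: pd.Series,
                biotypes: pd.Series,
                top_fraction: float = 0.20) -> dict[str, set[str]]:
    """Hub lncRNAs per module: lncRNA members whose kIM reaches the
    (1 - top_fraction) quantile of kIM over *all* module members."""
    hubs: dict[str, set[str]] = {}
    for label, members in module_labels.groupby(module_labels).groups.items():
        if label == UNASSIGNED:
            continue
        k = kim.reindex(members)
        threshold = float(np.quantile(k.to_numpy(), 1.0 - top_fraction))
        lnc_members = [m for m in members if biotypes.get(m) == "lncRNA"]
        hubs[label] = {m for m in lnc_members if k[m] >= threshold}
    return hubs


def build_network(matrix: ExpressionMatrix, ids, beta: int = 6,
                  min_size: int = 3, cut: str | float = "modularity",
                  cut_quantile: float = 0.95,
                  signed: bool = False) -> CoexprNetwork:
    adj = soft_adjacency(matrix, ids, beta=beta, signed=signed)
    tom = topological_overlap(adj)
    labels = detect_modules(tom, min_size=min_size, cut=cut, adjacency=adj,
                            cut_quantile=cut_quantile)
    return CoexprNetwork(feature_ids=list(adj.index), beta=beta,
                         adjacency=adj, tom=tom, module_labels=labels)
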