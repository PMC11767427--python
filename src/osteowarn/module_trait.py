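"""Weighted-correlation module detection and module/trait association.

A compact re-implementation of the WGCNA core: soft-threshold adjacency
a_ij = |cor(i,j)|^beta, topological overlap
TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
average-linkage clustering on 1 - TOM with a static cut, eigen-metabolite
(first PC of a module's standardized abundances), and Pearson
module-trait / biomarker-trait correlation tables.  Deviations from
canonical WGCNA (static rather than dynamic tree cut, unsigned network by
default) are deliberate simplifications.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: WGCNA-style module color names, assigned by decreasing module size.
_COLORS = ("turquoise", "blue", "brown", "yellow", "green", "red", "black",
           "pink", "magenta", "purple", "greenyellow", "tan", "salmon")
GREY = "grey"  # unassigned pool


def wgcna_adjacency(x: pd.DataFrame, beta: float = 6.0, signed: bool = False) -> pd.DataFrame:
    """Soft-threshold adjacency from the sample x metabolite matrix."""
    if beta <= 0:
        raise ValueError("soft power beta must be positive")
    corr = np.corrcoef(x.to_numpy(dtype=float), rowvar=False)
    if signed:
        a = ((1 + corr) / 2.0) ** beta
    else:
        a = np.abs(corr) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=x.columns, columns=x.columns)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency matrix (values in [0,1])."""
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def wgcna_modules(
    x: pd.DataFrame,
    beta: float = 6.0,
    cut_height: float = 0.97,
    min_size: int = 5,
    signed: bool = False,
) -> pd.Series:
    """Module color per metabolite from a static cut of the TOM dendrogram.

    Clusters below ``min_size`` fall into the grey (unassigned) pool;
    colors are assigned deterministically by decreasing module size
    (ties broken by the lexicographically smallest member).
    """
    if x.shape[1] < min_size:
        raise ValueError("fewer metabolites than min_size")
    adj = wgcna_adjacency(x, beta=beta, signed=signed)
    tom = tom_similarity(adj)
    dist = 1.0 - tom.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(link, t=cut_height, criterion="distance")

    cols = list(x.columns)
    groups = []
    for lab in np.unique(labels):
        members = sorted(cols[i] for i in np.flatnonzero(labels == lab))
        if len(members) >= min_size:
            groups.append(members)
    groups.sort(key=lambda g: (-len(g), g[0]))

    assignment = pd.Series(GREY, index=x.columns, name="module")
    for rank, members in enumerate(groups):
        color = _COLORS[rank] if rank < len(_COLORS) else f"module{rank}"
        assignment[members] = color
    return assignment


def eigen_metabolite(x: pd.DataFrame, members: list[str]) -> pd.Series:
    """First principal component of the module's standardized abundances.

    The sign is oriented so the eigen-metabolite correlates non-negatively
    with the mean module abundance.
    """
    sub = x[members].to_numpy(dtype=float)
    sd = sub.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    zs = (sub - sub.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(zs, full_matrices=False)
    pc = u[:, 0] * s[0]
    if np.corrcoef(pc, zs.mean(axis=1))[0, 1] < 0:
        pc = -pc
    return pd.Series(pc, index=x.index, name="eigen")


def trait_correlations(
    features: pd.DataFrame,
    traits: pd.DataFrame,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson r and p for every (feature, trait) cell.

    ``features`` holds eigen-metabolites (one column per module) or raw
    biomarker abundances; ``traits`` holds numeric clinical covariates.
    Missing trait values are handled pairwise-complete; cells with fewer
    than ``min_pairs`` complete pairs, or a constant side, are NA.
    Returns a long-format table (feature, trait, r, p, n, significant).
    """
    rows = []
    for feat in features.columns:
        f = features[feat]
        for trait in traits.columns:
            t = pd.to_numeric(traits[trait], errors="coerce")
            mask = f.notna() & t.notna()
            n = int(mask.sum())
            if n < min_pairs or f[mask].std() == 0 or t[mask].std() == 0:
                rows.append({"feature": feat, "trait": trait, "r": np.nan,
                             "p": np.nan, "n": n, "significant": False})
                continue
            r, p = stats.pearsonr(f[mask], t[mask])
            rows.append({"feature": feat, "trait": trait, "r": float(r),
                         "p": float(p), "n": n, "significant": bool(p < 0.05)})
    return pd.DataFrame(rows)
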