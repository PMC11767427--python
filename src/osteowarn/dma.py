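"""Differential metabolite analysis across the three ordered BMD stages.

Trend across control -> osteopenia -> osteoporosis is tested with the
Jonckheere-Terpstra statistic (exact permutation null at small n,
tie-corrected normal approximation otherwise); pairwise contrasts use the
Wilcoxon rank-sum test.  Ordination (PCA / PLS-DA) gives the usual visual
separation of stage metabolic profiles.  Significance defaults to raw
p < 0.05 with no multiplicity correction; Benjamini-Hochberg is optional.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import STAGES, Cohort

Alternative = Literal["increasing", "decreasing", "two_sided"]

#: Total sample size at or below which the exact permutation null is used.
EXACT_N_MAX = 12

STAGE_CONTRASTS = (
    ("control", "osteopenia"),
    ("control", "osteoporosis"),
    ("osteopenia", "osteoporosis"),
)


def _jt_statistic(groups: list[np.ndarray]) -> float:
    """J = sum over ordered group pairs of Mann-Whitney counts, ties as 1/2."""
    j = 0.0
    for i in range(len(groups)):
        for k in range(i + 1, len(groups)):
            a, b = groups[i], groups[k]
            j += np.sum(a[:, None] < b[None, :]) + 0.5 * np.sum(a[:, None] == b[None, :])
    return float(j)


def _jt_null_moments(sizes: np.ndarray, pooled: np.ndarray) -> tuple[float, float]:
    n = int(sizes.sum())
    mean = (n * n - np.sum(sizes**2)) / 4.0
    _, counts = np.unique(pooled, return_counts=True)
    t = counts.astype(float)
    s = sizes.astype(float)
    a = (n * (n - 1) * (2 * n + 5)
         - np.sum(s * (s - 1) * (2 * s + 5))
         - np.sum(t * (t - 1) * (2 * t + 5)))
    b = np.sum(s * (s - 1) * (s - 2)) * np.sum(t * (t - 1) * (t - 2))
    c = np.sum(s * (s - 1)) * np.sum(t * (t - 1))
    var = a / 72.0
    if n > 2:
        var += b / (36.0 * n * (n - 1) * (n - 2))
    var += c / (8.0 * n * (n - 1))
    return mean, float(var)


def _jt_exact_distribution(pooled: np.ndarray, sizes: Sequence[int]) -> np.ndarray:
    """All J values over the multinomial assignments of pooled values to groups."""
    n = len(pooled)
    cmp_mat = (pooled[:, None] < pooled[None, :]).astype(float)
    cmp_mat += 0.5 * (pooled[:, None] == pooled[None, :])
    out: list[float] = []

    def recurse(remaining: tuple[int, ...], assigned: list[np.ndarray]) -> None:
        if len(assigned) == len(sizes):
            j = 0.0
            for i in range(len(assigned)):
                for k in range(i + 1, len(assigned)):
                    j += cmp_mat[np.ix_(assigned[i], assigned[k])].sum()
            out.append(j)
            return
        size = sizes[len(assigned)]
        for combo in itertools.combinations(remaining, size):
            rest = tuple(x for x in remaining if x not in set(combo))
            recurse(rest, assigned + [np.asarray(combo)])

    recurse(tuple(range(n)), [])
    return np.asarray(out)


def jonckheere_terpstra(
    groups: Sequence[Sequence[float]],
    alternative: Alternative = "two_sided",
    method: Literal["auto", "exact", "asymptotic"] = "auto",
) -> tuple[float, float, float]:
    """Jonckheere-Terpstra test for an ordered trend across groups.

    Parameters
    ----------
    groups
        Numeric vectors in their hypothesised order (e.g. control,
        osteopenia, osteoporosis).
    alternative
        ``increasing`` (later groups stochastically larger),
        ``decreasing``, or ``two_sided``.
    method
        ``auto`` uses the exact permutation null when total n <= 12,
        the tie-corrected normal approximation otherwise.

    Returns
    -------
    (J, z, p)
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two ordered groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must contain at least one observation")
    pooled = np.concatenate(arrays)
    sizes = np.array([len(a) for a in arrays])
    j = _jt_statistic(arrays)
    mean, var = _jt_null_moments(sizes, pooled)

    if var <= 0:  # all values identical: no ordering information
        return j, 0.0, 1.0

    z = (j - mean) / np.sqrt(var)
    use_exact = method == "exact" or (method == "auto" and sizes.sum() <= EXACT_N_MAX)
    if use_exact:
        null = _jt_exact_distribution(pooled, sizes.tolist())
        p_inc = float(np.mean(null >= j - 1e-9))
        p_dec = float(np.mean(null <= j + 1e-9))
    else:
        p_inc = float(stats.norm.sf(z))
        p_dec = float(stats.norm.cdf(z))
    if alternative == "increasing":
        p = p_inc
    elif alternative == "decreasing":
        p = p_dec
    elif alternative == "two_sided":
        p = min(1.0, 2.0 * min(p_inc, p_dec))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return j, float(z), p


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null when min(n_a, n_b) <= 8 and the pooled data are tie-free;
    tie-corrected normal approximation otherwise.  Returns (U, p).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DMAResult:
    """Tables from the differential metabolite analysis."""

    trend_table: pd.DataFrame      # metabolite, J, z, p, direction
    pairwise_table: pd.DataFrame   # metabolite, contrast, W, p
    alpha: float

    @property
    def jt_significant(self) -> set[str]:
        t = self.trend_table
        return set(t.loc[t["p"] < self.alpha, "metabolite"])

    def pairwise_significant(self, contrast: str) -> set[str]:
        t = self.pairwise_table
        mask = (t["contrast"] == contrast) & (t["p"] < self.alpha)
        return set(t.loc[mask, "metabolite"])

    @property
    def significant_any(self) -> set[str]:
        return self.jt_significant | set(
            self.pairwise_table.loc[self.pairwise_table["p"] < self.alpha, "metabolite"]
        )


def run_dma(cohort: Cohort, alpha: float = 0.05, fdr: str | None = None) -> DMAResult:
    """Trend and pairwise rank tests for every metabolite.

    The cohort must be staged, filtered and imputed.  ``fdr='bh'``
    applies Benjamini-Hochberg within each table; the default (None)
    uses raw p-values.
    """
    stages = cohort.stages
    groups_idx = {s: cohort.stage_samples(s) for s in STAGES}
    for s, idx in groups_idx.items():
        if len(idx) < 2:
            raise ValueError(f"stage {s!r} has fewer than 2 samples")

    trend_rows, pair_rows = [], []
    for met in cohort.metabolite_ids:
        col = cohort.abundance[met]
        vecs = {s: col.loc[groups_idx[s]].to_numpy() for s in STAGES}
        j, z, p = jonckheere_terpstra([vecs[s] for s in STAGES])
        trend_rows.append({
            "metabolite": met, "J": j, "z": z, "p": p,
            "direction": "increasing" if z > 0 else ("decreasing" if z < 0 else "flat"),
        })
        for s1, s2 in STAGE_CONTRASTS:
            w, pw = wilcoxon_rank_sum(vecs[s1], vecs[s2])
            pair_rows.append({"metabolite": met, "contrast": f"{s1}-vs-{s2}",
                              "W": w, "p": pw})
    trend = pd.DataFrame(trend_rows)
    pairwise = pd.DataFrame(pair_rows)
    if fdr == "bh":
        from statsmodels.stats.multitest import multipletests
        trend["p"] = multipletests(trend["p"], method="fdr_bh")[1]
        pairwise["p"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    elif fdr is not None:
        raise ValueError(f"unknown fdr mode {fdr!r}")
    return DMAResult(trend, pairwise, alpha)


def ordination(
    cohort: Cohort,
    method: Literal["pca", "plsda"] = "pca",
    n_components: int = 2,
    log: bool = False,
) -> pd.DataFrame:
    """Per-sample ordination scores with stage labels for plotting.

    Metabolites are standardized to zero mean / unit SD (optionally after
    log transform).  PCA scores come from the SVD; PLS-DA scores from a
    PLS2 fit against one-hot stage labels.
    """
    x = cohort.abundance.to_numpy(dtype=float)
    if log:
        x = np.log(x)
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds min(n_samples, n_metabolites)")
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=0)) / sd

    if method == "pca":
        from sklearn.decomposition import PCA
        scores = PCA(n_components=n_components, svd_solver="full").fit_transform(xs)
    elif method == "plsda":
        from sklearn.cross_decomposition import PLSRegression
        stages = cohort.stages
        y = pd.get_dummies(stages).astype(float).to_numpy()
        pls = PLSRegression(n_components=n_components, scale=False).fit(xs, y)
        scores = pls.x_scores_
    else:
        raise ValueError(f"unknown ordination method {method!r}")

    out = pd.DataFrame(scores[:, :n_components],
                       index=cohort.sample_ids,
                       columns=[f"comp{i+1}" for i in range(n_components)])
    if "stage" in cohort.metadata.columns:
        out["stage"] = cohort.stages
    return out
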