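"""Individual edge-network analysis (iENA) and the sCI warning index.

Every quantity is anchored to reference statistics computed from the
control-stage samples only.  For one sample s and metabolites x, y:

    z_x(s)    = (x(s) - mu_x) / sigma_x
    sPCC_s(x,y) = z_x(s) * z_y(s)

i.e. the sample's standardized co-deviation from the reference — its
additive contribution to the reference Pearson correlation.  The
fourth-order edge-pair score standardizes the edge scores themselves by
their reference distribution:

    shPCC_s(e1,e2) = Z_{e1}(s) * Z_{e2}(s),
    Z_e(s) = (sPCC_s(e) - mean_ref sPCC(e)) / sd_ref sPCC(e)

The early-warning composite index over a "domain" metabolite module D is

    sCI(s) = mean_{x,y in D} |sPCC_s(x,y)|
             / mean_{x in D, y not in D} |sPCC_s(x,y)|
             * mean_{x in D} |x(s) - mu_x|

which peaks when the module's members deviate strongly and coherently
from the reference while decoupling from the rest of the network — the
dynamic-network-biomarker signature of a critical transition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohort import STAGES, Cohort

logger = logging.getLogger(__name__)

#: Floor applied to the sPCC_out denominator of sCI.
DENOMINATOR_EPS = 1e-8


@dataclass
class ReferenceStats:
    """Per-metabolite reference mean/SD from the control samples only."""

    mu: pd.Series
    sigma: pd.Series          # sample SD (ddof=1)
    values: pd.DataFrame      # reference abundance, retained metabolites
    dropped: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.mu.index

    @property
    def n(self) -> int:
        return len(self.values)


def build_reference(cohort: Cohort, reference_stage: str = "control") -> ReferenceStats:
    """Reference mean/SD per metabolite, from the reference stage only.

    Zero-variance metabolites are dropped with a warning.  Requires at
    least 3 reference samples.
    """
    idx = cohort.stage_samples(reference_stage)
    if len(idx) < 3:
        raise ValueError(
            f"reference stage {reference_stage!r} has {len(idx)} samples; need >= 3"
        )
    vals = cohort.abundance.loc[idx]
    mu = vals.mean(axis=0)
    sigma = vals.std(axis=0, ddof=1)
    dropped = sigma.index[sigma == 0].tolist()
    if dropped:
        logger.warning("dropping %d zero-variance metabolite(s) from reference: %s",
                       len(dropped), dropped)
    keep = sigma.index[sigma > 0]
    return ReferenceStats(mu[keep], sigma[keep], vals[keep], dropped)


def zscores(values: pd.DataFrame, ref: ReferenceStats) -> pd.DataFrame:
    """Reference-standardized deviations for many samples at once."""
    vals = values[ref.metabolite_ids]
    return (vals - ref.mu) / ref.sigma


def loo_zscores(ref: ReferenceStats) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-out z-scores and |x - mu| for the reference samples.

    Each reference sample is standardized against the mean/SD of the
    *other* reference samples, removing the in-sample optimism that would
    otherwise deflate control-stage scores.  Returns (z, absdev).
    """
    x = ref.values.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("leave-one-out reference needs >= 3 samples")
    mu = x.mean(axis=0)
    ss = ((x - mu) ** 2).sum(axis=0)
    d = x - mu
    mu_loo = mu - d / (n - 1)                      # mean without the sample
    ss_loo = ss - d**2 * n / (n - 1)
    var_loo = np.maximum(ss_loo, 0.0) / (n - 2)
    sd_loo = np.sqrt(var_loo)
    dev = x - mu_loo
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_loo > 0, dev / sd_loo, 0.0)
    cols = ref.metabolite_ids
    return (pd.DataFrame(z, index=ref.sample_ids, columns=cols),
            pd.DataFrame(np.abs(dev), index=ref.sample_ids, columns=cols))


def spcc(sample: pd.Series, ref: ReferenceStats, pair: tuple[str, str]) -> float:
    """Single-sample edge score sPCC_s(x, y) = z_x(s) * z_y(s)."""
    x, y = pair
    for m in (x, y):
        if m not in ref.metabolite_ids:
            raise KeyError(f"metabolite {m!r} not in reference")
    zx = (sample[x] - ref.mu[x]) / ref.sigma[x]
    zy = (sample[y] - ref.mu[y]) / ref.sigma[y]
    return float(zx * zy)


@dataclass
class EdgeNetwork:
    """Top-ranked metabolite pairs with per-sample edge scores."""

    edges: list[tuple[str, str]]            # lexicographically ordered pairs
    scores: pd.DataFrame                    # samples x edges (sPCC values)
    ref_edge_mean: pd.Series
    ref_edge_sd: pd.Series
    rule: str

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _edge_label(pair: tuple[str, str]) -> str:
    return f"{pair[0]}|{pair[1]}"


def select_top_edges(
    cohort: Cohort,
    ref: ReferenceStats,
    rule: str = "top_quantile",
    q: float = 0.01,
    top_k: int | None = None,
) -> EdgeNetwork:
    """Rank all metabolite pairs by mean |sPCC| and keep the top ones.

    Ranking uses the non-reference samples (the perturbed states); ties
    break lexicographically by pair id.  ``rule`` is ``top_quantile``
    (fraction q of all pairs) or ``top_k``.
    """
    mets = list(ref.metabolite_ids)
    if len(mets) < 2:
        raise ValueError("need at least two retained metabolites")
    z = zscores(cohort.abundance, ref)
    non_ref = z.index.difference(ref.sample_ids)
    rank_z = z.loc[non_ref] if len(non_ref) else z
    a = np.abs(rank_z.to_numpy(dtype=float))
    # mean_s |z_i z_j| = (|Z|^T |Z| / n)_{ij}
    m = a.T @ a / a.shape[0]
    pairs = list(itertools.combinations(range(len(mets)), 2))
    mean_abs = np.array([m[i, j] for i, j in pairs])
    n_pairs = len(pairs)
    if rule == "top_quantile":
        k = int(round(q * n_pairs))
    elif rule == "top_k":
        if top_k is None:
            raise ValueError("top_k rule requires top_k")
        k = int(top_k)
    else:
        raise ValueError(f"unknown edge selection rule {rule!r}")
    if k <= 0 or k > n_pairs:
        raise ValueError(f"edge selection yields {k} edges out of {n_pairs} pairs")

    labels = [(mets[i], mets[j]) for i, j in pairs]
    order = sorted(range(n_pairs), key=lambda t: (-mean_abs[t], labels[t]))
    chosen = [labels[t] for t in order[:k]]

    zv = z.to_numpy(dtype=float)
    met_pos = {m_: t for t, m_ in enumerate(mets)}
    cols = {}
    for pair in chosen:
        i, j = met_pos[pair[0]], met_pos[pair[1]]
        cols[_edge_label(pair)] = zv[:, i] * zv[:, j]
    scores = pd.DataFrame(cols, index=z.index)
    ref_scores = scores.loc[ref.sample_ids]
    return EdgeNetwork(
        edges=chosen,
        scores=scores,
        ref_edge_mean=ref_scores.mean(axis=0),
        ref_edge_sd=ref_scores.std(axis=0, ddof=1),
        rule=f"{rule}(q={q})" if rule == "top_quantile" else f"top_k(k={top_k})",
    )


def shpcc(
    sample: pd.Series,
    edge_pair: tuple[tuple[str, str], tuple[str, str]],
    ref: ReferenceStats,
    network: EdgeNetwork,
) -> float:
    """Fourth-order single-sample score between two edges.

    Standardizes each edge's sPCC by its reference distribution and
    multiplies; involves four metabolite values.  Returns NaN with a
    warning when a reference edge-score SD is zero.
    """
    zs = []
    for e in edge_pair:
        label = _edge_label(e)
        if label not in network.scores.columns:
            raise KeyError(f"edge {e} not in the edge network")
        sd = network.ref_edge_sd[label]
        if not sd > 0:
            logger.warning("edge pair %s skipped: reference edge-score SD is zero", edge_pair)
            return float("nan")
        score = spcc(sample, ref, e)
        zs.append((score - network.ref_edge_mean[label]) / sd)
    return float(zs[0] * zs[1])


def shpcc_matrix(network: EdgeNetwork, edge_pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Vectorized shPCC for many samples over the given edge-label pairs."""
    z = (network.scores - network.ref_edge_mean) / network.ref_edge_sd
    out = {}
    for e1, e2 in edge_pairs:
        out[f"{e1}~{e2}"] = z[e1] * z[e2]
    return pd.DataFrame(out, index=network.scores.index)


def detect_modules(
    cohort: Cohort,
    ref: ReferenceStats | None = None,
    min_size: int = 3,
    max_size: int = 30,
    cut_height: float = 0.7,
    method: str = "average",
) -> list[list[str]]:
    """Candidate metabolite modules by hierarchical clustering.

    Metabolites are clustered on 1 - |Pearson correlation| over all
    samples (average linkage) and the tree is cut at ``cut_height``;
    clusters within the size bounds are the candidates, so every
    metabolite belongs to at most one module.  If no cluster satisfies
    the bounds, falls back to the best fixed-k cut with a warning.
    """
    cols = list(ref.metabolite_ids) if ref is not None else list(cohort.metabolite_ids)
    x = cohort.abundance[cols].to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least two metabolites to cluster")
    corr = np.corrcoef(x, rowvar=False)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = linkage(squareform(dist, checks=False), method=method)

    def clusters_from(labels: np.ndarray, lo: int) -> list[list[str]]:
        mods = []
        for lab in np.unique(labels):
            members = [cols[i] for i in np.flatnonzero(labels == lab)]
            if lo <= len(members) <= max_size:
                mods.append(sorted(members))
        return sorted(mods, key=lambda m: (-len(m), m))

    modules = clusters_from(fcluster(link, t=cut_height, criterion="distance"), min_size)
    if modules:
        return modules

    logger.warning("no module within size bounds at cut height %.2f; "
                   "falling back to best fixed-k cut", cut_height)
    # smallest k whose cut yields a size-valid cluster, then relax the
    # lower bound to 2; keeps the candidate list lean
    for lo in (min_size, 2):
        for k in range(2, len(cols)):
            mods = clusters_from(fcluster(link, t=k, criterion="maxclust"), lo)
            if mods:
                return mods
    raise ValueError("no candidate module found at any cut")


def _sci_components(
    abs_z: np.ndarray, abs_dev: np.ndarray, in_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized sCI components for samples x metabolites arrays.

    Uses mean_{i<j in D}|z_i||z_j| = ((sum a)^2 - sum a^2)/2 / C(m,2)
    and mean_{i in D, j out} |z_i||z_j| = sum_in a * sum_out a / (m*(p-m)).
    """
    m = int(in_mask.sum())
    p = abs_z.shape[1]
    if m < 2:
        raise ValueError("module must have at least 2 members")
    a_in = abs_z[:, in_mask]
    a_out = abs_z[:, ~in_mask]
    s_in = a_in.sum(axis=1)
    spcc_in = (s_in**2 - (a_in**2).sum(axis=1)) / (m * (m - 1))
    if p - m > 0:
        spcc_out = s_in * a_out.sum(axis=1) / (m * (p - m))
    else:
        spcc_out = np.zeros_like(s_in)
    ssd_in = abs_dev[:, in_mask].mean(axis=1)
    floored = spcc_out < DENOMINATOR_EPS
    sci_val = spcc_in / np.maximum(spcc_out, DENOMINATOR_EPS) * ssd_in
    return sci_val, spcc_in, spcc_out, ssd_in, floored


def sci(
    sample: pd.Series,
    module: Sequence[str],
    ref: ReferenceStats,
    edge_universe: Sequence[str] | None = None,
) -> tuple[float, dict]:
    """Single-sample composite index for a candidate domain module.

    Returns (sCI, components) where components holds sPCC_in, sPCC_out,
    sSD_in and a ``floored`` flag set when the out-of-module denominator
    was clipped at epsilon.
    """
    universe = list(edge_universe) if edge_universe is not None else list(ref.metabolite_ids)
    module = sorted(module)
    missing = set(module) - set(universe)
    if missing:
        raise KeyError(f"module members outside the metabolite universe: {sorted(missing)}")
    vals = sample[universe].to_numpy(dtype=float)[None, :]
    mu = ref.mu[universe].to_numpy()
    sigma = ref.sigma[universe].to_numpy()
    abs_z = np.abs((vals - mu) / sigma)
    abs_dev = np.abs(vals - mu)
    in_mask = np.isin(np.asarray(universe), module)
    v, s_in, s_out, ssd, fl = _sci_components(abs_z, abs_dev, in_mask)
    return float(v[0]), {
        "spcc_in": float(s_in[0]),
        "spcc_out": float(s_out[0]),
        "ssd_in": float(ssd[0]),
        "floored": bool(fl[0]),
    }


@dataclass
class DomainModule:
    """The selected DNB module and its sCI trajectory across stages."""

    members: list[str]
    sci_per_sample: pd.Series
    stage_means: dict[str, float]
    critical_stage: str
    components: pd.DataFrame      # per-sample spcc_in / spcc_out / ssd_in / floored
    candidates: int = 0

    @property
    def floored_fraction(self) -> float:
        return float(self.components["floored"].mean())


def detect_critical_stage(
    cohort: Cohort,
    ref: ReferenceStats | None = None,
    min_size: int = 3,
    max_size: int = 30,
    cut_height: float = 0.7,
    aggregator: str = "mean",
) -> DomainModule:
    """Find the domain module and the stage its warning index peaks in.

    Candidate modules come from hierarchical clustering; for each, the
    per-sample sCI is computed (reference-stage samples are scored with
    leave-one-out reference statistics to avoid in-sample optimism) and
    averaged within stage.  The module with the highest best-stage mean
    sCI is the domain module; the argmax stage is the critical stage.
    """
    for s in STAGES:
        if len(cohort.stage_samples(s)) == 0:
            raise ValueError(f"stage {s!r} has no samples")
    if ref is None:
        ref = build_reference(cohort)
    modules = detect_modules(cohort, ref, min_size=min_size,
                             max_size=max_size, cut_height=cut_height)
    modules = [m for m in modules if len(m) >= 2]
    if not modules:
        raise ValueError("no candidate module of size >= 2")

    universe = list(ref.metabolite_ids)
    z_all = zscores(cohort.abundance, ref)
    dev_all = np.abs(
        cohort.abundance[universe] - ref.mu[universe]
    )
    z_loo, dev_loo = loo_zscores(ref)
    z_all.loc[ref.sample_ids] = z_loo
    dev_all.loc[ref.sample_ids] = dev_loo
    abs_z = np.abs(z_all.to_numpy(dtype=float))
    abs_dev = dev_all.to_numpy(dtype=float)

    stages = cohort.stages
    agg = np.mean if aggregator == "mean" else np.median

    best = None
    for module in modules:
        in_mask = np.isin(np.asarray(universe), module)
        vals, s_in, s_out, ssd, fl = _sci_components(abs_z, abs_dev, in_mask)
        per_sample = pd.Series(vals, index=cohort.sample_ids, name="sci")
        means = {s: float(agg(per_sample[stages == s])) for s in STAGES}
        score = max(means.values())
        if best is None or score > best[0]:
            comp = pd.DataFrame(
                {"sci": vals, "spcc_in": s_in, "spcc_out": s_out,
                 "ssd_in": ssd, "floored": fl},
                index=cohort.sample_ids,
            )
            best = (score, module, per_sample, means, comp)

    _, module, per_sample, means, comp = best
    critical = max(STAGES, key=lambda s: means[s])
    return DomainModule(
        members=list(module),
        sci_per_sample=per_sample,
        stage_means=means,
        critical_stage=critical,
        components=comp,
        candidates=len(modules),
    )
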