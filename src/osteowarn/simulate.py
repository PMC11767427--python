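"""Synthetic three-stage metabolomic cohorts with planted ground truth.

The generator encodes the dynamic-network-biomarker premise: a "domain"
block of metabolites whose intra-block correlation and variance surge at
the middle (osteopenia-like) stage while its coupling to the rest of the
network drops, a partial relaxation at the overt-disease stage, plus
monotone abundance trends for a subset of metabolites, missing-at-random
cells, and clinical covariates carrying an exposure -> mediator ->
binary-outcome path.  Concentrations are simulated on the log scale and
exponentiated, so abundances are positive (log-normal); rank-based tests
are invariant to this and correlation structure is approximately
preserved at the small log-SDs used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import STAGES, Cohort

#: Baseline log-scale SD of every metabolite (dimensionless, log-concentration).
BASE_LOG_SD = 0.25
#: Residual correlation among background metabolites.
BACKGROUND_RHO = 0.1


@dataclass
class SimConfig:
    """Generative parameters for a three-stage synthetic cohort.

    Stage-indexed tuples are ordered (control, osteopenia, osteoporosis).
    ``rho_in`` / ``rho_out`` / ``sd_scale`` encode the DNB signature:
    intra-domain correlation and variance peak at the middle stage while
    domain-to-background coupling dips.
    """

    n_per_stage: int = 50
    n_metabolites: int = 60
    domain_size: int = 10
    rho_in: tuple[float, float, float] = (0.2, 0.7, 0.35)
    rho_out: tuple[float, float, float] = (0.15, 0.05, 0.10)
    sd_scale: tuple[float, float, float] = (1.0, 2.0, 1.3)
    n_trend: int = 8
    trend_step: float = 0.5          # mean shift per stage, in units of BASE_LOG_SD
    mediation: dict = field(default_factory=lambda: {"alpha": 0.5, "beta": 0.8, "gamma": 0.3})
    missing_fraction: float = 0.05
    gender: str = "female"
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_stage < 2:
            raise ValueError("n_per_stage must be >= 2")
        if not 2 <= self.domain_size <= self.n_metabolites:
            raise ValueError("domain_size must be in [2, n_metabolites]")
        if self.domain_size + self.n_trend > self.n_metabolites:
            raise ValueError("domain and trend blocks exceed n_metabolites")
        if not 0 <= self.missing_fraction < 0.5:
            raise ValueError("missing_fraction must be in [0, 0.5)")
        for name in ("rho_in", "rho_out", "sd_scale"):
            if len(getattr(self, name)) != 3:
                raise ValueError(f"{name} must list one value per stage")

    @property
    def is_null(self) -> bool:
        """True when no DNB is planted (flat stage parameters)."""
        return (len(set(self.rho_in)) == 1 and len(set(self.rho_out)) == 1
                and len(set(self.sd_scale)) == 1)


@dataclass
class TruthTable:
    """Planted ground truth accompanying a generated dataset."""

    domain_members: list[str]
    trend_members: dict[str, int]          # metabolite id -> shift direction (+1/-1)
    mediator_id: str | None
    true_acme: float | None
    regime: str                            # "dnb" or "null"
    params: dict


def _stage_correlation(cfg: SimConfig, stage_idx: int) -> np.ndarray:
    p, d = cfg.n_metabolites, cfg.domain_size
    c = np.full((p, p), BACKGROUND_RHO)
    c[:d, :d] = cfg.rho_in[stage_idx]
    c[:d, d:] = cfg.rho_out[stage_idx]
    c[d:, :d] = cfg.rho_out[stage_idx]
    np.fill_diagonal(c, 1.0)
    try:
        np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"stage {STAGES[stage_idx]} correlation matrix is not positive definite "
            f"(rho_in={cfg.rho_in[stage_idx]}, rho_out={cfg.rho_out[stage_idx]}, "
            f"background={BACKGROUND_RHO})"
        ) from None
    return c


def generate_cohort(config: SimConfig) -> tuple[Cohort, TruthTable]:
    """Draw a three-stage cohort from the configured generative model.

    Per stage, log-abundances are multivariate normal with the block
    correlation structure above; domain SDs are multiplied by the stage's
    ``sd_scale``; trend metabolites drift by ``stage_index * trend_step``
    SD units (alternating directions).  Deterministic under a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p, d, n = config.n_metabolites, config.domain_size, config.n_per_stage
    met_ids = [f"M{i:03d}" for i in range(p)]
    domain = met_ids[:d]
    trend_ids = met_ids[d:d + config.n_trend]
    directions = {m: (1 if i % 2 == 0 else -1) for i, m in enumerate(trend_ids)}

    blocks = []
    for s_idx, stage in enumerate(STAGES):
        corr = _stage_correlation(config, s_idx)
        sd = np.full(p, BASE_LOG_SD)
        sd[:d] *= config.sd_scale[s_idx]
        cov = corr * np.outer(sd, sd)
        chol = np.linalg.cholesky(cov)
        mean = np.zeros(p)
        for i, m in enumerate(trend_ids):
            mean[d + i] = directions[m] * s_idx * config.trend_step * BASE_LOG_SD
        z = rng.standard_normal((n, p))
        blocks.append(mean + z @ chol.T)
    logvals = np.vstack(blocks)

    stages = np.repeat(list(STAGES), n)
    sample_ids = [f"S{i:04d}" for i in range(3 * n)]

    # exposure -> mediator path planted on one background metabolite
    med = config.mediation or {}
    mediator_id: str | None = None
    exposure = rng.standard_normal(3 * n)
    if med:
        mediator_id = met_ids[-1]
        logvals[:, -1] += med.get("alpha", 0.0) * exposure * BASE_LOG_SD

    abundance = pd.DataFrame(np.exp(logvals), index=sample_ids, columns=met_ids)

    if config.missing_fraction > 0:
        n_total = 3 * n
        k = int(round(config.missing_fraction * n_total))
        for j in range(p):
            rows = rng.choice(n_total, size=k, replace=False)
            abundance.iloc[rows, j] = np.nan

    metadata = pd.DataFrame(
        {
            "stage": stages,
            "gender": config.gender,
            "tffm": exposure,
            "osteocalcin": rng.standard_normal(3 * n),
            "pinp": rng.standard_normal(3 * n),
            "beta_ctx": rng.standard_normal(3 * n),
        },
        index=sample_ids,
    )

    truth = TruthTable(
        domain_members=domain,
        trend_members=directions,
        mediator_id=mediator_id,
        true_acme=None,
        regime="null" if config.is_null else "dnb",
        params={
            "rho_in": list(config.rho_in),
            "rho_out": list(config.rho_out),
            "sd_scale": list(config.sd_scale),
            "trend_step": config.trend_step,
            "mediation": dict(med),
            "seed": config.seed,
        },
    )
    return Cohort(abundance, metadata), truth


def true_acme(alpha: float, beta: float, gamma: float,
              control_value: float = -1.0, treat_value: float = 1.0,
              intercept: float = 0.0, n_nodes: int = 80) -> float:
    """Average causal mediation effect of the generative logistic model.

    With mediator M(t) ~ N(alpha*t, 1) and
    P(Y=1 | t, m) = expit(intercept + gamma*t + beta*m), the ACME at
    exposure level t' is the Gauss-Hermite integral of the potential
    outcome difference between mediator laws M(t1) and M(t0); the
    returned value averages over t' in {t0, t1} (risk-difference scale).
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    e = np.sqrt(2.0) * nodes          # standard-normal quadrature points
    w = weights / np.sqrt(np.pi)
    acmes = []
    for t_prime in (control_value, treat_value):
        p1 = np.sum(w * expit(intercept + gamma * t_prime + beta * (alpha * treat_value + e)))
        p0 = np.sum(w * expit(intercept + gamma * t_prime + beta * (alpha * control_value + e)))
        acmes.append(p1 - p0)
    return float(np.mean(acmes))


def generate_mediation_data(
    config: SimConfig, n: int | None = None
) -> tuple[pd.Series, pd.Series, pd.Series, TruthTable]:
    """Simulate an exposure -> mediator -> binary outcome triple.

    exposure ~ N(0,1); mediator = alpha*exposure + N(0,1);
    P(outcome=1) = expit(gamma*exposure + beta*mediator).  The analytic
    ACME (numeric integration) is stored in the TruthTable.
    """
    config.validate()
    if not config.mediation:
        raise ValueError("config.mediation must be set")
    med = config.mediation
    alpha, beta, gamma = med["alpha"], med["beta"], med["gamma"]
    if n is None:
        n = 3 * config.n_per_stage
    rng = np.random.default_rng(config.seed)
    exposure = rng.standard_normal(n)
    mediator = alpha * exposure + rng.standard_normal(n)
    prob = expit(gamma * exposure + beta * mediator)
    outcome = (rng.random(n) < prob).astype(int)
    idx = pd.RangeIndex(n)
    truth = TruthTable(
        domain_members=[],
        trend_members={},
        mediator_id="mediator",
        true_acme=true_acme(alpha, beta, gamma),
        regime="mediation",
        params={"alpha": alpha, "beta": beta, "gamma": gamma, "n": n, "seed": config.seed},
    )
    return (pd.Series(exposure, idx, name="exposure"),
            pd.Series(mediator, idx, name="mediator"),
            pd.Series(outcome, idx, name="outcome"),
            truth)


def generate_labeled_features(
    n: int = 160,
    n_informative: int = 5,
    n_noise: int = 15,
    shift: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Balanced two-class feature matrix for classifier calibration tests.

    Informative features are shifted by ``shift`` SD units in the positive
    class; noise features are standard normal in both classes.
    """
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], [n - n // 2, n // 2])
    p = n_informative + n_noise
    x = rng.standard_normal((n, p))
    x[:, :n_informative] += shift * y[:, None]
    cols = [f"F{i:02d}" for i in range(p)]
    idx = pd.Index([f"S{i:04d}" for i in range(n)])
    return (pd.DataFrame(x, index=idx, columns=cols),
            pd.Series(y, index=idx, name="label"),
            cols[:n_informative])
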