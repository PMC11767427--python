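"""Causal mediation with a continuous mediator and binary outcome.

Two fitted models — a linear regression of the mediator on the exposure
and a logistic regression of the outcome on exposure + mediator — feed a
quasi-Bayesian potential-outcomes algorithm: model parameters are drawn
from their asymptotic normal distribution, counterfactual mediator values
are simulated at the treat/control exposure levels (mean +/- 1 SD for a
continuous exposure), and potential-outcome probability differences are
averaged.  Effects are on the risk-difference scale; ACME + ADE equals
the total effect exactly by construction (shared mediator noise draws).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """Point estimates and percentile CIs on the risk-difference scale."""

    acme: float
    acme_ci: tuple[float, float]
    ade: float
    ade_ci: tuple[float, float]
    total: float
    total_ci: tuple[float, float]
    proportion_mediated: float | None   # reported only when total CI excludes 0
    n_draws: int
    n_obs: int
    exposure: str
    mediator: str
    outcome: str
    treat_value: float
    control_value: float

    @property
    def acme_significant(self) -> bool:
        lo, hi = self.acme_ci
        return not (lo <= 0.0 <= hi)

    @property
    def total_significant(self) -> bool:
        lo, hi = self.total_ci
        return not (lo <= 0.0 <= hi)

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure, "mediator": self.mediator, "outcome": self.outcome,
            "acme": self.acme, "acme_ci_low": self.acme_ci[0], "acme_ci_high": self.acme_ci[1],
            "ade": self.ade, "ade_ci_low": self.ade_ci[0], "ade_ci_high": self.ade_ci[1],
            "total": self.total, "total_ci_low": self.total_ci[0],
            "total_ci_high": self.total_ci[1],
            "proportion_mediated": self.proportion_mediated,
            "acme_significant": self.acme_significant,
            "total_significant": self.total_significant,
            "n_draws": self.n_draws, "n_obs": self.n_obs,
            "treat_value": self.treat_value, "control_value": self.control_value,
        }


def _percentile_ci(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    lo = (1 - level) / 2 * 100
    return (float(np.percentile(draws, lo)), float(np.percentile(draws, 100 - lo)))


def mediate(
    exposure,
    mediator,
    outcome,
    n_draws: int = 1000,
    seed: int = 0,
    treat_value: float | None = None,
    control_value: float | None = None,
    noise_draws: int = 100,
    names: tuple[str, str, str] = ("exposure", "mediator", "outcome"),
) -> MediationResult:
    """Estimate ACME, ADE and the total effect of an exposure on a
    binary outcome through a continuous mediator.

    Parameters
    ----------
    exposure, mediator
        Numeric vectors without missing values (drop incomplete rows
        upstream).
    outcome
        Binary vector in {0, 1}, both classes present.
    n_draws
        Quasi-Bayesian parameter draws (percentile 95% CIs over draws).
    treat_value, control_value
        Exposure contrast; defaults to mean +/- 1 SD of the exposure.
    noise_draws
        Mediator-noise simulations per parameter draw.
    """
    e = np.asarray(exposure, dtype=float).ravel()
    m = np.asarray(mediator, dtype=float).ravel()
    y = np.asarray(outcome, dtype=float).ravel()
    if not (len(e) == len(m) == len(y)):
        raise ValueError("exposure, mediator and outcome lengths differ")
    if np.isnan(e).any() or np.isnan(m).any() or np.isnan(y).any():
        raise ValueError("missing values present; drop incomplete rows upstream")
    if len(e) < 10:
        raise ValueError(f"only {len(e)} complete rows; need >= 10")
    uniq = set(np.unique(y))
    if not uniq <= {0.0, 1.0} or len(uniq) < 2:
        raise ValueError("outcome must be binary with both classes present")

    if treat_value is None:
        treat_value = float(e.mean() + e.std(ddof=1))
    if control_value is None:
        control_value = float(e.mean() - e.std(ddof=1))

    x_med = sm.add_constant(e)
    med_fit = sm.OLS(m, x_med).fit()
    sigma = float(np.sqrt(med_fit.scale))

    x_out = sm.add_constant(np.column_stack([e, m]))
    try:
        out_fit = sm.Logit(y, x_out).fit(disp=0, maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels-specific failure
        raise ValueError(
            "logistic outcome model failed (possible separation); "
            "consider a regularized fit"
        ) from exc
    if not np.all(np.isfinite(out_fit.params)) or np.abs(out_fit.params).max() > 50:
        raise ValueError("separation detected in the logistic outcome model; "
                         "consider a regularized fit")

    rng = np.random.default_rng(seed)
    med_draws = rng.multivariate_normal(med_fit.params, med_fit.cov_params(), size=n_draws)
    out_draws = rng.multivariate_normal(out_fit.params, out_fit.cov_params(), size=n_draws)
    eps = rng.standard_normal((n_draws, noise_draws))

    a0, a1 = med_draws[:, 0][:, None], med_draws[:, 1][:, None]
    m1 = a0 + a1 * treat_value + sigma * eps     # counterfactual mediator laws
    m0 = a0 + a1 * control_value + sigma * eps

    g0 = out_draws[:, 0][:, None]
    g1 = out_draws[:, 1][:, None]
    g2 = out_draws[:, 2][:, None]

    def p(t, mvals):
        return expit(g0 + g1 * t + g2 * mvals).mean(axis=1)

    p_t1_m1 = p(treat_value, m1)
    p_t1_m0 = p(treat_value, m0)
    p_t0_m1 = p(control_value, m1)
    p_t0_m0 = p(control_value, m0)

    acme_d = 0.5 * ((p_t1_m1 - p_t1_m0) + (p_t0_m1 - p_t0_m0))
    ade_d = 0.5 * ((p_t1_m1 - p_t0_m1) + (p_t1_m0 - p_t0_m0))
    total_d = p_t1_m1 - p_t0_m0          # = acme_d + ade_d identically

    acme, ade, total = (float(v.mean()) for v in (acme_d, ade_d, total_d))
    acme_ci = _percentile_ci(acme_d)
    ade_ci = _percentile_ci(ade_d)
    total_ci = _percentile_ci(total_d)
    total_sig = not (total_ci[0] <= 0.0 <= total_ci[1])
    prop = float(acme / total) if (total_sig and total != 0) else None

    return MediationResult(
        acme=acme, acme_ci=acme_ci,
        ade=ade, ade_ci=ade_ci,
        total=total, total_ci=total_ci,
        proportion_mediated=prop,
        n_draws=n_draws, n_obs=len(e),
        exposure=names[0], mediator=names[1], outcome=names[2],
        treat_value=treat_value, control_value=control_value,
    )
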