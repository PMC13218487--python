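"""Marginal likelihood by path sampling, and Bayes factors.

The log marginal likelihood is the thermodynamic integral
``log Z = ∫_0^1 E_beta[log L] d beta`` over power posteriors
``p_beta ∝ prior * L^beta``.  Expected log likelihoods are estimated by MCMC
at each beta on a Beta(shape, 1)-quantile schedule (concentrated near 0,
where the integrand varies fastest) and integrated with the trapezoid rule.
Power-posterior steps are independent and mergeable, so they can be run in
any order or in parallel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .diagnostics import ess as _ess


def power_posterior_schedule(n_steps: int = 30, shape: float = 0.3) -> np.ndarray:
    """Beta values ``(k/(K-1))**(1/shape)``, monotone from 0 to 1.

    ``shape=1`` gives uniform spacing; the default 0.3 concentrates steps
    near the prior end.
    """
    if n_steps < 2:
        raise ValueError("need at least two power-posterior steps")
    if shape <= 0:
        raise ValueError("shape must be positive")
    k = np.arange(n_steps, dtype=float)
    return (k / (n_steps - 1)) ** (1.0 / shape)


@dataclass
class PathSamplingResult:
    log_ml: float
    se: float
    steps: pd.DataFrame  # beta, mean_loglik, var_loglik, ess


def path_sampling_log_ml(
    run_power_chain: Callable[[float, int], np.ndarray],
    schedule: np.ndarray | None = None,
    ess_floor: float = 20.0,
) -> PathSamplingResult:
    """Estimate the log marginal likelihood.

    ``run_power_chain(beta, step_index)`` must return post-burn-in samples of
    the (untempered) log likelihood under the power posterior at ``beta``.
    Raises if a step's log-likelihood ESS falls below ``ess_floor``; warns if
    adjacent power posteriors barely overlap (their means differ by more than
    ten pooled standard deviations).
    """
    betas = np.asarray(schedule if schedule is not None else power_posterior_schedule())
    if len(betas) < 2 or not (betas[0] == 0.0 and betas[-1] == 1.0):
        raise ValueError("schedule must run from beta=0 to beta=1")
    rows = []
    for k, beta in enumerate(betas):
        ll = np.asarray(run_power_chain(float(beta), k), dtype=float)
        e = _ess(ll) if len(ll) >= 10 and np.ptp(ll) > 0 else float(len(ll))
        if e < ess_floor:
            raise RuntimeError(f"power posterior at beta={beta:.4g}: ESS {e:.1f} < {ess_floor}")
        rows.append({"beta": beta, "mean_loglik": ll.mean(), "var_loglik": ll.var(), "ess": e})
    df = pd.DataFrame(rows)
    means = df["mean_loglik"].to_numpy()
    sds = np.sqrt(df["var_loglik"].to_numpy())
    for k in range(len(betas) - 1):
        pooled = np.hypot(sds[k], sds[k + 1]) + 1e-12
        if abs(means[k + 1] - means[k]) > 10 * pooled:
            warnings.warn(
                f"adjacent power posteriors at beta={betas[k]:.3g},{betas[k+1]:.3g} barely overlap"
            )
    dbeta = np.diff(betas)
    log_ml = float(np.sum(dbeta * (means[:-1] + means[1:]) / 2.0))
    # trapezoid coefficient of each step's mean
    coef = np.zeros(len(betas))
    coef[:-1] += dbeta / 2.0
    coef[1:] += dbeta / 2.0
    mc_var = df["var_loglik"].to_numpy() / df["ess"].to_numpy()
    se = float(np.sqrt(np.sum(coef**2 * mc_var)))
    return PathSamplingResult(log_ml=log_ml, se=se, steps=df)


def bayes_factors(log_mls: dict[str, float] | list[float]) -> pd.DataFrame:
    """Bayes factors of each model against the best-supported model
    (``BF_i = exp(logML_i - max logML)``; the best model has BF 1)."""
    if isinstance(log_mls, dict):
        names = list(log_mls)
        vals = np.array([log_mls[n] for n in names], dtype=float)
    else:
        vals = np.asarray(log_mls, dtype=float)
        names = [f"model_{i+1}" for i in range(len(vals))]
    if len(vals) < 2:
        raise ValueError("need at least two models to compare")
    best = vals.max()
    return pd.DataFrame(
        {"model": names, "log_ml": vals, "bayes_factor_vs_best": np.exp(vals - best)}
    )
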