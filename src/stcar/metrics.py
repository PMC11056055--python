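"""Model evaluation: WAIC, RMSE, MAE, and predictive-interval coverage.

WAIC is computed from the matrix of per-draw, per-observation log likelihoods
as ``WAIC = -2 (lpd - pWAIC)``, where lpd is the log pointwise predictive
density (log of the posterior-mean density per observation, via log-sum-exp)
and pWAIC the variance-based effective-parameter correction (the per-point
posterior variance of the log density).  Lower is better.

Coverage validates a fitted model on held-out records: for each test cell the
2.5th and 97.5th percentiles of posterior-predictive count draws form a 95%
interval, and the coverage percentage is the share of observed test counts
falling inside their intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .mcmc import PosteriorDraws
from .models import STModel
from .simulate import _zero_truncated_poisson

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WaicResult:
    """WAIC decomposition; satisfies ``waic == -2 * (lpd - p_waic)``."""

    waic: float
    lpd: float
    p_waic: float


@dataclass(frozen=True)
class CoverageResult:
    """Coverage percentage of predictive intervals on held-out records."""

    cp: float                 # in [0, 100]
    lower: np.ndarray
    upper: np.ndarray
    level: float


def waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """WAIC from a (draws, records) log-likelihood matrix.

    With a single draw the effective-parameter term is zero (degenerate
    posterior) and a warning is issued.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log likelihood must be 2-D (draws, records)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log likelihoods")
    S = ll.shape[0]
    lpd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    if S < 2:
        logger.warning("single posterior draw: p_waic is 0 by convention")
        p = 0.0
    else:
        p = float(np.sum(ll.var(axis=0, ddof=1)))
    return WaicResult(waic=-2.0 * (lpd - p), lpd=lpd, p_waic=p)


def point_predictions(draws: PosteriorDraws, model: STModel) -> np.ndarray:
    """Posterior-mean fitted intensity ``E[mu_it | y]`` on the full panel."""
    acc = np.zeros(model.data.shape)
    for theta in draws.draws:
        acc += np.exp(model.linear_predictor(model.unpack(theta)))
    return acc / draws.n_kept


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error ``sqrt(mean((y - yhat)^2))``."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute error ``mean(|y - yhat|)``."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(y - yhat)))


def coverage(
    draws: PosteriorDraws,
    model: STModel,
    test_index: np.ndarray,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
    kind: str = "predictive",
) -> CoverageResult:
    """Coverage percentage of 100*level% intervals on held-out records.

    The model must have been fitted with the test cells masked out of the
    likelihood; their random effects are then posterior draws from the prior
    given the sampled hyperparameters.  ``kind="predictive"`` (default) draws
    a zero-truncated Poisson count per retained posterior state and takes
    equal-tailed percentiles of the counts; ``kind="mean"`` instead takes
    percentiles of the latent intensity mu (credible, not predictive,
    intervals).
    """
    test_index = np.asarray(test_index, dtype=int).ravel()
    if test_index.size == 0:
        raise ValueError("empty test set")
    if kind not in ("predictive", "mean"):
        raise ValueError("kind must be 'predictive' or 'mean'")
    if rng is None:
        rng = np.random.default_rng(draws.config.seed + 1)
    yf = model.data.y.ravel()[test_index]
    S = draws.n_kept
    sims = np.empty((S, test_index.size))
    for s, theta in enumerate(draws.draws):
        mu = np.exp(model.linear_predictor(model.unpack(theta))).ravel()[test_index]
        sims[s] = _zero_truncated_poisson(mu, rng) if kind == "predictive" else mu
    alpha = 100.0 * (1.0 - level) / 2.0
    lower = np.percentile(sims, alpha, axis=0)
    upper = np.percentile(sims, 100.0 - alpha, axis=0)
    cp = 100.0 * float(np.mean((lower <= yf) & (yf <= upper)))
    return CoverageResult(cp=cp, lower=lower, upper=upper, level=level)
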