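"""Covariate-adjusted Poisson background for breakpoint densities."""

from __future__ import annotations

import logging

import numpy as np
import statsmodels.api as sm

from ..cohort_io.model import InvalidInputError
from .tracks import BinnedTrack

logger = logging.getLogger(__name__)


def _standardize(columns: np.ndarray) -> np.ndarray:
    mu = columns.mean(axis=0)
    sd = columns.std(axis=0)
    sd[sd == 0] = 1.0  # constant covariates standardize to zero, not NaN
    return (columns - mu) / sd


def _ridge_poisson_irls(X: np.ndarray, y: np.ndarray, alpha: float = 1e-6) -> np.ndarray:
    """L2-regularized Poisson IRLS fallback for degenerate designs."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-12))
    penalty = alpha * np.eye(p)
    penalty[0, 0] = 0.0  # never shrink the intercept
    for _ in range(100):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        XtW = X.T * mu
        try:
            new = np.linalg.solve(XtW @ X + penalty, XtW @ z)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(XtW @ X + penalty, XtW @ z, rcond=None)[0]
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


def fit_background(counts: BinnedTrack, covariates=()) -> tuple:
    """Fit per-bin expected breakpoint counts by Poisson log-linear regression.

    Covariates are standardized genome-wide; with none supplied the expectation
    is the global mean count. Collinear designs fall back to a ridge IRLS fit
    (logged); fitted totals are renormalized to match the observed total.

    Returns (expected_track, coefficients).
    """
    for cov in covariates:
        if not counts.same_grid(cov):
            raise InvalidInputError("covariate track not on the count track's bin grid")

    y = counts.concat()
    if y.size == 0:
        raise InvalidInputError("empty count track")

    if len(covariates) == 0:
        expected = np.full_like(y, y.mean())
        return counts.like(expected), np.array([np.log(max(y.mean(), 1e-300))])

    Z = _standardize(np.column_stack([cov.concat() for cov in covariates]))
    X = np.column_stack([np.ones(y.size), Z])

    beta = None
    try:
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        if np.all(np.isfinite(fit.params)):
            beta = np.asarray(fit.params)
    except Exception as exc:  # statsmodels raises several flavours on separation
        logger.warning("Poisson GLM failed (%s); using ridge fallback", exc)
    if beta is None or not np.all(np.isfinite(beta)):
        logger.warning("degenerate covariate design; ridge IRLS fallback engaged")
        beta = _ridge_poisson_irls(X, y)

    expected = np.exp(np.clip(X @ beta, -30, 30))
    total = expected.sum()
    if total > 0:
        expected *= y.sum() / total
    return counts.like(expected), beta
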