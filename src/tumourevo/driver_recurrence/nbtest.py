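"""Negative-binomial recurrence testing of genomic elements.

Observed per-element mutation counts are compared against context-derived
expectations under a negative binomial with a single dispersion shared across
elements (estimated by maximum likelihood, method-of-moments fallback).
Large dispersions recover the Poisson limit exactly in the tail computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from ..cohort_io.model import InvalidInputError
from .elements import estimate_context_rates, expected_element_count, observed_element_count

#: Dispersion above which the NB is numerically indistinguishable from Poisson.
POISSON_THETA = 1e12

MIN_ELEMENTS = 20


@dataclass
class DriverCallNC:
    element_id: str
    observed_count: int
    expected_count: float
    dispersion: float
    p_value: float
    q_value: float
    significant: bool = False


def nb_tail(y: int, mu: float, theta: float) -> float:
    """Upper tail P(Y >= y) for NB(mean mu, dispersion theta); Poisson as theta -> inf."""
    if y <= 0:
        return 1.0
    if mu <= 0:
        return 0.0
    if theta >= POISSON_THETA or not np.isfinite(theta):
        return float(stats.poisson.sf(y - 1, mu))
    # P(Y >= y) = I_{mu/(theta+mu)}(y, theta); more accurate than nbinom.sf
    # for very large dispersions
    return float(special.betainc(y, theta, mu / (theta + mu)))


def _nb_loglik(theta: float, y: np.ndarray, mu: np.ndarray) -> float:
    if theta >= POISSON_THETA:
        return float(np.sum(stats.poisson.logpmf(y, mu)))
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def estimate_dispersion(observed, expected) -> float:
    """Shared NB dispersion across elements by ML over log(theta).

    Returns ``inf`` (Poisson) when the likelihood is maximized at the
    boundary or when variance does not exceed the mean.
    """
    y = np.asarray(observed, dtype=float)
    mu = np.asarray(expected, dtype=float)
    mask = mu > 0
    y, mu = y[mask], mu[mask]
    if y.size == 0:
        return np.inf

    def neg_ll(log_theta):
        return -_nb_loglik(np.exp(log_theta), y, mu)

    try:
        res = optimize.minimize_scalar(neg_ll, bounds=(-5.0, 25.0), method="bounded")
        if res.success and np.isfinite(res.fun):
            theta = float(np.exp(res.x))
            # boundary solution == no evidence of overdispersion
            if res.x >= 24.5:
                return np.inf
            return theta
    except (ValueError, FloatingPointError):  # pragma: no cover - numeric fallback
        pass
    warnings.warn("NB dispersion ML failed; falling back to method of moments")
    excess = np.sum((y - mu) ** 2 - mu)
    if excess <= 0:
        return np.inf
    return float(np.sum(mu**2) / excess)


def test_element_counts(element_ids, observed, expected, fdr: float = 0.05) -> list:
    """Per-element NB upper-tail test with shared dispersion and BH correction."""
    observed = np.asarray(observed, dtype=int)
    expected = np.asarray(expected, dtype=float)
    if len(element_ids) != observed.size or observed.size != expected.size:
        raise InvalidInputError("element ids, observed and expected must align")
    if observed.size < MIN_ELEMENTS:
        raise InvalidInputError(
            f"dispersion estimation requires >= {MIN_ELEMENTS} elements, got {observed.size}"
        )
    theta = estimate_dispersion(observed, expected)
    p_values = np.array(
        [nb_tail(int(y), float(mu), theta) for y, mu in zip(observed, expected)]
    )
    p_values = np.clip(p_values, np.finfo(float).tiny, 1.0)
    q_values = multipletests(p_values, method="fdr_bh")[1]
    calls = [
        DriverCallNC(
            element_id=eid,
            observed_count=int(y),
            expected_count=float(mu),
            dispersion=float(theta),
            p_value=float(p),
            q_value=float(q),
            significant=bool(q <= fdr),
        )
        for eid, y, mu, p, q in zip(element_ids, observed, expected, p_values, q_values)
    ]
    calls.sort(key=lambda c: (c.q_value, c.p_value, c.element_id))
    return calls


def test_elements(
    elements,
    cohort,
    callable_context_abundance: dict,
    rates: Optional[dict] = None,
    fdr: float = 0.05,
) -> list:
    """End-to-end non-coding recurrence test over a cohort.

    Rates default to the cohort-wide context background; expectations are
    pooled per element across samples.
    """
    if rates is None:
        rates = estimate_context_rates(cohort, callable_context_abundance)
    n = len(cohort)
    ids = [e.element_id for e in elements]
    observed = [observed_element_count(e, cohort) for e in elements]
    expected = [expected_element_count(e, rates, n_samples=n) for e in elements]
    return test_element_counts(ids, observed, expected, fdr=fdr)
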