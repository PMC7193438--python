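"""Person-measure estimation, standard errors, reliability, and fit statistics.

Maximum-likelihood estimation follows the Newton–Raphson scheme: the score of
the Rasch log-likelihood at the provisional measure is the residual sum
(observed − expected responses) and the negative curvature is the summed item
information, so each iteration moves the measure by ``score / information``.
Steps are damped to at most one logit and fall back to halving whenever the
log-likelihood would decrease; the likelihood is globally concave, so the
damped iteration converges for every mixed response pattern.  Perfect and
zero raw scores have no finite maximizer and are clamped to the ±8-logit
ability range with a flag.

A joint maximum-a-posteriori (MAP) estimator under a multivariate-normal
prior across domains is provided for the adaptive engine: unlike the MLE it
is defined before a mixed response pattern exists and lets information flow
between correlated domains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .rasch import (
    ABILITY_CLAMP,
    AbilityProfile,
    DomainCovariance,
    ItemBank,
    item_information,
    log_likelihood,
    response_probability,
)

__all__ = [
    "EstimationResult",
    "FitReport",
    "estimate_mle",
    "estimate_map",
    "standard_error",
    "reliability_from_sem",
    "fit_statistics",
]

#: Standardized-residual magnitude beyond which an item response is flagged
#: as aberrant.
ABERRANT_Z = 2.0


@dataclass(frozen=True)
class EstimationResult:
    """Outcome of one person-measure estimation."""

    theta: float
    sem: float
    n_iterations: int
    converged: bool
    clamped: bool

    def __post_init__(self) -> None:
        if not self.sem > 0:
            raise ValueError(f"SEM must be > 0, got {self.sem}")


@dataclass(frozen=True)
class FitReport:
    """Person-fit diagnostics for one response vector.

    ``outfit_msq`` is the outfit mean square — the mean squared standardized
    residual over the administered items, expected near 1 under model fit.
    ``z_by_item`` holds the per-item standardized residuals and
    ``aberrant_flags`` marks responses with |z| above 2.
    """

    outfit_msq: float
    z_by_item: np.ndarray
    aberrant_flags: np.ndarray


def _validate_pattern(responses, difficulties):
    x = np.asarray(responses, dtype=float)
    b = np.asarray(difficulties, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one response")
    if x.shape != b.shape:
        raise ValueError(f"responses {x.shape} vs difficulties {b.shape}")
    if not np.all(np.isin(x, (0.0, 1.0))):
        raise ValueError("responses must be 0 or 1")
    if not np.all(np.isfinite(b)):
        raise ValueError("difficulties must be finite")
    return x, b


def standard_error(theta: float, difficulties) -> float:
    """SEM of a person measure: reciprocal root of the summed information.

    ``SEM = 1 / sqrt(sum_i p_i (1 - p_i))`` over the administered items —
    strictly decreasing as items are appended (for fixed theta).
    """
    b = np.asarray(difficulties, dtype=float)
    if b.size == 0:
        raise ValueError("need at least one administered item")
    total = float(np.sum(item_information(theta, b)))
    return 1.0 / np.sqrt(total)


def reliability_from_sem(sem: float) -> float:
    """Person reliability under the unit true-score-variance convention.

    ``R = 1 − SEM²``, floored at 0; e.g. SEM ≈ 0.447 gives R = 0.80.
    """
    if not sem > 0:
        raise ValueError(f"SEM must be > 0, got {sem}")
    return max(0.0, 1.0 - sem * sem)


def estimate_mle(
    responses,
    difficulties,
    *,
    tol: float = 1e-4,
    max_iter: int = 50,
    clamp: tuple[float, float] = ABILITY_CLAMP,
) -> EstimationResult:
    """Newton–Raphson maximum-likelihood person measure for one domain.

    The update is ``theta += (raw score − expected score) / information``,
    damped to ±1 logit per step with halving on any likelihood decrease;
    convergence when the step falls below ``tol`` (default 1e-4 logits).
    All-correct / all-incorrect patterns return the clamp bound with
    ``clamped=True`` and the SEM evaluated there.
    """
    x, b = _validate_pattern(responses, difficulties)
    lo, hi = clamp
    raw = float(np.sum(x))

    if raw == 0.0 or raw == x.size:
        theta = lo if raw == 0.0 else hi
        return EstimationResult(
            theta=theta,
            sem=standard_error(theta, b),
            n_iterations=0,
            converged=True,
            clamped=True,
        )

    theta = 0.0
    ll = log_likelihood(x, np.full_like(b, theta), b)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = response_probability(theta, b)
        info = float(np.sum(p * (1.0 - p)))
        step = (raw - float(np.sum(p))) / info
        step = float(np.clip(step, -1.0, 1.0))  # damp big jumps
        # halve the step until the likelihood does not decrease
        for _ in range(30):
            cand = float(np.clip(theta + step, lo, hi))
            cand_ll = log_likelihood(x, np.full_like(b, cand), b)
            if cand_ll >= ll - 1e-12:
                break
            step /= 2.0
        moved = abs(cand - theta)
        theta, ll = cand, cand_ll
        if moved < tol:
            converged = True
            break

    clamped = theta in (lo, hi)
    return EstimationResult(
        theta=theta,
        sem=standard_error(theta, b),
        n_iterations=it,
        converged=converged,
        clamped=clamped,
    )


def estimate_map(
    responses: Mapping[str, int],
    bank: ItemBank,
    covariance: DomainCovariance,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> AbilityProfile:
    """Joint posterior mode across domains under a multivariate-normal prior.

    Parameters
    ----------
    responses : mapping item_id -> 0/1
        The administered responses, any subset of the bank (may be empty for
        a single domain; with no responses at all the prior mean 0 is
        returned).
    bank : ItemBank
    covariance : DomainCovariance
        Prior covariance across domains (mean zero).  With a diagonal matrix
        the estimate reduces to independent per-domain shrinkage; as the
        correlation approaches 1, data in one domain pull the others along.

    Returns
    -------
    AbilityProfile with posterior-mode measures and posterior-sd SEMs.
    """
    domains = list(bank.domains)
    if tuple(covariance.domains) != tuple(domains):
        raise ValueError("covariance domains must match bank domains")
    k = len(domains)
    dom_index = {d: j for j, d in enumerate(domains)}

    per_dom_b: list[list[float]] = [[] for _ in range(k)]
    per_dom_x: list[list[float]] = [[] for _ in range(k)]
    for item_id, resp in responses.items():
        if resp not in (0, 1):
            raise ValueError(f"response for {item_id!r} must be 0 or 1, got {resp!r}")
        it = bank[item_id]
        j = dom_index[it.domain]
        per_dom_b[j].append(it.difficulty)
        per_dom_x[j].append(float(resp))
    bs = [np.array(v) for v in per_dom_b]
    xs = [np.array(v) for v in per_dom_x]

    prec = covariance.precision
    theta = np.zeros(k)
    for _ in range(max_iter):
        score = np.array(
            [np.sum(xs[j] - response_probability(theta[j], bs[j])) if bs[j].size else 0.0
             for j in range(k)]
        )
        info = np.array(
            [np.sum(item_information(theta[j], bs[j])) if bs[j].size else 0.0
             for j in range(k)]
        )
        grad = score - prec @ theta
        hess = prec + np.diag(info)
        delta = np.linalg.solve(hess, grad)
        norm = float(np.max(np.abs(delta)))
        if norm > 1.0:  # damp, same 1-logit cap as the MLE path
            delta *= 1.0 / norm
        theta = theta + delta
        if norm < tol:
            break

    hess = covariance.precision + np.diag(
        [np.sum(item_information(theta[j], bs[j])) if bs[j].size else 0.0 for j in range(k)]
    )
    post_sd = np.sqrt(np.diag(np.linalg.inv(hess)))
    return AbilityProfile(
        theta_by_domain={d: float(t) for d, t in zip(domains, theta)},
        sem_by_domain={d: float(s) for d, s in zip(domains, post_sd)},
    )


def fit_statistics(responses, theta: float, difficulties) -> FitReport:
    """Outfit mean square and standardized residuals for one pattern.

    ``z_i = (x_i − p_i) / sqrt(p_i (1 − p_i))``; the outfit mean square is
    the mean of ``z_i²`` over the administered items, and responses with
    ``|z_i| > 2`` are flagged as aberrant.
    """
    x, b = _validate_pattern(responses, difficulties)
    p = response_probability(theta, b)
    z = (x - p) / np.sqrt(p * (1.0 - p))
    return FitReport(
        outfit_msq=float(np.mean(z**2)),
        z_by_item=np.asarray(z, dtype=float),
        aberrant_flags=np.abs(z) > ABERRANT_Z,
    )
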