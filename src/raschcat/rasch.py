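"""Dichotomous Rasch response model over a between-item multidimensional bank.

The Rasch (one-parameter logistic) model places person abilities and item
difficulties on a common logit scale: the probability that person *n* answers
item *i* correctly is

    P(x_ni = 1) = exp(theta_n - b_i) / (1 + exp(theta_n - b_i))

where ``theta`` is the person measure and ``b`` the item difficulty, both in
logits.  Each item belongs to exactly one developmental domain (between-item
multidimensionality): the five-domain structure of screening tools such as
MuSiC (cognitive, language, gross motor, fine motor, socioadaptive skills).

Everything downstream — item information, likelihoods, adaptive selection —
derives from this response function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit, log_expit

__all__ = [
    "Item",
    "ItemBank",
    "AbilityProfile",
    "DomainCovariance",
    "response_probability",
    "item_information",
    "log_likelihood",
]

#: Hard range for person measures, in logits.  Mirrors the ability range the
#: bank is calibrated for; maximum-likelihood estimates of perfect/zero score
#: patterns are clamped here instead of diverging.
ABILITY_CLAMP = (-8.0, 8.0)

#: Item difficulties outside this range trigger a validation warning (they are
#: almost certainly data errors for a screening instrument).
DIFFICULTY_WARN_RANGE = (-10.0, 10.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Item:
    """One calibrated dichotomous item.

    Parameters
    ----------
    item_id : str
        Unique identifier within the bank.
    domain : str
        Label of the single domain the item loads on.
    difficulty : float
        Item difficulty in logits.
    age_min_months, age_max_months : float, optional
        Age applicability window; ``None`` means unrestricted.
    """

    item_id: str
    domain: str
    difficulty: float
    age_min_months: float | None = None
    age_max_months: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.difficulty):
            raise ValueError(
                f"item {self.item_id!r}: difficulty must be finite, "
                f"got {self.difficulty!r}"
            )


class ItemBank:
    """Ordered collection of calibrated items grouped into domains.

    Invariants enforced at construction: item ids are unique, every item's
    domain appears in the domain list, and each domain holds at least one
    item.  Difficulties outside ±10 logits raise a warning (not an error).
    """

    def __init__(self, items: Iterable[Item], domains: Sequence[str] | None = None):
        self.items: tuple[Item, ...] = tuple(items)
        if not self.items:
            raise ValueError("item bank must contain at least one item")

        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item_id(s): {dupes}")

        seen_domains: list[str] = []
        for it in self.items:
            if it.domain not in seen_domains:
                seen_domains.append(it.domain)
        if domains is None:
            domains = seen_domains
        else:
            domains = list(domains)
            missing = [d for d in seen_domains if d not in domains]
            if missing:
                raise ValueError(f"item domain(s) not in domain list: {missing}")
            empty = [d for d in domains if d not in seen_domains]
            if empty:
                raise ValueError(f"domain(s) with no items: {empty}")
        self.domains: tuple[str, ...] = tuple(domains)

        lo, hi = DIFFICULTY_WARN_RANGE
        out = [it.item_id for it in self.items if not lo <= it.difficulty <= hi]
        if out:
            warnings.warn(
                f"item difficulties outside [{lo}, {hi}] logits: {out}",
                stacklevel=2,
            )

        self._by_id: dict[str, Item] = {it.item_id: it for it in self.items}

    # -- accessors ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> Item:
        return self._by_id[item_id]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    def items_in_domain(self, domain: str) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.domain == domain)

    def difficulties(self, domain: str | None = None) -> np.ndarray:
        src = self.items if domain is None else self.items_in_domain(domain)
        return np.array([it.difficulty for it in src], dtype=float)

    def item_ids(self, domain: str | None = None) -> list[str]:
        src = self.items if domain is None else self.items_in_domain(domain)
        return [it.item_id for it in src]

    def domain_sizes(self) -> dict[str, int]:
        return {d: len(self.items_in_domain(d)) for d in self.domains}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sizes = ", ".join(f"{d}={n}" for d, n in self.domain_sizes().items())
        return f"ItemBank({len(self)} items; {sizes})"


@dataclass
class AbilityProfile:
    """Per-domain person measures (logits) with optional standard errors."""

    theta_by_domain: dict[str, float]
    sem_by_domain: dict[str, float] | None = None

    def __post_init__(self) -> None:
        lo, hi = ABILITY_CLAMP
        for d, t in self.theta_by_domain.items():
            if not np.isfinite(t):
                raise ValueError(f"domain {d!r}: theta must be finite")
            if not lo <= t <= hi:
                raise ValueError(
                    f"domain {d!r}: theta {t} outside clamp range [{lo}, {hi}]"
                )
        if self.sem_by_domain is not None:
            for d, s in self.sem_by_domain.items():
                if not s > 0:
                    raise ValueError(f"domain {d!r}: SEM must be > 0, got {s}")

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(self.theta_by_domain)

    def theta_vector(self, domains: Sequence[str] | None = None) -> np.ndarray:
        domains = self.domains if domains is None else domains
        return np.array([self.theta_by_domain[d] for d in domains], dtype=float)

    def mean_measure(self) -> float:
        """Arithmetic mean of the domain measures (the global screening score)."""
        return float(np.mean(list(self.theta_by_domain.values())))


class DomainCovariance:
    """Symmetric positive-definite covariance across domains.

    Used both as the prior for joint (MAP) estimation and as the prior
    precision term seeding the provisional information matrix for D-optimal
    item selection.
    """

    def __init__(self, matrix: np.ndarray, domains: Sequence[str]):
        m = np.asarray(matrix, dtype=float)
        domains = tuple(domains)
        if m.shape != (len(domains), len(domains)):
            raise ValueError(
                f"covariance shape {m.shape} does not match {len(domains)} domains"
            )
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        eig = np.linalg.eigvalsh(m)
        if np.min(eig) <= 0:
            raise ValueError(
                f"covariance matrix must be positive definite (min eigenvalue {eig.min():.3g})"
            )
        self.matrix = (m + m.T) / 2.0
        self.domains = domains
        self._precision = np.linalg.inv(self.matrix)

    @classmethod
    def exchangeable(cls, domains: Sequence[str], rho: float, variance: float = 1.0
                     ) -> "DomainCovariance":
        """Equicorrelated covariance: unit-variance default, correlation ``rho``."""
        k = len(domains)
        if k > 1 and not (-1.0 / (k - 1) < rho < 1.0):
            raise ValueError(
                f"exchangeable correlation {rho} not positive definite for k={k}"
            )
        m = np.full((k, k), rho * variance)
        np.fill_diagonal(m, variance)
        return cls(m, domains)

    @property
    def correlation(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.matrix))
        return self.matrix / np.outer(sd, sd)

    @property
    def precision(self) -> np.ndarray:
        return self._precision

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DomainCovariance({len(self.domains)} domains)"


# ---------------------------------------------------------------------------
# response model
# ---------------------------------------------------------------------------

def _check_finite(name: str, x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return arr


def response_probability(theta, difficulty):
    """Probability of a correct response under the dichotomous Rasch model.

    ``P = exp(theta - b) / (1 + exp(theta - b))``, evaluated through the
    numerically stable logistic so that logit differences of ±35 and beyond
    neither overflow nor underflow to an exact 0 or 1.

    Accepts scalars or broadcastable arrays; returns values strictly in (0, 1).
    """
    t = _check_finite("theta", theta)
    b = _check_finite("difficulty", difficulty)
    p = expit(t - b)
    # keep strictly inside (0,1) even for extreme logit differences
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)
    return p if p.ndim else float(p)


def item_information(theta, difficulty):
    """Fisher information of one dichotomous Rasch item: ``p(1-p)``.

    Maximal (0.25) when ability matches difficulty and symmetric in
    ``theta - difficulty``; this is the reciprocal of the response variance,
    and its running sum drives the standard error of measurement.
    """
    t = _check_finite("theta", theta)
    b = _check_finite("difficulty", difficulty)
    z = t - b
    # p(1-p) = expit(z)*expit(-z); stable at both tails
    info = expit(z) * expit(-z)
    return info if info.ndim else float(info)


def log_likelihood(responses, thetas, difficulties) -> float:
    """Log-likelihood of dichotomous responses under the Rasch model.

    The likelihood is the product of per-item response probabilities; this
    returns its log: ``sum(log p_i)`` over successes plus ``sum(log(1-p_i))``
    over failures.  Missing responses must be excluded by the caller.

    Parameters
    ----------
    responses : array-like of {0, 1}
    thetas : array-like
        Per-item person measure (the domain measure of the item's domain).
    difficulties : array-like
        Per-item difficulty in logits.
    """
    x = np.asarray(responses, dtype=float)
    t = _check_finite("thetas", thetas)
    b = _check_finite("difficulties", difficulties)
    if not (x.shape == t.shape == b.shape) or x.ndim != 1:
        raise ValueError(
            f"length mismatch: responses {x.shape}, thetas {t.shape}, "
            f"difficulties {b.shape}"
        )
    if not np.all(np.isin(x, (0.0, 1.0))):
        raise ValueError("responses must be 0 or 1")
    z = t - b
    # log p = log_expit(z); log(1-p) = log_expit(-z)
    return float(np.sum(x * log_expit(z) + (1.0 - x) * log_expit(-z)))
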