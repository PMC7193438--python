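"""Seeded Monte Carlo generators for banks, abilities, and response matrices.

The study design these generators emulate: a 75-item, five-domain
developmental screening bank (domain sizes 11/13/19/18/14, difficulties
spanning −7.35 to 8.03 logits), 1000 simulated examinees with standard-normal
person measures clamped to [−8, 8] logits, and a full persons × items
dichotomous response matrix drawn cell-wise from the Rasch response
probability.

All generators are pure functions of their configuration (including the
seed): the same config yields byte-identical output.  Independent
sub-streams are derived from the seed for the bank, the abilities, and the
responses so the three draws do not alias each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .rasch import AbilityProfile, DomainCovariance, Item, ItemBank, response_probability

__all__ = [
    "DEFAULT_DOMAINS",
    "SimulationConfig",
    "generate_item_bank",
    "generate_abilities",
    "generate_responses",
    "abilities_to_frame",
]

#: The five developmental domains of the screening tool, in instrument order.
DEFAULT_DOMAINS = ("cognitive", "language", "gross_motor", "fine_motor", "social")

#: Per-domain item counts of the emulated 75-item bank.
DEFAULT_ITEMS_PER_DOMAIN = (11, 13, 19, 18, 14)

#: Published difficulty range of the calibrated bank, logits.
DEFAULT_DIFFICULTY_RANGE = (-7.35, 8.03)


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one Monte Carlo replicate.

    Attributes
    ----------
    n_persons : int
        Number of simulated examinees (study default 1000).
    items_per_domain : tuple of int
        Bank size per domain; default (11, 13, 19, 18, 14).
    domains : tuple of str
        Domain labels, parallel to ``items_per_domain``.
    difficulty_range : (float, float)
        Uniform support of generated item difficulties, logits.
    ability_clamp : (float, float)
        Person true measures are clamped to this range after the normal draw.
    domain_correlation : float or array
        Scalar exchangeable cross-domain correlation (default 0.9, matching
        the high observed between-domain consistency) or a full correlation /
        covariance matrix.
    seed : int
        Master seed; every generator stream derives from it.
    """

    n_persons: int = 1000
    items_per_domain: tuple[int, ...] = DEFAULT_ITEMS_PER_DOMAIN
    domains: tuple[str, ...] = DEFAULT_DOMAINS
    difficulty_range: tuple[float, float] = DEFAULT_DIFFICULTY_RANGE
    ability_clamp: tuple[float, float] = (-8.0, 8.0)
    domain_correlation: object = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError(f"n_persons must be >= 1, got {self.n_persons}")
        if len(self.items_per_domain) != len(self.domains):
            raise ValueError("items_per_domain and domains must have equal length")
        if any(n < 1 for n in self.items_per_domain):
            raise ValueError("every domain needs at least one item")
        lo, hi = self.difficulty_range
        if not lo <= hi:
            raise ValueError(f"difficulty_range low must be <= high, got ({lo}, {hi})")
        lo, hi = self.ability_clamp
        if not lo < hi:
            raise ValueError(f"ability_clamp low must be < high, got ({lo}, {hi})")
        self.covariance()  # validates the correlation input

    def covariance(self) -> DomainCovariance:
        """Cross-domain prior covariance implied by ``domain_correlation``."""
        rho = self.domain_correlation
        if np.isscalar(rho):
            rho = float(rho)
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"correlation must be in [-1, 1], got {rho}")
            # perfect correlation handled by degenerate draw in generate_abilities
            if rho == 1.0 or (len(self.domains) > 1 and rho == -1.0):
                raise_degenerate = rho == -1.0 and len(self.domains) > 2
                if raise_degenerate:
                    raise ValueError("correlation -1 is not positive definite for >2 domains")
                # substitute a near-degenerate PD matrix for validation purposes
                eps = 1e-9
                k = len(self.domains)
                m = np.full((k, k), rho * (1 - eps))
                np.fill_diagonal(m, 1.0)
                return DomainCovariance(m, self.domains)
            return DomainCovariance.exchangeable(self.domains, rho)
        m = np.asarray(rho, dtype=float)
        return DomainCovariance(m, self.domains)


def _stream(config: SimulationConfig, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), purpose]))


def generate_item_bank(config: SimulationConfig) -> ItemBank:
    """Draw a synthetic calibrated bank emulating the published item pool.

    Difficulties are uniform over ``config.difficulty_range`` (the publication
    reports only the range), sorted ascending within each domain; item ids are
    ``<domain>_<k>`` in that sorted order.  Deterministic given the seed.
    """
    rng = _stream(config, 1)
    items: list[Item] = []
    lo, hi = config.difficulty_range
    for domain, n in zip(config.domains, config.items_per_domain):
        diffs = np.sort(rng.uniform(lo, hi, size=n))
        for k, b in enumerate(diffs, start=1):
            items.append(Item(f"{domain}_{k:02d}", domain, float(b)))
    return ItemBank(items, domains=config.domains)


def generate_abilities(config: SimulationConfig) -> list[AbilityProfile]:
    """Draw correlated per-domain true person measures.

    One multivariate-normal draw per person: zero mean, unit variances, and
    the configured cross-domain correlation; each coordinate is then clamped
    to ``ability_clamp``.  A scalar correlation of exactly 1 degenerates to a
    single shared draw per person.
    """
    rng = _stream(config, 2)
    k = len(config.domains)
    lo, hi = config.ability_clamp
    if np.isscalar(config.domain_correlation) and float(config.domain_correlation) == 1.0:
        z = rng.standard_normal(config.n_persons)
        draws = np.repeat(z[:, None], k, axis=1)
    else:
        cov = config.covariance().matrix
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((config.n_persons, k))
        draws = z @ chol.T
    draws = np.clip(draws, lo, hi)
    return [
        AbilityProfile({d: float(t) for d, t in zip(config.domains, row)})
        for row in draws
    ]


def abilities_to_frame(profiles: Sequence[AbilityProfile]) -> pd.DataFrame:
    """Stack profiles into a persons × domains DataFrame of true measures."""
    domains = profiles[0].domains
    data = np.array([p.theta_vector(domains) for p in profiles])
    index = pd.Index([f"p{i + 1:04d}" for i in range(len(profiles))], name="person_id")
    return pd.DataFrame(data, index=index, columns=list(domains))


def generate_responses(
    abilities: Sequence[AbilityProfile],
    bank: ItemBank,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the full persons × items dichotomous response matrix.

    Cell (n, i) is Bernoulli with success probability
    ``response_probability(theta_n[domain(i)], difficulty_i)``.  Returned as a
    DataFrame indexed by person id with one integer 0/1 column per item id.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    domains = list(bank.domains)
    theta = np.array(
        [[p.theta_by_domain[d] for d in domains] for p in abilities]
    )  # persons × domains
    dom_index = {d: j for j, d in enumerate(domains)}
    cols = np.array([dom_index[it.domain] for it in bank], dtype=int)
    b = bank.difficulties()
    p = response_probability(theta[:, cols], b[None, :])
    x = (rng.random(p.shape) < p).astype(np.int8)
    index = pd.Index([f"p{i + 1:04d}" for i in range(len(abilities))], name="person_id")
    return pd.DataFrame(x, index=index, columns=bank.item_ids())
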