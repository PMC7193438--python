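"""Monte Carlo comparison of adaptive (MCAT) and nonadaptive (NAT) testing.

One comparison run simulates correlated true person measures, draws a single
complete persons × items response matrix, then scores every person twice:
nonadaptively (per-domain MLE over all items) and adaptively (replaying the
same recorded responses through the adaptive engine).  Replaying the same
row — rather than redrawing responses — makes the precision comparison
paired: any difference between the two scorings is attributable to item
selection alone.

The headline efficiency figure is the item-savings percentage
``100 · (NAT_total − mean MCAT total) / NAT_total``; precision is compared by
per-domain correlation of the two scorings and Welch two-sample tests on the
per-domain mean lengths and mean abilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .engine import StopRules, run_mcat, run_nat
from .estimate import fit_statistics
from .rasch import DomainCovariance, ItemBank
from .simulate import SimulationConfig, abilities_to_frame, generate_abilities, generate_responses

__all__ = [
    "ComparisonReport",
    "run_comparison",
    "savings_fraction",
    "estimate_matrix_summary",
    "two_sample_test",
]


def savings_fraction(nat_total: float, mcat_mean_total: float) -> float:
    """Item savings of adaptive testing, percent of the full bank length.

    ``100 · (nat_total − mcat_mean_total) / nat_total`` rounded to two
    decimals; e.g. 75 versus a mean of 40 items gives 46.67.
    """
    if not nat_total > 0:
        raise ValueError(f"nat_total must be > 0, got {nat_total}")
    if not 0 <= mcat_mean_total <= nat_total:
        raise ValueError(
            f"mcat_mean_total must be in [0, {nat_total}], got {mcat_mean_total}"
        )
    return round(100.0 * (nat_total - mcat_mean_total) / nat_total, 2)


def two_sample_test(values_a, values_b) -> tuple[float, float]:
    """Welch two-sample t test; returns (statistic, two-tailed p).

    Degenerate zero-variance inputs resolve analytically: equal means give
    (0, 1), separated means give (±inf, 0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    if se == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def estimate_matrix_summary(
    estimates: pd.DataFrame,
    sems: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Sample covariance/correlation of domain estimates, plus reliabilities.

    Parameters
    ----------
    estimates : DataFrame, persons × domains
    sems : DataFrame, persons × domains, optional
        Per-person SEMs; when given, each domain's reliability is
        ``1 / (1 + mean(SEM²))`` — true variance over observed variance
        under the unit true-score-variance convention, with the error
        variance estimated by the mean squared SEM.  Without SEMs the
        reliabilities are NaN.

    A domain with (numerically) zero variance gets NaN correlation entries
    off the diagonal rather than an error.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two persons")
    cov = estimates.cov()
    sd = np.sqrt(np.diag(cov.to_numpy()))
    degenerate = sd <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov.to_numpy() / np.outer(sd, sd)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.where(degenerate, np.nan, 1.0))
    corr = pd.DataFrame(corr, index=cov.index, columns=cov.columns)
    if sems is not None:
        rel = 1.0 / (1.0 + (sems**2).mean())
        rel = rel.reindex(estimates.columns)
    else:
        rel = pd.Series(np.nan, index=estimates.columns)
    rel.name = "reliability"
    return cov, corr, rel


@dataclass(frozen=True)
class ComparisonReport:
    """Aggregate of one MCAT-versus-NAT Monte Carlo run."""

    domains: tuple[str, ...]
    n_persons: int
    nat_items_by_domain: dict[str, int]
    mcat_mean_items_by_domain: dict[str, float]
    nat_mean_estimate_by_domain: dict[str, float]
    mcat_mean_estimate_by_domain: dict[str, float]
    savings_percent: float
    mcat_mean_total_items: float
    reliability_by_domain: dict[str, float]
    mcat_nat_correlation_by_domain: dict[str, float]
    truth_nat_correlation_by_domain: dict[str, float]
    nat_covariance: pd.DataFrame
    nat_correlation: pd.DataFrame
    length_test: tuple[float, float]
    ability_test: tuple[float, float]
    mean_outfit_by_domain: dict[str, float]
    nat_estimates: pd.DataFrame = field(repr=False)
    nat_sems: pd.DataFrame = field(repr=False)
    mcat_estimates: pd.DataFrame = field(repr=False)
    mcat_items: pd.DataFrame = field(repr=False)
    truths: pd.DataFrame = field(repr=False)
    responses: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        """JSON-serializable summary (drops the per-person tables)."""
        return {
            "domains": list(self.domains),
            "n_persons": self.n_persons,
            "nat_items_by_domain": self.nat_items_by_domain,
            "mcat_mean_items_by_domain": self.mcat_mean_items_by_domain,
            "nat_mean_estimate_by_domain": self.nat_mean_estimate_by_domain,
            "mcat_mean_estimate_by_domain": self.mcat_mean_estimate_by_domain,
            "savings_percent": self.savings_percent,
            "mcat_mean_total_items": self.mcat_mean_total_items,
            "reliability_by_domain": self.reliability_by_domain,
            "mcat_nat_correlation_by_domain": self.mcat_nat_correlation_by_domain,
            "truth_nat_correlation_by_domain": self.truth_nat_correlation_by_domain,
            "nat_covariance": self.nat_covariance.to_dict(),
            "nat_correlation": self.nat_correlation.to_dict(),
            "length_test": {"t": self.length_test[0], "p": self.length_test[1]},
            "ability_test": {"t": self.ability_test[0], "p": self.ability_test[1]},
            "mean_outfit_by_domain": self.mean_outfit_by_domain,
        }


def run_comparison(
    bank: ItemBank,
    n_persons: int = 1000,
    covariance: DomainCovariance | None = None,
    rules: StopRules | None = None,
    seed: int = 0,
) -> ComparisonReport:
    """Simulate one cohort and score it by NAT and MCAT.

    Truths are drawn from a zero-mean multivariate normal with the given
    cross-domain covariance (default: exchangeable correlation 0.9, unit
    variances), clamped to ±8 logits; a single complete response matrix is
    generated and both scorings replay it.  Deterministic given the seed.
    """
    domains = bank.domains
    if covariance is None:
        covariance = DomainCovariance.exchangeable(domains, 0.9)
    rules = rules or StopRules()

    config = SimulationConfig(
        n_persons=n_persons,
        items_per_domain=tuple(bank.domain_sizes()[d] for d in domains),
        domains=domains,
        domain_correlation=covariance.matrix,
        seed=seed,
    )
    profiles = generate_abilities(config)
    truths = abilities_to_frame(profiles)
    responses = generate_responses(profiles, bank, seed=seed)

    nat_theta = np.empty((n_persons, len(domains)))
    nat_sem = np.empty_like(nat_theta)
    mcat_theta = np.empty_like(nat_theta)
    mcat_items = np.empty((n_persons, len(domains)), dtype=int)
    outfit = np.empty_like(nat_theta)

    for i, (_, row) in enumerate(responses.iterrows()):
        nat = run_nat(row, bank)
        for j, d in enumerate(domains):
            nat_theta[i, j] = nat.theta_by_domain[d]
            nat_sem[i, j] = nat.sem_by_domain[d]
            ids = bank.item_ids(d)
            outfit[i, j] = fit_statistics(
                row[ids].to_numpy(dtype=float),
                nat.theta_by_domain[d],
                bank.difficulties(d),
            ).outfit_msq
        cat = run_mcat(row, bank, covariance, rules, keep_transcript=False)
        for j, d in enumerate(domains):
            mcat_theta[i, j] = cat.profile.theta_by_domain[d]
            mcat_items[i, j] = cat.n_items_by_domain[d]

    idx = responses.index
    nat_est = pd.DataFrame(nat_theta, index=idx, columns=list(domains))
    nat_sems = pd.DataFrame(nat_sem, index=idx, columns=list(domains))
    mcat_est = pd.DataFrame(mcat_theta, index=idx, columns=list(domains))
    items_df = pd.DataFrame(mcat_items, index=idx, columns=list(domains))

    nat_sizes = bank.domain_sizes()
    nat_total = sum(nat_sizes.values())
    mcat_mean_total = float(items_df.sum(axis=1).mean())

    cov, corr, rel = estimate_matrix_summary(nat_est, nat_sems)
    mcat_nat_corr = {
        d: float(np.corrcoef(nat_est[d], mcat_est[d])[0, 1]) for d in domains
    }
    truth_nat_corr = {
        d: float(np.corrcoef(truths[d], nat_est[d])[0, 1]) for d in domains
    }

    length_test = two_sample_test(
        [float(nat_sizes[d]) for d in domains],
        [float(items_df[d].mean()) for d in domains],
    )
    ability_test = two_sample_test(
        [float(nat_est[d].mean()) for d in domains],
        [float(mcat_est[d].mean()) for d in domains],
    )

    return ComparisonReport(
        domains=domains,
        n_persons=n_persons,
        nat_items_by_domain={d: nat_sizes[d] for d in domains},
        mcat_mean_items_by_domain={d: float(items_df[d].mean()) for d in domains},
        nat_mean_estimate_by_domain={d: float(nat_est[d].mean()) for d in domains},
        mcat_mean_estimate_by_domain={d: float(mcat_est[d].mean()) for d in domains},
        savings_percent=savings_fraction(nat_total, mcat_mean_total),
        mcat_mean_total_items=mcat_mean_total,
        reliability_by_domain={d: float(rel[d]) for d in domains},
        mcat_nat_correlation_by_domain=mcat_nat_corr,
        truth_nat_correlation_by_domain=truth_nat_corr,
        nat_covariance=cov,
        nat_correlation=corr,
        length_test=length_test,
        ability_test=ability_test,
        mean_outfit_by_domain={d: float(outfit[:, j].mean()) for j, d in enumerate(domains)},
        nat_estimates=nat_est,
        nat_sems=nat_sems,
        mcat_estimates=mcat_est,
        mcat_items=items_df,
        truths=truths,
        responses=responses,
    )
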