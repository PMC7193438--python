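"""Reliability-driven strata counts and logit cutoff points.

How many performance levels a scale can distinguish follows from its person
reliability R through the separation index G = sqrt(R / (1 − R)) and the
strata formula H = (4G + 1) / 3: reliability 0.67 supports two strata, 0.80
three, 0.90 four.  Cutoffs between strata are placed so each stratum holds an
equal share of a standard-logistic population — i.e. at the logistic
quantiles log(k / (H − k)) — which reproduces the conventional screening
thresholds 0 (two strata), ±0.7 (three), ±1.1/0 (four) and ±1.4/±0.4 (five)
once rounded to one decimal.  Adjacent thresholds are conventionally expected
to sit 1.4–5.0 logits apart; narrower gaps are reported as below-guideline
warnings, not errors.

Domain-level delay screening compares each domain measure against an
age-specific cutoff table; the packaged table carries the published
24-month row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .rasch import AbilityProfile

__all__ = [
    "CutoffScheme",
    "AgeCutoffTable",
    "SPACING_GUIDELINE",
    "separation_index",
    "strata_count",
    "equal_probability_cutoffs",
    "cutoff_probability",
    "validate_spacing",
    "classify_global",
    "flag_domain_delays",
]

#: Recommended range (logits) for the gap between adjacent thresholds.
SPACING_GUIDELINE = (1.4, 5.0)

_DEFAULT_LABELS = {2: ("low", "high"), 3: ("low", "medium", "high")}


def separation_index(reliability: float) -> float:
    """Person separation G = sqrt(R / (1 − R)) for reliability R in (0, 1)."""
    if not 0.0 < reliability < 1.0:
        raise ValueError(f"reliability must be in (0, 1), got {reliability}")
    return float(np.sqrt(reliability / (1.0 - reliability)))


def strata_count(reliability: float) -> int:
    """Number of statistically distinct strata: floor((4G + 1) / 3), min 1.

    Reproduces the conventional mapping 0.67 → 2, 0.80 → 3, 0.90 → 4.
    """
    g = separation_index(reliability)
    return max(1, int(np.floor((4.0 * g + 1.0) / 3.0)))


def equal_probability_cutoffs(n_strata: int) -> tuple[float, ...]:
    """Equal-population logit thresholds for ``n_strata`` strata.

    Thresholds are the standard-logistic quantiles log(k / (H − k)),
    k = 1..H−1, rounded to one decimal — e.g. (−0.7, 0.7) for three strata.
    """
    if n_strata < 2:
        raise ValueError(f"need at least 2 strata, got {n_strata}")
    h = n_strata
    return tuple(round(float(np.log(k / (h - k))), 1) for k in range(1, h))


def cutoff_probability(threshold: float) -> float:
    """Standard-logistic cumulative probability at a logit threshold.

    The population share falling below the threshold under equal-probability
    stratification, e.g. 0.67 at +0.7 logits.
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold!r}")
    return float(expit(threshold))


def validate_spacing(thresholds: Sequence[float]) -> tuple[bool, list[dict]]:
    """Check adjacent threshold gaps against the 1.4–5.0 logit guideline.

    Returns ``(all_within, report)`` where each report row carries the gap
    and a status of ``"within"``, ``"below_guideline"`` or
    ``"above_guideline"``.  Gaps outside the guideline are advisory only —
    the conventional four- and five-strata thresholds themselves sit 1.1 and
    1.0 logits apart.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two thresholds")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"thresholds must be strictly increasing, got {list(t)}")
    lo, hi = SPACING_GUIDELINE
    report = []
    for a, b in zip(t[:-1], t[1:]):
        gap = float(b - a)
        if gap < lo:
            status = "below_guideline"
        elif gap > hi:
            status = "above_guideline"
        else:
            status = "within"
        report.append({"lower": float(a), "upper": float(b), "gap": gap, "status": status})
    return all(r["status"] == "within" for r in report), report


@dataclass(frozen=True)
class CutoffScheme:
    """Global stratification scheme: strata count, thresholds, labels."""

    n_strata: int
    thresholds: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != self.n_strata:
            raise ValueError("need one label per stratum")
        if len(self.thresholds) != self.n_strata - 1:
            raise ValueError("need n_strata - 1 thresholds")
        t = np.asarray(self.thresholds)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if t.size and not np.allclose(t, -t[::-1]):
            raise ValueError("equal-probability thresholds must be symmetric about 0")

    @classmethod
    def equal_probability(
        cls, n_strata: int, labels: Sequence[str] | None = None
    ) -> "CutoffScheme":
        thresholds = equal_probability_cutoffs(n_strata)
        if labels is None:
            labels = _DEFAULT_LABELS.get(
                n_strata, tuple(f"stratum_{k}" for k in range(1, n_strata + 1))
            )
        return cls(n_strata=n_strata, thresholds=thresholds, labels=tuple(labels))

    @classmethod
    def from_reliability(cls, reliability: float) -> "CutoffScheme":
        return cls.equal_probability(max(2, strata_count(reliability)))


def classify_global(mean_measure: float, scheme: CutoffScheme) -> str:
    """Stratum label for a global (mean-of-domains) measure.

    A measure exactly on a threshold classifies into the upper stratum.
    """
    idx = int(np.searchsorted(scheme.thresholds, mean_measure, side="right"))
    return scheme.labels[idx]


class AgeCutoffTable:
    """Age- and domain-specific delay cutoffs in logits.

    Rows are (age_months, domain, cutoff); ``"mean"`` is accepted as a
    pseudo-domain for the global measure.  A domain measure strictly below
    its cutoff at the child's age flags a developmental delay.
    """

    def __init__(self, rows: Iterable[tuple[float, str, float]]):
        self._table: dict[tuple[float, str], float] = {}
        for age, domain, cutoff in rows:
            key = (float(age), str(domain))
            if key in self._table:
                raise ValueError(f"duplicate (age, domain) row: {key}")
            if not np.isfinite(cutoff):
                raise ValueError(f"cutoff for {key} must be finite")
            self._table[key] = float(cutoff)
        if not self._table:
            raise ValueError("cutoff table is empty")

    def ages(self) -> tuple[float, ...]:
        return tuple(sorted({a for a, _ in self._table}))

    def cutoff(self, age_months: float, domain: str) -> float:
        try:
            return self._table[(float(age_months), domain)]
        except KeyError:
            raise KeyError(
                f"no cutoff for domain {domain!r} at age {age_months} months"
            ) from None

    def domains_at(self, age_months: float) -> tuple[str, ...]:
        return tuple(d for (a, d) in self._table if a == float(age_months))


def flag_domain_delays(
    profile: AbilityProfile,
    age_months: float,
    table: AgeCutoffTable,
) -> tuple[dict[str, bool], bool]:
    """Per-domain delay flags at a given age, plus the any-delay indicator.

    A domain fails (``True``) iff its measure is strictly below the cutoff;
    a measure equal to the cutoff passes.  Domains present in the profile but
    absent from the table at that age raise a lookup error.
    """
    if float(age_months) not in table.ages():
        raise KeyError(f"age {age_months} months not present in cutoff table")
    flags = {
        d: profile.theta_by_domain[d] < table.cutoff(age_months, d)
        for d in profile.domains
        if d != "mean"
    }
    return flags, any(flags.values())
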