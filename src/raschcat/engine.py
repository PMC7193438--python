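"""Adaptive administration loop: D-optimal selection, stop rules, NAT scoring.

One adaptive session walks select → respond → re-estimate until every domain
has stopped.  Next-item selection is D-optimal across domains: the
provisional information matrix is

    M = Sigma⁻¹ + diag_d( sum of item information administered in d )

(prior precision plus per-domain accumulated Fisher information, all at the
provisional measures), and the chosen candidate is the unanswered item whose
hypothetical administration maximizes det(M′).  Because a candidate in domain
d adds a rank-one term u·e_d e_dᵀ, the determinant gain factors as
``1 + u · (M⁻¹)_dd`` — the engine ranks candidates by that closed form and a
test oracle checks it against brute-force determinants.

A domain stops once it has at least the minimum number of items (default 3)
and either its person reliability reaches the target (default 0.80) or the
mean of the last three absolute measure changes falls below 0.05 logits; a
domain with no items left stops unconditionally.  Nonadaptive testing (NAT)
— every item administered — is the reference mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimate import (
    estimate_map,
    estimate_mle,
    reliability_from_sem,
    standard_error,
)
from .rasch import (
    AbilityProfile,
    DomainCovariance,
    ItemBank,
    item_information,
    response_probability,
)

__all__ = [
    "StopRules",
    "CatSession",
    "CatResult",
    "start_session",
    "select_next_item",
    "record_response",
    "check_stop",
    "run_mcat",
    "run_nat",
]


@dataclass(frozen=True)
class StopRules:
    """Stop-rule configuration for one adaptive session.

    A domain is eligible to stop only after ``min_items_per_domain`` items
    (default 3); it then stops when person reliability reaches
    ``target_reliability`` (default 0.80) or when the mean of the last
    ``change_window`` absolute measure changes drops below
    ``change_threshold`` logits (defaults: window 3, threshold 0.05).
    """

    min_items_per_domain: int = 3
    target_reliability: float = 0.80
    change_threshold: float = 0.05
    change_window: int = 3

    def __post_init__(self) -> None:
        if self.min_items_per_domain < 1:
            raise ValueError("min_items_per_domain must be >= 1")
        if not 0.0 < self.target_reliability < 1.0:
            raise ValueError("target_reliability must be in (0, 1)")
        if not self.change_threshold > 0:
            raise ValueError("change_threshold must be > 0")
        if self.change_window < 1:
            raise ValueError("change_window must be >= 1")


@dataclass
class _DomainState:
    administered: list[str] = field(default_factory=list)
    responses: list[int] = field(default_factory=list)
    theta: float = 0.0
    sem: float | None = None
    sem_trace: list[float] = field(default_factory=list)
    changes: list[float] = field(default_factory=list)
    stopped: bool = False
    stop_reason: str | None = None


@dataclass
class CatSession:
    """Evolving state of one adaptive administration."""

    bank: ItemBank
    covariance: DomainCovariance
    rules: StopRules
    state: dict[str, _DomainState]
    step: int = 0
    transcript: list[dict] = field(default_factory=list)
    keep_transcript: bool = True

    @property
    def domains(self) -> tuple[str, ...]:
        return self.bank.domains

    @property
    def administered_ids(self) -> set[str]:
        return {i for st in self.state.values() for i in st.administered}

    def theta_by_domain(self) -> dict[str, float]:
        return {d: self.state[d].theta for d in self.domains}

    def sem_by_domain(self) -> dict[str, float | None]:
        return {d: self.state[d].sem for d in self.domains}

    def all_stopped(self) -> bool:
        return all(st.stopped for st in self.state.values())

    def remaining(self, domain: str) -> list[str]:
        used = set(self.state[domain].administered)
        return [i for i in self.bank.item_ids(domain) if i not in used]

    # -- information matrix -------------------------------------------------

    def information_matrix(self) -> np.ndarray:
        """Provisional information matrix M = Sigma⁻¹ + diag(accumulated info)."""
        info = np.array(
            [
                np.sum(
                    item_information(
                        self.state[d].theta,
                        [self.bank[i].difficulty for i in self.state[d].administered],
                    )
                )
                if self.state[d].administered
                else 0.0
                for d in self.domains
            ]
        )
        return self.covariance.precision + np.diag(info)


@dataclass(frozen=True)
class CatResult:
    """Final outcome of one adaptive (or replayed) administration."""

    profile: AbilityProfile
    n_items_by_domain: dict[str, int]
    stop_reason_by_domain: dict[str, str]
    sem_trace_by_domain: dict[str, list[float]]
    transcript: list[dict]

    @property
    def total_items(self) -> int:
        return sum(self.n_items_by_domain.values())


def start_session(
    bank: ItemBank,
    covariance: DomainCovariance | None = None,
    rules: StopRules | None = None,
    *,
    keep_transcript: bool = True,
) -> CatSession:
    """Open an adaptive session: provisional measures 0, nothing stopped."""
    if len(bank) == 0:
        raise ValueError("item bank is empty")
    if covariance is None:
        covariance = DomainCovariance(np.eye(len(bank.domains)), bank.domains)
    if tuple(covariance.domains) != tuple(bank.domains):
        raise ValueError("covariance domains must match bank domains")
    rules = rules or StopRules()
    return CatSession(
        bank=bank,
        covariance=covariance,
        rules=rules,
        state={d: _DomainState() for d in bank.domains},
        keep_transcript=keep_transcript,
    )


def select_next_item(session: CatSession) -> str | None:
    """D-optimal next item, or ``None`` when nothing remains to administer.

    Ranks every unanswered item of every non-stopped domain by the
    determinant of the provisional information matrix after its hypothetical
    administration; the rank-one update means the winner maximizes
    ``item_information(theta_d, b) · (M⁻¹)_dd``.  Exact ties resolve to the
    lowest item id.
    """
    minv = np.linalg.inv(session.information_matrix())
    best_gain = -np.inf
    best_id: str | None = None
    for j, d in enumerate(session.domains):
        st = session.state[d]
        if st.stopped:
            continue
        rem = session.remaining(d)
        if not rem:
            continue
        b = np.array([session.bank[i].difficulty for i in rem])
        gains = item_information(st.theta, b) * minv[j, j]
        top = float(np.max(gains))
        ties = [rem[t] for t in np.flatnonzero(gains == top)]
        cand = min(ties)
        if top > best_gain or (top == best_gain and (best_id is None or cand < best_id)):
            best_gain, best_id = top, cand
    return best_id


def _reestimate(session: CatSession, domain: str) -> None:
    """Refresh one domain's provisional measure after a new response.

    Mixed patterns use the Newton–Raphson MLE; all-correct / all-incorrect
    patterns fall back to a MAP estimate under the session's prior so early
    item selection is not hijacked by a ±8 clamp.
    """
    st = session.state[domain]
    b = np.array([session.bank[i].difficulty for i in st.administered])
    x = np.array(st.responses, dtype=float)
    old = st.theta
    if 0.0 < x.mean() < 1.0:
        res = estimate_mle(x, b)
        st.theta = res.theta
    else:
        responses = {
            i: r
            for d2 in session.domains
            for i, r in zip(session.state[d2].administered, session.state[d2].responses)
        }
        profile = estimate_map(responses, session.bank, session.covariance)
        st.theta = profile.theta_by_domain[domain]
    st.sem = standard_error(st.theta, b)
    st.sem_trace.append(st.sem)
    st.changes.append(abs(st.theta - old))


def record_response(session: CatSession, item_id: str, response: int) -> CatSession:
    """Record one answered item and update the session in place.

    Appends the response, re-estimates the answered domain's provisional
    measure, refreshes its SEM and change history, and re-evaluates the stop
    rules.  Raises on an already-administered item or a stopped domain.
    """
    if response not in (0, 1):
        raise ValueError(f"response must be 0 or 1, got {response!r}")
    item = session.bank[item_id]
    st = session.state[item.domain]
    if st.stopped:
        raise RuntimeError(f"domain {item.domain!r} already stopped")
    if item_id in st.administered:
        raise RuntimeError(f"item {item_id!r} already administered")

    st.administered.append(item_id)
    st.responses.append(int(response))
    _reestimate(session, item.domain)
    session.step += 1
    check_stop(session)

    if session.keep_transcript:
        session.transcript.append(
            {
                "step": session.step,
                "item_id": item_id,
                "domain": item.domain,
                "response": int(response),
                "theta_by_domain": session.theta_by_domain(),
                "sem_by_domain": session.sem_by_domain(),
                "det_information": float(np.linalg.det(session.information_matrix())),
                "stopped_domains": [d for d in session.domains if session.state[d].stopped],
            }
        )
    return session


def check_stop(session: CatSession) -> dict[str, str | None]:
    """Evaluate stop rules per domain; returns domain -> stop reason (or None).

    Order of evaluation: bank exhaustion stops a domain unconditionally;
    otherwise the min-items gate applies, then reliability, then estimate
    stability.
    """
    rules = session.rules
    for d in session.domains:
        st = session.state[d]
        if st.stopped:
            continue
        if not session.remaining(d):
            st.stopped, st.stop_reason = True, "exhausted"
            continue
        if len(st.administered) < rules.min_items_per_domain:
            continue
        if st.sem is not None and reliability_from_sem(st.sem) >= rules.target_reliability:
            st.stopped, st.stop_reason = True, "reliability"
            continue
        w = rules.change_window
        if len(st.changes) >= w and float(np.mean(st.changes[-w:])) < rules.change_threshold:
            st.stopped, st.stop_reason = True, "stable estimate"
    return {d: session.state[d].stop_reason for d in session.domains}


def _final_profile(session: CatSession) -> AbilityProfile:
    prior_sd = np.sqrt(np.diag(session.covariance.matrix))
    thetas, sems = {}, {}
    for j, d in enumerate(session.domains):
        st = session.state[d]
        thetas[d] = float(np.clip(st.theta, -8.0, 8.0))
        # a domain that never received an item keeps the prior spread as SEM
        sems[d] = st.sem if st.sem is not None else float(prior_sd[j])
    return AbilityProfile(theta_by_domain=thetas, sem_by_domain=sems)


def run_mcat(
    source: Mapping[str, int] | pd.Series | AbilityProfile,
    bank: ItemBank,
    covariance: DomainCovariance | None = None,
    rules: StopRules | None = None,
    seed: int | None = None,
    *,
    keep_transcript: bool = True,
) -> CatResult:
    """Run one full adaptive administration to completion.

    ``source`` is either a recorded response row (mapping/Series item_id ->
    0/1; replay mode) or a true :class:`AbilityProfile` (simulation mode —
    responses are drawn on demand from the Rasch model with the given seed).
    """
    session = start_session(bank, covariance, rules, keep_transcript=keep_transcript)
    simulate = isinstance(source, AbilityProfile)
    rng = np.random.default_rng(seed) if simulate else None

    while not session.all_stopped():
        item_id = select_next_item(session)
        if item_id is None:
            break
        item = bank[item_id]
        if simulate:
            p = response_probability(source.theta_by_domain[item.domain], item.difficulty)
            resp = int(rng.random() < p)
        else:
            resp = int(source[item_id])
            if resp not in (0, 1):
                raise ValueError(f"recorded response for {item_id!r} must be 0/1")
        record_response(session, item_id, resp)

    return CatResult(
        profile=_final_profile(session),
        n_items_by_domain={d: len(session.state[d].administered) for d in session.domains},
        stop_reason_by_domain={
            d: (session.state[d].stop_reason or "none") for d in session.domains
        },
        sem_trace_by_domain={d: list(session.state[d].sem_trace) for d in session.domains},
        transcript=list(session.transcript),
    )


def run_nat(row: Mapping[str, int] | pd.Series, bank: ItemBank) -> AbilityProfile:
    """Score a complete response row nonadaptively: per-domain MLE over all items.

    NAT is defined on complete data — a missing or non-binary cell for any
    bank item is an error.
    """
    thetas: dict[str, float] = {}
    sems: dict[str, float] = {}
    for d in bank.domains:
        ids = bank.item_ids(d)
        try:
            x = np.array([row[i] for i in ids], dtype=float)
        except KeyError as e:
            raise ValueError(f"response row missing item {e.args[0]!r}") from None
        if np.any(~np.isfinite(x)):
            missing = [i for i, v in zip(ids, x) if not np.isfinite(v)]
            raise ValueError(f"NAT requires complete data; missing cells: {missing}")
        res = estimate_mle(x, bank.difficulties(d))
        thetas[d] = res.theta
        sems[d] = res.sem
    return AbilityProfile(theta_by_domain=thetas, sem_by_domain=sems)
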