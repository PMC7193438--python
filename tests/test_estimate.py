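"""Estimation: MLE vs grid oracle, MAP, SEM, reliability, fit statistics."""

import numpy as np
import pytest

from raschcat import (
    AbilityProfile,
    DomainCovariance,
    Item,
    ItemBank,
    estimate_map,
    estimate_mle,
    fit_statistics,
    reliability_from_sem,
    standard_error,
)
from conftest import grid_mle


class TestEstimateMle:
    def test_symmetric_pattern_lands_at_midpoint(self):
        res = estimate_mle([1, 0], [-1.0, 1.0])
        assert res.theta == pytest.approx(0.0, abs=1e-6)
        assert res.converged and not res.clamped

    def test_three_item_pattern_matches_grid_oracle(self):
        res = estimate_mle([1, 1, 0], [-1.0, 0.0, 1.0])
        assert res.theta == pytest.approx(0.80, abs=1e-2)
        assert res.theta == pytest.approx(grid_mle([1, 1, 0], [-1, 0, 1]), abs=1e-3)

    @pytest.mark.parametrize("resp, bound", [([1, 1, 1], 8.0), ([0, 0, 0], -8.0)])
    def test_extreme_scores_clamped(self, resp, bound):
        res = estimate_mle(resp, [-1.0, 0.0, 1.0])
        assert res.theta == bound and res.clamped

    def test_agrees_with_grid_oracle_on_random_cases(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 200:
            n = int(rng.integers(2, 16))
            b = rng.uniform(-5, 5, size=n)
            x = rng.integers(0, 2, size=n)
            if x.sum() in (0, n):
                continue
            res = estimate_mle(x, b)
            assert res.converged
            assert res.theta == pytest.approx(grid_mle(x, b), abs=1e-3)
            checked += 1

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            estimate_mle([], [])


class TestEstimateMap:
    @staticmethod
    def _bank2():
        return ItemBank(
            [Item("a1", "a", -1.0), Item("a2", "a", 0.5), Item("b1", "b", 0.0)]
        )

    def test_no_responses_returns_prior_mean(self):
        bank = self._bank2()
        cov = DomainCovariance(np.eye(2), bank.domains)
        prof = estimate_map({}, bank, cov)
        assert prof.theta_by_domain == {"a": 0.0, "b": 0.0}
        assert prof.sem_by_domain["a"] == pytest.approx(1.0)

    def test_diagonal_prior_matches_grid_oracle(self):
        bank = self._bank2()
        cov = DomainCovariance(np.eye(2), bank.domains)
        prof = estimate_map({"a1": 1, "a2": 1}, bank, cov)
        # independent-domain oracle: dense maximization of penalized likelihood
        from scipy.special import log_expit

        grid = np.arange(-4, 4, 1e-3)
        b = np.array([-1.0, 0.5])
        post = np.sum(log_expit(grid[:, None] - b[None, :]), axis=1) - grid**2 / 2
        assert prof.theta_by_domain["a"] == pytest.approx(grid[np.argmax(post)], abs=1e-2)
        assert prof.theta_by_domain["b"] == pytest.approx(0.0, abs=1e-9)

    def test_near_perfect_correlation_pulls_empty_domain_along(self):
        bank = self._bank2()
        cov = DomainCovariance.exchangeable(bank.domains, 0.999)
        prof = estimate_map({"a1": 1, "a2": 1}, bank, cov)
        assert prof.theta_by_domain["b"] == pytest.approx(
            prof.theta_by_domain["a"], abs=0.01
        )

    def test_joint_mode_matches_dense_two_domain_grid(self):
        bank = self._bank2()
        cov = DomainCovariance.exchangeable(bank.domains, 0.6)
        responses = {"a1": 1, "a2": 0, "b1": 1}
        prof = estimate_map(responses, bank, cov)

        from scipy.special import log_expit

        g = np.arange(-3, 3, 0.01)
        ta, tb = np.meshgrid(g, g, indexing="ij")
        ll = (
            log_expit(ta - (-1.0))
            + log_expit(-(ta - 0.5))
            + log_expit(tb - 0.0)
        )
        prec = cov.precision
        quad = 0.5 * (
            prec[0, 0] * ta**2 + 2 * prec[0, 1] * ta * tb + prec[1, 1] * tb**2
        )
        post = ll - quad
        i, j = np.unravel_index(np.argmax(post), post.shape)
        assert prof.theta_by_domain["a"] == pytest.approx(g[i], abs=0.02)
        assert prof.theta_by_domain["b"] == pytest.approx(g[j], abs=0.02)

    def test_non_positive_definite_covariance_rejected(self):
        with pytest.raises(ValueError):
            DomainCovariance(np.array([[1.0, 1.5], [1.5, 1.0]]), ["a", "b"])


class TestStandardErrorAndReliability:
    def test_four_matched_items_give_unit_sem(self):
        assert standard_error(0.0, [0.0] * 4) == pytest.approx(1.0)

    def test_three_matched_items(self):
        assert standard_error(0.0, [0.0] * 3) == pytest.approx(1.1547, abs=1e-4)

    def test_appending_any_item_strictly_reduces_sem(self):
        rng = np.random.default_rng(3)
        b = list(rng.uniform(-6, 6, size=1))
        theta = 0.7
        prev = standard_error(theta, b)
        for extra in rng.uniform(-8, 8, size=15):
            b.append(extra)
            cur = standard_error(theta, b)
            assert cur < prev
            prev = cur

    def test_empty_item_set_rejected(self):
        with pytest.raises(ValueError):
            standard_error(0.0, [])

    @pytest.mark.parametrize(
        "sem, expected", [(0.447, 0.800), (1.0, 0.0), (0.316, 0.900)]
    )
    def test_reliability_identity(self, sem, expected):
        assert reliability_from_sem(sem) == pytest.approx(expected, abs=1e-3)

    def test_reliability_rejects_non_positive_sem(self):
        with pytest.raises(ValueError):
            reliability_from_sem(0.0)


class TestFitStatistics:
    def test_single_even_item(self):
        rep = fit_statistics([1], 0.0, [0.0])
        assert rep.z_by_item[0] == pytest.approx(1.0)
        assert rep.outfit_msq == pytest.approx(1.0)
        assert not rep.aberrant_flags.any()

    def test_expected_response_to_easy_item_has_tiny_residual(self):
        # p = 0.98 -> z = sqrt(0.02/0.98), z^2 ~ 0.0204
        theta = np.log(0.98 / 0.02)
        rep = fit_statistics([1], theta, [0.0])
        assert rep.z_by_item[0] == pytest.approx(0.1429, abs=1e-3)
        assert rep.outfit_msq == pytest.approx(0.0204, abs=1e-3)

    def test_surprising_failure_is_flagged(self):
        theta = np.log(0.9 / 0.1)
        rep = fit_statistics([0], theta, [0.0])
        assert rep.z_by_item[0] == pytest.approx(-3.0, abs=1e-9)
        assert rep.aberrant_flags[0]

    def test_outfit_is_mean_of_squared_residuals(self):
        rng = np.random.default_rng(5)
        b = rng.uniform(-2, 2, size=8)
        x = rng.integers(0, 2, size=8)
        rep = fit_statistics(x, 0.3, b)
        assert rep.outfit_msq == pytest.approx(np.mean(rep.z_by_item**2))

    def test_outfit_calibrated_near_one_on_moderate_bank(self):
        # items within ±2.5 logits of a known person: mean outfit over many
        # simulated patterns should sit near its expectation of 1 per domain
        rng = np.random.default_rng(17)
        b = np.linspace(-2.5, 2.5, 15)
        vals = []
        for _ in range(2000):
            theta = rng.normal()
            p = 1 / (1 + np.exp(-(theta - b)))
            x = (rng.random(15) < p).astype(float)
            vals.append(fit_statistics(x, theta, b).outfit_msq)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)
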