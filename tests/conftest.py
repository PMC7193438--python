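import numpy as np
import pytest

from raschcat import (
    DomainCovariance,
    Item,
    ItemBank,
    fixture_bank,
    run_comparison,
)


@pytest.fixture(scope="session")
def music_bank() -> ItemBank:
    """The packaged synthetic 75-item five-domain bank."""
    return fixture_bank()


@pytest.fixture(scope="session")
def toy_bank() -> ItemBank:
    """Small two-domain bank for fast engine walks."""
    items = [
        Item("a_1", "alpha", -1.5),
        Item("a_2", "alpha", -0.5),
        Item("a_3", "alpha", 0.0),
        Item("a_4", "alpha", 0.5),
        Item("a_5", "alpha", 1.5),
        Item("b_1", "beta", -2.0),
        Item("b_2", "beta", -1.0),
        Item("b_3", "beta", 0.0),
        Item("b_4", "beta", 1.0),
        Item("b_5", "beta", 2.0),
    ]
    return ItemBank(items)


@pytest.fixture(scope="session")
def toy_covariance(toy_bank) -> DomainCovariance:
    return DomainCovariance.exchangeable(toy_bank.domains, 0.5)


@pytest.fixture(scope="session")
def study_report(music_bank):
    """The full seeded 1000-person adaptive-vs-nonadaptive comparison.

    Session-scoped: it is the single most expensive computation in the suite
    and several checks (efficiency, recovery, precision) read from it.
    """
    return run_comparison(music_bank, n_persons=1000, seed=1)


def grid_mle(responses, difficulties, lo=-8.0, hi=8.0, step=1e-4):
    """Independent oracle: exhaustive grid search of the Rasch likelihood."""
    from scipy.special import log_expit

    x = np.asarray(responses, dtype=float)
    b = np.asarray(difficulties, dtype=float)
    grid = np.arange(lo, hi + step / 2, step)
    z = grid[:, None] - b[None, :]
    ll = np.sum(x * log_expit(z) + (1 - x) * log_expit(-z), axis=1)
    return float(grid[np.argmax(ll)])
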