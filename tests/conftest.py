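import numpy as np
import pytest

from itchoice import ItemSet, factorial_grid, kirby_mcq

# one moderate parameter set per model, inside all supports, giving
# non-degenerate choice probabilities on day- and month-scale items
MODEL_PARAMS = {
    "exponential": {"k": 0.05, "sigma": 0.1},
    "hyperbolic": {"k": 0.1, "sigma": 0.1},
    "double_exponential": {"beta": 0.2, "delta": 0.01, "omega": 0.4,
                           "sigma": 0.1},
    "generalized_hyperbolic": {"k": 0.1, "s": 0.8, "sigma": 0.1},
    "hyperboloid": {"k": 0.1, "s": 0.8, "sigma": 0.1},
    "generalized_hyperbola": {"alpha": 0.1, "beta": 0.08, "sigma": 0.1},
    "constant_sensitivity": {"alpha": 0.05, "beta": 0.9, "sigma": 0.1},
    "additive_utility": {"alpha": 0.9, "beta": 0.7, "lam": 0.5, "sigma": 0.3},
    "proportional_difference": {"delta": -0.1, "sigma": 2.0},
    "itch": {"beta_1": 0.1, "beta_xA": 0.02, "beta_xR": 1.5,
             "beta_tA": -0.05, "beta_tR": -1.0},
    "tradeoff": {"gamma": 0.2, "tau": 0.2, "kappa": 1.5, "alpha": 1.0,
                 "theta": 1.5, "eps": 0.3},
}


def random_items(rng, n=20, time_unit="days"):
    """Valid random SS/LL items with dispersed amounts and delays."""
    x_ss = rng.uniform(5, 80, n)
    x_ll = x_ss + rng.uniform(1, 100, n)
    t_ss = rng.uniform(0, 30, n)
    t_ll = t_ss + rng.uniform(1, 150, n)
    return ItemSet(x_ss=x_ss, t_ss=t_ss, x_ll=x_ll, t_ll=t_ll,
                   time_unit=time_unit)


@pytest.fixture(scope="session")
def kirby_items():
    return kirby_mcq()


@pytest.fixture(scope="session")
def factorial_items():
    return factorial_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(20230306)


@pytest.fixture
def two_items():
    return ItemSet(x_ss=[50.0, 20.0], t_ss=[0.0, 5.0],
                   x_ll=[100.0, 60.0], t_ll=[10.0, 40.0], time_unit="days")
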