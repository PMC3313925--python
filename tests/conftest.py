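import numpy as np
import pytest

import pgbkin as pk


@pytest.fixture(scope="session")
def solution_rates():
    return pk.SOLUTION_RATES


@pytest.fixture(scope="session")
def flash_conditions():
    return pk.Conditions(temperature_K=293.15, co_atm=1.0, phi=1.0)


@pytest.fixture(scope="session")
def flash_times():
    return np.logspace(-8, -2, 150)


@pytest.fixture(scope="session")
def flash_trace_pair(solution_rates):
    """Noisy 1 atm / 0.1 atm flash traces from the same rate set."""
    c1 = pk.Conditions(co_atm=1.0, phi=1.0)
    c01 = pk.Conditions(co_atm=0.1, phi=1.0)
    tr1 = pk.make_flash_trace(solution_rates, c1, noise=2e-3, seed=10)
    tr2 = pk.make_flash_trace(solution_rates, c01, noise=2e-3, seed=11)
    return tr1, tr2


def random_rateset(rng, fast_lo=1e4, fast_hi=1e8):
    """A random but physically plausible rate set (log-uniform draws)."""

    def draw(lo, hi):
        return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))

    return pk.RateSet(
        k1=draw(1e4, 1e6), km1=draw(1e4, 1e6),
        k2=draw(1e4, 1e6), km2=draw(1e3, 1e5),
        k3=draw(1e4, 1e6), km3=draw(1e3, 1e5),
        kin_r=draw(1e6, 1e9), kin_t=draw(1e6, 1e9),
        kout=draw(1e7, 1e9),
        kg_r=draw(1e6, 1e8), kg_t=draw(1e5, 1e8),
        kdiss_r=draw(1e-3, 1e0), kdiss_t=draw(1e-3, 1e0),
        kmig_r=draw(1e6, 1e8), kret_r=draw(1e6, 1e8),
        kmig_t=draw(1e6, 1e8), kret_t=draw(1e6, 1e8),
    )
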