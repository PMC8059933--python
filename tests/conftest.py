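import numpy as np
import pandas as pd
import pytest

from gcjoint.hazard import AssociationSpec
from gcjoint.joint import MCMCConfig, build_joint_data, fit_joint
from gcjoint.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """Compact cohort (40 females, 10-year window) shared across tests."""
    cfg = SimConfig(n_females=40, obs_window_years=10.0, n_groups=2, seed=7)
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def behavior_sim():
    """Small cohort with grooming/effort/agonism tables."""
    cfg = SimConfig(n_females=16, obs_window_years=6.0, n_groups=2, seed=11)
    return simulate_all(cfg, behavior=True)


@pytest.fixture(scope="session")
def default_sim():
    """The stated world: 242 females, 19.5-year window, default budget."""
    return simulate_all(SimConfig(seed=2))


@pytest.fixture(scope="session")
def fitted_auc():
    """Joint fit with cumulative (AUC) association on a default-scale cohort
    simulated with the realistic association magnitude."""
    cfg = SimConfig(seed=5, assoc=AssociationSpec("auc", 0.115))
    sim = simulate_all(cfg)
    data = build_joint_data(sim.fgc.design, sim.fgc.year_table, sim.records,
                            assoc_mode="auc")
    fit = fit_joint(data, mcmc_config=MCMCConfig.test_preset(seed=5))
    return sim, fit


def toy_weather(years=3, start="2001-01-01", rain=1.0, tmax=30.0, seed=None):
    """Deterministic daily weather record for anomaly oracles."""
    dates = pd.date_range(start, periods=int(365.25 * years) + 1, freq="D")
    rng = np.random.default_rng(seed) if seed is not None else None
    r = np.full(len(dates), float(rain)) if rng is None else rng.gamma(0.5, 2.0, len(dates))
    t = np.full(len(dates), float(tmax)) if rng is None else tmax + rng.normal(0, 2, len(dates))
    return pd.DataFrame({"rain": r, "tmax": t}, index=dates)
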