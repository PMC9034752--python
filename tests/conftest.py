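import numpy as np
import pandas as pd
import pytest

import rotadapt as ra

AFTEREFFECT_SUBSET = ["early_baseline", "late_baseline",
                      "early_aftereffect", "late_aftereffect"]


@pytest.fixture(scope="session")
def default_design():
    return ra.make_design(seed=1)


@pytest.fixture(scope="session")
def small_experiment(default_design):
    """Trial-level experiment: 3 groups x 6 subjects, default calibration."""
    gp = ra.default_group_params()
    return ra.simulate_experiment(default_design, gp, 6, seed=101, trajectories=False)


@pytest.fixture(scope="session")
def small_epoched(small_experiment):
    return ra.assign_epochs(small_experiment.trial_table.assign(valid=True))


@pytest.fixture(scope="session")
def small_fit(small_epoched):
    """A quick posterior fit on the aftereffect-relevant epochs, shared by tests."""
    sub = small_epoched[small_epoched["epoch"].isin(AFTEREFFECT_SUBSET)]
    spec = ra.build_model(sub)
    samples = ra.sample_posterior(spec, chains=2, burn_in=400, draws=1500, seed=202)
    return samples


def hierarchical_dataset(rng, cell_means, n_subj=6, trials_per_cell=8,
                         sigma_u=2.0, sigma_v=0.5, sigma_subj=5.0):
    """Data drawn directly from the hierarchical model with known cell means.

    ``cell_means`` has shape (E, G).  Used as the calibration oracle: the
    fitted posterior should cover these truths at its nominal rate.
    """
    E, G = cell_means.shape
    rows = []
    for j in range(G):
        for s in range(n_subj):
            u = rng.normal(0.0, sigma_u)
            sid = f"g{j}s{s}"
            for k in range(E):
                v = rng.normal(0.0, sigma_v)
                y = rng.normal(cell_means[k, j] + u + v, sigma_subj, size=trials_per_cell)
                rows.append(pd.DataFrame({
                    "subject_id": sid, "group": f"g{j}", "epoch": f"e{k}",
                    "movement_direction_deg": y, "valid": True}))
    return pd.concat(rows, ignore_index=True)


def straight_reach(direction_deg, *, amplitude=8.4, duration_ms=430.0,
                   hold_ms=300.0, rate_hz=200.0):
    """Noise-free minimum-jerk reach along an absolute direction."""
    from rotadapt.synthetic_data import min_jerk_position

    dt = 1000.0 / rate_hz
    t = np.arange(0.0, hold_ms + duration_ms + 2 * dt, dt)
    tm = np.clip(t - hold_ms, 0.0, duration_ms)
    r = min_jerk_position(tm, duration_ms, amplitude)
    th = np.radians(direction_deg)
    return np.column_stack([t, r * np.cos(th), r * np.sin(th)])
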