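import numpy as np
import pandas as pd
import pytest

from pelage import default_params, phase_durations, simulate_hf
from pelage.population import PatternRecord, build_lattice


@pytest.fixture(scope="session")
def defaults():
    return default_params()


@pytest.fixture(scope="session")
def baseline_traj(defaults):
    """Noise-free solitary follicle on the default parameters, six cycles."""
    act, inh, geom, thr, law = defaults
    return simulate_hf(act, inh, geom, thr, horizon=600.0, dt=0.0125,
                       growth_law=law, output_stride=1.0)


@pytest.fixture(scope="session")
def baseline_durations(baseline_traj):
    return phase_durations(baseline_traj)


def make_record(onsets_per_cycle, shape=None, period=90.0):
    """Scripted PatternRecord: only the transition log is populated.

    ``onsets_per_cycle``: list of 2D arrays (one per cycle) of anagen onset
    times; NaN marks a site without that cycle.  Phase/length/signal
    histories are filled with placeholders — the onset-map metrics read the
    transition log only.
    """
    onsets_per_cycle = [np.asarray(m, dtype=float) for m in onsets_per_cycle]
    shape = shape or onsets_per_cycle[0].shape
    lattice = build_lattice(shape, coupling_strength=0.0)
    coords = lattice.site_coords
    idx = lattice.site_index_grid()
    rows = []
    for k, m in enumerate(onsets_per_cycle, start=1):
        for r, c in coords:
            t = m[r, c]
            if np.isnan(t):
                continue
            rows.append({"time": t, "site": idx[r, c], "row": r, "col": c,
                         "from_phase": 0, "to_phase": 1, "cycle_index": k})
            rows.append({"time": t + period / 3, "site": idx[r, c], "row": r,
                         "col": c, "from_phase": 1, "to_phase": 0,
                         "cycle_index": k})
    tr = pd.DataFrame(rows).sort_values("time").reset_index(drop=True)
    times = np.array([0.0])
    S = lattice.n_sites
    return PatternRecord(
        times=times,
        phase=np.zeros((1, S), dtype=np.int8),
        length=np.full((1, S), 1.2),
        signal=np.zeros((1, S)),
        transitions=tr,
        lattice=lattice,
        site_coords=coords,
    )


@pytest.fixture
def scripted_record():
    return make_record
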