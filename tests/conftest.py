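import numpy as np
import pytest

from axoporate.axon_geometry import RVConfig, generate_rv, make_ensemble
from axoporate.axon_mechanics import LoadCase, MaterialTable, run_stretch
from axoporate.cortex_strain import ensemble_stats, max_strain_curve
from axoporate.membrane_synth import LeafletComposition, build_membrane


@pytest.fixture(scope="session")
def small_rv_config():
    """Coarse RV for fast unit tests."""
    return RVConfig(n_axial=12, n_circ=8, n_mt_rows=7)


@pytest.fixture(scope="session")
def small_rv(small_rv_config):
    return generate_rv(small_rv_config, seed=1)


@pytest.fixture(scope="session")
def short_load():
    return LoadCase(strain_rate=10.0, target_axonal_strain=0.10,
                    eps_grid=(0.02, 0.04, 0.06, 0.08, 0.10))


@pytest.fixture(scope="session")
def materials():
    return MaterialTable()


@pytest.fixture(scope="session")
def default_traj_rate1():
    """One full-depth default-geometry stretch at 1/s (shared: failure
    monotonicity, stability, strain-curve tests)."""
    rv = generate_rv(RVConfig(), seed=1)
    return run_stretch(rv, MaterialTable(), LoadCase(strain_rate=1.0))


@pytest.fixture(scope="session")
def small_membrane():
    """1/10-scale membrane (scales n_lipids and hydration together)."""
    return build_membrane(LeafletComposition(), n_lipids=670,
                          hydration_beads=10_000, seed=7)


@pytest.fixture(scope="session")
def default_ensemble_curves():
    """The reference experiment: 10 RVs x 4 rates at default materials.

    Session-scoped because it is the expensive core of the acceptance
    criteria (several minutes on one CPU).
    """
    cfg = RVConfig()
    mats = MaterialTable()
    rvs = make_ensemble(cfg, 10, base_seed=1)
    out = {}
    for rate in (1.0, 10.0, 20.0, 40.0):
        load = LoadCase(strain_rate=rate)
        curves = [max_strain_curve(run_stretch(rv, mats, load)) for rv in rvs]
        out[rate] = ensemble_stats(curves)
    return out
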