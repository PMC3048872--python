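import numpy as np
import pytest

import thermostab as ts
from thermostab.constants import celsius_to_kelvin


@pytest.fixture(scope="session")
def apo_params():
    """Reference apo two-state parameters (62.5 degC, 111.6 / 96.3 kcal/mol)."""
    return ts.APO_PARAMS


@pytest.fixture(scope="session")
def camp_params():
    return ts.CAMP_PARAMS


@pytest.fixture
def noiseless_excess(apo_params):
    """Noiseless excess thermogram on the standard 15-95 degC, 0.1 degC grid."""
    tg, _ = ts.simulate_thermogram(ts.SimulationSpec(params=apo_params))
    return tg.with_values(tg.values, stage="excess")


@pytest.fixture
def cd_params():
    return ts.CdMeltParams(
        tm_app=celsius_to_kelvin(68.0),
        dh_vh_app=90e3,
        native_intercept=-12.0,
        native_slope=0.02,
        denatured_intercept=-5.0,
        denatured_slope=0.01,
    )


@pytest.fixture
def linkage_params():
    # kd chosen so ~800 uM ligand raises the midpoint by ~10 degC
    return ts.LinkageParams(celsius_to_kelvin(62.5), 111.6e3, 6.5e-6)


def mc_surface_oracle(structure, probe=1.4, n_samples=200_000, seed=0):
    """Monte-Carlo rejection-sampling estimate of accessible surface area.

    Uniform random points on each atom's solvent-expanded sphere (normal
    deviates normalised to the sphere); a point counts when it lies
    outside every other expanded sphere.  Independent of the deterministic
    lattice used by the implementation.
    """
    rng = np.random.default_rng(seed)
    coords = structure.coords
    expanded = structure.radii + probe
    total = 0.0
    n = coords.shape[0]
    for i in range(n):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * v
        ok = np.ones(n_samples, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            ok &= np.sum((pts - coords[j]) ** 2, axis=1) >= expanded[j] ** 2
        total += ok.mean() * 4.0 * np.pi * expanded[i] ** 2
    return total
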