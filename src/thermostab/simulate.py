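"""Synthetic test-data generators.

These emulate the statistical structure of the real acquisitions the
analysis is designed for: excess heat-capacity scans over 15-95 degC at
1.5 K/min with a chemical baseline under the transition and iid Gaussian
instrument noise; sigmoidal single-wavelength CD melts with sloping
native/denatured baselines; Tm-vs-ligand titration series following
single-site binding linkage; and toy coordinate sets for ASA validation.

Every generator is a pure function of its arguments: the same spec and
seed give bit-identical output, and a ground-truth record is returned
alongside each dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import celsius_to_kelvin, kelvin_to_celsius
from .models import (
    CdMeltParams,
    LinkageParams,
    TwoStateParams,
    cd_two_state_signal,
    ligand_shifted_tm,
    two_state_excess_cp,
    unfolded_fraction,
)
from .structure import StructureModel, VDW_RADII
from .thermogram import MeltCurve, Thermogram, TitrationSeries

__all__ = [
    "SimulationSpec",
    "APO_PARAMS",
    "CAMP_PARAMS",
    "G325D_PARAMS",
    "simulate_thermogram",
    "simulate_cd_melt",
    "simulate_titration_series",
    "toy_structure",
]

# Reference parameter sets for the PKA RIalpha(92-381) constructs this
# package was built around (reporting units degC / kcal/mol):
# apo, cAMP-saturated, and the site-B mutant G325D in its apo form (same
# transition enthalpies as wild-type apo, shifted midpoint).
APO_PARAMS = TwoStateParams.from_celsius_kcal(62.5, 111.6, 96.3)
CAMP_PARAMS = TwoStateParams.from_celsius_kcal(71.0, 120.4, 139.9)
G325D_PARAMS = TwoStateParams.from_celsius_kcal(52.1, 111.6, 96.3)

#: Default instrument noise on molar heat capacity, cal/(mol K)
#: (0.1 kcal/(mol K), small against the ~12 kcal/(mol K) transition peak).
DEFAULT_DSC_NOISE = 100.0


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate: model parameters, grid, baseline, noise, seed.

    ``grid`` is (start, stop, step) in degC, stop inclusive.  ``baseline``
    gives (intercept, slope) pairs, in signal units vs degC, of the pre-
    and post-transition trends; the injected chemical baseline blends them
    with the true extent of conversion.  ``noise_sd`` is the iid Gaussian
    noise level in signal units (cal/(mol K) for thermograms).
    """

    params: TwoStateParams | CdMeltParams | LinkageParams
    grid: tuple[float, float, float] = (15.0, 95.0, 0.1)
    noise_sd: float = 0.0
    baseline: tuple[tuple[float, float], tuple[float, float]] | None = None
    seed: int = 0
    scan_rate_k_per_min: float = 1.5
    protein_conc_molar: float = 4e-6
    cell_volume_l: float = 0.527e-3
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        start, stop, step = self.grid
        if step <= 0 or stop <= start:
            raise ValueError("grid must be (start, stop, step) with step > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def temperature_celsius(self) -> np.ndarray:
        start, stop, step = self.grid
        n = int(round((stop - start) / step))
        return start + step * np.arange(n + 1)


def _baseline_values(spec: SimulationSpec, t_c, theta):
    if spec.baseline is None:
        return np.zeros_like(t_c)
    (a0, a1), (b0, b1) = spec.baseline
    pre = a0 + a1 * t_c
    post = b0 + b1 * t_c
    return (1.0 - theta) * pre + theta * post


def simulate_thermogram(spec: SimulationSpec):
    """Molar-stage thermogram: two-state peak + chemical baseline + noise.

    Returns (Thermogram, truth) where ``truth`` records the injected
    parameters, baseline and seed.
    """
    if not isinstance(spec.params, TwoStateParams):
        raise TypeError("simulate_thermogram needs TwoStateParams")
    t_c = spec.temperature_celsius()
    t_k = celsius_to_kelvin(t_c)
    cp = two_state_excess_cp(t_k, spec.params)
    theta = unfolded_fraction(t_k, spec.params)
    baseline = _baseline_values(spec, t_c, theta)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=t_c.size) if spec.noise_sd else 0.0
    tg = Thermogram(
        temperature_k=t_k,
        values=cp + baseline + noise,
        scan_rate_k_per_min=spec.scan_rate_k_per_min,
        protein_conc_molar=spec.protein_conc_molar,
        cell_volume_l=spec.cell_volume_l,
        stage="molar",
        meta={"seed": str(spec.seed)},
    )
    truth = {
        "tm_celsius": kelvin_to_celsius(spec.params.tm),
        "dh_cal_kcal": spec.params.dh_cal / 1e3,
        "dh_vh_kcal": spec.params.dh_vh / 1e3,
        "baseline": spec.baseline,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return tg, truth


def simulate_cd_melt(spec: SimulationSpec):
    """Single-wavelength melt from the two-state optical model + noise."""
    if not isinstance(spec.params, CdMeltParams):
        raise TypeError("simulate_cd_melt needs CdMeltParams")
    t_c = spec.temperature_celsius()
    t_k = celsius_to_kelvin(t_c)
    signal = cd_two_state_signal(t_k, spec.params)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=t_c.size) if spec.noise_sd else 0.0
    mc = MeltCurve(
        temperature_k=t_k,
        signal=signal + noise,
        wavelength_nm=spec.extra.get("wavelength_nm"),
        meta={"seed": str(spec.seed)},
    )
    truth = {
        "tm_app_celsius": kelvin_to_celsius(spec.params.tm_app),
        "dh_vh_app_kcal": spec.params.dh_vh_app / 1e3,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return mc, truth


def simulate_titration_series(
    linkage: LinkageParams, concs, noise_sd_tm: float = 0.0, seed: int = 0
):
    """(concentration, Tm) series from the binding-linkage relation + Tm noise."""
    concs = np.asarray(concs, dtype=float)
    tm = ligand_shifted_tm(concs, linkage)
    rng = np.random.default_rng(seed)
    if noise_sd_tm:
        tm = tm + rng.normal(0.0, noise_sd_tm, size=concs.size)
    series = TitrationSeries(concs, tm, meta={"seed": str(seed)})
    truth = {
        "tm0_celsius": kelvin_to_celsius(linkage.tm0),
        "dh0_kcal": linkage.dh0 / 1e3,
        "kd_molar": linkage.kd,
        "noise_sd_tm": noise_sd_tm,
        "seed": seed,
    }
    return series, truth


# ---------------------------------------------------------------------------
# toy coordinate sets


def _atoms(rows):
    elements, coords, names, idx, chains = [], [], [], [], []
    for el, xyz, res, i, chain in rows:
        elements.append(el)
        coords.append(xyz)
        names.append(res)
        idx.append(i)
        chains.append(chain)
    radii = np.array([VDW_RADII[e] for e in elements])
    return StructureModel(
        elements=tuple(elements),
        coords=np.asarray(coords, dtype=float),
        radii=radii,
        residue_names=tuple(names),
        residue_indices=tuple(idx),
        chain_ids=tuple(chains),
    )


def _helix_rows(n_res=20, chain="A", z0=0.0):
    """Idealised poly-alanine alpha-helix (N, CA, C, O, CB per residue).

    100 deg twist and 1.5 A rise per residue; atom placements are
    approximate but deterministic and give a compact rod.
    """
    rows = []
    for k in range(n_res):
        t = np.deg2rad(100.0 * k)
        z = z0 + 1.5 * k

        def cyl(r, dtheta_deg, dz):
            a = t + np.deg2rad(dtheta_deg)
            return [r * np.cos(a), r * np.sin(a), z + dz]

        rows.append(("N", cyl(1.6, -28.0, -0.9), "ALA", k + 1, chain))
        rows.append(("C", cyl(2.3, 0.0, 0.0), "ALA", k + 1, chain))    # CA
        rows.append(("C", cyl(1.7, 26.0, 0.6), "ALA", k + 1, chain))   # C'
        rows.append(("O", cyl(2.0, 41.0, 1.6), "ALA", k + 1, chain))
        rows.append(("C", cyl(3.4, 0.0, -0.8), "ALA", k + 1, chain))   # CB
    return rows


def toy_structure(kind: str) -> StructureModel:
    """Deterministic coordinate fixtures for ASA validation.

    Kinds: ``single_atom`` (one carbon at the origin), ``far_pair`` (two
    carbons 100 A apart), ``caged_atom`` (a carbon enclosed by 26 carbons
    on a 2.5 A cubic-lattice shell), ``mini_helix`` (ideal 20-residue
    poly-alanine helix), ``two_chain`` (two helices > 50 A apart).
    """
    if kind == "single_atom":
        return _atoms([("C", [0.0, 0.0, 0.0], "ALA", 1, "A")])
    if kind == "far_pair":
        return _atoms(
            [
                ("C", [0.0, 0.0, 0.0], "ALA", 1, "A"),
                ("C", [100.0, 0.0, 0.0], "ALA", 2, "A"),
            ]
        )
    if kind == "caged_atom":
        rows = [("C", [0.0, 0.0, 0.0], "ALA", 1, "A")]
        i = 2
        for dx in (-2.5, 0.0, 2.5):
            for dy in (-2.5, 0.0, 2.5):
                for dz in (-2.5, 0.0, 2.5):
                    if dx == dy == dz == 0.0:
                        continue
                    rows.append(("C", [dx, dy, dz], "ALA", i, "A"))
                    i += 1
        return _atoms(rows)
    if kind == "mini_helix":
        m = _atoms(_helix_rows())
        return StructureModel(
            elements=m.elements, coords=m.coords, radii=m.radii,
            residue_names=m.residue_names, residue_indices=m.residue_indices,
            chain_ids=m.chain_ids, sequences={"A": "A" * 20},
        )
    if kind == "two_chain":
        rows = _helix_rows(chain="A")
        far = [(el, [x + 80.0, y, z], res, i, "B")
               for el, (x, y, z), res, i, _ in _helix_rows(chain="B")]
        m = _atoms(rows + far)
        return StructureModel(
            elements=m.elements, coords=m.coords, radii=m.radii,
            residue_names=m.residue_names, residue_indices=m.residue_indices,
            chain_ids=m.chain_ids, sequences={"A": "A" * 20, "B": "A" * 20},
        )
    raise ValueError(f"unknown toy structure kind {kind!r}")
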