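"""Protein structures and solvent-accessible surface area (ASA).

Coordinates are read from PDB files (via gemmi, first model only) into a
flat heavy-atom table with element-based van der Waals radii.  Accessible
areas are computed with the Shrake-Rupley method on a deterministic
golden-spiral sphere lattice, and split into apolar (C, S) and polar
(N, O) classes — the split that structure-energetics correlations
consume.  The fully-unfolded reference state is an additive sum of
per-residue extended Gly-X-Gly accessibilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    APOLAR_ELEMENTS,
    GXG_REFERENCE_ASA,
    ONE_TO_THREE,
    POLAR_ELEMENTS,
    PROBE_RADIUS,
    VDW_RADII,
)

__all__ = [
    "StructureModel",
    "AsaBreakdown",
    "parse_structure",
    "shrake_rupley_asa",
    "classify_polarity",
    "unfolded_reference_asa",
    "delta_asa",
]

THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


@dataclass(frozen=True)
class StructureModel:
    """Heavy-atom coordinate model.

    Parallel arrays: ``elements`` (symbols), ``coords`` (n, 3) angstrom,
    ``radii`` (n,) angstrom, ``residue_names``, ``residue_indices``,
    ``chain_ids``.  ``sequences`` maps chain id to a one-letter string of
    its standard residues.
    """

    elements: tuple[str, ...]
    coords: np.ndarray
    radii: np.ndarray
    residue_names: tuple[str, ...]
    residue_indices: tuple[int, ...]
    chain_ids: tuple[str, ...]
    sequences: dict = field(default_factory=dict)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        radii = np.asarray(self.radii, dtype=float)
        n = coords.shape[0]
        if not (len(self.elements) == radii.size == n
                == len(self.residue_names) == len(self.residue_indices)
                == len(self.chain_ids)):
            raise ValueError("atom attribute arrays must have equal length")
        if n and not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if n and not np.all(radii > 0):
            raise ValueError("van der Waals radii must be positive")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "radii", radii)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def select_chains(self, chains) -> "StructureModel":
        chains = set(chains)
        keep = [i for i, c in enumerate(self.chain_ids) if c in chains]
        return StructureModel(
            elements=tuple(self.elements[i] for i in keep),
            coords=self.coords[keep],
            radii=self.radii[keep],
            residue_names=tuple(self.residue_names[i] for i in keep),
            residue_indices=tuple(self.residue_indices[i] for i in keep),
            chain_ids=tuple(self.chain_ids[i] for i in keep),
            sequences={c: s for c, s in self.sequences.items() if c in chains},
        )


@dataclass(frozen=True)
class AsaBreakdown:
    """Accessible surface split by polarity class, angstrom^2.

    ``per_atom`` holds atom-level areas (or per-residue areas for the
    additive unfolded reference); its sum equals apolar + polar.
    """

    apolar: float
    polar: float
    per_atom: np.ndarray

    def __post_init__(self):
        if self.apolar < 0 or self.polar < 0:
            raise ValueError("areas must be non-negative")
        object.__setattr__(self, "per_atom", np.asarray(self.per_atom, dtype=float))

    @property
    def total(self) -> float:
        return self.apolar + self.polar


def classify_polarity(element: str, residue: str | None = None) -> str:
    """Polarity class of a heavy atom: C and S apolar, N and O polar.

    The residue context is accepted for interface stability but the split
    is by element, the convention the ASA-energetics coefficients assume.
    """
    el = element.upper()
    if el in APOLAR_ELEMENTS:
        return "apolar"
    if el in POLAR_ELEMENTS:
        return "polar"
    raise ValueError(f"no polarity class for element {el!r}")


def parse_structure(
    pdb_source,
    include_hetero: bool = False,
    include_chains=None,
    on_unknown_element: str = "skip",
) -> StructureModel:
    """Parse PDB text (or a file path) into a heavy-atom model.

    Only the first model is read.  HETATM records (ligands, waters) are
    excluded unless ``include_hetero`` (waters are always dropped), so
    bound nucleotides do not contribute buried surface by default.  For
    alternate locations the highest-occupancy conformer is kept, ties
    resolved toward altloc 'A'.  Hydrogens are always dropped (heavy-atom
    convention).  Elements without a tabulated radius are skipped with a
    warning or raise, per ``on_unknown_element`` ("skip" | "fail").
    """
    if on_unknown_element not in ("skip", "fail"):
        raise ValueError("on_unknown_element must be 'skip' or 'fail'")
    text = pdb_source
    if "\n" not in str(pdb_source):
        with open(pdb_source) as fh:
            text = fh.read()
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    model = st[0]

    elements, coords, radii = [], [], []
    res_names, res_idx, chain_ids = [], [], []
    sequences: dict[str, list[str]] = {}
    for chain in model:
        if include_chains is not None and chain.name not in set(include_chains):
            continue
        seq: list[str] = []
        for residue in chain:
            is_het = residue.het_flag == "H"
            if residue.is_water():
                continue
            if is_het and not include_hetero:
                continue
            if not is_het and residue.name in THREE_TO_ONE:
                seq.append(THREE_TO_ONE[residue.name])
            # pick one conformer per atom name: max occupancy, tie -> 'A'/blank
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                    continue
                if (atom.occ, -ord(atom.altloc or "A")) > (
                    prev.occ, -ord(prev.altloc or "A")
                ):
                    best[atom.name] = atom
            for atom in best.values():
                el = atom.element.name.upper()
                if el == "H" or el == "D":
                    continue
                if el not in VDW_RADII:
                    if on_unknown_element == "fail":
                        raise ValueError(f"no van der Waals radius for element {el!r}")
                    continue
                elements.append(el)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                radii.append(VDW_RADII[el])
                res_names.append(residue.name)
                res_idx.append(residue.seqid.num)
                chain_ids.append(chain.name)
        if seq:
            sequences[chain.name] = "".join(seq)

    if not elements:
        raise ValueError("no usable heavy atoms found in PDB input")
    return StructureModel(
        elements=tuple(elements),
        coords=np.asarray(coords, dtype=float),
        radii=np.asarray(radii, dtype=float),
        residue_names=tuple(res_names),
        residue_indices=tuple(res_idx),
        chain_ids=tuple(chain_ids),
        sequences=sequences,
    )


def sphere_lattice(n_points: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n_points, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_points)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_asa(
    structure: StructureModel,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = 960,
) -> AsaBreakdown:
    """Shrake-Rupley accessible surface area with a polarity split.

    Each atom's solvent-expanded sphere (radius r_i + probe) is sampled on
    a fixed golden-spiral lattice; a sample point is accessible when it
    lies outside every neighbour's expanded sphere.  The per-atom area is
    the accessible fraction times the expanded-sphere area.  Results are
    bit-reproducible: the point set is deterministic.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a usable estimate")
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    n = structure.n_atoms
    pts = sphere_lattice(n_points)
    coords = structure.coords
    expanded = structure.radii + probe_radius
    per_atom = np.zeros(n)
    if n:
        tree = cKDTree(coords)
        reach = float(expanded.max())
        for i in range(n):
            sphere = coords[i] + expanded[i] * pts
            neigh = [j for j in tree.query_ball_point(coords[i], expanded[i] + reach)
                     if j != i]
            accessible = np.ones(n_points, dtype=bool)
            for j in neigh:
                d2 = np.sum((sphere - coords[j]) ** 2, axis=1)
                accessible &= d2 >= expanded[j] ** 2
            per_atom[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2

    apolar = polar = 0.0
    for i, el in enumerate(structure.elements):
        if classify_polarity(el) == "apolar":
            apolar += per_atom[i]
        else:
            polar += per_atom[i]
    return AsaBreakdown(apolar=float(apolar), polar=float(polar), per_atom=per_atom)


def unfolded_reference_asa(sequence: str, on_unknown: str = "fail") -> AsaBreakdown:
    """Additive extended-state reference ASA for a one-letter sequence.

    Sums per-residue apolar/polar accessibilities of X in an extended
    Gly-X-Gly tripeptide (bundled table).  ``per_atom`` holds one entry
    per residue (its total area).
    """
    if on_unknown not in ("skip", "fail"):
        raise ValueError("on_unknown must be 'skip' or 'fail'")
    apolar = polar = 0.0
    per_res = []
    for letter in sequence:
        three = ONE_TO_THREE.get(letter.upper())
        if three is None:
            if on_unknown == "fail":
                raise ValueError(f"non-standard residue code {letter!r}")
            continue
        ap, pol = GXG_REFERENCE_ASA[three]
        apolar += ap
        polar += pol
        per_res.append(ap + pol)
    return AsaBreakdown(apolar=apolar, polar=polar, per_atom=np.asarray(per_res))


def delta_asa(folded: AsaBreakdown, unfolded: AsaBreakdown) -> tuple[float, float]:
    """Surface exposed on unfolding, (apolar, polar); positive for compact folds."""
    return unfolded.apolar - folded.apolar, unfolded.polar - folded.polar
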