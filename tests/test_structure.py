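"""PDB parsing, Shrake-Rupley surface areas, and the polarity split."""

import numpy as np
import pytest

import thermostab as ts
from thermostab.structure import sphere_lattice

from conftest import mc_surface_oracle


def pdb_line(serial, name, resname, chain, resseq, x, y, z, element,
             altloc=" ", occ=1.0, record="ATOM"):
    return (
        f"{record:<6}{serial:>5} {name:<4}{altloc}{resname:>3} {chain}"
        f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


class TestParseStructure:
    def test_single_atom_record(self):
        text = pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C") + "\nEND\n"
        model = ts.parse_structure(text)
        assert model.n_atoms == 1
        assert model.radii[0] == pytest.approx(1.70)
        assert model.sequences == {"A": "A"}

    def test_hetero_ligand_excluded_by_default(self):
        lines = [
            pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
            pdb_line(2, "C1", "CMP", "A", 2, 5.0, 0.0, 0.0, "C", record="HETATM"),
            pdb_line(3, "O1", "CMP", "A", 2, 6.0, 0.0, 0.0, "O", record="HETATM"),
            "END",
        ]
        text = "\n".join(lines) + "\n"
        assert ts.parse_structure(text).n_atoms == 1
        assert ts.parse_structure(text, include_hetero=True).n_atoms == 3

    def test_waters_always_dropped(self):
        lines = [
            pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
            pdb_line(2, "O", "HOH", "A", 2, 5.0, 0.0, 0.0, "O", record="HETATM"),
            "END",
        ]
        model = ts.parse_structure("\n".join(lines) + "\n", include_hetero=True)
        assert model.n_atoms == 1

    def test_altloc_keeps_highest_occupancy(self):
        lines = [
            pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C", altloc="A", occ=0.4),
            pdb_line(2, "CA", "ALA", "A", 1, 3.0, 0.0, 0.0, "C", altloc="B", occ=0.6),
            "END",
        ]
        model = ts.parse_structure("\n".join(lines) + "\n")
        assert model.n_atoms == 1
        assert model.coords[0, 0] == pytest.approx(3.0)

    def test_altloc_tie_prefers_a(self):
        lines = [
            pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C", altloc="A", occ=0.5),
            pdb_line(2, "CA", "ALA", "A", 1, 3.0, 0.0, 0.0, "C", altloc="B", occ=0.5),
            "END",
        ]
        model = ts.parse_structure("\n".join(lines) + "\n")
        assert model.n_atoms == 1
        assert model.coords[0, 0] == pytest.approx(0.0)

    def test_unknown_element_skip_or_fail(self):
        lines = [
            pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
            pdb_line(2, "FE", "HEM", "A", 2, 5.0, 0.0, 0.0, "FE", record="HETATM"),
            "END",
        ]
        text = "\n".join(lines) + "\n"
        assert ts.parse_structure(text, include_hetero=True).n_atoms == 1
        with pytest.raises(ValueError, match="radius"):
            ts.parse_structure(text, include_hetero=True, on_unknown_element="fail")

    def test_chain_selection(self):
        lines = [
            pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
            pdb_line(2, "CA", "GLY", "B", 1, 30.0, 0.0, 0.0, "C"),
            "END",
        ]
        model = ts.parse_structure("\n".join(lines) + "\n", include_chains=["A"])
        assert model.chain_ids == ("A",)


class TestPolarity:
    @pytest.mark.parametrize(
        "element,expected",
        [("C", "apolar"), ("S", "apolar"), ("N", "polar"), ("O", "polar")],
    )
    def test_classes(self, element, expected):
        assert ts.classify_polarity(element) == expected

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            ts.classify_polarity("P")


class TestShrakeRupley:
    def test_isolated_sphere_analytic(self):
        asa = ts.shrake_rupley_asa(ts.toy_structure("single_atom"))
        exact = 4 * np.pi * (1.70 + 1.4) ** 2
        assert asa.total == pytest.approx(exact, rel=0.005)
        assert asa.polar == 0.0

    def test_far_pair_no_occlusion(self):
        pair = ts.shrake_rupley_asa(ts.toy_structure("far_pair"))
        single = ts.shrake_rupley_asa(ts.toy_structure("single_atom"))
        assert pair.total == pytest.approx(2 * single.total, rel=1e-12)

    def test_probe_radius_monotone_exact_for_isolated_atom(self):
        single = ts.toy_structure("single_atom")
        areas = [
            ts.shrake_rupley_asa(single, probe_radius=p).total for p in (0.0, 1.0, 1.4, 2.0)
        ]
        assert np.all(np.diff(areas) > 0)
        for probe, area in zip((0.0, 1.0, 1.4, 2.0), areas):
            assert area == pytest.approx(4 * np.pi * (1.70 + probe) ** 2, rel=1e-12)

    def test_caged_atom_fully_occluded(self):
        asa = ts.shrake_rupley_asa(ts.toy_structure("caged_atom"))
        assert asa.per_atom[0] < 0.5

    def test_distant_chains_additive(self):
        both = ts.shrake_rupley_asa(ts.toy_structure("two_chain"))
        two = ts.toy_structure("two_chain")
        a = ts.shrake_rupley_asa(two.select_chains(["A"]))
        b = ts.shrake_rupley_asa(two.select_chains(["B"]))
        assert both.total == pytest.approx(a.total + b.total, rel=1e-6)
        assert both.apolar == pytest.approx(a.apolar + b.apolar, rel=1e-6)

    def test_per_atom_sums_to_class_totals(self):
        asa = ts.shrake_rupley_asa(ts.toy_structure("mini_helix"))
        assert asa.per_atom.sum() == pytest.approx(asa.apolar + asa.polar, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monte_carlo_oracle_agreement_on_clusters(self, seed):
        """Lattice sampling vs independent random-direction sampling."""
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 12)
        elements = rng.choice(["C", "N", "O", "S"], size=n)
        model = ts.StructureModel(
            elements=tuple(elements),
            coords=rng.uniform(0, 5.0, size=(n, 3)),
            radii=np.array([ts.structure.VDW_RADII[e] for e in elements]),
            residue_names=("ALA",) * n,
            residue_indices=tuple(range(1, n + 1)),
            chain_ids=("A",) * n,
        )
        sr = ts.shrake_rupley_asa(model).total
        mc = mc_surface_oracle(model, n_samples=100_000, seed=seed + 100)
        assert sr == pytest.approx(mc, rel=0.02)

    def test_deterministic_lattice(self):
        assert np.array_equal(sphere_lattice(960), sphere_lattice(960))
        helix = ts.toy_structure("mini_helix")
        a = ts.shrake_rupley_asa(helix)
        b = ts.shrake_rupley_asa(helix)
        assert np.array_equal(a.per_atom, b.per_atom)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ts.shrake_rupley_asa(ts.toy_structure("single_atom"), n_points=50)


class TestUnfoldedReference:
    def test_empty_sequence(self):
        asa = ts.unfolded_reference_asa("")
        assert asa.total == 0.0

    def test_glycine_additivity(self):
        from thermostab.constants import GXG_REFERENCE_ASA

        gg = ts.unfolded_reference_asa("GG")
        ap, pol = GXG_REFERENCE_ASA["GLY"]
        assert gg.apolar == pytest.approx(2 * ap)
        assert gg.polar == pytest.approx(2 * pol)

    def test_sum_matches_direct_table_summation(self):
        from thermostab.constants import GXG_REFERENCE_ASA, ONE_TO_THREE

        seq = "ACDEFGHIKLMNPQRSTVWY"
        asa = ts.unfolded_reference_asa(seq)
        expect_ap = sum(GXG_REFERENCE_ASA[ONE_TO_THREE[c]][0] for c in seq)
        expect_pol = sum(GXG_REFERENCE_ASA[ONE_TO_THREE[c]][1] for c in seq)
        assert asa.apolar == pytest.approx(expect_ap)
        assert asa.polar == pytest.approx(expect_pol)

    def test_unknown_residue_handling(self):
        with pytest.raises(ValueError):
            ts.unfolded_reference_asa("AXA")
        skipped = ts.unfolded_reference_asa("AXA", on_unknown="skip")
        double = ts.unfolded_reference_asa("AA")
        assert skipped.total == pytest.approx(double.total)


class TestDeltaAsa:
    def test_identical_inputs_zero(self):
        asa = ts.unfolded_reference_asa("AAA")
        assert ts.delta_asa(asa, asa) == (0.0, 0.0)

    def test_zero_folded_equals_unfolded_totals(self):
        unfolded = ts.unfolded_reference_asa("AAA")
        folded = ts.AsaBreakdown(0.0, 0.0, np.zeros(0))
        assert ts.delta_asa(folded, unfolded) == (unfolded.apolar, unfolded.polar)

    def test_compact_helix_buries_surface_in_both_classes(self):
        helix = ts.toy_structure("mini_helix")
        folded = ts.shrake_rupley_asa(helix)
        unfolded = ts.unfolded_reference_asa(helix.sequences["A"])
        dap, dpol = ts.delta_asa(folded, unfolded)
        assert dap > 0
        assert dpol > 0
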