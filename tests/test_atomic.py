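"""Atomic model generation, crossover backbone adjustment, PDB round trip."""

import numpy as np
import pytest

from dnafem import fixtures as fx
from dnafem.atomic import (
    BACKBONE_SUGAR,
    GLYCOSIDIC,
    adjust_crossover_backbone,
    generate_atoms,
    read_pdb,
    reference_nucleotide,
    write_pdb,
)
from dnafem.mechanics import build_model
from dnafem.solver import solve_equilibrium
from dnafem.topology import build_topology


@pytest.fixture(scope="module")
def junction_atoms(solved_junction):
    design, topo, model, sol = solved_junction
    return design, topo, model, sol, generate_atoms(sol, design, model, topo)


class TestReferenceBasepair:
    @pytest.mark.parametrize("pair", [("A", "T"), ("G", "C"), ("T", "A"), ("C", "G")])
    def test_watson_crick_geometry(self, pair):
        """Glycosidic distances and H-bond donor/acceptor separation sane."""
        b1, b2 = pair
        n1, e1, X1 = reference_nucleotide(b1, "ref")
        n2, e2, X2 = reference_nucleotide(b2, "comp")
        i1 = {n: i for i, n in enumerate(n1)}
        i2 = {n: i for i, n in enumerate(n2)}
        c1c1 = np.linalg.norm(X1[i1["C1'"]] - X2[i2["C1'"]])
        assert c1c1 == pytest.approx(10.44, abs=0.01)
        # central WC H-bond (purine N1 - pyrimidine N3)
        wc1 = "N1" if b1 in "AG" else "N3"
        wc2 = "N1" if b2 in "AG" else "N3"
        d = np.linalg.norm(X1[i1[wc1]] - X2[i2[wc2]])
        assert 2.2 < d < 3.3

    def test_full_heavy_atom_complement(self):
        for base, count in [("A", 21), ("G", 22), ("T", 20), ("C", 19)]:
            names, elements, X = reference_nucleotide(base)
            assert len(names) == count
            assert "P" in names and "C1'" in names
            assert np.all(np.isfinite(X))


class TestGenerateAtoms:
    def test_single_bp_identity_frame(self):
        """A 1-bp design at the identity frame reproduces the reference bp."""
        d = fx.make_duplex_design(1)
        topo = build_topology(d)
        model = build_model(topo, d)
        sol = solve_equilibrium(model)
        am = generate_atoms(sol, d, model, topo)
        names, _, Xref = reference_nucleotide("A", "ref")
        got = am.xyz[am.nucleotide_id == 0]
        # node frame e1 <-> template +y: compare after the fixed axis mapping
        M = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        assert np.allclose(got, Xref @ M.T, atol=1e-9)

    def test_bform_twist_between_steps(self):
        d = fx.make_duplex_design(10)
        topo = build_topology(d)
        model = build_model(topo, d)
        sol = solve_equilibrium(model)
        am = generate_atoms(sol, d, model, topo)
        c1 = []
        for nid in range(0, 20, 2):  # reference strand nucleotides
            idxs = am.residue_atoms(nid)
            c1.append(am.xyz[idxs[am.name[idxs] == "C1'"][0]])
        c1 = np.array(c1)
        v = c1[:, :2]
        ang = [
            np.degrees(np.arctan2(v[i, 0] * v[i + 1, 1] - v[i, 1] * v[i + 1, 0],
                                  np.dot(v[i], v[i + 1])))
            for i in range(len(v) - 1)
        ]
        assert np.allclose(ang, 34.2857, atol=0.01)
        assert np.allclose(np.diff(c1[:, 2]), 3.4, atol=1e-6)

    def test_atom_count_deterministic_in_sequence(self, junction_atoms):
        design, topo, model, sol, am = junction_atoms
        per_base = {"A": 21, "G": 22, "T": 20, "C": 19}
        expected = sum(per_base[nt.base] for nt in design.nucleotides.values())
        assert len(am) == expected

    def test_rigid_placement_preserves_intra_bp_distances(self, junction_atoms):
        design, topo, model, sol, am = junction_atoms
        names, _, Xref = reference_nucleotide("A", "ref")
        for nid in [n for n, nt in design.nucleotides.items() if nt.base == "A"][:3]:
            idxs = am.residue_atoms(nid)
            got = am.xyz[idxs]
            D_got = np.linalg.norm(got[:, None] - got[None, :], axis=-1)
            D_ref = np.linalg.norm(Xref[:, None] - Xref[None, :], axis=-1)
            assert np.allclose(D_got, D_ref, atol=1e-9)


class TestCrossoverAdjustment:
    def test_no_junction_no_change(self):
        d = fx.make_duplex_design(8)
        topo = build_topology(d)
        model = build_model(topo, d)
        sol = solve_equilibrium(model)
        am = generate_atoms(sol, d, model, topo)
        before = am.xyz.copy()
        adjust_crossover_backbone(am, topo, d)
        assert np.array_equal(am.xyz, before)

    def test_only_crossing_strand_backbone_moves(self, solved_junction):
        design, topo, model, sol = solved_junction
        am = generate_atoms(sol, design, model, topo)
        before = am.xyz.copy()
        adjust_crossover_backbone(am, topo, design)
        delta = np.abs(am.xyz - before).max(axis=1)
        movers = set(am.nucleotide_id[delta > 1e-12].tolist())
        crossing = set()
        for j in topo.junctions:
            for a, b in j.crossing_links():
                crossing |= {a, b}
        assert movers == crossing
        base_sel = ~np.isin(am.name, BACKBONE_SUGAR)
        assert np.array_equal(am.xyz[base_sel], before[base_sel])

    def test_axis_distance_preserved(self, solved_junction):
        design, topo, model, sol = solved_junction
        am = generate_atoms(sol, design, model, topo)
        nid = topo.junctions[0].crossing_links()[0][0]
        idxs = am.residue_atoms(nid)
        names = am.name[idxs]
        p0 = am.xyz[idxs[names == "C1'"][0]]
        axis = am.xyz[idxs[names == GLYCOSIDIC[design.nucleotides[nid].base]][0]] - p0

        def dist_to_axis(pt):
            v = pt - p0
            return np.linalg.norm(v - np.dot(v, axis) / np.dot(axis, axis) * axis)

        before = {n: dist_to_axis(am.xyz[idxs[names == n][0]])
                  for n in ("P", "C4'", "O3'")}
        adjust_crossover_backbone(am, topo, design)
        after = {n: dist_to_axis(am.xyz[idxs[names == n][0]])
                 for n in ("P", "C4'", "O3'")}
        for n in before:
            assert after[n] == pytest.approx(before[n], abs=1e-9)

    def test_single_application_enforced(self, solved_junction):
        design, topo, model, sol = solved_junction
        am = generate_atoms(sol, design, model, topo)
        adjust_crossover_backbone(am, topo, design)
        with pytest.raises(ValueError, match="already applied"):
            adjust_crossover_backbone(am, topo, design)


class TestPDB:
    def test_roundtrip_at_format_precision(self, junction_atoms, tmp_path):
        design, topo, model, sol, am = junction_atoms
        p = tmp_path / "j.pdb"
        write_pdb(am, p)
        back = read_pdb(p)
        assert len(back) == len(am)
        assert back.name.tolist() == am.name.tolist()
        assert back.resid.tolist() == am.resid.tolist()
        assert np.abs(back.xyz - am.xyz).max() < 1e-3 + 1e-6

    def test_one_chain_per_strand(self, junction_atoms, tmp_path):
        design, topo, model, sol, am = junction_atoms
        assert len(set(am.chain.tolist())) == len(design.strands())
        assert am.resid.min() == 1
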