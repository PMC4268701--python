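"""Element energies, junction ground state, analytic gradients, model counts."""

import numpy as np
import pytest

from dnafem import fixtures as fx
from dnafem import geometry as geo
from dnafem.mechanics import (
    ElasticParams,
    beam_properties,
    build_model,
    junction_energy,
    junction_ground_geometry,
    junction_rest_connector,
    total_energy,
    total_gradient,
)
from dnafem.topology import build_topology

rng = np.random.default_rng(3)


class TestBeamProperties:
    def test_defaults(self, params):
        EA, EI, GJ, L0, tw = beam_properties(params)
        assert (EA, EI, GJ, L0) == (1100.0, 230.0, 460.0, 0.34)
        assert tw == pytest.approx(34.2857, abs=1e-3)

    def test_nick_scaling(self):
        p = ElasticParams(nick_factor_b=0.01)
        EA, EI, GJ, _, _ = beam_properties(p, is_nick=True)
        assert EI == pytest.approx(2.3)
        assert GJ == pytest.approx(4.6)
        assert EA == 1100.0  # stretch modulus never scaled

    def test_nick_b1_identical(self, params):
        assert beam_properties(params, True) == beam_properties(params, False)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ElasticParams(bend_modulus=-1.0)
        with pytest.raises(ValueError):
            ElasticParams(J_twist0=200.0)


class TestJunctionGroundState:
    def test_interhelical_distance(self, params):
        (xA, RA), (xB, RB) = junction_ground_geometry(params)
        assert np.linalg.norm(xB - xA) == pytest.approx(1.85)

    def test_scissor_angle_right_handed(self, params):
        (xA, RA), (xB, RB) = junction_ground_geometry(params)
        a3, b3 = RA[:, 2], RB[:, 2]
        # undirected line-crossing angle is 60 deg
        assert np.degrees(np.arccos(abs(np.dot(a3, b3)))) == pytest.approx(60.0)
        # right-handed: rotating line A toward line B about the A->B normal
        n = (xB - xA) / np.linalg.norm(xB - xA)
        assert np.dot(np.cross(a3, -b3), n) > 0

    def test_degenerate_parallel_ground_state(self):
        p = ElasticParams(J_twist0=1e-9) if False else ElasticParams(J_twist0=1e-6)
        (xA, RA), (xB, RB) = junction_ground_geometry(p)
        assert abs(np.dot(RA[:, 2], RB[:, 2])) == pytest.approx(1.0, abs=1e-9)

    def test_ground_state_energy_zero(self, solved_junction):
        design, topo, model, _ = solved_junction
        E, G = junction_energy(model, 0, model.x0, model.R0)
        assert E == pytest.approx(0.0, abs=1e-18)
        assert np.allclose(G, 0.0, atol=1e-9)


class TestJunctionEnergy:
    def _model_with_scissor(self, delta_deg, a=1.0):
        params = ElasticParams(stiffness_factor_a=a)
        design = fx.make_single_junction_design(6, params=params)
        topo = build_topology(design)
        model = build_model(topo, design, params)
        x = model.x0.copy()
        R = model.R0.copy()
        iA, iB = model.helix_nodes[0]
        axis = (x[iB] - x[iA]) / np.linalg.norm(x[iB] - x[iA])
        R[iB] = geo.exp_so3(axis * np.radians(delta_deg)) @ R[iB]
        return model, x, R

    def test_pure_scissor_quadratic(self):
        """10 deg extra scissor costs 1/2 * 135.3 * (0.1745)^2 = 2.06 pN nm."""
        model, x, R = self._model_with_scissor(10.0)
        E, _ = junction_energy(model, 0, x, R)
        assert E == pytest.approx(0.5 * 135.3 * np.radians(10.0) ** 2, rel=1e-9)
        assert E == pytest.approx(2.06, abs=0.01)

    def test_stiffness_factor_linearity(self):
        m1, x, R = self._model_with_scissor(10.0, a=1.0)
        m2, x2, R2 = self._model_with_scissor(10.0, a=2.0)
        E1, _ = junction_energy(m1, 0, x, R)
        E2, _ = junction_energy(m2, 0, x2, R2)
        assert E2 == pytest.approx(2 * E1, rel=1e-12)

    def test_spring_axes(self, params):
        c_rest, Q_rest, axes, kr, ktr = junction_rest_connector(params)
        assert kr == pytest.approx([1353.0, 1353.0, 135.3])
        assert ktr == pytest.approx(1.7e4)
        assert c_rest == pytest.approx([1.85, 0.0, 0.0])


def _perturbed_state(model, scale_x=0.05, scale_r=0.2):
    x = model.x0 + scale_x * rng.standard_normal(model.x0.shape)
    R = geo.normalize_rotations(
        geo.exp_so3(scale_r * rng.standard_normal((model.n_nodes, 3))) @ model.R0
    )
    return x, R


@pytest.mark.parametrize("fixture_name", ["duplex", "junction", "tile"])
def test_gradients_match_finite_differences(fixture_name):
    """Analytic generalized forces agree with central FD of the energy."""
    design = {
        "duplex": lambda: fx.make_duplex_design(15, nick_steps=(6,)),
        "junction": lambda: fx.make_single_junction_design(6),
        "tile": lambda: fx.make_lattice_design(fx.LatticeSpec(10, 10, 2, 2, stub_bp=4)),
    }[fixture_name]()
    topo = build_topology(design)
    model = build_model(topo, design, ElasticParams(nick_factor_b=0.5))
    x, R = _perturbed_state(model)
    g = total_gradient(model, x, R, w_constraint=1.0)
    h = 1e-5
    worst = 0.0
    E0, _ = total_energy(model, x, R, 1.0)
    scale = max(1.0, abs(E0))
    for node in range(0, model.n_nodes, max(1, model.n_nodes // 12)):
        for dof in range(6):
            vals = []
            for sgn in (h, -h):
                xs, Rs = x.copy(), R.copy()
                if dof < 3:
                    xs[node, dof] += sgn
                else:
                    ax = np.zeros(3)
                    ax[dof - 3] = sgn
                    Rs[node] = geo.exp_so3(ax) @ R[node]
                E, _ = total_energy(model, xs, Rs, 1.0)
                vals.append(E)
            fd = (vals[0] - vals[1]) / (2 * h)
            ref = max(1.0, abs(fd), 1e-6 * scale)
            worst = max(worst, abs(fd - g[node, dof]) / ref)
    assert worst < 1e-6


def test_energy_rigid_motion_invariance(solved_junction):
    design, topo, model, _ = solved_junction
    x, R = _perturbed_state(model)
    E0, _ = total_energy(model, x, R, 1.0)
    w = rng.standard_normal(3)
    Q = geo.exp_so3(w / np.linalg.norm(w) * 1.1)
    t = np.array([3.0, -7.0, 2.0])
    E1, _ = total_energy(model, x @ Q.T + t, Q @ R, 1.0)
    assert E1 == pytest.approx(E0, rel=1e-9)


def test_beam_energy_zero_only_at_rest(duplex21):
    design, topo = duplex21
    model = build_model(topo, design)
    E, _ = total_energy(model, model.x0, model.R0)
    assert E == pytest.approx(0.0, abs=1e-12)
    x, R = _perturbed_state(model, 0.01, 0.02)
    E2, _ = total_energy(model, x, R)
    assert E2 > 1e-3


class TestModelCounts:
    def test_plain_duplex(self, duplex21):
        design, topo = duplex21
        model = build_model(topo, design)
        c = model.counts
        assert (c["n_bp_nodes"], c["n_bp_step_beams"]) == (21, 20)
        assert c["n_junctions"] == c["n_constraints"] == 0

    def test_isolated_junction(self, solved_junction):
        _, _, model, _ = solved_junction
        c = model.counts
        assert (c["n_bp_nodes"], c["n_bp_step_beams"], c["n_junctions"]) == (40, 36, 1)
        assert c["n_constraints"] == 0
        assert c["n_aux_helix_nodes"] == 2

    def test_tile_connectivity(self, tile2x2):
        _, design, topo = tile2x2
        model = build_model(topo, design)
        assert model.counts["n_junctions"] == 4
        assert model.counts["n_constraints"] == 4  # one weld per connecting duplex

    def test_missing_isomer_rejected(self, junction_design):
        design, topo = junction_design
        import copy

        topo2 = copy.deepcopy(topo)
        topo2.junctions[0].isomer = None
        with pytest.raises(ValueError, match="isomer"):
            build_model(topo2, design)


def test_stress_free_exploded_initialization():
    """Every generated family starts at exactly zero elastic energy."""
    designs = [
        fx.make_single_junction_design(8),
        fx.make_lattice_design(fx.LatticeSpec(10, 10, 2, 2, stub_bp=4)),
        fx.make_ring_design(fx.RingSpec([100, 150], crossovers_per_pair=3)),
        fx.make_tensegrity_design(fx.TensegritySpec()),
    ]
    for design in designs:
        topo = build_topology(design)
        model = build_model(topo, design)
        E, _ = total_energy(model, model.x0, model.R0, w_constraint=0.0)
        assert E < 1e-15
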