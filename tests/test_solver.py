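"""Equilibrium solve, normal modes and thermal fluctuations vs closed forms."""

import numpy as np
import pytest

from dnafem import fixtures as fx
from dnafem import geometry as geo
from dnafem.mechanics import ElasticParams, build_model, close_loop
from dnafem.solver import (
    SolveSchedule,
    energy_report,
    normal_modes,
    solve_equilibrium,
    thermal_rmsf,
)
from dnafem.topology import build_topology

KBT298 = 0.0138065 * 298.0


class TestEquilibrium:
    def test_rest_duplex_is_fixed_point(self, solved_straight100):
        _, _, model, sol = solved_straight100
        assert sol.converged
        assert sol.energies["total"] == pytest.approx(0.0, abs=1e-9)
        assert np.abs(sol.x - model.x0).max() < 1e-9

    def test_ring_closure_radius(self, solved_ring_closure):
        """Closed 100-bp loop relaxes to the analytic circle L/2pi = 5.411 nm."""
        _, _, model, sol = solved_ring_closure
        assert sol.converged
        x = sol.x[:100]
        r = np.linalg.norm(x - x.mean(axis=0), axis=1)
        assert r.mean() == pytest.approx(100 * 0.34 / (2 * np.pi), rel=0.02)

    def test_ring_closure_bend_energy(self, solved_ring_closure):
        """Bending energy matches 1/2 B L / R^2 = 133.5 pN nm within 2%."""
        _, _, _, sol = solved_ring_closure
        rep = energy_report(sol)
        L = 100 * 0.34
        R = L / (2 * np.pi)
        analytic = 0.5 * 230.0 * L / R**2
        assert rep["bend"] == pytest.approx(analytic, rel=0.02)
        # free twist at the nick: torsional energy relaxes away
        assert rep["twist"] < 0.01 * analytic
        assert rep["stretch"] < 0.01 * analytic

    def test_energy_report_sums(self, solved_ring_closure):
        _, _, _, sol = solved_ring_closure
        rep = energy_report(sol)
        total = rep.pop("total")
        assert sum(rep.values()) == pytest.approx(total, rel=1e-9)

    def test_constraint_gap_tolerances(self, solved_ring_closure):
        _, _, _, sol = solved_ring_closure
        assert sol.gap_x < 1e-3   # nm
        assert sol.gap_r < 1e-3   # rad

    def test_determinism(self):
        """Identical model + schedule reproduce iteration counts and frames."""
        def run():
            design = fx.make_single_junction_design(6)
            topo = build_topology(design)
            model = build_model(topo, design)
            x0 = model.x0.copy()
            model.x0[:] = x0 + 0.0
            sol = solve_equilibrium(model)
            return sol

        a, b = run(), run()
        assert a.n_iterations == b.n_iterations
        assert [t["iterations"] for t in a.trace] == [t["iterations"] for t in b.trace]
        assert np.array_equal(a.x, b.x)

    def test_rigid_motion_of_initial_state(self):
        """Rigidly moved initial configurations give the same internal energy."""
        spec = fx.LatticeSpec(10, 10, 2, 2, stub_bp=4)
        design = fx.make_lattice_design(spec)
        topo = build_topology(design)
        model = build_model(topo, design)
        sol = solve_equilibrium(model)

        rng = np.random.default_rng(11)
        w = rng.standard_normal(3)
        Q = geo.exp_so3(w / np.linalg.norm(w) * 0.9)
        t = np.array([4.0, 1.0, -6.0])
        model2 = build_model(topo, design)
        model2.x0 = model.x0 @ Q.T + t
        model2.R0 = Q @ model.R0
        sol2 = solve_equilibrium(model2)
        assert sol2.energies["total"] == pytest.approx(sol.energies["total"], abs=1e-4)

    def test_junction_scale_linearity(self):
        """At fixed rotational deflection, scaling a scales the junction energy.

        The deflection rotates the helix nodes in place (the a-independent
        translational centre coupling stays at rest).
        """
        from dnafem.mechanics import total_energy

        design = fx.make_single_junction_design(6)
        topo = build_topology(design)
        m1 = build_model(topo, design, ElasticParams(stiffness_factor_a=1.0))
        m2 = build_model(topo, design, ElasticParams(stiffness_factor_a=2.0))
        rng = np.random.default_rng(5)
        x = m1.x0.copy()
        R = m1.R0.copy()
        _, iB = m1.helix_nodes[0]
        R[iB] = geo.exp_so3(0.2 * rng.standard_normal(3)) @ R[iB]
        _, c1 = total_energy(m1, x, R)
        _, c2 = total_energy(m2, x, R)
        assert c1["junction"] > 0
        assert c2["junction"] == pytest.approx(2 * c1["junction"], rel=1e-12)


class TestNormalModes:
    def test_free_duplex_six_rigid_modes(self, solved_straight100):
        _, _, model, sol = solved_straight100
        modes = normal_modes(model, sol, n_modes=20)
        assert modes.n_rigid == 6
        assert np.all(modes.eigenvalues[~modes.rigid] > 0)

    def test_stiffness_doubling_doubles_eigenvalues(self):
        design = fx.make_duplex_design(30)
        topo = build_topology(design)
        p2 = ElasticParams(stretch_modulus=2200, bend_modulus=460, twist_modulus=920)
        sols = []
        for p in (ElasticParams(), p2):
            model = build_model(topo, design, p)
            sol = solve_equilibrium(model)
            modes = normal_modes(model, sol, n_modes=12)
            sols.append(modes.eigenvalues[~modes.rigid][:5])
        assert sols[1] == pytest.approx(2 * sols[0], rel=1e-6)

    def test_free_beam_lowest_bending_mode(self, solved_straight100):
        """Lowest non-rigid eigenvalue vs the classical free-free closed form.

        The stiffness-spectrum eigenproblem weights every DOF equally, so the
        classical Euler-Bernoulli value carries the standard Rayleigh
        rotary-inertia correction evaluated on the analytic mode shape.
        """
        _, _, model, sol = solved_straight100
        modes = normal_modes(model, sol, n_modes=10)
        lam1 = modes.eigenvalues[~modes.rigid][0]
        L = 99 * 0.34
        bl = 4.730040744862704
        b = bl / L
        x = np.linspace(0, L, 4001)
        s = (np.cosh(bl) - np.cos(bl)) / (np.sinh(bl) - np.sin(bl))
        w = np.cosh(b * x) + np.cos(b * x) - s * (np.sinh(b * x) + np.sin(b * x))
        wp = b * (np.sinh(b * x) - np.sin(b * x)) - s * b * (np.cosh(b * x) + np.cos(b * x))
        I0 = np.trapezoid(w**2, x)
        I1 = np.trapezoid(wp**2, x)
        lam_classical = 230.0 * b**4 * 0.34 * I0 / (I0 + I1)
        assert lam1 == pytest.approx(lam_classical, rel=0.05)


class TestThermalRMSF:
    def test_zero_temperature(self, solved_straight100):
        _, _, model, sol = solved_straight100
        modes = normal_modes(model, sol, n_modes=30)
        assert np.allclose(thermal_rmsf(modes, temperature=0.0), 0.0)

    def test_monotone_in_temperature(self, solved_straight100):
        _, _, model, sol = solved_straight100
        modes = normal_modes(model, sol, n_modes=30)
        r1 = thermal_rmsf(modes, 150.0)
        r2 = thermal_rmsf(modes, 298.0)
        assert np.all(r2 >= r1)

    def test_cantilever_tip_fluctuation(self):
        """Clamped 10-step duplex: tip transverse std = sqrt(kBT L^3/3B)."""
        design = fx.make_duplex_design(11)
        topo = build_topology(design)
        model = build_model(topo, design)
        sol = solve_equilibrium(model)
        modes = normal_modes(model, sol, n_modes=60, clamp_anchor=True)
        keep = (~modes.rigid) & (modes.eigenvalues > 0)
        V = modes.mode_shapes[:, keep]
        lam = modes.eigenvalues[keep]
        tip = 10
        var = np.array([
            KBT298 * np.sum(V[6 * tip + a, :] ** 2 / lam) for a in range(2)
        ])
        L = 10 * 0.34
        analytic = KBT298 * L**3 / (3 * 230.0)
        assert np.sqrt(var[0]) == pytest.approx(np.sqrt(analytic), rel=0.05)
        assert np.sqrt(var[1]) == pytest.approx(np.sqrt(analytic), rel=0.05)
        assert np.sqrt(analytic) == pytest.approx(0.48, abs=0.01)

    def test_rmsf_shape_and_positivity(self, solved_junction):
        _, _, model, sol = solved_junction
        modes = normal_modes(model, sol, n_modes=50)
        rmsf = thermal_rmsf(modes)
        assert rmsf.shape == (model.n_bp_nodes,)
        assert np.all(rmsf >= 0)
        assert np.all(np.isfinite(rmsf))
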