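"""Geometrically nonlinear equilibrium solve and normal-mode analysis.

The mechanical ground state is computed by ramping the end-pairing
constraint stiffness from a small fraction to a stiff weld over a geometric
load schedule, relaxing the full model with damped Newton iterations at
every step (analytic gradients, finite-difference element tangents, sparse
factorization, backtracking line search).  Orientations update
multiplicatively (left rotation increments), so large 3D rotations are
handled without gyroscopic singularities.

Normal modes are eigenpairs of the tangent stiffness at equilibrium; thermal
fluctuations follow from equipartition, Cov = k_B T K^+ restricted to the
non-rigid subspace, reported per bp as positional root-mean-square
fluctuations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import eigsh, splu

from . import geometry as geo
from .mechanics import (
    FEModel,
    assemble_hessian,
    constraint_gaps,
    total_energy,
    total_gradient,
)

log = logging.getLogger(__name__)


@dataclass
class SolveSchedule:
    """Load-ramp and Newton settings (all config-exposed).

    The constraint weight ramps geometrically from ``ramp_start`` to 1 over
    ``n_ramp_steps``, followed by ``n_weld_steps`` stiffening steps up to
    ``weld_factor`` times the nominal B-form step stiffness, which pushes the
    residual end-pairing pose gap below ``tol_gap_x`` / ``tol_gap_r``.
    """

    n_ramp_steps: int = 20
    ramp_start: float = 1e-3
    weld_factor: float = 1e3
    n_weld_steps: int = 3
    tol_force: float = 1e-4        # pN, per-DOF residual at the final stage
    tol_moment: float = 1e-4       # pN nm
    intermediate_tol_factor: float = 1e3
    max_newton_iter: int = 400
    intermediate_max_iter: int = 20
    max_line_search: int = 40
    max_step_x: float = 0.75       # nm, per-node Newton step cap
    max_step_r: float = 0.5        # rad
    tol_gap_x: float = 1e-3        # nm
    tol_gap_r: float = 1e-3        # rad

    def stages(self, has_constraints: bool) -> list[float]:
        if not has_constraints:
            return [1.0]
        ramp = list(np.geomspace(self.ramp_start, 1.0, self.n_ramp_steps))
        weld = list(np.geomspace(1.0, self.weld_factor, self.n_weld_steps + 1)[1:])
        return ramp + weld


@dataclass
class Solution:
    x: np.ndarray
    R: np.ndarray
    energies: dict[str, float]
    converged: bool
    trace: list[dict] = field(default_factory=list)
    w_final: float = 1.0
    gap_x: float = 0.0
    gap_r: float = 0.0
    worst_constraint: int | None = None
    n_iterations: int = 0


@dataclass
class ModeResult:
    eigenvalues: np.ndarray          # ascending, generalized stiffness units
    mode_shapes: np.ndarray          # (ndof, k)
    rigid: np.ndarray                # boolean mask of rigid-body modes
    clamped: bool
    model: FEModel

    @property
    def n_rigid(self) -> int:
        return int(self.rigid.sum())


def _free_dof_mask(model: FEModel, anchor: bool) -> np.ndarray:
    mask = np.ones(model.ndof, dtype=bool)
    if anchor:
        a = model.anchor
        mask[6 * a : 6 * a + 6] = False
    return mask


def solve_equilibrium(
    model: FEModel,
    schedule: SolveSchedule | None = None,
    anchor: bool = True,
) -> Solution:
    """Ramped-load Newton relaxation to the mechanical ground state.

    Deterministic for a given model and schedule.  During the solve one
    node's frame is fixed to remove the rigid-body null space; the internal
    equilibrium is unaffected and the anchor is released for reporting.
    """
    if schedule is None:
        schedule = SolveSchedule()
    x = model.x0.copy()
    R = model.R0.copy()
    has_constraints = bool(model.constraint_mask().any()) or bool(model.axis_welds)
    free = _free_dof_mask(model, anchor)
    trace: list[dict] = []
    stages = schedule.stages(has_constraints)
    total_iters = 0
    ok = True
    for si, w in enumerate(stages):
        final = si == len(stages) - 1
        tol_f = schedule.tol_force * (1.0 if final else schedule.intermediate_tol_factor)
        tol_m = schedule.tol_moment * (1.0 if final else schedule.intermediate_tol_factor)
        max_iter = schedule.max_newton_iter if final else schedule.intermediate_max_iter
        x, R, info = _newton_stage(model, x, R, w, free, schedule, tol_f, tol_m, max_iter)
        total_iters += info["iterations"]
        info["stage_weight"] = w
        trace.append(info)
        if not info["converged"]:
            # an intermediate stage hitting its iteration cap only degrades
            # the warm start; equilibrium is judged by the final stage
            if final:
                ok = False
            log.log(
                logging.WARNING if final else logging.INFO,
                "stage %d (w=%.3g) hit iteration cap: %s", si, w, info,
            )
            if not np.isfinite(info["energy"]):
                ok = False
                break

    E, cats = total_energy(model, x, R, stages[-1])
    gaps_x, gaps_r = constraint_gaps(model, x, R)
    gap_x = float(gaps_x.max()) if gaps_x.size else 0.0
    gap_r = float(gaps_r.max()) if gaps_r.size else 0.0
    worst = int(np.argmax(gaps_x)) if gaps_x.size else None
    converged = ok and (not has_constraints or (gap_x < schedule.tol_gap_x and gap_r < schedule.tol_gap_r))
    if not converged:
        log.warning(
            "solve did not fully converge: gap_x=%.3g nm gap_r=%.3g rad (worst constraint %s)",
            gap_x, gap_r, worst,
        )
    cats["total"] = E
    return Solution(
        x=x, R=R, energies=cats, converged=converged, trace=trace,
        w_final=stages[-1], gap_x=gap_x, gap_r=gap_r,
        worst_constraint=worst, n_iterations=total_iters,
    )


def _newton_stage(model, x, R, w, free, schedule, tol_f, tol_m, max_iter=None):
    E, _ = total_energy(model, x, R, w)
    n_iter = 0
    converged = False
    resid_f = resid_m = np.inf
    lam0 = 0.0
    if max_iter is None:
        max_iter = schedule.max_newton_iter
    for n_iter in range(1, max_iter + 1):
        g = total_gradient(model, x, R, w)
        gf = g.reshape(-1)[free]
        resid_f = float(np.abs(g[:, :3]).max()) if g.size else 0.0
        resid_m = float(np.abs(g[:, 3:]).max()) if g.size else 0.0
        # residual measured on free DOFs only (anchor reactions excluded)
        gfree = np.zeros_like(g.reshape(-1))
        gfree[free] = gf
        gfree = gfree.reshape(-1, 6)
        resid_f = float(np.abs(gfree[:, :3]).max())
        resid_m = float(np.abs(gfree[:, 3:]).max())
        if resid_f < tol_f and resid_m < tol_m:
            converged = True
            break
        H = assemble_hessian(model, x, R, w)
        Hff = H[free][:, free].tocsc()
        delta = None
        lam = lam0
        dmax = float(Hff.diagonal().max()) if Hff.shape[0] else 1.0
        for _attempt in range(12):
            try:
                Hreg = Hff if lam == 0.0 else (Hff + lam * sparse.identity(Hff.shape[0], format="csc"))
                lu = splu(Hreg)
                step = lu.solve(-gf)
            except RuntimeError:
                lam = max(lam * 10.0, 1e-8 * dmax)
                continue
            if np.dot(step, gf) < 0 and np.all(np.isfinite(step)):
                delta = step
                break
            lam = max(lam * 10.0, 1e-8 * dmax)
        if delta is None:
            break
        # cap the per-node step (trust region), then backtracking line search
        dview = np.zeros(model.ndof)
        dview[free] = delta
        dnodes = dview.reshape(-1, 6)
        mx = float(np.abs(dnodes[:, :3]).max()) if dnodes.size else 0.0
        mr = float(np.abs(dnodes[:, 3:]).max()) if dnodes.size else 0.0
        cap = min(1.0,
                  schedule.max_step_x / mx if mx > 0 else 1.0,
                  schedule.max_step_r / mr if mr > 0 else 1.0)
        delta = delta * cap
        alpha = 1.0
        accepted = False
        slope = float(np.dot(delta, gf))
        for _ls in range(schedule.max_line_search):
            xn, Rn = _apply_step(model, x, R, free, delta * alpha)
            En, _ = total_energy(model, xn, Rn, w)
            if np.isfinite(En) and En <= E + 1e-4 * alpha * slope:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        x, R, E = xn, Rn, En
        lam0 = 0.0 if alpha == 1.0 else lam
    return x, R, {
        "converged": converged, "iterations": n_iter,
        "residual_force": resid_f, "residual_moment": resid_m, "energy": E,
    }


def _apply_step(model, x, R, free, delta_free):
    d = np.zeros(model.ndof)
    d[free] = delta_free
    d = d.reshape(-1, 6)
    xn = x + d[:, :3]
    Rn = geo.normalize_rotations(geo.exp_so3(d[:, 3:]) @ R)
    return xn, Rn


def energy_report(solution: Solution) -> dict[str, float]:
    """Per-category elastic energy table (pN nm); categories sum to total."""
    cats = dict(solution.energies)
    total = cats.pop("total", sum(cats.values()))
    cats["total"] = sum(v for k, v in cats.items() if k != "total")
    assert abs(cats["total"] - total) < 1e-6 * max(1.0, abs(total))
    return cats


DENSE_LIMIT = 1900  # DOF count below which the full spectrum is computed densely


def normal_modes(
    model: FEModel,
    solution: Solution,
    n_modes: int = 100,
    clamp_anchor: bool = False,
    rigid_threshold: float = 1e-8,
) -> ModeResult:
    """Lowest eigenpairs of the tangent stiffness at equilibrium.

    Rigid-body modes are identified by eigenvalue magnitude relative to the
    largest eigenvalue estimate (threshold ``rigid_threshold``); an
    unconstrained converged model has exactly six.  A negative eigenvalue
    beyond tolerance triggers an instability warning (saddle point).
    """
    K = assemble_hessian(model, solution.x, solution.R, solution.w_final)
    free = _free_dof_mask(model, clamp_anchor)
    Kff = K[free][:, free]
    n = Kff.shape[0]
    if n <= DENSE_LIMIT:
        vals, vecs = np.linalg.eigh(Kff.toarray())
        if n_modes < n:
            vals, vecs = vals[: max(n_modes, 6)], vecs[:, : max(n_modes, 6)]
        scale = float(np.abs(Kff.diagonal()).max()) if n else 1.0
    else:
        scale = float(np.abs(Kff.diagonal()).max())
        k = min(n_modes, n - 2)
        vals, vecs = eigsh(Kff.tocsc(), k=k, sigma=-1e-6 * scale, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    thresh = rigid_threshold * scale
    rigid = np.abs(vals) < thresh
    if np.any(vals < -thresh):
        log.warning(
            "normal modes: negative eigenvalue %.3g beyond tolerance — saddle point",
            float(vals.min()),
        )
    shapes = np.zeros((model.ndof, vecs.shape[1]))
    shapes[free] = vecs
    return ModeResult(eigenvalues=vals, mode_shapes=shapes, rigid=rigid,
                      clamped=clamp_anchor, model=model)


def thermal_rmsf(modes: ModeResult, temperature: float | None = None) -> np.ndarray:
    """Per-bp positional RMSF (nm) by equipartition over non-rigid modes.

    Cov(positions) = k_B T * pseudo-inverse of the stiffness restricted to
    the non-rigid subspace; the RMSF of bp ``i`` is the square root of the
    summed variance of its three positional DOFs.  Zero at T = 0 and
    monotone non-decreasing in T.
    """
    model = modes.model
    kBT = model.params.kBT(temperature)
    keep = (~modes.rigid) & (modes.eigenvalues > 0)
    lam = modes.eigenvalues[keep]
    V = modes.mode_shapes[:, keep].reshape(model.n_nodes, 6, -1)
    var = np.einsum("nak,k->na", V[:, :3, :] ** 2, 1.0 / lam) * kBT
    rmsf = np.sqrt(var.sum(axis=1))
    return rmsf[: model.n_bp_nodes]


def solution_frames_table(model: FEModel, solution: Solution) -> "np.ndarray":
    """(n_bp, 8) array: node index, position (nm), orientation quaternion."""
    q = geo.quat_from_matrix(solution.R[: model.n_bp_nodes])
    idx = np.arange(model.n_bp_nodes)[:, None]
    return np.hstack([idx, solution.x[: model.n_bp_nodes], q])
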