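"""Finite-element model assembly: bp nodes, beam and junction elements.

Mechanical model
----------------
Each basepair is a node with six degrees of freedom (position in nm +
orientation as a proper rotation; the bp triad's third axis is the helical
axis, the first axis the roll reference pointing at the paired-helix side at
junctions).  B-form duplexes are chains of two-node elastic beam elements
with rest rise 0.34 nm and rest twist 360/10.5 deg per bp step, carrying the
empirical stretch (1100 pN), bend (230 pN nm^2) and twist (460 pN nm^2)
moduli.  Nicked steps optionally scale bend and twist by a factor ``b``.

A stacked-X four-way junction is modelled with two auxiliary "helix" nodes,
one per coaxially stacked arm pair, joined to the four flanking bp nodes by
half-step stacking connectors, plus one junction connector between the two
helix nodes.  The junction connector's rest pose places the two helical axes
1.85 nm apart along the common normal (the junction frame's e3, the scissor
axis) with a right-handed interhelical angle J_twist = 60 deg; rotational
springs of 1353 / 1353 / 135.3 pN nm/rad act about the junction frame's
e1 / e2 / e3.  Its elastic energy is zero exactly at the ground state.

End-pairing constraints (duplex ends that must become continuous B-form DNA)
are connector elements whose rest pose is the ideal bp step and whose
stiffness is ramped by the solver.

Energies are quadratic in rotation-vector error measures (matrix logarithm of
the relative rotation), so e.g. a pure scissor deflection of d radians costs
exactly 1/2 * k_twist * d^2.  All gradients are analytic (verified against
finite differences); tangent stiffness is assembled element-wise by central
finite differences of the analytic gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry as geo
from .design import Design
from .topology import Topology

log = logging.getLogger(__name__)

KB = 0.0138065  # Boltzmann constant, pN nm / K


@dataclass
class ElasticParams:
    """Elastic constants of duplexes and junctions (pN, nm, deg units)."""

    axial_rise: float = 0.34          # nm per bp step
    bp_per_turn: float = 10.5
    stretch_modulus: float = 1100.0   # pN
    bend_modulus: float = 230.0       # pN nm^2
    twist_modulus: float = 460.0      # pN nm^2
    nick_factor_b: float = 1.0        # multiplier on bend/twist moduli at nicks
    junction_offset: float = 0.925    # nm, centre to each helix axis (1.85/2)
    J_twist0: float = 60.0            # deg, right-handed ground-state scissor angle
    k_rot_e1: float = 1353.0          # pN nm / rad
    k_rot_e2: float = 1353.0          # pN nm / rad
    k_twist: float = 135.3            # pN nm / rad, about e3
    stiffness_factor_a: float = 1.0   # multiplier on junction rotational stiffnesses
    temperature: float = 298.0        # K
    junction_translational_stiffness: float = 1.7e4  # pN/nm, centre coupling
    shear_factor: float = 100.0       # shear penalty = factor * EA / L (Kirchhoff limit)

    def __post_init__(self) -> None:
        for name in ("axial_rise", "bp_per_turn", "stretch_modulus", "bend_modulus",
                     "twist_modulus", "nick_factor_b", "junction_offset",
                     "k_rot_e1", "k_rot_e2", "k_twist", "stiffness_factor_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.J_twist0 < 180.0:
            raise ValueError("J_twist0 must lie in (0, 180) degrees")

    @property
    def rest_twist_deg(self) -> float:
        return 360.0 / self.bp_per_turn

    def kBT(self, temperature: float | None = None) -> float:
        T = self.temperature if temperature is None else temperature
        return KB * T

    def with_factors(self, a: float | None = None, b: float | None = None) -> "ElasticParams":
        kw = {}
        if a is not None:
            kw["stiffness_factor_a"] = a
        if b is not None:
            kw["nick_factor_b"] = b
        return replace(self, **kw)


def beam_properties(params: ElasticParams, is_nick: bool = False):
    """(EA, EI, GJ, rest_length, rest_twist_deg) for a bp-step beam.

    Nicked steps scale the bend and twist moduli by ``nick_factor_b``; the
    stretch modulus is never scaled.
    """
    b = params.nick_factor_b if is_nick else 1.0
    return (
        params.stretch_modulus,
        params.bend_modulus * b,
        params.twist_modulus * b,
        params.axial_rise,
        params.rest_twist_deg,
    )


# -- canonical junction ground state ------------------------------------------


def junction_ground_geometry(params: ElasticParams):
    """Helix-node poses of the stacked-X ground state, in the junction frame.

    Returns ``((xA, RA), (xB, RB))``.  The junction frame has e3 along the
    common normal of the two helical axes (the scissor axis); the helix axes
    lie in planes perpendicular to e3, symmetric about e1, separated by
    2 * junction_offset along e3 and subtending the right-handed scissor
    angle J_twist0.  Each helix-node frame has its third axis along the helix
    "through" direction and its first axis pointing at the partner helix.
    The junction elastic energy of this configuration is exactly zero.
    """
    half = np.radians(params.J_twist0) / 2.0
    e1, e2, e3 = np.eye(3)
    a3 = np.cos(-half) * e1 + np.sin(-half) * e2   # helix A through-direction
    b3 = -(np.cos(half) * e1 + np.sin(half) * e2)  # helix B: antiparallel sense
    xA = -params.junction_offset * e3
    xB = +params.junction_offset * e3
    RA = np.stack([e3, np.cross(a3, e3), a3], axis=1)
    RB = np.stack([-e3, np.cross(b3, -e3), b3], axis=1)
    return (xA, RA), (xB, RB)


def junction_rest_connector(params: ElasticParams):
    """Rest transform + spring axes of the junction connector (A-node local).

    Returns ``(c_rest, Q_rest, axes, kr, ktr)`` where ``axes`` columns are
    the junction frame's e1/e2/e3 expressed in the B-node local frame (the
    frame in which the rotation-error vector lives), and ``kr`` the
    rotational stiffnesses about them (scaled by ``stiffness_factor_a``).
    """
    (xA, RA), (xB, RB) = junction_ground_geometry(params)
    c_rest = RA.T @ (xB - xA)
    Q_rest = RA.T @ RB
    axes = RB.T @ np.eye(3)  # junction e1,e2,e3 in B-local coordinates
    a = params.stiffness_factor_a
    kr = np.array([params.k_rot_e1 * a, params.k_rot_e2 * a, params.k_twist * a])
    return c_rest, Q_rest, axes, kr, params.junction_translational_stiffness


# -- element arrays -----------------------------------------------------------


@dataclass
class BeamArrays:
    """Vectorized two-node bp-step beam elements."""

    i: np.ndarray
    j: np.ndarray
    EA: np.ndarray
    EI: np.ndarray
    GJ: np.ndarray
    L0: np.ndarray
    phi0: np.ndarray     # rest twist, rad
    ksh: np.ndarray      # shear penalty, pN/nm
    is_nick: np.ndarray

    def __len__(self) -> int:
        return len(self.i)


@dataclass
class ConnectorArrays:
    """Generalized 6-DOF spring between two nodes with a rest transform.

    Used for junction elements, junction-internal stacking half-steps and
    ramped end-pairing (weld) constraints.  ``category`` is one of
    ``junction``, ``stacking``, ``constraint``.
    """

    i: np.ndarray
    j: np.ndarray
    c_rest: np.ndarray    # (n,3) rest offset, i-local
    Q_rest: np.ndarray    # (n,3,3) rest relative rotation
    axes: np.ndarray      # (n,3,3) spring axes (columns), B/j-local
    kr: np.ndarray        # (n,3) rotational stiffness about axes
    ktr: np.ndarray       # (n,) isotropic translational stiffness
    category: np.ndarray  # (n,) object array of category strings

    def __len__(self) -> int:
        return len(self.i)


@dataclass
class AxisWeld:
    """Position + axis-alignment constraint with free roll (twist released)."""

    i: int
    j: int
    L0: float       # rest separation along the mean axis (0 for coincidence)
    ktr: float
    kr: float


@dataclass
class FEModel:
    x0: np.ndarray                   # (N,3) initial node positions, nm
    R0: np.ndarray                   # (N,3,3) initial node orientations
    beams: BeamArrays
    connectors: ConnectorArrays
    axis_welds: list[AxisWeld]
    params: ElasticParams
    n_bp_nodes: int                  # bp nodes come first; aux helix nodes after
    bp_node: dict[tuple[int, int], int] = field(default_factory=dict)  # (duplex,pos)->node
    node_bp: list[tuple[int, int] | None] = field(default_factory=list)
    helix_nodes: dict[int, tuple[int, int]] = field(default_factory=dict)  # junction->(A,B)
    counts: dict[str, int] = field(default_factory=dict)
    anchor: int = 0

    @property
    def n_nodes(self) -> int:
        return self.x0.shape[0]

    @property
    def ndof(self) -> int:
        return 6 * self.n_nodes

    def constraint_mask(self) -> np.ndarray:
        return self.connectors.category == "constraint"


# -- energies and analytic gradients ------------------------------------------


def _beam_terms(model: FEModel, x: np.ndarray, R: np.ndarray, grad: bool = True):
    """Per-element beam energies by category and 12-DOF gradients."""
    b = model.beams
    n = len(b)
    if n == 0:
        z = np.zeros(0)
        return {"stretch": z, "bend": z, "twist": z, "shear": z}, np.zeros((0, 12))
    Ri, Rj = R[b.i], R[b.j]
    xi, xj = x[b.i], x[b.j]
    return _beam_terms_raw(b, xi, Ri, xj, Rj, grad)


def _beam_terms_raw(b: BeamArrays, xi, Ri, xj, Rj, grad: bool = True):
    Rrel = np.swapaxes(Ri, -1, -2) @ Rj
    theta = geo.log_so3(Rrel)                      # (n,3) in i-local coords
    # de-twist symmetrically so the rest twist does not bleed into the bend
    # components of the log strain (a 3% artefact at 34.3 deg/step otherwise)
    half = np.zeros((len(b), 3))
    half[:, 2] = 0.5 * b.phi0
    D = geo.exp_so3(half)                          # Rz(phi0/2) per element
    the = geo.log_so3(np.swapaxes(D, -1, -2) @ Rrel @ np.swapaxes(D, -1, -2))
    kb = b.EI / b.L0
    kt = b.GJ / b.L0
    E_bend = 0.5 * kb * (the[:, 0] ** 2 + the[:, 1] ** 2)
    E_twist = 0.5 * kt * the[:, 2] ** 2

    H = geo.exp_so3(0.5 * theta)
    Rm = Ri @ H
    d = xj - xi
    t = np.einsum("nba,nb->na", Rm, d)             # Rm^T d
    ka = b.EA / b.L0
    E_ax = 0.5 * ka * (t[:, 2] - b.L0) ** 2
    E_sh = 0.5 * b.ksh * (t[:, 0] ** 2 + t[:, 1] ** 2)
    terms = {"stretch": E_ax, "bend": E_bend, "twist": E_twist, "shear": E_sh}
    if not grad:
        return terms, None

    g_theta = np.stack([kb * the[:, 0], kb * the[:, 1], kt * the[:, 2]], axis=1)
    # d the = Jl^-1(the) @ D^T @ u for a left-increment u in i-local coords,
    # hence the torque on node j is Ri @ D @ Jl^-T(the) @ g_theta
    Jinv = geo.left_jacobian_inv(the)
    tau_rot = np.einsum("nab,nbd,ncd,nc->na", Ri, D, Jinv, g_theta)

    g_t = np.stack([b.ksh * t[:, 0], b.ksh * t[:, 1], ka * (t[:, 2] - b.L0)], axis=1)
    f = np.einsum("nab,nb->na", Rm, g_t)           # world force on node j
    tau_m = np.cross(f, d)                         # torque conjugate to midframe spin
    # midframe spin distribution: d(omega_m) = (I - M) d(omega_i) + M d(omega_j)
    M = 0.5 * np.einsum(
        "nab,nbc,ncd,ned->nae", Ri, geo.left_jacobian(0.5 * theta), geo.left_jacobian_inv(theta), Ri
    )
    tau_i = -tau_rot + tau_m - np.einsum("nba,nb->na", M, tau_m)
    tau_j = tau_rot + np.einsum("nba,nb->na", M, tau_m)
    G = np.concatenate([-f, tau_i, f, tau_j], axis=1)
    return terms, G


def _connector_terms(model: FEModel, x, R, w_constraint: float = 1.0, grad: bool = True):
    c = model.connectors
    n = len(c)
    if n == 0:
        z = np.zeros(0)
        return {"junction": z, "stacking": z, "constraint": z}, np.zeros((0, 12))
    Ri, Rj = R[c.i], R[c.j]
    xi, xj = x[c.i], x[c.j]
    weight = np.where(c.category == "constraint", w_constraint, 1.0)
    E, G = _connector_terms_raw(c, xi, Ri, xj, Rj, weight, grad)
    terms = {
        cat: np.where(c.category == cat, E, 0.0)
        for cat in ("junction", "stacking", "constraint")
    }
    return terms, G


def _connector_terms_raw(c: ConnectorArrays, xi, Ri, xj, Rj, weight, grad: bool = True):
    Rrel = np.swapaxes(Ri, -1, -2) @ Rj
    Rerr = np.swapaxes(c.Q_rest, -1, -2) @ Rrel
    phi = geo.log_so3(Rerr)                        # error rotation, rest-j-local
    phi_s = np.einsum("nba,nb->na", c.axes, phi)   # components on spring axes
    kr = c.kr * weight[:, None]
    E_rot = 0.5 * np.sum(kr * phi_s**2, axis=1)

    d = xj - xi
    t = np.einsum("nba,nb->na", Ri, d)             # i-local separation
    terr = t - c.c_rest
    ktr = c.ktr * weight
    E_tr = 0.5 * ktr * np.sum(terr**2, axis=1)
    E = E_rot + E_tr
    if not grad:
        return E, None

    g_phi = np.einsum("nab,nb->na", c.axes, kr * phi_s)
    RiQ = Ri @ c.Q_rest
    tau = np.einsum("nab,ncb,nc->na", RiQ, geo.left_jacobian_inv(phi), g_phi)

    g_t = ktr[:, None] * terr
    f = np.einsum("nab,nb->na", Ri, g_t)
    tau_i_tr = np.cross(f, d)
    G = np.concatenate([-f, -tau + tau_i_tr, f, tau], axis=1)
    return E, G


def _axis_weld_terms(model: FEModel, x, R, w: float, grad: bool = True):
    """Free-roll welds: position coincidence along the mean axis + axis alignment."""
    E_total = 0.0
    G = np.zeros((len(model.axis_welds), 12))
    energies = np.zeros(len(model.axis_welds))
    for k, aw in enumerate(model.axis_welds):
        ai = R[aw.i][:, 2]
        aj = R[aw.j][:, 2]
        d = x[aw.j] - x[aw.i]
        terr = d - aw.L0 * 0.5 * (ai + aj)
        ktr, kr = aw.ktr * w, aw.kr * w
        dot = float(np.dot(ai, aj))
        E = 0.5 * ktr * float(np.dot(terr, terr)) + kr * (1.0 - dot)
        energies[k] = E
        E_total += E
        if not grad:
            continue
        f = ktr * terr
        tau_align = -kr * np.cross(ai, aj)
        tau_i = tau_align - 0.5 * aw.L0 * ktr * np.cross(ai, terr)
        tau_j = -tau_align - 0.5 * aw.L0 * ktr * np.cross(aj, terr)
        G[k] = np.concatenate([-f, tau_i, f, tau_j])
    return energies, G


def junction_energy(model: FEModel, junction_id: int, x: np.ndarray, R: np.ndarray):
    """Energy (pN nm) and 12-DOF generalized force of one junction connector.

    The gradient is the exact analytic derivative of the quadratic
    rotational-spring energy; it vanishes at the ground state.
    """
    c = model.connectors
    idx = [k for k in range(len(c)) if c.category[k] == "junction"][junction_id]
    sub = ConnectorArrays(
        i=c.i[idx : idx + 1], j=c.j[idx : idx + 1],
        c_rest=c.c_rest[idx : idx + 1], Q_rest=c.Q_rest[idx : idx + 1],
        axes=c.axes[idx : idx + 1], kr=c.kr[idx : idx + 1],
        ktr=c.ktr[idx : idx + 1], category=c.category[idx : idx + 1],
    )
    E, G = _connector_terms_raw(
        sub, x[sub.i], R[sub.i], x[sub.j], R[sub.j], np.ones(1), grad=True
    )
    return float(E[0]), G[0]


def total_energy(model: FEModel, x, R, w_constraint: float = 1.0) -> tuple[float, dict]:
    bterms, _ = _beam_terms(model, x, R, grad=False)
    cterms, _ = _connector_terms(model, x, R, w_constraint, grad=False)
    aE, _ = _axis_weld_terms(model, x, R, w_constraint, grad=False)
    cats = {k: float(v.sum()) for k, v in bterms.items()}
    for k, v in cterms.items():
        cats[k] = cats.get(k, 0.0) + float(v.sum())
    cats["constraint"] = cats.get("constraint", 0.0) + float(aE.sum())
    return sum(cats.values()), cats


def total_gradient(model: FEModel, x, R, w_constraint: float = 1.0) -> np.ndarray:
    """Generalized forces: (N,6) array of (dE/dx, dE/d omega) per node."""
    g = np.zeros((model.n_nodes, 6))
    _, Gb = _beam_terms(model, x, R, grad=True)
    b = model.beams
    if len(b):
        np.add.at(g, b.i, Gb[:, 0:6].reshape(-1, 6))
        np.add.at(g, b.j, Gb[:, 6:12].reshape(-1, 6))
    _, Gc = _connector_terms(model, x, R, w_constraint, grad=True)
    c = model.connectors
    if len(c):
        np.add.at(g, c.i, Gc[:, 0:6])
        np.add.at(g, c.j, Gc[:, 6:12])
    if model.axis_welds:
        _, Ga = _axis_weld_terms(model, x, R, w_constraint, grad=True)
        for k, aw in enumerate(model.axis_welds):
            g[aw.i] += Ga[k, 0:6]
            g[aw.j] += Ga[k, 6:12]
    return g


def _perturbed(x, R, nodes, dof, h):
    """Copy of the poses of ``nodes`` with local dof (0-5) perturbed by h."""
    xs = x[nodes].copy()
    Rs = R[nodes].copy()
    if dof < 3:
        xs[:, dof] += h
    else:
        axis = np.zeros(3)
        axis[dof - 3] = h
        Rs = geo.exp_so3(np.broadcast_to(axis, (len(nodes), 3))) @ Rs
    return xs, Rs


def assemble_hessian(model: FEModel, x, R, w_constraint: float = 1.0, h: float = 1e-5):
    """Sparse tangent stiffness from central FD of the analytic element gradients."""
    from scipy import sparse

    rows, cols, vals = [], [], []

    def scatter(idx_i, idx_j, Hloc):
        # Hloc: (n,12,12) local stiffness; symmetrize for FD noise
        Hloc = 0.5 * (Hloc + np.swapaxes(Hloc, 1, 2))
        nodes = np.stack([idx_i, idx_j], axis=1)  # (n,2)
        base = 6 * nodes                          # (n,2)
        for a in range(2):
            for bb in range(2):
                block = Hloc[:, 6 * a : 6 * a + 6, 6 * bb : 6 * bb + 6]
                r = (base[:, a][:, None, None] + np.arange(6)[None, :, None])
                cc = (base[:, bb][:, None, None] + np.arange(6)[None, None, :])
                rows.append(np.broadcast_to(r, block.shape).ravel())
                cols.append(np.broadcast_to(cc, block.shape).ravel())
                vals.append(block.ravel())

    b = model.beams
    if len(b):
        Hloc = np.zeros((len(b), 12, 12))
        for k in range(12):
            node_sel, dof = (b.i, k) if k < 6 else (b.j, k - 6)
            out = []
            for sgn in (+1.0, -1.0):
                xs, Rs = _perturbed(x, R, node_sel, dof % 6, sgn * h)
                if k < 6:
                    _, G = _beam_terms_raw(b, xs, Rs, x[b.j], R[b.j])
                else:
                    _, G = _beam_terms_raw(b, x[b.i], R[b.i], xs, Rs)
                out.append(G)
            Hloc[:, :, k] = (out[0] - out[1]) / (2 * h)
        scatter(b.i, b.j, Hloc)

    c = model.connectors
    if len(c):
        weight = np.where(c.category == "constraint", w_constraint, 1.0)
        Hloc = np.zeros((len(c), 12, 12))
        for k in range(12):
            node_sel = c.i if k < 6 else c.j
            out = []
            for sgn in (+1.0, -1.0):
                xs, Rs = _perturbed(x, R, node_sel, k % 6, sgn * h)
                if k < 6:
                    _, G = _connector_terms_raw(c, xs, Rs, x[c.j], R[c.j], weight)
                else:
                    _, G = _connector_terms_raw(c, x[c.i], R[c.i], xs, Rs, weight)
                out.append(G)
            Hloc[:, :, k] = (out[0] - out[1]) / (2 * h)
        scatter(c.i, c.j, Hloc)

    for aw in model.axis_welds:
        # small dense FD on the single-element gradient
        Hloc = np.zeros((1, 12, 12))
        sub = FEModel(
            x0=model.x0, R0=model.R0,
            beams=BeamArrays(*[np.zeros(0)] * 8, is_nick=np.zeros(0, dtype=bool)),
            connectors=ConnectorArrays(
                i=np.zeros(0, dtype=int), j=np.zeros(0, dtype=int),
                c_rest=np.zeros((0, 3)), Q_rest=np.zeros((0, 3, 3)),
                axes=np.zeros((0, 3, 3)), kr=np.zeros((0, 3)), ktr=np.zeros(0),
                category=np.array([], dtype=object),
            ),
            axis_welds=[aw], params=model.params, n_bp_nodes=model.n_bp_nodes,
        )
        for k in range(12):
            node = aw.i if k < 6 else aw.j
            out = []
            for sgn in (+1.0, -1.0):
                xs = x.copy(); Rs = R.copy()
                xp, Rp = _perturbed(x, R, np.array([node]), k % 6, sgn * h)
                xs[node], Rs[node] = xp[0], Rp[0]
                _, G = _axis_weld_terms(sub, xs, Rs, w_constraint)
                out.append(G[0])
            Hloc[0, :, k] = (out[0] - out[1]) / (2 * h)
        scatter(np.array([aw.i]), np.array([aw.j]), Hloc)

    nd = model.ndof
    if not rows:
        return sparse.csr_matrix((nd, nd))
    H = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nd, nd),
    ).tocsr()
    return 0.5 * (H + H.T)


def constraint_gaps(model: FEModel, x, R):
    """(position gap nm, orientation gap rad) per end-pairing constraint."""
    c = model.connectors
    mask = model.constraint_mask()
    gaps_x, gaps_r = [], []
    for k in np.nonzero(mask)[0]:
        Ri, Rj = R[c.i[k]], R[c.j[k]]
        d = x[c.j[k]] - x[c.i[k]]
        terr = Ri.T @ d - c.c_rest[k]
        phi = geo.log_so3(c.Q_rest[k].T @ (Ri.T @ Rj))
        gaps_x.append(float(np.linalg.norm(terr)))
        gaps_r.append(float(np.linalg.norm(phi)))
    for aw in model.axis_welds:
        ai, aj = R[aw.i][:, 2], R[aw.j][:, 2]
        d = x[aw.j] - x[aw.i]
        gaps_x.append(float(np.linalg.norm(d - aw.L0 * 0.5 * (ai + aj))))
        gaps_r.append(float(np.arccos(np.clip(np.dot(ai, aj), -1, 1))))
    return np.array(gaps_x), np.array(gaps_r)


# -- model construction -------------------------------------------------------


def _step_pose(x, R, s, L0, phi0):
    """Advance a bp pose by ``s`` helical steps about its own e3."""
    Rz = geo.exp_so3(np.array([0.0, 0.0, s * phi0]))
    return x + s * L0 * R[:, 2], R @ Rz


_FLIP = geo.exp_so3(np.array([np.pi, 0.0, 0.0]))  # e3 -> -e3, keeps e1


def drawn_bp_poses(design: Design, topology: Topology):
    """Reconstruct bp frames from drawn nucleotide coordinates.

    Position = midpoint of the paired nucleotides; e3 follows the duplex
    bp-order direction; e1 is the in-plane direction from the bp centre to
    the reference-strand nucleotide (the drawn roll).
    """
    poses = {}
    for di, dup in enumerate(topology.duplexes):
        centers = np.array([
            0.5 * (np.asarray(design.nucleotides[a].xyz) + np.asarray(design.nucleotides[b].xyz))
            for a, b in dup.bp_list
        ])
        n = len(centers)
        for p in range(n):
            if dup.closed:
                nxt, prv = centers[(p + 1) % n], centers[(p - 1) % n]
            else:
                nxt = centers[min(p + 1, n - 1)]
                prv = centers[max(p - 1, 0)]
            e3 = nxt - prv
            nrm = np.linalg.norm(e3)
            e3 = e3 / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
            ref = np.asarray(design.nucleotides[dup.bp_list[p][0]].xyz) - centers[p]
            R = geo.orthonormal_frame(e3, hint=ref if np.linalg.norm(ref) > 1e-9 else None)
            poses[(di, p)] = (centers[p], R)
    return poses


def build_model(
    topology: Topology,
    design: Design,
    params: ElasticParams | None = None,
    mode: str = "exploded",
) -> FEModel:
    """Assemble the finite element model from a parsed design.

    ``mode='exploded'`` (default, the structure-prediction configuration):
    every junction is instantiated in its exact ground-state geometry at the
    pose fitted from the designed coordinates, arms are regenerated as
    straight stress-free B-form helices carrying half of each connecting
    duplex, and one end-pairing constraint per connectivity entry welds the
    facing duplex ends during the solve.  Duplexes not attached to any
    junction keep their drawn coordinates.

    ``mode='as_drawn'``: all bp poses are taken from the drawn coordinates
    and no end-pairing constraints are generated (the drawing must be
    topologically continuous).
    """
    if params is None:
        params = ElasticParams()
    if mode not in ("exploded", "as_drawn"):
        raise ValueError(f"unknown build mode {mode!r}")
    for j in topology.junctions:
        if j.isomer is None:
            raise ValueError(f"junction {j.id} has no isomer state")

    L0 = params.axial_rise
    phi0 = np.radians(params.rest_twist_deg)
    drawn = drawn_bp_poses(design, topology)
    poses: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    helix_poses: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}  # (junction, helix)
    stack_conn: list[tuple] = []   # (hnode_key, bpkey, flip) half-step stacking links
    junction_pairs: list[tuple[tuple[int, int], tuple[int, int]]] = []

    attached = topology.attachments
    weld_steps: dict[int, int] = {}
    if mode == "exploded":
        for _a, _b, dref, nbp in topology.connectivity:
            # split near the middle, but never at a nick: the weld is
            # stiffened to rigidity and must not override reduced nick moduli
            s0 = (nbp + 1) // 2 - 1
            nicks = set(topology.duplexes[dref].nicks)
            for off in (0, 1, -1, 2, -2, 3, -3):
                if s0 + off not in nicks and 0 <= s0 + off < nbp - 1:
                    weld_steps[dref] = s0 + off
                    break
            else:
                weld_steps[dref] = s0

    if topology.junctions:
        (cA, RA0), (cB, RB0) = junction_ground_geometry(params)
        for j in topology.junctions:
            pair_nodes = []
            drawn_fit = []
            for hk, (p, q) in enumerate(j.stacked_pairs()):
                ap, aq = j.arms[p], j.arms[q]
                bp_p = topology.duplexes[ap.duplex].end_bp(ap.end)
                bp_q = topology.duplexes[aq.duplex].end_bp(aq.end)
                ctr_p = _bp_center_xyz(design, bp_p)
                ctr_q = _bp_center_xyz(design, bp_q)
                pos = 0.5 * (ctr_p + ctr_q)
                through = ctr_q - ctr_p
                nt = np.linalg.norm(through)
                through = through / nt if nt > 1e-9 else np.array([0, 0, 1.0])
                drawn_fit.append((pos, through))
                pair_nodes.append(((p, q), bp_p, bp_q))
            posA, thrA = drawn_fit[0]
            posB, thrB = drawn_fit[1]
            n3 = posB - posA
            nn = np.linalg.norm(n3)
            n3 = n3 / nn if nn > 1e-9 else np.array([0, 0, 1.0])
            RA_drawn = _helix_frame(thrA, n3)
            RB_drawn = _helix_frame(thrB, -n3)
            if mode == "exploded":
                # place the junction in its exact ground-state geometry at the
                # centre pose averaging the two drawn helix fits
                T1 = (posA - RA_drawn @ RA0.T @ cA, RA_drawn @ RA0.T)
                T2 = (posB - RB_drawn @ RB0.T @ cB, RB_drawn @ RB0.T)
                Tc = (0.5 * (T1[0] + T2[0]), geo.midpoint_rotation(T1[1], T2[1]))
                hA = (Tc[0] + Tc[1] @ cA, geo.normalize_rotations(Tc[1] @ RA0))
                hB = (Tc[0] + Tc[1] @ cB, geo.normalize_rotations(Tc[1] @ RB0))
            else:
                # fit helix-node poses from the drawn flank bp frames (roll
                # included), so the drawn crossover register strains the
                # junction spring rather than the stacking steps
                hA = _helix_fit_from_drawn(drawn, topology, j, pair_nodes[0][0], L0, phi0)
                hB = _helix_fit_from_drawn(drawn, topology, j, pair_nodes[1][0], L0, phi0)
            helix_poses[(j.id, 0)] = hA
            helix_poses[(j.id, 1)] = hB
            junction_pairs.append(((j.id, 0), (j.id, 1)))
            for hk, ((p, q), bp_p, bp_q) in enumerate(pair_nodes):
                hx, hR = helix_poses[(j.id, hk)]
                for arm_idx, sgn in ((p, -1.0), (q, +1.0)):
                    arm = j.arms[arm_idx]
                    along = (arm.end == 0) if sgn > 0 else (arm.end == 1)
                    if mode == "exploded":
                        _generate_arm(
                            topology, poses, arm, hx, hR, sgn, L0, phi0,
                            attached, weld_steps,
                        )
                    stack_conn.append(
                        ((j.id, hk), _flank_key(topology, arm), sgn, not along)
                    )

    # duplexes not reached by arm regeneration keep drawn poses
    for di, dup in enumerate(topology.duplexes):
        for p in range(dup.length_bp):
            poses.setdefault((di, p), drawn[(di, p)])

    # ---- node numbering: bp nodes first (duplex order), aux helix nodes after
    bp_node: dict[tuple[int, int], int] = {}
    node_bp: list[tuple[int, int] | None] = []
    xs, Rs = [], []
    for di, dup in enumerate(topology.duplexes):
        for p in range(dup.length_bp):
            bp_node[(di, p)] = len(xs)
            node_bp.append((di, p))
            xv, Rv = poses[(di, p)]
            xs.append(xv)
            Rs.append(Rv)
    n_bp_nodes = len(xs)
    helix_node_idx: dict[tuple[int, int], int] = {}
    for key, (xv, Rv) in helix_poses.items():
        helix_node_idx[key] = len(xs)
        node_bp.append(None)
        xs.append(xv)
        Rs.append(Rv)
    x0 = np.array(xs).reshape(-1, 3)
    R0 = np.array(Rs).reshape(-1, 3, 3)

    # ---- beams within duplexes (weld steps of split duplexes excluded)
    EA, EI, GJ, _, _ = beam_properties(params)
    EIn = params.bend_modulus * params.nick_factor_b
    GJn = params.twist_modulus * params.nick_factor_b
    ksh = params.shear_factor * EA / L0
    bi, bj, bEA, bEI, bGJ, bL0, bphi, bksh, bnick = ([] for _ in range(9))
    for di, dup in enumerate(topology.duplexes):
        nick_set = set(dup.nicks)
        nsteps = dup.length_bp if dup.closed else dup.length_bp - 1
        for s in range(nsteps):
            if weld_steps.get(di) == s:
                continue
            i_n = bp_node[(di, s)]
            j_n = bp_node[(di, (s + 1) % dup.length_bp)]
            nick = s in nick_set
            bi.append(i_n); bj.append(j_n)
            bEA.append(EA)
            bEI.append(EIn if nick else EI)
            bGJ.append(GJn if nick else GJ)
            bL0.append(L0); bphi.append(phi0); bksh.append(ksh)
            bnick.append(nick)
    beams = BeamArrays(
        i=np.array(bi, dtype=int), j=np.array(bj, dtype=int),
        EA=np.array(bEA), EI=np.array(bEI), GJ=np.array(bGJ),
        L0=np.array(bL0), phi0=np.array(bphi), ksh=np.array(bksh),
        is_nick=np.array(bnick, dtype=bool),
    )

    # ---- connectors: junction springs, stacking half-steps, weld constraints
    ci, cj, cc, cQ, cax, ckr, cktr, ccat = ([] for _ in range(8))

    def add_connector(i_n, j_n, c_rest, Q_rest, axes, kr, ktr, cat):
        ci.append(i_n); cj.append(j_n); cc.append(c_rest); cQ.append(Q_rest)
        cax.append(axes); ckr.append(kr); cktr.append(ktr); ccat.append(cat)

    jc_rest, jQ_rest, jaxes, jkr, jktr = junction_rest_connector(params)
    for (keyA, keyB) in junction_pairs:
        add_connector(
            helix_node_idx[keyA], helix_node_idx[keyB],
            jc_rest, jQ_rest, jaxes, jkr, jktr, "junction",
        )
    # stacking half-steps: rest transform is the ideal half B-form step from
    # the helix node to the flanking bp (with a frame flip when the bp's
    # duplex runs against the helix through-direction)
    Lh = 0.5 * L0
    kb_h = EI / Lh
    kt_h = GJ / Lh
    ktr_h = EA / Lh
    for hkey, bpkey, sgn, flip in stack_conn:
        i_n = helix_node_idx[hkey]
        j_n = bp_node[bpkey]
        c_rest = np.array([0.0, 0.0, sgn * Lh])
        Q_rest = geo.exp_so3(np.array([0.0, 0.0, sgn * 0.5 * phi0]))
        if flip:
            Q_rest = Q_rest @ _FLIP
        axes = np.eye(3)  # j-local axes: bend about e1/e2, twist about helix e3
        add_connector(i_n, j_n, c_rest, Q_rest, axes,
                      np.array([kb_h, kb_h, kt_h]), ktr_h, "stacking")
    # end-pairing welds
    step_c = np.array([0.0, 0.0, L0])
    step_Q = geo.exp_so3(np.array([0.0, 0.0, phi0]))
    for di, s in weld_steps.items():
        dup = topology.duplexes[di]
        i_n = bp_node[(di, s)]
        j_n = bp_node[(di, s + 1)]
        nick = s in set(dup.nicks)
        kbend = (EIn if nick else EI) / L0
        ktwist = (GJn if nick else GJ) / L0
        add_connector(i_n, j_n, step_c, step_Q, np.eye(3),
                      np.array([kbend, kbend, ktwist]), EA / L0, "constraint")

    connectors = ConnectorArrays(
        i=np.array(ci, dtype=int), j=np.array(cj, dtype=int),
        c_rest=np.array(cc).reshape(-1, 3), Q_rest=np.array(cQ).reshape(-1, 3, 3),
        axes=np.array(cax).reshape(-1, 3, 3), kr=np.array(ckr).reshape(-1, 3),
        ktr=np.array(cktr), category=np.array(ccat, dtype=object),
    )

    counts = {
        "n_bp_nodes": n_bp_nodes,
        "n_bp_step_beams": len(beams),
        "n_junctions": len(topology.junctions),
        "n_constraints": int(np.sum(connectors.category == "constraint")),
        "n_aux_helix_nodes": len(helix_node_idx),
        "n_stacking_connectors": int(np.sum(connectors.category == "stacking")),
    }
    log.info("FE model: %s", counts)
    return FEModel(
        x0=x0, R0=R0, beams=beams, connectors=connectors, axis_welds=[],
        params=params, n_bp_nodes=n_bp_nodes, bp_node=bp_node, node_bp=node_bp,
        helix_nodes={
            j.id: (helix_node_idx[(j.id, 0)], helix_node_idx[(j.id, 1)])
            for j in topology.junctions
        } if helix_node_idx else {},
        counts=counts,
    )


def close_loop(model: FEModel, node_i: int, node_j: int, free_twist: bool = True) -> None:
    """Add an end-pairing constraint closing node_i -> node_j into a loop.

    ``free_twist=True`` uses an axis-alignment weld that leaves the roll
    about the helical axis unconstrained (a nick with released torsion);
    otherwise a full 6-DOF weld with the ideal B-form step as rest pose is
    appended.  The constraint participates in the solver's load ramp.
    """
    p = model.params
    L0 = p.axial_rise
    if free_twist:
        model.axis_welds.append(
            AxisWeld(i=node_i, j=node_j, L0=L0,
                     ktr=p.stretch_modulus / L0, kr=p.bend_modulus / L0)
        )
        return
    c = model.connectors
    kb = p.bend_modulus / L0
    kt = p.twist_modulus / L0
    model.connectors = ConnectorArrays(
        i=np.append(c.i, node_i), j=np.append(c.j, node_j),
        c_rest=np.vstack([c.c_rest, [0.0, 0.0, L0]]),
        Q_rest=np.concatenate(
            [c.Q_rest, geo.exp_so3(np.array([[0.0, 0.0, np.radians(p.rest_twist_deg)]]))]
        ),
        axes=np.concatenate([c.axes, np.eye(3)[None]]),
        kr=np.vstack([c.kr, [kb, kb, kt]]),
        ktr=np.append(c.ktr, p.stretch_modulus / L0),
        category=np.append(c.category, "constraint"),
    )


def _bp_center_xyz(design: Design, bp) -> np.ndarray:
    a, b = bp
    return 0.5 * (np.asarray(design.nucleotides[a].xyz) + np.asarray(design.nucleotides[b].xyz))


def _helix_frame(through: np.ndarray, toward_partner: np.ndarray) -> np.ndarray:
    """Helix-node frame: e3 = through direction, e1 -> partner helix."""
    return geo.orthonormal_frame(through, hint=toward_partner)


def _helix_fit_from_drawn(drawn, topology: Topology, j, pair, L0, phi0):
    """Helix-node pose estimated from the two drawn flanking bp poses."""
    p, q = pair
    ests = []
    for arm_idx, sgn in ((p, -1.0), (q, +1.0)):
        arm = j.arms[arm_idx]
        x, Rst = drawn[_flank_key(topology, arm)]
        along = (arm.end == 0) if sgn > 0 else (arm.end == 1)
        Rthr = Rst if along else Rst @ _FLIP
        ests.append(_step_pose(x, Rthr, -sgn * 0.5, L0, phi0))
    xm = 0.5 * (ests[0][0] + ests[1][0])
    Rm = geo.normalize_rotations(geo.midpoint_rotation(ests[0][1], ests[1][1]))
    return (xm, Rm)


def _flank_key(topology: Topology, arm) -> tuple[int, int]:
    dup = topology.duplexes[arm.duplex]
    return (arm.duplex, 0 if arm.end == 0 else dup.length_bp - 1)


def _generate_arm(topology, poses, arm, hx, hR, sgn, L0, phi0, attached, weld_steps):
    """Regenerate the bps this junction arm owns as straight B-form helix.

    ``sgn`` +1: the arm lies ahead of the helix node along its through
    direction (first stacked-pair member behind, second ahead).  The arm owns
    its duplex up to the weld split (the whole duplex when the far end is
    free).
    """
    dup = topology.duplexes[arm.duplex]
    n = dup.length_bp
    far_end = 1 - arm.end
    far_attached = attached[arm.duplex][far_end] is not None
    if far_attached:
        split = weld_steps.get(arm.duplex, (n + 1) // 2 - 1) + 1
        own = split if arm.end == 0 else n - split
    else:
        own = n
    # duplex bp-order direction vs helix through direction: ahead-side arms
    # (sgn>0) extend along the through direction, behind-side arms against it
    along_duplex = (arm.end == 0) if sgn > 0 else (arm.end == 1)
    # walk outward from the flank bp
    if arm.end == 0:
        positions = range(0, own)
    else:
        positions = range(n - 1, n - 1 - own, -1)
    for k, p in enumerate(positions):
        xk, Rk = _step_pose(hx, hR, sgn * (0.5 + k), L0, phi0)
        if not along_duplex:
            Rk = Rk @ _FLIP
        poses[(arm.duplex, p)] = (xk, Rk)
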