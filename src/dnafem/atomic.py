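"""All-atom model generation from equilibrium basepair frames.

Standard reference atomic structures for the four Watson-Crick basepairs are
assembled at import-support time from the ideal nucleotide geometries in
biotite's bundled chemical component dictionary: each base is superimposed
into an idealized Watson-Crick pairing frame (C1'-C1' distance 10.44 A,
glycosidic C1'-N bond subtending 54.5 deg with the C1'-C1' line, basepair
pseudo-dyad along the frame x-axis), bringing its sugar and phosphate along
rigidly.  Each equilibrium bp node pose then places one reference bp; the
crossover backbone adjustment afterwards rotates the phosphate/sugar atoms
of the crossing-strand nucleotides at every four-way junction by 45 deg
about the glycosidic C1'->N1 axis (N9 for purines, whose glycosidic
nitrogen is N9; config-overridable), following free-junction crystal
geometry.

Coordinates are in Angstrom throughout this module (nm * 10 at the
solution/atomic interface).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .design import NONE_ID, Design
from .mechanics import FEModel
from .solver import Solution
from .topology import Topology

log = logging.getLogger(__name__)

PURINES = {"A": "N9", "G": "N9"}
GLYCOSIDIC = {"A": "N9", "G": "N9", "T": "N1", "C": "N1"}
WC_EDGE = {"A": "N1", "G": "N1", "T": "N3", "C": "N3"}
CCD_NAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}

C1C1_DIST = 10.44       # A, C1'-C1' across a Watson-Crick pair
LAMBDA_DEG = 54.5       # deg, angle C1'->N vs C1'->C1'
BACKBONE_SUGAR = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'"]

_CHAIN_LABELS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


@dataclass
class AtomicModel:
    """Flat atom table grouped by (chain, residue, atom name)."""

    chain: np.ndarray      # per-atom chain label (str)
    resid: np.ndarray      # per-atom residue number, 1-based along each strand
    resname: np.ndarray    # 'DA'/'DT'/'DG'/'DC'
    name: np.ndarray       # atom name
    element: np.ndarray
    xyz: np.ndarray        # (n, 3) Angstrom
    nucleotide_id: np.ndarray   # design nucleotide id per atom
    bfactor: np.ndarray | None = None
    flags: dict = field(default_factory=dict)   # e.g. unpaired / adjusted residues

    def __len__(self) -> int:
        return len(self.name)

    def atom_keys(self) -> list[tuple]:
        return list(zip(self.chain.tolist(), self.resid.tolist(), self.name.tolist()))

    def residue_atoms(self, nucleotide_id: int) -> np.ndarray:
        return np.nonzero(self.nucleotide_id == nucleotide_id)[0]


@lru_cache(maxsize=None)
def _ideal_residue(base: str):
    """Heavy atoms of the CCD ideal nucleotide, minus the 5'-terminal OP3."""
    import biotite.structure.info as info

    res = info.residue(CCD_NAME[base])
    keep = (res.element != "H") & (res.atom_name != "OP3")
    res = res[keep]
    return res.atom_name.tolist(), res.element.tolist(), res.coord.astype(float)


def _base_ring_atoms(base: str) -> list[str]:
    if base in PURINES:
        return ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"]
    return ["N1", "C2", "N3", "C4", "C5", "C6"]


@lru_cache(maxsize=None)
def reference_nucleotide(base: str, strand: str = "ref"):
    """Ideal nucleotide posed in the canonical bp frame.

    The frame: bp centre at the origin, helical axis +z, reference-strand
    C1' on the +y side; the complementary strand is generated by the
    pseudo-dyad (180 deg rotation about x).  Returns (names, elements,
    coords (n,3) A).
    """
    names, elements, X = _ideal_residue(base)
    idx = {n: i for i, n in enumerate(names)}
    gly = GLYCOSIDIC[base]
    c1 = X[idx["C1'"]]
    n_g = X[idx[gly]]
    ring = [idx[a] for a in _base_ring_atoms(base)]
    ring_X = X[ring]
    # base plane normal from the ring atoms
    cen = ring_X.mean(axis=0)
    normal = np.linalg.svd(ring_X - cen)[2][2]

    lam = np.radians(LAMBDA_DEG)
    y1 = C1C1_DIST / 2.0
    c1_t = np.array([0.0, y1, 0.0])
    # glycosidic bond points toward the minor-groove side (-x)
    bond = np.linalg.norm(n_g - c1)
    d_t = np.array([-np.sin(lam), -np.cos(lam), 0.0])
    n_t = c1_t + bond * d_t

    # rigid transform: N -> n_t, C1' direction -> d_t (reversed), plane -> z=0
    # choose the plane-normal sign placing the WC-edge atom nearest the origin
    best = None
    for sgn in (+1.0, -1.0):
        R = _frame_map(n_g, c1, normal * sgn, n_t, c1_t)
        Xt = (X - n_g) @ R.T + n_t
        wc = Xt[idx[WC_EDGE[base]]]
        score = np.linalg.norm(wc[:2])
        if best is None or score < best[0]:
            best = (score, Xt)
    Xt = best[1]
    if strand == "comp":
        Xt = Xt * np.array([1.0, -1.0, -1.0])   # dyad flip about x
    return names, elements, Xt


def _frame_map(origin, p1, normal, origin_t, p1_t):
    """Rotation taking (origin->p1, normal) onto (origin_t->p1_t, +z)."""
    a1 = p1 - origin
    a1 = a1 / np.linalg.norm(a1)
    a3 = normal / np.linalg.norm(normal)
    a3 = a3 - np.dot(a3, a1) * a1
    a3 /= np.linalg.norm(a3)
    a2 = np.cross(a3, a1)
    b1 = p1_t - origin_t
    b1 = b1 / np.linalg.norm(b1)
    b3 = np.array([0.0, 0.0, 1.0])
    b3 = b3 - np.dot(b3, b1) * b1
    b3 /= np.linalg.norm(b3)
    b2 = np.cross(b3, b1)
    A = np.stack([a1, a2, a3], axis=1)
    B = np.stack([b1, b2, b3], axis=1)
    return B @ A.T


# node-frame convention: e1 points to the reference nucleotide (template +y),
# e3 is the helical axis (template +z); e2 completes the right-handed triad
_TEMPLATE_TO_NODE = np.array(
    [[0.0, 1.0, 0.0],
     [-1.0, 0.0, 0.0],
     [0.0, 0.0, 1.0]]
).T


def generate_atoms(
    solution: Solution,
    design: Design,
    model: FEModel,
    topology: Topology,
    bfactor_rmsf: np.ndarray | None = None,
) -> AtomicModel:
    """Place reference bp atoms at every equilibrium bp node pose.

    Residue and chain bookkeeping follows the design's strand decomposition
    (one chain per strand, residues numbered 1-based 5'->3').  Unpaired
    nucleotides are placed from the nearest paired neighbour's frame,
    extrapolated along the backbone, and flagged in ``model.flags``.
    ``bfactor_rmsf`` (nm, per bp node) is written as B-factors in Angstrom.
    """
    strands = design.strands()
    chain_of: dict[int, str] = {}
    resid_of: dict[int, int] = {}
    rollover = len(strands) > len(_CHAIN_LABELS)
    for si, chain in enumerate(strands):
        label = _CHAIN_LABELS[si % len(_CHAIN_LABELS)]
        for pos, nid in enumerate(chain):
            chain_of[nid] = label
            resid_of[nid] = pos + 1
    if rollover:
        log.warning("more than %d strands: chain labels roll over deterministically",
                    len(_CHAIN_LABELS))

    # map nucleotide -> (node, role)
    node_of: dict[int, tuple[int, str]] = {}
    for (di, p), node in model.bp_node.items():
        ref, comp = topology.duplexes[di].bp_list[p]
        node_of[ref] = (node, "ref")
        node_of[comp] = (node, "comp")

    cols = {k: [] for k in
            ("chain", "resid", "resname", "name", "element", "xyz", "nid", "bf")}
    unpaired = []
    for nid in sorted(design.nucleotides):
        nt = design.nucleotides[nid]
        if nt.base not in CCD_NAME:
            raise ValueError(f"nucleotide {nid}: missing/invalid base identity")
        if nid in node_of:
            node, role = node_of[nid]
        else:
            unpaired.append(nid)
            anchor = _nearest_paired(design, node_of, nid)
            if anchor is None:
                raise ValueError(f"unpaired nucleotide {nid} has no paired neighbour")
            node, role = anchor
        x = solution.x[node] * 10.0          # nm -> A
        R = solution.R[node] @ _TEMPLATE_TO_NODE
        names, elements, Xt = reference_nucleotide(nt.base, role if nid in node_of else "ref")
        Xw = Xt @ R.T + x
        n = len(names)
        cols["chain"] += [chain_of[nid]] * n
        cols["resid"] += [resid_of[nid]] * n
        cols["resname"] += [CCD_NAME[nt.base]] * n
        cols["name"] += names
        cols["element"] += elements
        cols["xyz"].append(Xw)
        cols["nid"] += [nid] * n
        bf = 0.0
        if bfactor_rmsf is not None and node < len(bfactor_rmsf):
            bf = float(bfactor_rmsf[node] * 10.0)
        cols["bf"] += [bf] * n

    am = AtomicModel(
        chain=np.array(cols["chain"]),
        resid=np.array(cols["resid"], dtype=int),
        resname=np.array(cols["resname"]),
        name=np.array(cols["name"]),
        element=np.array(cols["element"]),
        xyz=np.vstack(cols["xyz"]),
        nucleotide_id=np.array(cols["nid"], dtype=int),
        bfactor=np.array(cols["bf"]) if bfactor_rmsf is not None else None,
        flags={"unpaired": unpaired, "crossover_adjusted": []},
    )
    log.info("atomic model: %d atoms, %d chains, %d unpaired nucleotides",
             len(am), len(set(am.chain.tolist())), len(unpaired))
    return am


def _nearest_paired(design, node_of, nid):
    seen = set()
    frontier = [nid]
    while frontier:
        cur = frontier.pop(0)
        for nxt in (design.nucleotides[cur].neighbor5, design.nucleotides[cur].neighbor3):
            if nxt == NONE_ID or nxt in seen or nxt not in design.nucleotides:
                continue
            if nxt in node_of:
                return node_of[nxt]
            seen.add(nxt)
            frontier.append(nxt)
    return None


def adjust_crossover_backbone(
    am: AtomicModel,
    topology: Topology,
    design: Design,
    angle_deg: float = 45.0,
    sign: int = 1,
) -> AtomicModel:
    """Rotate crossover phosphate/sugar atoms about the C1'->N glycosidic axis.

    At every four-way junction, both nucleotides flanking each crossing-strand
    (branch-point) backbone link have their phosphate and sugar atoms rotated
    by ``sign * angle_deg`` about the vector from C1' to the glycosidic
    nitrogen (N1, or N9 for purines).  Base atoms are untouched; C1' lies on
    the axis.  The adjustment is applied once per residue (re-application is
    refused via the ``crossover_adjusted`` flag).
    """
    moved = set(am.flags.get("crossover_adjusted", []))
    theta = np.radians(angle_deg) * sign
    targets = []
    for j in topology.junctions:
        for a, b in j.crossing_links():
            targets += [a, b]
    for nid in targets:
        if nid in moved:
            raise ValueError(f"crossover adjustment already applied to nucleotide {nid}")
        idxs = am.residue_atoms(nid)
        if len(idxs) == 0:
            continue
        names = am.name[idxs]
        sel_c1 = idxs[names == "C1'"]
        base = design.nucleotides[nid].base
        sel_n = idxs[names == GLYCOSIDIC[base]]
        if len(sel_c1) == 0 or len(sel_n) == 0:
            raise ValueError(f"nucleotide {nid} lacks C1' or glycosidic N for the axis")
        p0 = am.xyz[sel_c1[0]]
        axis = am.xyz[sel_n[0]] - p0
        axis = axis / np.linalg.norm(axis)
        K = np.array([
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ])
        R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        move = idxs[np.isin(names, BACKBONE_SUGAR)]
        am.xyz[move] = (am.xyz[move] - p0) @ R.T + p0
        moved.add(nid)
    am.flags["crossover_adjusted"] = sorted(moved)
    log.info("crossover adjustment: rotated backbone of %d nucleotides by %g deg",
             len(targets), sign * angle_deg)
    return am


# -- PDB I/O ------------------------------------------------------------------


def write_pdb(am: AtomicModel, path: str | Path) -> None:
    """Write ATOM/TER/END records (one chain per strand, coordinates in A)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(am)
    arr = struc.AtomArray(n)
    arr.coord = am.xyz.astype(np.float32)
    arr.chain_id = am.chain
    arr.res_id = am.resid
    arr.res_name = am.resname
    arr.atom_name = am.name
    arr.element = am.element
    arr.hetero = np.zeros(n, dtype=bool)
    if am.bfactor is not None:
        arr.set_annotation("b_factor", am.bfactor.astype(float))
    arr.set_annotation("occupancy", np.ones(n))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
    log.info("wrote %d atoms to %s", n, path)


def read_pdb(path: str | Path) -> AtomicModel:
    """Read a PDB file into an AtomicModel (heavy atoms, ATOM records)."""
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(str(path)).get_structure(model=1)
    arr = arr[arr.element != "H"]
    return AtomicModel(
        chain=np.array(arr.chain_id),
        resid=np.array(arr.res_id, dtype=int),
        resname=np.array(arr.res_name),
        name=np.array(arr.atom_name),
        element=np.array(arr.element),
        xyz=np.array(arr.coord, dtype=float),
        nucleotide_id=-np.ones(arr.array_length(), dtype=int),
    )
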