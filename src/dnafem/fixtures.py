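"""Programmatic design generators for every studied assembly family.

All generators are deterministic (sequences follow a fixed cyclic ACGT
assignment; mechanics in this model is sequence-independent) and produce
designs that pass :func:`dnafem.design.validate_design` with zero
violations.  Geometry conventions: coordinates in nm; a basepair drawn at
pose ``(x, R)`` places its reference-strand nucleotide at ``x + r*R@e1`` and
the complementary nucleotide at ``x - r*R@e1`` with ``r = 0.9`` nm.

Junction strand routing follows the canonical antiparallel stacked-X motif:
at every four-way junction the two "top" strands of the stacked helices run
through continuously while the two complementary strands exchange helices
(the crossing strands / branch points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .design import Design, Nucleotide, validate_design
from .mechanics import ElasticParams, junction_ground_geometry, _step_pose

BP_RADIUS = 0.9  # nm, drawn nucleotide offset from the helix axis
_BASES = "ACGT"
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _seq(n: int, start: int = 0) -> str:
    return "".join(_BASES[(start + i) % 4] for i in range(n))


@dataclass
class RingSpec:
    """Concentric-ring design family (closed circular duplex per layer)."""

    circumferences_bp: list[int] = field(default_factory=lambda: [100, 150, 200, 250])
    crossovers_per_pair: int = 5
    spacing: float = 2.5          # nm, designed interlayer spacing
    rise: float = 0.34

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.circumferences_bp):
            raise ValueError("circumferences must be positive")
        if self.crossovers_per_pair < 0:
            raise ValueError("crossover count must be >= 0")


@dataclass
class LatticeSpec:
    """N x M four-way-junction tile ribbon with arm lengths (n_x, n_y)."""

    n_x: int = 21
    n_y: int = 21
    repeats_x: int = 2
    repeats_y: int = 2
    stub_bp: int = 8
    rise: float = 0.34
    layer_gap: float = 1.85       # nm between the x- and y-helix layers
    nick_arms: bool = True        # sticky-end tile joints: nick mid-arm

    def __post_init__(self) -> None:
        if self.n_x < 8 or self.n_y < 8:
            raise ValueError("arm lengths n_x, n_y must be >= 8 bp")
        if self.repeats_x < 1 or self.repeats_y < 1:
            raise ValueError("repeat counts must be >= 1")
        if self.stub_bp < 4:
            raise ValueError("boundary stubs must be >= 4 bp")


@dataclass
class TensegritySpec:
    """Three mutually orthogonal duplex-strut families woven by junctions.

    One cell contributes one strut period per axis and three four-way
    junctions (x-y, y-z, z-x).  Multi-cell designs merge collinear struts
    into continuous duplexes (the inter-cell connections).
    """

    cells: tuple[int, int, int] = (1, 1, 1)
    strut_period_bp: int = 21
    stub_bp: int = 6
    junction_site_1: int = 13     # bp offset of the first junction in a period
    junction_site_2: int = 8
    rise: float = 0.34

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.cells):
            raise ValueError("cell counts must be >= 1")
        if not 2 <= self.junction_site_2 < self.junction_site_1 <= self.strut_period_bp - 2:
            raise ValueError("junction sites must be interior and ordered")


class _Builder:
    """Incremental nucleotide/strand assembly with automatic ids."""

    def __init__(self, name: str):
        self.design = Design(name=name)
        self._next = 0

    def new_id(self) -> int:
        i = self._next
        self._next += 1
        return i

    def add_nt(self, nid: int, base: str, xyz) -> None:
        self.design.add(Nucleotide(nid, base, tuple(float(v) for v in xyz)))

    def link(self, five: int, three: int) -> None:
        self.design.nucleotides[five].neighbor3 = three
        self.design.nucleotides[three].neighbor5 = five

    def pair(self, a: int, b: int) -> None:
        self.design.nucleotides[a].pair = b
        self.design.nucleotides[b].pair = a

    def finish(self) -> Design:
        violations = validate_design(self.design)
        if violations:
            raise AssertionError(
                f"generator bug: {len(violations)} violations, first: {violations[0]}"
            )
        self.design.assign_strands()
        return self.design


def _place_bp(builder: _Builder, base: str, x: np.ndarray, R: np.ndarray) -> tuple[int, int]:
    """Create the two nucleotides of one bp; returns (ref_id, comp_id)."""
    a = builder.new_id()
    b = builder.new_id()
    e1 = R[:, 0]
    builder.add_nt(a, base, x + BP_RADIUS * e1)
    builder.add_nt(b, _COMP[base], x - BP_RADIUS * e1)
    builder.pair(a, b)
    return a, b


# -- plain duplexes -----------------------------------------------------------


def make_duplex_design(
    n_bp: int,
    name: str = "duplex",
    nick_steps: tuple[int, ...] = (),
    arc_angle_deg: float = 0.0,
    params: ElasticParams | None = None,
) -> Design:
    """A single double helix of ``n_bp`` basepairs.

    Drawn straight along +z, or (``arc_angle_deg`` > 0) as a planar circular
    arc subtending that angle — useful as a smooth starting shape for
    ring-closure studies.  ``nick_steps`` cuts the complementary strand's
    backbone at the given bp-step indices.
    """
    if params is None:
        params = ElasticParams()
    L0, phi0 = params.axial_rise, np.radians(params.rest_twist_deg)
    b = _Builder(name)
    seq = _seq(n_bp)
    ids = []
    if arc_angle_deg <= 0:
        for k in range(n_bp):
            R = geo.exp_so3(np.array([0.0, 0.0, k * phi0]))
            ids.append(_place_bp(b, seq[k], np.array([0.0, 0.0, k * L0]), R))
    else:
        total = np.radians(arc_angle_deg)
        arc_R = (n_bp - 1) * L0 / total if total > 0 else np.inf
        for k in range(n_bp):
            a = k * total / max(n_bp - 1, 1)
            center = arc_R * np.array([np.cos(a) - 1.0, np.sin(a), 0.0])
            e3 = np.array([-np.sin(a), np.cos(a), 0.0])
            base_frame = geo.orthonormal_frame(e3, hint=np.array([0.0, 0.0, 1.0]))
            R = base_frame @ geo.exp_so3(np.array([0.0, 0.0, k * phi0]))
            ids.append(_place_bp(b, seq[k], center, R))
    for k in range(n_bp - 1):
        b.link(ids[k][0], ids[k + 1][0])
        if k not in nick_steps:
            b.link(ids[k + 1][1], ids[k][1])
    return b.finish()


# -- single four-way junction -------------------------------------------------


def make_single_junction_design(
    arm_bp: int = 10,
    name: str = "junction4",
    params: ElasticParams | None = None,
) -> Design:
    """One immobile four-way junction with four ``arm_bp``-bp arms.

    Drawn directly in the stacked-X ground-state geometry.  Four strands of
    2*arm_bp nt each: two continuous (one per stacked helix) and two
    crossing at the branch points.
    """
    if params is None:
        params = ElasticParams()
    L0, phi0 = params.axial_rise, np.radians(params.rest_twist_deg)
    (xA, RA), (xB, RB) = junction_ground_geometry(params)
    b = _Builder(name)

    def helix_bps(x0, R0):
        """bp ids and poses at through-steps +-(0.5+k), junction-centred."""
        out = {}
        for k in range(arm_bp):
            for sgn in (-1.0, +1.0):
                s = sgn * (0.5 + k)
                x, R = _step_pose(x0, R0, s, L0, phi0)
                out[s] = (x, R)
        return dict(sorted(out.items()))

    helices = []
    for x0, R0 in ((xA, RA), (xB, RB)):
        poses = helix_bps(x0, R0)
        ids = {}
        for i, (s, (x, R)) in enumerate(poses.items()):
            ids[s] = _place_bp(b, _seq(1, i)[0], x, R)
        helices.append((poses, ids))

    steps = sorted(helices[0][0])
    for poses, ids in helices:
        # top strand: continuous 5'->3' along +through
        for s1, s2 in zip(steps[:-1], steps[1:]):
            b.link(ids[s1][0], ids[s2][0])
        # bottom strand: 5'->3' along -through, cut at the junction
        for s1, s2 in zip(steps[:-1], steps[1:]):
            if (s1, s2) != (-0.5, 0.5):
                b.link(ids[s2][1], ids[s1][1])
    idsA, idsB = helices[0][1], helices[1][1]
    # crossing strands: bottom of A (arriving at +0.5) continues on B behind
    b.link(idsA[0.5][1], idsB[-0.5][1])
    b.link(idsB[0.5][1], idsA[-0.5][1])
    return b.finish()


# -- concentric rings ---------------------------------------------------------


def make_ring_design(spec: RingSpec, name: str = "rings") -> Design:
    """Concentric closed circular duplexes joined by four-way junctions.

    Layer ``k`` (circumference ``n_k`` bp) is drawn in the z = 0 plane at
    radius ``r_0 + k * spacing`` with alternating circulation sense, so that
    adjacent layers are locally antiparallel at the crossovers.  Each
    adjacent layer pair is joined by ``crossovers_per_pair`` junctions at
    evenly spaced azimuths, staggered between pairs.
    """
    ns = spec.circumferences_bp
    r0 = ns[0] * spec.rise / (2 * np.pi)
    radii = [r0 + k * spec.spacing for k in range(len(ns))]
    b = _Builder(name)

    ring_ids = []
    for k, (n, r) in enumerate(zip(ns, radii)):
        sense = 1 if k % 2 == 0 else -1
        # closed duplex: drawn roll advances by a quantized closure twist
        # (integer linking number nearest to n/10.5 turns)
        link = round(n / 10.5)
        phi_ring = 2 * np.pi * link / n
        ids = []
        for t in range(n):
            th = sense * 2 * np.pi * t / n
            x = r * np.array([np.cos(th), np.sin(th), 0.0])
            e3 = sense * np.array([-np.sin(th), np.cos(th), 0.0])
            radial = np.array([np.cos(th), np.sin(th), 0.0])
            R = geo.orthonormal_frame(e3, hint=radial) @ geo.exp_so3(
                np.array([0.0, 0.0, t * phi_ring])
            )
            ids.append(_place_bp(b, _seq(1, t)[0], x, R))
        ring_ids.append(ids)

    # backbone links, before crossover rewiring: both strands closed circles
    alpha_next: list[dict[int, int]] = []   # t -> next t along alpha (5'->3')
    for k, n in enumerate(ns):
        alpha_next.append({t: (t + 1) % n for t in range(n)})
    # alpha: continuous circle; beta runs antiparallel (5'->3' against alpha)
    beta_cut: list[set[tuple[int, int]]] = [set() for _ in ns]   # beta links removed
    crossings: list[tuple[int, int]] = []   # extra backbone links (5' id, 3' id)

    for p in range(len(ns) - 1):
        C = spec.crossovers_per_pair
        if C == 0:
            continue
        for c in range(C):
            psi = 2 * np.pi * (c + 0.5 * (p % 2)) / C
            flank = []
            for k in (p, p + 1):
                n = ns[k]
                sense = 1 if k % 2 == 0 else -1
                tstar = (sense * psi * n / (2 * np.pi)) % n
                behind = int(np.floor(tstar)) % n
                ahead = (behind + 1) % n
                flank.append((behind, ahead))
            (bA, aA), (bB, aB) = flank
            # cut beta on both rings at the junction step, then exchange
            beta_cut[p].add((bA, aA))
            beta_cut[p + 1].add((bB, aB))
            crossings.append((ring_ids[p][aA][1], ring_ids[p + 1][bB][1]))
            crossings.append((ring_ids[p + 1][aB][1], ring_ids[p][bA][1]))

    for k, n in enumerate(ns):
        ids = ring_ids[k]
        for t in range(n):
            t2 = (t + 1) % n
            b.link(ids[t][0], ids[t2][0])          # alpha 5'->3'
            if (t, t2) not in beta_cut[k]:
                b.link(ids[t2][1], ids[t][1])      # beta antiparallel
    for five, three in crossings:
        b.link(five, three)
    return b.finish()


# -- tile ribbons -------------------------------------------------------------


def make_lattice_design(spec: LatticeSpec, name: str = "lattice") -> Design:
    """Ribbon of four-way junctions with arm lengths (n_x, n_y).

    The x-helices (one per row) lie in the z = 0 plane and the y-helices
    (one per column) in the z = layer_gap plane; a junction joins them at
    every (column, row) grid point, so the junction count is
    repeats_x * repeats_y.  Boundary arms are ``stub_bp``-bp stubs so every
    junction carries four arms.
    """
    rise = spec.rise
    dx, dy = spec.n_x * rise, spec.n_y * rise
    s = spec.stub_bp
    nrow = 2 * s + (spec.repeats_x - 1) * spec.n_x   # bps per x-line
    ncol = 2 * s + (spec.repeats_y - 1) * spec.n_y
    b = _Builder(name)

    def line_ids(n_bp, origin, e3, e1_hint, phase):
        ids = []
        frame = geo.orthonormal_frame(np.asarray(e3, dtype=float), hint=np.asarray(e1_hint, dtype=float))
        for m in range(n_bp):
            x = np.asarray(origin) + (m - s + 0.5) * rise * frame[:, 2]
            R = frame @ geo.exp_so3(np.array([0.0, 0.0, (m + phase) * np.radians(360.0 / 10.5)]))
            ids.append(_place_bp(b, _seq(1, m)[0], x, R))
        return ids

    # x-helices run +x; y-helices run -y so that the two stacked helices of
    # every junction are locally antiparallel, as in the stacked-X motif
    rows = [
        line_ids(nrow, (0.0, iy * dy, 0.0), (1, 0, 0), (0, 0, 1), 0)
        for iy in range(spec.repeats_y)
    ]
    cols = [
        line_ids(ncol, (ix * dx, (spec.repeats_y - 1) * dy, spec.layer_gap), (0, -1, 0), (0, 0, -1), 0)
        for ix in range(spec.repeats_x)
    ]

    def flanks(idx, n_arm):
        m = s + idx * n_arm
        return m - 1, m  # behind, ahead of the junction along the line

    cut_rows = [set() for _ in rows]
    cut_cols = [set() for _ in cols]
    crossings = []
    for iy in range(spec.repeats_y):
        for ix in range(spec.repeats_x):
            rb, ra = flanks(ix, spec.n_x)
            cb, ca = flanks(spec.repeats_y - 1 - iy, spec.n_y)
            cut_rows[iy].add(rb)       # bottom strand cut at step rb -> ra
            cut_cols[ix].add(cb)
            crossings.append((rows[iy][ra][1], cols[ix][cb][1]))
            crossings.append((cols[ix][ca][1], rows[iy][rb][1]))

    # sticky-end tile joints in the middle of every inter-junction segment:
    # one nick per strand, offset by two steps (the sticky-end overlap)
    nick_rows_t: set[int] = set()
    nick_rows_b: set[int] = set()
    nick_cols_t: set[int] = set()
    nick_cols_b: set[int] = set()
    if spec.nick_arms:
        for i in range(spec.repeats_x - 1):
            mid = s + i * spec.n_x + spec.n_x // 2
            nick_rows_t.add(mid - 2)
            nick_rows_b.add(mid)
        for i in range(spec.repeats_y - 1):
            mid = s + i * spec.n_y + spec.n_y // 2
            nick_cols_t.add(mid - 2)
            nick_cols_b.add(mid)

    for iy, ids in enumerate(rows):
        for m in range(nrow - 1):
            if m not in nick_rows_t:
                b.link(ids[m][0], ids[m + 1][0])
            if m not in cut_rows[iy] and m not in nick_rows_b:
                b.link(ids[m + 1][1], ids[m][1])
    for ix, ids in enumerate(cols):
        for m in range(ncol - 1):
            if m not in nick_cols_t:
                b.link(ids[m][0], ids[m + 1][0])
            if m not in cut_cols[ix] and m not in nick_cols_b:
                b.link(ids[m + 1][1], ids[m][1])
    for five, three in crossings:
        b.link(five, three)
    return b.finish()


# -- tensegrity-like 3D weave -------------------------------------------------


def make_tensegrity_design(spec: TensegritySpec, name: str = "tensegrity") -> Design:
    """Periodic three-axis strut weave joined by four-way junctions.

    Emulates the tensegrity-triangle motif topologically: three families of
    straight duplex struts along x, y and z, pairwise offset by 1.85 nm and
    woven together by one four-way junction per strut pair per cell (3 per
    cell).  Collinear struts of adjacent cells form one continuous duplex
    (the inter-cell connection).  Does not claim base-level identity with
    any deposited crystal design.
    """
    n1, n2, n3 = spec.cells
    rise = spec.rise
    P = spec.strut_period_bp * rise
    stub = spec.stub_bp
    gap = 1.85
    a_off = spec.junction_site_1 * rise
    b = _Builder(name)

    # line origins: x-lines indexed (j,k); y-lines (k,i); z-lines (i,j)
    def build_line(n_cells_along, origin, e3, e1_hint):
        n_bp = 2 * stub + n_cells_along * spec.strut_period_bp
        ids = []
        frame = geo.orthonormal_frame(np.asarray(e3, dtype=float), hint=np.asarray(e1_hint, dtype=float))
        for m in range(n_bp):
            x = np.asarray(origin, dtype=float) + (m - stub + 0.5) * rise * frame[:, 2]
            R = frame @ geo.exp_so3(np.array([0.0, 0.0, m * np.radians(360.0 / 10.5)]))
            ids.append(_place_bp(b, _seq(1, m)[0], x, R))
        return ids

    # strut senses chosen so each junction's two helices are locally
    # antiparallel-ish (stacked-X): x-struts +x, y-struts -y, z-struts +z
    xl = {(j, k): build_line(n1, (0.0, j * P, k * P), (1, 0, 0), (0, 0, 1))
          for j in range(n2) for k in range(n3)}
    yl = {(k, i): build_line(n2, (i * P + a_off, (n2 - 1) * P, k * P + gap), (0, -1, 0), (0, 0, -1))
          for k in range(n3) for i in range(n1)}
    zl = {(i, j): build_line(n3, (i * P + a_off - gap, j * P + gap, 0.0), (0, 0, 1), (1, 0, 0))
          for i in range(n1) for j in range(n2)}

    cuts: dict[int, set[int]] = {}
    crossings = []

    def junction(line_a, site_a, line_b, site_b):
        """Weave two lines: bottom strands exchange at the given bp steps."""
        ra, aa = site_a - 1, site_a
        rb, ab = site_b - 1, site_b
        cuts.setdefault(id(line_a), set()).add(ra)
        cuts.setdefault(id(line_b), set()).add(rb)
        crossings.append((line_a[aa][1], line_b[rb][1]))
        crossings.append((line_b[ab][1], line_a[ra][1]))

    s1, s2 = spec.junction_site_1, spec.junction_site_2
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                jr = n2 - 1 - j  # y-struts run -y: cell j sits at reversed index
                junction(xl[(j, k)], stub + i * spec.strut_period_bp + s1,
                         yl[(k, i)], stub + jr * spec.strut_period_bp + s1)
                junction(yl[(k, i)], stub + jr * spec.strut_period_bp + s2,
                         zl[(i, j)], stub + k * spec.strut_period_bp + s1)
                junction(zl[(i, j)], stub + k * spec.strut_period_bp + s2,
                         xl[(j, k)], stub + i * spec.strut_period_bp + s2)

    for line in list(xl.values()) + list(yl.values()) + list(zl.values()):
        cut = cuts.get(id(line), set())
        for m in range(len(line) - 1):
            b.link(line[m][0], line[m + 1][0])
            if m not in cut:
                b.link(line[m + 1][1], line[m][1])
    for five, three in crossings:
        b.link(five, three)
    return b.finish()
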