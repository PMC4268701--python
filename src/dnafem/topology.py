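"""Strand-graph traversal: duplexes, nicks, four-way junctions, isomers.

The design graph (nucleotides + backbone + pairing edges) is decomposed into

* **duplexes** — maximal runs of coaxially stacked basepairs.  Two adjacent
  basepairs belong to the same duplex when the backbone either continues on
  both strands (reciprocal antiparallel edges) or terminates on exactly one
  strand while the other continues (a *nick*, recorded by step index);
* **junctions** — groups of four duplex ends whose innermost basepairs are
  joined cyclically by four inter-duplex backbone links (two "continuous"
  strand links inside the coaxially stacked arm pairs and two "crossing"
  strand links, the branch points);
* **connectivity** — which junction arm ends each duplex joins.

The isomeric state of a junction (which adjacent arm pairs stack) is assigned
once from the initial Cartesian coordinates and is immutable thereafter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .design import NONE_ID, Design

log = logging.getLogger(__name__)


class UnsupportedMotifError(ValueError):
    """Branch motif that is not a four-way junction."""


@dataclass
class Duplex:
    """Maximal run of stacked basepairs.

    ``bp_list`` holds ``(ref, comp)`` nucleotide-id tuples ordered 5'->3'
    along the reference strand (the strand containing the duplex's minimum
    nucleotide id).  ``nicks`` are 0-based bp-step indices at which one
    backbone is discontinuous between stacked basepairs.  ``closed`` marks a
    circular duplex (the step from the last bp back to the first exists).
    """

    bp_list: list[tuple[int, int]]
    nicks: list[int] = field(default_factory=list)
    closed: bool = False

    @property
    def length_bp(self) -> int:
        return len(self.bp_list)

    def end_bp(self, end: int) -> tuple[int, int]:
        return self.bp_list[0] if end == 0 else self.bp_list[-1]


@dataclass
class ArmRef:
    """One junction arm: a duplex end. ``end`` 0 = bp_list[0], 1 = last bp."""

    duplex: int
    end: int


@dataclass
class Junction:
    id: int
    arms: list[ArmRef]                      # cyclic order of the 4 arms
    cycle_links: list[tuple[int, int]]      # backbone link (a -> b) joining arm i to arm i+1
    center_xyz: np.ndarray = field(default_factory=lambda: np.zeros(3))
    isomer: int | None = None               # 0: stack (0,1)&(2,3); 1: stack (1,2)&(3,0)

    def stacked_pairs(self) -> list[tuple[int, int]]:
        if self.isomer is None:
            raise ValueError(f"junction {self.id} has no isomer state")
        return [(0, 1), (2, 3)] if self.isomer == 0 else [(1, 2), (3, 0)]

    def crossing_links(self) -> list[tuple[int, int]]:
        """The two branch-point backbone links (between non-stacked arms)."""
        if self.isomer is None:
            raise ValueError(f"junction {self.id} has no isomer state")
        # cycle_links[i] joins arm i and arm i+1; it crosses between helices
        # iff arms i, i+1 are not a stacked pair.
        crossing = [1, 3] if self.isomer == 0 else [0, 2]
        return [self.cycle_links[i] for i in crossing]


@dataclass
class Topology:
    duplexes: list[Duplex]
    junctions: list[Junction]
    # one entry per duplex: ((junction, arm) | None) for each of its two ends
    attachments: list[tuple[tuple[int, int] | None, tuple[int, int] | None]]

    @property
    def connectivity(self) -> list[tuple[tuple[int, int], tuple[int, int], int, int]]:
        """Duplexes joining two junction arms: (end_a, end_b, duplex, bp count)."""
        out = []
        for d, (a, b) in enumerate(self.attachments):
            if a is not None and b is not None:
                out.append((a, b, d, self.duplexes[d].length_bp))
        return out

    def total_bp(self) -> int:
        return sum(d.length_bp for d in self.duplexes)

    def report(self) -> str:
        lines = ["# duplex table", "idx\tlen_bp\tclosed\tnicks\tfirst_bp\tlast_bp"]
        for i, d in enumerate(self.duplexes):
            lines.append(
                f"{i}\t{d.length_bp}\t{int(d.closed)}\t{','.join(map(str, d.nicks)) or '-'}"
                f"\t{d.bp_list[0]}\t{d.bp_list[-1]}"
            )
        lines += ["", "# junction table", "idx\tisomer\tarms(duplex:end)\tcenter_nm"]
        for j in self.junctions:
            arms = ",".join(f"{a.duplex}:{a.end}" for a in j.arms)
            c = np.array2string(np.asarray(j.center_xyz), precision=2)
            lines.append(f"{j.id}\t{j.isomer}\t{arms}\t{c}")
        lines += ["", "# connectivity table", "end_a\tend_b\tduplex\tbp"]
        for a, b, d, n in self.connectivity:
            lines.append(f"J{a[0]}.arm{a[1]}\tJ{b[0]}.arm{b[1]}\t{d}\t{n}")
        return "\n".join(lines)


# -----------------------------------------------------------------------------


def _bp_key(design: Design, nid: int) -> tuple[int, int] | None:
    p = design.nucleotides[nid].pair
    if p == NONE_ID:
        return None
    return (nid, p) if nid < p else (p, nid)


def _step_kind(design: Design, a: int, b: int) -> str:
    """Classify backbone edge a->b (both paired, different bps).

    Returns 'internal' (duplex continues on both strands), 'nick' (complement
    terminates on both half-links), or 'branch'.
    """
    nts = design.nucleotides
    pa, pb = nts[a].pair, nts[b].pair
    if nts[pb].neighbor3 == pa:
        return "internal"
    if nts[pb].neighbor3 == NONE_ID and nts[pa].neighbor5 == NONE_ID:
        return "nick"
    return "branch"


def find_duplexes(design: Design) -> list[Duplex]:
    """Group paired bases into maximal stacked runs with recorded nicks.

    Total bp count is conserved: every basepair lands in exactly one duplex.
    """
    nts = design.nucleotides
    bps: dict[tuple[int, int], None] = {}
    for nid, nt in nts.items():
        key = _bp_key(design, nid)
        if key is not None:
            bps.setdefault(key, None)

    # adjacency between bps via duplex-internal (or nick) steps
    adj: dict[tuple[int, int], list[tuple[tuple[int, int], bool]]] = {k: [] for k in bps}
    for a, nt in nts.items():
        b = nt.neighbor3
        if b == NONE_ID or nt.pair == NONE_ID:
            continue
        if b not in nts or nts[b].pair == NONE_ID:
            continue
        ka, kb = _bp_key(design, a), _bp_key(design, b)
        if ka == kb:
            continue
        kind = _step_kind(design, a, b)
        if kind == "branch":
            continue
        pair = (kb, kind == "nick")
        if pair not in adj[ka]:
            adj[ka].append(pair)
        rpair = (ka, kind == "nick")
        if rpair not in adj[kb]:
            adj[kb].append(rpair)

    seen: set[tuple[int, int]] = set()
    duplexes: list[Duplex] = []
    for start in sorted(bps):
        if start in seen:
            continue
        # walk to one extreme of the path (or back to start for a cycle)
        def neighbors(k):
            return [n for n, _ in adj[k]]

        cur, prev = start, None
        steps = 0
        while True:
            nbrs = [n for n in neighbors(cur) if n != prev]
            if not nbrs or steps > len(bps):
                break
            prev, cur = cur, nbrs[0]
            if cur == start:
                break
            steps += 1
        closed = cur == start and steps > 0
        first = min((k for k in _component(start, neighbors)), default=start) if closed else cur
        chain = [first]
        prev = None
        while True:
            nbrs = [n for n in neighbors(chain[-1]) if n != prev]
            if not nbrs:
                break
            prev = chain[-1]
            nxt = nbrs[0]
            if nxt == first:
                break
            chain.append(nxt)
        seen.update(chain)
        duplexes.append(_orient_duplex(design, chain, closed, adj))
    duplexes.sort(key=lambda d: min(min(bp) for bp in d.bp_list))
    return duplexes


def _component(start, neighbors):
    out = {start}
    stack = [start]
    while stack:
        k = stack.pop()
        for n in neighbors(k):
            if n not in out:
                out.add(n)
                stack.append(n)
    return out


def _orient_duplex(design: Design, chain, closed: bool, adj) -> Duplex:
    """Orient bp order 5'->3' along the reference strand and record nicks."""
    nts = design.nucleotides
    all_ids = [i for bp in chain for i in bp]
    ref_strand = nts[min(all_ids)].strand_id
    # orient: find a step where the reference strand advances 3'-ward
    def ref_advances(c):
        for i in range(len(c) - 1):
            (a1, b1), (a2, b2) = c[i], c[i + 1]
            for u in (a1, b1):
                if nts[u].strand_id == ref_strand:
                    if nts[u].neighbor3 in c[i + 1]:
                        return True
                    if nts[u].neighbor5 in c[i + 1]:
                        return False
        return True

    if not ref_advances(chain):
        chain = chain[::-1]
    if closed:
        m = chain.index(min(chain, key=min))
        chain = chain[m:] + chain[:m]
    # reference-strand nucleotide first in each bp tuple (bps the reference
    # strand does not touch keep ascending-id order)
    bp_list = []
    for lo, hi in chain:
        bp_list.append((lo, hi) if nts[lo].strand_id == ref_strand else (hi, lo))
    nicks = []
    nsteps = len(chain) if closed else len(chain) - 1
    for i in range(nsteps):
        ka, kb = chain[i], chain[(i + 1) % len(chain)]
        if any(n and k == kb for k, n in adj[ka]):
            nicks.append(i)
    return Duplex(bp_list=bp_list, nicks=sorted(nicks), closed=closed)


def find_junctions(design: Design, duplexes: list[Duplex]) -> list[Junction]:
    """Group inter-duplex backbone links into four-way junctions.

    Every backbone edge whose flanking basepairs lie in different duplexes is
    a junction link; links must form disjoint 4-cycles over duplex-end
    basepairs, otherwise the motif is unsupported.
    """
    nts = design.nucleotides
    bp_to_duplex: dict[tuple[int, int], tuple[int, int]] = {}
    end_of: dict[tuple[int, int], tuple[int, int]] = {}
    for di, d in enumerate(duplexes):
        for pos, (a, b) in enumerate(d.bp_list):
            key = (a, b) if a < b else (b, a)
            bp_to_duplex[key] = (di, pos)
        for e in (0, 1):
            a, b = d.end_bp(e)
            end_of.setdefault((a, b) if a < b else (b, a), (di, e))

    links: list[tuple[int, int]] = []
    for a, nt in sorted(nts.items()):
        b = nt.neighbor3
        if b == NONE_ID or nt.pair == NONE_ID or b not in nts or nts[b].pair == NONE_ID:
            continue
        ka, kb = _bp_key(design, a), _bp_key(design, b)
        if ka == kb or ka is None or kb is None:
            continue
        if bp_to_duplex[ka][0] != bp_to_duplex[kb][0]:
            links.append((a, b))

    # connected components over bps joined by links
    graph: dict[tuple[int, int], list[tuple[tuple[int, int], tuple[int, int]]]] = {}
    for a, b in links:
        ka, kb = _bp_key(design, a), _bp_key(design, b)
        graph.setdefault(ka, []).append((kb, (a, b)))
        graph.setdefault(kb, []).append((ka, (a, b)))

    seen: set[tuple[int, int]] = set()
    junctions: list[Junction] = []
    for start in sorted(graph):
        if start in seen:
            continue
        comp = _component(start, lambda k: [n for n, _ in graph[k]])
        seen.update(comp)
        nlinks = sum(len(graph[k]) for k in comp) // 2
        if len(comp) != 4 or nlinks != 4 or any(len(graph[k]) != 2 for k in comp):
            ids = sorted(i for k in comp for i in k)
            raise UnsupportedMotifError(
                f"branch motif with {len(comp)} arm-end bps and {nlinks} links is not a "
                f"four-way junction (nucleotides {ids})"
            )
        # walk the 4-cycle
        cycle = [min(comp)]
        prev = None
        cyc_links = []
        while len(cycle) < 4:
            for n, link in graph[cycle[-1]]:
                if n != prev or len(graph[cycle[-1]]) == 1:
                    if n not in cycle:
                        cyc_links.append(link)
                        prev = cycle[-1]
                        cycle.append(n)
                        break
            else:
                break
        # closing link
        for n, link in graph[cycle[-1]]:
            if n == cycle[0] and link not in cyc_links:
                cyc_links.append(link)
                break
        if len(cycle) != 4 or len(cyc_links) != 4:
            ids = sorted(i for k in comp for i in k)
            raise UnsupportedMotifError(f"junction links do not form a 4-cycle (nucleotides {ids})")
        arms = []
        for bp in cycle:
            if bp not in end_of:
                di, pos = bp_to_duplex[bp]
                raise UnsupportedMotifError(
                    f"junction touches bp {bp} at interior position {pos} of duplex {di}"
                )
            di, e = end_of[bp]
            arms.append(ArmRef(duplex=di, end=e))
        centers = np.array([_bp_center(design, bp) for bp in cycle])
        junctions.append(
            Junction(
                id=len(junctions),
                arms=arms,
                cycle_links=cyc_links,
                center_xyz=centers.mean(axis=0),
            )
        )
    return junctions


def _bp_center(design: Design, bp: tuple[int, int]) -> np.ndarray:
    a, b = bp
    return 0.5 * (
        np.asarray(design.nucleotides[a].xyz) + np.asarray(design.nucleotides[b].xyz)
    )


def arm_axis(design: Design, duplexes: list[Duplex], arm: ArmRef, k: int | None = None) -> np.ndarray:
    """Unit vector pointing from the junction flank bp into the arm.

    Estimated from the flanking bp centre to the bp centre ``k`` steps into
    the arm, ``k = min(3, length-1)`` by default — robust to single-bp noise.
    """
    d = duplexes[arm.duplex]
    if k is None:
        k = min(3, d.length_bp - 1)
    k = max(1, k)
    if arm.end == 0:
        a, b = d.bp_list[0], d.bp_list[min(k, d.length_bp - 1)]
    else:
        a, b = d.bp_list[-1], d.bp_list[max(0, d.length_bp - 1 - k)]
    v = _bp_center(design, b) - _bp_center(design, a)
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError(f"degenerate arm axis for duplex {arm.duplex} end {arm.end}")
    return v / n


def assign_isomer(junction: Junction, design: Design, duplexes: list[Duplex],
                  tol: float = 1e-9) -> int:
    """Assign the stacking isomer from initial arm-axis angles.

    Arm 0 stacks with whichever cyclic neighbour (arm 1 or arm 3) subtends an
    angle closer to 180 deg.  On an exact tie (within ``tol``) the lower
    cyclic neighbour giving the larger dot-product magnitude wins, with a
    logged warning.  The assignment is deterministic, invariant to rigid
    motion of the coordinates, and immutable once set.
    """
    if junction.isomer is not None:
        return junction.isomer
    v = [arm_axis(design, duplexes, a) for a in junction.arms]
    d01 = float(np.clip(np.dot(v[0], v[1]), -1, 1))
    d03 = float(np.clip(np.dot(v[0], v[3]), -1, 1))
    ang01, ang03 = np.degrees(np.arccos(d01)), np.degrees(np.arccos(d03))
    gap = abs(abs(ang01 - 180.0) - abs(ang03 - 180.0))
    if gap < tol:
        log.warning(
            "junction %d: isomer tie (angles %.3f / %.3f deg); tie-break by dot magnitude",
            junction.id, ang01, ang03,
        )
        if abs(abs(d01) - abs(d03)) < tol:
            isomer = 0
        else:
            isomer = 0 if abs(d01) > abs(d03) else 1
    else:
        isomer = 0 if abs(ang01 - 180.0) < abs(ang03 - 180.0) else 1
    junction.isomer = isomer
    return isomer


def build_topology(design: Design) -> Topology:
    """Full extraction: duplexes, junctions with isomers, attachments."""
    duplexes = find_duplexes(design)
    junctions = find_junctions(design, duplexes)
    for j in junctions:
        assign_isomer(j, design, duplexes)
    attachments: list[list[tuple[int, int] | None]] = [[None, None] for _ in duplexes]
    for j in junctions:
        for ai, arm in enumerate(j.arms):
            attachments[arm.duplex][arm.end] = (j.id, ai)
    topo = Topology(
        duplexes=duplexes,
        junctions=junctions,
        attachments=[tuple(a) for a in attachments],
    )
    log.info(
        "topology: %d duplexes (%d bp), %d junctions, %d inter-junction duplexes",
        len(duplexes), topo.total_bp(), len(junctions), len(topo.connectivity),
    )
    return topo
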