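"""Nucleotide-level design model and file I/O.

A *design* is the strand-graph description of a programmed DNA assembly:
one record per nucleotide carrying its base identity, initial 3D position
(nm), 5'/3' backbone neighbours and Watson-Crick partner.  Strands are the
maximal 5'->3' backbone chains or cycles; they partition the nucleotides.

Two on-disk formats are supported:

* the canonical ``dnafem`` dialect — a line-oriented text format defined by
  this package (documented in :data:`CANONICAL_HEADER` and the README);
* a best-effort importer for Tiamat-style XML design files.  Tiamat's native
  schema is not publicly documented; the importer targets the field mapping
  described in :func:`read_tiamat` and warns (rather than fails) on
  unrecognized content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree

log = logging.getLogger(__name__)

NONE_ID = -1
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
CANONICAL_HEADER = "# dnafem-design v1"


class DesignError(ValueError):
    """Malformed design file or invalid design graph."""


@dataclass
class Nucleotide:
    """A single nucleotide vertex of the strand graph.

    ``neighbor5``/``neighbor3``/``pair`` hold the id of the linked nucleotide
    or ``NONE_ID`` (-1) when the link is absent; links are never encoded by
    omission.
    """

    id: int
    base: str
    xyz: tuple[float, float, float]
    neighbor5: int = NONE_ID
    neighbor3: int = NONE_ID
    pair: int = NONE_ID
    strand_id: int = NONE_ID


@dataclass
class Design:
    nucleotides: dict[int, Nucleotide] = field(default_factory=dict)
    name: str = "design"
    source_format: str = "canonical"

    def __post_init__(self) -> None:
        if self.nucleotides and any(
            n.strand_id == NONE_ID for n in self.nucleotides.values()
        ):
            self.assign_strands()

    def __len__(self) -> int:
        return len(self.nucleotides)

    def add(self, nt: Nucleotide) -> None:
        if nt.id in self.nucleotides:
            raise DesignError(f"duplicate nucleotide id {nt.id}")
        self.nucleotides[nt.id] = nt

    # -- strand decomposition -------------------------------------------------

    def strands(self) -> list[list[int]]:
        """Maximal 5'->3' chains/cycles, ordered by minimum member id.

        Each strand is returned as the list of nucleotide ids in 5'->3'
        order; cycles start at their minimum id.
        """
        nts = self.nucleotides
        seen: set[int] = set()
        strands: list[list[int]] = []
        for start in sorted(nts):
            if start in seen:
                continue
            # walk to the 5' terminus (or detect a cycle)
            cur = start
            while nts[cur].neighbor5 != NONE_ID:
                cur = nts[cur].neighbor5
                if cur == start:  # cycle
                    break
            if nts[cur].neighbor5 != NONE_ID:  # cycle: canonical start = min id
                cyc = [start]
                nxt = nts[start].neighbor3
                while nxt != start:
                    cyc.append(nxt)
                    nxt = nts[nxt].neighbor3
                m = cyc.index(min(cyc))
                chain = cyc[m:] + cyc[:m]
            else:
                chain = [cur]
                while nts[chain[-1]].neighbor3 != NONE_ID:
                    chain.append(nts[chain[-1]].neighbor3)
            seen.update(chain)
            strands.append(chain)
        strands.sort(key=min)
        return strands

    def assign_strands(self) -> None:
        for sid, chain in enumerate(self.strands()):
            for nid in chain:
                self.nucleotides[nid].strand_id = sid

    def n_pairs(self) -> int:
        return sum(1 for n in self.nucleotides.values() if n.pair != NONE_ID) // 2


# -- validation ---------------------------------------------------------------


@dataclass
class Violation:
    rule: str
    ids: tuple[int, ...]
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.message}"


def validate_design(design: Design) -> list[Violation]:
    """Check every structural invariant of the design graph.

    Returns an empty list iff the design is valid.  Each violation names the
    offending nucleotide ids and the violated rule.
    """
    out: list[Violation] = []
    nts = design.nucleotides
    for nid, nt in nts.items():
        if nt.base not in COMPLEMENT:
            out.append(Violation("base", (nid,), f"nucleotide {nid}: base {nt.base!r} not in ACGT"))
        for attr in ("neighbor5", "neighbor3", "pair"):
            ref = getattr(nt, attr)
            if ref != NONE_ID and ref not in nts:
                out.append(
                    Violation("dangling", (nid, ref), f"nucleotide {nid}: {attr} -> {ref} does not exist")
                )
    for nid, nt in nts.items():
        n3 = nt.neighbor3
        if n3 != NONE_ID and n3 in nts and nts[n3].neighbor5 != nid:
            out.append(
                Violation(
                    "backbone",
                    (nid, n3),
                    f"backbone not reciprocal: {nid}.neighbor3={n3} but {n3}.neighbor5={nts[n3].neighbor5}",
                )
            )
        p = nt.pair
        if p != NONE_ID and p in nts:
            if p == nid:
                out.append(Violation("pair", (nid,), f"nucleotide {nid} paired with itself"))
            elif nts[p].pair != nid:
                out.append(
                    Violation(
                        "pair",
                        (nid, p),
                        f"pairing not symmetric: {nid}.pair={p} but {p}.pair={nts[p].pair}",
                    )
                )
            elif nid < p and COMPLEMENT.get(nt.base) != nts[p].base:
                out.append(
                    Violation(
                        "complement",
                        (nid, p),
                        f"non-Watson-Crick pair {nt.base}-{nts[p].base} between {nid} and {p}",
                    )
                )
    return out


def _require_valid(design: Design) -> None:
    violations = validate_design(design)
    if violations:
        msg = "; ".join(str(v) for v in violations[:20])
        raise DesignError(f"invalid design ({len(violations)} violations): {msg}")


# -- canonical dialect --------------------------------------------------------


def write_design(design: Design, path: str | Path) -> None:
    """Write the canonical line-oriented design dialect.

    One ``nt`` record per nucleotide: ``nt id base x y z n5 n3 pair`` with
    coordinates in nm printed with ``repr`` precision so that a read/write
    round trip is bitwise exact.
    """
    _require_valid(design)
    path = Path(path)
    lines = [CANONICAL_HEADER, f"name {design.name}"]
    for nid in sorted(design.nucleotides):
        nt = design.nucleotides[nid]
        x, y, z = nt.xyz
        lines.append(
            f"nt {nid} {nt.base} {x!r} {y!r} {z!r} {nt.neighbor5} {nt.neighbor3} {nt.pair}"
        )
    path.write_text("\n".join(lines) + "\n")
    log.info("wrote design %s: %d nucleotides -> %s", design.name, len(design), path)


def _read_canonical(path: Path) -> Design:
    design = Design(name=path.stem, source_format="canonical")
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        if tok[0] == "name":
            design.name = " ".join(tok[1:]) or design.name
            continue
        if tok[0] != "nt":
            raise DesignError(f"{path}:{lineno}: unknown record {tok[0]!r}")
        if len(tok) != 9:
            raise DesignError(f"{path}:{lineno}: expected 9 fields in nt record, got {len(tok)}")
        try:
            nid = int(tok[1])
            base = tok[2]
            xyz = (float(tok[3]), float(tok[4]), float(tok[5]))
            n5, n3, pair = int(tok[6]), int(tok[7]), int(tok[8])
        except ValueError as exc:
            raise DesignError(f"{path}:{lineno}: malformed nt record: {exc}") from exc
        design.add(Nucleotide(nid, base, xyz, n5, n3, pair))
    return design


# -- Tiamat-style import ------------------------------------------------------


def read_tiamat(path: str | Path) -> Design:
    """Best-effort importer for Tiamat-style XML design files.

    Assumed schema (reverse-engineered; Tiamat's format is not publicly
    specified): a root element containing ``<nucleotide>`` (or ``<nt>``)
    elements with an ``id`` and ``base`` given as attributes or child
    elements, a position as ``<position x= y= z=>`` (or ``x``/``y``/``z``
    children) in nm, and ``neighbor5``/``neighbor3``/``pair`` links (aliases
    ``five``/``three``/``complement`` accepted; ``-1`` or absence means no
    link).  Unrecognized elements and attributes are ignored with a logged
    warning.
    """
    path = Path(path)
    try:
        root = ElementTree.parse(path).getroot()
    except ElementTree.ParseError as exc:
        raise DesignError(f"{path}: not parseable as Tiamat XML: {exc}") from exc
    design = Design(name=path.stem, source_format="tiamat")
    known_tags = {"nucleotide", "nt"}
    link_alias = {
        "neighbor5": "neighbor5",
        "five": "neighbor5",
        "neighbor3": "neighbor3",
        "three": "neighbor3",
        "pair": "pair",
        "complement": "pair",
    }
    unknown: set[str] = set()
    for el in root.iter():
        if el is root or el.tag not in known_tags:
            if el is not root and el.tag not in {"position", "x", "y", "z", *link_alias}:
                unknown.add(el.tag)
            continue
        fields: dict[str, str] = dict(el.attrib)
        for child in el:
            if child.tag == "position":
                fields.update({k: v for k, v in child.attrib.items() if k in "xyz"})
            elif child.tag in {"x", "y", "z"}:
                fields[child.tag] = (child.text or "").strip()
            elif child.tag in link_alias:
                fields[link_alias[child.tag]] = (child.text or "").strip()
            else:
                unknown.add(child.tag)
        for key, target in link_alias.items():
            if key in fields and target not in fields:
                fields[target] = fields[key]
        try:
            nid = int(fields["id"])
            base = fields.get("base", "A").upper()
            xyz = (float(fields.get("x", 0.0)), float(fields.get("y", 0.0)), float(fields.get("z", 0.0)))
        except (KeyError, ValueError) as exc:
            raise DesignError(f"{path}: malformed nucleotide record {fields!r}: {exc}") from exc

        def _link(name: str) -> int:
            v = fields.get(name, "")
            return int(v) if v not in ("", None) else NONE_ID

        design.add(
            Nucleotide(nid, base, xyz, _link("neighbor5"), _link("neighbor3"), _link("pair"))
        )
    if unknown:
        log.warning("%s: ignored unrecognized Tiamat fields: %s", path, sorted(unknown))
    return design


# -- front door ---------------------------------------------------------------


def read_design(path: str | Path, format: str = "auto") -> Design:
    """Read and validate a design file.

    ``format`` is one of ``canonical``, ``tiamat`` or ``auto`` (sniffed from
    the file header).  The returned design satisfies every invariant
    (validated; strands assigned deterministically by ascending minimum
    nucleotide id).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        head = path.read_text()[:256].lstrip()
        format = "canonical" if head.startswith(CANONICAL_HEADER) else (
            "tiamat" if head.startswith("<") else "canonical"
        )
    if format == "canonical":
        design = _read_canonical(path)
    elif format == "tiamat":
        design = read_tiamat(path)
    else:
        raise ValueError(f"unknown design format {format!r}")
    _require_valid(design)
    design.assign_strands()
    log.info(
        "read design %s (%s): %d nucleotides, %d strands, %d pairs",
        design.name, format, len(design), len(design.strands()), design.n_pairs(),
    )
    return design


def designs_isomorphic(a: Design, b: Design) -> bool:
    """Graph isomorphism of two designs under the canonical strand labelling.

    Relabels both designs by (strand rank, position along strand) and compares
    bases and link structure; initial coordinates are ignored.
    """

    def canonical(d: Design) -> list[tuple]:
        order: dict[int, tuple[int, int]] = {}
        for sid, chain in enumerate(d.strands()):
            for pos, nid in enumerate(chain):
                order[nid] = (sid, pos)
        rows = []
        for nid in sorted(order, key=order.get):
            nt = d.nucleotides[nid]
            rows.append(
                (
                    order[nid],
                    nt.base,
                    order.get(nt.neighbor5),
                    order.get(nt.neighbor3),
                    order.get(nt.pair),
                )
            )
        return rows

    return canonical(a) == canonical(b)
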