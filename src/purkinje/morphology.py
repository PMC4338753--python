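"""Purkinje cell morphology: axon, soma and surrogate dendritic tree.

The cell is represented as a tree of cylindrical *sections*, each carrying a
region tag that later drives channel placement.  The axon is deterministic
(initial segment, paraAIS, four myelinated internodes alternating with three
nodes of Ranvier, and a two-section collateral stemming from the second
node).  The soma is a single cylinder of 29.8 x 29.8 um.  The dendritic tree
of the original guinea-pig reconstruction is not available as coordinates,
so a seeded surrogate generator emulates its printed aggregates: section
count, diameter range 0.67-9.22 um, three branch orders (trunk, principal,
terminal) and a total cell area of ~70,000 um^2.

Sections are discretized into compartments with the standard lambda rule
(compartment length <= d_lambda * AC length constant at 100 Hz); myelinated
sections use a single compartment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

ROOT = -1  # parent marker of the root section


class RegionTag(str, Enum):
    """Electrotonic region of a section; drives channel placement."""

    SOMA = "soma"
    TRUNK = "trunk_dendrite"
    PRINCIPAL = "principal_dendrite"
    TERMINAL = "terminal_dendrite"
    AIS = "AIS"
    PARA_AIS = "paraAIS"
    MYELIN = "myelin"
    NODE = "node"
    COLLATERAL = "collateral"


#: tags that make up the dendritic tree
DENDRITE_TAGS = (RegionTag.TRUNK, RegionTag.PRINCIPAL, RegionTag.TERMINAL)
#: tags that make up the axon
AXON_TAGS = (RegionTag.AIS, RegionTag.PARA_AIS, RegionTag.MYELIN,
             RegionTag.NODE, RegionTag.COLLATERAL)

# dendritic calibre limits of the source reconstruction (um)
DEND_DIAM_MIN, DEND_DIAM_MAX = 0.67, 9.22
DEND_LEN_MIN, DEND_LEN_MAX = 1.0, 10.0
# diameter thresholds separating the two named recording classes (um)
PRINCIPAL_DIAM_MIN = 8.0
TERMINAL_DIAM_MAX = 3.5

SOMA_DIAM = SOMA_LEN = 29.8


class MorphologyError(ValueError):
    """Malformed or inconsistent morphology."""


class InfeasibleTargetError(MorphologyError):
    """Surrogate generator cannot reach the requested area."""


@dataclass
class SectionGeometry:
    """A single unbranched cylindrical section.

    Parameters
    ----------
    id : int
        0-based section index, unique within a morphology.
    parent_id : int
        Index of the parent section, or ``ROOT`` (-1) for the root.
    tag : RegionTag
        Electrotonic region of the section.
    diameter, length : float
        Cylinder dimensions in micrometres.
    n_compartments : int
        Number of iso-potential compartments the section is split into.
    """

    id: int
    parent_id: int
    tag: RegionTag
    diameter: float
    length: float
    n_compartments: int = 1

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise MorphologyError(
                f"section {self.id}: nonpositive dimensions "
                f"(d={self.diameter}, L={self.length})")
        if self.n_compartments < 1:
            raise MorphologyError(f"section {self.id}: n_compartments < 1")

    @property
    def lateral_area(self) -> float:
        """Lateral cylinder area pi*d*L in um^2 (the membrane area used
        throughout; the soma is represented by its lateral area too)."""
        return math.pi * self.diameter * self.length


@dataclass
class PassiveParams:
    """Passive membrane and axoplasm parameters.

    ``cm_specific`` and ``g_leak`` map region tags to specific capacitance
    (uF/cm^2) and leak conductance (S/cm^2); missing tags fall back to the
    ``*_default`` scalar.  ``ra`` is the axial resistivity in Ohm*cm and
    ``e_leak`` the leak reversal in mV.

    Defaults encode the model's calibration: somatic Cm 0.77 uF/cm^2,
    dendritic Cm raised to account for the spiny membrane (so that the
    somatically measured input capacitance reaches ~1090 pF on a 70,000 um^2
    cell), myelin at low capacitance, Ra 122 Ohm*cm, and leak densities
    pinned by the passive calibration script so that the somatic input
    resistance of the surrogate cell is ~14 MOhm.
    """

    cm_default: float = 0.77
    cm_specific: dict = field(default_factory=lambda: {
        RegionTag.SOMA: 0.77,
        RegionTag.TRUNK: 2.045,
        RegionTag.PRINCIPAL: 2.045,
        RegionTag.TERMINAL: 2.045,
        RegionTag.MYELIN: 0.06,
    })
    ra: float = 122.0
    g_leak_default: float = 2.1e-5
    g_leak: dict = field(default_factory=lambda: {
        RegionTag.TRUNK: 1.367e-4,
        RegionTag.PRINCIPAL: 1.367e-4,
        RegionTag.TERMINAL: 1.367e-4,
        RegionTag.MYELIN: 2.0e-6,
        RegionTag.NODE: 1.0e-4,
        RegionTag.PARA_AIS: 5.0e-3,
        RegionTag.COLLATERAL: 5.0e-3,
    })
    e_leak: float = -54.0

    def cm_of(self, tag: RegionTag) -> float:
        return self.cm_specific.get(tag, self.cm_default)

    def g_leak_of(self, tag: RegionTag) -> float:
        return self.g_leak.get(tag, self.g_leak_default)


def lambda_f(diameter: float, ra: float, cm: float, f: float = 100.0) -> float:
    """AC length constant (um) of an infinite cable at frequency ``f`` Hz.

    Standard discretization rule: lambda_f = 1e5 * sqrt(d / (4 pi f Ra Cm))
    with d in um, Ra in Ohm*cm and Cm in uF/cm^2.
    """
    return 1e5 * math.sqrt(diameter / (4.0 * math.pi * f * ra * cm))


@dataclass
class Morphology:
    """A connected, acyclic tree of sections plus generator metadata."""

    sections: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- bookkeeping ------------------------------------------------------
    def validate(self) -> None:
        ids = [s.id for s in self.sections]
        if len(set(ids)) != len(ids):
            raise MorphologyError("duplicate section ids")
        idset = set(ids)
        roots = [s for s in self.sections if s.parent_id == ROOT]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, got {len(roots)}")
        for s in self.sections:
            if s.parent_id != ROOT and s.parent_id not in idset:
                raise MorphologyError(f"section {s.id}: unknown parent {s.parent_id}")
            if s.parent_id == s.id:
                raise MorphologyError(f"section {s.id}: is its own parent")
        # acyclicity / connectivity: walk up from every section
        by_id = {s.id: s for s in self.sections}
        for s in self.sections:
            seen = set()
            cur = s
            while cur.parent_id != ROOT:
                if cur.id in seen:
                    raise MorphologyError(f"cycle through section {s.id}")
                seen.add(cur.id)
                cur = by_id[cur.parent_id]

    def __len__(self) -> int:
        return len(self.sections)

    def by_id(self, sid: int) -> SectionGeometry:
        for s in self.sections:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def with_tag(self, tag: RegionTag) -> list:
        return [s for s in self.sections if s.tag == tag]

    def children_of(self, sid: int) -> list:
        return [s for s in self.sections if s.parent_id == sid]

    # -- geometry ---------------------------------------------------------
    def total_area(self) -> float:
        """Total membrane area in um^2 (sum of lateral section areas)."""
        return sum(s.lateral_area for s in self.sections)

    def path_length(self, sid_a: int, sid_b: int) -> float:
        """Midpoint-to-midpoint path length (um) between two sections.

        Children attach at the distal (1.0) end of their parent, so the path
        between two sections in different subtrees passes through the distal
        end of their nearest common ancestor.
        """
        if sid_a == sid_b:
            return 0.0
        anc_a = self._ancestry(sid_a)
        anc_b = self._ancestry(sid_b)
        idx_a = {s.id: i for i, s in enumerate(anc_a)}
        for j, s in enumerate(anc_b):
            if s.id in idx_a:
                common, i = s.id, idx_a[s.id]
                break
        else:
            raise MorphologyError("sections not connected")

        def to_distal_end(chain, k):
            # midpoint of chain[0] up to the distal end of chain[k]
            return chain[0].length / 2.0 + sum(s.length for s in chain[1:k])

        if common == sid_a:          # a is an ancestor of b
            return to_distal_end(anc_b, j) + anc_a[0].length / 2.0
        if common == sid_b:          # b is an ancestor of a
            return to_distal_end(anc_a, i) + anc_b[0].length / 2.0
        return to_distal_end(anc_a, i) + to_distal_end(anc_b, j)

    def _ancestry(self, sid: int) -> list:
        by_id = {s.id: s for s in self.sections}
        chain = [by_id[sid]]
        while chain[-1].parent_id != ROOT:
            chain.append(by_id[chain[-1].parent_id])
        return chain

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "metadata": self.metadata,
            "sections": [
                {"id": s.id, "parent_id": s.parent_id, "tag": s.tag.value,
                 "diameter": s.diameter, "length": s.length,
                 "n_compartments": s.n_compartments}
                for s in self.sections
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "Morphology":
        text = Path(source).read_text() if isinstance(source, (str, Path)) \
            and "\n" not in str(source) and Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        secs = [SectionGeometry(d["id"], d["parent_id"], RegionTag(d["tag"]),
                                d["diameter"], d["length"], d["n_compartments"])
                for d in payload["sections"]]
        return cls(secs, payload.get("metadata", {}))


# ---------------------------------------------------------------------------
# deterministic axon (12 sections)
# ---------------------------------------------------------------------------

def build_axon(start_id: int = 0, parent_id: int = ROOT) -> list:
    """Build the 12 axonal sections.

    Chain: AIS (17 x 0.97 um) -> paraAIS (4 x 0.97) -> [myelin (100 x 0.73),
    node (4 x 0.73)] x 3 -> myelin, with a collateral of two 100 x 0.6 um
    sections branching from the 2nd node.  Bit-identical across calls.
    """
    secs = []
    nid = start_id

    def add(tag, d, L, parent):
        nonlocal nid
        s = SectionGeometry(nid, parent, tag, d, L)
        secs.append(s)
        nid += 1
        return s.id

    ais = add(RegionTag.AIS, 0.97, 17.0, parent_id)
    para = add(RegionTag.PARA_AIS, 0.97, 4.0, ais)
    prev = para
    node_ids = []
    for k in range(3):
        prev = add(RegionTag.MYELIN, 0.73, 100.0, prev)
        prev = add(RegionTag.NODE, 0.73, 4.0, prev)
        node_ids.append(prev)
    add(RegionTag.MYELIN, 0.73, 100.0, prev)            # 4th internode
    c1 = add(RegionTag.COLLATERAL, 0.6, 100.0, node_ids[1])
    add(RegionTag.COLLATERAL, 0.6, 100.0, c1)
    return secs


def build_soma(sid: int = 0) -> SectionGeometry:
    """The soma as a single 29.8 x 29.8 um cylinder (lateral area ~2790 um^2)."""
    return SectionGeometry(sid, ROOT, RegionTag.SOMA, SOMA_DIAM, SOMA_LEN)


def soma_axon_area() -> float:
    """Lateral area (um^2) of the canonical soma plus axon."""
    soma = build_soma()
    return soma.lateral_area + sum(s.lateral_area for s in build_axon(1, 0))


# ---------------------------------------------------------------------------
# surrogate dendrites
# ---------------------------------------------------------------------------

def generate_surrogate_dendrites(target_area: float, n_sections: int,
                                 seed: int, start_id: int = 12,
                                 parent_id: int = 0,
                                 strict_ranges: bool = False) -> list:
    """Generate a seeded surrogate dendritic tree.

    The tree is connected, acyclic and has three branch orders: *trunk*
    sections (d > 8 um) attached to the soma, *principal* sections
    (3.5 <= d <= 8, tagged principal along with the trunk-adjacent
    intermediate calibres) and *terminal* sections (d < 3.5 um).  Diameters
    taper outward (child <= parent).  Section lengths are scaled to a common
    factor so that the summed dendritic lateral area equals
    ``target_area - (soma + axon area)`` to within 2%.

    For reduced trees (``n_sections`` far below the 1599 of the source
    reconstruction) the per-section area needed to reach the target exceeds
    what the source calibre/length ranges allow; each surrogate section then
    stands for a cluster of real branchlets and its length is allowed to
    exceed the 10 um upper range (diameters stay in range).  With
    ``strict_ranges=True`` this relaxation is disabled and an
    :class:`InfeasibleTargetError` is raised instead.

    Parameters
    ----------
    target_area : float
        Target *total cell* area in um^2 (soma + axon + dendrites).
    n_sections : int
        Number of dendritic sections (>= 3, one per order minimum).
    seed : int
        Generator seed; identical seeds give identical trees.
    start_id, parent_id : int
        First section id to use and the id of the soma to attach to.
    """
    if n_sections < 3:
        raise InfeasibleTargetError("need at least 3 dendritic sections")
    dend_target = target_area - soma_axon_area()
    if dend_target <= 0:
        raise InfeasibleTargetError("target area does not exceed soma+axon area")

    rng = np.random.default_rng(seed)
    n_trunk = max(1, int(round(0.04 * n_sections)))
    n_principal = max(1, int(round(0.36 * n_sections)))
    n_terminal = n_sections - n_trunk - n_principal
    if n_terminal < 1:
        n_trunk, n_principal, n_terminal = 1, 1, n_sections - 2

    d_trunk = np.sort(rng.uniform(PRINCIPAL_DIAM_MIN + 0.2, DEND_DIAM_MAX,
                                  n_trunk))[::-1]
    d_prin = np.sort(rng.uniform(TERMINAL_DIAM_MAX, PRINCIPAL_DIAM_MIN,
                                 n_principal))[::-1]
    d_term = np.sort(rng.uniform(DEND_DIAM_MIN, TERMINAL_DIAM_MAX - 0.01,
                                 n_terminal))[::-1]
    diam = np.concatenate([d_trunk, d_prin, d_term])
    tags = ([RegionTag.TRUNK] * n_trunk + [RegionTag.PRINCIPAL] * n_principal
            + [RegionTag.TERMINAL] * n_terminal)

    # raw lengths inside the source range, then a global scale to the target
    raw_len = rng.uniform(DEND_LEN_MIN, DEND_LEN_MAX, n_sections)
    hi = DEND_LEN_MAX if strict_ranges else math.inf
    length = _fit_lengths(diam, raw_len, dend_target, DEND_LEN_MIN, hi,
                          n_sections)

    # topology: trunk chain on the soma; each later section attaches to a
    # random already-placed section of equal or thicker calibre
    secs = []
    ids = np.arange(start_id, start_id + n_sections)
    parents = np.empty(n_sections, dtype=int)
    parents[0] = parent_id
    for i in range(1, n_trunk):
        parents[i] = ids[i - 1]          # trunk is a chain
    for i in range(n_trunk, n_sections):
        # candidates: any placed section with diameter >= this one
        cand = np.nonzero(diam[:i] >= diam[i] - 1e-12)[0]
        if cand.size == 0:
            cand = np.array([i - 1])
        parents[i] = ids[rng.choice(cand)]
    for i in range(n_sections):
        secs.append(SectionGeometry(int(ids[i]), int(parents[i]), tags[i],
                                    float(diam[i]), float(length[i])))
    return secs


def _fit_lengths(diam, raw_len, target, lo, hi, n_sections):
    """Scale lengths to a summed lateral area of ``target``, projecting onto
    the box [lo, hi] and rescaling the unconstrained sections iteratively."""
    length = raw_len * (target / float(np.sum(math.pi * diam * raw_len)))
    for _ in range(200):
        clipped = np.clip(length, lo, hi)
        area = float(np.sum(math.pi * diam * clipped))
        err = target - area
        if abs(err) <= 1e-3 * target:
            return clipped
        free = (clipped > lo * (1 + 1e-12)) & (clipped < hi)
        denom = float(np.sum(math.pi * diam[free] * clipped[free]))
        if not np.any(free) or denom == 0.0:
            break
        length = clipped.copy()
        length[free] *= 1.0 + err / denom
    raise InfeasibleTargetError(
        f"cannot reach {target:.0f} um^2 of dendrite with {n_sections} "
        f"sections inside the allowed calibre/length ranges")


def build_cell(n_dend: int = 1599, seed: int = 1,
               target_area: float = 70000.0,
               passive: PassiveParams | None = None) -> Morphology:
    """Assemble the full cell: soma (root) + axon + surrogate dendrites.

    Section ids: soma 0, axon 1-11, dendrites 12 onward.  Compartment counts
    are assigned by the lambda rule using ``passive`` (defaults used when
    omitted).
    """
    soma = build_soma(0)
    axon = build_axon(1, 0)
    dend = generate_surrogate_dendrites(target_area, n_dend, seed,
                                        start_id=12, parent_id=0)
    m = Morphology([soma] + axon + dend,
                   metadata={"seed": seed, "n_dend": n_dend,
                             "target_area": target_area})
    assign_compartments(m, passive or PassiveParams())
    return m


def assign_compartments(m: Morphology, passive: PassiveParams,
                        f: float = 100.0, d_lambda: float = 0.1) -> None:
    """Set ``n_compartments`` per section: length <= d_lambda * lambda_f,
    except myelinated sections which always use one compartment."""
    for s in m.sections:
        if s.tag is RegionTag.MYELIN:
            s.n_compartments = 1
            continue
        lam = lambda_f(s.diameter, passive.ra, passive.cm_of(s.tag), f)
        s.n_compartments = max(1, int(math.ceil(s.length / (d_lambda * lam))))


# ---------------------------------------------------------------------------
# SWC exchange
# ---------------------------------------------------------------------------

# custom SWC type mapping (documented external interface)
_TAG_TO_SWC = {
    RegionTag.SOMA: 1, RegionTag.AIS: 2, RegionTag.TRUNK: 5,
    RegionTag.PRINCIPAL: 6, RegionTag.TERMINAL: 7, RegionTag.PARA_AIS: 8,
    RegionTag.MYELIN: 9, RegionTag.NODE: 10, RegionTag.COLLATERAL: 11,
}
_SWC_TO_TAG = {v: k for k, v in _TAG_TO_SWC.items()}
# standard types from foreign files
_SWC_TO_TAG.setdefault(3, RegionTag.TERMINAL)
_SWC_TO_TAG.setdefault(4, RegionTag.PRINCIPAL)


class SWCError(MorphologyError):
    """Malformed SWC record or topology."""


def write_swc(m: Morphology, path) -> None:
    """Write the morphology as 7-column SWC, one point per section.

    Cylinder-per-segment convention: each non-root point defines a section
    from its parent's point to itself; coordinates are synthesized (path
    distance along x, a per-branch y offset) since the model is not embedded
    in 3-D.  Radii are half the section diameters; the root (soma) point
    carries the soma radius.
    """
    by_id = {s.id: s for s in m.sections}
    order = _topo_order(m)
    coords: dict[int, tuple] = {}
    lines = ["# purkinje surrogate morphology",
             "# columns: id type x y z radius parent"]
    for k, s in enumerate(order):
        if s.parent_id == ROOT:
            coords[s.id] = (0.0, 0.0, 0.0)
        else:
            px, py, pz = coords[s.parent_id]
            # deterministic small transverse offset keeps points distinct
            y = py + 1e-3 * ((s.id % 7) - 3)
            dy = y - py
            dx = math.sqrt(max(s.length ** 2 - dy ** 2, 1e-12))
            coords[s.id] = (px + dx, y, pz)
        x, y, z = coords[s.id]
        swc_parent = s.parent_id if s.parent_id != ROOT else -1
        lines.append(f"{s.id + 1} {_TAG_TO_SWC[s.tag]} {x:.9f} {y:.9f} {z:.9f} "
                     f"{s.diameter / 2.0:.9f} "
                     f"{swc_parent + 1 if swc_parent != -1 else -1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path, merge_unbranched: bool = False) -> Morphology:
    """Read a 7-column SWC file into a :class:`Morphology`.

    Each non-root point becomes one section whose length is the Euclidean
    distance to its parent point and whose diameter is twice its radius;
    the root point becomes the root section (a cylinder with length equal
    to its diameter when it has no extent of its own).  With
    ``merge_unbranched=True``, chains of same-type, same-radius points are
    collapsed into single sections (useful for foreign point-dense files;
    disabled by default to keep write/read round trips exact).
    """
    rows = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        txt = raw.split("#", 1)[0].strip()
        if not txt:
            continue
        parts = txt.split()
        if len(parts) != 7:
            raise SWCError(f"line {ln}: expected 7 columns, got {len(parts)}")
        try:
            pid = int(parts[0]); typ = int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            par = int(parts[6])
        except ValueError as exc:
            raise SWCError(f"line {ln}: {exc}") from None
        if pid == par:
            raise SWCError(f"line {ln}: point {pid} is its own parent")
        if pid in rows:
            raise SWCError(f"line {ln}: duplicate point id {pid}")
        rows[pid] = (typ, x, y, z, r, par)

    # cycle check
    for pid in rows:
        seen = set()
        cur = pid
        while cur != -1:
            if cur in seen:
                raise SWCError(f"cyclic parentage through point {pid}")
            seen.add(cur)
            if cur not in rows and cur != -1:
                raise SWCError(f"unknown parent {cur}")
            cur = rows[cur][5]

    secs = []
    id_map = {}
    nxt = 0
    for pid in sorted(rows):
        typ, x, y, z, r, par = rows[pid]
        tag = _SWC_TO_TAG.get(typ, RegionTag.TERMINAL)
        if par == -1:
            secs.append(SectionGeometry(nxt, ROOT, tag, 2 * r, 2 * r))
        else:
            tp, xp, yp, zp, rp, _ = rows[par]
            L = math.dist((x, y, z), (xp, yp, zp))
            if L <= 0:
                raise SWCError(f"point {pid}: zero-length segment")
            secs.append(SectionGeometry(nxt, id_map[par], tag, 2 * r, L))
        id_map[pid] = nxt
        nxt += 1

    m = Morphology(secs)
    if merge_unbranched:
        m = _merge_chains(m)
    return m


def _merge_chains(m: Morphology) -> Morphology:
    """Collapse unbranched same-tag, same-diameter chains into single
    sections (summing lengths)."""
    nchild = {s.id: 0 for s in m.sections}
    for s in m.sections:
        if s.parent_id != ROOT:
            nchild[s.parent_id] += 1
    by_id = {s.id: s for s in m.sections}
    merged_into = {}
    out = []
    for s in _topo_order(m):
        p = merged_into.get(s.parent_id, s.parent_id)
        if (p != ROOT and p in by_id):
            ps = next(o for o in out if o.id == p)
            if (nchild[s.parent_id] == 1 and ps.tag == s.tag
                    and abs(ps.diameter - s.diameter) < 1e-9
                    and ps.parent_id != ROOT):
                ps.length += s.length
                merged_into[s.id] = ps.id
                continue
        out.append(SectionGeometry(s.id, p, s.tag, s.diameter, s.length,
                                   s.n_compartments))
    # renumber densely
    remap = {s.id: i for i, s in enumerate(out)}
    dense = [SectionGeometry(remap[s.id],
                             remap[s.parent_id] if s.parent_id != ROOT else ROOT,
                             s.tag, s.diameter, s.length, s.n_compartments)
             for s in out]
    return Morphology(dense)


def _topo_order(m: Morphology) -> list:
    """Sections ordered parents-first."""
    by_id = {s.id: s for s in m.sections}
    out, placed = [], set()
    pending = list(m.sections)
    while pending:
        rest = []
        for s in pending:
            if s.parent_id == ROOT or s.parent_id in placed:
                out.append(s)
                placed.add(s.id)
            else:
                rest.append(s)
        if len(rest) == len(pending):
            raise MorphologyError("unreachable sections (cycle?)")
        pending = rest
    return out
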