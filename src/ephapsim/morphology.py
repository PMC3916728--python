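"""SWC morphology reading, validation and electrical compartmentalization.

A neuron is read from the standard 7-column SWC format (id, type, x, y, z,
radius, parent; '#' comments), reconstructed as a tree of typed cylinders,
decomposed into unbranched *sections*, and discretized into electrical
compartments with the d_lambda rule: each section is split into an odd number
of compartments no longer than ``d_lambda`` times the AC length constant at
``f_lambda`` (default 100 Hz).

Every compartment is assigned an ``x`` coordinate (in mm) along the
somatodendritic axis — the first principal axis of the morphology's point
cloud, with the soma center at the origin and the apical centroid on the
positive side.  The extracellular field varies along this axis only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import IntEnum
import numpy as np
import pandas as pd

ROOT_MARKER = -1


class Structure(IntEnum):
    """SWC structure codes."""

    SOMA = 1
    AXON = 2
    BASAL = 3
    APICAL = 4


class SwcStructureError(ValueError):
    """Raised when an SWC file violates tree-structural invariants."""


@dataclass(frozen=True)
class SwcPoint:
    id: int
    structure: Structure
    position: np.ndarray  # (3,) um
    radius: float  # um
    parent_id: int  # ROOT_MARKER for the root

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"SWC point {self.id}: radius must be > 0, got {self.radius}")


@dataclass
class Section:
    """Maximal unbranched chain of same-type SWC points."""

    id: int
    structure: Structure
    point_ids: list[int]          # ordered, proximal -> distal
    parent_section: int           # -1 for the root section
    parent_point_id: int          # attachment point in the parent section (-1 if root)
    length: float = 0.0           # um, sum of inter-point distances


@dataclass
class MorphologyTree:
    points: list[SwcPoint]
    sections: list[Section]

    @property
    def point_index(self) -> dict[int, int]:
        return {p.id: i for i, p in enumerate(self.points)}

    def points_of(self, structure: Structure) -> list[SwcPoint]:
        return [p for p in self.points if p.structure == structure]

    def soma_center(self) -> np.ndarray:
        soma = self.points_of(Structure.SOMA)
        return np.mean([p.position for p in soma], axis=0)


def read_swc(source) -> MorphologyTree:
    """Parse an SWC character stream (string, file path, or file object).

    Raises :class:`SwcStructureError` on dangling parents, cycles, forward
    references, duplicate ids or a disconnected/soma-less tree, and
    ``ValueError`` on non-positive radii or unknown structure codes.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and text.endswith(".swc"):
            with open(text) as fh:
                text = fh.read()
    points: list[SwcPoint] = []
    seen: dict[int, int] = {}
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SwcStructureError(f"line {lineno}: expected 7 columns, got {len(cols)}")
        pid, code = int(cols[0]), int(cols[1])
        x, y, z, r = (float(c) for c in cols[2:6])
        parent = int(cols[6])
        try:
            structure = Structure(code)
        except ValueError:
            raise ValueError(f"line {lineno}: unsupported structure code {code}") from None
        if pid in seen:
            raise SwcStructureError(f"line {lineno}: duplicate point id {pid}")
        if parent != ROOT_MARKER and parent not in seen:
            # covers dangling ids, forward references and self-cycles alike:
            # SWC requires a parent to precede its children
            raise SwcStructureError(
                f"line {lineno}: parent id {parent} of point {pid} not yet defined"
            )
        seen[pid] = len(points)
        points.append(SwcPoint(pid, structure, np.array([x, y, z]), r, parent))
    if not points:
        raise SwcStructureError("empty SWC stream")
    roots = [p for p in points if p.parent_id == ROOT_MARKER]
    if len(roots) != 1:
        raise SwcStructureError(f"expected exactly one root point, found {len(roots)}")
    if not any(p.structure == Structure.SOMA for p in points):
        raise SwcStructureError("no soma points in file")
    tree = MorphologyTree(points=points, sections=[])
    tree.sections = _build_sections(tree)
    return tree


def write_swc(tree: MorphologyTree) -> str:
    lines = ["# generated by ephapsim"]
    for p in tree.points:
        x, y, z = p.position
        lines.append(
            f"{p.id} {int(p.structure)} {x:.6f} {y:.6f} {z:.6f} {p.radius:.6f} {p.parent_id}"
        )
    return "\n".join(lines) + "\n"


def _build_sections(tree: MorphologyTree) -> list[Section]:
    idx = tree.point_index
    children: dict[int, list[int]] = {p.id: [] for p in tree.points}
    for p in tree.points:
        if p.parent_id != ROOT_MARKER:
            children[p.parent_id].append(p.id)

    def same_type_children(p: SwcPoint) -> list[int]:
        return [c for c in children[p.id]
                if tree.points[idx[c]].structure == p.structure]

    def starts_section(p: SwcPoint) -> bool:
        # a chain continues through the *unique* same-type child; children of
        # a different type (e.g. dendrites off the soma) attach mid-chain
        if p.parent_id == ROOT_MARKER:
            return True
        par = tree.points[idx[p.parent_id]]
        return par.structure != p.structure or len(same_type_children(par)) > 1

    sections: list[Section] = []
    sec_of_point: dict[int, int] = {}
    for p in tree.points:
        if not starts_section(p):
            continue
        chain = [p.id]
        cur = p
        while len(same_type_children(cur)) == 1:
            nxt = tree.points[idx[same_type_children(cur)[0]]]
            chain.append(nxt.id)
            cur = nxt
        sec = Section(
            id=len(sections),
            structure=p.structure,
            point_ids=chain,
            parent_section=-1,
            parent_point_id=p.parent_id,
        )
        sections.append(sec)
        for pid in chain:
            sec_of_point[pid] = sec.id
    for sec in sections:
        if sec.parent_point_id != ROOT_MARKER:
            sec.parent_section = sec_of_point[sec.parent_point_id]
        sec.length = sum(length for length, _d, _a, _b in _section_segments(tree, sec))
    return sections


def _section_segments(tree, sec):
    """Cylindrical segments of a section: (length, diameter, p_start, p_end).

    Each SWC point defines a cylinder from its parent's position to its own,
    with the distal (child) point's diameter.  The first segment of a
    non-root section runs from the attachment point in the parent section.
    A single-point root soma is modeled as a cylinder of length 2r.
    """
    idx = tree.point_index
    pts = [tree.points[idx[pid]] for pid in sec.point_ids]
    segs = []
    if sec.parent_point_id != ROOT_MARKER:
        prev = tree.points[idx[sec.parent_point_id]]
        chain = [prev] + pts
    else:
        chain = pts
    if len(chain) == 1:
        p = chain[0]
        segs.append((2 * p.radius, 2 * p.radius, p.position, p.position))
        return segs
    for a, b in zip(chain[:-1], chain[1:]):
        length = float(np.linalg.norm(b.position - a.position))
        if length == 0.0:
            continue
        segs.append((length, 2 * b.radius, a.position, b.position))
    return segs


# ---------------------------------------------------------------------------
# Discretization (d_lambda rule)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscretizationConfig:
    d_lambda: float = 0.1      # fraction of the 100 Hz length constant
    f_lambda: float = 100.0    # Hz
    Ra: float = 150.0          # Ohm cm
    Cm: float = 1.0            # uF/cm^2

    def __post_init__(self):
        for name in ("d_lambda", "f_lambda", "Ra", "Cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.d_lambda >= 1:
            raise ValueError("d_lambda must be < 1")


def lambda_f(diam_um: float, f_hz: float, Ra: float, Cm: float) -> float:
    """AC length constant (um) of a cylinder of diameter ``diam_um``.

    lambda_f = 0.5 * sqrt(d / (pi * f * Ra * Cm)) in consistent units;
    with d in um, Ra in Ohm cm and Cm in uF/cm^2 this is
    1e5 * sqrt(d / (4 pi f Ra Cm)) um.
    """
    return 1e5 * np.sqrt(diam_um / (4.0 * np.pi * f_hz * Ra * Cm))


def n_compartments_for(length_um: float, lam_um: float, d_lambda: float) -> int:
    """Odd compartment count per the d_lambda rule."""
    return int((length_um / (d_lambda * lam_um) + 0.9) / 2.0) * 2 + 1


@dataclass
class Compartment:
    index: int
    section_id: int
    structure: Structure
    diameter: float       # um (length-weighted mean over its arc span)
    length: float         # um
    area: float           # cm^2, lateral surface pi*d*L
    x_mm: float           # position along the somatodendritic axis
    parent: int           # compartment index, -1 for root
    r_axial: float        # MOhm to parent (-1 -> nan)


@dataclass
class CompartmentalModel:
    """Discretized electrical model of one morphology.

    Arrays are indexed by compartment, ordered so that a parent always
    precedes its children (Hines ordering).
    """

    diameter: np.ndarray
    length: np.ndarray
    area: np.ndarray          # cm^2
    x_mm: np.ndarray
    structure: np.ndarray     # int codes (Structure)
    parent: np.ndarray        # int, -1 for root
    r_axial: np.ndarray       # MOhm to parent, nan for root
    section_id: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_compartments(self) -> int:
        return len(self.diameter)

    def __len__(self) -> int:
        return self.n_compartments

    def validate(self) -> None:
        n = self.n_compartments
        if n == 0:
            raise ValueError("empty model")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise SwcStructureError(f"model must have exactly one root, found {len(roots)}")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise SwcStructureError("compartments are not in parent-before-child order")

    def somatodendritic_extent(self) -> tuple[float, float]:
        """(x_min, x_max) in mm over all compartments."""
        return float(self.x_mm.min()), float(self.x_mm.max())

    def counts_by_structure(self) -> dict[str, int]:
        return {
            s.name.lower(): int(np.sum(self.structure == int(s)))
            for s in Structure
        }

    def compartments(self) -> list[Compartment]:
        return [
            Compartment(i, int(self.section_id[i]), Structure(int(self.structure[i])),
                        float(self.diameter[i]), float(self.length[i]), float(self.area[i]),
                        float(self.x_mm[i]), int(self.parent[i]), float(self.r_axial[i]))
            for i in range(self.n_compartments)
        ]

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "index": np.arange(self.n_compartments),
            "type": [Structure(int(s)).name.lower() for s in self.structure],
            "diameter_um": self.diameter,
            "length_um": self.length,
            "x_mm": self.x_mm,
            "parent_index": self.parent,
        })


def _half_axial_resistance(Ra: float, length_um, diam_um):
    """Axial resistance (MOhm) of half a cylindrical compartment:
    r = 4 Ra (L/2) / (pi d^2), which is 4e-2 Ra (L/2) / (pi d^2) MOhm
    with Ra in Ohm cm and L, d in um."""
    return 4e-2 * Ra * (np.asarray(length_um) / 2.0) / (np.pi * np.asarray(diam_um) ** 2)


def _axis_of(tree: MorphologyTree) -> tuple[np.ndarray, np.ndarray]:
    """Somatodendritic axis: first principal component of the point cloud,
    oriented so the apical centroid has positive projection; origin at the
    soma centroid."""
    origin = tree.soma_center()
    pos = np.array([p.position for p in tree.points]) - origin
    if len(pos) < 2 or np.allclose(pos, 0):
        return origin, np.array([1.0, 0.0, 0.0])
    _u, _s, vt = np.linalg.svd(pos, full_matrices=False)
    axis = vt[0]
    apical = [p.position for p in tree.points_of(Structure.APICAL)]
    if apical:
        ref = np.mean(apical, axis=0) - origin
    else:
        ref = pos[np.argmax(np.linalg.norm(pos, axis=1))]
    if np.dot(axis, ref) < 0:
        axis = -axis
    return origin, axis


def discretize(tree: MorphologyTree, cfg: DiscretizationConfig | None = None) -> CompartmentalModel:
    """Split every section into an odd number of compartments per the
    d_lambda rule and assign somatodendritic x coordinates (mm)."""
    cfg = cfg or DiscretizationConfig()
    origin, axis = _axis_of(tree)

    diameter, length, area, x_mm, structure = [], [], [], [], []
    parent, r_axial, section_id = [], [], []
    # (section, local j) -> compartment index bookkeeping
    first_comp: dict[int, int] = {}
    comps_of_sec: dict[int, list[int]] = {}
    half_r: list[float] = []

    for sec in tree.sections:
        segs = _section_segments(tree, sec)
        if not segs:
            raise SwcStructureError(f"section {sec.id} has zero length")
        seg_len = np.array([s[0] for s in segs])
        seg_d = np.array([s[1] for s in segs])
        if np.any(seg_d <= 0):
            raise ValueError(f"section {sec.id}: non-positive diameter")
        L = float(seg_len.sum())
        d_mean = float(np.sum(seg_len * seg_d) / L)
        lam = lambda_f(d_mean, cfg.f_lambda, cfg.Ra, cfg.Cm)
        n = n_compartments_for(L, lam, cfg.d_lambda)
        # arc-length boundaries of segments and compartments
        seg_edges = np.concatenate([[0.0], np.cumsum(seg_len)])
        comp_edges = np.linspace(0.0, L, n + 1)
        sec_comp_idx = []
        for j in range(n):
            a, b = comp_edges[j], comp_edges[j + 1]
            # length-weighted mean diameter over [a, b]
            lo = np.clip(seg_edges[:-1], a, b)
            hi = np.clip(seg_edges[1:], a, b)
            w = hi - lo
            dj = float(np.sum(w * seg_d) / (b - a))
            lj = b - a
            mid = 0.5 * (a + b)
            k = min(np.searchsorted(seg_edges, mid, side="right") - 1, len(segs) - 1)
            frac = (mid - seg_edges[k]) / max(seg_len[k], 1e-12)
            p0, p1 = segs[k][2], segs[k][3]
            midpoint = p0 + frac * (p1 - p0)
            idx = len(diameter)
            sec_comp_idx.append(idx)
            diameter.append(dj)
            length.append(lj)
            area.append(np.pi * dj * lj * 1e-8)  # um^2 -> cm^2
            x_mm.append(float(np.dot(midpoint - origin, axis)) * 1e-3)
            structure.append(int(sec.structure))
            section_id.append(sec.id)
            half_r.append(float(_half_axial_resistance(cfg.Ra, lj, dj)))
            if j == 0:
                parent.append(-2)  # resolved below
                r_axial.append(np.nan)
            else:
                parent.append(idx - 1)
                r_axial.append(half_r[idx] + half_r[idx - 1])
        first_comp[sec.id] = sec_comp_idx[0]
        comps_of_sec[sec.id] = sec_comp_idx

    # connect first compartment of each section to its parent section
    for sec in tree.sections:
        i0 = first_comp[sec.id]
        if sec.parent_section < 0:
            parent[i0] = -1
            continue
        # attach to the parent-section compartment containing the attachment
        # point's arc position (normally the distal end -> last compartment)
        psec = tree.sections[sec.parent_section]
        segs = _section_segments(tree, psec)
        arc = 0.0
        chain_ids = ([psec.parent_point_id] if psec.parent_point_id != ROOT_MARKER else []) \
            + psec.point_ids
        pidx = tree.point_index
        pos = {pid: tree.points[pidx[pid]].position for pid in chain_ids}
        for a, b in zip(chain_ids[:-1], chain_ids[1:]):
            arc += float(np.linalg.norm(pos[b] - pos[a]))
            if b == sec.parent_point_id:
                break
        plist = comps_of_sec[psec.id]
        L_p = max(psec.length, 1e-12)
        j = min(int(arc / L_p * len(plist)), len(plist) - 1)
        target = plist[j]
        parent[i0] = target
        r_axial[i0] = half_r[i0] + half_r[target]

    model = CompartmentalModel(
        diameter=np.array(diameter), length=np.array(length), area=np.array(area),
        x_mm=np.array(x_mm), structure=np.array(structure, dtype=np.int64),
        parent=np.array(parent, dtype=np.int64), r_axial=np.array(r_axial),
        section_id=np.array(section_id, dtype=np.int64),
        meta={"d_lambda": cfg.d_lambda, "Ra": cfg.Ra, "Cm": cfg.Cm},
    )
    model.validate()
    return model


def uniform_cylinder(n: int, length_um: float, diam_um: float, Ra: float = 150.0,
                     structure: Structure = Structure.SOMA) -> CompartmentalModel:
    """Unbranched uniform cylinder of ``n`` compartments (validation helper)."""
    lj = length_um / n
    half = float(_half_axial_resistance(Ra, lj, diam_um))
    parent = np.arange(-1, n - 1)
    r = np.full(n, 2 * half)
    r[0] = np.nan
    return CompartmentalModel(
        diameter=np.full(n, diam_um), length=np.full(n, lj),
        area=np.full(n, np.pi * diam_um * lj * 1e-8),
        x_mm=(np.arange(n) + 0.5) * lj * 1e-3,
        structure=np.full(n, int(structure), dtype=np.int64),
        parent=parent, r_axial=r, section_id=np.zeros(n, dtype=np.int64),
        meta={"Ra": Ra},
    )


def somatodendritic_extent(model: CompartmentalModel) -> tuple[float, float]:
    return model.somatodendritic_extent()
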