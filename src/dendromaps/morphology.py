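"""SWC morphologies: reading, writing, morphometry and discretization.

A :class:`MorphTree` is a rooted tree of 3-D points with radii following SWC
semantics (type 1 = soma, 3 = basal dendrite, 4 = apical dendrite).  Trees
are decomposed into :class:`Section` objects (maximal unbranched runs of
nodes) and discretized into a :class:`CompartmentGrid` of odd numbers of
equal-length segments per section using the d_lambda rule: every segment is
kept shorter than a fixed fraction (default 0.1) of the 100 Hz space
constant computed from the section's mean diameter and local axial
resistivity.

All geometry is in micrometers; only the total dendritic length is reported
in millimeters, matching the convention of the morphometric literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import StructuralError, SwcParseError

SOMA, AXON, BASAL, APICAL = 1, 2, 3, 4
DENDRITE_TYPES = (BASAL, APICAL)


@dataclass(frozen=True)
class MorphNode:
    """A single SWC point: id, type, position (um), radius (um), parent id."""

    node_id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 for the root

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Section:
    """Maximal unbranched run of nodes.

    ``node_ids`` lists the nodes whose parent edges belong to this section;
    ``anchor_id`` is the proximal attachment node (branch point or soma node)
    that provides the proximal geometry but whose own parent edge belongs to
    the upstream section.
    """

    section_id: int
    node_ids: list[int]
    anchor_id: int
    parent_section: int | None  # section_id, None when attached to soma
    type_code: int
    length: float  # um
    is_trunk: bool = False
    is_terminal: bool = False


@dataclass(frozen=True)
class Segment:
    """One electrical compartment produced by the d_lambda discretization."""

    index: int
    section_id: int
    parent_index: int  # -1 for the soma segment
    length: float  # um
    diameter: float  # um at the segment midpoint
    area: float  # um^2, frustum lateral area over the segment span
    path_distance: float  # um, soma centroid to segment midpoint along the tree
    radial_distance: float  # um, straight-line distance of the midpoint
    type_code: int
    is_trunk: bool


class MorphTree:
    """Rooted tree of :class:`MorphNode` with per-node labels.

    Nodes are stored in topological order (every parent precedes its
    children).  ``labels`` carries optional per-node string tags; the tag
    ``"trunk"`` marks the somatoapical trunk used for location-matched
    measurements.
    """

    def __init__(self, nodes: list[MorphNode], labels: dict[int, str] | None = None):
        self.nodes = list(nodes)
        self.labels: dict[int, str] = dict(labels or {})
        self._index = {n.node_id: i for i, n in enumerate(self.nodes)}
        self._children: dict[int, list[int]] = {}
        self.validate()

    # -- validation and basic structure ------------------------------------

    def validate(self) -> None:
        if not self.nodes:
            raise StructuralError("empty morphology")
        if len(self._index) != len(self.nodes):
            raise StructuralError("duplicate node ids")
        roots = [n for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise StructuralError(f"expected exactly one root, found {len(roots)}")
        self._children = {n.node_id: [] for n in self.nodes}
        seen: set[int] = set()
        for n in self.nodes:
            if n.radius <= 0:
                raise StructuralError(f"node {n.node_id}: non-positive radius")
            if n.parent_id != -1:
                if n.parent_id not in self._index:
                    raise StructuralError(
                        f"node {n.node_id}: parent {n.parent_id} does not exist"
                    )
                if n.parent_id not in seen:
                    raise StructuralError(
                        f"node {n.node_id}: parent {n.parent_id} appears after child"
                    )
                self._children[n.parent_id].append(n.node_id)
            seen.add(n.node_id)

    def node(self, node_id: int) -> MorphNode:
        return self.nodes[self._index[node_id]]

    def children(self, node_id: int) -> list[int]:
        return self._children[node_id]

    @property
    def root(self) -> MorphNode:
        return self.nodes[0]

    @property
    def soma_ids(self) -> list[int]:
        ids = [n.node_id for n in self.nodes if n.type_code == SOMA]
        return ids if ids else [self.root.node_id]

    @property
    def soma_centroid(self) -> np.ndarray:
        """Radius-weighted mean position of the soma nodes."""
        soma = [self.node(i) for i in self.soma_ids]
        w = np.array([n.radius for n in soma])
        pos = np.array([[n.x, n.y, n.z] for n in soma])
        return (w[:, None] * pos).sum(axis=0) / w.sum()

    # -- morphometry --------------------------------------------------------

    def edge_length(self, node_id: int) -> float:
        """Euclidean length of the edge from ``node_id`` to its parent."""
        n = self.node(node_id)
        if n.parent_id == -1:
            return 0.0
        p = self.node(n.parent_id)
        return float(np.linalg.norm(n.position - p.position))

    def radial_distance(self, node_id: int) -> float:
        """Straight-line 3-D distance from the soma centroid (um)."""
        return float(np.linalg.norm(self.node(node_id).position - self.soma_centroid))

    def path_distance(self, node_id: int) -> float:
        """Arc length along the tree from the soma to the node (um).

        Edges between soma nodes contribute zero (the soma is the origin).
        """
        d = 0.0
        n = self.node(node_id)
        while n.parent_id != -1:
            p = self.node(n.parent_id)
            if not (n.type_code == SOMA and p.type_code == SOMA):
                d += float(np.linalg.norm(n.position - p.position))
            n = p
        return d

    def total_dendritic_length(self) -> float:
        """Summed length of all dendritic (type 3/4) edges, in millimeters.

        Soma-soma edges and the axon are excluded; the edge joining a
        dendrite's first node to a soma node counts as dendritic.
        """
        total = 0.0
        for n in self.nodes:
            if n.parent_id != -1 and n.type_code in DENDRITE_TYPES:
                total += self.edge_length(n.node_id)
        return total / 1000.0

    def trunk_node_ids(self) -> list[int]:
        """Apical-trunk node ids from labels, or inferred if unlabelled.

        Inference walks from the soma along the apical subtree, at every
        branch point following the thickest child, until a terminal node.
        """
        tagged = [i for i in (n.node_id for n in self.nodes) if self.labels.get(i) == "trunk"]
        if tagged:
            return tagged
        # infer: start at the apical child of the soma with the largest radius
        start = None
        for sid in self.soma_ids:
            for c in self.children(sid):
                cn = self.node(c)
                if cn.type_code == APICAL and (start is None or cn.radius > self.node(start).radius):
                    start = c
        if start is None:
            return []
        ids = []
        cur = start
        while True:
            ids.append(cur)
            kids = [c for c in self.children(cur) if self.node(c).type_code == APICAL]
            if not kids:
                break
            cur = max(kids, key=lambda c: (self.node(c).radius, -c))
        return ids

    # -- sections -----------------------------------------------------------

    def sections(self) -> list[Section]:
        """Decompose the dendritic arbor into maximal unbranched runs.

        The soma itself is section 0 (type 1); every other section starts at
        a child of a branch point (or of the soma) and runs through
        single-child nodes to the next branch point or terminal.
        """
        trunk = set(self.trunk_node_ids())
        soma_ids = set(self.soma_ids)
        sections: list[Section] = [
            Section(
                section_id=0,
                node_ids=[i for i in self.soma_ids],
                anchor_id=self.soma_ids[0],
                parent_section=None,
                type_code=SOMA,
                length=0.0,
                is_trunk=False,
                is_terminal=False,
            )
        ]
        # section starts: non-soma nodes whose parent is soma or a branch point
        owner: dict[int, int] = {}  # node_id -> section_id (for non-soma nodes)
        for n in self.nodes:
            if n.type_code == SOMA or n.parent_id == -1:
                continue
            parent = self.node(n.parent_id)
            parent_is_fork = (
                parent.type_code == SOMA
                or len([c for c in self.children(parent.node_id)
                        if self.node(c).type_code != SOMA]) > 1
            )
            label_boundary = self.labels.get(n.node_id) != self.labels.get(parent.node_id)
            if parent_is_fork or label_boundary or parent.node_id not in owner:
                chain = [n.node_id]
                cur = n.node_id
                while True:
                    kids = [c for c in self.children(cur) if self.node(c).type_code != SOMA]
                    if len(kids) != 1:
                        break
                    # a label boundary (e.g. trunk -> oblique after the other
                    # branch of a fork was pruned away) still ends the section,
                    # so labelled structures never merge with their neighbours
                    if self.labels.get(kids[0]) != self.labels.get(cur):
                        break
                    cur = kids[0]
                    chain.append(cur)
                length = sum(self.edge_length(i) for i in chain)
                sec = Section(
                    section_id=len(sections),
                    node_ids=chain,
                    anchor_id=n.parent_id,
                    parent_section=None,  # resolved below
                    type_code=n.type_code,
                    length=length,
                    is_trunk=all(i in trunk for i in chain) and bool(trunk),
                    is_terminal=not [
                        c for c in self.children(chain[-1]) if self.node(c).type_code != SOMA
                    ],
                )
                sections.append(sec)
                for i in chain:
                    owner[i] = sec.section_id
        for sec in sections[1:]:
            sec.parent_section = 0 if sec.anchor_id in soma_ids else owner[sec.anchor_id]
        return sections

    # -- convenience --------------------------------------------------------

    def subtree(self, keep_ids: set[int]) -> "MorphTree":
        """New tree restricted to ``keep_ids`` (must be ancestor-closed)."""
        nodes = [n for n in self.nodes if n.node_id in keep_ids]
        labels = {i: t for i, t in self.labels.items() if i in keep_ids}
        return MorphTree(nodes, labels)

    def morphometry(self) -> pd.DataFrame:
        """Per-section report: id, length, midpoint path/radial distance, diameter."""
        rows = []
        for sec in self.sections():
            if sec.type_code == SOMA:
                continue
            chain = [sec.anchor_id] + sec.node_ids
            pts = np.array([self.node(i).position for i in chain])
            radii = np.array([self.node(i).radius for i in chain])
            arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
            mid = arc[-1] / 2.0
            pos = _interp_vec(arc, pts, mid)
            rad = float(np.interp(mid, arc, radii))
            rows.append(
                dict(
                    section_id=sec.section_id,
                    length_um=sec.length,
                    path_um=self.path_distance(sec.anchor_id) + mid,
                    radial_um=float(np.linalg.norm(pos - self.soma_centroid)),
                    diameter_um=2.0 * rad,
                    type_code=sec.type_code,
                    is_trunk=sec.is_trunk,
                    is_terminal=sec.is_terminal,
                )
            )
        return pd.DataFrame(rows)


def _interp_vec(arc: np.ndarray, pts: np.ndarray, s: float) -> np.ndarray:
    return np.array([np.interp(s, arc, pts[:, k]) for k in range(pts.shape[1])])


# -- SWC I/O ----------------------------------------------------------------


def read_swc(path) -> MorphTree:
    """Parse a standard 7-column SWC file into a validated :class:`MorphTree`.

    Raises :class:`SwcParseError` with the offending line number on malformed
    content and :class:`StructuralError` on tree violations (orphan parents,
    non-positive radii, multiple roots).
    """
    nodes: list[MorphNode] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(f"expected 7 columns, got {len(parts)}", lineno)
            try:
                nid = int(parts[0])
                tcode = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(str(exc), lineno) from None
            if nid <= 0:
                raise SwcParseError(f"non-positive node id {nid}", lineno)
            nodes.append(MorphNode(nid, tcode, x, y, z, r, pid))
    return MorphTree(nodes)


def write_swc(tree: MorphTree, path) -> dict[int, int]:
    """Write standard SWC; returns the old-id -> new-id renumbering map.

    Node ids are renumbered contiguously from 1 in topological order so the
    output is valid for any consumer; read(write(tree)) reproduces the tree
    node-for-node up to that renumbering (identity for already-contiguous
    trees).
    """
    if not tree.nodes:
        raise StructuralError("refusing to write an empty morphology")
    mapping = {n.node_id: i + 1 for i, n in enumerate(tree.nodes)}
    with open(path, "w") as fh:
        fh.write("# SWC written by dendromaps\n")
        fh.write("# id type x y z radius parent\n")
        for n in tree.nodes:
            pid = -1 if n.parent_id == -1 else mapping[n.parent_id]
            fh.write(
                f"{mapping[n.node_id]} {n.type_code} {n.x:.6g} {n.y:.6g} "
                f"{n.z:.6g} {n.radius:.6g} {pid}\n"
            )
    return mapping


# -- spatial functions -------------------------------------------------------


def total_dendritic_length(tree: MorphTree) -> float:
    """Total dendritic length in mm (module-level alias)."""
    return tree.total_dendritic_length()


def radial_distance(tree: MorphTree, node_id: int) -> float:
    return tree.radial_distance(node_id)


def path_distance(tree: MorphTree, node_id: int) -> float:
    return tree.path_distance(node_id)


def space_constant_100(diameter: float, ra: float, cm: float, freq: float = 100.0) -> float:
    """AC space constant lambda_f in um.

    lambda_f = 1e5 * sqrt(d / (4 pi f R_a C_m)) with d in um, R_a in Ohm*cm,
    C_m in uF/cm^2 and f in Hz.  At high frequency the membrane impedance is
    dominated by capacitance, which makes lambda_f independent of R_m; 100 Hz
    is the conventional evaluation point for the d_lambda discretization
    rule.
    """
    if diameter <= 0 or ra <= 0 or cm <= 0 or freq <= 0:
        raise ValueError("space_constant_100 requires strictly positive arguments")
    return 1e5 * math.sqrt(diameter / (4.0 * math.pi * freq * ra * cm))


# -- discretization ----------------------------------------------------------


class CompartmentGrid:
    """Discretized morphology: ordered segments with parent links.

    Segment 0 is the soma.  Segments are in topological order (parent index
    < own index), which the cable solver relies on for its linear-time tree
    elimination.
    """

    def __init__(self, tree: MorphTree, segments: list[Segment]):
        self.tree = tree
        self.segments = segments
        sec_ids = {}
        for s in segments:
            sec_ids.setdefault(s.section_id, []).append(s.index)
        self._by_section = sec_ids

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def soma_index(self) -> int:
        return 0

    def section_segments(self, section_id: int) -> list[int]:
        return self._by_section[section_id]

    def trunk_indices(self) -> list[int]:
        """Trunk segment indices ordered by path distance; soma first."""
        idx = [s.index for s in self.segments if s.is_trunk]
        idx.sort(key=lambda i: self.segments[i].path_distance)
        return [self.soma_index] + idx

    def locate(self, distance: float, kind: str = "radial", trunk_only: bool = True) -> int:
        """Index of the segment whose midpoint is nearest ``distance`` (um).

        ``kind`` selects the coordinate ('radial' or 'path'); by default only
        somatoapical trunk segments (plus the soma) are candidates, matching
        the convention that measurement sites sit on the trunk.
        """
        if kind not in ("radial", "path"):
            raise ValueError("kind must be 'radial' or 'path'")
        cands = self.trunk_indices() if trunk_only else [s.index for s in self.segments]
        key = (lambda i: self.segments[i].radial_distance) if kind == "radial" else (
            lambda i: self.segments[i].path_distance
        )
        return min(cands, key=lambda i: (abs(key(i) - distance), i))

    def dendritic_indices(self) -> list[int]:
        return [s.index for s in self.segments if s.type_code in DENDRITE_TYPES]


def _frustum_area(r0: float, r1: float, length: float) -> float:
    slant = math.sqrt(length * length + (r1 - r0) ** 2)
    return math.pi * (r0 + r1) * slant


def _odd_segment_count(length: float, lam100: float, d_lambda: float) -> int:
    if length <= 0:
        return 1
    n = int(math.floor(length / (d_lambda * lam100))) + 1
    if n % 2 == 0:
        n += 1
    # guard the strict inequality L/n < d_lambda * lam100
    while length / n >= d_lambda * lam100:
        n += 2
    return n


def compartmentalize(
    tree: MorphTree,
    ra_at=None,
    cm: float = 1.0,
    d_lambda: float = 0.1,
) -> CompartmentGrid:
    """Discretize every section into the smallest odd number of equal segments
    satisfying the d_lambda rule.

    ``ra_at`` is a callable mapping radial distance (um) to axial resistivity
    (Ohm*cm); it defaults to a uniform 70 Ohm*cm.  lambda_100 for a section
    uses the section's length-weighted mean diameter and the resistivity at
    the section midpoint.  Spatial biophysical profiles are later evaluated
    at segment midpoints, which the odd counts guarantee to include an
    on-center point per section.
    """
    if ra_at is None:
        ra_at = lambda x: 70.0  # noqa: E731
    if not (0 < d_lambda <= 1):
        raise ValueError("d_lambda must be in (0, 1]")
    sections = tree.sections()
    centroid = tree.soma_centroid
    segments: list[Segment] = []

    # soma segment: cylinder equivalent (single node -> L = 2r convention)
    soma_nodes = [tree.node(i) for i in tree.soma_ids]
    if len(soma_nodes) == 1:
        r = soma_nodes[0].radius
        soma_len, soma_diam, soma_area = 2 * r, 2 * r, 2 * math.pi * r * 2 * r
    else:
        pts = np.array([n.position for n in soma_nodes])
        radii = np.array([n.radius for n in soma_nodes])
        seglens = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        soma_len = float(seglens.sum())
        soma_diam = float(2 * radii.mean())
        soma_area = float(
            sum(_frustum_area(radii[i], radii[i + 1], seglens[i]) for i in range(len(seglens)))
        )
        if soma_area <= 0:  # degenerate coincident soma points
            soma_area = 2 * math.pi * radii.mean() * 2 * radii.mean()
    segments.append(
        Segment(0, 0, -1, soma_len, soma_diam, soma_area, 0.0, 0.0, SOMA, False)
    )
    sec_last_seg = {0: 0}

    for sec in sections:
        if sec.type_code == SOMA:
            continue
        chain = [sec.anchor_id] + sec.node_ids
        pts = np.array([tree.node(i).position for i in chain])
        radii = np.array([tree.node(i).radius for i in chain])
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        L = float(arc[-1])
        if L <= 0:  # zero-length section collapses onto its anchor
            sec_last_seg[sec.section_id] = sec_last_seg[sec.parent_section]
            continue
        # length-weighted mean diameter over the chain
        edge_mid_d = radii[:-1] + radii[1:]  # = 2 * mean radius per edge
        edge_len = np.diff(arc)
        mean_diam = float((edge_mid_d * edge_len).sum() / L)
        mid_radial = float(
            np.linalg.norm(_interp_vec(arc, pts, L / 2.0) - centroid)
        )
        lam = space_constant_100(mean_diam, float(ra_at(mid_radial)), cm)
        n = _odd_segment_count(L, lam, d_lambda)
        seg_len = L / n
        path0 = tree.path_distance(sec.anchor_id)
        parent_seg = sec_last_seg[sec.parent_section]
        for k in range(n):
            s0, s1 = k * seg_len, (k + 1) * seg_len
            smid = 0.5 * (s0 + s1)
            pos = _interp_vec(arc, pts, smid)
            diam = 2.0 * float(np.interp(smid, arc, radii))
            # frustum area integrated over the span using the node radii profile
            sub = np.unique(np.concatenate([[s0, s1], arc[(arc > s0) & (arc < s1)]]))
            area = 0.0
            for a0, a1 in zip(sub[:-1], sub[1:]):
                r0 = float(np.interp(a0, arc, radii))
                r1 = float(np.interp(a1, arc, radii))
                area += _frustum_area(r0, r1, a1 - a0)
            idx = len(segments)
            segments.append(
                Segment(
                    index=idx,
                    section_id=sec.section_id,
                    parent_index=parent_seg,
                    length=seg_len,
                    diameter=diam,
                    area=area,
                    path_distance=path0 + smid,
                    radial_distance=float(np.linalg.norm(pos - centroid)),
                    type_code=sec.type_code,
                    is_trunk=sec.is_trunk,
                )
            )
            parent_seg = idx
        sec_last_seg[sec.section_id] = parent_seg

    return CompartmentGrid(tree, segments)
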