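"""Dendritic atrophy via uniform pruning across radial strata.

Atrophied trees are strict subtrees of the base reconstruction: pruning
removes whole terminal sections only, never adds or reroutes nodes, so any
surviving location keeps its exact path distance, radial distance and
diameter across the whole series (which is what makes same-location
comparisons across atrophy levels meaningful).

"Uniform across dendritic strata" is implemented over concentric radial-
distance bins (default width 50 um, mirroring hippocampal laminae): every
removal step targets the stratum whose removed share of *prunable* length
lags the global removed share most, and removes its longest terminal
section that still fits the remaining removal budget.  The soma and apical
trunk are protected by default, so the most atrophied members collapse
toward the bare trunk.  Whole-section removal cannot hit a length target
exactly; achieved lengths are kept within 0.1 mm of target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .morphology import DENDRITE_TYPES, MorphTree, Section

TOLERANCE_MM = 0.1


@dataclass
class PruneRecord:
    """Provenance for one series member: what was removed to reach it."""

    target_mm: float
    achieved_mm: float
    removed_node_ids: list[int]
    removed_sections: list[dict]  # section id, length_um, stratum


@dataclass
class PruneSeries:
    """Ordered atrophy series: (length mm, tree) pairs plus provenance."""

    members: list[tuple[float, MorphTree]]
    provenance: list[PruneRecord]
    stratum_width: float

    def __len__(self) -> int:
        return len(self.members)

    def lengths(self) -> list[float]:
        return [round(t.total_dendritic_length(), 6) for _, t in self.members]


def _section_stratum(tree: MorphTree, sec: Section, width: float) -> int:
    """Stratum of a section = radial bin of its arc midpoint."""
    chain = [sec.anchor_id] + sec.node_ids
    arc = np.concatenate(
        [[0.0], np.cumsum([tree.edge_length(i) for i in sec.node_ids])]
    )
    mid_i = int(np.searchsorted(arc, arc[-1] / 2.0))
    return int(tree.radial_distance(chain[min(mid_i, len(chain) - 1)]) // width)


def _edge_strata_length(tree: MorphTree, node_ids, width: float) -> dict[int, float]:
    """Per-stratum length of the given nodes' parent edges (edge midpoint bin)."""
    out: dict[int, float] = {}
    centroid = tree.soma_centroid
    for nid in node_ids:
        n = tree.node(nid)
        if n.parent_id == -1 or n.type_code not in DENDRITE_TYPES:
            continue
        p = tree.node(n.parent_id)
        mid = 0.5 * (n.position + p.position)
        stratum = int(np.linalg.norm(mid - centroid) // width)
        out[stratum] = out.get(stratum, 0.0) + tree.edge_length(nid)
    return out


def _protected_ids(tree: MorphTree, protected_sections: set[int] | None) -> set[int]:
    """Node ids that may never be removed: soma, trunk, and extra sections."""
    keep = set(tree.soma_ids) | set(tree.trunk_node_ids())
    if protected_sections:
        for sec in tree.sections():
            if sec.section_id in protected_sections:
                keep.update(sec.node_ids)
    return keep


def prune_to_length(
    tree: MorphTree,
    target_mm: float,
    stratum_width: float = 50.0,
    protected_sections: set[int] | None = None,
    _return_record: bool = False,
):
    """Subtree of ``tree`` with total dendritic length within 0.1 mm of target.

    Iteratively removes whole unprotected terminal sections, always from the
    stratum most under-pruned relative to the uniform quota (quota and
    shares computed over prunable length; ties broken by smallest section
    id).  Raises :class:`ConfigurationError` when the protected skeleton
    alone exceeds the target by more than the tolerance; a target at or
    above the current length is a no-op.
    """
    current_mm = tree.total_dendritic_length()
    if target_mm >= current_mm - 1e-9:
        record = PruneRecord(target_mm, current_mm, [], [])
        return (tree, record) if _return_record else tree

    protected = _protected_ids(tree, protected_sections)
    work = tree
    removal_um = (current_mm - target_mm) * 1000.0
    tol_um = TOLERANCE_MM * 1000.0

    # quota reference: prunable length per stratum of the *input* tree
    all_ids = [n.node_id for n in tree.nodes]
    prunable_ids = [i for i in all_ids if i not in protected]
    prunable_by_stratum = _edge_strata_length(tree, prunable_ids, stratum_width)
    prunable_total = sum(prunable_by_stratum.values())
    if prunable_total < removal_um - tol_um:
        raise ConfigurationError(
            f"target {target_mm} mm below the protected skeleton "
            f"({current_mm - prunable_total / 1000.0:.3f} mm)"
        )

    removed_by_stratum: dict[int, float] = {s: 0.0 for s in prunable_by_stratum}
    removed_nodes: list[int] = []
    removed_secs: list[dict] = []
    removed_um = 0.0

    while removal_um - removed_um > tol_um:
        budget = removal_um - removed_um
        sections = work.sections()
        candidates = []  # (stratum, section)
        for sec in sections:
            if sec.type_code not in DENDRITE_TYPES or not sec.is_terminal:
                continue
            if any(i in protected for i in sec.node_ids):
                continue
            if sec.length > budget + tol_um:
                continue
            candidates.append((_section_stratum(work, sec, stratum_width), sec))
        if not candidates:
            break
        global_frac = (removed_um + 1e-9) / prunable_total
        # deficit of each stratum relative to the uniform quota
        def deficit(stratum: int) -> float:
            avail = prunable_by_stratum.get(stratum, 0.0)
            if avail <= 0:
                return -np.inf
            return global_frac - removed_by_stratum.get(stratum, 0.0) / avail

        best = max(
            candidates,
            key=lambda cs: (deficit(cs[0]), cs[1].length, -cs[1].section_id),
        )
        stratum, sec = best
        for s_bin, ln in _edge_strata_length(work, sec.node_ids, stratum_width).items():
            removed_by_stratum[s_bin] = removed_by_stratum.get(s_bin, 0.0) + ln
        removed_um += sec.length
        removed_nodes.extend(sec.node_ids)
        removed_secs.append(
            dict(section_id=sec.section_id, length_um=sec.length, stratum=stratum)
        )
        keep = {n.node_id for n in work.nodes} - set(sec.node_ids)
        work = work.subtree(keep)

    achieved = work.total_dendritic_length()
    if abs(achieved - target_mm) > TOLERANCE_MM + 1e-9:
        raise ConfigurationError(
            f"could not reach {target_mm} mm within {TOLERANCE_MM} mm "
            f"(achieved {achieved:.3f} mm); terminal sections too coarse"
        )
    record = PruneRecord(target_mm, achieved, removed_nodes, removed_secs)
    return (work, record) if _return_record else work


def generate_prune_series(
    tree: MorphTree,
    step_mm: float = 1.0,
    floor_mm: float = 1.0,
    stratum_width: float = 50.0,
    protected_sections: set[int] | None = None,
) -> PruneSeries:
    """Chained atrophy series: each member pruned from its predecessor.

    Targets run {L0, L0 - step, ...} down to the last value >= floor; a
    17.5 mm base with 1 mm steps yields 17 members (17.5 ... 1.5 mm).
    """
    length0 = tree.total_dendritic_length()
    if length0 <= floor_mm:
        raise ConfigurationError("base tree is already at or below the floor")
    targets = [length0]
    while targets[-1] - step_mm >= floor_mm - 1e-9:
        targets.append(targets[-1] - step_mm)
    members = [(length0, tree)]
    provenance = [PruneRecord(length0, length0, [], [])]
    current = tree
    for target in targets[1:]:
        current, record = prune_to_length(
            current, target, stratum_width, protected_sections, _return_record=True
        )
        members.append((record.achieved_mm, current))
        provenance.append(record)
    return PruneSeries(members, provenance, stratum_width)


def stratum_balance_audit(series: PruneSeries) -> pd.DataFrame:
    """Recompute per-stratum removed shares from provenance (brute force).

    For every stratum that held prunable length in the base tree, reports
    the cumulative removed fraction after the last member against the global
    removed fraction, plus the coarsest removable unit (longest removed
    section) as the attainable granularity.
    """
    base = series.members[0][1]
    protected = _protected_ids(base, None)
    prunable_ids = [n.node_id for n in base.nodes if n.node_id not in protected]
    avail = _edge_strata_length(base, prunable_ids, series.stratum_width)
    removed: dict[int, float] = {s: 0.0 for s in avail}
    longest: dict[int, float] = {s: 0.0 for s in avail}
    for record in series.provenance:
        per = _edge_strata_length(base, record.removed_node_ids, series.stratum_width)
        for s, ln in per.items():
            removed[s] = removed.get(s, 0.0) + ln
        for sec in record.removed_sections:
            s = sec["stratum"]
            longest[s] = max(longest.get(s, 0.0), sec["length_um"])
    total_avail = sum(avail.values())
    total_removed = sum(removed.values())
    global_frac = total_removed / total_avail if total_avail else 0.0
    rows = []
    for s in sorted(avail):
        if avail[s] <= 0:
            continue
        frac = removed[s] / avail[s]
        rows.append(
            dict(
                stratum=s,
                prunable_um=avail[s],
                removed_um=removed[s],
                removed_frac=frac,
                global_frac=global_frac,
                deviation=frac - global_frac,
                granularity_frac=max(longest.get(s, 0.0), 0.0) / avail[s],
            )
        )
    return pd.DataFrame(rows)
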