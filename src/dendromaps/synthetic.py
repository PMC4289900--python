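"""Stylized CA1-pyramidal-like morphology generator.

Emulates the gross architecture of a reconstructed CA1 pyramidal cell: a
compact soma at the origin, a straight apical trunk of ~450 um with a
tapering diameter (4 -> 1 um by default), oblique branches of stochastic
length attached along the trunk, and a basal binary tree below the soma.
Total dendritic length is controlled exactly: oblique and basal branch
lengths are drawn from the configured distributions and then rescaled so
the tree hits the target length (17.5 mm by default, the scale of a full
CA1 reconstruction), which makes the published accession unnecessary for
exercising the pipeline.

Branch lengths and topology are set analytically; the 3-D embedding
(branch azimuths) is cosmetic, so path lengths and diameters -- the
quantities the electrical model depends on -- are exact by construction.
Trees are fully reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .morphology import APICAL, BASAL, SOMA, MorphNode, MorphTree


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters (lengths um unless noted)."""

    target_total_length: float = 17.5  # mm
    trunk_length: float = 450.0  # radial extent of the trunk tip from the soma
    # real CA1 trunks meander: path length exceeds radial extent roughly
    # twofold, which sets the electrotonic separation of the distal tree;
    # the trunk is embedded as a gentle helix with this path/radial ratio
    trunk_tortuosity: float = 2.0
    trunk_helix_radius: float = 40.0
    trunk_diameter_start: float = 4.0
    trunk_diameter_end: float = 0.5
    trunk_node_spacing: float = 10.0
    oblique_mean_length: float = 120.0
    oblique_sd_length: float = 40.0
    oblique_min_length: float = 30.0
    oblique_diameter: float = 0.8
    # obliques attach along essentially the whole trunk (radial span), as in
    # CA1 reconstructions; the distal ones place prunable membrane inside
    # the high-density end of the HCN gradient
    oblique_zone: tuple[float, float] = (40.0, 400.0)
    oblique_branch_prob: float = 0.35  # chance an oblique bifurcates once
    basal_fraction: float = 0.3  # share of non-trunk length in the basal tree
    basal_stems: int = 3  # primary basal dendrites leaving the soma
    basal_max_span: float = 300.0  # radial depth of the basal field
    basal_branch_length: float = 120.0  # preferred branch length; depth adapts
    basal_diameter: float = 1.0
    # apical tuft: the distal arbor beyond the trunk tip (stratum
    # lacunosum-moleculare), sitting inside the high-density end of the HCN
    # gradient; its share is taken from the apical (non-basal) budget
    tuft_fraction: float = 0.35
    tuft_max_span: float = 250.0  # radial depth of the tuft zone beyond the trunk tip
    tuft_branch_length: float = 120.0  # preferred branch length; depth adapts
    tuft_diameter: float = 0.6
    soma_radius: float = 10.0
    node_spacing: float = 10.0
    seed: int = 1

    def __post_init__(self):
        trunk_path = self.trunk_length * max(self.trunk_tortuosity, 1.0)
        if self.target_total_length * 1000.0 < trunk_path:
            raise ConfigurationError("target length shorter than the apical trunk path")
        if min(self.trunk_length, self.oblique_mean_length, self.soma_radius) <= 0:
            raise ConfigurationError("all lengths must be positive")
        if not 0.0 <= self.basal_fraction < 1.0:
            raise ConfigurationError("basal_fraction must be in [0, 1)")


class _Builder:
    def __init__(self):
        self.nodes: list[MorphNode] = []
        self.labels: dict[int, str] = {}

    def add(self, type_code, pos, radius, parent_id, label=None) -> int:
        nid = len(self.nodes) + 1
        self.nodes.append(
            MorphNode(nid, type_code, float(pos[0]), float(pos[1]), float(pos[2]),
                      float(radius), parent_id)
        )
        if label:
            self.labels[nid] = label
        return nid

    def add_straight(self, type_code, start, direction, length, radius0, radius1,
                     spacing, parent_id, label=None) -> int:
        """Chain of nodes along ``direction``; returns the distal node id."""
        direction = np.asarray(direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
        n = max(int(math.ceil(length / spacing)), 1)
        pid = parent_id
        for k in range(1, n + 1):
            s = length * k / n
            pos = np.asarray(start) + direction * s
            r = radius0 + (radius1 - radius0) * (s / length)
            pid = self.add(type_code, pos, r, pid, label)
        return pid


def generate_stylized_ca1(params: SynthParams = SynthParams()) -> MorphTree:
    """Build a stylized CA1 tree whose total dendritic length is within 2%
    of ``params.target_total_length`` (exact up to floating point, since
    branch lengths are rescaled analytically)."""
    rng = np.random.default_rng(params.seed)
    target_um = params.target_total_length * 1000.0
    b = _Builder()

    # soma: three type-1 nodes, radius-weighted centroid at the origin
    r = params.soma_radius
    root = b.add(SOMA, (0.0, 0.0, 0.0), r, -1)
    b.add(SOMA, (0.0, -r, 0.0), 0.8 * r, root)
    top = b.add(SOMA, (0.0, r, 0.0), 0.8 * r, root)

    # apical trunk: helix along +y whose path length is tortuosity x radial
    # extent; the climb rate keeps radial distance ~ arc/tortuosity so the
    # radial parameter profiles sample the trunk exactly as in a meandering
    # reconstruction
    spacing = params.trunk_node_spacing
    tort = max(params.trunk_tortuosity, 1.0)
    trunk_path = params.trunk_length * tort
    n_trunk = max(int(math.ceil(trunk_path / spacing)), 2)
    climb = 1.0 / tort
    rho = params.trunk_helix_radius if tort > 1.0 else 0.0
    omega = math.sqrt(max(1.0 - climb * climb, 0.0)) / rho if rho > 0 else 0.0
    pid = root
    trunk_ids: list[int] = []
    trunk_arc: list[float] = []
    for k in range(1, n_trunk + 1):
        s = trunk_path * k / n_trunk
        frac = s / trunk_path
        rad = 0.5 * (
            params.trunk_diameter_start
            + (params.trunk_diameter_end - params.trunk_diameter_start) * frac
        )
        if rho > 0:
            # unit-speed helix starting at the origin: lateral circle of
            # radius rho entered smoothly via a (cos-1, sin) parametrization
            pos = (rho * (math.cos(omega * s) - 1.0), climb * s, rho * math.sin(omega * s))
        else:
            pos = (0.0, s, 0.0)
        pid = b.add(APICAL, pos, rad, pid, "trunk")
        trunk_ids.append(pid)
        trunk_arc.append(s)

    remaining = target_um - trunk_path
    basal_budget = params.basal_fraction * remaining
    apical_budget = remaining - basal_budget
    tuft_budget = params.tuft_fraction * apical_budget
    oblique_budget = apical_budget - tuft_budget

    # obliques: lateral branches in the xz plane, lengths rescaled to budget
    if oblique_budget > 0:
        n_obl = max(int(round(oblique_budget / params.oblique_mean_length)), 1)
        lengths = rng.normal(params.oblique_mean_length, params.oblique_sd_length, n_obl)
        lengths = np.clip(lengths, params.oblique_min_length, None)
        lengths *= oblique_budget / lengths.sum()
        # oblique_zone is a radial-distance span; trunk arc ~ radial * tortuosity
        attach = np.sort(rng.uniform(*params.oblique_zone, n_obl)) * tort
        azimuth = rng.uniform(0.0, 2.0 * np.pi, n_obl)
        branches = rng.random(n_obl) < params.oblique_branch_prob
        for L, a, az, split in zip(lengths, attach, azimuth, branches):
            host = trunk_ids[int(np.argmin(np.abs(np.array(trunk_arc) - a)))]
            start = b.nodes[host - 1].position
            d = np.array([math.cos(az), 0.15, math.sin(az)])
            if split and L > 2.5 * params.oblique_min_length:
                stem = 0.4 * L
                tip = b.add_straight(APICAL, start, d, stem,
                                     params.oblique_diameter / 2,
                                     params.oblique_diameter / 2,
                                     params.node_spacing, host)
                mid = b.nodes[tip - 1].position
                for sign in (+1.0, -1.0):
                    d2 = np.array([math.cos(az + sign * 0.5), 0.15,
                                   math.sin(az + sign * 0.5)])
                    b.add_straight(APICAL, mid, d2, 0.5 * (L - stem),
                                   params.oblique_diameter / 2,
                                   params.oblique_diameter / 2,
                                   params.node_spacing, tip)
            else:
                b.add_straight(APICAL, start, d, L,
                               params.oblique_diameter / 2,
                               params.oblique_diameter / 2,
                               params.node_spacing, host)

    # apical tuft: binary tree fanning out above the trunk tip; depth adapts
    # so branch lengths stay near the preferred value and the tuft's radial
    # span stays within its zone (the distal ~250 um beyond the trunk tip)
    if tuft_budget > 0:
        depth = 1
        while depth < 8:
            n_b = 2 ** (depth + 1) - 2
            seg_len = tuft_budget / n_b
            if seg_len <= params.tuft_branch_length and depth * seg_len <= params.tuft_max_span:
                break
            depth += 1
        n_branches = 2 ** (depth + 1) - 2
        seg_len = tuft_budget / n_branches
        tip_pos = b.nodes[pid - 1].position
        frontier = [(pid, tip_pos, np.array([0.0, 1.0, 0.0]))]
        for lvl in range(1, depth + 1):
            new_frontier = []
            for pid_t, pos, d in frontier:
                for sign in (+1.0, -1.0):
                    az = rng.uniform(0.0, 2.0 * np.pi)
                    lateral = np.array([math.cos(az), 0.0, math.sin(az)])
                    d2 = d + sign * 0.5 * lateral
                    d2 /= np.linalg.norm(d2)
                    tip = b.add_straight(APICAL, pos, d2, seg_len,
                                         params.tuft_diameter / 2,
                                         params.tuft_diameter / 2,
                                         params.node_spacing, pid_t)
                    new_frontier.append((tip, b.nodes[tip - 1].position, d2))
            frontier = new_frontier

    # basal trees: several primary stems from the soma, each a binary tree
    # with depth adapted so branch lengths stay near the preferred value and
    # the basal field's radial span stays realistic
    if basal_budget > 0 and params.basal_stems > 0:
        per_stem = basal_budget / params.basal_stems
        depth = 1
        while depth < 8:
            n_b = 2 ** (depth + 1) - 2
            seg_len = per_stem / n_b
            if seg_len <= params.basal_branch_length and depth * seg_len <= params.basal_max_span:
                break
            depth += 1
        n_b = 2 ** (depth + 1) - 2
        seg_len = per_stem / n_b
        for stem in range(params.basal_stems):
            az0 = 2.0 * np.pi * stem / params.basal_stems
            d0 = np.array([0.5 * math.cos(az0), -1.0, 0.5 * math.sin(az0)])
            d0 /= np.linalg.norm(d0)
            # stems leave from the soma centroid so branch lengths are exact
            frontier = [(root, np.array([0.0, 0.0, 0.0]), d0)]
            for lvl in range(1, depth + 1):
                new_frontier = []
                for pid_b, pos, d in frontier:
                    for sign in (+1.0, -1.0):
                        az = rng.uniform(0.0, 2.0 * np.pi)
                        lateral = np.array([math.cos(az), 0.0, math.sin(az)])
                        d2 = d + sign * 0.45 * lateral
                        d2 /= np.linalg.norm(d2)
                        tip = b.add_straight(BASAL, pos, d2, seg_len,
                                             params.basal_diameter / 2,
                                             params.basal_diameter / 2,
                                             params.node_spacing, pid_b)
                        new_frontier.append((tip, b.nodes[tip - 1].position, d2))
                frontier = new_frontier

    tree = MorphTree(b.nodes, b.labels)
    achieved = tree.total_dendritic_length()
    if abs(achieved - params.target_total_length) > 0.02 * params.target_total_length:
        raise ConfigurationError(
            f"generated length {achieved:.3f} mm misses target "
            f"{params.target_total_length:.3f} mm by more than 2%"
        )
    return tree
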