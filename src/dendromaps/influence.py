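"""Influence fields of a localized HCN-conductance cluster.

A cluster of total conductance G (nS) dropped on the segment at path
distance x_i adds G / area to that segment's specific HCN density (i.e.,
the insertion is normalized by the host compartment's surface area).  For a
measurement M evaluated along the trunk coordinate x, the unnormalized
influence factor is

    IF_M(x; x_i) = |M_org(x) - M_new(x; x_i)| / M_org(x)

(M_org without, M_new with the cluster), the normalized influence field is
Lambda_M = IF_M / max_x IF_M, and the spatial extent of influence is the
area under either curve over the trunk path length [0, L_d] (trapezoid).

Both background configurations are supported: the passive model (the
cluster is the only active conductance) and the gradient model (the
cluster rides on top of the baseline HCN gradient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cable import build_cable_system
from .exceptions import ConfigurationError
from .measurements import ChirpStimulus, REDUCED_AMPLITUDES, chirp_profiles, measure_rin, resonance_measures
from .model import NeuronModel


@dataclass(frozen=True)
class ChannelCluster:
    """A point HCN-conductance cluster on the apical trunk.

    ``location_um`` is a path distance from the soma; ``total_conductance``
    is in nS and is applied as density = total / host-segment area.  When
    ``total_conductance`` is None, a physiologically scaled default is used:
    the gradient half-maximum density gbar_h(350 um) = 675 uS/cm^2 times the
    host segment's area.
    """

    location_um: float
    total_conductance: float | None = None  # nS

    def resolve_conductance(self, model: NeuronModel, seg_index: int) -> float:
        if self.total_conductance is not None:
            return self.total_conductance
        area = model.grid.segments[seg_index].area
        return 675.0 * area * 1e-5  # uS/cm^2 * um^2 -> nS


def default_cluster(model: NeuronModel) -> ChannelCluster:
    """Cluster at the center of the apical trunk (half its path length)."""
    trunk = model.grid.trunk_indices()[1:]
    if not trunk:
        raise ConfigurationError("model has no labelled apical trunk")
    tip = max(model.grid.segments[i].path_distance for i in trunk)
    return ChannelCluster(location_um=tip / 2.0)


def insert_cluster(model: NeuronModel, cluster: ChannelCluster) -> NeuronModel:
    """New model with the cluster's density added to the host segment.

    The original model is untouched; successive insertions are additive.
    The location must resolve to a trunk segment within the trunk extent.
    """
    trunk = model.grid.trunk_indices()[1:]
    if not trunk:
        raise ConfigurationError("model has no labelled apical trunk")
    tip = max(model.grid.segments[i].path_distance for i in trunk)
    if not 0.0 <= cluster.location_um <= tip + 1e-9:
        raise ConfigurationError(
            f"cluster at {cluster.location_um} um is beyond the trunk ({tip:.1f} um)"
        )
    seg = model.grid.locate(cluster.location_um, kind="path")
    g_total = cluster.resolve_conductance(model, seg)
    mech = model.mech.copy()
    area = model.grid.segments[seg].area
    mech.gh[seg] += g_total / area * 1e5  # nS / um^2 -> uS/cm^2
    system = build_cable_system(model.grid, mech, hold=model.hold_potential)
    return model.with_system(system, mech)


@dataclass
class InfluenceField:
    """Spatial influence profile of one cluster on one measurement."""

    table: pd.DataFrame  # columns: site, x_um, m_org, m_new, influence, lam
    measurement: str  # 'rin' | 'f_r'
    background: str  # 'passive' | 'gradient'
    cluster: ChannelCluster
    degenerate: bool = False  # max IF == 0: Lambda undefined, reported as 0

    def auc(self) -> tuple[float, float]:
        """(normalized, unnormalized) trapezoid AUC over trunk path length."""
        x = self.table["x_um"].to_numpy()
        auc_norm = float(np.trapezoid(self.table["lam"].to_numpy(), x))
        auc_unnorm = float(np.trapezoid(self.table["influence"].to_numpy(), x))
        return auc_norm, auc_unnorm


def _measure(model: NeuronModel, site: int, measurement: str,
             chirp: ChirpStimulus | None) -> float:
    if measurement == "rin":
        return measure_rin(model, site, amplitudes=REDUCED_AMPLITUDES)
    if measurement == "f_r":
        loc, _ = chirp_profiles(model, site, chirp=chirp)
        return resonance_measures(loc).f_r
    raise ConfigurationError(f"unsupported influence measurement {measurement!r}")


def influence_field(
    model: NeuronModel,
    cluster: ChannelCluster,
    measurement: str = "rin",
    sites: list[int] | None = None,
    chirp: ChirpStimulus | None = None,
) -> InfluenceField:
    """Influence field of ``cluster`` on ``measurement`` along the trunk.

    ``sites`` defaults to every trunk segment midpoint (plus the soma).  On
    a passive background the reference f_R sits at the band floor (0.5 Hz >
    0) at every site, so the division in IF is always well defined; sites
    with M_org = 0 would be excluded, which cannot occur for R_in or f_R.
    """
    background = "passive" if model.is_passive else "gradient"
    if sites is None:
        sites = model.grid.trunk_indices()
    perturbed = insert_cluster(model, cluster)
    rows = []
    for site in sites:
        m_org = _measure(model, site, measurement, chirp)
        m_new = _measure(perturbed, site, measurement, chirp)
        rows.append(
            dict(
                site=site,
                x_um=model.grid.segments[site].path_distance,
                m_org=m_org,
                m_new=m_new,
                influence=abs(m_org - m_new) / m_org if m_org != 0 else np.nan,
            )
        )
    table = pd.DataFrame(rows).dropna(subset=["influence"]).sort_values("x_um")
    peak = table["influence"].max()
    degenerate = not peak > 0
    table["lam"] = 0.0 if degenerate else table["influence"] / peak
    return InfluenceField(table.reset_index(drop=True), measurement, background,
                          cluster, degenerate)


def auc(field: InfluenceField) -> tuple[float, float]:
    return field.auc()


def arbor_influence_map(
    model: NeuronModel,
    cluster: ChannelCluster,
    measurement: str = "rin",
    sites: list[int] | None = None,
    chirp: ChirpStimulus | None = None,
) -> pd.DataFrame:
    """Unnormalized influence for every dendritic segment (trunk, obliques,
    basal), keyed by segment index -- the whole-arbor view of the field."""
    if sites is None:
        sites = [model.grid.soma_index] + model.grid.dendritic_indices()
    perturbed = insert_cluster(model, cluster)
    rows = []
    for site in sites:
        m_org = _measure(model, site, measurement, chirp)
        m_new = _measure(perturbed, site, measurement, chirp)
        seg = model.grid.segments[site]
        rows.append(
            dict(
                site=site,
                section_id=seg.section_id,
                path_um=seg.path_distance,
                radial_um=seg.radial_distance,
                is_trunk=seg.is_trunk or site == model.grid.soma_index,
                m_org=m_org,
                m_new=m_new,
                influence=abs(m_org - m_new) / m_org if m_org != 0 else np.nan,
            )
        )
    return pd.DataFrame(rows)
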