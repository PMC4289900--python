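"""Full-study orchestration: morphology -> atrophy series -> maps -> fields.

:func:`run_experiment` executes the whole protocol for a configuration:
obtain the base morphology (SWC file or synthetic), generate the chained
prune series, build the passive and (optionally) HCN-gradient models for
every member, evaluate the nine-measurement battery at the canonical trunk
sites (soma, ~150 um, ~300 um radial by default), compute constriction
ratios, and run the influence-field experiments.  Outputs are tidy CSV
tables plus a JSON summary with full provenance (config hash, seed,
package version); re-running the same configuration reproduces identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biophysics import HcnDistribution, HcnKinetics, PassiveProfile
from .exceptions import ConfigurationError
from .influence import ChannelCluster, default_cluster, influence_field
from .measurements import (
    ALL_MEASUREMENTS,
    ChirpStimulus,
    DEFAULT_AMPLITUDES,
    REDUCED_AMPLITUDES,
    map_over_locations,
    measure_rin,
    normalize_chirp_amplitude,
)
from .model import NeuronModel
from .morphology import MorphTree, read_swc, write_swc
from .pruning import generate_prune_series
from .synthetic import SynthParams, generate_stylized_ca1

log = logging.getLogger("dendromaps")


@dataclass
class ExperimentConfig:
    """Schema-validated study configuration (YAML/JSON friendly)."""

    swc_path: str | None = None
    synthetic: dict = field(default_factory=dict)  # SynthParams overrides
    seed: int = 1

    prune_step_mm: float = 1.0
    prune_floor_mm: float = 1.0
    stratum_width_um: float = 50.0

    passive: dict = field(default_factory=dict)  # PassiveProfile overrides
    hcn: dict | None = field(default_factory=dict)  # None -> passive only
    kinetics: dict = field(default_factory=dict)  # HcnKinetics overrides

    dt_ms: float = 0.1
    chirp_duration_s: float = 10.0
    chirp_f_end_hz: float = 25.0
    chirp_amplitude_pa: float = 50.0
    settle_ms: float = 200.0
    d_lambda: float = 0.1
    rin_reduced_range: bool = False

    site_radial_um: tuple[float, ...] = (0.0, 150.0, 300.0)

    influence_enabled: bool = True
    influence_members: int = 3  # evenly spaced members to analyze
    influence_sites: int = 12  # trunk sites per field
    influence_cluster_um: float | None = None  # None -> trunk center
    influence_cluster_ns: float | None = None  # None -> scaled default

    output_dir: str = "results"

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.swc_path is not None and not Path(cfg.swc_path).exists():
            raise ConfigurationError(f"SWC file not found: {cfg.swc_path}")
        if cfg.dt_ms <= 0 or cfg.chirp_duration_s <= 0:
            raise ConfigurationError("dt and chirp duration must be positive")
        return cfg

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["site_radial_um"] = list(self.site_radial_um)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class StudyResult:
    """All tables produced by one experiment run."""

    maps: pd.DataFrame  # member x site x background x 9 measurements
    length_functions: pd.DataFrame  # measurement vs length at fixed sites
    constriction: pd.DataFrame
    influence: pd.DataFrame
    provenance: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        # atomic-ish: write to temp names, then rename
        for name, df in [
            ("maps", self.maps),
            ("length_functions", self.length_functions),
            ("constriction", self.constriction),
            ("influence", self.influence),
        ]:
            tmp = out / f".{name}.csv.tmp"
            df.to_csv(tmp, index=False, float_format="%.8g")
            tmp.replace(out / f"{name}.csv")
        (out / "summary.json").write_text(json.dumps(self.provenance, indent=2))


def constriction_ratio(map_df: pd.DataFrame, proximal_label: str,
                       distal_label: str, measurement: str) -> float:
    """M(distal) / M(proximal) from a single member's measurement map."""
    prox = map_df.loc[map_df.site_label == proximal_label, measurement]
    dist = map_df.loc[map_df.site_label == distal_label, measurement]
    if prox.empty or dist.empty or prox.iloc[0] == 0:
        return float("nan")  # missing site or zero-valued reference -> gap
    return float(dist.iloc[0] / prox.iloc[0])


def _base_tree(cfg: ExperimentConfig) -> MorphTree:
    if cfg.swc_path:
        return read_swc(cfg.swc_path)
    params = SynthParams(**{"seed": cfg.seed, **cfg.synthetic})
    return generate_stylized_ca1(params)


def run_experiment(cfg: ExperimentConfig) -> StudyResult:
    """Execute the full study; see the module docstring."""
    t0 = time.time()
    rin_amps = REDUCED_AMPLITUDES if cfg.rin_reduced_range else DEFAULT_AMPLITUDES
    profile = PassiveProfile(**cfg.passive)
    kinetics = HcnKinetics(**cfg.kinetics)
    dist = HcnDistribution(**cfg.hcn) if cfg.hcn is not None else None

    tree = _base_tree(cfg)
    log.info("base morphology: %.3f mm dendritic length, %d nodes",
             tree.total_dendritic_length(), len(tree.nodes))
    series = generate_prune_series(
        tree, cfg.prune_step_mm, cfg.prune_floor_mm, cfg.stratum_width_um
    )
    log.info("prune series: %d members (%.2f .. %.2f mm)",
             len(series), series.members[0][0], series.members[-1][0])

    def build(member_tree, background_dist):
        return NeuronModel.build(
            member_tree, profile, background_dist, kinetics,
            d_lambda=cfg.d_lambda, dt=cfg.dt_ms, settle_time=cfg.settle_ms,
        )

    backgrounds = ["passive"] + (["gradient"] if dist is not None else [])
    labels = {f"{int(round(x))}um": x for x in cfg.site_radial_um}

    map_rows = []
    models: dict[tuple[int, str], NeuronModel] = {}
    base_rin_som: dict[str, float] = {}
    for mi, (length, member) in enumerate(series.members):
        for bg in backgrounds:
            model = build(member, dist if bg == "gradient" else None)
            models[(mi, bg)] = model
            amp = cfg.chirp_amplitude_pa
            if bg == "gradient":
                rin_som = measure_rin(model, model.grid.soma_index, amplitudes=rin_amps)
                if bg not in base_rin_som:
                    base_rin_som[bg] = rin_som
                amp = normalize_chirp_amplitude(
                    base_rin_som[bg], rin_som, cfg.chirp_amplitude_pa
                )
            chirp = ChirpStimulus(
                amplitude=amp, f_end=cfg.chirp_f_end_hz,
                duration=cfg.chirp_duration_s, dt=cfg.dt_ms,
            )
            sites = {lbl: model.grid.locate(x, kind="radial")
                     for lbl, x in labels.items()}
            mm = map_over_locations(model, list(sites.values()), chirp=chirp,
                                    rin_amplitudes=rin_amps)
            mm.insert(0, "site_label", list(sites.keys()))
            mm.insert(0, "background", bg)
            mm.insert(0, "length_mm", length)
            mm.insert(0, "member", mi)
            map_rows.append(mm)
            log.info("member %d (%.2f mm, %s): maps done [%.1f s]",
                     mi, length, bg, time.time() - t0)
    maps = pd.concat(map_rows, ignore_index=True)

    lf_rows = []
    for m in ALL_MEASUREMENTS:
        sub = maps[["member", "length_mm", "background", "site_label", m]].copy()
        sub = sub.rename(columns={m: "value"})
        sub["measurement"] = m
        lf_rows.append(sub)
    length_functions = pd.concat(lf_rows, ignore_index=True)

    proximal = min(labels, key=lambda k: labels[k])
    distal = max(labels, key=lambda k: labels[k])
    con_rows = []
    for (mi, length, bg), sub in maps.groupby(["member", "length_mm", "background"]):
        for m in ALL_MEASUREMENTS:
            con_rows.append(
                dict(member=mi, length_mm=length, background=bg, measurement=m,
                     ratio=constriction_ratio(sub, proximal, distal, m))
            )
    constriction = pd.DataFrame(con_rows)

    infl_rows = []
    if cfg.influence_enabled:
        n = len(series.members)
        pick = sorted({0, n - 1} | set(
            np.linspace(0, n - 1, cfg.influence_members).astype(int).tolist()
        ))[: max(cfg.influence_members, 2)]
        for mi in pick:
            length = series.members[mi][0]
            for bg in backgrounds:
                model = models[(mi, bg)]
                trunk = model.grid.trunk_indices()
                stride = max(len(trunk) // cfg.influence_sites, 1)
                sites = trunk[::stride]
                cluster = (
                    ChannelCluster(cfg.influence_cluster_um, cfg.influence_cluster_ns)
                    if cfg.influence_cluster_um is not None
                    else default_cluster(model)
                )
                chirp = ChirpStimulus(duration=cfg.chirp_duration_s,
                                      f_end=cfg.chirp_f_end_hz, dt=cfg.dt_ms)
                for meas in ("rin", "f_r"):
                    fld = influence_field(model, cluster, meas, sites, chirp=chirp)
                    a_norm, a_unnorm = fld.auc()
                    infl_rows.append(
                        dict(member=mi, length_mm=length, background=bg,
                             measurement=meas, cluster_um=cluster.location_um,
                             auc_norm_um=a_norm, auc_unnorm_um=a_unnorm,
                             degenerate=fld.degenerate)
                    )
                log.info("member %d (%s): influence fields done [%.1f s]",
                         mi, bg, time.time() - t0)
    influence = pd.DataFrame(infl_rows)

    provenance = dict(
        package="dendromaps",
        version=__version__,
        config=cfg.to_dict(),
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        n_members=len(series.members),
        member_lengths_mm=series.lengths(),
        runtime_s=round(time.time() - t0, 2),
    )
    return StudyResult(maps, length_functions, constriction, influence, provenance)
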