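"""Convenience container bundling morphology, mechanisms and cable system."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biophysics import (
    HcnDistribution,
    HcnKinetics,
    MechanismAssignment,
    PassiveProfile,
    assign_mechanisms,
)
from .cable import CableSystem, build_cable_system, settle
from .morphology import CompartmentGrid, MorphTree, compartmentalize


@dataclass
class NeuronModel:
    """A simulatable neuron: tree + grid + mechanisms + cable system.

    ``dt`` and ``settle_time`` are the model's default integration step and
    pre-measurement relaxation window (ms); measurement routines use them
    unless overridden.  The settled state is computed lazily and cached --
    every measurement on the same model reuses it.
    """

    tree: MorphTree
    grid: CompartmentGrid
    mech: MechanismAssignment
    system: CableSystem
    profile: PassiveProfile
    dist: HcnDistribution | None
    dt: float = 0.1
    v_init: float = -65.0
    settle_time: float = 200.0
    hold_potential: float | None = -65.0
    _settled: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @classmethod
    def build(
        cls,
        tree: MorphTree,
        profile: PassiveProfile = PassiveProfile(),
        dist: HcnDistribution | None = None,
        kinetics: HcnKinetics = HcnKinetics(),
        d_lambda: float = 0.1,
        dt: float = 0.1,
        v_init: float = -65.0,
        settle_time: float = 200.0,
        hold_potential: float | None = -65.0,
    ) -> "NeuronModel":
        grid = compartmentalize(tree, ra_at=profile.ra, cm=profile.cm, d_lambda=d_lambda)
        mech = assign_mechanisms(grid, profile, dist, kinetics)
        system = build_cable_system(grid, mech, hold=hold_potential)
        return cls(tree, grid, mech, system, profile, dist,
                   dt=dt, v_init=v_init, settle_time=settle_time,
                   hold_potential=hold_potential)

    @property
    def is_passive(self) -> bool:
        return bool(np.all(self.system.g_h == 0))

    def settled_state(self) -> tuple[np.ndarray, np.ndarray]:
        if self._settled is None:
            if self.is_passive and np.all(self.system.e_l == self.v_init):
                v = np.full(len(self.system), self.v_init)
                self._settled = (v, np.asarray(self.system.kinetics.m_inf(v)))
            else:
                self._settled = settle(
                    self.system, self.settle_time, self.dt, self.v_init
                )
        return self._settled

    def with_system(self, system: CableSystem, mech: MechanismAssignment) -> "NeuronModel":
        """Sibling model sharing geometry but with different mechanisms."""
        return NeuronModel(
            self.tree, self.grid, mech, system, self.profile, self.dist,
            dt=self.dt, v_init=self.v_init, settle_time=self.settle_time,
            hold_potential=self.hold_potential,
        )
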