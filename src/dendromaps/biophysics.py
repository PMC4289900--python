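"""Spatial biophysical profiles and HCN gating kinetics.

The model's passive parameters vary sigmoidally with radial distance x (um)
from the soma along the somatoapical arbor:

    R_m(x) = R_m^som + (R_m^end - R_m^som) / (1 + exp((250 - x)/50))   kOhm*cm^2
    R_a(x) = R_a^som + (R_a^end - R_a^som) / (1 + exp((250 - x)/50))   Ohm*cm

with R_m 55 -> 20 kOhm*cm^2 and R_a 70 -> 30 Ohm*cm between the soma and the
distal end of the apical trunk, C_m = 1 uF/cm^2 throughout.  These profiles
keep the local input resistance roughly uniform (~120 MOhm) along the trunk
of the full passive model.  The HCN (h) conductance density rises ~25-fold
along the same axis:

    gbar_h(x) = 50 * (1 + 25 / (1 + exp(-(x - 350)/15)))   uS/cm^2

Basal dendrites and the soma take the x = 0 values of all three profiles.

HCN gating uses a single first-order activation gate, hyperpolarization
activated: m_inf(V) = 1/(1 + exp((V - V_half)/k)) with V_half = -82 mV and
k = 9 mV, and a voltage-dependent time constant from a two-term exponential
rate expression peaking near -75 mV (60 ms at the 34 degC simulation
temperature, i.e. tau(-65 mV) ~ 51 ms, consistent with near-physiological
dendritic h-current recordings and with the theta-range resonance the
gradient produces).  A Q10 of 4.5 rescales tau when the simulation runs at
a different temperature than the kinetics reference.  Reversal E_h = -30 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import StructuralError
from .morphology import APICAL, SOMA, CompartmentGrid


def _sigmoid(z):
    # numerically safe logistic
    return 1.0 / (1.0 + np.exp(np.clip(z, -60.0, 60.0)))


@dataclass(frozen=True)
class PassiveProfile:
    """Sigmoidal passive-parameter profiles along the somatoapical axis."""

    rm_som: float = 55.0  # kOhm*cm^2
    rm_end: float = 20.0
    ra_som: float = 70.0  # Ohm*cm
    ra_end: float = 30.0
    half_distance: float = 250.0  # um
    slope: float = 50.0  # um
    cm: float = 1.0  # uF/cm^2
    e_pas: float = -65.0  # mV

    def __post_init__(self):
        if min(self.rm_som, self.rm_end, self.ra_som, self.ra_end, self.cm) <= 0:
            raise ValueError("resistivities and capacitance must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def rm(self, x):
        """R_m at radial distance x (um), in kOhm*cm^2."""
        return self.rm_som + (self.rm_end - self.rm_som) * _sigmoid(
            (self.half_distance - x) / self.slope
        )

    def ra(self, x):
        """R_a at radial distance x (um), in Ohm*cm."""
        return self.ra_som + (self.ra_end - self.ra_som) * _sigmoid(
            (self.half_distance - x) / self.slope
        )


@dataclass(frozen=True)
class HcnDistribution:
    """Sigmoidal somatoapical gradient of maximal HCN conductance density."""

    g_base: float = 50.0  # uS/cm^2 at the soma
    fold: float = 25.0  # distal increase factor
    half_distance: float = 350.0  # um
    slope: float = 15.0  # um

    def __post_init__(self):
        if self.g_base < 0 or self.fold < 0:
            raise ValueError("conductance parameters must be non-negative")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def gh(self, x):
        """gbar_h at radial distance x (um), in uS/cm^2."""
        return self.g_base * (1.0 + self.fold * _sigmoid(-(x - self.half_distance) / self.slope))


@dataclass(frozen=True)
class HcnKinetics:
    """First-order HCN activation gate with Q10 temperature scaling.

    tau(V) = tau_peak / (q_t * cosh((V - tau_vpeak)/tau_sigma)) where
    q_t = q10^((t_sim - t_ref)/10); the cosh form is the reciprocal of a
    symmetric two-term exponential rate sum.
    """

    v_half: float = -82.0  # mV
    k: float = 9.0  # mV, inverse slope (positive: activates on hyperpolarization)
    tau_peak: float = 60.0  # ms at t_ref
    tau_vpeak: float = -75.0  # mV
    tau_sigma: float = 17.0  # mV
    e_h: float = -30.0  # mV
    q10: float = 4.5
    t_ref: float = 34.0  # degC; defaults are quoted at simulation temperature
    t_sim: float = 34.0  # degC

    def __post_init__(self):
        if self.k <= 0 or self.q10 <= 0 or self.tau_peak <= 0 or self.tau_sigma <= 0:
            raise ValueError("k, q10 and tau parameters must be positive")

    @property
    def q_t(self) -> float:
        return self.q10 ** ((self.t_sim - self.t_ref) / 10.0)

    def m_inf(self, v):
        return _sigmoid((np.asarray(v, dtype=float) - self.v_half) / self.k)

    def tau(self, v):
        """Activation time constant in ms at the simulation temperature."""
        u = (np.asarray(v, dtype=float) - self.tau_vpeak) / self.tau_sigma
        return self.tau_peak / (np.cosh(np.clip(u, -60, 60)) * self.q_t)

    def dminf_dv(self, v):
        m = self.m_inf(v)
        return -m * (1.0 - m) / self.k


def rm_at(x, profile: PassiveProfile = PassiveProfile()):
    return profile.rm(x)


def ra_at(x, profile: PassiveProfile = PassiveProfile()):
    return profile.ra(x)


def gh_at(x, dist: HcnDistribution = HcnDistribution()):
    return dist.gh(x)


def hcn_activation(v, kin: HcnKinetics = HcnKinetics()):
    """(m_inf, tau_ms) of the HCN gate at membrane potential v (mV)."""
    return kin.m_inf(v), kin.tau(v)


@dataclass
class MechanismAssignment:
    """Per-segment specific parameters evaluated on a compartment grid.

    Apical segments are parameterized at their midpoint radial distance;
    somatic and basal segments take the somatic (x = 0) values of every
    profile, as do any non-apical compartments.
    """

    rm: np.ndarray  # kOhm*cm^2
    ra: np.ndarray  # Ohm*cm
    cm: np.ndarray  # uF/cm^2
    gh: np.ndarray  # uS/cm^2
    e_pas: float
    kinetics: HcnKinetics = field(default_factory=HcnKinetics)

    def copy(self) -> "MechanismAssignment":
        return MechanismAssignment(
            self.rm.copy(), self.ra.copy(), self.cm.copy(), self.gh.copy(),
            self.e_pas, self.kinetics,
        )


def assign_mechanisms(
    grid: CompartmentGrid,
    profile: PassiveProfile = PassiveProfile(),
    dist: HcnDistribution | None = None,
    kinetics: HcnKinetics = HcnKinetics(),
) -> MechanismAssignment:
    """Evaluate the spatial profiles on every segment of ``grid``.

    ``dist=None`` builds the passive model (gbar_h identically zero).  The
    assignment is a pure function of its inputs: the same grid and profiles
    always yield identical arrays.
    """
    n = len(grid)
    if n == 0:
        raise StructuralError("empty compartment grid")
    x = np.array(
        [
            s.radial_distance if s.type_code == APICAL else 0.0
            for s in grid.segments
        ]
    )
    rm = np.asarray(profile.rm(x), dtype=float)
    ra = np.asarray(profile.ra(x), dtype=float)
    cm = np.full(n, profile.cm, dtype=float)
    gh = np.asarray(dist.gh(x), dtype=float) if dist is not None else np.zeros(n)
    return MechanismAssignment(rm, ra, cm, gh, profile.e_pas, kinetics)
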