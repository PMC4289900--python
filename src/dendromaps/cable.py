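"""Branched-cable assembly and implicit time integration.

A :class:`CableSystem` holds absolute per-segment electrical quantities
derived from a :class:`~dendromaps.morphology.CompartmentGrid` and a
:class:`~dendromaps.biophysics.MechanismAssignment`: membrane capacitance,
leak and maximal HCN conductances (specific values times frustum area) and
the axial coupling conductance between neighbouring segment midpoints (the
series resistance of the two adjoining half-segments).

Internal units: mV, ms, pA, nS, pF -- a consistent set (pF*mV/ms = pA) that
avoids the underflow-prone uS/cm^2-to-absolute conversions.  1 mV / 1 pA =
1 GOhm, so impedances convert to MOhm with a factor of 1000.

Integration is Crank-Nicolson by default (``theta = 0.5``; ``theta = 1``
gives backward Euler as a first-order fallback) with an exact linear-time
tree solve per step (ordered elimination on the Hines structure).  The HCN
gate advances by the locally exact exponential (Rush-Larsen) rule using
m_inf and tau evaluated at the current voltage.  The stiffness of fine
spatial grids at small time steps rules out explicit schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import spsolve

from .biophysics import HcnKinetics, MechanismAssignment
from .exceptions import NumericalError, StructuralError
from .morphology import CompartmentGrid


@dataclass
class CableSystem:
    """Absolute electrical parameters of a discretized neuron."""

    parent: np.ndarray  # int32, parent segment index, -1 for the root (soma)
    g_ax: np.ndarray  # nS, coupling between each segment and its parent (0 at root)
    c: np.ndarray  # pF
    g_l: np.ndarray  # nS
    e_l: np.ndarray  # mV, per segment (balanced when holding at a set potential)
    g_h: np.ndarray  # nS (maximal)
    e_h: float  # mV
    kinetics: HcnKinetics
    grid: CompartmentGrid | None = None

    def __len__(self) -> int:
        return len(self.c)

    def copy(self) -> "CableSystem":
        return CableSystem(
            self.parent.copy(), self.g_ax.copy(), self.c.copy(), self.g_l.copy(),
            self.e_l.copy(), self.g_h.copy(), self.e_h, self.kinetics, self.grid,
        )


@dataclass
class SimProtocol:
    """Stimulation/recording protocol for :func:`simulate`.

    ``stimuli`` maps segment indices to current waveforms in pA sampled on
    the protocol's time base (``duration/dt + 1`` points); shorter waveforms
    are zero-padded.  ``settle_time`` is run (and discarded) before the
    stimulus window whenever the caller requests it via :func:`settle`.
    """

    duration: float  # ms
    dt: float = 0.025  # ms (25 us)
    v_init: float = -65.0  # mV
    temperature: float = 34.0  # degC
    stimuli: dict[int, np.ndarray] = field(default_factory=dict)
    record_sites: list[int] = field(default_factory=list)
    settle_time: float = 200.0  # ms

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt


@dataclass
class VoltageTrace:
    """Recorded membrane potentials: time (ms) x record sites (mV)."""

    time: np.ndarray
    voltages: np.ndarray  # shape (n_samples, n_sites)
    sites: list[int]

    def at(self, site: int) -> np.ndarray:
        return self.voltages[:, self.sites.index(site)]


def build_cable_system(
    grid: CompartmentGrid,
    mech: MechanismAssignment,
    hold: float | None = None,
) -> CableSystem:
    """Assemble absolute conductances/capacitances from specific values.

    Axial coupling between a segment and its parent is the reciprocal of the
    summed half-segment series resistances, each computed from that
    segment's own local axial resistivity, length and diameter.

    ``hold`` (mV) balances the leak reversal per compartment so that the
    model rests exactly at the given potential with the HCN gate at
    m_inf(hold): e_l_i = e_pas + gbar_h_i * m_inf(hold) * (hold - e_h) /
    g_l_i.  This implements "membrane potential set at ``hold``" for
    HCN-endowed models, whose strong distal h conductance would otherwise
    drift the resting potential several mV depolarized and shift every
    voltage-dependent measurement.  For passive models the adjustment is
    identically zero.
    """
    n = len(grid)
    if len(mech.rm) != n:
        raise StructuralError("grid and mechanism assignment sizes differ")
    parent = np.array([s.parent_index for s in grid.segments], dtype=np.int32)
    length = np.array([s.length for s in grid.segments])
    diam = np.array([s.diameter for s in grid.segments])
    area = np.array([s.area for s in grid.segments])
    if np.any(diam <= 0) or np.any(area <= 0):
        raise StructuralError("zero-diameter or zero-area segment")
    if np.any(parent[1:] < 0) or np.any(parent[1:] >= np.arange(1, n)):
        raise StructuralError("segments are not in parent-before-child order")

    # half-segment axial resistance in Ohm: ra [Ohm*cm] * (L/2) [um] / (pi r^2) [um^2] * 1e4
    r_half = mech.ra * (length / 2.0) / (np.pi * (diam / 2.0) ** 2) * 1e4
    g_ax = np.zeros(n)
    for i in range(1, n):
        g_ax[i] = 1e9 / (r_half[i] + r_half[parent[i]])

    c = mech.cm * area * 1e-2  # pF
    g_l = area / mech.rm * 1e-2  # nS
    g_h = mech.gh * area * 1e-5  # nS
    e_l = np.full(n, float(mech.e_pas))
    if hold is not None:
        m_hold = float(mech.kinetics.m_inf(hold))
        e_l += g_h * m_hold * (hold - mech.kinetics.e_h) / g_l
    return CableSystem(parent, g_ax, c, g_l, e_l, g_h,
                       float(mech.kinetics.e_h), mech.kinetics, grid)


# -- steady state ------------------------------------------------------------


def steady_state(
    system: CableSystem,
    injections: dict[int, float] | None = None,
    v_guess: np.ndarray | None = None,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> np.ndarray:
    """DC solution of the nonlinear system (leak + HCN at m_inf(V)).

    ``injections`` maps segment indices to constant currents in pA.  Damped
    Newton iteration on the tree-structured Jacobian; converged when the net
    current into every segment is below ``tol`` pA (well inside the 1 pA
    charge-balance requirement).
    """
    n = len(system)
    kin = system.kinetics
    i_inj = np.zeros(n)
    for site, amp in (injections or {}).items():
        i_inj[site] += amp
    v = system.e_l.copy() if v_guess is None else v_guess.copy()

    rows, cols = [], []
    for i in range(1, n):
        p = int(system.parent[i])
        rows += [i, p]
        cols += [p, i]

    def residual(v):
        m = kin.m_inf(v)
        f = system.g_l * (system.e_l - v) + system.g_h * m * (system.e_h - v) + i_inj
        ax = system.g_ax[1:] * (v[system.parent[1:]] - v[1:])
        f[1:] += ax
        np.add.at(f, system.parent[1:], -ax)
        return f

    f = residual(v)
    for _ in range(max_iter):
        if np.max(np.abs(f)) < tol:
            return v
        m = kin.m_inf(v)
        dgdv = system.g_h * (m + kin.dminf_dv(v) * (v - system.e_h))
        diag = -(system.g_l + dgdv)
        ax_tot = np.zeros(n)
        for i in range(1, n):
            ax_tot[i] += system.g_ax[i]
            ax_tot[int(system.parent[i])] += system.g_ax[i]
        diag -= ax_tot
        data = np.concatenate([diag, np.repeat(system.g_ax[1:], 2)])
        jac = csc_matrix(
            (data, (np.concatenate([np.arange(n), rows]),
                    np.concatenate([np.arange(n), cols]))),
            shape=(n, n),
        )
        step = spsolve(jac, -f)
        alpha, norm0 = 1.0, np.max(np.abs(f))
        while alpha > 1e-4:
            v_new = v + alpha * step
            f_new = residual(v_new)
            if np.max(np.abs(f_new)) < norm0:
                v, f = v_new, f_new
                break
            alpha /= 2.0
        else:
            raise NumericalError("steady_state: damping failed to reduce residual")
    raise NumericalError(
        f"steady_state did not converge (residual {np.max(np.abs(f)):.3g} pA)"
    )


# -- time integration --------------------------------------------------------


@njit(cache=True)
def _integrate_kernel(
    parent, g_ax, c, g_l, e_l, g_h, e_h,
    v_half, k_slope, tau_peak, tau_vpeak, tau_sigma, q_t,
    dt, theta, stim_idx, stim, rec_idx, v, m, n_steps,
):
    n = v.shape[0]
    n_rec = rec_idx.shape[0]
    rec = np.empty((n_steps + 1, n_rec))
    rec_m = np.empty((n_steps + 1, n_rec))
    for k in range(n_rec):
        rec[0, k] = v[rec_idx[k]]
        rec_m[0, k] = m[rec_idx[k]]
    d = np.empty(n)
    b = np.empty(n)
    off = theta * g_ax
    c_dt = c / dt
    status = -1
    for step in range(n_steps):
        # Rush-Larsen gate update at the current voltage
        for i in range(n):
            if g_h[i] > 0.0:
                u = (v[i] - tau_vpeak) / tau_sigma
                if u > 60.0:
                    u = 60.0
                elif u < -60.0:
                    u = -60.0
                tau = tau_peak / (np.cosh(u) * q_t)
                z = (v[i] - v_half) / k_slope
                if z > 60.0:
                    z = 60.0
                elif z < -60.0:
                    z = -60.0
                minf = 1.0 / (1.0 + np.exp(z))
                m[i] = minf + (m[i] - minf) * np.exp(-dt / tau)
        # assemble diag and rhs
        for i in range(n):
            ghm = g_h[i] * m[i]
            gm = g_l[i] + ghm
            s = g_l[i] * e_l[i] + ghm * e_h
            d[i] = c_dt[i] + theta * gm
            b[i] = c_dt[i] * v[i] + theta * s + (1.0 - theta) * (s - gm * v[i])
        for i in range(1, n):
            p = parent[i]
            d[i] += off[i]
            d[p] += off[i]
            if theta < 1.0:
                a = (1.0 - theta) * g_ax[i] * (v[p] - v[i])
                b[i] += a
                b[p] -= a
        for j in range(stim_idx.shape[0]):
            if theta < 1.0:
                amp = 0.5 * (stim[j, step] + stim[j, step + 1])
            else:
                amp = stim[j, step + 1]
            b[stim_idx[j]] += amp
        # Hines elimination (children come after parents)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            r = off[i] / d[i]
            d[p] -= off[i] * r
            b[p] += r * b[i]
        v[0] = b[0] / d[0]
        for i in range(1, n):
            v[i] = (b[i] + off[i] * v[parent[i]]) / d[i]
        for k in range(n_rec):
            rec[step + 1, k] = v[rec_idx[k]]
            rec_m[step + 1, k] = m[rec_idx[k]]
        if not np.isfinite(v[0]):
            status = step
            break
    return rec, rec_m, status


def simulate(
    system: CableSystem,
    protocol: SimProtocol,
    state: tuple[np.ndarray, np.ndarray] | None = None,
    theta: float = 0.5,
    return_state: bool = False,
):
    """Integrate the cable equations under ``protocol``.

    ``state`` optionally supplies initial (v, m) arrays -- e.g. a settled
    state from :func:`settle`; otherwise the model starts at ``v_init`` with
    the HCN gate at m_inf(v_init).  ``theta`` selects Crank-Nicolson (0.5,
    default, second order) or backward Euler (1.0).

    Returns a :class:`VoltageTrace`, plus the final (v, m) state when
    ``return_state`` is set.
    """
    n = len(system)
    if state is not None:
        v0, m0 = state[0].copy(), state[1].copy()
    else:
        v0 = np.full(n, protocol.v_init)
        m0 = np.asarray(system.kinetics.m_inf(v0), dtype=float)
    n_steps = protocol.n_steps
    stim_sites = sorted(protocol.stimuli)
    stim = np.zeros((max(len(stim_sites), 1), n_steps + 1))
    for j, site in enumerate(stim_sites):
        w = np.asarray(protocol.stimuli[site], dtype=float)
        stim[j, : min(len(w), n_steps + 1)] = w[: n_steps + 1]
    stim_idx = np.array(stim_sites or [0], dtype=np.int32)
    rec_sites = list(protocol.record_sites) or [0]
    rec_idx = np.array(rec_sites, dtype=np.int32)
    kin = system.kinetics

    rec, rec_m, status = _integrate_kernel(
        system.parent, system.g_ax, system.c, system.g_l, system.e_l,
        system.g_h, system.e_h,
        kin.v_half, kin.k, kin.tau_peak, kin.tau_vpeak, kin.tau_sigma, kin.q_t,
        protocol.dt, theta, stim_idx, stim, rec_idx, v0, m0, n_steps,
    )
    if status >= 0:
        raise NumericalError(
            f"non-finite voltage at t = {(status + 1) * protocol.dt:.3f} ms"
        )
    trace = VoltageTrace(protocol.time, rec, rec_sites)
    if return_state:
        return trace, (v0, m0)
    return trace


def settle(
    system: CableSystem,
    duration: float = 200.0,
    dt: float = 0.1,
    v_init: float = -65.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Relax the model from (v_init, m_inf(v_init)) with no stimulus.

    Initialization at m_inf(v_init) is not the true network steady state
    when HCN is present; running a settle window and discarding it removes
    the resulting transient before any measurement.
    """
    protocol = SimProtocol(duration=duration, dt=dt, v_init=v_init, record_sites=[0])
    _, state = simulate(system, protocol, return_state=True)
    return state
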