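"""Shared fixtures and independent oracles for the test suite.

The frequency-domain oracle here solves the linearized (passive) cable
system with dense complex linear algebra at each frequency -- a route
entirely independent of the time-stepping solver and the FFT-based
impedance estimator it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

import dendromaps as dm
from dendromaps.biophysics import HcnKinetics
from dendromaps.cable import CableSystem


FAST_CHIRP = dm.ChirpStimulus(amplitude=25.0, duration=10.0, dt=0.1)


def make_rc_system(r_mohm: float = 100.0, tau_ms: float = 10.0) -> CableSystem:
    """Single passive compartment with given input resistance and time constant."""
    g = 1e3 / r_mohm  # nS
    c = tau_ms * g  # pF
    return CableSystem(
        parent=np.array([-1], dtype=np.int32),
        g_ax=np.zeros(1),
        c=np.array([c]),
        g_l=np.array([g]),
        e_l=np.array([-65.0]),
        g_h=np.zeros(1),
        e_h=-30.0,
        kinetics=HcnKinetics(),
    )


def make_chain_system(g_l, c, g_ax) -> CableSystem:
    """Unbranched passive chain; g_ax[i] couples compartment i to i-1."""
    n = len(g_l)
    parent = np.arange(-1, n - 1, dtype=np.int32)
    ga = np.concatenate([[0.0], np.asarray(g_ax, dtype=float)])
    return CableSystem(
        parent=parent,
        g_ax=ga,
        c=np.asarray(c, dtype=float),
        g_l=np.asarray(g_l, dtype=float),
        e_l=np.full(n, -65.0),
        g_h=np.zeros(n),
        e_h=-30.0,
        kinetics=HcnKinetics(),
    )


def freq_domain_impedance(system: CableSystem, inject: int, record: int,
                          freqs: np.ndarray) -> np.ndarray:
    """Complex transfer impedance (MOhm) of a passive cable system.

    Direct admittance-matrix solve, (G_l + jwC + L_ax) V = e_inject, at each
    frequency; L_ax is the axial Laplacian.
    """
    n = len(system)
    lap = np.zeros((n, n), dtype=complex)
    for i in range(1, n):
        p = int(system.parent[i])
        g = system.g_ax[i]
        lap[i, i] += g
        lap[p, p] += g
        lap[i, p] -= g
        lap[p, i] -= g
    out = np.empty(len(freqs), dtype=complex)
    rhs = np.zeros(n)
    rhs[inject] = 1.0  # 1 pA
    for k, f in enumerate(freqs):
        jw = 2j * np.pi * f * 1e-3  # 1/ms
        a = np.diag(system.g_l + jw * system.c) + lap
        v = np.linalg.solve(a, rhs)
        out[k] = v[record] * 1000.0  # mV/pA -> MOhm
    return out


@pytest.fixture(scope="session")
def small_tree():
    return dm.generate_stylized_ca1(dm.SynthParams(target_total_length=3.0, seed=11))


@pytest.fixture(scope="session")
def passive_small(small_tree):
    return dm.NeuronModel.build(small_tree)


@pytest.fixture(scope="session")
def gradient_small(small_tree):
    return dm.NeuronModel.build(small_tree, dist=dm.HcnDistribution())


@pytest.fixture(scope="session")
def base_tree():
    """Full-scale synthetic base morphology (~17.5 mm)."""
    return dm.generate_stylized_ca1(dm.SynthParams(seed=1))


@pytest.fixture(scope="session")
def atrophy_series(base_tree):
    """The full chained atrophy series: 17 members, ~1 mm steps, 17.5 down
    to ~1.6 mm.  Simulation-heavy tests subsample members via SERIES_PICKS."""
    return dm.generate_prune_series(base_tree, step_mm=1.0, floor_mm=1.0)


# five members spanning the full range (~17.5, 13.5, 9.5, 5.5, 1.6 mm)
SERIES_PICKS = (0, 4, 8, 12, 16)
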