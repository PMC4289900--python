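"""The impedance measurement battery.

Input resistance (R_in) is the least-squares slope of the steady-state V-I
relation under 300 ms current pulses.  Frequency-dependent properties come
from the chirp (ZAP) protocol: a constant-amplitude sinusoid whose
instantaneous frequency sweeps linearly from 0 to 25 Hz; the impedance is
the ratio of the Fourier transforms of the voltage response and the
stimulus,

    Z(f) = V(f) / I(f),    |Z| = sqrt(Re^2 + Im^2),    phi = atan2(Im, Re).

From a local profile (record where you inject) or transfer profile (record
at the soma) the battery extracts the resonance frequency f_R (argmax of
|Z| with three-point parabolic refinement), the peak impedance |Z|_max, the
resonance strength Q = |Z(f_R)|/|Z(0.5 Hz)| and the total inductive phase
Phi_L = integral of phi over the region where phi > 0 (rad*Hz).  The
analysis band is [0.5, 25] Hz: the chirp starts at 0 Hz where the transform
ratio is ill-conditioned, and Q is defined against |Z(0.5)|.

Maps aggregate these measures over trunk locations and, via an atrophy
series, over total dendritic length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cable import CableSystem, SimProtocol, VoltageTrace, simulate
from .exceptions import ConfigurationError, MeasurementError
from .model import NeuronModel

LOCAL_MEASUREMENTS = ("rin", "f_r", "z_loc_max", "phi_l", "q")
TRANSFER_MEASUREMENTS = ("f_tr", "z_tr_max", "phi_l_tr", "q_tr")
ALL_MEASUREMENTS = LOCAL_MEASUREMENTS + TRANSFER_MEASUREMENTS


@dataclass(frozen=True)
class ChirpStimulus:
    """Constant-amplitude chirp with linearly increasing frequency."""

    amplitude: float = 50.0  # pA
    f_start: float = 0.0  # Hz
    f_end: float = 25.0  # Hz
    duration: float = 25.0  # s
    dt: float = 0.1  # ms

    def waveform(self) -> np.ndarray:
        """Sampled current in pA; phase = 2*pi*(f0*t + (f1-f0)*t^2/(2T))."""
        n = int(round(self.duration * 1000.0 / self.dt))
        t = np.arange(n + 1) * (self.dt / 1000.0)  # s
        phase = 2.0 * np.pi * (
            self.f_start * t + (self.f_end - self.f_start) * t**2 / (2.0 * self.duration)
        )
        return self.amplitude * np.sin(phase)


def make_chirp(spec: ChirpStimulus = ChirpStimulus()) -> np.ndarray:
    return spec.waveform()


def normalize_chirp_amplitude(
    base_rin_som: float, model_rin_som: float, base_amplitude: float = 50.0
) -> float:
    """Scale the chirp amplitude by the ratio of somatic input resistances.

    Keeps the somatic peak-to-peak voltage response comparable across pruned
    morphologies of an HCN-endowed model; the base (unpruned) model receives
    exactly the base amplitude.
    """
    if base_rin_som <= 0 or model_rin_som <= 0:
        raise ValueError("input resistances must be positive")
    return base_amplitude * base_rin_som / model_rin_som


@dataclass
class ImpedanceProfile:
    """Complex impedance on a frequency grid (MOhm)."""

    frequency: np.ndarray  # Hz, strictly increasing
    z: np.ndarray  # complex, MOhm
    kind: str = "local"  # 'local' | 'transfer'

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.z.real, self.z.imag)

    @property
    def phase(self) -> np.ndarray:
        return np.arctan2(self.z.imag, self.z.real)


@dataclass(frozen=True)
class ImpedanceMeasures:
    """Scalar summary of one impedance profile."""

    f_r: float  # Hz
    z_max: float  # MOhm
    q: float  # dimensionless
    phi_l: float  # rad*Hz
    kind: str = "local"


DEFAULT_AMPLITUDES = tuple(range(-50, 51, 10))  # pA
REDUCED_AMPLITUDES = tuple(range(-25, 26, 5))


def measure_rin(
    model: NeuronModel,
    site: int,
    amplitudes=DEFAULT_AMPLITUDES,
    pulse_ms: float = 300.0,
    readout_ms: float = 10.0,
) -> float:
    """Input resistance (MOhm) from the V-I slope at ``site``.

    Current pulses of each amplitude are run from the cached settled state;
    the steady-state voltage is the mean over the final ``readout_ms`` of
    the pulse.  The slope is the ordinary least-squares fit of V against I.
    """
    amps = np.asarray(sorted(amplitudes), dtype=float)
    if len(amps) < 2 or abs(amps.sum()) > 1e-9 * np.abs(amps).max():
        raise ConfigurationError("amplitudes must be a symmetric set about 0 pA")
    state = model.settled_state()
    n_samples = int(round(pulse_ms / model.dt)) + 1
    vss = np.empty_like(amps)
    tail = max(int(round(readout_ms / model.dt)), 1)
    for j, amp in enumerate(amps):
        if amp == 0.0:
            vss[j] = state[0][site]
            continue
        protocol = SimProtocol(
            duration=pulse_ms, dt=model.dt, v_init=model.v_init,
            stimuli={site: np.full(n_samples, amp)}, record_sites=[site],
        )
        trace = simulate(model.system, protocol, state=state)
        vss[j] = trace.at(site)[-tail:].mean()
    order = np.argsort(amps)
    dv = np.diff(vss[order])
    if np.any(dv <= 0):
        raise MeasurementError("non-monotone V-I relation")
    slope = np.polyfit(amps, vss, 1)[0]  # mV/pA = GOhm
    return float(slope * 1000.0)  # MOhm


def compute_impedance(
    stimulus: np.ndarray,
    response: np.ndarray,
    dt: float,
    band: tuple[float, float] = (0.5, 25.0),
    kind: str = "local",
    smooth: bool = False,
    smooth_window_hz: float = 0.25,
) -> ImpedanceProfile:
    """Z(f) = FFT(V)/FFT(I) on the discrete grid, restricted to ``band``.

    ``dt`` in ms.  Means are removed before transforming (the DC bin is
    outside the band anyway).  Optional boxcar smoothing of the complex
    profile over a fixed ``smooth_window_hz`` window, off by default.
    """
    if len(stimulus) != len(response):
        raise MeasurementError("stimulus and response must share a time base")
    i_f = np.fft.rfft(stimulus - stimulus.mean())
    v_f = np.fft.rfft(response - response.mean())
    freqs = np.fft.rfftfreq(len(stimulus), d=dt / 1000.0)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    floor = 1e-6 * np.abs(i_f).max()
    if np.any(np.abs(i_f[sel]) < floor):
        raise MeasurementError("insufficient stimulus excitation inside the band")
    z = v_f[sel] / i_f[sel] * 1000.0  # mV/pA = GOhm -> MOhm
    f = freqs[sel]
    if smooth:
        win = max(int(round(smooth_window_hz / (f[1] - f[0]))), 1)
        kernel = np.ones(win) / win
        z = np.convolve(z, kernel, mode="same")
    return ImpedanceProfile(f, z, kind)


def chirp_profiles(
    model: NeuronModel,
    site: int,
    chirp: ChirpStimulus | None = None,
    band: tuple[float, float] = (0.5, 25.0),
    tail_s: float = 2.0,
) -> tuple[ImpedanceProfile, ImpedanceProfile]:
    """(local, transfer) impedance profiles from one chirp injection.

    The chirp is injected at ``site``; the voltage is recorded both there
    (local) and at the soma (transfer), so a single simulation yields both
    profiles.  Distances attributed to either profile are those of the
    injection site.

    A silent ``tail_s`` window is appended after the chirp and included in
    the transform: it lets the response decay to rest, removing the
    truncation (spectral-leakage) bias at the band edges that a record cut
    mid-oscillation would cause.
    """
    if chirp is None:
        chirp = ChirpStimulus(dt=model.dt, duration=10.0)
    wave = chirp.waveform()
    n_tail = int(round(tail_s * 1000.0 / chirp.dt))
    soma = model.grid.soma_index
    rec = [site] if site == soma else [site, soma]
    protocol = SimProtocol(
        duration=(chirp.duration + tail_s) * 1000.0, dt=model.dt, v_init=model.v_init,
        stimuli={site: wave}, record_sites=rec,
    )
    trace = simulate(model.system, protocol, state=model.settled_state())
    # drop the final sample so the record length is exactly an integral
    # number of seconds and the transform grid lands on round frequencies
    full_wave = np.concatenate([wave, np.zeros(n_tail)])[:-1]
    local = compute_impedance(full_wave, trace.at(site)[:-1], model.dt, band, "local")
    transfer = compute_impedance(full_wave, trace.at(soma)[:-1], model.dt, band, "transfer")
    return local, transfer


def local_impedance(model: NeuronModel, site: int, **kw) -> ImpedanceProfile:
    return chirp_profiles(model, site, **kw)[0]


def transfer_impedance(model: NeuronModel, site: int, **kw) -> ImpedanceProfile:
    return chirp_profiles(model, site, **kw)[1]


def resonance_measures(profile: ImpedanceProfile) -> ImpedanceMeasures:
    """f_R, |Z|_max, Q and Phi_L of one impedance profile.

    f_R is the grid argmax of |Z| refined by a three-point parabola (ties
    broken toward lower frequency); at a band edge no refinement is applied,
    so a strictly low-pass profile reports f_R at the band floor with Q = 1.
    Phi_L integrates the positive part of the phase by the trapezoid rule.
    """
    f, mag, phase = profile.frequency, profile.magnitude, profile.phase
    k = int(np.argmax(mag))
    if 0 < k < len(f) - 1:
        y0, y1, y2 = mag[k - 1], mag[k], mag[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            f_r = f[k] + delta * (f[1] - f[0])
            z_max = y1 - 0.25 * (y0 - y2) * delta
        else:
            f_r, z_max = float(f[k]), float(y1)
    else:
        f_r, z_max = float(f[k]), float(mag[k])
    z_ref = float(np.interp(0.5, f, mag)) if f[0] <= 0.5 else float(mag[0])
    q = z_max / z_ref
    phi_l = float(np.trapezoid(np.clip(phase, 0.0, None), f))
    return ImpedanceMeasures(float(f_r), float(z_max), float(q), phi_l, profile.kind)


def measure_battery(
    model: NeuronModel,
    site: int,
    chirp: ChirpStimulus | None = None,
    rin_amplitudes=DEFAULT_AMPLITUDES,
) -> dict[str, float]:
    """All nine measurements at one site (five local, four transfer)."""
    loc, tr = chirp_profiles(model, site, chirp=chirp)
    ml, mt = resonance_measures(loc), resonance_measures(tr)
    rin = measure_rin(model, site, amplitudes=rin_amplitudes)
    return {
        "rin": rin,
        "f_r": ml.f_r, "z_loc_max": ml.z_max, "phi_l": ml.phi_l, "q": ml.q,
        "f_tr": mt.f_r, "z_tr_max": mt.z_max, "phi_l_tr": mt.phi_l, "q_tr": mt.q,
    }


def map_over_locations(
    model: NeuronModel,
    sites: list[int],
    chirp: ChirpStimulus | None = None,
    rin_amplitudes=DEFAULT_AMPLITUDES,
) -> pd.DataFrame:
    """Measurement map: one row per site with distances and all nine measures."""
    rows = []
    for site in sites:
        seg = model.grid.segments[site]
        row = dict(
            site=site,
            path_um=seg.path_distance,
            radial_um=seg.radial_distance,
        )
        row.update(measure_battery(model, site, chirp=chirp, rin_amplitudes=rin_amplitudes))
        rows.append(row)
    return pd.DataFrame(rows)


def map_over_series(
    models: list[tuple[float, NeuronModel]],
    locate: dict[str, float],
    measurement: str,
    chirp: ChirpStimulus | None = None,
    rin_amplitudes=DEFAULT_AMPLITUDES,
) -> pd.DataFrame:
    """A measurement as a function of total dendritic length.

    ``models`` pairs each series member's length (mm) with its model;
    ``locate`` maps site labels to radial distances (um) resolved per member
    (trunk sites persist across an atrophy series, so the same physical
    location is measured in every member).  Missing measurements appear as
    NaN gaps, never as silently dropped rows.
    """
    if measurement not in ALL_MEASUREMENTS:
        raise ConfigurationError(f"unknown measurement {measurement!r}")
    rows = []
    for length, model in models:
        for label, dist_um in locate.items():
            site = model.grid.locate(dist_um, kind="radial")
            try:
                value = measure_battery(
                    model, site, chirp=chirp, rin_amplitudes=rin_amplitudes
                )[measurement]
            except MeasurementError:
                value = np.nan
            rows.append(
                dict(length_mm=length, site_label=label, site=site,
                     measurement=measurement, value=value)
            )
    return pd.DataFrame(rows)
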