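"""Chirp stimulus, impedance estimation and the resonance measures."""

import numpy as np
import pytest

import dendromaps as dm
from dendromaps.cable import SimProtocol, simulate
from dendromaps.exceptions import ConfigurationError, MeasurementError
from dendromaps.measurements import (
    ChirpStimulus,
    ImpedanceProfile,
    REDUCED_AMPLITUDES,
    compute_impedance,
    make_chirp,
    measure_rin,
    normalize_chirp_amplitude,
    resonance_measures,
)

from conftest import FAST_CHIRP, make_rc_system


class TestChirp:
    def test_starts_at_zero_with_full_amplitude(self):
        w = make_chirp(ChirpStimulus(duration=25.0, dt=1.0))
        assert w[0] == 0.0
        assert np.max(np.abs(w)) == pytest.approx(50.0, rel=1e-3)

    def test_zero_crossing_count(self):
        """Total cycles = integral of the instantaneous frequency = 312.5,
        hence ~625 zero crossings over the 25 s sweep."""
        w = make_chirp(ChirpStimulus(duration=25.0, dt=1.0))
        crossings = int(np.sum(np.diff(np.signbit(w))!= 0))
        assert abs(crossings - 625) <= 2

    def test_linear_frequency_sweep(self):
        spec = ChirpStimulus(duration=10.0, dt=0.1)
        w = spec.waveform()
        # instantaneous frequency at T/2 is f_end/2: count crossings in a
        # narrow window around T/2 and compare with the local frequency
        mid = len(w) // 2
        win = w[mid - 2000 : mid + 2000]  # 0.4 s window
        crossings = int(np.sum(np.diff(np.signbit(win))!= 0))
        assert crossings == pytest.approx(2 * 12.5 * 0.4, abs=2)

    def test_normalization(self):
        assert normalize_chirp_amplitude(80.0, 80.0) == 50.0
        assert normalize_chirp_amplitude(80.0, 160.0) == 25.0
        with pytest.raises(ValueError):
            normalize_chirp_amplitude(-1.0, 50.0)


class TestComputeImpedance:
    def test_rc_closed_form(self):
        sys_ = make_rc_system(r_mohm=100.0, tau_ms=10.0)
        chirp = ChirpStimulus(dt=0.05, duration=10.0)
        w = chirp.waveform()
        n_tail = int(2000.0 / 0.05)
        pr = SimProtocol(duration=12000.0, dt=0.05, stimuli={0: w}, record_sites=[0])
        tr = simulate(sys_, pr)
        full = np.concatenate([w, np.zeros(n_tail)])[:-1]
        prof = compute_impedance(full, tr.voltages[:-1, 0], 0.05)
        f = prof.frequency
        expected = 100.0 / (1 + 2j * np.pi * f * 0.010)
        assert np.max(np.abs(prof.z - expected) / np.abs(expected)) < 0.01

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(MeasurementError):
            compute_impedance(np.zeros(10), np.zeros(11), 0.1)

    def test_insufficient_excitation_rejected(self):
        n = 20000
        t = np.arange(n) * 0.1 / 1000.0
        stim = np.sin(2 * np.pi * 3.0 * t)  # tone: no energy elsewhere in band
        with pytest.raises(MeasurementError):
            compute_impedance(stim, stim.copy(), 0.1)


class TestResonanceMeasures:
    def synthetic_profile(self, mags, f0=0.5, df=0.1):
        f = f0 + df * np.arange(len(mags))
        return ImpedanceProfile(f, np.asarray(mags, dtype=complex))

    def test_low_pass_pins_to_band_floor(self):
        f = np.arange(0.5, 25.05, 0.1)
        prof = ImpedanceProfile(f, (100.0 / (1 + 1j * f / 3.0)))
        m = resonance_measures(prof)
        assert m.f_r == 0.5
        assert m.q == pytest.approx(1.0)
        assert m.phi_l == 0.0

    def test_band_pass_peak_recovered(self):
        """Constructed magnitude with analytic maximum at 7 Hz."""
        f = np.arange(0.5, 25.05, 0.1)
        mag = 50.0 / np.sqrt(1.0 + ((f**2 - 49.0) / (4.0 * f)) ** 2)
        prof = ImpedanceProfile(f, mag.astype(complex))
        m = resonance_measures(prof)
        assert m.f_r == pytest.approx(7.0, abs=0.05)
        assert m.z_max == pytest.approx(50.0, rel=1e-3)
        assert m.q > 1.0

    def test_negative_phase_gives_zero_inductive_area(self):
        f = np.arange(0.5, 25.05, 0.1)
        z = np.full(len(f), 10.0) * np.exp(-0.1j)
        m = resonance_measures(ImpedanceProfile(f, z))
        assert m.phi_l == 0.0

    def test_inductive_area_trapezoid(self):
        f = np.arange(0.5, 25.05, 0.1)
        phase = np.where(f < 5.0, 0.2, -0.3)
        z = 10.0 * np.exp(1j * phase)
        m = resonance_measures(ImpedanceProfile(f, z))
        # positive region spans [0.5, ~5): area ~ 0.2 * 4.5
        assert m.phi_l == pytest.approx(0.9, abs=0.02)


class TestMeasureRin:
    def test_exact_linear_system_any_amplitudes(self):
        model = _FakeModelRC()
        for amps in ((-50, 0, 50), REDUCED_AMPLITUDES):
            assert measure_rin(model, 0, amplitudes=amps) == pytest.approx(100.0, rel=5e-3)

    def test_asymmetric_amplitudes_rejected(self, passive_small):
        with pytest.raises(ConfigurationError):
            measure_rin(passive_small, 0, amplitudes=(0, 10, 20))

    def test_passive_default_vs_reduced_range_agree(self, passive_small):
        site = passive_small.grid.locate(150.0)
        full = measure_rin(passive_small, site)
        red = measure_rin(passive_small, site, amplitudes=REDUCED_AMPLITUDES)
        assert red == pytest.approx(full, rel=0.02)


class _FakeModelRC:
    """Single-compartment RC model exposing the NeuronModel surface that
    measure_rin uses (closed-form R = 100 MOhm)."""

    def __init__(self):
        self.system = make_rc_system(r_mohm=100.0, tau_ms=10.0)
        self.dt = 0.05
        self.v_init = -65.0

    def settled_state(self):
        v = np.full(1, -65.0)
        return v, np.asarray(self.system.kinetics.m_inf(v))


class TestLocalTransfer:
    def test_soma_site_gives_identical_profiles(self, passive_small):
        loc, tr = dm.chirp_profiles(passive_small, passive_small.grid.soma_index,
                                    chirp=FAST_CHIRP)
        assert np.allclose(loc.z, tr.z)

    def test_transfer_dc_below_local_dc(self, passive_small):
        site = passive_small.grid.locate(300.0)
        loc, tr = dm.chirp_profiles(passive_small, site, chirp=FAST_CHIRP)
        assert tr.magnitude[0] < loc.magnitude[0]

    def test_transfer_reciprocity(self, passive_small):
        """Transfer impedance site->soma equals soma->site (passive)."""
        site = passive_small.grid.locate(300.0)
        _, forward = dm.chirp_profiles(passive_small, site, chirp=FAST_CHIRP)
        # reverse direction: inject at soma, record at site
        from dendromaps.measurements import compute_impedance
        wave = FAST_CHIRP.waveform()
        n_tail = int(2000.0 / FAST_CHIRP.dt)
        pr = SimProtocol(duration=12000.0, dt=FAST_CHIRP.dt,
                         stimuli={passive_small.grid.soma_index: wave},
                         record_sites=[site])
        trc = simulate(passive_small.system, pr,
                       state=passive_small.settled_state())
        full = np.concatenate([wave, np.zeros(n_tail)])[:-1]
        backward = compute_impedance(full, trc.voltages[:-1, 0], FAST_CHIRP.dt,
                                     kind="transfer")
        err = np.abs(forward.z - backward.z) / np.abs(forward.z)
        assert np.max(err) < 0.005

    def test_battery_matches_map(self, gradient_small):
        site = gradient_small.grid.locate(150.0)
        row = dm.map_over_locations(gradient_small, [site], chirp=FAST_CHIRP,
                                    rin_amplitudes=REDUCED_AMPLITUDES).iloc[0]
        direct = dm.measure_battery(gradient_small, site, chirp=FAST_CHIRP,
                                    rin_amplitudes=REDUCED_AMPLITUDES)
        for key, val in direct.items():
            assert row[key] == pytest.approx(val, rel=1e-12)

    def test_normalized_chirp_equalizes_somatic_response(self, atrophy_series):
        """Across successive pruned members, amplitude normalization keeps
        the somatic peak-to-peak chirp response comparable (within ~10%)."""
        picks = [0, 1, 2]
        p2p = []
        base_rin = None
        for idx in picks:
            length, member = atrophy_series.members[idx]
            model = dm.NeuronModel.build(member, dist=dm.HcnDistribution())
            rin = measure_rin(model, 0, amplitudes=REDUCED_AMPLITUDES)
            if base_rin is None:
                base_rin = rin
            amp = normalize_chirp_amplitude(base_rin, rin, 50.0)
            chirp = ChirpStimulus(amplitude=amp, duration=10.0, dt=model.dt)
            wave = chirp.waveform()
            pr = SimProtocol(duration=10000.0, dt=model.dt,
                             stimuli={0: wave}, record_sites=[0])
            tr = simulate(model.system, pr, state=model.settled_state())
            v = tr.voltages[:, 0]
            p2p.append(float(v.max() - v.min()))
        assert max(p2p) / min(p2p) < 1.10
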