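"""Forward model and synthetic trace generator."""

import numpy as np
import pytest

from cifns.geometry import efnd_profile, get_array
from cifns.signal_processing import average_repeats, extract_response_amplitude
from cifns.stimulation import StimulusSpec
from cifns.synthetic_emg import (
    CHANNELS,
    EmgTrace,
    ForwardModelParams,
    cmap_amplitude,
    insertion_schedule,
    simulate_insertion_experiment,
    simulate_postinsertion_sweep,
    synthesize_trace,
    threshold_current,
)


class TestCmapAmplitude:
    def test_sigmoid_midpoint_at_threshold(self):
        """At I = I_th(d) the evoked amplitude is exactly A_max / 2."""
        params = ForwardModelParams(noise_sd_uv=0.0)
        for d in (0.5, 2.0, 5.0):
            i_th = threshold_current(d, params)
            for ch in CHANNELS:
                a = cmap_amplitude(i_th, d, params, ch)
                assert a == pytest.approx(params.cmap_amplitude_uv[ch] / 2)

    def test_frozen_formula_value(self):
        """Independent scalar evaluation of the recruitment formula:
        I0=300, d0=2, k=6, A_max=100, I=450, d=1 -> I_th=375, x=1.2,
        A = 100/(1+e^-1.2) = 76.852478."""
        params = ForwardModelParams(
            base_threshold_cu=300.0,
            distance_scale_mm=2.0,
            recruitment_steepness=6.0,
            cmap_amplitude_uv={"periocular": 100.0, "perioral": 100.0},
        )
        assert cmap_amplitude(450.0, 1.0, params, "periocular") == pytest.approx(
            76.852478349902, abs=1e-9
        )

    def test_monotone_in_current_and_distance(self):
        """Strictly increasing in current, strictly decreasing in distance,
        over a parameter grid."""
        params = ForwardModelParams()
        currents = np.linspace(50, 1500, 30)
        distances = np.linspace(0.3, 9.0, 25)
        for d in distances[::5]:
            a = [cmap_amplitude(i, d, params) for i in currents]
            assert np.all(np.diff(a) > 0)
        for i in currents[::5]:
            a = [cmap_amplitude(i, d, params) for d in distances]
            assert np.all(np.diff(a) < 0)

    def test_approaches_floor_at_large_distance(self):
        """As d grows the amplitude decreases monotonically toward the
        recruitment-curve floor A_max * sigmoid(-k) (~0.25% of A_max)."""
        params = ForwardModelParams()
        a_max = params.cmap_amplitude_uv["periocular"]
        floor = a_max / (1 + np.exp(params.recruitment_steepness))
        prev = np.inf
        for d in (10.0, 20.0, 50.0, 1000.0):
            a = cmap_amplitude(500.0, d, params)
            assert floor < a < prev
            prev = a
        assert prev < 1.001 * floor

    def test_domain_errors(self):
        params = ForwardModelParams()
        with pytest.raises(ValueError):
            cmap_amplitude(450.0, 0.0, params)
        with pytest.raises(ValueError):
            cmap_amplitude(-1.0, 1.0, params)


class TestSynthesizeTrace:
    def test_sample_count_and_channels(self, quiet_params):
        trace = synthesize_trace(StimulusSpec(), {"periocular": 50.0, "perioral": 250.0},
                                 quiet_params, rng=0)
        assert set(trace.channels) == set(CHANNELS)
        n = round(trace.sampling_rate_hz * trace.duration_ms / 1000)
        assert all(len(trace.samples_uv[ch]) == n for ch in CHANNELS)
        assert trace.sampling_rate_hz == 38400.0
        assert len(trace.epochs()) == 2

    def test_zero_amplitude_gives_flat_response_window(self, quiet_params):
        """Amplitude 0, noise 0: only the artifact remains; the response
        window is flat."""
        trace = synthesize_trace(StimulusSpec(), {ch: 0.0 for ch in CHANNELS},
                                 quiet_params, rng=0)
        meas = extract_response_amplitude(trace.epochs()[0])
        for ch in CHANNELS:
            # only the artifact tail (<= 1e-4 of its amplitude) leaks past
            # the blanking boundary
            leak_bound = 1e-4 * quiet_params.artifact_amplitude_uv[ch]
            assert meas.amplitude_uv[ch] <= leak_bound

    @pytest.mark.parametrize("amp", [5.0, 40.0, 300.0])
    def test_peak_to_peak_matches_request(self, amp, quiet_params):
        """Noise-free synthesized peak-to-peak equals the requested CMAP
        amplitude within 1% (waveform normalization contract)."""
        trace = synthesize_trace(StimulusSpec(), {ch: amp for ch in CHANNELS},
                                 quiet_params, rng=0)
        meas = extract_response_amplitude(average_repeats(trace.epochs()))
        for ch in CHANNELS:
            assert meas.amplitude_uv[ch] == pytest.approx(amp, rel=0.01)

    def test_same_seed_bit_identical(self):
        params = ForwardModelParams()
        amps = {"periocular": 30.0, "perioral": 150.0}
        t1 = synthesize_trace(StimulusSpec(), amps, params, rng=42)
        t2 = synthesize_trace(StimulusSpec(), amps, params, rng=42)
        for ch in CHANNELS:
            np.testing.assert_array_equal(t1.samples_uv[ch], t2.samples_uv[ch])

    def test_channel_noise_independent(self):
        params = ForwardModelParams(
            artifact_amplitude_uv={"periocular": 0.0, "perioral": 0.0}
        )
        trace = synthesize_trace(StimulusSpec(), {ch: 0.0 for ch in CHANNELS}, params, rng=7)
        r = np.corrcoef(trace.samples_uv["periocular"], trace.samples_uv["perioral"])[0, 1]
        assert abs(r) < 0.1

    def test_artifact_asymmetry(self, quiet_params):
        """The periocular stimulation artifact is a multiple of the perioral one."""
        trace = synthesize_trace(StimulusSpec(), {ch: 0.0 for ch in CHANNELS},
                                 quiet_params, rng=0)
        peri = np.abs(trace.samples_uv["periocular"]).max()
        oral = np.abs(trace.samples_uv["perioral"]).max()
        assert peri == pytest.approx(10 * oral, rel=1e-9)

    def test_negative_amplitude_rejected(self, quiet_params):
        with pytest.raises(ValueError):
            synthesize_trace(StimulusSpec(), {"periocular": -1.0, "perioral": 0.0},
                             quiet_params)

    def test_tsv_roundtrip(self, tmp_path):
        params = ForwardModelParams()
        trace = synthesize_trace(StimulusSpec(), {"periocular": 30.0, "perioral": 150.0},
                                 params, rng=3)
        path = tmp_path / "trace.tsv"
        trace.to_tsv(path)
        back = EmgTrace.from_tsv(path)
        assert back.sampling_rate_hz == trace.sampling_rate_hz
        assert back.stimulus == trace.stimulus
        for ch in CHANNELS:
            np.testing.assert_allclose(back.samples_uv[ch], trace.samples_uv[ch],
                                       rtol=0, atol=1e-8)


class TestInsertionExperiment:
    def test_schedule(self):
        assert insertion_schedule(2) == [2, 4, 6, 8, 10, 12]
        assert insertion_schedule(12) == [12]
        assert insertion_schedule(5) == [5, 10, 12]

    def test_amplitude_peaks_at_closest_approach(self, spiral, facial_nerve, quiet_params):
        """Noise-free amplitude sequence is maximal at the step whose tip
        EFND is minimal, for every array type."""
        for name in ("Standard", "FLEX28", "FLEX24"):
            spec = get_array(name)
            rec = simulate_insertion_experiment(
                spec, spiral, facial_nerve, quiet_params, 472.5, rng=0
            )
            amps = []
            tip_efnd = []
            for n, trace in rec:
                meas = extract_response_amplitude(average_repeats(trace.epochs()))
                amps.append(meas.amplitude_uv["perioral"])
                tip_efnd.append(efnd_profile(spec, spiral, facial_nerve, n).distances[1])
            assert int(np.argmax(amps)) == int(np.argmin(tip_efnd))

    def test_long_array_terminal_re_rise(self, spiral, facial_nerve, quiet_params):
        """FLEX28's tip re-approaches the nerve in the mid turn: the final
        step's amplitude rises again after the post-peak decline."""
        rec = simulate_insertion_experiment(
            get_array("FLEX28"), spiral, facial_nerve, quiet_params, 472.5, rng=0
        )
        amps = [
            extract_response_amplitude(average_repeats(t.epochs())).amplitude_uv["perioral"]
            for _, t in rec
        ]
        peak = int(np.argmax(amps))
        assert peak < len(amps) - 1
        assert amps[-1] > min(amps[peak:-1])

    def test_short_array_no_re_rise(self, spiral, facial_nerve, quiet_params):
        rec = simulate_insertion_experiment(
            get_array("FLEX24"), spiral, facial_nerve, quiet_params, 472.5, rng=0
        )
        amps = [
            extract_response_amplitude(average_repeats(t.epochs())).amplitude_uv["perioral"]
            for _, t in rec
        ]
        peak = int(np.argmax(amps))
        assert np.all(np.diff(amps[peak:]) < 0)

    def test_step_12_single_measurement(self, spiral, facial_nerve, quiet_params, flex28):
        rec = simulate_insertion_experiment(
            flex28, spiral, facial_nerve, quiet_params, 472.5, step=12, rng=0
        )
        assert [n for n, _ in rec] == [12]


class TestPostinsertionSweep:
    def test_amplitudes_anti_monotone_with_efnd(self, spiral, facial_nerve,
                                                quiet_params, flex28):
        """Noise-free per-contact amplitude ranks are the reverse of EFND ranks."""
        sweep = simulate_postinsertion_sweep(
            flex28, spiral, facial_nerve, quiet_params, 472.5, rng=0
        )
        efnd = efnd_profile(flex28, spiral, facial_nerve)
        contacts = sorted(sweep)
        amps = [
            extract_response_amplitude(average_repeats(sweep[c].epochs()))
            .amplitude_uv["perioral"]
            for c in contacts
        ]
        dists = [efnd.distances[c] for c in contacts]
        assert np.argsort(amps).tolist() == np.argsort(dists)[::-1].tolist()

    def test_apical_half_dominates(self, spiral, facial_nerve, quiet_params):
        """Mean amplitude over contacts 1-6 exceeds that over 7-12 for a
        fully inserted long array."""
        for name in ("Standard", "FLEX28"):
            sweep = simulate_postinsertion_sweep(
                get_array(name), spiral, facial_nerve, quiet_params, 472.5, rng=0
            )
            amps = {
                c: extract_response_amplitude(average_repeats(t.epochs()))
                .amplitude_uv["perioral"]
                for c, t in sweep.items()
            }
            apical = np.mean([amps[c] for c in range(1, 7)])
            basal = np.mean([amps[c] for c in range(7, 13)])
            assert apical > basal

    def test_seeded_reproducibility(self, spiral, facial_nerve, flex28):
        params = ForwardModelParams()
        s1 = simulate_postinsertion_sweep(flex28, spiral, facial_nerve, params, 472.5, rng=9)
        s2 = simulate_postinsertion_sweep(flex28, spiral, facial_nerve, params, 472.5, rng=9)
        for c in s1:
            np.testing.assert_array_equal(
                s1[c].samples_uv["perioral"], s2[c].samples_uv["perioral"]
            )


class TestParamsValidation:
    def test_latency_must_clear_artifact(self):
        with pytest.raises(ValueError):
            ForwardModelParams(cmap_latency_ms=0.5, artifact_decay_ms=0.2)

    def test_positive_scales(self):
        with pytest.raises(ValueError):
            ForwardModelParams(distance_scale_mm=0.0)
        with pytest.raises(ValueError):
            ForwardModelParams(noise_sd_uv=-1.0)
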