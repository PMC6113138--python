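"""ASSR band-pass, epoching, 40 Hz power and intertrial coherence."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import quiet_config
from mouseeg.assr import assr_bandpass, assr_itc, assr_power, segment_assr
from mouseeg.erp import EpochSet
from mouseeg.errors import AnalysisError, ParameterError
from mouseeg.protocols import make_assr_protocol
from mouseeg.simulate import SignalRecording, SimConfig, render_session

FS = 1000.0


def _sine_rec(freq, n=4000, amp=1.0):
    t = np.arange(n) / FS
    x = amp * np.sin(2 * np.pi * freq * t)
    return SignalRecording(np.stack([x, np.zeros(n)]), FS, ["EEG1", "TRIG"])


def _epochs_from_trials(trials, pre_ms=400.0, post_ms=2400.0):
    data = np.asarray(trials)[:, None, :]
    return EpochSet(data, FS, pre_ms, post_ms,
                    np.array(["train_onset"] * data.shape[0]))


class TestBandpass:
    def test_passband_tone_preserved_and_unshifted(self):
        rec = _sine_rec(40.0)
        out = assr_bandpass(rec).data[0]
        mid = slice(1000, 3000)
        assert np.abs(out[mid]).max() >= 0.95
        xc = np.correlate(out[mid], rec.data[0][mid], mode="full")
        shift = np.argmax(xc) - (len(out[mid]) - 1)
        assert abs(shift) <= 1

    @pytest.mark.parametrize("freq", [20.0, 80.0])
    def test_stopband_attenuation(self, freq):
        out = assr_bandpass(_sine_rec(freq)).data[0]
        assert np.abs(out[1000:3000]).max() < 0.5

    def test_dc_removed(self):
        rec = SignalRecording(np.vstack([np.full(4000, 7.0), np.zeros(4000)]),
                              FS, ["EEG1", "TRIG"])
        out = assr_bandpass(rec).data[0]
        assert np.abs(out[1000:3000]).max() < 1e-6

    def test_impulse_response_symmetric(self):
        x = np.zeros(4001)
        x[2000] = 1.0
        rec = SignalRecording(np.stack([x, np.zeros_like(x)]), FS,
                              ["EEG1", "TRIG"])
        h = assr_bandpass(rec).data[0]
        np.testing.assert_allclose(h, h[::-1], atol=1e-10)

    def test_invalid_band(self):
        with pytest.raises(ParameterError):
            assr_bandpass(_sine_rec(40.0), center_hz=40.0, half_width_hz=50.0)
        with pytest.raises(ParameterError):
            assr_bandpass(_sine_rec(40.0), center_hz=499.0)


class TestSegmentation:
    def test_epoch_length_2800_samples(self, quiet_cfg):
        proto = make_assr_protocol(10, 2.0, 40.0, 3.0, 1000)
        rec = render_session(proto, quiet_cfg)
        ep = segment_assr(rec)
        assert ep.n_trials == 10
        assert ep.n_samples == 2800

    def test_epoch_length_scales_with_rate(self):
        cfg = quiet_config(fs=500.0)
        proto = make_assr_protocol(3, 2.0, 40.0, 3.0, 500)
        ep = segment_assr(render_session(proto, cfg))
        assert ep.n_samples == 1400

    def test_train_without_post_context_excluded(self, quiet_cfg):
        proto = make_assr_protocol(5, 2.0, 40.0, 3.0, 1000)
        rec = render_session(proto, quiet_cfg)
        cut = SignalRecording(
            rec.data[:, : int(rec.events["onset_sample"].max()) + 100],
            rec.fs, list(rec.channel_labels),
            events=rec.events[rec.events["onset_sample"]
                              < rec.data.shape[1] - 100],
        )
        ep = segment_assr(cut)
        assert ep.n_trials == 4
        assert len(ep.excluded_events) == 1


class TestPower:
    def test_quadratic_in_entrainment_amplitude(self):
        proto = make_assr_protocol(8, 2.0, 40.0, 3.0, 1000)
        powers = {}
        for amp in (15.0, 30.0):
            cfg = quiet_config(seed=3, assr_amplitude_uV=amp)
            ep = segment_assr(assr_bandpass(render_session(proto, cfg)))
            powers[amp] = assr_power(ep)
        assert powers[30.0] / powers[15.0] == pytest.approx(4.0, rel=0.02)

    def test_zero_entrainment_noiseless_is_silent(self):
        proto = make_assr_protocol(4, 2.0, 40.0, 3.0, 1000)
        cfg = quiet_config(assr_amplitude_uV=0.0)
        ep = segment_assr(assr_bandpass(render_session(proto, cfg)))
        assert assr_power(ep) == pytest.approx(0.0, abs=1e-9)

    def test_power_is_phase_blind(self):
        proto = make_assr_protocol(60, 2.0, 40.0, 1.0, 1000)
        powers = []
        for jit in (0.0, 1.0):
            cfg = quiet_config(seed=9, assr_phase_jitter_rad_sd=jit)
            ep = segment_assr(assr_bandpass(render_session(proto, cfg)))
            powers.append(assr_power(ep))
        assert powers[1] == pytest.approx(powers[0], rel=0.05)


class TestItc:
    def test_identical_trials_fully_locked(self):
        t = np.arange(2800) / FS
        trial = np.sin(2 * np.pi * 40 * (t - 0.4))
        res = assr_itc(_epochs_from_trials(np.tile(trial, (10, 1))))
        assert res.itc_40hz == pytest.approx(1.0, abs=1e-9)

    def test_opposite_phases_cancel(self):
        t = np.arange(2800) / FS
        a = np.sin(2 * np.pi * 40 * t)
        res = assr_itc(_epochs_from_trials([a, -a]))
        assert res.itc_40hz == pytest.approx(0.0, abs=1e-9)

    def test_uniform_random_phases_rayleigh_floor(self):
        rng = np.random.default_rng(11)
        t = np.arange(2800) / FS
        vals = []
        for _ in range(8):
            phases = rng.uniform(0, 2 * np.pi, 100)
            trials = [np.sin(2 * np.pi * 40 * t + ph) for ph in phases]
            vals.append(assr_itc(_epochs_from_trials(trials)).itc_40hz)
        # resultant of n random unit vectors has mean length ~ sqrt(pi/(4n))
        assert np.mean(vals) == pytest.approx(np.sqrt(np.pi / 400), rel=0.35)

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(13)
        t = np.arange(2800) / FS
        trials = [np.sin(2 * np.pi * 40 * t + ph)
                  for ph in rng.normal(0, 0.7, 12)]
        base = assr_itc(_epochs_from_trials(trials)).itc_40hz
        scaled = [tr * s for tr, s in zip(trials, rng.uniform(0.2, 5.0, 12))]
        assert assr_itc(_epochs_from_trials(scaled)).itc_40hz == pytest.approx(
            base, abs=1e-9
        )

    @given(rot=st.floats(0.0, 2 * np.pi))
    def test_common_rotation_invariance(self, rot):
        t = np.arange(2800) / FS
        phases = [0.1, 0.5, 1.2, 2.0]
        base_trials = [np.sin(2 * np.pi * 40 * t + p) for p in phases]
        rot_trials = [np.sin(2 * np.pi * 40 * t + p + rot) for p in phases]
        a = assr_itc(_epochs_from_trials(base_trials)).itc_40hz
        b = assr_itc(_epochs_from_trials(rot_trials)).itc_40hz
        assert b == pytest.approx(a, abs=1e-7)

    def test_monotone_nonincreasing_in_jitter(self):
        proto = make_assr_protocol(120, 2.0, 40.0, 1.0, 1000)
        vals = []
        for jit in (0.0, 0.5, 1.0, 2.0):
            cfg = quiet_config(seed=19, assr_phase_jitter_rad_sd=jit)
            ep = segment_assr(assr_bandpass(render_session(proto, cfg)))
            vals.append(assr_itc(ep).itc_40hz)
        assert all(a >= b - 1e-6 for a, b in zip(vals, vals[1:]))
        assert vals[0] > vals[-1]

    def test_needs_two_trials(self):
        t = np.arange(2800) / FS
        with pytest.raises(AnalysisError):
            assr_itc(_epochs_from_trials([np.sin(2 * np.pi * 40 * t)]))

    def test_power_and_itc_are_independent_axes(self):
        proto = make_assr_protocol(60, 2.0, 40.0, 1.0, 1000)
        base_cfg = quiet_config(seed=29, assr_phase_jitter_rad_sd=0.4)
        amp_cfg = dataclasses.replace(base_cfg, assr_amplitude_uV=60.0)
        jit_cfg = dataclasses.replace(base_cfg, assr_phase_jitter_rad_sd=1.2)
        res = {
            name: assr_itc(segment_assr(assr_bandpass(render_session(proto, c))))
            for name, c in [("base", base_cfg), ("amp", amp_cfg), ("jit", jit_cfg)]
        }
        assert res["amp"].power_40hz / res["base"].power_40hz == pytest.approx(
            4.0, rel=0.05)
        assert res["amp"].itc_40hz == pytest.approx(res["base"].itc_40hz, abs=0.02)
        assert res["jit"].power_40hz == pytest.approx(res["base"].power_40hz,
                                                      rel=0.1)
        assert res["jit"].itc_40hz < res["base"].itc_40hz - 0.2
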