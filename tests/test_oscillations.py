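"""Morlet decomposition and basal/evoked band-power readouts."""

import dataclasses

import numpy as np
import pytest

from conftest import quiet_config
from mouseeg.errors import AnalysisError, ParameterError
from mouseeg.oscillations import (
    GAMMA,
    THETA,
    MorletSpec,
    basal_power,
    evoked_band_power,
    morlet_kernel,
    normalize_to_recording,
    transform_array,
    whole_recording_band_power,
)
from mouseeg.protocols import make_paired_click_protocol
from mouseeg.simulate import BurstSpec, DrugEffect, SimConfig, render_session
from mouseeg import erp

FS = 1000.0


def _chirp(n=1000):
    t = np.arange(n) / FS
    return np.sin(2 * np.pi * (38 * t + 15 * t**2))


class TestTransform:
    def test_matches_direct_convolution_oracle(self):
        x = _chirp()
        freqs = np.array([35.0, 47.0, 63.0, 80.0])
        tfr = transform_array(x, FS, freqs)
        for i, f in enumerate(freqs):
            psi = morlet_kernel(f, FS)
            oracle = np.convolve(x, psi, mode="same") / FS
            sel = tfr.valid[i]
            err = np.abs(tfr.coefs[0, i, sel] - oracle[sel]).max()
            assert err / np.abs(oracle[sel]).max() < 1e-9

    def test_pure_tone_peaks_at_own_layer(self):
        t = np.arange(1000) / FS
        tfr = transform_array(np.sin(2 * np.pi * 50 * t), FS, GAMMA.frequencies)
        p = np.nanmean(
            np.where(tfr.valid[None], np.abs(tfr.coefs) ** 2, np.nan), axis=2
        )[0]
        assert GAMMA.frequencies[np.argmax(p)] == 50.0

    def test_power_scales_quadratically(self):
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 50 * t)
        f = np.array([50.0])
        p1 = transform_array(x, FS, f)
        p2 = transform_array(2 * x, FS, f)
        sel = p1.valid[0]
        ratio = (np.abs(p2.coefs[0, 0, sel]) ** 2) / (np.abs(p1.coefs[0, 0, sel]) ** 2)
        np.testing.assert_allclose(ratio, 4.0, rtol=1e-9)

    def test_unit_tone_layer_power(self):
        t = np.arange(2000) / FS
        tfr = transform_array(np.sin(2 * np.pi * 40 * t), FS, np.array([40.0]))
        sel = tfr.valid[0]
        assert np.abs(tfr.coefs[0, 0, sel]).mean() ** 2 == pytest.approx(0.25,
                                                                         rel=0.01)

    def test_too_short_epoch_lists_usable_layers(self):
        with pytest.raises(AnalysisError, match="usable layers"):
            transform_array(np.zeros(300), FS, THETA.frequencies)

    def test_edge_coefficients_marked_invalid(self):
        tfr = transform_array(np.ones(1000), FS, np.array([35.0]))
        half = (len(morlet_kernel(35.0, FS)) - 1) // 2
        assert not tfr.valid[0, :half].any()
        assert tfr.valid[0, half : 1000 - half].all()


class TestBandPower:
    def test_noiseless_recording_has_no_basal_power(self, quiet_cfg):
        proto = make_paired_click_protocol(3, 0.5, 4.0, 1000)
        rec = render_session(proto, quiet_cfg)
        on = rec.events[rec.events.label == "click1"]["onset_sample"].to_numpy()
        assert basal_power(rec, on, GAMMA) == pytest.approx(0.0, abs=1e-12)

    def test_basal_gamma_scale_recovery(self):
        # pure band-limited gamma noise: power must track the variance knob
        proto = make_paired_click_protocol(60, 0.5, 4.0, 1000)
        vals = {}
        for s in (1.0, 2.0):
            cfg = SimConfig(noise_sd_uV=0.0, basal_theta_sd_uV=0.0,
                            basal_gamma_sd_uV=8.0, seed=17)
            rec = render_session(proto, cfg, DrugEffect(basal_gamma_scale=s))
            on = rec.events[rec.events.label == "click1"]["onset_sample"].to_numpy()
            vals[s] = basal_power(rec, on, GAMMA)
        assert vals[2.0] / vals[1.0] == pytest.approx(2.0, rel=0.1)

    def test_bin_outside_recording_is_error(self, quiet_cfg):
        proto = make_paired_click_protocol(2, 0.5, 4.0, 1000)
        rec = render_session(proto, quiet_cfg)
        with pytest.raises(AnalysisError):
            basal_power(rec, np.array([100]), GAMMA)

    def test_evoked_zero_for_stationary_noise(self):
        # no stimulus-locked content at all: bursts off AND deflections off
        # (a 120 µV Gaussian bump has real gamma-band energy of its own)
        cfg = quiet_config(seed=23, basal_gamma_sd_uV=10.0)
        cfg.erp_components = ()
        proto = make_paired_click_protocol(60, 0.5, 4.0, 1000)
        rec = render_session(proto, cfg)
        click1 = rec.events[rec.events.label == "click1"]
        on = click1["onset_sample"].to_numpy()
        bas = basal_power(rec, on, GAMMA)
        ep = erp.segment(rec, click1, pre_ms=1200.0, post_ms=1400.0)
        ev = evoked_band_power(ep, GAMMA, (-5.0, 45.0), bas)
        assert abs(ev) < 0.35 * bas

    def test_evoked_monotone_in_burst_amplitude(self):
        proto = make_paired_click_protocol(10, 0.5, 4.0, 1000)
        out = []
        for amp in (10.0, 20.0, 40.0):
            cfg = quiet_config(seed=2)
            cfg = dataclasses.replace(
                cfg, gamma_burst=BurstSpec(50.0, amp, 20.0, 10.0)
            )
            rec = render_session(proto, cfg)
            click1 = rec.events[rec.events.label == "click1"]
            ep = erp.segment(rec, click1, pre_ms=1200.0, post_ms=1400.0)
            on = click1["onset_sample"].to_numpy()
            out.append(evoked_band_power(ep, GAMMA, (-5.0, 45.0),
                                         basal_power(rec, on, GAMMA)))
        assert out[0] < out[1] < out[2]

    def test_evoked_insensitive_to_basal_level(self):
        # burst fixed, basal noise variance doubled: evoked ~ unchanged
        proto = make_paired_click_protocol(60, 0.5, 4.0, 1000)
        res = []
        for s in (1.0, 2.0):
            cfg = SimConfig(noise_sd_uV=0.0, basal_theta_sd_uV=0.0,
                            basal_gamma_sd_uV=6.0, seed=31)
            rec = render_session(proto, cfg, DrugEffect(basal_gamma_scale=s))
            click1 = rec.events[rec.events.label == "click1"]
            on = click1["onset_sample"].to_numpy()
            ep = erp.segment(rec, click1, pre_ms=1200.0, post_ms=1400.0)
            res.append(evoked_band_power(ep, GAMMA, (-5.0, 45.0),
                                         basal_power(rec, on, GAMMA)))
        assert res[1] == pytest.approx(res[0], abs=0.35 * abs(res[0]))

    def test_power_additivity_uncorrelated(self):
        rng = np.random.default_rng(5)
        t = np.arange(2000) / FS
        burst = 10 * np.sin(2 * np.pi * 50 * t)
        noise = rng.normal(0, 8, (100, 2000))
        f = np.array([50.0])

        def mean_power(x):
            tfr = transform_array(x, FS, f)
            return np.abs(tfr.coefs[:, 0, tfr.valid[0]] ** 2).mean()

        total = mean_power(burst[None, :] + noise)
        parts = mean_power(np.tile(burst, (1, 1))) + mean_power(noise)
        assert total == pytest.approx(parts, rel=0.1)


class TestNormalization:
    def _rec(self, scale=1.0, seed=41):
        cfg = quiet_config(seed=seed, basal_gamma_sd_uV=8.0 * scale)
        cfg.erp_components = ()  # pure stationary band noise
        proto = make_paired_click_protocol(10, 0.5, 4.0, 1000)
        return render_session(proto, cfg)

    def test_whole_recording_mean_normalizes_to_one(self):
        rec = self._rec()
        mean_power = whole_recording_band_power(rec, GAMMA)
        assert normalize_to_recording(mean_power, rec, GAMMA) == pytest.approx(1.0)

    def test_zero_value_normalizes_to_zero(self):
        assert normalize_to_recording(0.0, self._rec(), GAMMA) == 0.0

    def test_scale_invariance(self):
        rec1, rec2 = self._rec(1.0), self._rec(2.0)
        v1 = basal_power(
            rec1, rec1.events[rec1.events.label == "click1"]["onset_sample"].to_numpy(),
            GAMMA)
        v2 = basal_power(
            rec2, rec2.events[rec2.events.label == "click1"]["onset_sample"].to_numpy(),
            GAMMA)
        n1 = normalize_to_recording(v1, rec1, GAMMA)
        n2 = normalize_to_recording(v2, rec2, GAMMA)
        assert n2 == pytest.approx(n1, rel=0.05)

    def test_short_recording_rejected(self):
        from mouseeg.simulate import SignalRecording

        rec = SignalRecording(np.ones((2, 5000)), 1000.0, ["EEG1", "TRIG"])
        with pytest.raises(ParameterError):
            normalize_to_recording(1.0, rec, GAMMA)

    def test_zero_normalizer_rejected(self):
        from mouseeg.simulate import SignalRecording

        rec = SignalRecording(np.zeros((2, 20000)), 1000.0, ["EEG1", "TRIG"])
        with pytest.raises(AnalysisError, match="zero"):
            normalize_to_recording(1.0, rec, GAMMA)


class TestMorletSpec:
    def test_gamma_layer_set(self):
        assert len(GAMMA.frequencies) == 46
        assert GAMMA.frequencies[0] == 35.0 and GAMMA.frequencies[-1] == 80.0

    def test_invalid_band(self):
        with pytest.raises(ParameterError):
            MorletSpec(50.0, 40.0)
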