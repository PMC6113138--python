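"""Synthetic mouse-EEG generator.

Produces multichannel recordings (µV, two cortical channels plus a trigger
channel) with the statistical structure every analysis stage assumes, so that
each biomarker has a known ground truth:

* 1/f ("pink") or white background noise, plus stationary band-limited noise
  floors in the gamma (35–80 Hz) and theta (4–12 Hz) bands that play the role
  of *basal* oscillatory power;
* stimulus-locked ERP deflections modeled as Gaussian-windowed bumps (P20,
  N40, P80, P120 by default — the murine analogues of the human P50, N100,
  P200, P300), with per-trial latency and amplitude jitter;
* sensory gating: the N1 of the second click of a pair is scaled by a
  ``gating_factor`` in [0, 1];
* brief gamma- and theta-band bursts time-locked near the P1 latency, which
  realize *evoked* oscillatory power;
* 40 Hz steady-state entrainment during click trains, with per-trial phase
  offsets drawn from a normal distribution (the knob behind intertrial
  coherence);
* oddball deviance: the deviant tone's N1 is scaled up relative to the
  standard's, producing a mismatch-negativity difference wave;
* per-animal persistent multiplicative offsets (random-intercept structure)
  and "drug effects" expressed as multiplicative changes to the generative
  parameters.

Scales are conventions chosen to resemble epidural mouse EEG (ERP deflections
of order 100 µV on a noise floor of a few tens of µV); only relative changes
matter to the implemented measures.

Determinism: a single master seed spawns independent substreams for the
background noise, the per-trial jitter and the artifact injection, so adding
or removing one source leaves the others bit-identical, and each animal ×
treatment cell of a cohort gets its own substream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .protocols import TRIGGER_LABELS

__all__ = [
    "SimulationError",
    "ErpComponentSpec",
    "BurstSpec",
    "SimConfig",
    "DrugEffect",
    "SignalRecording",
    "default_erp_components",
    "generate_background",
    "render_session",
    "simulate_cohort",
    "iter_cohort",
]

TRIGGER_CHANNEL = "TRIG"
TRIGGER_PULSE_UV = 500.0
TRIGGER_PULSE_MS = 10.0


class SimulationError(ValueError):
    """Invalid simulation parameters or impossible render request."""


@dataclass(frozen=True)
class ErpComponentSpec:
    """One ERP deflection: a Gaussian bump in time.

    ``amplitude_uV`` is signed (negative = trough); ``width_ms`` is the
    Gaussian standard deviation. Per-trial jitter: latency shifts are drawn
    from N(0, ``jitter_latency_ms_sd``) and amplitudes are multiplied by
    ``1 + N(0, jitter_amp_frac_sd)``.
    """

    name: str
    latency_ms: float
    width_ms: float
    amplitude_uV: float
    jitter_latency_ms_sd: float = 0.0
    jitter_amp_frac_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise SimulationError("component width must be positive")
        if self.jitter_latency_ms_sd < 0 or self.jitter_amp_frac_sd < 0:
            raise SimulationError("jitter standard deviations must be >= 0")


def default_erp_components(
    jitter_latency_ms_sd: float = 1.5, jitter_amp_frac_sd: float = 0.08
) -> tuple[ErpComponentSpec, ...]:
    """P20/N40/P80/P120 family with a 180 µV P1N1 span (inclusion floor 100 µV)."""
    mk = lambda n, lat, w, a: ErpComponentSpec(
        n, lat, w, a, jitter_latency_ms_sd, jitter_amp_frac_sd
    )
    return (
        mk("P1", 20.0, 6.0, 60.0),
        mk("N1", 40.0, 8.0, -120.0),
        mk("P80", 80.0, 15.0, 50.0),
        mk("P120", 120.0, 25.0, 35.0),
    )


@dataclass(frozen=True)
class BurstSpec:
    """Stimulus-locked oscillatory burst (Gaussian-windowed sinusoid)."""

    freq_hz: float
    amplitude_uV: float
    center_ms: float
    width_ms: float  # Gaussian sd of the envelope


@dataclass
class SimConfig:
    """Generative parameters for one cohort (before drug effects).

    All amplitudes in µV, times in ms unless suffixed otherwise. Multiplying
    a ``*_scale`` knob of :class:`DrugEffect` rescales the matching parameter
    before rendering.
    """

    fs: float = 1000.0
    noise_spectrum: str = "pink"  # "pink" | "white"
    noise_sd_uV: float = 15.0
    basal_gamma_sd_uV: float = 8.0
    basal_theta_sd_uV: float = 12.0
    gamma_band: tuple[float, float] = (35.0, 80.0)
    theta_band: tuple[float, float] = (4.0, 12.0)
    erp_components: tuple[ErpComponentSpec, ...] = field(
        default_factory=default_erp_components
    )
    gating_factor: float = 0.5
    gamma_burst: BurstSpec = field(
        default_factory=lambda: BurstSpec(50.0, 25.0, 20.0, 10.0)
    )
    theta_burst: BurstSpec = field(
        default_factory=lambda: BurstSpec(8.0, 40.0, 100.0, 35.0)
    )
    assr_amplitude_uV: float = 30.0
    assr_phase_jitter_rad_sd: float = 0.4
    assr_rate_hz: float = 40.0
    assr_train_s: float = 2.0
    mmn_deviant_n1_scale: float = 1.8
    animal_offsets_sd: float = 0.15
    artifact_rate: float = 0.0
    artifact_amp_uV: float = 1500.0
    n_channels: int = 2
    lead_in_s: float = 5.0
    tail_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_spectrum not in ("pink", "white"):
            raise SimulationError(f"unknown noise spectrum {self.noise_spectrum!r}")
        if not 0.0 <= self.gating_factor <= 1.0:
            raise SimulationError("gating_factor must lie in [0, 1]")
        for name in ("noise_sd_uV", "basal_gamma_sd_uV", "basal_theta_sd_uV",
                     "assr_phase_jitter_rad_sd", "animal_offsets_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.mmn_deviant_n1_scale < 1.0:
            raise SimulationError("mmn_deviant_n1_scale must be >= 1")


@dataclass(frozen=True)
class DrugEffect:
    """Multiplicative treatment effect on the generative parameters.

    ``*_scale`` knobs are positive multipliers in the *power* sense for the
    oscillatory readouts (a ``basal_gamma_scale`` of 2 doubles basal gamma
    power) and in the amplitude sense for ERP components. ``assr_jitter_add_rad``
    adds to the per-trial phase-jitter standard deviation.
    """

    n1_scale: float = 1.0
    basal_gamma_scale: float = 1.0
    evoked_gamma_scale: float = 1.0
    theta_scale: float = 1.0
    assr_amp_scale: float = 1.0
    assr_jitter_add_rad: float = 0.0
    mmn_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n1_scale", "basal_gamma_scale", "evoked_gamma_scale",
                     "theta_scale", "assr_amp_scale", "mmn_scale"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be > 0")
        if self.assr_jitter_add_rad < 0:
            raise SimulationError("assr_jitter_add_rad must be >= 0")


IDENTITY_EFFECT = DrugEffect()

#: a strong NMDA-antagonist-like effect: N1 down, basal gamma up, evoked
#: gamma down, evoked theta down, ASSR power and phase locking down, MMN down.
ANTAGONIST_HIGH_DOSE = DrugEffect(
    n1_scale=0.5,
    basal_gamma_scale=2.5,
    evoked_gamma_scale=0.4,
    theta_scale=0.5,
    assr_amp_scale=0.5,
    assr_jitter_add_rad=0.8,
    mmn_scale=0.5,
)


@dataclass
class SignalRecording:
    """Multichannel time series in µV with labeled events.

    ``data`` is channels × samples; channels whose label is not ``TRIG`` are
    EEG signal channels. ``events`` uses recording-relative onset samples.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    events: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if np.isnan(self.data).any():
            raise SimulationError("recording contains NaN")
        if len(self.channel_labels) != self.data.shape[0]:
            raise SimulationError("channel label count does not match data")
        if self.events is not None and len(self.events):
            o = self.events["onset_sample"].to_numpy()
            if o.min() < 0 or o.max() >= self.n_samples:
                raise SimulationError("event onsets outside recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def signal_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.channel_labels) if c != TRIGGER_CHANNEL]

    @property
    def trigger_index(self) -> int | None:
        for i, c in enumerate(self.channel_labels):
            if c == TRIGGER_CHANNEL:
                return i
        return None

    def signal_data(self) -> np.ndarray:
        return self.data[self.signal_indices]

    def channel_mean(self) -> np.ndarray:
        """Mean across the EEG signal channels (the analysis trace)."""
        return self.signal_data().mean(axis=0)


# ---------------------------------------------------------------------------
# noise synthesis


def _pink_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Zero-mean noise with power spectral density ∝ 1/f, normalized to sd."""
    white = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    w = np.zeros_like(f)
    w[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * w, n)
    x -= x.mean()
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float], sd: float
) -> np.ndarray:
    """Stationary band-limited Gaussian noise with realization sd equal to sd."""
    white = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    x -= x.mean()
    s = x.std()
    return x * (sd / s) if s > 0 else x


def generate_background(
    duration_s: float, cfg: SimConfig, *, include_band_noise: bool = True
) -> SignalRecording:
    """Background-only recording (no stimuli, flat trigger channel).

    Deterministic under ``cfg.seed``: the noise substream is the same one
    :func:`render_session` uses, so a background render and a noiseless
    stimulus render add up to the full render sample-for-sample.
    """
    if duration_s <= 0:
        raise SimulationError("duration_s must be positive")
    n = int(round(duration_s * cfg.fs))
    noise_rng = np.random.Generator(
        np.random.Philox(np.random.SeedSequence([cfg.seed, 0]))
    )
    data = np.zeros((cfg.n_channels + 1, n))
    for ch in range(cfg.n_channels):
        if cfg.noise_spectrum == "pink":
            base = _pink_noise(noise_rng, n, cfg.fs, cfg.noise_sd_uV)
        else:
            base = cfg.noise_sd_uV * noise_rng.standard_normal(n)
        data[ch] = base
        if include_band_noise:
            data[ch] += _band_noise(noise_rng, n, cfg.fs, cfg.gamma_band,
                                    cfg.basal_gamma_sd_uV)
            data[ch] += _band_noise(noise_rng, n, cfg.fs, cfg.theta_band,
                                    cfg.basal_theta_sd_uV)
    labels = [f"EEG{i + 1}" for i in range(cfg.n_channels)] + [TRIGGER_CHANNEL]
    return SignalRecording(data, cfg.fs, labels, meta={"seed": cfg.seed})


# ---------------------------------------------------------------------------
# session rendering


def _add_gaussian_bump(
    trace: np.ndarray, fs: float, onset: int, latency_ms: float, width_ms: float,
    amp: float,
) -> None:
    sd = width_ms / 1000.0 * fs
    center = onset + latency_ms / 1000.0 * fs
    lo = max(0, int(math.floor(center - 5 * sd)))
    hi = min(trace.size, int(math.ceil(center + 5 * sd)) + 1)
    if lo >= hi:
        return
    idx = np.arange(lo, hi)
    trace[lo:hi] += amp * np.exp(-((idx - center) ** 2) / (2 * sd * sd))


def _add_burst(
    trace: np.ndarray, fs: float, onset: int, burst: BurstSpec, amp_scale: float
) -> None:
    sd = burst.width_ms / 1000.0 * fs
    center = onset + burst.center_ms / 1000.0 * fs
    lo = max(0, int(math.floor(center - 5 * sd)))
    hi = min(trace.size, int(math.ceil(center + 5 * sd)) + 1)
    if lo >= hi:
        return
    idx = np.arange(lo, hi)
    env = np.exp(-((idx - center) ** 2) / (2 * sd * sd))
    carrier = np.cos(2 * np.pi * burst.freq_hz * (idx - onset) / fs)
    trace[lo:hi] += burst.amplitude_uV * amp_scale * env * carrier


def render_session(
    protocol: pd.DataFrame,
    cfg: SimConfig,
    effect: DrugEffect | None = None,
    *,
    animal_gain: float = 1.0,
    meta: Mapping | None = None,
) -> SignalRecording:
    """Render a stimulation session into a :class:`SignalRecording`.

    The recording starts ``cfg.lead_in_s`` before the first stimulus (so
    every trial has pre-stimulus context) and ends ``cfg.tail_s`` after the
    last. Event onsets in the returned table are recording-relative. A 10 ms
    +500 µV rectangular pulse marks every trial-level event on the trigger
    channel. ``animal_gain`` multiplies the whole EEG trace (noise and
    signal), emulating a persistent per-animal amplitude offset.
    """
    if protocol is None or not len(protocol):
        raise SimulationError("protocol is empty")
    eff = effect or IDENTITY_EFFECT
    fs = cfg.fs
    lead = int(round(cfg.lead_in_s * fs))
    last = int(protocol["onset_sample"].max())
    n = int(math.ceil((lead + last + cfg.tail_s * fs) / fs) * fs)

    ss = np.random.SeedSequence([cfg.seed, 0])
    noise_rng = np.random.Generator(np.random.Philox(ss))
    trial_rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([cfg.seed, 1])))
    artifact_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))

    events = protocol.copy()
    events["onset_sample"] = events["onset_sample"].astype(np.int64) + lead
    events["onset_s"] = events["onset_sample"] / fs
    beyond = events["onset_sample"] >= n
    if beyond.any():
        raise SimulationError(
            f"event index {int(np.flatnonzero(beyond)[0])} beyond rendered duration"
        )

    # --- noise (per channel, independent; own substream) ---
    gamma_sd = cfg.basal_gamma_sd_uV * math.sqrt(eff.basal_gamma_scale)
    noise = np.zeros((cfg.n_channels, n))
    for ch in range(cfg.n_channels):
        if cfg.noise_spectrum == "pink":
            noise[ch] = _pink_noise(noise_rng, n, fs, cfg.noise_sd_uV)
        else:
            noise[ch] = cfg.noise_sd_uV * noise_rng.standard_normal(n)
        noise[ch] += _band_noise(noise_rng, n, fs, cfg.gamma_band, gamma_sd)
        noise[ch] += _band_noise(noise_rng, n, fs, cfg.theta_band, cfg.basal_theta_sd_uV)

    # --- stimulus-locked signal (shared across EEG channels; own substream) ---
    sig = np.zeros(n)
    trig = np.zeros(n)
    pulse = int(round(TRIGGER_PULSE_MS / 1000.0 * fs))
    jitter_sd = cfg.assr_phase_jitter_rad_sd + eff.assr_jitter_add_rad
    train_len = int(round(cfg.assr_train_s * fs))
    dev_scale = cfg.mmn_deviant_n1_scale * eff.mmn_scale

    for row in events.itertuples(index=False):
        onset = int(row.onset_sample)
        label = row.label
        if label in TRIGGER_LABELS:
            trig[onset:onset + pulse] = TRIGGER_PULSE_UV
        if label in ("click1", "click2", "standard", "deviant"):
            for comp in cfg.erp_components:
                lat = comp.latency_ms + trial_rng.normal(0, comp.jitter_latency_ms_sd)
                amp = comp.amplitude_uV * (
                    1.0 + trial_rng.normal(0, comp.jitter_amp_frac_sd)
                )
                if comp.name == "N1":
                    amp *= eff.n1_scale
                    if label == "click2":
                        amp *= cfg.gating_factor
                    if label == "deviant":
                        amp *= dev_scale
                _add_gaussian_bump(sig, fs, onset, lat, comp.width_ms, amp)
            if label in ("click1", "click2"):
                _add_burst(sig, fs, onset, cfg.gamma_burst,
                           math.sqrt(eff.evoked_gamma_scale))
                _add_burst(sig, fs, onset, cfg.theta_burst,
                           math.sqrt(eff.theta_scale))
        elif label == "train_onset":
            phase = trial_rng.normal(0, jitter_sd)
            hi = min(n, onset + train_len)
            t = np.arange(onset, hi) - onset
            sig[onset:hi] += (
                cfg.assr_amplitude_uV * eff.assr_amp_scale
                * np.cos(2 * np.pi * cfg.assr_rate_hz * t / fs + phase)
            )
        # per-click 'click' children carry no waveform of their own

    if cfg.artifact_rate > 0:
        for row in events.itertuples(index=False):
            if row.label in TRIGGER_LABELS and artifact_rng.random() < cfg.artifact_rate:
                onset = int(row.onset_sample) + int(0.1 * fs)
                width = int(0.03 * fs)
                sig[onset:onset + width] += cfg.artifact_amp_uV

    data = np.vstack([animal_gain * (noise + sig[None, :]), trig[None, :]])
    labels = [f"EEG{i + 1}" for i in range(cfg.n_channels)] + [TRIGGER_CHANNEL]
    rec_meta = {"seed": cfg.seed, "animal_gain": animal_gain}
    if meta:
        rec_meta.update(meta)
    return SignalRecording(data, fs, labels, events=events, meta=rec_meta)


# ---------------------------------------------------------------------------
# cohorts


def animal_gains(n_animals: int, cfg: SimConfig) -> np.ndarray:
    """Persistent per-animal multiplicative offsets, 1 + N(0, offsets_sd)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    g = 1.0 + rng.normal(0.0, cfg.animal_offsets_sd, size=n_animals)
    return np.clip(g, 0.05, None)


def iter_cohort(
    protocol: pd.DataFrame,
    n_animals: int,
    treatments: Sequence[str],
    cfg: SimConfig,
    effects: Mapping[str, DrugEffect],
) -> Iterator[SignalRecording]:
    """Yield one recording per animal × treatment (row-major by animal).

    Each animal keeps one multiplicative gain across all its treatments (the
    random-intercept structure of the within-subject design); each cell gets
    an independent seed substream derived from ``cfg.seed``.
    """
    if n_animals < 2:
        raise SimulationError("n_animals must be >= 2 for the mixed model")
    unknown = [t for t in treatments if t not in effects]
    if unknown:
        raise SimulationError(f"no DrugEffect given for treatments: {unknown}")
    gains = animal_gains(n_animals, cfg)
    for a in range(n_animals):
        for ti, treat in enumerate(treatments):
            sub_seed = int(
                np.random.SeedSequence([cfg.seed, 100 + a, ti]).generate_state(1)[0]
                % (2**31 - 1)
            )
            sub_cfg = replace(cfg, seed=sub_seed)
            yield render_session(
                protocol,
                sub_cfg,
                effects[treat],
                animal_gain=float(gains[a]),
                meta={"animal_id": f"m{a:02d}", "treatment": treat},
            )


def simulate_cohort(
    protocol: pd.DataFrame,
    n_animals: int,
    treatments: Sequence[str],
    cfg: SimConfig,
    effects: Mapping[str, DrugEffect],
) -> list[SignalRecording]:
    """Materialized :func:`iter_cohort` (one recording per animal × treatment)."""
    return list(iter_cohort(protocol, n_animals, treatments, cfg, effects))
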