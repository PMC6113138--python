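"""Event-related potential analysis.

Segmentation around stimulus onsets (default 200 ms pre / 1000 ms post),
per-trial baseline normalization to the pre-stimulus mean, trial averaging,
N1 measurement (maximum negative deflection 30–50 ms post-stimulus, the
murine N40), the paired-click sensory-gating ratio, and the P1N1 amplitude
screen used for animal inclusion.

Conventions: the N1 is measured on the trial-average waveform; epochs carry
the mean of the two cortical channels into the scalar measures; the gating
ratio is reported as S2/S1 (|N1 of click2| / |N1 of click1|) so that gating
disruption *increases* the readout — intact gating gives values well below 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import AnalysisError, ParameterError
from .simulate import SignalRecording

__all__ = [
    "EpochSet",
    "Waveform",
    "ErpMeasure",
    "segment",
    "baseline_correct",
    "average_erp",
    "measure_n1",
    "gating_ratio",
    "screen_animal",
]


@dataclass
class EpochSet:
    """Trials × channels × samples cut around stimulus onsets.

    ``data`` is in µV; time 0 is stimulus onset; sample ``i`` sits at
    ``(i - n_pre)/fs`` seconds. ``kept`` is the artifact-rejection mask
    (True = analyze); ``excluded_events`` lists protocol rows that lacked
    full pre/post context in the recording.
    """

    data: np.ndarray
    fs: float
    pre_ms: float
    post_ms: float
    labels: np.ndarray
    kept: np.ndarray = None  # type: ignore[assignment]
    excluded_events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ParameterError("epoch data must be trials x channels x samples")
        if self.kept is None:
            self.kept = np.ones(self.n_trials, dtype=bool)
        self.kept = np.asarray(self.kept, dtype=bool)
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.n_trials or len(self.kept) != self.n_trials:
            raise ParameterError("labels/kept length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_pre(self) -> int:
        return int(round(self.pre_ms / 1000.0 * self.fs))

    @property
    def times_ms(self) -> np.ndarray:
        return (np.arange(self.n_samples) - self.n_pre) / self.fs * 1000.0

    def channel_mean(self) -> np.ndarray:
        """Trials × samples mean across channels."""
        return self.data.mean(axis=1)

    def kept_data(self) -> np.ndarray:
        return self.data[self.kept]

    def select(self, label: str) -> "EpochSet":
        m = self.labels == label
        return replace(
            self, data=self.data[m], labels=self.labels[m], kept=self.kept[m]
        )


@dataclass
class Waveform:
    """A single time series locked to stimulus onset (µV vs. ms)."""

    t_ms: np.ndarray
    data: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.t_ms.shape != self.data.shape:
            raise ParameterError("waveform time and data shapes differ")


@dataclass(frozen=True)
class ErpMeasure:
    """Scalar ERP readouts from one average waveform."""

    n1_amplitude_uV: float
    n1_latency_ms: float
    p1_amplitude_uV: float
    p1_latency_ms: float

    @property
    def p1n1_uV(self) -> float:
        """Peak-to-trough span P1 − N1 (positive for a normal ERP)."""
        return self.p1_amplitude_uV - self.n1_amplitude_uV


def segment(
    rec: SignalRecording,
    events: pd.DataFrame | None = None,
    *,
    label: str | None = None,
    pre_ms: float = 200.0,
    post_ms: float = 1000.0,
) -> EpochSet:
    """Cut one epoch per event from the EEG signal channels.

    Events whose pre/post window does not fit inside the recording are
    excluded and reported in ``excluded_events``. Raises
    :class:`AnalysisError` if no usable event remains.
    """
    if events is None:
        events = rec.events
    if events is None or not len(events):
        raise AnalysisError("no events to segment around")
    if label is not None:
        events = events[events["label"] == label]
        if not len(events):
            raise AnalysisError(f"no events with label {label!r}")
    if pre_ms < 0 or post_ms <= 0:
        raise ParameterError("pre_ms must be >= 0 and post_ms > 0")
    n_pre = int(round(pre_ms / 1000.0 * rec.fs))
    n_post = int(round(post_ms / 1000.0 * rec.fs))
    sig = rec.signal_data()
    trials, labels, excluded = [], [], []
    for row in events.itertuples(index=True):
        onset = int(row.onset_sample)
        lo, hi = onset - n_pre, onset + n_post
        if lo < 0 or hi > rec.n_samples:
            excluded.append(row.Index)
            continue
        trials.append(sig[:, lo:hi])
        labels.append(row.label)
    if not trials:
        raise AnalysisError("no event has full pre/post context in the recording")
    return EpochSet(
        np.stack(trials), rec.fs, pre_ms, post_ms, np.asarray(labels),
        excluded_events=excluded,
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the pre-stimulus mean per trial and channel."""
    if epochs.n_pre == 0:
        raise AnalysisError("baseline correction needs a pre-stimulus window")
    base = epochs.data[:, :, : epochs.n_pre].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def average_erp(epochs: EpochSet) -> Waveform:
    """Pointwise mean across kept trials, averaged over channels."""
    if not epochs.kept.any():
        raise AnalysisError("no trials remain after rejection")
    avg = epochs.kept_data().mean(axis=0).mean(axis=0)
    return Waveform(epochs.times_ms, avg)


def _extremum(
    wave: Waveform, window_ms: tuple[float, float], mode: str
) -> tuple[float, float]:
    lo, hi = window_ms
    if lo >= hi:
        raise ParameterError("window bounds must be increasing")
    m = (wave.t_ms >= lo) & (wave.t_ms <= hi)
    if not m.any():
        raise ParameterError(
            f"window {window_ms} ms lies outside the epoch "
            f"({wave.t_ms[0]:.0f}..{wave.t_ms[-1]:.0f} ms)"
        )
    seg = wave.data[m]
    idx = int(np.argmin(seg) if mode == "min" else np.argmax(seg))  # earliest tie
    return float(seg[idx]), float(wave.t_ms[m][idx])


def measure_n1(
    wave: Waveform,
    window_ms: tuple[float, float] = (30.0, 50.0),
    p1_window_ms: tuple[float, float] = (15.0, 30.0),
) -> ErpMeasure:
    """Measure N1 (and P1) on an average ERP.

    N1 amplitude is the minimum value in ``window_ms`` (signed, normally
    negative) and its latency the time of that minimum, ties broken to the
    earliest sample. P1 is the maximum in ``p1_window_ms``.
    """
    n1_amp, n1_lat = _extremum(wave, window_ms, "min")
    p1_amp, p1_lat = _extremum(wave, p1_window_ms, "max")
    return ErpMeasure(n1_amp, n1_lat, p1_amp, p1_lat)


def gating_ratio(m1: ErpMeasure, m2: ErpMeasure) -> float:
    """Sensory gating ratio S2/S1 = |N1(click2)| / |N1(click1)|.

    Intact gating < 1; disrupted gating approaches (or exceeds) 1.
    """
    if m1.n1_amplitude_uV == 0:
        raise AnalysisError("gating ratio undefined: click1 N1 amplitude is zero")
    return abs(m2.n1_amplitude_uV) / abs(m1.n1_amplitude_uV)


def screen_animal(measure: ErpMeasure, min_p1n1_uV: float = 100.0) -> bool:
    """Animal inclusion screen: keep animals whose P1N1 span reaches the floor."""
    return measure.p1n1_uV >= min_p1n1_uV
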