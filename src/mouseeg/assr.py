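"""40 Hz auditory steady-state response (ASSR) analysis.

A click train at 40 Hz entrains a cortical oscillation; two readouts
characterize it per session:

* **ASSR power** — the accumulated power of the 40 Hz Morlet layer over the
  2 s stimulation window, averaged across trials (amplitude-sensitive,
  phase-blind);
* **intertrial coherence (ITC)**, also called the phase-locking factor — at
  each time point, the magnitude of the across-trial mean of the
  unit-normalized complex coefficients, ``ITC(t) = |mean_k c_k(t)/|c_k(t)||``.
  It ranges from 0 (random phase across trials) to 1 (perfect phase locking)
  and is invariant to per-trial amplitude scaling. The scalar readout is the
  time-mean (optionally median) of ITC(t) over the trial window.

Preprocessing follows the standard recipe: a zero-phase (forward–backward)
second-order Butterworth band-pass 5 Hz either side of the stimulation
frequency (35–45 Hz for 40 Hz), then 2.8 s epochs with 400 ms pre-trial,
2 s trial and 400 ms post-trial periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .erp import EpochSet, segment
from .errors import AnalysisError, ParameterError
from .oscillations import transform_array
from .simulate import SignalRecording

__all__ = [
    "AssrResult",
    "assr_bandpass",
    "segment_assr",
    "assr_power",
    "assr_itc",
]


@dataclass
class AssrResult:
    """Per-session ASSR summary at the stimulation frequency."""

    power_40hz: float
    itc_40hz: float
    itc_curve: np.ndarray
    itc_times_ms: np.ndarray
    n_trials: int
    n_excluded_coefs: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.itc_40hz <= 1.0 + 1e-12):
            raise AnalysisError("ITC outside [0, 1]; inconsistent coefficients")


def assr_bandpass(
    rec: SignalRecording, center_hz: float = 40.0, half_width_hz: float = 5.0
) -> SignalRecording:
    """Zero-phase second-order Butterworth band-pass around the train rate.

    Applied forward and backward (``sosfiltfilt``), so the passband signal is
    not delayed; only the EEG signal channels are filtered, the trigger
    channel is left untouched.
    """
    if half_width_hz <= 0 or center_hz - half_width_hz <= 0:
        raise ParameterError("invalid band edges")
    if center_hz + half_width_hz >= rec.fs / 2:
        raise ParameterError("band extends beyond Nyquist")
    sos = sps.butter(
        2,
        [center_hz - half_width_hz, center_hz + half_width_hz],
        btype="bandpass",
        fs=rec.fs,
        output="sos",
    )
    data = rec.data.copy()
    for i in rec.signal_indices:
        data[i] = sps.sosfiltfilt(sos, data[i])
    return SignalRecording(
        data, rec.fs, list(rec.channel_labels), events=rec.events,
        meta={**rec.meta, "bandpass_hz": (center_hz - half_width_hz,
                                          center_hz + half_width_hz)},
    )


def segment_assr(
    rec: SignalRecording,
    events: pd.DataFrame | None = None,
    *,
    pre_ms: float = 400.0,
    trial_ms: float = 2000.0,
    post_ms: float = 400.0,
) -> EpochSet:
    """Cut 2.8 s epochs (pre + trial + post) around ``train_onset`` events."""
    return segment(
        rec, events, label="train_onset", pre_ms=pre_ms, post_ms=trial_ms + post_ms
    )


def _layer_coefs(
    epochs: EpochSet, freq_hz: float, cycles: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tfr = transform_array(
        epochs.channel_mean()[epochs.kept],
        epochs.fs,
        np.array([freq_hz]),
        cycles,
        times_ms=epochs.times_ms,
    )
    return tfr.coefs[:, 0, :], tfr.valid[0], tfr.times_ms


def assr_power(
    epochs: EpochSet,
    freq_hz: float = 40.0,
    cycles: float = 5.0,
    trial_window_ms: tuple[float, float] = (0.0, 2000.0),
) -> float:
    """Accumulated 40 Hz layer power over the stimulation window.

    Power is summed over the in-window samples (an "accumulated" rather than
    mean quantity) and averaged across trials.
    """
    if not epochs.kept.any():
        raise AnalysisError("no kept trials")
    coefs, valid, t = _layer_coefs(epochs, freq_hz, cycles)
    m = (t >= trial_window_ms[0]) & (t <= trial_window_ms[1]) & valid
    if not m.any():
        raise AnalysisError("no valid coefficients in the trial window")
    return float((np.abs(coefs[:, m]) ** 2).sum(axis=1).mean())


def assr_itc(
    epochs: EpochSet,
    freq_hz: float = 40.0,
    cycles: float = 5.0,
    trial_window_ms: tuple[float, float] = (0.0, 2000.0),
    reduction: str = "mean",
) -> AssrResult:
    """Intertrial coherence of the 40 Hz layer.

    Coefficients with zero magnitude cannot be phase-normalized; those
    trial/time cells are excluded from the across-trial mean and counted in
    ``n_excluded_coefs``.
    """
    if int(epochs.kept.sum()) < 2:
        raise AnalysisError("ITC needs at least 2 trials")
    if reduction not in ("mean", "median"):
        raise ParameterError(f"unknown reduction {reduction!r}")
    coefs, valid, t = _layer_coefs(epochs, freq_hz, cycles)
    mag = np.abs(coefs)
    nonzero = mag > 0
    unit = np.zeros_like(coefs)
    unit[nonzero] = coefs[nonzero] / mag[nonzero]
    counts = nonzero.sum(axis=0)
    with np.errstate(invalid="ignore"):
        itc_t = np.abs(unit.sum(axis=0)) / np.where(counts > 0, counts, 1)
    itc_t[counts < 2] = np.nan
    m = (t >= trial_window_ms[0]) & (t <= trial_window_ms[1]) & valid
    in_win = itc_t[m]
    in_win = in_win[~np.isnan(in_win)]
    if in_win.size == 0:
        raise AnalysisError("no valid ITC samples in the trial window")
    scalar = float(np.mean(in_win) if reduction == "mean" else np.median(in_win))
    power = assr_power(epochs, freq_hz, cycles, trial_window_ms)
    return AssrResult(
        power_40hz=power,
        itc_40hz=min(scalar, 1.0),
        itc_curve=itc_t[m],
        itc_times_ms=t[m],
        n_trials=int(epochs.kept.sum()),
        n_excluded_coefs=int((~nonzero).sum()),
    )
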