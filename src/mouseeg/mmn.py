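"""Mismatch negativity (MMN) analysis for oddball sessions.

The MMN is the negative deflection of the deviant-minus-standard difference
wave. To keep both averages on an equal footing, only the *last* standard
tone before each deviant enters the standard average (one matched pair per
deviant, pooled across flip-flop blocks). The MMN magnitude is quantified as
the area under the difference wave within a 50 ms window centered on its
most negative post-stimulus peak (±25 ms), by trapezoidal integration at the
native sampling rate — a signed quantity, more negative meaning a larger
MMN.

Robust-MMN screen: an animal shows usable MMN if the ratio of its standard
to deviant N1 amplitudes reaches a threshold (default 0.5). The ratio is
taken as |N1(standard)| / |N1(deviant)|; a deviant response much larger than
the standard's leaves headroom to detect pharmacological MMN reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .erp import Waveform, measure_n1
from .errors import AnalysisError, ParameterError

__all__ = [
    "MmnResult",
    "match_trials",
    "difference_wave",
    "mmn_auc",
    "robust_mmn",
    "analyze_mmn",
]


@dataclass
class MmnResult:
    """Per-session MMN summary."""

    standard_erp: Waveform
    deviant_erp: Waveform
    difference: Waveform
    peak_latency_ms: float
    auc_uV_ms: float  # signed; negative for a genuine MMN
    std_dev_ratio: float
    robust: bool

    @property
    def auc_abs_uV_ms(self) -> float:
        return abs(self.auc_uV_ms)


def match_trials(events: pd.DataFrame) -> list[tuple[int, int]]:
    """Pair each deviant with the last standard preceding it in its block.

    Returns row-index pairs ``(standard_idx, deviant_idx)`` into ``events``;
    equal counts of standards and deviants enter the averages by
    construction. Deviants with no preceding standard are skipped with a
    warning.
    """
    if "label" not in events.columns:
        raise ParameterError("event table lacks a label column")
    pairs: list[tuple[int, int]] = []
    skipped = 0
    last_standard: dict[int, int] = {}
    for idx, row in enumerate(events.itertuples(index=False)):
        block = int(getattr(row, "block_id", 0))
        if row.label == "standard":
            last_standard[block] = idx
        elif row.label == "deviant":
            if block in last_standard:
                pairs.append((last_standard[block], idx))
            else:
                skipped += 1
    if not pairs:
        raise AnalysisError("no deviant with a preceding standard")
    if skipped:
        warnings.warn(f"{skipped} deviant(s) had no preceding standard; skipped",
                      stacklevel=2)
    return pairs


def difference_wave(standard_erp: Waveform, deviant_erp: Waveform) -> Waveform:
    """Deviant minus standard average ERP."""
    if standard_erp.data.shape != deviant_erp.data.shape:
        raise ParameterError("standard and deviant waveforms differ in length")
    return Waveform(deviant_erp.t_ms, deviant_erp.data - standard_erp.data)


def mmn_auc(
    diff: Waveform,
    window_half_ms: float = 25.0,
    search_ms: tuple[float, float] = (20.0, 100.0),
) -> tuple[float, float]:
    """Peak-centered area under the difference wave.

    The peak is the most negative point of ``diff`` within ``search_ms``
    post-stimulus; the AUC is the trapezoidal integral over peak ± 25 ms in
    µV·ms (negative for a genuine MMN). If the integration window is clipped
    by the epoch edge the AUC covers the clipped span, with a warning.
    Returns ``(peak_latency_ms, auc_uV_ms)``.
    """
    if window_half_ms <= 0:
        raise ParameterError("window_half_ms must be positive")
    lo, hi = search_ms
    m = (diff.t_ms >= lo) & (diff.t_ms <= hi)
    if not m.any():
        raise ParameterError(f"search window {search_ms} ms outside epoch")
    seg = diff.data[m]
    peak_t = float(diff.t_ms[m][int(np.argmin(seg))])
    w = (diff.t_ms >= peak_t - window_half_ms) & (diff.t_ms <= peak_t + window_half_ms)
    span = diff.t_ms[w]
    if span[0] > peak_t - window_half_ms + 1e-9 or span[-1] < peak_t + window_half_ms - 1e-9:
        warnings.warn(
            "MMN integration window clipped by the epoch edge; AUC covers "
            f"{span[0]:.0f}..{span[-1]:.0f} ms",
            stacklevel=2,
        )
    auc = float(np.trapezoid(diff.data[w], diff.t_ms[w]))
    return peak_t, auc


def robust_mmn(
    standard_erp: Waveform,
    deviant_erp: Waveform,
    threshold: float = 0.5,
    n1_window_ms: tuple[float, float] = (30.0, 50.0),
) -> tuple[float, bool]:
    """Standard/deviant N1 amplitude ratio and the robust-MMN flag.

    ``robust`` is True when ``|N1(standard)| / |N1(deviant)| >= threshold``.
    """
    m_std = measure_n1(standard_erp, window_ms=n1_window_ms)
    m_dev = measure_n1(deviant_erp, window_ms=n1_window_ms)
    if m_dev.n1_amplitude_uV == 0:
        raise AnalysisError("standard/deviant ratio undefined: deviant N1 is zero")
    ratio = abs(m_std.n1_amplitude_uV) / abs(m_dev.n1_amplitude_uV)
    return ratio, ratio >= threshold


def analyze_mmn(
    standard_erp: Waveform,
    deviant_erp: Waveform,
    *,
    window_half_ms: float = 25.0,
    search_ms: tuple[float, float] = (20.0, 100.0),
    robust_threshold: float = 0.5,
) -> MmnResult:
    """Difference wave, peak-centered AUC and the robust-MMN screen in one go."""
    diff = difference_wave(standard_erp, deviant_erp)
    peak_t, auc = mmn_auc(diff, window_half_ms, search_ms)
    ratio, robust = robust_mmn(standard_erp, deviant_erp, robust_threshold)
    return MmnResult(
        standard_erp=standard_erp,
        deviant_erp=deviant_erp,
        difference=diff,
        peak_latency_ms=peak_t,
        auc_uV_ms=auc,
        std_dev_ratio=ratio,
        robust=robust,
    )
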