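"""Recording I/O and preprocessing.

EDF (European Data Format) is the on-disk contract: recordings are written
as plain EDF (16-bit samples, physical unit µV, one dedicated trigger
channel) with the event table as a tab-separated sidecar. Reading goes
through :mod:`mne`; writing is a minimal EDF encoder kept here because the
format is simple and the files must round-trip bit-faithfully up to the
16-bit quantization step.

Event recovery reconstructs stimulus onsets from rising threshold crossings
of the trigger channel (pulses are 10 ms, +500 µV; default threshold half
that). Labels are re-derived from inter-onset intervals where the timeline
is self-describing (paired clicks, trains); oddball sessions need the
protocol sidecar, since standards and deviants are isochronous.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .erp import EpochSet
from .errors import AnalysisError, FormatError, ParameterError
from .protocols import EVENT_COLUMNS, TRIGGER_LABELS, events_from_tsv, events_to_tsv
from .simulate import TRIGGER_CHANNEL, TRIGGER_PULSE_UV, SignalRecording

__all__ = [
    "RejectionMask",
    "write_edf",
    "read_edf",
    "extract_events",
    "reject_artifacts",
    "events_to_tsv",
    "events_from_tsv",
]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def _fmt8(value: float) -> str:
    for prec in range(7, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= 8 and "e" not in s and "E" not in s:
            return s
    return f"{value:.1e}"[:8]


def write_edf(rec: SignalRecording, path: str | Path, *, events_sidecar: bool = True) -> Path:
    """Write a recording as plain EDF with 1-second data records.

    Each channel gets a symmetric physical range just covering its data, so
    the 16-bit quantization step is as small as the data allow. The final
    record is zero-padded if the recording is not a whole number of seconds.
    If the recording has events and ``events_sidecar`` is set, they are
    written next to the EDF as ``<stem>.events.tsv``.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise FormatError(f"EDF writer requires an integer sampling rate, got {fs}")
    n_ch, n_samp = rec.data.shape
    n_records = int(math.ceil(n_samp / spr))
    header_bytes = 256 * (1 + n_ch)

    head = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(header_bytes), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )

    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1.0)
    phys_max = np.array([float(_fmt8(v * 1.0001)) for v in phys_max])
    gains = (phys_max * 2) / (_DIG_MAX - _DIG_MIN)

    fields = []
    for getter, width in [
        (lambda i: rec.channel_labels[i], 16),
        (lambda i: "", 80),
        (lambda i: "uV", 8),
        (lambda i: _fmt8(-phys_max[i]), 8),
        (lambda i: _fmt8(phys_max[i]), 8),
        (lambda i: str(_DIG_MIN), 8),
        (lambda i: str(_DIG_MAX), 8),
        (lambda i: "", 80),
        (lambda i: str(spr), 8),
        (lambda i: "", 32),
    ]:
        fields.append(b"".join(_pad(getter(i), width) for i in range(n_ch)))

    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samp] = rec.data
    # EDF affine mapping: phys = (dig - dig_min) * gain + phys_min
    digital = np.clip(
        np.rint((padded + phys_max[:, None]) / gains[:, None]) + _DIG_MIN,
        _DIG_MIN,
        _DIG_MAX,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(b"".join(fields))
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())

    if events_sidecar and rec.events is not None:
        events_to_tsv(rec.events, path.with_suffix(".events.tsv"))
    return path


def _validate_edf_header(path: Path) -> None:
    size = path.stat().st_size
    if size < 256:
        raise FormatError(f"{path}: file shorter than an EDF header")
    with open(path, "rb") as fh:
        head = fh.read(256)
        try:
            header_bytes = int(head[184:192])
            n_records = int(head[236:244])
            n_ch = int(head[252:256])
        except ValueError as exc:
            raise FormatError(f"{path}: corrupt EDF header") from exc
        if size < header_bytes:
            raise FormatError(f"{path}: truncated EDF header")
        sig_head = fh.read(header_bytes - 256)
    try:
        spr = [
            int(sig_head[n_ch * 216 + i * 8 : n_ch * 216 + (i + 1) * 8])
            for i in range(n_ch)
        ]
    except ValueError as exc:
        raise FormatError(f"{path}: corrupt EDF signal headers") from exc
    expected = header_bytes + n_records * sum(spr) * 2
    if size != expected:
        raise FormatError(
            f"{path}: truncated or padded EDF data ({size} bytes, expected {expected})"
        )


def read_edf(path: str | Path, *, load_events: bool = True) -> SignalRecording:
    """Read an EDF file into a :class:`SignalRecording` (µV).

    The file's physical scaling is applied; channel labels and sampling rate
    come from the header. If ``<stem>.events.tsv`` exists and
    ``load_events`` is set, the event table sidecar is attached.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    _validate_edf_header(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data_uv = raw.get_data() * 1e6  # mne scales µV-dimensioned channels to V
    labels = list(raw.ch_names)
    events = None
    sidecar = path.with_suffix(".events.tsv")
    if load_events and sidecar.exists():
        events = events_from_tsv(sidecar)
    return SignalRecording(
        data_uv, fs, labels, events=events, meta={"source": str(path)}
    )


# ---------------------------------------------------------------------------
# event recovery


def _label_by_intervals(onsets: np.ndarray, fs: float, tol_samples: int = 5) -> list[str]:
    """Heuristic label reconstruction from inter-onset intervals.

    Two interval clusters that alternate → paired clicks (short gap =
    click2). One (long) interval cluster → generic ``stim`` labels; the
    caller should supply the protocol table when stimulus identity matters
    (oddball sessions are isochronous by design).
    """
    n = len(onsets)
    if n <= 1:
        return ["stim"] * n
    d = np.diff(onsets)
    if d.max() - d.min() <= 2 * tol_samples:
        return ["stim"] * n
    mid = (d.min() + d.max()) / 2.0
    short = d < mid
    labels = ["click1"]
    for s in short:
        labels.append("click2" if s else "click1")
    # require strict alternation for the paired-click reading
    ok = all(
        (labels[i] == "click1") == (labels[i + 1] == "click2")
        for i in range(n - 1)
    )
    if not ok:
        return ["stim"] * n
    return labels


def extract_events(
    rec: SignalRecording,
    threshold_uV: float = TRIGGER_PULSE_UV / 2,
    protocol: pd.DataFrame | None = None,
    tol_samples: int = 5,
) -> pd.DataFrame:
    """Recover stimulus events from the trigger channel.

    One event per rising crossing of ``threshold_uV``; the onset is the
    first supra-threshold sample. If ``protocol`` is given, its trial-level
    rows (the labels that carry a trigger pulse) must match the detected
    pulses one-for-one, and labels, blocks and tone frequencies are copied
    from it; otherwise labels are reconstructed from inter-onset intervals.
    """
    ti = rec.trigger_index
    if ti is None:
        raise AnalysisError(f"recording has no {TRIGGER_CHANNEL!r} channel")
    x = rec.data[ti]
    above = x >= threshold_uV
    rising = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    if len(rising) == 0:
        warnings.warn("no trigger crossings found; returning empty event table",
                      stacklevel=2)
        return pd.DataFrame(columns=EVENT_COLUMNS)

    if protocol is not None:
        trial = protocol[protocol["label"].isin(TRIGGER_LABELS)].reset_index(drop=True)
        if len(trial) != len(rising):
            raise AnalysisError(
                f"detected {len(rising)} trigger pulses but protocol has "
                f"{len(trial)} trial-level events"
            )
        rel = rising - rising[0]
        proto_rel = (
            trial["onset_sample"].to_numpy() - int(trial["onset_sample"].iloc[0])
        )
        if np.abs(rel - proto_rel).max() > tol_samples:
            raise AnalysisError(
                "trigger pulse spacing does not match the supplied protocol"
            )
        out = trial.copy()
        out["onset_sample"] = rising
        out["onset_s"] = rising / rec.fs
        return out[EVENT_COLUMNS]

    labels = _label_by_intervals(rising, rec.fs, tol_samples)
    return pd.DataFrame(
        {
            "onset_sample": rising,
            "onset_s": rising / rec.fs,
            "label": labels,
            "block_id": 0,
            "tone_freq_hz": np.nan,
        }
    )[EVENT_COLUMNS]


# ---------------------------------------------------------------------------
# artifact rejection


@dataclass
class RejectionMask:
    """Per-trial keep/drop decision with reason codes (never silently applied)."""

    keep: np.ndarray
    reasons: list[str]

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if len(self.reasons) != len(self.keep):
            raise ParameterError("mask length must equal trial count")

    @property
    def n_dropped(self) -> int:
        return int((~self.keep).sum())


def reject_artifacts(
    epochs: EpochSet, peak_to_peak_limit_uV: float = 800.0
) -> RejectionMask:
    """Flag trials whose within-epoch peak-to-peak range exceeds the limit.

    The criterion is evaluated per signal channel; a trial is dropped if any
    channel exceeds the limit. The mask is returned, not applied — callers
    decide (``epochs.kept &= mask.keep``). Idempotent by construction: the
    surviving trials all satisfy the bound.
    """
    if peak_to_peak_limit_uV <= 0:
        raise ParameterError("peak-to-peak limit must be positive")
    if epochs.n_trials == 0:
        raise AnalysisError("no epochs to screen")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x channels
    bad = (ptp > peak_to_peak_limit_uV).any(axis=1)
    reasons = ["amplitude" if b else "" for b in bad]
    return RejectionMask(~bad, reasons)
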