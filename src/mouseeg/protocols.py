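"""Auditory stimulation timelines.

Three session types drive the biomarker readouts:

* paired-click ERP sessions (click1/click2 pairs for N1 and sensory gating),
* 40 Hz click-train sessions for the auditory steady-state response (ASSR),
* oddball sessions (frequent standard tone, rare deviant tone) for mismatch
  negativity (MMN), optionally with a flip-flop design in which the standard
  and deviant tone frequencies swap halfway through the session.

A protocol is an *event table*: a tidy :class:`pandas.DataFrame` with one row
per stimulus event and columns ``onset_sample`` (0-based, at the session
sampling rate), ``onset_s``, ``label``, ``block_id`` and ``tone_freq_hz``.
Protocol timing is fully deterministic — there is no randomness in any
timeline, so event tables are reproducible bit-exactly from their parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolError",
    "ProtocolSpec",
    "EVENT_COLUMNS",
    "make_paired_click_protocol",
    "make_assr_protocol",
    "make_oddball_protocol",
    "make_protocol",
    "validate_events",
    "events_to_tsv",
    "events_from_tsv",
]

EVENT_COLUMNS = ["onset_sample", "onset_s", "label", "block_id", "tone_freq_hz"]

#: labels that correspond to a trial-level stimulus (one trigger pulse each);
#: per-click children inside an ASSR train are bookkeeping only.
TRIGGER_LABELS = frozenset({"click1", "click2", "train_onset", "standard", "deviant"})


class ProtocolError(ValueError):
    """Invalid stimulation-protocol parameters."""


def _frame(onsets: Iterable[int], labels, blocks, freqs, fs: float) -> pd.DataFrame:
    onsets = np.asarray(list(onsets), dtype=np.int64)
    df = pd.DataFrame(
        {
            "onset_sample": onsets,
            "onset_s": onsets / fs,
            "label": list(labels),
            "block_id": np.asarray(list(blocks), dtype=np.int64),
            "tone_freq_hz": np.asarray(list(freqs), dtype=float),
        }
    )
    return df[EVENT_COLUMNS]


def validate_events(events: pd.DataFrame) -> None:
    """Check structural invariants of an event table.

    Onsets must be non-decreasing overall and strictly increasing within each
    label (a train onset and its first click may share a sample), and every
    deviant must be preceded by at least one standard within its block.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ProtocolError(f"event table missing columns: {missing}")
    onsets = events["onset_sample"].to_numpy()
    if len(onsets) and np.any(np.diff(onsets) < 0):
        raise ProtocolError("event onsets must be non-decreasing")
    for label, grp in events.groupby("label"):
        o = grp["onset_sample"].to_numpy()
        if np.any(np.diff(o) <= 0):
            raise ProtocolError(f"onsets not strictly increasing within label {label!r}")
    for block, grp in events.groupby("block_id"):
        labels = grp["label"].tolist()
        for i, lab in enumerate(labels):
            if lab == "deviant" and "standard" not in labels[:i]:
                raise ProtocolError(
                    f"deviant without preceding standard in block {block}"
                )


def make_paired_click_protocol(
    n_pairs: int,
    intra_pair_s: float = 0.5,
    inter_pair_s: float = 10.0,
    fs: float = 1000.0,
) -> pd.DataFrame:
    """Paired-click ERP timeline: ``n_pairs`` click pairs.

    Clicks within a pair are ``intra_pair_s`` apart; after the second click
    of a pair, ``inter_pair_s`` of silence elapses before the next pair, so
    the pair-to-pair cycle is ``intra_pair_s + inter_pair_s``. Labels
    alternate ``click1``/``click2``. The standard session is 300 pairs with a
    0.5 s intra-pair and 10 s inter-pair interval.
    """
    if n_pairs < 1:
        raise ProtocolError("n_pairs must be >= 1")
    if intra_pair_s <= 0 or inter_pair_s <= 0 or fs <= 0:
        raise ProtocolError("intervals and sampling rate must be positive")
    cycle = int(round((intra_pair_s + inter_pair_s) * fs))
    intra = int(round(intra_pair_s * fs))
    onsets, labels = [], []
    for k in range(n_pairs):
        onsets += [k * cycle, k * cycle + intra]
        labels += ["click1", "click2"]
    n = 2 * n_pairs
    return _frame(onsets, labels, [0] * n, [np.nan] * n, fs)


def make_assr_protocol(
    n_trains: int,
    train_s: float = 2.0,
    rate_hz: float = 40.0,
    iti_s: float = 30.0,
    fs: float = 1000.0,
) -> pd.DataFrame:
    """40 Hz (or other rate) click-train timeline for the ASSR session.

    Each train lasts ``train_s`` seconds at ``rate_hz`` clicks per second and
    is followed by ``iti_s`` of silence. One ``train_onset`` event marks each
    train; its constituent clicks are emitted as child ``click`` events (the
    first click coincides with the train onset). The standard session is
    100 trains of 2 s at 40 Hz with a 30 s inter-train interval.
    """
    if n_trains < 1:
        raise ProtocolError("n_trains must be >= 1")
    if train_s <= 0 or rate_hz <= 0 or iti_s <= 0 or fs <= 0:
        raise ProtocolError("intervals and rates must be positive")
    if rate_hz >= fs / 2:
        raise ProtocolError(
            f"click rate {rate_hz} Hz is not representable at fs={fs} Hz"
        )
    n_clicks_f = rate_hz * train_s
    n_clicks = int(round(n_clicks_f))
    if abs(n_clicks_f - n_clicks) > 1e-9:
        n_clicks = int(np.floor(n_clicks_f))
        warnings.warn(
            f"rate_hz*train_s = {n_clicks_f:.3f} is not a whole number of "
            f"clicks; truncating to {n_clicks}",
            stacklevel=2,
        )
    cycle = int(round((train_s + iti_s) * fs))
    onsets, labels = [], []
    for k in range(n_trains):
        t0 = k * cycle
        onsets.append(t0)
        labels.append("train_onset")
        for i in range(n_clicks):
            onsets.append(t0 + int(round(i * fs / rate_hz)))
            labels.append("click")
    n = len(onsets)
    return _frame(onsets, labels, [0] * n, [np.nan] * n, fs)


def make_oddball_protocol(
    n_cycles: int,
    deviant_period: int = 20,
    tone_s: float = 0.05,
    isi_s: float = 0.5,
    f_std: float = 9000.0,
    f_dev: float = 12000.0,
    flip_flop: bool = True,
    fs: float = 1000.0,
) -> pd.DataFrame:
    """Oddball (MMN) timeline as ``n_cycles`` deterministic cycles.

    Each cycle is ``deviant_period - 1`` standards followed by one deviant,
    so the deviant fraction is exactly ``1/deviant_period`` (5% for the
    standard every-20th design). Tones are ``tone_s`` long with an ``isi_s``
    inter-stimulus interval, i.e. a fixed onset-to-onset step. With
    ``flip_flop`` the standard and deviant tone frequencies swap at cycle
    ``n_cycles/2`` (block 0 → block 1), so each frequency serves as standard
    in exactly one half.
    """
    if n_cycles < 1:
        raise ProtocolError("n_cycles must be >= 1")
    if deviant_period < 2:
        raise ProtocolError("deviant_period must be >= 2")
    if tone_s <= 0 or isi_s <= 0 or fs <= 0:
        raise ProtocolError("intervals must be positive")
    if f_std == f_dev:
        raise ProtocolError("standard and deviant tone frequencies must differ")
    if flip_flop and n_cycles % 2:
        raise ProtocolError("flip_flop requires an even number of cycles")
    step = int(round((tone_s + isi_s) * fs))
    onsets, labels, blocks, freqs = [], [], [], []
    half = n_cycles // 2
    for c in range(n_cycles):
        block = int(flip_flop and c >= half)
        std_f, dev_f = (f_std, f_dev) if block == 0 else (f_dev, f_std)
        for j in range(deviant_period):
            onsets.append((c * deviant_period + j) * step)
            is_dev = j == deviant_period - 1
            labels.append("deviant" if is_dev else "standard")
            blocks.append(block)
            freqs.append(dev_f if is_dev else std_f)
    return _frame(onsets, labels, blocks, freqs, fs)


@dataclass
class ProtocolSpec:
    """Declarative protocol description, e.g. parsed from a YAML config."""

    kind: str  # "erp" | "assr" | "mmn"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("erp", "assr", "mmn"):
            raise ProtocolError(f"unknown protocol kind {self.kind!r}")

    def build(self, fs: float = 1000.0) -> pd.DataFrame:
        return make_protocol(self.kind, fs=fs, **self.params)


def make_protocol(kind: str, fs: float = 1000.0, **params) -> pd.DataFrame:
    """Dispatch on protocol kind (``erp``, ``assr`` or ``mmn``)."""
    builders = {
        "erp": make_paired_click_protocol,
        "assr": make_assr_protocol,
        "mmn": make_oddball_protocol,
    }
    if kind not in builders:
        raise ProtocolError(f"unknown protocol kind {kind!r}")
    return builders[kind](fs=fs, **params)


def events_to_tsv(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event table as a UTF-8 tab-separated sidecar file."""
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False, encoding="utf-8")


def events_from_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ProtocolError(f"event TSV {path} missing columns: {missing}")
    return df[EVENT_COLUMNS]
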