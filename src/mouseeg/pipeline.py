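"""End-to-end orchestration: simulate → preprocess → analyze → stats.

A *run* turns a declarative config (YAML/dict) into a directory of
artifacts: optional EDF recordings with event-table sidecars, a tidy
biomarker CSV (one row per animal × treatment × parameter), a contrasts CSV
with the mixed-model estimates, and a manifest recording the seed and config
so any run can be replayed bit-identically.

The default demo cohort is a scaled-down version of a within-subject
NMDA-antagonist study: 12 animals measured at vehicle baseline, under a
high antagonist dose, and after washout, across the three stimulation
protocols. Session sizes (trials per session, inter-trial gaps) are reduced
relative to a full recording day so a complete cohort runs on a laptop; the
generative effect sizes are chosen large, as they are for an efficacious
dose, so the directional pattern of the readouts is unambiguous.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import assr as assr_mod
from . import erp as erp_mod
from . import io as io_mod
from . import mmn as mmn_mod
from . import oscillations as osc_mod
from . import stats as stats_mod
from .errors import AnalysisError, ParameterError
from .protocols import make_protocol
from .simulate import (
    ANTAGONIST_HIGH_DOSE,
    DrugEffect,
    SignalRecording,
    SimConfig,
    iter_cohort,
)

__all__ = [
    "default_demo_config",
    "analyze_erp_session",
    "analyze_assr_session",
    "analyze_mmn_session",
    "run_cohort",
    "fit_all_contrasts",
    "run_experiment",
]

#: parameters entering each protocol's Bonferroni family
FAMILY_PARAMETERS = {
    "erp": ["n1_amp", "gating_ratio", "basal_gamma", "evoked_gamma",
            "basal_theta", "evoked_theta"],
    "assr": ["assr_power", "assr_itc"],
    "mmn": ["mmn_auc"],
}


def default_demo_config(seed: int = 1) -> dict:
    """Scaled-down demo study: 12 animals, baseline / high dose / washout."""
    return {
        "seed": seed,
        "n_animals": 12,
        "treatments": ["vehicle_baseline", "antagonist_high", "vehicle_washout"],
        "effects": {
            "vehicle_baseline": {},
            "antagonist_high": dataclasses.asdict(ANTAGONIST_HIGH_DOSE),
            "vehicle_washout": {},
        },
        "protocols": {
            "erp": {"n_pairs": 30, "intra_pair_s": 0.5, "inter_pair_s": 4.0},
            "assr": {"n_trains": 20, "train_s": 2.0, "rate_hz": 40.0, "iti_s": 3.0},
            "mmn": {"n_cycles": 16, "deviant_period": 10, "tone_s": 0.05,
                    "isi_s": 0.5, "f_std": 9000.0, "f_dev": 12000.0,
                    "flip_flop": True},
        },
        "sim": {},
        "write_edf": False,
        "artifact_limit_uV": 800.0,
        "normalize_oscillations": False,
    }


def _build_sim_config(config: Mapping) -> SimConfig:
    sim = dict(config.get("sim", {}))
    sim.setdefault("seed", config.get("seed", 0))
    return SimConfig(**sim)


def _build_effects(config: Mapping) -> dict[str, DrugEffect]:
    return {k: DrugEffect(**v) for k, v in config.get("effects", {}).items()}


def _validate_config(config: Mapping) -> None:
    for key in ("seed", "n_animals", "treatments", "effects", "protocols"):
        if key not in config:
            raise ParameterError(f"config missing required field {key!r}")
    for t in config["treatments"]:
        if t not in config["effects"]:
            raise ParameterError(f"config missing effects entry for treatment {t!r}")


# ---------------------------------------------------------------------------
# per-session analyses


def analyze_erp_session(
    rec: SignalRecording,
    *,
    artifact_limit_uV: float = 800.0,
    normalize: bool = False,
) -> dict[str, float]:
    """All ERP-protocol readouts for one recording.

    N1 amplitude is reported as a magnitude (µV, larger = stronger response);
    the gating ratio is S2/S1. Basal and evoked gamma/theta power come from
    the Morlet decomposition with the evoked windows anchored at the
    session's measured P1 latency.
    """
    events = rec.events
    ep1 = erp_mod.baseline_correct(erp_mod.segment(rec, events, label="click1"))
    ep2 = erp_mod.baseline_correct(erp_mod.segment(rec, events, label="click2",
                                                   post_ms=450.0))
    for ep in (ep1, ep2):
        mask = io_mod.reject_artifacts(ep, artifact_limit_uV)
        ep.kept &= mask.keep
    avg1 = erp_mod.average_erp(ep1)
    avg2 = erp_mod.average_erp(ep2)
    m1 = erp_mod.measure_n1(avg1)
    m2 = erp_mod.measure_n1(avg2)
    gating = erp_mod.gating_ratio(m1, m2)
    included = erp_mod.screen_animal(m1)

    click1 = events[events["label"] == "click1"]
    onsets = click1["onset_sample"].to_numpy()
    osc_ep = erp_mod.segment(rec, click1, pre_ms=1200.0, post_ms=1400.0)
    osc_ep.kept &= io_mod.reject_artifacts(osc_ep, artifact_limit_uV).keep
    p1 = m1.p1_latency_ms
    basal_g = osc_mod.basal_power(rec, onsets, osc_mod.GAMMA)
    basal_t = osc_mod.basal_power(rec, onsets, osc_mod.THETA)
    evoked_g = osc_mod.evoked_band_power(
        osc_ep, osc_mod.GAMMA, (p1 - 25.0, p1 + 25.0), basal_g
    )
    evoked_t = osc_mod.evoked_band_power(
        osc_ep, osc_mod.THETA, (p1 - 20.0, p1 + 180.0), basal_t
    )
    if normalize:
        basal_g = osc_mod.normalize_to_recording(basal_g, rec, osc_mod.GAMMA)
        evoked_g = osc_mod.normalize_to_recording(evoked_g, rec, osc_mod.GAMMA)
        basal_t = osc_mod.normalize_to_recording(basal_t, rec, osc_mod.THETA)
        evoked_t = osc_mod.normalize_to_recording(evoked_t, rec, osc_mod.THETA)
    return {
        "n1_amp": abs(m1.n1_amplitude_uV),
        "n1_latency": m1.n1_latency_ms,
        "p1n1": m1.p1n1_uV,
        "included": float(included),
        "gating_ratio": gating,
        "basal_gamma": basal_g,
        "evoked_gamma": evoked_g,
        "basal_theta": basal_t,
        "evoked_theta": evoked_t,
        "n_kept_trials": float(ep1.kept.sum()),
    }


def analyze_assr_session(
    rec: SignalRecording, *, artifact_limit_uV: float = 800.0
) -> dict[str, float]:
    """ASSR power and intertrial coherence at the 40 Hz layer."""
    band = assr_mod.assr_bandpass(rec)
    epochs = assr_mod.segment_assr(band, rec.events)
    epochs.kept &= io_mod.reject_artifacts(epochs, artifact_limit_uV).keep
    res = assr_mod.assr_itc(epochs)
    return {
        "assr_power": res.power_40hz,
        "assr_itc": res.itc_40hz,
        "n_trials": float(res.n_trials),
    }


def analyze_mmn_session(
    rec: SignalRecording,
    *,
    artifact_limit_uV: float = 800.0,
    pre_ms: float = 50.0,
    post_ms: float = 300.0,
) -> dict[str, float]:
    """MMN readouts: |AUC|, peak latency and the robust-MMN screen.

    Short epochs (default −50..300 ms) keep the following tone of the rapid
    oddball sequence out of both averages.
    """
    events = rec.events
    pairs = mmn_mod.match_trials(events)
    std_rows = events.iloc[[p[0] for p in pairs]]
    dev_rows = events.iloc[[p[1] for p in pairs]]

    def _avg(rows: pd.DataFrame) -> erp_mod.Waveform:
        ep = erp_mod.baseline_correct(
            erp_mod.segment(rec, rows, pre_ms=pre_ms, post_ms=post_ms)
        )
        ep.kept &= io_mod.reject_artifacts(ep, artifact_limit_uV).keep
        return erp_mod.average_erp(ep)

    result = mmn_mod.analyze_mmn(_avg(std_rows), _avg(dev_rows))
    return {
        "mmn_auc": result.auc_abs_uV_ms,
        "mmn_auc_signed": result.auc_uV_ms,
        "mmn_peak_latency": result.peak_latency_ms,
        "std_dev_ratio": result.std_dev_ratio,
        "robust_mmn": float(result.robust),
        "n_pairs": float(len(pairs)),
    }


_ANALYZERS = {
    "erp": analyze_erp_session,
    "assr": analyze_assr_session,
    "mmn": analyze_mmn_session,
}


# ---------------------------------------------------------------------------
# cohort-level driver


def run_cohort(
    config: Mapping,
    *,
    out_dir: Path | None = None,
) -> pd.DataFrame:
    """Simulate and analyze every animal × treatment × protocol cell.

    Returns the tidy biomarker table; when ``out_dir`` is given, EDF files
    (if ``write_edf``) and the per-stage CSV land there.
    """
    _validate_config(config)
    cfg = _build_sim_config(config)
    effects = _build_effects(config)
    treatments = list(config["treatments"])
    n_animals = int(config["n_animals"])
    write_edf = bool(config.get("write_edf", False)) and out_dir is not None
    limit = float(config.get("artifact_limit_uV", 800.0))
    normalize = bool(config.get("normalize_oscillations", False))

    rows: list[dict] = []
    for proto_name, proto_params in config["protocols"].items():
        protocol = make_protocol(proto_name, fs=cfg.fs, **proto_params)
        analyzer = _ANALYZERS[proto_name]
        # protocol-specific seed substream keeps protocols independent
        proto_key = zlib.crc32(proto_name.encode()) % (2**31)
        proto_seed = int(
            np.random.SeedSequence(
                [int(config["seed"]), proto_key]
            ).generate_state(1)[0] % (2**31 - 1)
        )
        proto_cfg = dataclasses.replace(cfg, seed=proto_seed)
        for rec in iter_cohort(protocol, n_animals, treatments, proto_cfg, effects):
            if write_edf:
                rec_dir = Path(out_dir) / "recordings"
                rec_dir.mkdir(parents=True, exist_ok=True)
                stem = f"{proto_name}_{rec.meta['animal_id']}_{rec.meta['treatment']}"
                io_mod.write_edf(rec, rec_dir / f"{stem}.edf")
            kwargs = {"artifact_limit_uV": limit}
            if proto_name == "erp":
                kwargs["normalize"] = normalize
            readouts = analyzer(rec, **kwargs)
            for param, value in readouts.items():
                rows.append(
                    {
                        "animal_id": rec.meta["animal_id"],
                        "treatment": rec.meta["treatment"],
                        "protocol": proto_name,
                        "parameter": param,
                        "value": value,
                    }
                )
    table = stats_mod.make_biomarker_table(rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / "biomarkers.csv", index=False)
    return table


def fit_all_contrasts(
    table: pd.DataFrame,
    config: Mapping,
    *,
    baseline: str = "vehicle_baseline",
    washout: str = "vehicle_washout",
) -> pd.DataFrame:
    """Mixed-model contrasts for every family parameter, with family alphas.

    The Bonferroni family of each protocol divides 0.05 by the number of
    dose treatments times the number of family parameters; washout contrasts
    are exempt.
    """
    doses = [t for t in config["treatments"] if t not in (baseline, washout)]
    frames = []
    for proto_name, params in FAMILY_PARAMETERS.items():
        if proto_name not in config["protocols"]:
            continue
        alpha_star = stats_mod.bonferroni_alpha(max(len(doses), 1), len(params))
        for param in params:
            sub = table[(table["protocol"] == proto_name)
                        & (table["parameter"] == param)]
            if sub.empty:
                continue
            contrasts = stats_mod.fit_contrasts(
                sub, param, baseline=baseline, washout=washout
            )
            rep = stats_mod.summarize(contrasts, alpha_star)
            rep.insert(0, "parameter", param)
            rep.insert(0, "protocol", proto_name)
            frames.append(rep)
    if not frames:
        raise AnalysisError("no analyzable parameters in the biomarker table")
    return pd.concat(frames, ignore_index=True)


def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_experiment(config: Mapping, out_dir: str | Path) -> Path:
    """Full reproducible run: recordings, biomarker CSV, contrasts CSV, manifest.

    Deterministic under a fixed seed — rerunning with the same config yields
    byte-identical CSVs. Stages are sequential; a stage failure raises with
    the stage name, and completed CSVs from a previous run are reused when
    present (delete the directory for a clean rerun).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _validate_config(config)

    bio_path = out / "biomarkers.csv"
    try:
        if bio_path.exists():
            table = pd.read_csv(bio_path)
        else:
            table = run_cohort(config, out_dir=out)
    except Exception as exc:
        raise AnalysisError(f"stage 'cohort' failed: {exc}") from exc

    contrasts_path = out / "contrasts.csv"
    try:
        if not contrasts_path.exists():
            report = fit_all_contrasts(table, config)
            report.to_csv(contrasts_path, index=False)
            lines = [
                f"{r.protocol}/{r.parameter}  {r.contrast}: "
                f"Estimated difference: {r.estimate:.4g}; confidence limits: "
                f"{r.ci_low:.4g} to {r.ci_high:.4g}; P = {r.p_value:.4g}"
                f"{' *' if r.significant else ''}"
                for r in report.itertuples(index=False)
            ]
            (out / "report.txt").write_text("\n".join(lines) + "\n")
    except Exception as exc:
        raise AnalysisError(f"stage 'stats' failed: {exc}") from exc

    import mouseeg

    manifest = {
        "config": dict(config),
        "config_hash": _config_hash(config),
        "seed": config["seed"],
        "package_version": getattr(mouseeg, "__version__", "unknown"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
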