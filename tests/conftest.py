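"""Shared fixtures: deterministic, stripped-down simulation configs."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from mouseeg.simulate import BurstSpec, SimConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def quiet_config(seed: int = 0, **overrides) -> SimConfig:
    """Noise-free, jitter-free config with oscillatory bursts disabled.

    Isolates the ERP pathway: renders contain only the deterministic
    Gaussian deflections (plus whatever the overrides re-enable).
    """
    kwargs = dict(
        seed=seed,
        noise_sd_uV=0.0,
        basal_gamma_sd_uV=0.0,
        basal_theta_sd_uV=0.0,
        assr_phase_jitter_rad_sd=0.0,
        gamma_burst=BurstSpec(50.0, 0.0, 20.0, 10.0),
        theta_burst=BurstSpec(8.0, 0.0, 100.0, 35.0),
    )
    kwargs.update(overrides)
    cfg = SimConfig(**kwargs)
    cfg.erp_components = tuple(
        dataclasses.replace(c, jitter_latency_ms_sd=0.0, jitter_amp_frac_sd=0.0)
        for c in cfg.erp_components
    )
    return cfg


@pytest.fixture
def quiet_cfg() -> SimConfig:
    return quiet_config()
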