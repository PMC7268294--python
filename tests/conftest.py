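"""Shared fixtures: compact synthetic sessions reused across test modules."""

from __future__ import annotations

import dataclasses

import pytest

from splitbelt.config import ProtocolConfig, default_epoch_plan
from splitbelt.pipeline import extract_stride_table
from splitbelt.synth import (default_adaptation_params, generate_stride_series,
                             synthesize_trial)


def small_config(slope_deg: float = 0.0, mid_speed: float = 0.70,
                 paretic_side: str = "left", adaptation: int = 100,
                 baseline: int = 45, post: int = 20,
                 include_slow: bool | None = None) -> ProtocolConfig:
    """A short session: enough strides for outcomes, cheap to synthesize."""
    config = ProtocolConfig(
        subject_id="T1", mass_kg=70.0, paretic_side=paretic_side,
        slope_deg=slope_deg, mid_speed=mid_speed)
    include_slow = (slope_deg == 0.0) if include_slow is None else include_slow
    plan = default_epoch_plan(config, baseline_strides=baseline,
                              adaptation_strides=adaptation, post_strides=post,
                              include_baseline_slow=include_slow)
    return dataclasses.replace(config, epoch_plan=plan)


@pytest.fixture(scope="session")
def flat_config() -> ProtocolConfig:
    return small_config(slope_deg=0.0)


@pytest.fixture(scope="session")
def incline_config() -> ProtocolConfig:
    return small_config(slope_deg=8.5, include_slow=False)


@pytest.fixture(scope="session")
def clean_trial(flat_config):
    """Noise-free flat session: (params, realized truth, recording, table)."""
    params = default_adaptation_params(0.0, noisy=False)
    truth = generate_stride_series(params, flat_config.epoch_plan, seed=3)
    recording, realized = synthesize_trial(truth, flat_config, seed=4, params=params)
    table = extract_stride_table(recording, flat_config)
    return params, realized, recording, table


@pytest.fixture(scope="session")
def noisy_trial(incline_config):
    """Realistic-noise incline session: (params, realized truth, recording, table)."""
    params = default_adaptation_params(8.5, noisy=True)
    truth = generate_stride_series(params, incline_config.epoch_plan, seed=11)
    recording, realized = synthesize_trial(truth, incline_config, seed=12, params=params)
    table = extract_stride_table(recording, incline_config)
    return params, realized, recording, table
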