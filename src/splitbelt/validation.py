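"""Parameter-recovery validation harnesses.

These routines run the full generator -> signals -> events -> parameters ->
outcomes loop over a synthetic cohort modeled on the reference participants
(their printed mid speeds and incline-session slopes) and measure how well
the pipeline recovers the generator's known exponential truths, both
noise-free and under realistic sensor/stride noise.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .cohort import reference_cohort
from .config import ProtocolConfig, default_epoch_plan
from .outcomes import compute_outcomes
from .pipeline import extract_stride_table
from .synth import (AdaptationParams, default_adaptation_params,
                    generate_stride_series, synthesize_trial)

logger = logging.getLogger(__name__)

#: stride-table column -> truth-table column for the recovered parameters
RECOVERY_COLUMNS = {
    "sla": "sla",
    "prop_paretic_nkg": "prop_paretic",
    "prop_nonparetic_nkg": "prop_nonparetic",
}


def cohort_configs(mass_kg: float = 70.0,
                   adaptation_strides: int = 600,
                   baseline_strides: int = 50,
                   post_strides: int = 300) -> list[tuple[ProtocolConfig, ProtocolConfig]]:
    """(flat, incline) session configs for each reference participant.

    Mid speeds and incline slopes follow the published table; the flat
    session includes the slow-baseline epoch, the incline session does not.
    """
    pairs = []
    for _, row in reference_cohort().iterrows():
        paretic = "left" if row["affected_side"] == "L" else "right"
        flat = ProtocolConfig(row["subject_id"], mass_kg, paretic, 0.0,
                              mid_speed=row["mid_speed"])
        flat = dataclasses.replace(flat, epoch_plan=default_epoch_plan(
            flat, baseline_strides=baseline_strides,
            adaptation_strides=adaptation_strides, post_strides=post_strides,
            include_baseline_slow=True))
        incline = ProtocolConfig(row["subject_id"], mass_kg, paretic,
                                 row["incline_slope_deg"], mid_speed=row["mid_speed"])
        incline = dataclasses.replace(incline, epoch_plan=default_epoch_plan(
            incline, baseline_strides=baseline_strides,
            adaptation_strides=adaptation_strides, post_strides=post_strides,
            include_baseline_slow=False))
        pairs.append((flat, incline))
    return pairs


def analytic_outcomes(params: AdaptationParams, config: ProtocolConfig,
                      late: int = 40, early: int = 5) -> dict[str, dict[str, float]]:
    """Expected outcome measures from the noise-free curves.

    Evaluates the exponential curves (no noise), derives SLA from the
    geometry, and applies the outcome-window definitions analytically.
    """
    clean = dataclasses.replace(
        params, curves={k: dataclasses.replace(c, noise_sd=0.0)
                        for k, c in params.curves.items()})
    truth = generate_stride_series(clean, config.epoch_plan, seed=0)
    t = truth.table
    out: dict[str, dict[str, float]] = {}
    for table_col, truth_col in RECOVERY_COLUMNS.items():
        base = t.loc[t["epoch"] == "baseline_mid", truth_col].to_numpy()[-late:].mean()
        adapt = t.loc[t["epoch"] == "adaptation", truth_col].to_numpy()
        post = t.loc[t["epoch"] == "post_adaptation", truth_col].to_numpy()
        out[table_col] = {
            "baseline": float(base),
            "late_adaptation": float(adapt[-late:].mean() - base),
            "after_effects": float(post[:early].mean() - base),
        }
    return out


def run_trial(config: ProtocolConfig, seed: int, noisy: bool):
    params = default_adaptation_params(config.slope_deg, noisy=noisy)
    truth = generate_stride_series(params, config.epoch_plan, seed=seed)
    recording, realized = synthesize_trial(truth, config, seed=seed + 1, params=params)
    table = extract_stride_table(recording, config)
    out = compute_outcomes(table, config.processing, config.subject_id,
                           "incline" if config.slope_deg > 0 else "flat")
    return params, realized, table, out


def recovery_noise_free(seed: int = 0, n_subjects: int = 12,
                        adaptation_strides: int = 600,
                        post_strides: int = 300) -> dict[str, float]:
    """Noise-free full-loop recovery over the synthetic cohort (both sessions).

    Outcome errors are measured against the same windows applied to the
    generator's realized truth.  Returns the worst-case absolute SLA errors
    and relative propulsion errors over all sessions.
    """
    worst = {"sla_late_adaptation_abs_err": 0.0, "sla_after_effects_abs_err": 0.0,
             "prop_late_adaptation_rel_err": 0.0, "prop_after_effects_rel_err": 0.0}
    pairs = cohort_configs(adaptation_strides=adaptation_strides,
                           post_strides=post_strides)[:n_subjects]
    for i, sessions in enumerate(pairs):
        for config in sessions:
            _, realized, table, out = run_trial(config, seed=seed + 13 * i, noisy=False)
            t = realized.table
            for table_col, truth_col in RECOVERY_COLUMNS.items():
                base = t.loc[t["epoch"] == "baseline_mid", truth_col].to_numpy()[-40:].mean()
                late = t.loc[t["epoch"] == "adaptation", truth_col].to_numpy()[-40:].mean() - base
                ae = t.loc[t["epoch"] == "post_adaptation", truth_col].to_numpy()[:5].mean() - base
                m = out.measures[table_col]
                if table_col == "sla":
                    worst["sla_late_adaptation_abs_err"] = max(
                        worst["sla_late_adaptation_abs_err"], abs(m["late_adaptation"] - late))
                    worst["sla_after_effects_abs_err"] = max(
                        worst["sla_after_effects_abs_err"], abs(m["after_effects"] - ae))
                else:
                    scale = max(abs(base), 0.1)
                    worst["prop_late_adaptation_rel_err"] = max(
                        worst["prop_late_adaptation_rel_err"],
                        abs(m["late_adaptation"] - late) / scale)
                    worst["prop_after_effects_rel_err"] = max(
                        worst["prop_after_effects_rel_err"],
                        abs(m["after_effects"] - ae) / scale)
    worst["n_sessions"] = 2 * len(pairs)
    return worst


def recovery_noisy(seed: int = 0, n_seeds: int = 20, mid_speed: float = 0.70,
                   slope_deg: float = 8.5,
                   adaptation_strides: int = 600,
                   post_strides: int = 300) -> dict[str, dict[str, float]]:
    """Noisy recovery: mean outcome bias vs. the analytic truth over seeded
    replicates, reported alongside 3 x the standard error across seeds."""
    config = ProtocolConfig("noisy", 70.0, "right", slope_deg, mid_speed=mid_speed)
    config = dataclasses.replace(config, epoch_plan=default_epoch_plan(
        config, adaptation_strides=adaptation_strides, post_strides=post_strides))
    params = default_adaptation_params(slope_deg, noisy=True)
    expected = analytic_outcomes(params, config)
    samples: dict[tuple[str, str], list[float]] = {}
    for k in range(n_seeds):
        _, _, _, out = run_trial(config, seed=seed + 1000 + 31 * k, noisy=True)
        for param in RECOVERY_COLUMNS:
            for measure in ("late_adaptation", "after_effects"):
                samples.setdefault((param, measure), []).append(
                    out.measures[param][measure])
    report: dict[str, dict[str, float]] = {}
    for (param, measure), values in samples.items():
        arr = np.asarray(values)
        sem = float(arr.std(ddof=1) / np.sqrt(len(arr)))
        bias = float(arr.mean() - expected[param][measure])
        report[f"{param}.{measure}"] = {
            "bias": bias, "sem": sem, "three_sem": 3 * sem,
            "within_3_sem": bool(abs(bias) <= 3 * sem),
        }
    return report
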