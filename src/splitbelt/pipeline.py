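"""End-to-end orchestration: raw trial -> stride table -> epoch outcomes,
plus the cohort-level statistics battery.

The per-session chain is: rotate markers and forces into the surface frame,
median-filter the normal force and low-pass the AP force, detect heel
strikes (10 N offline threshold) per belt, segment paretic-referenced
strides, label them with epochs from the belt-speed schedule, then measure
per stride the step lengths / SLA / leg orientations at the heel-strike
frames and the per-leg peak propulsion in stance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import ProtocolConfig
from .events import assign_epochs, detect_stance, segment_strides
from .io import STRIDE_TABLE_COLUMNS, TrialRecording
from .kinetics import KineticError, normalize_force, peak_propulsion
from .outcomes import EpochOutcomes, compute_outcomes
from .preprocess import fill_gaps, lowpass_ap, median_filter_normal, rotate_to_surface
from .spatial import stride_spatial
from . import stats as sb_stats

logger = logging.getLogger(__name__)


def extract_stride_table(recording: TrialRecording, config: ProtocolConfig,
                         fill_marker_gaps: bool = True) -> pd.DataFrame:
    """Full extraction from a raw (lab-frame) recording to the stride table."""
    proc = config.processing
    markers = {}
    for name, series in recording.markers.items():
        surf = rotate_to_surface(series, config.slope_deg)
        if fill_marker_gaps and not surf.valid.all():
            surf = fill_gaps(surf)
        markers[name] = surf

    stride_rows = []
    events_by_leg = {}
    forces_surface = {}
    for leg in ("paretic", "nonparetic"):
        side = config.paretic_side if leg == "paretic" else config.nonparetic_side
        force = rotate_to_surface(recording.forces[side], config.slope_deg)
        force = median_filter_normal(force, proc.median_window_ms)
        force = lowpass_ap(force, proc.lowpass_cutoff_hz)
        forces_surface[leg] = force
        events_by_leg[leg] = detect_stance(
            force, proc.hs_threshold_offline_n, proc.min_stance_ms,
            proc.min_swing_ms, leg=leg)

    strides = segment_strides(events_by_leg["paretic"], events_by_leg["nonparetic"])
    strides = assign_epochs(strides, config.epoch_plan, recording.schedule)

    ap_nkg = {
        leg: np.asarray(normalize_force(forces_surface[leg].f_ap, config.mass_kg))
        for leg in ("paretic", "nonparetic")
    }
    times = {leg: forces_surface[leg].times for leg in ("paretic", "nonparetic")}
    se_times = {
        leg: np.array([e.time for e in events_by_leg[leg] if e.kind == "stance_end"])
        for leg in ("paretic", "nonparetic")
    }

    for stride in strides:
        spatial = stride_spatial(markers, config.paretic_side,
                                 t_paretic_hs=stride.end.time,
                                 t_nonparetic_hs=stride.contra.time)
        props = {}
        for leg, t_hs in (("paretic", stride.start.time), ("nonparetic", stride.contra.time)):
            t_se = se_times[leg][np.searchsorted(se_times[leg], t_hs)] \
                if np.any(se_times[leg] > t_hs) else times[leg][-1]
            t = times[leg]
            i0 = int(np.searchsorted(t, t_hs - 1e-9))
            i1 = int(np.searchsorted(t, t_se + 1e-9))
            try:
                kin = peak_propulsion(ap_nkg[leg][i0:i1], t[i0:i1], t_hs, t_se)
                props[leg] = kin.peak_propulsion
            except KineticError:
                logger.warning("stride %d: empty %s stance; propulsion missing",
                               stride.ordinal, leg)
                props[leg] = np.nan
        stride_rows.append({
            "stride_idx": stride.ordinal,
            "epoch": stride.epoch,
            "lead_leg": "paretic",
            "sl_paretic_mm": spatial.sl_paretic,
            "sl_nonparetic_mm": spatial.sl_nonparetic,
            "sla": spatial.sla,
            "alpha_paretic_mm": spatial.alpha_paretic,
            "alpha_nonparetic_mm": spatial.alpha_nonparetic,
            "x_paretic_mm": spatial.x_paretic,
            "x_nonparetic_mm": spatial.x_nonparetic,
            "prop_paretic_nkg": props["paretic"],
            "prop_nonparetic_nkg": props["nonparetic"],
        })
    table = pd.DataFrame(stride_rows, columns=STRIDE_TABLE_COLUMNS)
    logger.info("extracted %d strides (%s)", len(table),
                table["epoch"].value_counts().to_dict() if len(table) else {})
    return table


def run_session(config: ProtocolConfig, seed: int,
                params=None, session: str = "") -> tuple[pd.DataFrame, EpochOutcomes, "object"]:
    """Simulate one session and analyze it; returns (stride table, outcomes,
    realized truth).  Convenience wrapper used by the CLI and validation."""
    from .synth import default_adaptation_params, generate_stride_series, synthesize_trial

    params = params or default_adaptation_params(config.slope_deg)
    truth = generate_stride_series(params, config.epoch_plan, seed=seed)
    recording, realized = synthesize_trial(truth, config, seed=seed + 1, params=params)
    table = extract_stride_table(recording, config)
    out = compute_outcomes(table, config.processing,
                           subject_id=config.subject_id,
                           session=session or ("incline" if config.slope_deg > 0 else "flat"))
    return table, out, realized


# -- cohort-level statistics battery -----------------------------------------

#: (parameter, outcome) pairs compared flat vs. incline with paired t-tests
PAIRED_CONTRASTS = [
    ("sla", "baseline"),
    ("sla", "late_adaptation"),
    ("sla", "delta_adapt"),
    ("sla", "after_effects"),
    ("prop_paretic_nkg", "late_adaptation"),
    ("prop_nonparetic_nkg", "late_adaptation"),
    ("prop_paretic_nkg", "delta_adapt"),
    ("prop_nonparetic_nkg", "delta_adapt"),
    ("prop_paretic_nkg", "after_effects"),
    ("prop_nonparetic_nkg", "after_effects"),
]


def outcomes_frame(outcomes: list[EpochOutcomes]) -> pd.DataFrame:
    """Long-form cohort table: subject, session, parameter, <measures>."""
    return pd.concat([o.to_frame() for o in outcomes], ignore_index=True)


def group_stats(outcomes: list[EpochOutcomes], seed: int = 0) -> dict:
    """The study-style group analysis on a cohort of flat+incline outcomes.

    Runs (a) Lilliefors normality gates on each tested sample, (b) paired
    flat-vs-incline t-tests on SLA and propulsion outcome measures, (c)
    one-sample t-tests (Bonferroni) of the step-length delta-post values
    against zero, (d) the repeated-measures ANOVAs — baseline propulsion and
    baseline trailing position with slope x leg as within factors, and the
    step-length changes with slope x leg within and epoch (dAdapt vs. dPost)
    as the between factor — and (e) through-origin regressions relating
    slow-baseline leg orientations to late adaptation and late adaptation to
    early post-adaptation.
    """
    cohort = outcomes_frame(outcomes)
    sessions = sorted(cohort["session"].unique())
    if set(sessions) != {"flat", "incline"}:
        raise ValueError(f"need flat and incline sessions, got {sessions}")
    wide = cohort.set_index(["subject_id", "session", "parameter"]).sort_index()

    def sample(session, parameter, measure):
        sel = wide.xs((session, parameter), level=("session", "parameter"))[measure]
        return sel.sort_index().to_numpy(float)

    report: dict = {"paired_t": {}, "one_sample_t": {}, "anova": {},
                    "regression": {}, "normality": {}}

    for param, measure in PAIRED_CONTRASTS:
        flat = sample("flat", param, measure)
        incl = sample("incline", param, measure)
        key = f"{param}.{measure}"
        report["paired_t"][key] = sb_stats.paired_t(incl, flat).to_dict()
        gate = sb_stats.lilliefors(incl - flat, n_replicates=2000, seed=seed)
        report["normality"][key] = {"D": gate.D, "p": gate.p, "normal_at_05": gate.p > 0.05}

    # step-length de-adaptation vs. zero, per leg and slope (Bonferroni m=4)
    dpost = {
        f"{leg}.{session}": sample(session, f"sl_{leg}_mm", "delta_post")
        for leg in ("paretic", "nonparetic") for session in ("flat", "incline")
    }
    results = sb_stats.one_sample_t_bonferroni(list(dpost.values()), mu0=0.0, m=4)
    report["one_sample_t"] = {k: r.to_dict() for k, r in zip(dpost, results)}

    # ANOVAs with subject as random factor
    def long_baseline(parameter_by_leg):
        rows = []
        for session in ("flat", "incline"):
            for leg in ("paretic", "nonparetic"):
                vals = sample(session, parameter_by_leg.format(leg=leg), "baseline")
                subjects = sorted(cohort["subject_id"].unique())
                rows += [{"subject": s, "slope": session, "leg": leg, "value": v}
                         for s, v in zip(subjects, vals)]
        return pd.DataFrame(rows)

    for name, pattern in (("baseline_propulsion", "prop_{leg}_nkg"),
                          ("baseline_trailing_x", "x_{leg}_mm")):
        res = sb_stats.rm_anova(long_baseline(pattern), dv="value",
                                subject="subject", within=["slope", "leg"])
        report["anova"][name] = res.effects.to_dict(orient="records")

    rows = []
    for session in ("flat", "incline"):
        for leg in ("paretic", "nonparetic"):
            for measure in ("delta_adapt", "delta_post"):
                vals = sample(session, f"sl_{leg}_mm", measure)
                subjects = sorted(cohort["subject_id"].unique())
                rows += [{"subject": f"{s}#{measure}", "slope": session, "leg": leg,
                          "epoch": measure, "value": v}
                         for s, v in zip(subjects, vals)]
    res = sb_stats.rm_anova(pd.DataFrame(rows), dv="value", subject="subject",
                            within=["slope", "leg"], between="epoch")
    report["anova"]["step_length_changes"] = res.effects.to_dict(orient="records")

    # regressions: slow baseline -> late adaptation (paretic leg, flat session),
    # late adaptation -> early post (ipsilateral alpha, contralateral X, pooled)
    flat_rows = wide.xs("flat", level="session")
    has_slow = "baseline_slow_raw" in flat_rows.columns and \
        flat_rows["baseline_slow_raw"].notna().any()
    if has_slow:
        z, y = [], []
        for param in ("alpha_paretic_mm", "x_paretic_mm"):
            z.append(sample("flat", param, "baseline_slow_raw"))
            y.append(sample("flat", param, "late_adaptation_raw"))
        fit = sb_stats.regress_origin(np.concatenate(z), np.concatenate(y))
        report["regression"]["slow_baseline_vs_late_adaptation"] = fit.to_dict()

    z, y = [], []
    for session in ("flat", "incline"):
        for leg, contra in (("paretic", "nonparetic"), ("nonparetic", "paretic")):
            z.append(sample(session, f"alpha_{leg}_mm", "late_adaptation_raw"))
            y.append(sample(session, f"alpha_{leg}_mm", "early_post_raw"))
            z.append(sample(session, f"x_{contra}_mm", "late_adaptation_raw"))
            y.append(sample(session, f"x_{leg}_mm", "early_post_raw"))
    fit = sb_stats.regress_origin(np.concatenate(z), np.concatenate(y))
    report["regression"]["late_adaptation_vs_early_post"] = fit.to_dict()
    return report


def stats_report_frame(report: dict) -> pd.DataFrame:
    """Flatten a :func:`group_stats` report into one row per test."""
    rows = []
    for kind in ("paired_t", "one_sample_t"):
        for key, vals in report.get(kind, {}).items():
            rows.append({"test": kind, "name": key, **vals})
    for name, effects in report.get("anova", {}).items():
        for eff in effects:
            rows.append({"test": "rm_anova", "name": f"{name}:{eff['effect']}",
                         **{k: eff[k] for k in ("F", "df_num", "df_den", "p", "eta_sq")}})
    for name, vals in report.get("regression", {}).items():
        rows.append({"test": "regress_origin", "name": name,
                     **{k: v for k, v in vals.items() if k != "ci95"},
                     "ci_lo": vals["ci95"][0], "ci_hi": vals["ci95"][1]})
    return pd.DataFrame(rows)
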