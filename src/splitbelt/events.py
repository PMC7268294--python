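"""Gait events from normal ground-reaction forces.

Heel strikes are threshold crossings of the normal force: 10 N on
median-filtered data for offline analysis, 30 N on raw data to emulate the
real-time stride counter.  Sub-physiological excursions are debounced: brief
force dropouts within a stance are merged and brief blips in swing are
ignored.  A stride is the interval between two consecutive heel strikes of
the same (reference) leg and must contain exactly one contralateral strike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocess import ForceSeries

logger = logging.getLogger(__name__)


class EventError(ValueError):
    """Invalid event-detection input."""


@dataclass(frozen=True)
class GaitEvent:
    leg: str          # 'paretic' | 'nonparetic'
    kind: str         # 'heel_strike' | 'stance_end'
    time: float       # s
    sample: int       # index into the force series


@dataclass(frozen=True)
class StrideIndex:
    """One reference-leg stride: [start, end) heel strikes + the contralateral
    heel strike inside it."""

    ordinal: int
    leg: str
    start: GaitEvent
    end: GaitEvent
    contra: GaitEvent
    stance_end: GaitEvent | None = None        # reference-leg stance end after start
    contra_stance_end: GaitEvent | None = None
    epoch: str | None = None


def detect_stance(
    force: ForceSeries,
    threshold_n: float = 10.0,
    min_stance_ms: float = 100.0,
    min_swing_ms: float = 100.0,
    leg: str = "paretic",
) -> list[GaitEvent]:
    """Detect heel strikes and stance ends by thresholding the normal force.

    A heel strike is the first sample at or above ``threshold_n`` of each
    suprathreshold run lasting at least ``min_stance_ms``; the stance end is
    the first sample below threshold of the following subthreshold run lasting
    at least ``min_swing_ms``.  Shorter excursions in either direction are
    debounced (sub-threshold dropouts shorter than ``min_swing_ms`` are merged
    into the surrounding stance first, then stances shorter than
    ``min_stance_ms`` are discarded).
    """
    fn = np.asarray(force.f_normal)
    if len(fn) == 0 or not np.any(fn >= threshold_n):
        logger.warning("force %s: no samples reach %.1f N; no events", force.side, threshold_n)
        return []
    rate = force.rate_hz
    min_stance = int(round(min_stance_ms * rate / 1000.0))
    min_swing = int(round(min_swing_ms * rate / 1000.0))

    above = fn >= threshold_n
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]    # half-open suprathreshold runs

    # merge stances separated by sub-threshold runs shorter than min_swing
    merged: list[list[int]] = []
    for s, e in zip(starts, stops):
        if merged and s - merged[-1][1] < min_swing:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    events: list[GaitEvent] = []
    n = len(fn)
    for s, e in merged:
        if e - s < min_stance:
            continue
        events.append(GaitEvent(leg, "heel_strike", float(force.times[s]), s))
        if e < n:   # stance running to the end of the record has no stance_end
            events.append(GaitEvent(leg, "stance_end", float(force.times[e]), e))
    return events


def segment_strides(
    reference_events: list[GaitEvent],
    contra_events: list[GaitEvent],
) -> list[StrideIndex]:
    """Pair consecutive reference-leg heel strikes into strides.

    Malformed intervals — containing zero or more than one contralateral heel
    strike — are dropped and counted in the log.  Fewer than two reference
    heel strikes yields an empty list with a warning.
    """
    ref_hs = [e for e in reference_events if e.kind == "heel_strike"]
    con_hs = [e for e in contra_events if e.kind == "heel_strike"]
    ref_se = [e for e in reference_events if e.kind == "stance_end"]
    con_se = [e for e in contra_events if e.kind == "stance_end"]
    if len(ref_hs) < 2:
        logger.warning("fewer than 2 reference heel strikes; no strides")
        return []
    con_times = np.array([e.time for e in con_hs])
    strides: list[StrideIndex] = []
    dropped = 0
    for k in range(len(ref_hs) - 1):
        start, end = ref_hs[k], ref_hs[k + 1]
        inside = np.flatnonzero((con_times >= start.time) & (con_times < end.time))
        if len(inside) != 1:
            dropped += 1
            continue
        contra = con_hs[int(inside[0])]
        stance_end = next((e for e in ref_se if e.time > start.time), None)
        if stance_end is not None and stance_end.time >= end.time:
            stance_end = None
        contra_stance_end = next((e for e in con_se if e.time > contra.time), None)
        strides.append(
            StrideIndex(
                ordinal=len(strides), leg=start.leg, start=start, end=end,
                contra=contra, stance_end=stance_end,
                contra_stance_end=contra_stance_end,
            )
        )
    if dropped:
        logger.info("segment_strides: dropped %d malformed stride interval(s)", dropped)
    return strides


def build_schedule(epoch_plan, stride_estimates: dict[str, float],
                   break_s: float = 5.0) -> pd.DataFrame:
    """Nominal belt-speed schedule from an epoch plan and per-epoch stride
    duration estimates (used by the generator; real recordings carry their
    measured schedule)."""
    rows, t = [], 0.0
    for spec in epoch_plan:
        dur = spec.planned_strides * stride_estimates[spec.name]
        rows.append((spec.name, t, t + dur, spec.left_belt_speed, spec.right_belt_speed))
        t += dur + break_s
    return pd.DataFrame(rows, columns=["epoch", "t_start", "t_end", "left_speed", "right_speed"])


def assign_epochs(
    strides: list[StrideIndex],
    epoch_plan,
    schedule: pd.DataFrame,
) -> list[StrideIndex]:
    """Label each stride with the epoch active at its starting heel strike.

    ``schedule`` has columns epoch, t_start, t_end (s), left_speed,
    right_speed — the belt-speed log of the session.  Strides that start
    outside every scheduled epoch, or that span an epoch boundary (start and
    end in different epochs), are dropped with a warning.  The schedule must
    cover every epoch named in the plan.
    """
    plan_names = [spec.name for spec in epoch_plan]
    missing = set(plan_names) - set(schedule["epoch"])
    if missing:
        raise EventError(f"schedule missing epoch(s): {sorted(missing)}")

    starts = schedule["t_start"].to_numpy()
    ends = schedule["t_end"].to_numpy()
    names = schedule["epoch"].to_list()

    def epoch_at(t: float) -> str | None:
        hit = np.flatnonzero((starts <= t) & (t < ends))
        return names[int(hit[0])] if len(hit) else None

    labeled: list[StrideIndex] = []
    dropped_outside = dropped_spanning = 0
    for stride in strides:
        e_start = epoch_at(stride.start.time)
        if e_start is None:
            dropped_outside += 1
            continue
        e_end = epoch_at(stride.end.time)
        if e_end != e_start:
            dropped_spanning += 1
            continue
        labeled.append(replace(stride, ordinal=len(labeled), epoch=e_start))
    if dropped_outside or dropped_spanning:
        logger.info("assign_epochs: dropped %d stride(s) outside schedule, %d spanning a transition",
                    dropped_outside, dropped_spanning)
    counts = pd.Series([s.epoch for s in labeled]).value_counts().to_dict() if labeled else {}
    logger.info("strides per epoch: %s", counts)
    return labeled


def events_table(events: list[GaitEvent]) -> pd.DataFrame:
    """Debug view: one row per event (time_s, leg, kind, sample_idx)."""
    return pd.DataFrame(
        [(e.time, e.leg, e.kind, e.sample) for e in events],
        columns=["time_s", "leg", "kind", "sample_idx"],
    )
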