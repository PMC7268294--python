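"""Readers and writers for the pipeline's on-disk formats.

All formats are plain TSV/JSON:

* ``markers.tsv`` — long form: time_s, marker, x_mm, y_mm, z_mm (NaN rows are
  occluded frames); markers ankle_L/ankle_R/troch_L/troch_R are required.
* ``forces.tsv`` — time_s, side, f_ap_n, f_ml_n, f_normal_n with one force
  plate per belt (side in {left, right}).
* ``schedule.tsv`` — the belt-speed log: epoch, t_start, t_end, left_speed,
  right_speed.
* ``truth.tsv`` — the generator's stride-indexed truth table.
* ``stride_table.tsv`` — one row per stride with the documented columns.
* ``outcomes.json`` — the five outcome measures keyed by parameter.

Marker and force clocks share t = 0 at recording start; no cross-correlation
alignment is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ProtocolConfig
from .outcomes import EpochOutcomes
from .preprocess import ForceSeries, MarkerTimeSeries

logger = logging.getLogger(__name__)

REQUIRED_MARKERS = ("ankle_L", "ankle_R", "troch_L", "troch_R")

MARKER_COLUMNS = ["time_s", "marker", "x_mm", "y_mm", "z_mm"]
FORCE_COLUMNS = ["time_s", "side", "f_ap_n", "f_ml_n", "f_normal_n"]
SCHEDULE_COLUMNS = ["epoch", "t_start", "t_end", "left_speed", "right_speed"]
STRIDE_TABLE_COLUMNS = [
    "stride_idx", "epoch", "lead_leg",
    "sl_paretic_mm", "sl_nonparetic_mm", "sla",
    "alpha_paretic_mm", "alpha_nonparetic_mm",
    "x_paretic_mm", "x_nonparetic_mm",
    "prop_paretic_nkg", "prop_nonparetic_nkg",
]


class FormatError(ValueError):
    """Malformed on-disk data."""


@dataclass
class TrialRecording:
    """One session's raw signals plus protocol metadata."""

    markers: dict[str, MarkerTimeSeries]
    forces: dict[str, ForceSeries]
    schedule: pd.DataFrame
    meta: dict = field(default_factory=dict)


def _require_columns(frame: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def write_markers(markers: dict[str, MarkerTimeSeries], path) -> None:
    frames = []
    for name, series in markers.items():
        positions = series.positions.copy()
        positions[~series.valid] = np.nan
        frames.append(pd.DataFrame({
            "time_s": series.times, "marker": name,
            "x_mm": positions[:, 0], "y_mm": positions[:, 1], "z_mm": positions[:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_markers(path, expected_rate_hz: float | None = None) -> dict[str, MarkerTimeSeries]:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, MARKER_COLUMNS, path)
    missing = set(REQUIRED_MARKERS) - set(frame["marker"].unique())
    if missing:
        raise FormatError(f"{path}: missing required marker(s) {sorted(missing)}")
    markers = {}
    for name, group in frame.groupby("marker", sort=False):
        times = group["time_s"].to_numpy(float)
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise FormatError(f"{path}: non-monotone timestamps for marker {name}")
        if expected_rate_hz is not None and len(times) > 1:
            rate = 1.0 / float(np.median(np.diff(times)))
            if abs(rate - expected_rate_hz) > 0.01 * expected_rate_hz:
                raise FormatError(
                    f"{path}: marker {name} sampling rate {rate:.1f} Hz "
                    f"does not match declared {expected_rate_hz:.1f} Hz")
        positions = group[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        valid = np.all(np.isfinite(positions), axis=1)
        positions[~valid] = np.nan
        markers[name] = MarkerTimeSeries(str(name), times, positions, valid=valid)
    return markers


def write_forces(forces: dict[str, ForceSeries], path) -> None:
    frames = []
    for side, series in forces.items():
        frames.append(pd.DataFrame({
            "time_s": series.times, "side": side,
            "f_ap_n": series.f_ap, "f_ml_n": series.f_ml, "f_normal_n": series.f_normal,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_forces(path, expected_rate_hz: float | None = None) -> dict[str, ForceSeries]:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, FORCE_COLUMNS, path)
    forces = {}
    for side, group in frame.groupby("side", sort=False):
        if side not in ("left", "right"):
            raise FormatError(f"{path}: unknown side {side!r}")
        times = group["time_s"].to_numpy(float)
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise FormatError(f"{path}: non-monotone timestamps for side {side}")
        if expected_rate_hz is not None and len(times) > 1:
            rate = 1.0 / float(np.median(np.diff(times)))
            if abs(rate - expected_rate_hz) > 0.01 * expected_rate_hz:
                raise FormatError(
                    f"{path}: side {side} sampling rate {rate:.1f} Hz "
                    f"does not match declared {expected_rate_hz:.1f} Hz")
        forces[str(side)] = ForceSeries(
            str(side), times, group["f_ap_n"].to_numpy(float),
            group["f_ml_n"].to_numpy(float), group["f_normal_n"].to_numpy(float))
    return forces


def write_schedule(schedule: pd.DataFrame, path) -> None:
    schedule.to_csv(path, sep="\t", index=False)


def read_schedule(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, SCHEDULE_COLUMNS, path)
    return frame


def read_trial(
    markers_path,
    forces_path,
    config: ProtocolConfig,
    schedule_path=None,
    marker_rate_hz: float | None = 100.0,
    force_rate_hz: float | None = 1000.0,
) -> TrialRecording:
    """Load a raw trial (lab frame) from its marker/force/schedule files."""
    markers = read_markers(markers_path, marker_rate_hz)
    forces = read_forces(forces_path, force_rate_hz)
    for side in ("left", "right"):
        if side not in forces:
            raise FormatError(f"{forces_path}: missing force plate for side {side!r}")
    schedule = read_schedule(schedule_path) if schedule_path else pd.DataFrame(
        columns=SCHEDULE_COLUMNS)
    return TrialRecording(markers=markers, forces=forces, schedule=schedule,
                          meta={"subject_id": config.subject_id})


def write_stride_table(table: pd.DataFrame, path) -> None:
    _require_columns(table, STRIDE_TABLE_COLUMNS, "stride table")
    table[STRIDE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_stride_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, STRIDE_TABLE_COLUMNS, path)
    return frame


def write_truth(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_outcomes(outcomes: EpochOutcomes | list[EpochOutcomes], path) -> None:
    items = outcomes if isinstance(outcomes, list) else [outcomes]
    payload = [
        {"subject_id": o.subject_id, "session": o.session, "measures": o.measures}
        for o in items
    ]
    Path(path).write_text(json.dumps(payload if isinstance(outcomes, list) else payload[0],
                                     indent=2, sort_keys=True))


def read_outcomes(path) -> EpochOutcomes | list[EpochOutcomes]:
    raw = json.loads(Path(path).read_text())
    def build(d):
        return EpochOutcomes(subject_id=d["subject_id"], session=d["session"],
                             measures=d["measures"])
    return [build(d) for d in raw] if isinstance(raw, list) else build(raw)
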