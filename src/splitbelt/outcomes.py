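"""Epoch outcome measures per gait parameter.

Five measures summarize each stride-by-stride parameter time course:

* Baseline — mean of the last 40 strides of the mid-speed baseline epoch;
* Late Adaptation — mean of the last 40 adaptation strides, minus Baseline;
* After-Effects — mean of the first 5 post-adaptation strides, minus Baseline;
* dAdapt — late minus early (first 5 strides) adaptation means;
* dPost — Baseline minus early post-adaptation mean (= -After-Effects;
  Baseline serves as the proxy for late post-adaptation).

Missing-flagged (NaN) strides are skipped; the window simply extends over the
nearest valid strides of the epoch.  Time-course outputs are binned as means
of 5 consecutive strides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ProcessingParams

logger = logging.getLogger(__name__)

#: stride-table columns treated as gait parameters
PARAMETERS = (
    "sla",
    "sl_paretic_mm", "sl_nonparetic_mm",
    "alpha_paretic_mm", "alpha_nonparetic_mm",
    "x_paretic_mm", "x_nonparetic_mm",
    "prop_paretic_nkg", "prop_nonparetic_nkg",
)


class OutcomeError(ValueError):
    pass


@dataclass
class EpochOutcomes:
    """The five outcome measures per parameter, plus raw window means."""

    subject_id: str
    session: str                                  # e.g. 'flat' | 'incline'
    measures: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": p, **vals} for p, vals in self.measures.items()
        ]
        frame = pd.DataFrame(rows)
        frame.insert(0, "session", self.session)
        frame.insert(0, "subject_id", self.subject_id)
        return frame


def _window_mean(values: np.ndarray, count: int, side: str, label: str) -> float:
    """Mean over the first/last ``count`` valid (non-NaN) entries."""
    valid = values[np.isfinite(values)]
    if len(valid) < count:
        raise OutcomeError(
            f"{label}: {len(valid)} valid strides, need >= {count}"
        )
    window = valid[:count] if side == "first" else valid[-count:]
    return float(np.mean(window))


def compute_outcomes(
    stride_table: pd.DataFrame,
    windows: ProcessingParams | None = None,
    subject_id: str = "",
    session: str = "",
    parameters=PARAMETERS,
) -> EpochOutcomes:
    """Collapse a stride table into the five outcome measures per parameter.

    Requires >= ``late_window_strides`` valid baseline-mid strides,
    >= ``late + early`` adaptation strides and >= ``early`` post strides
    (insufficient epochs raise :class:`OutcomeError` naming the epoch).
    Raw epoch-window means are stored alongside the derived measures
    (``*_raw`` keys, plus the slow-baseline mean when that epoch is present)
    because the regression analyses operate on unbiased raw positions.
    """
    windows = windows or ProcessingParams()
    late, early = windows.late_window_strides, windows.early_window_strides
    epochs = stride_table["epoch"]
    out = EpochOutcomes(subject_id=subject_id, session=session)
    has_slow = bool((epochs == "baseline_slow").any())
    for param in parameters:
        if param not in stride_table.columns:
            continue
        base = stride_table.loc[epochs == "baseline_mid", param].to_numpy(float)
        adapt = stride_table.loc[epochs == "adaptation", param].to_numpy(float)
        post = stride_table.loc[epochs == "post_adaptation", param].to_numpy(float)
        baseline = _window_mean(base, late, "last", "baseline_mid")
        if np.sum(np.isfinite(adapt)) < late + early:
            raise OutcomeError(
                f"adaptation: {np.sum(np.isfinite(adapt))} valid strides, "
                f"need >= {late + early}"
            )
        late_raw = _window_mean(adapt, late, "last", "adaptation")
        early_raw = _window_mean(adapt, early, "first", "adaptation")
        early_post_raw = _window_mean(post, early, "first", "post_adaptation")
        measures = {
            "baseline": baseline,
            "late_adaptation": late_raw - baseline,
            "after_effects": early_post_raw - baseline,
            "delta_adapt": late_raw - early_raw,
            "delta_post": baseline - early_post_raw,
            "early_adaptation_raw": early_raw,
            "late_adaptation_raw": late_raw,
            "early_post_raw": early_post_raw,
        }
        if has_slow:
            slow = stride_table.loc[epochs == "baseline_slow", param].to_numpy(float)
            measures["baseline_slow_raw"] = _window_mean(
                slow, min(late, max(1, np.sum(np.isfinite(slow)))), "last", "baseline_slow"
            )
        out.measures[param] = measures
    return out


def remove_baseline_bias(stride_series: pd.Series | np.ndarray, baseline: float):
    """Subtract the subject-session baseline from every stride value.

    Returns a pandas Series with ``attrs['bias_removed']`` set; re-applying to
    an already-unbiased series raises (the operation is not idempotent).
    """
    series = pd.Series(np.asarray(stride_series, dtype=float) - baseline)
    if isinstance(stride_series, pd.Series):
        if stride_series.attrs.get("bias_removed"):
            raise OutcomeError("baseline bias already removed from this series")
        series.index = stride_series.index
    series.attrs["bias_removed"] = True
    return series


def bin_strides(stride_series, bin_size: int = 5) -> pd.DataFrame:
    """Non-overlapping means of ``bin_size`` consecutive strides.

    The trailing partial bin is kept and flagged (``full == False``).
    Returns columns bin_idx, value, n_strides, full.
    """
    if bin_size < 1:
        raise OutcomeError(f"bin_size must be >= 1, got {bin_size}")
    values = np.asarray(stride_series, dtype=float)
    rows = []
    for b, start in enumerate(range(0, len(values), bin_size)):
        chunk = values[start:start + bin_size]
        rows.append(
            (b, float(np.nanmean(chunk)) if np.any(np.isfinite(chunk)) else np.nan,
             int(np.sum(np.isfinite(chunk))), len(chunk) == bin_size)
        )
    return pd.DataFrame(rows, columns=["bin_idx", "value", "n_strides", "full"])


def binned_timecourse(stride_table: pd.DataFrame, bin_size: int = 5,
                      parameters=PARAMETERS) -> pd.DataFrame:
    """Per-epoch 5-stride-binned time course for every parameter (long form)."""
    frames = []
    for epoch, group in stride_table.groupby("epoch", sort=False):
        for param in parameters:
            if param not in group.columns:
                continue
            binned = bin_strides(group[param].to_numpy(), bin_size)
            binned.insert(0, "parameter", param)
            binned.insert(0, "epoch", epoch)
            frames.append(binned)
    return pd.concat(frames, ignore_index=True)
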