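"""Per-stride spatial gait parameters in the surface frame.

Step length (SL) is the anterior-posterior distance between the two ankle
markers at the leading leg's heel strike.  Each step decomposes about the
body: the leading leg lands at alpha (> 0, ahead of the hips) and the
trailing leg sits at X (< 0, behind the hips), with alpha_lead - X_trail
equal to the step length.  The hip reference is the mean of the two greater
trochanter markers.  Step length asymmetry (SLA) is the step length
difference normalized by stride length:

    SLA = (SL_nonparetic - SL_paretic) / (SL_nonparetic + SL_paretic)

positive when the non-paretic step is the longer one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import MarkerTimeSeries

logger = logging.getLogger(__name__)


class SpatialError(ValueError):
    pass


@dataclass(frozen=True)
class StrideSpatial:
    """Spatial parameters of one stride (NaN where a marker was missing)."""

    sl_paretic: float
    sl_nonparetic: float
    sla: float
    alpha_paretic: float
    alpha_nonparetic: float
    x_paretic: float
    x_nonparetic: float

    @property
    def stride_length(self) -> float:
        return self.sl_paretic + self.sl_nonparetic


def step_length(ankle_lead_x: float, ankle_trail_x: float) -> float:
    """Anterior-posterior ankle-to-ankle distance (mm), leading minus trailing."""
    return float(ankle_lead_x - ankle_trail_x)


def step_length_asymmetry(sl_nonparetic: float, sl_paretic: float) -> float:
    """(SL_np - SL_p) / (SL_np + SL_p); NaN when the stride length is not positive."""
    denom = sl_nonparetic + sl_paretic
    if not denom > 0:
        logger.warning("non-positive stride length (%.1f); SLA undefined", denom)
        return float("nan")
    return float((sl_nonparetic - sl_paretic) / denom)


def leg_orientations(
    ankle_lead_x: float,
    ankle_trail_x: float,
    troch_left_x: float,
    troch_right_x: float,
) -> tuple[float, float]:
    """(alpha_lead, X_trail) in mm about the hip midpoint.

    hip = mean of the trochanter x-coordinates; alpha = leading ankle - hip
    (positive ahead), X = trailing ankle - hip (negative behind).  By
    construction alpha - X equals the step length.
    """
    hip_x = 0.5 * (troch_left_x + troch_right_x)
    return float(ankle_lead_x - hip_x), float(ankle_trail_x - hip_x)


def marker_x_at(series: MarkerTimeSeries, time_s: float) -> float:
    """Surface-frame x of a marker at the frame nearest to an event time.

    Events come from the 1000 Hz force clock; the nearest 100 Hz kinematic
    frame is at most 5 ms away.  Returns NaN (and logs) when that frame is
    masked invalid, which flags the stride for listwise exclusion.
    """
    idx = int(np.clip(np.searchsorted(series.times, time_s), 0, len(series.times) - 1))
    if idx > 0 and abs(series.times[idx - 1] - time_s) <= abs(series.times[idx] - time_s):
        idx -= 1
    if not series.valid[idx]:
        logger.warning("marker %s invalid at frame %d (t=%.3f s)", series.name, idx, time_s)
        return float("nan")
    return float(series.positions[idx, 0])


def stride_spatial(
    markers: dict[str, MarkerTimeSeries],
    paretic_side: str,
    t_paretic_hs: float,
    t_nonparetic_hs: float,
) -> StrideSpatial:
    """Spatial parameters of one stride from its two heel-strike times.

    ``markers`` must contain ankle_L/ankle_R/troch_L/troch_R in the surface
    frame.  ``t_nonparetic_hs`` is the contralateral heel strike inside the
    stride and ``t_paretic_hs`` the paretic heel strike ending it (the two
    consecutive steps of the stride).
    """
    suffix_p = "L" if paretic_side == "left" else "R"
    suffix_np = "R" if paretic_side == "left" else "L"
    ankle_p, ankle_np = markers[f"ankle_{suffix_p}"], markers[f"ankle_{suffix_np}"]
    troch_l, troch_r = markers["troch_L"], markers["troch_R"]

    # non-paretic step: non-paretic leg leads, paretic trails
    lead_np = marker_x_at(ankle_np, t_nonparetic_hs)
    trail_p = marker_x_at(ankle_p, t_nonparetic_hs)
    alpha_np, x_p = leg_orientations(
        lead_np, trail_p,
        marker_x_at(troch_l, t_nonparetic_hs), marker_x_at(troch_r, t_nonparetic_hs),
    )
    sl_np = step_length(lead_np, trail_p)

    # paretic step: paretic leg leads, non-paretic trails
    lead_p = marker_x_at(ankle_p, t_paretic_hs)
    trail_np = marker_x_at(ankle_np, t_paretic_hs)
    alpha_p, x_np = leg_orientations(
        lead_p, trail_np,
        marker_x_at(troch_l, t_paretic_hs), marker_x_at(troch_r, t_paretic_hs),
    )
    sl_p = step_length(lead_p, trail_np)

    sla = step_length_asymmetry(sl_np, sl_p) if np.isfinite(sl_np + sl_p) else float("nan")
    return StrideSpatial(
        sl_paretic=sl_p, sl_nonparetic=sl_np, sla=sla,
        alpha_paretic=alpha_p, alpha_nonparetic=alpha_np,
        x_paretic=x_p, x_nonparetic=x_np,
    )
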