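"""Per-stride propulsion extraction from the anterior-posterior force.

The AP ground-reaction force in stance is biphasic: a braking (negative)
phase under the leading leg followed by a propulsion (positive) phase as the
leg trails.  Peak propulsion is the maximum body-weight-normalized AP force
in stance, excluding the brief positive transient that can follow heel
strike.  The exclusion is operationalized by anchoring the search window at
the braking minimum: the peak is taken over [argmin(AP), stance end].  No
slope-specific gravity bias is removed here; epoch differencing downstream
takes care of biases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import ForceSeries

logger = logging.getLogger(__name__)


class KineticError(ValueError):
    pass


@dataclass(frozen=True)
class StrideKinetics:
    """Propulsion diagnostics for one leg's stance within a stride."""

    peak_propulsion: float      # N/kg
    braking_min: float          # N/kg (diagnostic)
    search_start_s: float       # start of the propulsion search window
    stance_end_s: float
    atypical: bool = False      # AP never negative in stance


def normalize_force(force_n: np.ndarray | float, mass_kg: float) -> np.ndarray | float:
    """Force in N/kg (division by body mass)."""
    if not mass_kg > 0:
        raise KineticError(f"mass_kg must be positive, got {mass_kg}")
    return force_n / mass_kg


def peak_propulsion(
    ap_nkg: np.ndarray,
    times: np.ndarray,
    t_heel_strike: float,
    t_stance_end: float,
    mode: str = "braking_anchor",
) -> StrideKinetics:
    """Peak propulsion (N/kg) within one stance interval.

    ``ap_nkg`` must already be low-pass filtered and normalized.  With the
    default ``braking_anchor`` rule the search for the maximum starts at the
    braking minimum; ``zero_crossing`` instead starts at the first
    positive-to-negative zero crossing after heel strike.  If the AP force is
    never negative in stance, the maximum over the second half of stance is
    returned and the stride is flagged atypical.
    """
    sel = (times >= t_heel_strike) & (times < t_stance_end)
    idx = np.flatnonzero(sel)
    if len(idx) == 0:
        raise KineticError(
            f"empty stance window [{t_heel_strike:.3f}, {t_stance_end:.3f}] s"
        )
    ap = ap_nkg[idx]
    t = times[idx]
    if not np.any(ap < 0):
        half = idx[len(idx) // 2:]
        logger.warning("stance at %.3f s: AP never negative; flagged atypical", t_heel_strike)
        return StrideKinetics(
            peak_propulsion=float(np.max(ap_nkg[half])),
            braking_min=float(np.min(ap)),
            search_start_s=float(times[half[0]]),
            stance_end_s=t_stance_end,
            atypical=True,
        )
    if mode == "braking_anchor":
        anchor = int(np.argmin(ap))
    elif mode == "zero_crossing":
        neg = np.flatnonzero(ap < 0)
        anchor = int(neg[0])
    else:
        raise KineticError(f"unknown propulsion mode {mode!r}")
    return StrideKinetics(
        peak_propulsion=float(np.max(ap[anchor:])),
        braking_min=float(np.min(ap)),
        search_start_s=float(t[anchor]),
        stance_end_s=t_stance_end,
    )


def propulsion_impulse(
    ap_nkg: np.ndarray,
    times: np.ndarray,
    t_heel_strike: float,
    t_stance_end: float,
) -> float:
    """Diagnostic extra: time integral of the positive AP force over stance
    (N.s/kg)."""
    sel = (times >= t_heel_strike) & (times < t_stance_end)
    if not np.any(sel):
        raise KineticError("empty stance window")
    ap = np.clip(ap_nkg[sel], 0.0, None)
    return float(np.trapezoid(ap, times[sel]))
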