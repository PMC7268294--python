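"""Synthetic split-belt trials: stride-parameter truth plus raw signals.

The generator has two stages.  :func:`generate_stride_series` draws the
stride-by-stride *truth*: each gait parameter follows a single-exponential
time course within its epoch (initial value -> steady state with time
constant tau during adaptation; after-effect decaying back to baseline with
tau_w during post-adaptation; stationary baselines), plus i.i.d. Gaussian
stride-to-stride noise.  :func:`synthesize_trial` then renders raw marker and
force signals that encode that truth:

* heel-strike times follow from the spatial truth and the belt speeds — the
  interval from one leg's landing (alpha) to the contralateral landing is the
  time its ankle needs to travel from alpha to its trailing position X at
  belt speed — and are snapped to the 100 Hz marker grid;
* ankle markers are anchored exactly at hip + alpha at the own heel strike
  and hip + X at the contralateral heel strike (piecewise-linear stance at
  ~belt speed, smooth swing);
* the normal force is a double-hump stance template with a fast loading
  transient so the 10 N / 30 N threshold crossings stay within ~1 ms of the
  scheduled heel strike at every walking speed;
* the AP force is braking-then-propulsion with the propulsion lobe's maximum
  equal to the stride's true peak (N/kg x mass), plus a small positive
  transient right after heel strike to exercise the exclusion rule;
* everything is generated in the surface frame and rotated to the lab frame
  by the session slope, so the preprocessing stage has to undo it.

Resting breaks between epochs are zero-force gaps.  Identical seeds produce
bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import ProtocolConfig
from .preprocess import (FORCE_RATE_HZ, MARKER_RATE_HZ, ForceSeries,
                         MarkerTimeSeries, surface_to_lab)

logger = logging.getLogger(__name__)

G_M_S2 = 9.81

LEGS = ("paretic", "nonparetic")

#: curves required to synthesize raw signals
TRIAL_CURVES = (
    "alpha_paretic", "alpha_nonparetic",
    "x_paretic", "x_nonparetic",
    "prop_paretic", "prop_nonparetic",
)


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class ParamCurve:
    """Exponential epoch model of one gait parameter.

    baseline: stationary mean in the mid-speed baseline epoch (parameter
    units); p0 / p_ss / tau: initial value, steady state and stride time
    constant of the adaptation epoch; a0 / tau_w: after-effect amplitude over
    baseline and washout constant in post-adaptation; noise_sd:
    stride-to-stride SD; baseline_slow: mean of the slow baseline epoch
    (defaults to ``baseline``).
    """

    baseline: float
    p0: float
    p_ss: float
    tau: float
    a0: float = 0.0
    tau_w: float = 20.0
    noise_sd: float = 0.0
    baseline_slow: float | None = None

    def __post_init__(self) -> None:
        if not self.tau > 0 or not self.tau_w > 0:
            raise GenerationError(f"time constants must be positive (tau={self.tau}, tau_w={self.tau_w})")
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")

    def epoch_values(self, epoch: str, n: int) -> np.ndarray:
        """Noise-free curve over ``n`` strides of one epoch (0-based index)."""
        s = np.arange(n, dtype=float)
        if epoch == "adaptation":
            return self.p_ss + (self.p0 - self.p_ss) * np.exp(-s / self.tau)
        if epoch == "post_adaptation":
            return self.baseline + self.a0 * np.exp(-s / self.tau_w)
        if epoch == "baseline_slow":
            value = self.baseline if self.baseline_slow is None else self.baseline_slow
            return np.full(n, value)
        if epoch == "baseline_mid":
            return np.full(n, self.baseline)
        raise GenerationError(f"unknown epoch {epoch!r}")


@dataclass
class AdaptationParams:
    """Generator configuration: one :class:`ParamCurve` per parameter plus
    waveform/timing constants."""

    curves: dict[str, ParamCurve]
    stride_duration_s: float = 1.5       # nominal; realized timing follows geometry
    braking_nkg: float = 1.2             # braking-lobe amplitude
    transient_nkg: float = 0.3           # post-heel-strike positive AP transient
    stance_fraction: float = 0.65
    break_s: float = 5.0                 # zero-force rest between epochs
    lead_in_s: float = 2.0
    marker_noise_mm: float = 0.0
    force_noise_n: float = 0.0
    hip_height_mm: float = 950.0
    hip_sway_mm: float = 8.0
    hip_sway_period_s: float = 1.3

    def __post_init__(self) -> None:
        if self.stride_duration_s <= 0:
            raise GenerationError("stride_duration_s must be positive")
        for name, curve in self.curves.items():
            vals = [curve.baseline, curve.p0, curve.p_ss]
            if name.startswith("alpha") and not all(v > 0 for v in vals):
                raise GenerationError(f"{name}: landing positions must be > 0")
            if name.startswith("x_") and not all(v < 0 for v in vals):
                raise GenerationError(f"{name}: trailing positions must be < 0")


def default_adaptation_params(
    slope_deg: float = 0.0,
    noisy: bool = True,
) -> AdaptationParams:
    """Study-like generator defaults.

    Geometry (mm) and propulsion (N/kg) curves qualitatively reproduce
    split-belt adaptation with the paretic leg on the slow belt: an early
    negative step-length-asymmetry perturbation adapting toward symmetry,
    positive SLA after-effects, a paretic propulsion deficit, and larger
    propulsion / more posterior trailing positions on an incline.
    """
    s = slope_deg
    prop_shift = 0.09 * s               # incline demands more propulsion
    x_shift = -3.0 * s                  # trailing positions more posterior uphill
    ae_gain = 1.0 + 0.04 * s            # larger after-effects on the incline
    pos_sd = 8.0 if noisy else 0.0
    prop_sd = 0.12 if noisy else 0.0
    curves = {
        "alpha_paretic": ParamCurve(230.0, 200.0, 240.0, 30.0,
                                    a0=10.0 * ae_gain, tau_w=20.0,
                                    noise_sd=pos_sd, baseline_slow=200.0),
        "alpha_nonparetic": ParamCurve(250.0, 260.0, 300.0, 40.0,
                                       a0=50.0 * ae_gain, tau_w=20.0,
                                       noise_sd=pos_sd, baseline_slow=220.0),
        "x_paretic": ParamCurve(-270.0 + x_shift, -160.0 + x_shift,
                                -220.0 + x_shift, 30.0,
                                a0=-30.0 * ae_gain, tau_w=20.0,
                                noise_sd=pos_sd, baseline_slow=-240.0 + x_shift),
        "x_nonparetic": ParamCurve(-290.0 + x_shift, -340.0 + x_shift,
                                   -300.0 + x_shift, 40.0,
                                   a0=70.0 * ae_gain, tau_w=20.0,
                                   noise_sd=pos_sd, baseline_slow=-260.0 + x_shift),
        "prop_paretic": ParamCurve(1.0 + prop_shift, 0.4 + prop_shift,
                                   0.9 + prop_shift, 40.0,
                                   a0=0.1, tau_w=15.0, noise_sd=prop_sd,
                                   baseline_slow=0.8 + prop_shift),
        "prop_nonparetic": ParamCurve(1.5 + prop_shift, 1.8 + prop_shift,
                                      1.6 + prop_shift, 40.0,
                                      a0=-0.5, tau_w=15.0, noise_sd=prop_sd,
                                      baseline_slow=1.2 + prop_shift),
    }
    return AdaptationParams(
        curves=curves,
        marker_noise_mm=0.5 if noisy else 0.0,
        force_noise_n=2.0 if noisy else 0.0,
    )


@dataclass
class SyntheticTruth:
    """Stride-indexed true parameter values and the event times used to
    synthesize the signals."""

    table: pd.DataFrame                   # stride_idx, epoch, one col per curve
    events: pd.DataFrame | None = None    # time_s, leg, kind (set by synthesis)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.events is not None and len(self.events):
            for leg in self.events["leg"].unique():
                t = self.events.loc[self.events["leg"] == leg, "time_s"].to_numpy()
                if not np.all(np.diff(t) > 0):
                    raise GenerationError(f"event times for {leg} not strictly increasing")


def generate_stride_series(
    params: AdaptationParams,
    epoch_plan,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw the stride-by-stride truth for every parameter curve.

    Within adaptation p(s) = p_ss + (p0 - p_ss) exp(-s/tau) + eps_s; within
    post-adaptation p(s) = baseline + a0 exp(-s/tau_w) + eps_s; baselines are
    stationary; eps_s i.i.d. N(0, noise_sd^2).  Reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for spec in epoch_plan:
        n = spec.planned_strides
        cols = {"stride_idx": np.arange(offset, offset + n), "epoch": spec.name}
        for name, curve in params.curves.items():
            values = curve.epoch_values(spec.name, n)
            if curve.noise_sd > 0:
                values = values + rng.normal(0.0, curve.noise_sd, size=n)
            cols[name] = values
        frames.append(pd.DataFrame(cols))
        offset += n
    table = pd.concat(frames, ignore_index=True)
    if {"alpha_paretic", "x_nonparetic", "alpha_nonparetic", "x_paretic"} <= set(table.columns):
        table["sl_paretic"] = table["alpha_paretic"] - table["x_nonparetic"]
        table["sl_nonparetic"] = table["alpha_nonparetic"] - table["x_paretic"]
        table["sla"] = (table["sl_nonparetic"] - table["sl_paretic"]) / (
            table["sl_nonparetic"] + table["sl_paretic"])
    return SyntheticTruth(table=table, seed=seed)


# -- signal synthesis --------------------------------------------------------

_GRID = 1.0 / MARKER_RATE_HZ


def _snap(t: float, after: float | None = None) -> float:
    """Snap to the marker frame grid, strictly after ``after`` if given."""
    snapped = round(t * MARKER_RATE_HZ) / MARKER_RATE_HZ
    if after is not None and snapped <= after:
        snapped = after + _GRID
    return snapped


@dataclass
class _Stance:
    t_hs: float
    dur: float
    pos_hs: float            # absolute surface x (mm) at heel strike
    slope_mm_s: float        # backward travel rate during stance
    prop_nkg: float
    t_next_hs: float | None  # next own heel strike (None at record end)


def synthesize_trial(
    truth: SyntheticTruth,
    config: ProtocolConfig,
    seed: int = 0,
    params: AdaptationParams | None = None,
) -> tuple["TrialRecording", SyntheticTruth]:
    """Render raw lab-frame signals for a stride truth table.

    Returns the trial recording and the *realized* truth: the input table
    augmented with realized step lengths / SLA and the scheduled event times
    after snapping to the marker grid.  Sensor noise (controlled by
    ``params``) is drawn from ``seed`` independently of the stride noise.
    """
    from .io import TrialRecording   # local import to avoid a cycle

    params = params or default_adaptation_params(config.slope_deg)
    missing = [c for c in TRIAL_CURVES if c not in truth.table.columns]
    if missing:
        raise GenerationError(f"truth table missing curves: {missing}")
    rng = np.random.default_rng(seed)
    table = truth.table.copy()

    hip_x = _hip_x_factory(params)
    mass = config.mass_kg
    bw_n = mass * G_M_S2

    stances: dict[str, list[_Stance]] = {"paretic": [], "nonparetic": []}
    anchors: dict[str, list[tuple[float, float]]] = {"paretic": [], "nonparetic": []}
    events_rows = []
    schedule_rows = []
    t_cursor = params.lead_in_s
    t_hp_col = np.full(len(table), np.nan)
    t_hnp_col = np.full(len(table), np.nan)
    t_end_col = np.full(len(table), np.nan)

    for spec in config.epoch_plan:
        rows = table.index[table["epoch"] == spec.name]
        if len(rows) == 0:
            continue
        n = len(rows)
        v_p = config.belt_speed(spec, "paretic") * 1000.0     # mm/s
        v_np = config.belt_speed(spec, "nonparetic") * 1000.0
        alpha_p = table.loc[rows, "alpha_paretic"].to_numpy()
        alpha_np = table.loc[rows, "alpha_nonparetic"].to_numpy()
        x_p = table.loc[rows, "x_paretic"].to_numpy()
        x_np = table.loc[rows, "x_nonparetic"].to_numpy()
        prop_p = np.maximum(table.loc[rows, "prop_paretic"].to_numpy(), 0.05)
        prop_np = np.maximum(table.loc[rows, "prop_nonparetic"].to_numpy(), 0.05)

        hp = np.empty(n + 1)
        hnp = np.empty(n)
        hp[0] = _snap(t_cursor)
        for k in range(n):
            a_land = alpha_p[k - 1] if k > 0 else alpha_p[0]
            dt1 = (a_land - x_p[k]) / v_p
            hnp[k] = _snap(hp[k] + dt1, after=hp[k])
            dt2 = (alpha_np[k] - x_np[k]) / v_np
            hp[k + 1] = _snap(hnp[k] + dt2, after=hnp[k])
        t_hp_col[rows] = hp[1:]       # paretic step of stride k measured at hp[k+1]
        t_hnp_col[rows] = hnp
        t_end_col[rows] = hp[1:]

        # paretic stances (n + 1: one per heel strike, incl. the epoch-final one)
        strides_T = np.diff(hp)
        for k in range(n + 1):
            a_land = alpha_p[k - 1] if k > 0 else alpha_p[0]
            pos_hs = hip_x(hp[k]) + a_land
            if k < n:
                T = strides_T[k]
                line_slope = (hip_x(hnp[k]) + x_p[k] - pos_hs) / (hnp[k] - hp[k])
                dur = _stance_duration(T, hnp[k] - hp[k], params.stance_fraction, hp[k])
                nxt = hp[k + 1]
            else:
                T = strides_T[-1]
                line_slope = -v_p
                dur = params.stance_fraction * T
                nxt = None
            stances["paretic"].append(_Stance(hp[k], dur, pos_hs, line_slope,
                                              prop_p[min(k, n - 1)], nxt))
            anchors["paretic"].append((hp[k], pos_hs))
            events_rows.append((hp[k], "paretic", "heel_strike"))
        # non-paretic stances (n)
        for k in range(n):
            pos_hs = hip_x(hnp[k]) + alpha_np[k]
            T = (hnp[k + 1] - hnp[k]) if k < n - 1 else strides_T[-1]
            line_slope = (hip_x(hp[k + 1]) + x_np[k] - pos_hs) / (hp[k + 1] - hnp[k])
            dur = _stance_duration(T, hp[k + 1] - hnp[k], params.stance_fraction, hnp[k])
            nxt = hnp[k + 1] if k < n - 1 else None
            stances["nonparetic"].append(_Stance(hnp[k], dur, pos_hs, line_slope,
                                                 prop_np[k], nxt))
            anchors["nonparetic"].append((hnp[k], pos_hs))
            events_rows.append((hnp[k], "nonparetic", "heel_strike"))

        epoch_end = hp[n] + stances["paretic"][-1].dur
        schedule_rows.append((spec.name, hp[0] - 0.5 * _GRID, epoch_end + 0.5 * _GRID,
                              spec.left_belt_speed, spec.right_belt_speed))
        t_cursor = epoch_end + params.break_s

    # link the epoch-final paretic stance's swing to the next epoch's landing
    for leg in LEGS:
        seq = stances[leg]
        for i in range(len(seq) - 1):
            if seq[i].t_next_hs is None:
                seq[i].t_next_hs = seq[i + 1].t_hs

    t_total = t_cursor - params.break_s + params.lead_in_s
    n_force = int(round(t_total * FORCE_RATE_HZ)) + 1
    t_force = np.arange(n_force) / FORCE_RATE_HZ
    n_marker = int(round(t_total * MARKER_RATE_HZ)) + 1
    t_marker = np.arange(n_marker) / MARKER_RATE_HZ

    # realized step lengths / asymmetry (anchors encode the targets exactly)
    table["sl_paretic"] = table["alpha_paretic"] - table["x_nonparetic"]
    table["sl_nonparetic"] = table["alpha_nonparetic"] - table["x_paretic"]
    table["sla"] = (table["sl_nonparetic"] - table["sl_paretic"]) / (
        table["sl_nonparetic"] + table["sl_paretic"])
    table["t_paretic_hs"] = t_hp_col
    table["t_nonparetic_hs"] = t_hnp_col
    table["t_stride_end"] = t_end_col

    markers: dict[str, MarkerTimeSeries] = {}
    forces: dict[str, ForceSeries] = {}
    for leg in LEGS:
        side = config.paretic_side if leg == "paretic" else config.nonparetic_side
        f_n, f_ap = _render_forces(t_force, stances[leg], bw_n, mass, params)
        x = _render_ankle(t_marker, stances[leg], anchors[leg])
        z = _render_ankle_z(t_marker, stances[leg])
        y = np.full(n_marker, 120.0 if side == "left" else -120.0)
        markers[f"ankle_{side[0].upper()}"] = MarkerTimeSeries(
            f"ankle_{side[0].upper()}", t_marker,
            np.column_stack([x, y, z]), frame="surface")
        forces[side] = ForceSeries(side, t_force, f_ap,
                                   np.zeros(n_force), f_n, frame="surface")

    hip = hip_x(t_marker)
    for name, y_off, x_off in (("troch_L", 100.0, 6.0), ("troch_R", -100.0, -6.0)):
        markers[name] = MarkerTimeSeries(
            name, t_marker,
            np.column_stack([hip + x_off, np.full(n_marker, y_off),
                             np.full(n_marker, params.hip_height_mm)]),
            frame="surface")

    # surface -> lab rotation, then sensor noise in the lab frame
    for name, series in markers.items():
        x_lab, z_lab = surface_to_lab(series.positions[:, 0], series.positions[:, 2],
                                      config.slope_deg)
        positions = np.column_stack([x_lab, series.positions[:, 1], z_lab])
        if params.marker_noise_mm > 0:
            positions = positions + rng.normal(0.0, params.marker_noise_mm, positions.shape)
        markers[name] = replace(series, positions=positions, frame="lab")
    for side, series in forces.items():
        ap_lab, n_lab = surface_to_lab(series.f_ap, series.f_normal, config.slope_deg)
        ml = series.f_ml
        if params.force_noise_n > 0:
            ap_lab = ap_lab + rng.normal(0.0, params.force_noise_n, n_force)
            ml = ml + rng.normal(0.0, params.force_noise_n, n_force)
            n_lab = n_lab + rng.normal(0.0, params.force_noise_n, n_force)
        forces[side] = replace(series, f_ap=ap_lab, f_ml=ml, f_normal=n_lab, frame="lab")

    events = pd.DataFrame(sorted(events_rows), columns=["time_s", "leg", "kind"])
    schedule = pd.DataFrame(
        schedule_rows, columns=["epoch", "t_start", "t_end", "left_speed", "right_speed"])
    realized = SyntheticTruth(table=table, events=events, seed=truth.seed)
    recording = TrialRecording(markers=markers, forces=forces, schedule=schedule,
                               meta={"subject_id": config.subject_id,
                                     "slope_deg": config.slope_deg,
                                     "seed": seed})
    logger.info("synthesized trial %s: %.0f s, %d strides",
                config.subject_id, t_total, len(table))
    return recording, realized


def _stance_duration(T: float, dt_contra: float, stance_fraction: float,
                     t_hs: float) -> float:
    """Stance length covering the contralateral strike, leaving a real swing."""
    dur = max(stance_fraction * T, dt_contra + 0.08 * T)
    max_dur = T - 0.15
    if dur > max_dur:
        raise GenerationError(
            f"stride at t={t_hs:.2f}s too short ({T:.3f}s) for the stance template"
        )
    return dur


def _hip_x_factory(params: AdaptationParams):
    amp, period = params.hip_sway_mm, params.hip_sway_period_s

    def hip_x(t):
        return amp * np.sin(2.0 * np.pi * np.asarray(t) / period)

    return hip_x


def _render_forces(t: np.ndarray, stances: list[_Stance], bw_n: float,
                   mass: float, params: AdaptationParams):
    """Fill normal and AP force arrays from stance templates."""
    f_n = np.zeros(len(t))
    f_ap = np.zeros(len(t))
    for st in stances:
        i0 = int(round(st.t_hs * FORCE_RATE_HZ))
        i1 = min(int((st.t_hs + st.dur) * FORCE_RATE_HZ), len(t) - 1)
        if i1 <= i0:
            continue
        ts = t[i0:i1 + 1]
        u = (ts - st.t_hs) / st.dur
        template = bw_n * (0.95 * np.sin(np.pi * u) + 0.25 * np.sin(3.0 * np.pi * u))
        dt_hs = ts - st.t_hs
        loading = 0.2 * bw_n * (1.0 - np.exp(-dt_hs / 0.002)) * np.exp(-dt_hs / 0.05)
        f_n[i0:i1 + 1] = np.maximum(template, 0.0) + loading
        brake = np.where(u < 0.5, -params.braking_nkg * np.sin(2.0 * np.pi * u), 0.0)
        prop = np.where(u >= 0.5, -st.prop_nkg * np.sin(2.0 * np.pi * u), 0.0)
        transient = params.transient_nkg * np.exp(-0.5 * ((u - 0.025) / 0.012) ** 2)
        f_ap[i0:i1 + 1] = mass * (brake + prop + transient)
    return f_n, f_ap


def _render_ankle(t: np.ndarray, stances: list[_Stance],
                  anchors: list[tuple[float, float]]) -> np.ndarray:
    """Piecewise ankle x: anchored linear stance, cosine-blend swing."""
    x = np.empty(len(t))
    if not stances:
        return np.zeros(len(t))
    x[:] = stances[0].pos_hs
    for i, st in enumerate(stances):
        t_toe = st.t_hs + st.dur
        i0 = np.searchsorted(t, st.t_hs, side="left")
        i1 = np.searchsorted(t, t_toe, side="right")
        x[i0:i1] = st.pos_hs + st.slope_mm_s * (t[i0:i1] - st.t_hs)
        pos_toe = st.pos_hs + st.slope_mm_s * st.dur
        if st.t_next_hs is None:
            x[i1:] = pos_toe
            continue
        pos_next = anchors[i + 1][1]
        j1 = np.searchsorted(t, st.t_next_hs, side="left")
        tau = (t[i1:j1] - t_toe) / (st.t_next_hs - t_toe)
        x[i1:j1] = pos_toe + (pos_next - pos_toe) * 0.5 * (1.0 - np.cos(np.pi * tau))
    return x


def _render_ankle_z(t: np.ndarray, stances: list[_Stance],
                    z_ground: float = 80.0, lift: float = 60.0) -> np.ndarray:
    """Ankle height: flat in stance, a sine bump in swing."""
    z = np.full(len(t), z_ground)
    for st in stances:
        if st.t_next_hs is None:
            continue
        t_toe = st.t_hs + st.dur
        i1 = np.searchsorted(t, t_toe, side="right")
        j1 = np.searchsorted(t, st.t_next_hs, side="left")
        if j1 > i1:
            tau = (t[i1:j1] - t_toe) / (st.t_next_hs - t_toe)
            z[i1:j1] = z_ground + lift * np.sin(np.pi * tau)
    return z


def punch_gaps(series: MarkerTimeSeries, n_gaps: int, max_gap_frames: int,
               seed: int = 0) -> MarkerTimeSeries:
    """Mask random interior runs of frames (occlusion model for testing the
    gap filler)."""
    rng = np.random.default_rng(seed)
    valid = series.valid.copy()
    n = len(valid)
    for _ in range(n_gaps):
        length = int(rng.integers(1, max_gap_frames + 1))
        start = int(rng.integers(1, max(2, n - length - 1)))
        valid[start:start + length] = False
    positions = series.positions.copy()
    positions[~valid] = np.nan
    return replace(series, positions=positions, valid=valid)
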