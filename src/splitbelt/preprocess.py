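"""Signal conditioning: frame rotation, marker gap filling, force filtering.

Coordinate convention: +x anterior (uphill on an incline), +y mediolateral,
+z orthogonal to the treadmill surface; positions in mm, forces in N, time in
seconds, 0-based frame indices.  Raw recordings arrive in the lab frame; all
spatial and kinetic analysis happens in the surface frame, reached by rotating
about the mediolateral axis by the session slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.interpolate import InterpolatedUnivariateSpline
from scipy.ndimage import median_filter as _nd_median

logger = logging.getLogger(__name__)

MARKER_RATE_HZ = 100.0
FORCE_RATE_HZ = 1000.0


class PreprocessError(ValueError):
    """Invalid preprocessing parameters or inputs."""


@dataclass
class MarkerTimeSeries:
    """One marker's trajectory (nominally 100 Hz).

    ``positions`` is (n, 3) in mm; invalid (occluded) frames are flagged in
    ``valid`` and their positions are meaningless.  ``filled`` flags frames
    reconstructed by gap filling.
    """

    name: str
    times: np.ndarray            # (n,) seconds, strictly increasing
    positions: np.ndarray        # (n, 3) mm
    valid: np.ndarray | None = None
    frame: str = "lab"           # 'lab' | 'surface'
    filled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.times), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.filled is None:
            self.filled = np.zeros(len(self.times), dtype=bool)
        if self.positions.shape != (len(self.times), 3):
            raise PreprocessError(
                f"marker {self.name}: positions shape {self.positions.shape} "
                f"does not match {len(self.times)} frames"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise PreprocessError(f"marker {self.name}: times not strictly increasing")

    @property
    def rate_hz(self) -> float:
        if len(self.times) < 2:
            return MARKER_RATE_HZ
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclass
class ForceSeries:
    """One belt's force-plate signals (nominally 1000 Hz).

    Components: ``f_ap`` anterior-posterior, ``f_ml`` mediolateral,
    ``f_normal`` orthogonal to the surface (or vertical in the lab frame).
    """

    side: str                    # 'left' | 'right'
    times: np.ndarray            # (n,) seconds
    f_ap: np.ndarray             # (n,) N
    f_ml: np.ndarray             # (n,) N
    f_normal: np.ndarray         # (n,) N
    frame: str = "lab"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("f_ap", "f_ml", "f_normal"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != self.times.shape:
                raise PreprocessError(f"force {self.side}: {name} length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise PreprocessError(f"force {self.side}: times not strictly increasing")

    @property
    def rate_hz(self) -> float:
        if len(self.times) < 2:
            return FORCE_RATE_HZ
        return 1.0 / float(np.median(np.diff(self.times)))


# -- rotation ----------------------------------------------------------------

def _rotate_xz(x: np.ndarray, z: np.ndarray, slope_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotate (x, z) pairs about the mediolateral axis by -slope_deg."""
    theta = np.deg2rad(slope_deg)
    c, s = np.cos(theta), np.sin(theta)
    return x * c + z * s, -x * s + z * c


def surface_to_lab(x: np.ndarray, z: np.ndarray, slope_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`_rotate_xz`: express surface-frame vectors in the lab."""
    return _rotate_xz(x, z, -slope_deg)


def rotate_to_surface(series, slope_deg: float):
    """Rotate a marker or force series from the lab frame to the surface frame.

    The rotation is about +y by ``-slope_deg`` so that +x points uphill along
    the belt and +z is orthogonal to the surface.  Positions and force vectors
    transform identically.  A new series is returned; slope 0 is the identity.
    """
    if not abs(slope_deg) < 90:
        raise PreprocessError(f"|slope_deg| must be < 90, got {slope_deg}")
    if isinstance(series, MarkerTimeSeries):
        x, z = _rotate_xz(series.positions[:, 0], series.positions[:, 2], slope_deg)
        positions = np.column_stack([x, series.positions[:, 1], z])
        return replace(series, positions=positions, frame="surface",
                       valid=series.valid.copy(), filled=series.filled.copy())
    if isinstance(series, ForceSeries):
        f_ap, f_normal = _rotate_xz(series.f_ap, series.f_normal, slope_deg)
        return replace(series, f_ap=f_ap, f_ml=series.f_ml.copy(),
                       f_normal=f_normal, frame="surface")
    raise TypeError(f"cannot rotate {type(series).__name__}")


# -- marker gap filling ------------------------------------------------------

def _gap_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of invalid runs."""
    padded = np.concatenate([[True], valid, [True]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def fill_gaps(series: MarkerTimeSeries, max_gap_frames: int = 10,
              context_frames: int = 10) -> MarkerTimeSeries:
    """Fill interior marker gaps with an interpolating quintic spline.

    Each interior gap of at most ``max_gap_frames`` frames is reconstructed,
    per coordinate, from a quintic B-spline fit through up to
    ``context_frames`` valid frames on each side.  Longer gaps and
    leading/trailing gaps are left masked (reported via the log, not raised).
    Originally valid frames are never altered; filled frames are flagged in
    ``filled``.
    """
    valid = series.valid
    if valid.sum() < 6:
        raise PreprocessError(f"marker {series.name}: need >= 6 valid frames to fill gaps")
    if valid.all():
        return series
    positions = series.positions.copy()
    filled = series.filled.copy()
    new_valid = valid.copy()
    valid_idx = np.flatnonzero(valid)
    skipped = 0
    for start, stop in _gap_runs(valid):
        if start == 0 or stop == len(valid):   # leading/trailing gap
            skipped += 1
            continue
        if stop - start > max_gap_frames:
            skipped += 1
            continue
        left = valid_idx[valid_idx < start][-context_frames:]
        right = valid_idx[valid_idx >= stop][:context_frames]
        support = np.concatenate([left, right])
        if len(support) < 6:
            skipped += 1
            continue
        t_support = series.times[support]
        t_gap = series.times[start:stop]
        for axis in range(3):
            spline = InterpolatedUnivariateSpline(t_support, positions[support, axis], k=5)
            positions[start:stop, axis] = spline(t_gap)
        filled[start:stop] = True
        new_valid[start:stop] = True
    if skipped:
        logger.warning("marker %s: %d gap(s) left unfilled (edge or longer than %d frames)",
                       series.name, skipped, max_gap_frames)
    return replace(series, positions=positions, valid=new_valid, filled=filled)


# -- force filtering ---------------------------------------------------------

def lowpass_ap(series: ForceSeries, cutoff_hz: float = 20.0) -> ForceSeries:
    """Zero-phase 4th-order Butterworth low-pass on the AP component only."""
    fs = series.rate_hz
    if not cutoff_hz < fs / 2:
        raise PreprocessError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({fs / 2} Hz)")
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    f_ap = signal.sosfiltfilt(sos, series.f_ap)
    return replace(series, f_ap=f_ap, f_ml=series.f_ml.copy(), f_normal=series.f_normal.copy())


def median_filter_normal(series: ForceSeries, window_ms: float = 5.0) -> ForceSeries:
    """Centered running median on the normal-force channel.

    The window spans ``window_ms`` of samples (5 samples at 1000 Hz for the
    default 5 ms); at the edges it shrinks to the available samples.
    """
    window = max(1, int(round(window_ms * series.rate_hz / 1000.0)))
    f_normal = centered_median(series.f_normal, window)
    return replace(series, f_ap=series.f_ap.copy(), f_ml=series.f_ml.copy(), f_normal=f_normal)


def centered_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median whose window shrinks at the array edges."""
    if window <= 1 or len(x) == 0:
        return np.asarray(x, dtype=float).copy()
    half = (window - 1) // 2
    window = 2 * half + 1   # force odd, centered
    out = _nd_median(np.asarray(x, dtype=float), size=window, mode="nearest")
    for i in range(min(half, len(x))):            # shrink at edges
        out[i] = np.median(x[: i + half + 1])
        out[len(x) - 1 - i] = np.median(x[len(x) - 1 - i - half:])
    return out
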