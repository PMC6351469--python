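"""Gaze event detection and oculomotor feature extraction.

Events are detected with a velocity-threshold (I-VT) classifier: angular
speed is estimated by central differences over valid samples, runs above
the threshold become saccades and runs below become fixations. Short
fixations are discarded (the two flanking saccades, if any, are merged).
Invalid gaps longer than ``max_gap_ms`` split the recording into
independent segments, so a long fixation interrupted by a blink yields two
fixation events separated by the gap.

Event duration is the time span between the first and last sample of the
event (a single-sample event is assigned one sample period).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .types import (
    DegenerateGeometryError,
    FEATURE_NAMES,
    GazeEvent,
    GazeRecording,
    InvalidInputError,
)

DEFAULT_VELOCITY_THRESHOLD = 30.0  # deg/s
DEFAULT_MIN_FIXATION_MS = 60.0
DEFAULT_MAX_GAP_MS = 75.0
DEFAULT_WINDOW_LEN = 1.0  # s


@dataclass(frozen=True)
class GazeEventSequence:
    events: tuple[GazeEvent, ...]

    def durations_ms(self, kind: str) -> np.ndarray:
        return np.array([e.duration_ms for e in self.events if e.kind == kind])

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)


def _segment_bounds(valid_idx: np.ndarray, t: np.ndarray, max_gap_s: float) -> list[np.ndarray]:
    """Split valid-sample indices into segments at gaps longer than max_gap_s."""
    if len(valid_idx) == 0:
        return []
    gaps = np.diff(t[valid_idx])
    cut = np.flatnonzero(gaps > max_gap_s) + 1
    return np.split(valid_idx, cut)


def _merge_contiguous(events: list[GazeEvent]) -> list[GazeEvent]:
    """Merge temporally contiguous events of the same kind."""
    merged: list[GazeEvent] = []
    for ev in events:
        if merged and merged[-1].kind == ev.kind and np.isclose(merged[-1].end, ev.start):
            merged[-1] = GazeEvent(ev.kind, merged[-1].start, ev.end)
        else:
            merged.append(ev)
    return merged


def detect_events_ivt(
    gaze: GazeRecording,
    velocity_threshold: float = DEFAULT_VELOCITY_THRESHOLD,
    min_fixation_ms: float = DEFAULT_MIN_FIXATION_MS,
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
) -> GazeEventSequence:
    """Classify a gaze trace into alternating fixations and saccades."""
    if velocity_threshold <= 0:
        raise InvalidInputError("velocity_threshold must be positive")
    dt = 1.0 / gaze.rate
    t = gaze.t
    vi = np.flatnonzero(gaze.valid)
    if len(vi) < 3:
        warnings.warn("fewer than 3 valid samples; no events detected", stacklevel=2)
        return GazeEventSequence(events=())

    events: list[GazeEvent] = []
    for seg in _segment_bounds(vi, t, max_gap_ms / 1000.0):
        if len(seg) < 3:
            continue
        ts, xs, ys = t[seg], gaze.gx[seg], gaze.gy[seg]
        # central differences over neighbouring valid samples; endpoints copy
        speed = np.empty(len(seg))
        speed[1:-1] = np.hypot(xs[2:] - xs[:-2], ys[2:] - ys[:-2]) / (ts[2:] - ts[:-2])
        speed[0] = speed[1]
        speed[-1] = speed[-2]
        is_sac = speed > velocity_threshold
        # runs of equal label
        run_starts = np.flatnonzero(np.diff(is_sac.astype(int)) != 0) + 1
        bounds = np.concatenate(([0], run_starts, [len(seg)]))
        seg_events: list[GazeEvent] = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            kind = "saccade" if is_sac[a] else "fixation"
            start, end = ts[a], ts[b - 1]
            if end == start:  # single-sample run
                end = start + dt
            seg_events.append(GazeEvent(kind, float(start), float(end)))
        # discard too-short fixations, then merge saccades left adjacent
        kept = [
            e
            for e in seg_events
            if not (e.kind == "fixation" and e.duration_ms < min_fixation_ms)
        ]
        merged: list[GazeEvent] = []
        for ev in kept:
            if merged and merged[-1].kind == "saccade" and ev.kind == "saccade":
                merged[-1] = GazeEvent("saccade", merged[-1].start, ev.end)
            else:
                merged.append(ev)
        events.extend(_merge_contiguous(merged))
    return GazeEventSequence(events=tuple(events))


@dataclass(frozen=True)
class EllipseParams:
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # (horizontal-ish, vertical-ish) after rotation
    orientation: float  # rad
    area: float  # deg^2


def confidence_ellipse(points: np.ndarray, coverage: float = 0.95) -> EllipseParams:
    """Ellipse covering the stated fraction of a bivariate Gaussian cloud.

    Semi-axes are ``sqrt(q * eigenvalue)`` of the sample covariance with
    ``q`` the chi-square(2) quantile at ``coverage``. The first reported
    semi-axis is the one whose eigenvector is closest to the x direction.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2 or len(P) < 3:
        raise InvalidInputError("need >= 3 two-dimensional points")
    if not 0.0 < coverage < 1.0:
        raise InvalidInputError("coverage must lie in (0, 1)")
    mean = P.mean(axis=0)
    cov = np.cov(P.T)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[0] <= 1e-12 * max(eigval[1], 1.0):
        raise DegenerateGeometryError("points are collinear or coincident")
    q = sps.chi2.ppf(coverage, df=2)
    semi = np.sqrt(q * eigval)
    # order axes by closeness of the eigenvector to the horizontal direction
    horiz = int(np.argmax(np.abs(eigvec[0, :])))
    vert = 1 - horiz
    angle = float(np.arctan2(eigvec[1, horiz], eigvec[0, horiz]))
    return EllipseParams(
        center=(float(mean[0]), float(mean[1])),
        semi_axes=(float(semi[horiz]), float(semi[vert])),
        orientation=angle,
        area=float(np.pi * semi[0] * semi[1]),
    )


def points_in_ellipse(points: np.ndarray, ell: EllipseParams) -> np.ndarray:
    """Boolean mask of points inside the ellipse (used by coverage checks)."""
    P = np.asarray(points, dtype=float) - np.asarray(ell.center)
    c, s = np.cos(ell.orientation), np.sin(ell.orientation)
    u = P[:, 0] * c + P[:, 1] * s
    v = -P[:, 0] * s + P[:, 1] * c
    a, b = ell.semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _moment_stats(d: np.ndarray) -> tuple[float, float, float, float]:
    """mean, population SD, skewness, kurtosis (normal = 3); degenerate -> 0."""
    if len(d) == 0:
        return float("nan"), float("nan"), 0.0, 0.0
    mean = float(np.mean(d))
    sd = float(np.std(d))
    if len(d) < 2 or sd == 0.0:
        return mean, 0.0, 0.0, 0.0
    skew = float(sps.skew(d, bias=True))
    kurt = float(sps.kurtosis(d, fisher=False, bias=True))
    return mean, sd, skew, kurt


def extract_feature_vector(
    gaze: GazeRecording,
    events: GazeEventSequence,
    window_len: float = DEFAULT_WINDOW_LEN,
    coverage: float = 0.95,
) -> dict[str, float]:
    """Compute the 18 oculomotor biomarkers for one recording.

    Dynamic features are evaluated per consecutive non-overlapping
    ``window_len``-second window (trailing partial window dropped) and
    averaged; velocity features are global means of the instantaneous
    speeds; duration statistics cover the fixation and saccade duration
    distributions. Undefined ratios (no saccades, zero vertical range) are
    reported as NaN rather than infinity. Alongside the 18 features the
    mean ellipse axes and event counts are returned.
    """
    if not events.events:
        raise InvalidInputError("event sequence is empty")
    if gaze.duration < 10.0:
        raise InvalidInputError("recording must be at least 10 s long")
    w = int(round(window_len * gaze.rate))
    n_win = len(gaze.gx) // w
    ranges_x, ranges_y, sds_x, sds_y = [], [], [], []
    areas, axes_h, axes_v = [], [], []
    for k in range(n_win):
        sl = slice(k * w, (k + 1) * w)
        m = gaze.valid[sl]
        if m.sum() < 2:
            continue
        xs = gaze.gx[sl][m]
        ys = gaze.gy[sl][m]
        ranges_x.append(np.ptp(xs))
        ranges_y.append(np.ptp(ys))
        sds_x.append(np.std(xs))
        sds_y.append(np.std(ys))
        if m.sum() >= 3:
            try:
                ell = confidence_ellipse(np.column_stack([xs, ys]), coverage)
            except DegenerateGeometryError:
                continue
            areas.append(ell.area)
            axes_h.append(2.0 * ell.semi_axes[0])
            axes_v.append(2.0 * ell.semi_axes[1])

    range_x = float(np.mean(ranges_x)) if ranges_x else float("nan")
    range_y = float(np.mean(ranges_y)) if ranges_y else float("nan")

    # instantaneous velocities over consecutive valid samples
    vi = np.flatnonzero(gaze.valid)
    ts, xs, ys = gaze.t[vi], gaze.gx[vi], gaze.gy[vi]
    dts = np.diff(ts)
    keep = dts <= 2.5 / gaze.rate  # skip across blink gaps
    dx = np.diff(xs)[keep] / dts[keep]
    dy = np.diff(ys)[keep] / dts[keep]
    vel_x = float(np.mean(np.abs(dx))) if len(dx) else float("nan")
    vel_y = float(np.mean(np.abs(dy))) if len(dy) else float("nan")
    vel = float(np.mean(np.hypot(dx, dy))) if len(dx) else float("nan")

    fix_d = events.durations_ms("fixation")
    sac_d = events.durations_ms("saccade")
    mean_fix, sd_fix, skew_fix, kurt_fix = _moment_stats(fix_d)
    mean_sac, sd_sac, skew_sac, kurt_sac = _moment_stats(sac_d)

    n_fix, n_sac = len(fix_d), len(sac_d)
    feats = {
        "RangeX": range_x,
        "RangeY": range_y,
        "RatioRange": range_x / range_y if range_y > 0 else float("nan"),
        "VarianceX": float(np.mean(sds_x)) if sds_x else float("nan"),
        "VarianceY": float(np.mean(sds_y)) if sds_y else float("nan"),
        "VelocityX": vel_x,
        "VelocityY": vel_y,
        "Velocity": vel,
        "EllArea": float(np.mean(areas)) if areas else float("nan"),
        "MeanFix": mean_fix,
        "VarianceFix": sd_fix,
        "SkewFix": skew_fix,
        "KurtFix": kurt_fix,
        "MeanSac": mean_sac,
        "VarianceSac": sd_sac,
        "SkewSac": skew_sac,
        "KurtSac": kurt_sac,
        "Fix2SacNratio": n_fix / n_sac if n_sac > 0 else float("nan"),
    }
    assert tuple(feats) == FEATURE_NAMES
    feats["EllAxisH"] = float(np.mean(axes_h)) if axes_h else float("nan")
    feats["EllAxisV"] = float(np.mean(axes_v)) if axes_v else float("nan")
    feats["n_fixations"] = float(n_fix)
    feats["n_saccades"] = float(n_sac)
    return feats
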