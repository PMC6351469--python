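"""Seeded synthetic cohorts coupling gaze behaviour to postural sway.

A latent per-subject severity in [0, 1] drives, in opposite directions,
the statistics of an alternating fixation/saccade gaze process (shorter
fixations, wider scanning when impaired) and the fraction of time the
center of pressure spends in a high-variance "burst" regime. Group-level
calibration endpoints for the gaze process follow the published contrasts
between severely and mildly impaired patients (mean fixation duration
~316 ms -> ~153 ms, horizontal scan range widening ~2.4x). Everything is
deterministic given the seed, and the planted truth (severity, burst
fractions, event logs) is returned alongside the recordings so downstream
stages can be tested against it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    CONTROL,
    CohortConfig,
    GazeRecording,
    InvalidInputError,
    PATIENT,
    RawCoPRecording,
    SeverityProfile,
)

# ---------------------------------------------------------------------------
# gaze generation


@dataclass(frozen=True)
class GazeGenParams:
    """Calibration constants of the synthetic gaze process."""

    mean_fix_ms_intact: float = 316.0
    mean_fix_ms_impaired: float = 153.0
    fix_floor_ms: float = 40.0
    fix_log_sigma: float = 0.9
    # stationary SD of fixation targets (deg); widens with severity
    # (calibrated so the extracted per-second ranges land near the
    # published endpoints: RangeX ~6.0 -> ~14.6 deg/s)
    target_sd_x_intact: float = 3.3
    target_sd_x_impaired: float = 6.2
    target_sd_y_intact: float = 1.75
    target_sd_y_impaired: float = 3.9
    target_ar: float = 0.3  # AR(1) coefficient of successive targets
    # main-sequence rule: duration = slope * amplitude + intercept
    saccade_ms_per_deg: float = 2.2
    saccade_intercept_ms: float = 21.0
    jitter_sd_deg: float = 0.05
    blink_fraction: float = 0.05
    blink_min_ms: float = 100.0
    blink_max_ms: float = 300.0


def _lerp(a: float, b: float, u: float) -> float:
    return a + (b - a) * u


def _lognormal_with_mean(rng: np.random.Generator, mean: float, sigma: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size)
    mu = np.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size)


@dataclass(frozen=True)
class GazeTruth:
    """Planted event log for one synthetic gaze recording."""

    events: tuple[tuple[str, float, float], ...]  # (kind, start_s, end_s)
    mean_fix_ms: float
    target_sd_x: float
    target_sd_y: float


def generate_gaze_recording(
    profile: SeverityProfile,
    rate: float = 100.0,
    duration: float = 60.0,
    seed: int = 0,
    params: GazeGenParams = GazeGenParams(),
    effect_scale: float = 1.0,
) -> tuple[GazeRecording, GazeTruth]:
    """Synthesize one gaze trace as alternating fixations and saccades."""
    if duration < 10.0 or rate < 50.0:
        raise InvalidInputError("require duration >= 10 s and rate >= 50 Hz")
    rng = np.random.default_rng(seed)
    s = float(np.clip(effect_scale * profile.severity, 0.0, 1.0))
    mean_fix = _lerp(params.mean_fix_ms_intact, params.mean_fix_ms_impaired, s)
    sd_x = _lerp(params.target_sd_x_intact, params.target_sd_x_impaired, s)
    sd_y = _lerp(params.target_sd_y_intact, params.target_sd_y_impaired, s)

    # event timeline: fixation at target, saccade to the next target
    events: list[tuple[str, float, float]] = []
    seg_pos: list[tuple[float, float]] = []  # target at each fixation
    t = 0.0
    ar = params.target_ar
    cx = rng.normal(0.0, sd_x) if sd_x > 0 else 0.0
    cy = rng.normal(0.0, sd_y) if sd_y > 0 else 0.0
    while t < duration:
        d_fix = (
            params.fix_floor_ms
            + _lognormal_with_mean(rng, mean_fix - params.fix_floor_ms, params.fix_log_sigma, 1)[0]
        ) / 1000.0
        events.append(("fixation", t, min(t + d_fix, duration)))
        seg_pos.append((cx, cy))
        t += d_fix
        if t >= duration:
            break
        nx = ar * cx + (rng.normal(0.0, sd_x * np.sqrt(1 - ar**2)) if sd_x > 0 else 0.0)
        ny = ar * cy + (rng.normal(0.0, sd_y * np.sqrt(1 - ar**2)) if sd_y > 0 else 0.0)
        amp = float(np.hypot(nx - cx, ny - cy))
        d_sac = (params.saccade_intercept_ms + params.saccade_ms_per_deg * amp) / 1000.0
        events.append(("saccade", t, min(t + d_sac, duration)))
        t += d_sac
        cx, cy = nx, ny

    # rasterize
    n = int(round(duration * rate))
    ts = np.arange(n) / rate
    gx = np.empty(n)
    gy = np.empty(n)
    starts = np.array([e[1] for e in events])
    idx = np.clip(np.searchsorted(starts, ts, side="right") - 1, 0, len(events) - 1)
    fix_i = -1
    for k in range(n):
        kind, t0, t1 = events[idx[k]]
        if kind == "fixation":
            fix_i = idx[k] // 2
            gx[k], gy[k] = seg_pos[fix_i]
        else:
            a = seg_pos[idx[k] // 2]
            b = seg_pos[min(idx[k] // 2 + 1, len(seg_pos) - 1)]
            u = (ts[k] - t0) / max(t1 - t0, 1e-9)
            u = 3 * u**2 - 2 * u**3  # smoothstep velocity profile
            gx[k] = a[0] + (b[0] - a[0]) * u
            gy[k] = a[1] + (b[1] - a[1]) * u
    if params.jitter_sd_deg > 0:
        gx += rng.normal(0.0, params.jitter_sd_deg, n)
        gy += rng.normal(0.0, params.jitter_sd_deg, n)

    valid = np.ones(n, dtype=bool)
    if params.blink_fraction > 0:
        mean_gap_s = (params.blink_min_ms + params.blink_max_ms) / 2000.0
        n_blinks = rng.poisson(params.blink_fraction * duration / mean_gap_s)
        for _ in range(n_blinks):
            b0 = rng.uniform(0.0, duration)
            b1 = b0 + rng.uniform(params.blink_min_ms, params.blink_max_ms) / 1000.0
            valid[(ts >= b0) & (ts < b1)] = False

    rec = GazeRecording(subject_id=profile.subject_id, rate=rate, gx=gx, gy=gy, valid=valid)
    truth = GazeTruth(events=tuple(events), mean_fix_ms=mean_fix, target_sd_x=sd_x, target_sd_y=sd_y)
    return rec, truth


# ---------------------------------------------------------------------------
# center-of-pressure generation


@dataclass(frozen=True)
class CoPGenParams:
    """Two-regime mean-reverting sway surrogate."""

    rate: float = 50.0  # nominal Hz
    timestamp_jitter: float = 0.3  # fraction of the nominal period, uniform
    ou_tau: float = 0.5  # s, mean-reversion time constant
    quiet_sd_x: float = 0.30  # cm
    quiet_sd_y: float = 0.40  # cm
    burst_var_mult: float = 16.0  # variance inflation inside bursts
    burst_mean_s: float = 1.0
    slope_a: float = 0.6  # burst fraction = clip(a * severity + offset, 0, 1)
    offset_eo: float = 0.05
    offset_ec: float = 0.20


@dataclass(frozen=True)
class CoPTruth:
    f_planted: float
    burst_intervals: tuple[tuple[float, float], ...]


def planted_burst_fraction(severity: float, condition: str, params: CoPGenParams) -> float:
    offset = params.offset_ec if condition == "EC" else params.offset_eo
    return float(np.clip(params.slope_a * severity + offset, 0.0, 1.0))


def _burst_schedule(
    rng: np.random.Generator, duration: float, f: float, mean_burst: float
) -> list[tuple[float, float]]:
    """Alternating-renewal burst intervals with stationary occupancy f."""
    if f <= 0.0:
        return []
    if f >= 1.0:
        return [(0.0, duration)]
    mean_quiet = mean_burst * (1.0 - f) / f
    intervals: list[tuple[float, float]] = []
    t = 0.0
    in_burst = bool(rng.random() < f)
    # stationary start: residual of the current segment
    while t < duration:
        length = rng.exponential(mean_burst if in_burst else mean_quiet)
        if in_burst:
            intervals.append((t, min(t + length, duration)))
        t += length
        in_burst = not in_burst
    return intervals


def generate_cop_recording(
    profile: SeverityProfile,
    condition: str,
    duration: float = 30.0,
    seed: int = 0,
    params: CoPGenParams = CoPGenParams(),
) -> tuple[RawCoPRecording, CoPTruth]:
    """Mean-reverting sway with interleaved high-variance bursts.

    The burst-time fraction is ``clip(a * severity + b_condition, 0, 1)``
    with the eyes-closed offset above the eyes-open one. Timestamps are
    jittered uniformly around the nominal period.
    """
    if duration < 25.0:
        raise InvalidInputError("CoP recording must cover at least the 25 s scored epoch")
    rng = np.random.default_rng(seed)
    f = planted_burst_fraction(profile.severity, condition, params)
    intervals = _burst_schedule(rng, duration, f, params.burst_mean_s)

    n = int(round(duration * params.rate))
    j = params.timestamp_jitter
    if j > 0:
        t = (np.arange(n) + rng.uniform(-j, j, n)) / params.rate
        t.sort()  # jitter < 0.5 keeps order in practice; sort guarantees it
        t -= t[0]
    else:
        t = np.arange(n) / params.rate

    mult = np.ones(n)
    for a, b in intervals:
        mult[(t >= a) & (t < b)] = np.sqrt(params.burst_var_mult)
    x = np.empty(n)
    y = np.empty(n)
    x[0] = rng.normal(0.0, params.quiet_sd_x * mult[0])
    y[0] = rng.normal(0.0, params.quiet_sd_y * mult[0])
    dts = np.diff(t)
    phi = np.exp(-dts / params.ou_tau)
    innov = np.sqrt(1.0 - phi**2)
    ex = rng.standard_normal(n - 1)
    ey = rng.standard_normal(n - 1)
    for k in range(n - 1):
        sx = params.quiet_sd_x * mult[k + 1]
        sy = params.quiet_sd_y * mult[k + 1]
        x[k + 1] = phi[k] * x[k] + sx * innov[k] * ex[k]
        y[k + 1] = phi[k] * y[k] + sy * innov[k] * ey[k]

    rec = RawCoPRecording(subject_id=profile.subject_id, condition=condition, t=t, x=x, y=y)
    return rec, CoPTruth(f_planted=f, burst_intervals=tuple(intervals))


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SyntheticCohort:
    config: CohortConfig
    profiles: list[SeverityProfile]
    gaze: dict[str, GazeRecording]
    gaze_truth: dict[str, GazeTruth]
    cop: dict[tuple[str, str], RawCoPRecording]  # (subject_id, condition)
    cop_truth: dict[tuple[str, str], CoPTruth]
    truth: pd.DataFrame = field(repr=False, default=None)


def _attention_subscore(rng: np.random.Generator, severity: float) -> int:
    base = round(37.0 - 14.0 * severity) + int(rng.integers(-2, 3))
    return int(np.clip(base, 0, 37))


def draw_profiles(config: CohortConfig, rng: np.random.Generator) -> list[SeverityProfile]:
    """Controls get low severities, patients span the full impaired range."""
    profiles = []
    for i in range(config.n_patients):
        sev = float(rng.uniform(0.15, 1.0))
        profiles.append(
            SeverityProfile(f"P{i + 1:02d}", PATIENT, sev, _attention_subscore(rng, sev))
        )
    for i in range(config.n_controls):
        sev = float(rng.uniform(0.0, 0.25))
        profiles.append(
            SeverityProfile(f"C{i + 1:02d}", CONTROL, sev, _attention_subscore(rng, sev))
        )
    return profiles


def generate_cohort(
    config: CohortConfig,
    gaze_params: GazeGenParams = GazeGenParams(),
    cop_params: CoPGenParams = CoPGenParams(),
) -> SyntheticCohort:
    """Deterministically generate a full cohort plus its planted truth table."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    profile_rng = np.random.default_rng(root.spawn(1)[0])
    profiles = draw_profiles(config, profile_rng)
    subject_seeds = root.spawn(len(profiles))

    gaze, gaze_truth, cop, cop_truth = {}, {}, {}, {}
    rows = []
    for profile, ss in zip(profiles, subject_seeds):
        g_seed, eo_seed, ec_seed = [int(s.generate_state(1)[0]) for s in ss.spawn(3)]
        rec, gt = generate_gaze_recording(
            profile,
            rate=config.gaze_rate,
            duration=config.gaze_duration,
            seed=g_seed,
            params=gaze_params,
            effect_scale=config.effect_scale,
        )
        gaze[profile.subject_id] = rec
        gaze_truth[profile.subject_id] = gt
        fs = {}
        for cond, cseed in (("EO", eo_seed), ("EC", ec_seed)):
            crec, ct = generate_cop_recording(
                profile, cond, config.cop_duration_per_condition, cseed, cop_params
            )
            cop[(profile.subject_id, cond)] = crec
            cop_truth[(profile.subject_id, cond)] = ct
            fs[cond] = ct.f_planted
        rows.append(
            {
                "subject_id": profile.subject_id,
                "group": profile.group,
                "severity": profile.severity,
                "f_EO": fs["EO"],
                "f_EC": fs["EC"],
                "attention_subscore": profile.attention_subscore,
            }
        )
    truth = pd.DataFrame(rows)
    return SyntheticCohort(
        config=config,
        profiles=profiles,
        gaze=gaze,
        gaze_truth=gaze_truth,
        cop=cop,
        cop_truth=cop_truth,
        truth=truth,
    )


def cohort_frames(cohort: SyntheticCohort) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Long-format gaze, CoP and truth tables matching the on-disk CSV schema."""
    gaze_parts = []
    for sid, rec in cohort.gaze.items():
        gaze_parts.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "t_s": rec.t,
                    "gaze_x_deg": rec.gx,
                    "gaze_y_deg": rec.gy,
                    "valid": rec.valid.astype(int),
                }
            )
        )
    cop_parts = []
    for (sid, cond), rec in cohort.cop.items():
        cop_parts.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "condition": cond,
                    "t_s": rec.t,
                    "cop_x_cm": rec.x,
                    "cop_y_cm": rec.y,
                }
            )
        )
    return pd.concat(gaze_parts, ignore_index=True), pd.concat(cop_parts, ignore_index=True), cohort.truth
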