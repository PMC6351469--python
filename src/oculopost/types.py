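"""Shared dataclasses for recordings, scores and model outputs."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EO = "EO"
EC = "EC"
CONDITIONS = (EO, EC)

PATIENT = "patient"
CONTROL = "control"

#: Canonical order of the 18 oculomotor biomarkers.
FEATURE_NAMES = (
    "RangeX",
    "RangeY",
    "RatioRange",
    "VarianceX",
    "VarianceY",
    "VelocityX",
    "VelocityY",
    "Velocity",
    "EllArea",
    "MeanFix",
    "VarianceFix",
    "SkewFix",
    "KurtFix",
    "MeanSac",
    "VarianceSac",
    "SkewSac",
    "KurtSac",
    "Fix2SacNratio",
)


class InvalidInputError(ValueError):
    """Raised when an input violates a precondition."""


class DegenerateGeometryError(ValueError):
    """Raised when a geometric construction is undefined (e.g. collinear points)."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge; carries diagnostics."""


@dataclass(frozen=True)
class RawCoPRecording:
    """Irregularly timestamped 2-D center-of-pressure trajectory."""

    subject_id: str
    condition: str
    t: np.ndarray  # seconds, strictly increasing
    x: np.ndarray  # cm
    y: np.ndarray  # cm

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(t) == len(x) == len(y)):
            raise InvalidInputError("t, x, y must have equal length")
        if len(t) < 2:
            raise InvalidInputError("CoP recording needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError(
                f"timestamps not strictly increasing for subject {self.subject_id}"
            )
        if self.condition not in CONDITIONS:
            raise InvalidInputError(f"condition must be one of {CONDITIONS}")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class UniformCoPSignal:
    """Uniformly resampled CoP trajectory (constant period ``1/rate``)."""

    rate: float
    x: np.ndarray
    y: np.ndarray
    t0: float = 0.0

    @property
    def duration(self) -> float:
        return len(self.x) / self.rate

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.x)) / self.rate


@dataclass(frozen=True)
class GazeRecording:
    """Uniformly sampled gaze-angle trajectory with per-sample validity."""

    subject_id: str
    rate: float
    gx: np.ndarray  # degrees
    gy: np.ndarray  # degrees
    valid: np.ndarray  # bool

    def __post_init__(self) -> None:
        gx = np.asarray(self.gx, dtype=float)
        gy = np.asarray(self.gy, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        if not (len(gx) == len(gy) == len(valid)):
            raise InvalidInputError("gx, gy, valid must have equal length")
        object.__setattr__(self, "gx", gx)
        object.__setattr__(self, "gy", gy)
        object.__setattr__(self, "valid", valid)

    @property
    def duration(self) -> float:
        return len(self.gx) / self.rate

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.gx)) / self.rate


@dataclass(frozen=True)
class GazeEvent:
    kind: str  # "fixation" | "saccade"
    start: float  # s
    end: float  # s

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1000.0


@dataclass(frozen=True)
class PosturalScore:
    subject_id: str
    score: float  # 0 (worst) .. 100 (best)
    f_eo: float
    f_ec: float


@dataclass
class SeverityProfile:
    """Latent per-subject clinical state driving both gaze and sway statistics."""

    subject_id: str
    group: str  # "patient" | "control"
    severity: float  # 0 = intact, 1 = maximally impaired
    attention_subscore: int  # 0..37

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise InvalidInputError("severity must lie in [0, 1]")
        if not 0 <= self.attention_subscore <= 37:
            raise InvalidInputError("attention_subscore must lie in [0, 37]")
        if self.group not in (PATIENT, CONTROL):
            raise InvalidInputError("group must be 'patient' or 'control'")


@dataclass
class CohortConfig:
    n_patients: int = 10
    n_controls: int = 9
    gaze_rate: float = 100.0  # Hz
    gaze_duration: float = 60.0  # s
    cop_duration_per_condition: float = 30.0  # s
    seed: int = 0
    effect_scale: float = 1.0  # 0 decouples gaze statistics from severity

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise InvalidInputError("cohort counts must be >= 1")
        if self.gaze_rate <= 0 or self.gaze_duration <= 0:
            raise InvalidInputError("gaze rate and duration must be positive")
        if self.cop_duration_per_condition <= 0:
            raise InvalidInputError("cop duration must be positive")
        if self.effect_scale < 0:
            raise InvalidInputError("effect_scale must be >= 0")
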