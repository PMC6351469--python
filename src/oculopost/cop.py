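"""Center-of-pressure processing.

Resamples irregular statokinesigrams to a uniform grid (sliding-window
average with interpolation fallback), summarizes the trajectory in short
non-overlapping windows, classifies windows as quiet/unquiet with a
two-component Gaussian mixture fitted on the pooled cohort, and turns the
unquiet fractions of the eyes-open and eyes-closed conditions into a 0-100
postural score (100 = fully quiet).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .types import (
    ConvergenceError,
    InvalidInputError,
    PosturalScore,
    RawCoPRecording,
    UniformCoPSignal,
)

DEFAULT_RATE = 25.0  # Hz
DEFAULT_WINDOW_LEN = 1.0  # s
DEFAULT_KEEP_LAST = 25.0  # s, the scored epoch per condition

DESCRIPTOR_NAMES = ("path_length_cm", "positional_sd_cm", "mean_speed_cm_s")


def _swarii_1d(t: np.ndarray, v: np.ndarray, grid: np.ndarray, window: float) -> np.ndarray:
    lo = np.searchsorted(t, grid - window / 2.0, side="left")
    hi = np.searchsorted(t, grid + window / 2.0, side="right")
    csum = np.concatenate(([0.0], np.cumsum(v)))
    count = hi - lo
    out = np.empty_like(grid)
    nonempty = count > 0
    out[nonempty] = (csum[hi[nonempty]] - csum[lo[nonempty]]) / count[nonempty]
    if np.any(~nonempty):
        out[~nonempty] = np.interp(grid[~nonempty], t, v)
    return out


def swarii_resample(
    raw: RawCoPRecording,
    rate: float = DEFAULT_RATE,
    window: float | None = None,
) -> UniformCoPSignal:
    """Resample an irregular recording to a uniform grid.

    Each grid value is the mean of raw samples within a centered window of
    width ``window`` (default one grid period); empty windows fall back to
    linear interpolation between the nearest raw samples. The grid spans
    ``[t_min, t_max]`` of the raw record.
    """
    if rate <= 0:
        raise InvalidInputError("rate must be positive")
    if window is None:
        window = 1.0 / rate
    if window <= 0:
        raise InvalidInputError("window must be positive")
    t = raw.t
    n_grid = int(np.floor((t[-1] - t[0]) * rate + 1e-9)) + 1
    grid = t[0] + np.arange(n_grid) / rate
    x = _swarii_1d(t, raw.x, grid, window)
    y = _swarii_1d(t, raw.y, grid, window)
    return UniformCoPSignal(rate=rate, x=x, y=y, t0=float(t[0]))


@dataclass(frozen=True)
class WindowDescriptorSet:
    """Per-window sway descriptors over the scored tail of one condition."""

    window_len: float
    descriptors: np.ndarray  # (n_windows, 3): path length, positional SD, mean speed
    window_starts: np.ndarray  # s, start time of each window

    def __len__(self) -> int:
        return len(self.descriptors)


def window_descriptors(
    signal: UniformCoPSignal,
    window_len: float = DEFAULT_WINDOW_LEN,
    keep_last: float = DEFAULT_KEEP_LAST,
) -> WindowDescriptorSet:
    """Describe the final ``keep_last`` seconds in non-overlapping windows.

    Only the tail is scored: everything before it is treated as
    acclimatization. Descriptors per window: path length (cm), positional
    standard deviation (cm), mean speed (cm/s).
    """
    if window_len <= 0 or keep_last < window_len:
        raise InvalidInputError("require keep_last >= window_len > 0")
    if signal.duration + 1e-9 < keep_last:
        raise InvalidInputError(
            f"signal duration {signal.duration:.2f}s shorter than keep_last {keep_last}s"
        )
    n_keep = int(round(keep_last * signal.rate))
    x = signal.x[-n_keep:]
    y = signal.y[-n_keep:]
    t_tail = signal.t0 + (len(signal.x) - n_keep) / signal.rate
    w = int(round(window_len * signal.rate))
    n_win = n_keep // w
    desc = np.empty((n_win, 3))
    starts = np.empty(n_win)
    dt = 1.0 / signal.rate
    for k in range(n_win):
        xs = x[k * w : (k + 1) * w]
        ys = y[k * w : (k + 1) * w]
        steps = np.hypot(np.diff(xs), np.diff(ys))
        path = float(np.sum(steps))
        sd = float(np.sqrt(np.mean((xs - xs.mean()) ** 2 + (ys - ys.mean()) ** 2)))
        desc[k] = (path, sd, path / (w * dt))
        starts[k] = t_tail + k * w * dt
    return WindowDescriptorSet(window_len=window_len, descriptors=desc, window_starts=starts)


@dataclass(frozen=True)
class QuietUnquietModel:
    """Two-component Gaussian mixture over window descriptors.

    ``unquiet_component`` is the component whose mean has the larger
    Euclidean norm. A degenerate fit (zero-variance descriptor cloud) is
    flagged and labels every window quiet.
    """

    means: np.ndarray  # (2, 3)
    covariances: np.ndarray  # (2, 3, 3)
    weights: np.ndarray  # (2,)
    unquiet_component: int
    degenerate: bool = False

    def _mixture(self) -> GaussianMixture:
        gm = GaussianMixture(n_components=2, covariance_type="full")
        gm.means_ = self.means
        gm.covariances_ = self.covariances
        gm.weights_ = self.weights
        gm.precisions_cholesky_ = np.array(
            [np.linalg.cholesky(np.linalg.inv(c)).T for c in self.covariances]
        )
        return gm

    def label_unquiet(self, descriptors: np.ndarray) -> np.ndarray:
        """Boolean mask of windows assigned to the unquiet component."""
        if self.degenerate:
            return np.zeros(len(descriptors), dtype=bool)
        labels = self._mixture().predict(np.asarray(descriptors, dtype=float))
        return labels == self.unquiet_component


def fit_quiet_unquiet_model(
    descriptors: np.ndarray | WindowDescriptorSet,
    seed: int = 0,
    max_iter: int = 500,
) -> QuietUnquietModel:
    """Fit the quiet/unquiet mixture by EM with k-means initialization.

    ``descriptors`` should pool windows across the whole cohort (both
    groups and both conditions) so the quiet/unquiet labels share one
    cohort-level meaning.
    """
    if isinstance(descriptors, WindowDescriptorSet):
        descriptors = descriptors.descriptors
    X = np.asarray(descriptors, dtype=float)
    if X.ndim != 2 or len(X) < 20:
        raise InvalidInputError("need at least 20 pooled windows to fit the mixture")
    if np.allclose(X.std(axis=0), 0.0):
        mean = X.mean(axis=0)
        cov = np.eye(X.shape[1]) * 1e-6
        return QuietUnquietModel(
            means=np.stack([mean, mean]),
            covariances=np.stack([cov, cov]),
            weights=np.array([1.0, 0.0]),
            unquiet_component=1,
            degenerate=True,
        )
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        init_params="kmeans",
        n_init=1,
        max_iter=max_iter,
        reg_covar=1e-9,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            gm.fit(X)
        except ConvergenceWarning as exc:  # pragma: no cover - rare
            raise ConvergenceError(
                f"EM did not converge after {max_iter} iterations "
                f"(n_windows={len(X)}, lower_bound={gm.lower_bound_:.4g})"
            ) from exc
    unquiet = int(np.argmax(np.linalg.norm(gm.means_, axis=1)))
    return QuietUnquietModel(
        means=gm.means_,
        covariances=gm.covariances_,
        weights=gm.weights_,
        unquiet_component=unquiet,
    )


def postural_score_from_fractions(f_eo: float, f_ec: float) -> float:
    """0-100 score: mean of the two conditions' quiet fractions, rescaled."""
    if not (0.0 <= f_eo <= 1.0 and 0.0 <= f_ec <= 1.0):
        raise InvalidInputError("unquiet fractions must lie in [0, 1]")
    return 100.0 * ((1.0 - f_eo) + (1.0 - f_ec)) / 2.0


def compute_postural_score(
    model: QuietUnquietModel,
    eo: WindowDescriptorSet,
    ec: WindowDescriptorSet,
    subject_id: str = "",
) -> PosturalScore:
    """Score one subject from both conditions' window descriptors."""
    if eo is None or ec is None:
        raise InvalidInputError("both EO and EC conditions are required")
    f_eo = float(np.mean(model.label_unquiet(eo.descriptors)))
    f_ec = float(np.mean(model.label_unquiet(ec.descriptors)))
    return PosturalScore(
        subject_id=subject_id,
        score=postural_score_from_fractions(f_eo, f_ec),
        f_eo=f_eo,
        f_ec=f_ec,
    )
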