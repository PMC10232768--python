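"""Temporal cleanup of BOLD runs: motion nuisance regression and bandpass.

Two operations are applied, in this order, to every functional run before
any analysis: (1) ordinary least-squares removal of six head-motion time
courses (x/y/z translations and pitch/yaw/roll rotations) plus an intercept,
and (2) a zero-phase Butterworth bandpass filter, by default [0.01, 0.1] Hz.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import butter, filtfilt
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import BoldRun

__all__ = ["regress_nuisance", "bandpass", "preprocess_run",
           "NuisanceRegressor", "TemporalBandpass"]

log = logging.getLogger(__name__)


def regress_nuisance(run: BoldRun, nuisance: np.ndarray | None = None) -> BoldRun:
    """Replace every voxel time course by its OLS residual on [1 | motion].

    ``nuisance`` is a (T, 6) matrix of motion courses; if None, the run's own
    recorded courses are used. Residuals are orthogonal to the regressors.
    """
    if nuisance is None:
        nuisance = run.nuisance
    if nuisance is None:
        raise ValueError("no nuisance courses supplied and none recorded on the run")
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim != 2 or nuisance.shape[0] != run.n_volumes:
        raise ValueError(
            f"nuisance length {nuisance.shape} does not match run "
            f"t-dimension {run.n_volumes}")
    if not np.all(np.isfinite(nuisance)):
        raise ValueError("nuisance courses must be finite")
    n_t = run.n_volumes
    design = np.column_stack([np.ones(n_t), nuisance])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        log.warning("rank-deficient nuisance design; using pseudoinverse")
    pinv = np.linalg.pinv(design)
    flat = run.data.reshape(-1, n_t).T.astype(float)  # (T, V)
    beta = pinv @ flat
    resid = flat - design @ beta
    out = resid.T.reshape(run.data.shape).astype(run.data.dtype, copy=False)
    return run.with_data(out)


def _design_matrix_settling(b: np.ndarray, a: np.ndarray) -> int:
    # filtfilt's default edge padding: 3 * max(len(a), len(b))
    return 3 * max(len(a), len(b))


def bandpass(run: BoldRun, low_hz: float = 0.01, high_hz: float = 0.1,
             order: int = 4) -> BoldRun:
    """Zero-phase (forward-backward) Butterworth bandpass along time."""
    fs = 1.0 / run.tr
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low_hz < high_hz, got [{low_hz}, {high_hz}]")
    if high_hz >= nyq:
        raise ValueError(
            f"high edge {high_hz} Hz is at or above the Nyquist frequency {nyq:.4g} Hz")
    b, a = butter(order, [low_hz / nyq, high_hz / nyq], btype="bandpass")
    settle = _design_matrix_settling(b, a)
    if run.n_volumes < 3 * settle:
        raise ValueError(
            f"run has {run.n_volumes} volumes; bandpass requires at least "
            f"{3 * settle} (3x the filter settling length of {settle} samples)")
    flat = run.data.reshape(-1, run.n_volumes).astype(float)
    filtered = filtfilt(b, a, flat, axis=1)
    out = filtered.reshape(run.data.shape).astype(run.data.dtype, copy=False)
    return run.with_data(out)


def preprocess_run(run: BoldRun, nuisance: np.ndarray | None = None,
                   low_hz: float = 0.01, high_hz: float = 0.1) -> BoldRun:
    """Nuisance regression followed by bandpass filtering."""
    return bandpass(regress_nuisance(run, nuisance), low_hz, high_hz)


class NuisanceRegressor(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping :func:`regress_nuisance`."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return [regress_nuisance(run) for run in X]


class TemporalBandpass(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping :func:`bandpass`."""

    def __init__(self, low_hz: float = 0.01, high_hz: float = 0.1, order: int = 4):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.order = order

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return [bandpass(run, self.low_hz, self.high_hz, self.order) for run in X]
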