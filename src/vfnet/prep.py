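"""ROI-level denoising: outlier frames, confound regression, band-pass filtering.

Mirrors the connectivity-toolbox convention: nuisance regression first
(motion, outlier-frame spikes, task effect, white-matter/CSF channels),
then a zero-phase band-pass keeping 0.009-0.10 Hz.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .design import TaskDesign, task_regressor
from .timeseries import ConfoundTable, RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "detect_outlier_frames",
    "build_confound_table",
    "regress_confounds",
    "bandpass",
    "prep_subject",
]

# Conventional outlier thresholds (intermediate ART-style settings); the
# source analysis names the detection tool but not its thresholds.
DEFAULT_Z_THRESH = 5.0
DEFAULT_MOTION_THRESH_MM = 0.9

DEFAULT_LOW_HZ = 0.009
DEFAULT_HIGH_HZ = 0.10


def detect_outlier_frames(
    series: RoiTimeSeries,
    motion: pd.DataFrame | np.ndarray,
    z_thresh: float = DEFAULT_Z_THRESH,
    motion_thresh_mm: float = DEFAULT_MOTION_THRESH_MM,
) -> np.ndarray:
    """Flag frames with extreme global signal or large framewise motion.

    A frame is flagged when the global-signal z-score exceeds ``z_thresh``
    or the framewise motion differential (max absolute first difference
    over the six parameters, rotations treated on the mm scale) exceeds
    ``motion_thresh_mm``; the two criteria are OR-combined.
    """
    if z_thresh <= 0 or motion_thresh_mm <= 0:
        raise ValueError("thresholds must be positive")
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != series.n_timepoints:
        raise ValueError(
            f"motion has {motion.shape[0]} frames, series has {series.n_timepoints}"
        )
    gs = series.data.mean(axis=0)
    sd = gs.std(ddof=1)
    z = np.zeros_like(gs) if sd == 0 else (gs - gs.mean()) / sd
    fd = np.zeros(series.n_timepoints)
    fd[1:] = np.abs(np.diff(motion, axis=0)).max(axis=1)
    return (np.abs(z) > z_thresh) | (fd > motion_thresh_mm)


def build_confound_table(
    motion: pd.DataFrame,
    outlier_frames: np.ndarray,
    design: TaskDesign | None = None,
    nuisance: pd.DataFrame | None = None,
) -> ConfoundTable:
    """Assemble the full nuisance design: motion, spikes, task effect, nuisance signals.

    Outlier frames become one-hot spike columns (regression rather than
    deletion, preserving timepoint alignment for the filter). The task
    effect is the HRF-convolved boxcar plus its temporal derivative.
    """
    parts = [motion.reset_index(drop=True)]
    n_t = len(motion)
    outlier_frames = np.asarray(outlier_frames, dtype=bool)
    if outlier_frames.shape[0] != n_t:
        raise ValueError("outlier flag length mismatch")
    for frame in np.flatnonzero(outlier_frames):
        col = np.zeros(n_t)
        col[frame] = 1.0
        parts.append(pd.DataFrame({f"outlier_{frame:04d}": col}))
    if design is not None:
        reg = task_regressor(design, derivative=True)
        parts.append(pd.DataFrame(reg, columns=["task_hrf", "task_hrf_dt"]))
    if nuisance is not None:
        parts.append(nuisance.reset_index(drop=True))
    return ConfoundTable(pd.concat(parts, axis=1))


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Greedily drop columns that add no rank (constant duplicates, collinear)."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            logger.warning("dropping collinear confound column %r", names[j])
    return X[:, keep], [names[k] for k in keep]


def regress_confounds(series: RoiTimeSeries, confounds: ConfoundTable) -> RoiTimeSeries:
    """OLS residual of every region's signal on [intercept | confounds].

    Residuals are orthogonal to every confound column (and demeaned, since
    the intercept is always included).
    """
    if confounds.n_timepoints != series.n_timepoints:
        raise ValueError("confound table length does not match series")
    X = confounds.matrix
    names = list(confounds.frame.columns)
    X = np.column_stack([np.ones(series.n_timepoints), X])
    names = ["intercept"] + names
    X, _ = _drop_collinear(X, names)
    Y = series.data.T  # timepoints x regions
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return series.copy_with(resid.T)


def bandpass(
    series: RoiTimeSeries,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass (order 2, applied forward-backward)."""
    nyq = 1.0 / (2.0 * series.tr_s)
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyq:
        raise ValueError(f"high_hz {high_hz} exceeds the Nyquist frequency {nyq} Hz")
    b, a = butter(2, [low_hz / nyq, high_hz / nyq], btype="bandpass")
    filtered = filtfilt(b, a, series.data, axis=1)
    return series.copy_with(filtered)


def prep_subject(
    series: RoiTimeSeries,
    motion: pd.DataFrame,
    design: TaskDesign | None = None,
    nuisance: pd.DataFrame | None = None,
    z_thresh: float = DEFAULT_Z_THRESH,
    motion_thresh_mm: float = DEFAULT_MOTION_THRESH_MM,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> RoiTimeSeries:
    """Full denoising chain: detect outliers, regress confounds, band-pass."""
    flags = detect_outlier_frames(series, motion, z_thresh, motion_thresh_mm)
    confounds = build_confound_table(motion, flags, design, nuisance)
    resid = regress_confounds(series, confounds)
    out = bandpass(resid, low_hz, high_hz)
    out.prepped = True
    return out
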