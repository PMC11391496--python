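"""ROI-level block-design GLM and the laterality index of task activation.

Each region's signal is regressed on the HRF-convolved task regressor
(plus drift and intercept); the per-region task t statistics are the
ROI-level analogue of a first-level contrast map. The laterality index
over a cortical mask is LI = (L - R) / (L + R) for the suprathreshold
positive t-mass in the left (L) and right (R) masked regions, classified
left-dominant when LI > 0.2, right-dominant when LI < -0.2, and
bilateral-dominant otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import TaskDesign, task_regressor
from .timeseries import RoiTimeSeries

__all__ = ["build_design_matrix", "fit_glm", "laterality_index", "LateralityResult"]

#: Suprathreshold cutoff on region t-values entering the LI mass sums.
DEFAULT_T_THRESHOLD = 2.0


def build_design_matrix(design: TaskDesign, n_drift: int = 2) -> pd.DataFrame:
    """Design matrix [task | cosine drifts | intercept] at TR resolution."""
    n_t = design.n_timepoints
    cols = {"task": task_regressor(design)}
    t = np.arange(n_t)
    for j in range(1, n_drift + 1):
        cols[f"drift_{j}"] = np.cos(np.pi * j * (t + 0.5) / n_t)
    cols["intercept"] = np.ones(n_t)
    X = pd.DataFrame(cols)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


def fit_glm(series: RoiTimeSeries, design: pd.DataFrame | TaskDesign) -> pd.DataFrame:
    """Per-region OLS estimates for the task regressor.

    Returns a table indexed by region with columns ``beta``, ``t`` and
    two-sided ``p`` (residual degrees of freedom n - p).
    """
    X_frame = build_design_matrix(design) if isinstance(design, TaskDesign) else design
    X = X_frame.to_numpy(dtype=float)
    if X.shape[0] != series.n_timepoints:
        raise ValueError("design matrix length does not match series")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    task_col = list(X_frame.columns).index("task")
    Y = series.data.T
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[task_col, task_col])
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = beta[task_col] / se
    pval = 2 * stats.t.sf(np.abs(tval), dof)
    return pd.DataFrame(
        {"beta": beta[task_col], "t": tval, "p": pval}, index=series.region_labels
    )


@dataclass(frozen=True)
class LateralityResult:
    li: float
    dominance: str  # left / right / bilateral
    left_mass: float
    right_mass: float
    degenerate: bool = False


def classify_dominance(li: float) -> str:
    if li > 0.2:
        return "left"
    if li < -0.2:
        return "right"
    return "bilateral"


def laterality_index(
    t_values: pd.Series,
    regions: pd.DataFrame,
    mask_cortex: str = "frontal",
    threshold: float = DEFAULT_T_THRESHOLD,
) -> LateralityResult:
    """LI of suprathreshold positive t-mass within a cortical mask.

    ``mask_cortex`` selects all regions whose cortex label contains the
    substring (e.g. ``"frontal"`` pools left-frontal and right-frontal).
    Both hemispheres must be represented in the mask. With no
    suprathreshold mass at all the LI is undefined; a degenerate
    bilateral result is returned.
    """
    mask = regions["cortex"].str.contains(mask_cortex)
    sel = regions[mask]
    if not {"left", "right"} <= set(sel["hemisphere"]):
        raise ValueError(f"mask {mask_cortex!r} must cover both hemispheres")
    masses = {}
    for hemi in ("left", "right"):
        names = sel.loc[sel["hemisphere"] == hemi, "name"]
        t = t_values.reindex(names).to_numpy(dtype=float)
        supra = t[t > threshold]
        masses[hemi] = float(supra.sum())
    L, R = masses["left"], masses["right"]
    if L + R == 0:
        return LateralityResult(0.0, "bilateral", L, R, degenerate=True)
    li = (L - R) / (L + R)
    return LateralityResult(float(li), classify_dominance(li), L, R)
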