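"""Per-subject weighted connectivity and the ROI edge-feature table.

Connectivity is the Pearson correlation between two regions' denoised
time series; the group comparison operates on the Fisher-z transformed
correlations between each of the six ROIs and every other region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries import RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "correlation_matrix",
    "fisher_z",
    "extract_edge_features",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region Pearson-r matrix, zero diagonal by convention."""

    values: np.ndarray
    region_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if v.shape[0] != len(self.region_labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if np.abs(v).max() > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_labels, columns=self.region_labels)


def correlation_matrix(series: RoiTimeSeries, require_prepped: bool = True) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of the (denoised) regional signals.

    The diagonal is set to 0. A constant region has undefined correlation;
    its row and column are zeroed with a warning. By default a series that
    has not been through the denoising chain is rejected.
    """
    if require_prepped and not series.prepped:
        raise ValueError(
            "series has not been denoised; run the prep stage first "
            "or pass require_prepped=False"
        )
    if series.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    data = series.data
    constant = data.std(axis=1) == 0
    if constant.any():
        logger.warning(
            "%d constant region(s); their correlations are set to 0", int(constant.sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(data)
    R[constant, :] = 0.0
    R[:, constant] = 0.0
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 0.0)
    R = np.clip(R, -1.0, 1.0)
    return ConnectivityMatrix(R, list(series.region_labels), series.subject_id)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilising transform z = atanh(r).

    Values with \\|r\\| >= 1 are clipped to +/-(1 - 1e-7) with a warning.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1):
        logger.warning("correlation(s) at |r| >= 1 clipped before Fisher z")
        arr = np.clip(arr, -(1 - 1e-7), 1 - 1e-7)
    z = np.arctanh(arr)
    return float(z) if np.isscalar(r) else z


def edge_feature_columns(region_labels: list[str], rois: list[str]) -> list[tuple[str, str]]:
    """Ordered (ROI, region) pairs, ROI first, ROI-ROI duplicates appearing once.

    A pair of two ROIs is kept only in its canonical orientation (lower
    region index first), so with 6 ROIs among 132 regions the table has
    6 x 131 - C(6, 2) = 771 columns.
    """
    index = {name: i for i, name in enumerate(region_labels)}
    unknown = [r for r in rois if r not in index]
    if unknown:
        raise ValueError(f"unknown ROI label(s) {unknown}; valid labels: {region_labels}")
    roi_set = set(rois)
    cols = []
    for roi in rois:
        for region in region_labels:
            if region == roi:
                continue
            if region in roi_set and index[region] < index[roi]:
                continue  # canonical orientation already emitted
            cols.append((roi, region))
    return cols


def extract_edge_features(
    matrices: dict[str, ConnectivityMatrix], rois: list[str]
) -> pd.DataFrame:
    """Fisher-z edge features, one row per subject, one column per (ROI, region) pair."""
    if not matrices:
        raise ValueError("no connectivity matrices supplied")
    first = next(iter(matrices.values()))
    labels = first.region_labels
    for m in matrices.values():
        if m.region_labels != labels:
            raise ValueError("subjects do not share region labels")
    cols = edge_feature_columns(labels, rois)
    index = {name: i for i, name in enumerate(labels)}
    ii = np.array([index[a] for a, _ in cols])
    jj = np.array([index[b] for _, b in cols])
    rows = {sid: fisher_z(m.values[ii, jj]) for sid, m in matrices.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    frame.columns = [f"{a}~{b}" for a, b in cols]
    frame.index.name = "subject_id"
    return frame
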