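"""Core per-subject data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["RoiTimeSeries", "ConfoundTable"]


@dataclass
class RoiTimeSeries:
    """One subject's ROI-averaged BOLD signal.

    Attributes
    ----------
    data : ndarray, shape (n_regions, n_timepoints)
        Signal matrix in arbitrary units. Must be finite.
    tr_s : float
        Sampling interval (repetition time) in seconds.
    region_labels : list of str
        Region names, one per row.
    subject_id : str
        Identifier carried through the pipeline.
    prepped : bool
        True once the series has been confound-regressed and band-pass
        filtered; connectivity refuses raw series.

    Notes
    -----
    No constraint relates the number of timepoints to the number of
    regions; short runs (timepoints < 2 x regions) are accepted, the
    downstream correlation estimate is simply noisier.
    """

    data: np.ndarray
    tr_s: float
    region_labels: list[str]
    subject_id: str = ""
    prepped: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (regions x timepoints)")
        if self.data.shape[0] != len(self.region_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.region_labels)} region labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray, prepped: bool | None = None) -> "RoiTimeSeries":
        return replace(
            self,
            data=np.asarray(data, dtype=float),
            prepped=self.prepped if prepped is None else prepped,
        )

    def to_frame(self) -> pd.DataFrame:
        """Timepoints x regions table (the on-disk TSV orientation)."""
        return pd.DataFrame(self.data.T, columns=self.region_labels)


@dataclass
class ConfoundTable:
    """Per-subject nuisance regressors, timepoints x columns.

    Columns comprise rigid-body motion parameters, one-hot indicators for
    outlier frames, task-effect regressors (HRF-convolved boxcar and its
    temporal derivative), and nuisance signal channels standing in for
    white-matter / CSF averages.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.isna().any().any():
            raise ValueError("confound table contains missing values")

    @property
    def n_timepoints(self) -> int:
        return len(self.frame)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def with_columns(self, other: pd.DataFrame) -> "ConfoundTable":
        if len(other) != self.n_timepoints:
            raise ValueError("confound column length mismatch")
        return ConfoundTable(pd.concat([self.frame, other], axis=1))
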