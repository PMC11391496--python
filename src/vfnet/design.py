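"""Block task design and haemodynamic response modelling.

The verbal-fluency paradigm is a classic block design: each block pairs a
rest period with a covert word-generation period, and the whole run is a
fixed number of such blocks sampled at a constant repetition time (TR).
The expected BOLD response to the task blocks is the boxcar indicator of
the task periods convolved with a canonical haemodynamic response
function (HRF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskDesign",
    "make_design",
    "canonical_hrf",
    "task_regressor",
]


@dataclass(frozen=True)
class TaskDesign:
    """A block design of alternating rest and task segments.

    Attributes
    ----------
    n_blocks : int
        Number of rest+task blocks.
    rest_duration_s, task_duration_s : float
        Segment durations in seconds.
    tr_s : float
        Repetition time (sampling interval) in seconds.
    onsets : tuple of (start_s, duration_s, condition)
        Ordered, non-overlapping segments starting with rest.
    """

    n_blocks: int
    rest_duration_s: float
    task_duration_s: float
    tr_s: float
    onsets: tuple[tuple[float, float, str], ...] = field(default=())

    @property
    def total_duration_s(self) -> float:
        return self.n_blocks * (self.rest_duration_s + self.task_duration_s)

    @property
    def n_timepoints(self) -> int:
        n = self.total_duration_s / self.tr_s
        n_int = int(round(n))
        if abs(n - n_int) > 1e-9:
            raise ValueError(
                f"total duration {self.total_duration_s}s is not a multiple of TR {self.tr_s}s"
            )
        return n_int

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.tr_s

    def boxcar(self) -> np.ndarray:
        """Task indicator (1 during task segments, 0 during rest) at TR resolution."""
        box = np.zeros(self.n_timepoints)
        t = self.frame_times
        for start, dur, cond in self.onsets:
            if cond == "task":
                box[(t >= start) & (t < start + dur)] = 1.0
        return box


def make_design(
    n_blocks: int = 5,
    rest_s: float = 30.0,
    task_s: float = 30.0,
    tr_s: float = 1.0,
) -> TaskDesign:
    """Build an alternating rest/task block design, rest first.

    Defaults correspond to the verbal-fluency paradigm: five blocks of
    30 s rest followed by 30 s covert word generation, TR = 1 s, hence
    300 timepoints.
    """
    if n_blocks <= 0 or rest_s <= 0 or task_s <= 0 or tr_s <= 0:
        raise ValueError("all design arguments must be positive")
    onsets = []
    t = 0.0
    for _ in range(int(n_blocks)):
        onsets.append((t, float(rest_s), "rest"))
        t += rest_s
        onsets.append((t, float(task_s), "task"))
        t += task_s
    return TaskDesign(
        n_blocks=int(n_blocks),
        rest_duration_s=float(rest_s),
        task_duration_s=float(task_s),
        tr_s=float(tr_s),
        onsets=tuple(onsets),
    )


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR.

    Response peak at 6 s, undershoot peak at 16 s, peak-to-undershoot
    ratio 6 (the SPM default parameterisation). The kernel is normalised
    to unit peak so regressor amplitudes stay on the signal scale.
    """
    from scipy.stats import gamma

    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    t = np.arange(0, duration_s + tr_s / 2, tr_s)
    # shape/scale parameterisation: peak = (shape-1)*scale
    peak = gamma.pdf(t, a=6, scale=1.0)
    undershoot = gamma.pdf(t, a=16, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def hrf_temporal_derivative(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Finite-difference temporal derivative of the canonical HRF."""
    h = canonical_hrf(tr_s, duration_s)
    return np.gradient(h, tr_s)


def task_regressor(design: TaskDesign, derivative: bool = False) -> np.ndarray:
    """Boxcar convolved with the canonical HRF (and optionally its derivative).

    Returns an array of shape (n_timepoints,) or (n_timepoints, 2) when
    ``derivative`` is requested.
    """
    box = design.boxcar()
    h = canonical_hrf(design.tr_s)
    reg = np.convolve(box, h)[: design.n_timepoints]
    if not derivative:
        return reg
    d = np.convolve(box, hrf_temporal_derivative(design.tr_s))[: design.n_timepoints]
    return np.column_stack([reg, d])
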