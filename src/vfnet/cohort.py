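"""Synthetic cohort generator for the three-group verbal-fluency study design.

Emulates the statistical structure the downstream analysis assumes: a
healthy-control group and two patient groups (temporal lobe epilepsy with
and without hippocampal sclerosis), 132-region BOLD-like time series under
a five-block rest/task design, group-specific connectivity perturbations
centred on a seed region (the left anterior inferior temporal gyrus
analogue), demographic covariates, and verbal-fluency scores that track a
subject's seed-region connectivity.

Generative model per subject
----------------------------
1. A target correlation matrix: block structure by cortex (within 0.4,
   between 0.1) plus the subject's group effect-map offsets on the seed
   region's edges and a subject-level random offset; repaired to positive
   semi-definite by eigenvalue clipping when needed.
2. Latent innovations drawn from N(0, target), temporally smoothed by a
   unit-variance AR(1) recursion (cross-correlations are preserved).
3. Plus a task response (boxcar convolved with the canonical HRF, scaled
   per region), a slow cosine drift, and white observation noise.
4. Six rigid-body motion traces (random walks with occasional spikes) and
   two nuisance channels standing in for white-matter/CSF averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import TaskDesign, task_regressor
from .timeseries import RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "GROUPS",
    "ROI_NAMES",
    "SEED_REGION",
    "CohortConfig",
    "SubjectData",
    "Cohort",
    "make_region_table",
    "default_region_table",
    "base_correlation",
    "target_correlation",
    "nearest_psd",
    "simulate_subject",
    "simulate_cohort",
]

GROUPS = ("HC", "TLE-HS", "TLE-NHS")

#: The six left frontal/temporal seed regions of interest.
ROI_NAMES = ("L_triIFG", "L_operIFG", "L_aMTG", "L_aITG", "L_toMTG", "L_toITG")

#: The region whose connectivity carries the group effect by default.
SEED_REGION = "L_aITG"


def make_region_table(
    cortex_sizes: dict[str, int],
    roi_names: tuple[str, ...] = (),
    named: dict[str, tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Build a region-metadata table.

    Parameters
    ----------
    cortex_sizes : dict
        Cortex label -> number of regions. Labels starting with ``left-``
        / ``right-`` set the hemisphere; anything else alternates
        left/right with the remainder midline.
    roi_names : tuple of str
        Region names flagged as ROIs (must exist in the table).
    named : dict
        Overrides ``{name: (cortex, index-within-cortex)}`` so specific
        anatomical analogues get stable names.
    """
    rows = []
    named = named or {}
    placed: dict[tuple[str, int], str] = {
        (cortex, idx): name for name, (cortex, idx) in named.items()
    }
    for cortex, size in cortex_sizes.items():
        for i in range(size):
            name = placed.get((cortex, i), f"{cortex}_{i:02d}")
            if cortex.startswith("left-"):
                hemi = "left"
            elif cortex.startswith("right-"):
                hemi = "right"
            else:
                hemi = ("left", "right")[i % 2] if i < size - (size % 2) else "midline"
            rows.append({"name": name, "hemisphere": hemi, "cortex": cortex})
    table = pd.DataFrame(rows)
    if table["name"].duplicated().any():
        raise ValueError("duplicate region names")
    missing = set(roi_names) - set(table["name"])
    if missing:
        raise ValueError(f"ROI names not in table: {sorted(missing)}")
    table["is_roi"] = table["name"].isin(roi_names)
    return table


def default_region_table() -> pd.DataFrame:
    """The default 132-region parcellation analogue.

    91 cortical (four frontal/temporal blocks of 20 plus 11 midline),
    15 subcortical and 26 cerebellar regions; six left frontal/temporal
    regions are flagged as ROIs.
    """
    named = {
        "L_triIFG": ("left-frontal", 0),
        "L_operIFG": ("left-frontal", 1),
        "L_aMTG": ("left-temporal", 0),
        "L_aITG": ("left-temporal", 1),
        "L_toMTG": ("left-temporal", 2),
        "L_toITG": ("left-temporal", 3),
    }
    sizes = {
        "left-frontal": 20,
        "left-temporal": 20,
        "right-frontal": 20,
        "right-temporal": 20,
        "midline-other": 11,
        "subcortical": 15,
        "cerebellar": 26,
    }
    return make_region_table(sizes, roi_names=ROI_NAMES, named=named)


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults are the study conditions.

    Group sizes follow the study design (29 HC, 30 TLE-HS, 28 TLE-NHS).
    The effect map perturbs every edge of ``seed_region``: reduced
    connectivity in the sclerosis-like group, enhanced in the
    non-sclerosis-like group (correlation-scale offsets; the magnitudes
    are free parameters of the generator, not estimates).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 29, "TLE-HS": 30, "TLE-NHS": 28}
    )
    effect_map: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "TLE-HS": {SEED_REGION: -0.15},
            "TLE-NHS": {SEED_REGION: +0.10},
        }
    )
    within_cortex_r: float = 0.4
    between_cortex_r: float = 0.1
    subject_conn_sd: float = 0.05  # subject-level jitter on seed-region edges
    ar_coef: float = 0.4
    noise_sd: float = 0.4  # white observation noise, signal units
    drift_amplitude: float = 0.3
    task_amplitude: float = 0.6  # BOLD response amplitude in task-responsive cortices
    task_cortices: tuple[str, ...] = ("left-frontal", "left-temporal")
    # covariates: mean/sd pairs; MoCA means differ by group
    age_mean: float = 35.0
    age_sd: float = 10.0
    education_mean: float = 12.0
    education_sd: float = 3.0
    moca_mean: dict[str, float] = field(
        default_factory=lambda: {"HC": 27.0, "TLE-HS": 24.5, "TLE-NHS": 25.0}
    )
    moca_sd: float = 1.5
    # verbal-fluency score model: score = intercept + slope * seed mean r + noise
    score_model: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "vfc": (6.0, 10.0, 1.0),
            "vfp": (8.0, 14.0, 1.2),
            "vfs": (12.0, 8.0, 1.5),
        }
    )
    seed_region: str = SEED_REGION
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 subjects")
        if not -1 < self.ar_coef < 1:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        for name, sd in [
            ("noise_sd", self.noise_sd),
            ("subject_conn_sd", self.subject_conn_sd),
            ("age_sd", self.age_sd),
            ("education_sd", self.education_sd),
            ("moca_sd", self.moca_sd),
        ]:
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_overrides(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class SubjectData:
    """Everything the generator emits for one subject."""

    series: RoiTimeSeries
    motion: pd.DataFrame  # 6 rigid-body columns
    nuisance: pd.DataFrame  # white-matter / CSF analogue channels
    outlier_frames: np.ndarray  # boolean ground-truth spike frames
    seed_mean_r: float  # subject's target mean seed-region correlation


@dataclass
class Cohort:
    """A simulated study: per-subject data plus metadata tables."""

    subjects: dict[str, SubjectData]
    table: pd.DataFrame  # one row per subject
    regions: pd.DataFrame
    design: TaskDesign
    config: CohortConfig

    def series_of(self, subject_id: str) -> RoiTimeSeries:
        return self.subjects[subject_id].series


def base_correlation(regions: pd.DataFrame, within: float = 0.4, between: float = 0.1) -> np.ndarray:
    """Block-structured base correlation: ``within`` inside a cortex, ``between`` across."""
    cortex = regions["cortex"].to_numpy()
    same = cortex[:, None] == cortex[None, :]
    C = np.where(same, within, between)
    np.fill_diagonal(C, 1.0)
    return C


def nearest_psd(C: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Repair a symmetric matrix to positive semi-definite by eigenvalue clipping.

    Eigenvalues below ``eps`` are raised to ``eps``; the result is rescaled
    back to unit diagonal. Returns the input untouched when already PSD.
    """
    w, V = np.linalg.eigh((C + C.T) / 2)
    if w.min() >= eps:
        return C
    logger.warning("target correlation not PSD (min eig %.2e); clipping", w.min())
    w = np.clip(w, eps, None)
    C2 = (V * w) @ V.T
    d = np.sqrt(np.diag(C2))
    C2 = C2 / np.outer(d, d)
    np.fill_diagonal(C2, 1.0)
    return C2


def target_correlation(
    group: str,
    regions: pd.DataFrame,
    config: CohortConfig,
    subject_offset: float = 0.0,
) -> np.ndarray:
    """Group target correlation: base blocks + effect-map offsets on seed edges."""
    C = base_correlation(regions, config.within_cortex_r, config.between_cortex_r)
    names = regions["name"].to_numpy()
    offsets = dict(config.effect_map.get(group, {}))
    where = np.flatnonzero(names == config.seed_region)
    shift = offsets.get(config.seed_region, 0.0) + subject_offset
    if len(where) == 0:
        if shift != 0.0:
            raise ValueError(
                f"seed_region {config.seed_region!r} not in the region table but "
                "effect offsets target it"
            )
        return nearest_psd(C)
    seed_idx = int(where[0])
    if shift != 0.0:
        C[seed_idx, :] += shift
        C[:, seed_idx] += shift
        C[seed_idx, seed_idx] = 1.0
        C = np.clip(C, -0.99, 0.99)
        np.fill_diagonal(C, 1.0)
    return nearest_psd(C)


def _simulate_motion(rng: np.random.Generator, n_t: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Six rigid-body parameters as slow random walks with rare spikes."""
    steps = rng.normal(0.0, 0.01, size=(n_t, 6))
    motion = np.cumsum(steps, axis=0)
    outliers = np.zeros(n_t, dtype=bool)
    n_spikes = rng.poisson(1.5)
    if n_spikes:
        frames = rng.choice(np.arange(5, n_t), size=min(n_spikes, n_t - 5), replace=False)
        motion[frames] += rng.normal(0.0, 1.5, size=(len(frames), 6))
        outliers[frames] = True
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    return pd.DataFrame(motion, columns=cols), outliers


def simulate_subject(
    group: str,
    design: TaskDesign,
    regions: pd.DataFrame,
    config: CohortConfig,
    seed: int | np.random.SeedSequence,
    subject_id: str = "sub-000",
) -> SubjectData:
    """Simulate one subject's ROI time series and confound channels."""
    if group not in config.group_sizes:
        raise ValueError(f"unknown group {group!r}; known: {sorted(config.group_sizes)}")
    rng = np.random.default_rng(seed)
    n_regions = len(regions)
    n_t = design.n_timepoints

    subject_offset = rng.normal(0.0, config.subject_conn_sd)
    C = target_correlation(group, regions, config, subject_offset)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n_regions))
    innovations = L @ rng.standard_normal((n_regions, n_t))
    # unit-variance AR(1) smoothing along time; cross-correlations preserved
    phi = config.ar_coef
    latent = lfilter([np.sqrt(1 - phi**2)], [1.0, -phi], innovations, axis=1)

    t = design.frame_times
    reg = task_regressor(design)
    amp = np.where(
        regions["cortex"].isin(config.task_cortices).to_numpy(), config.task_amplitude, 0.0
    )
    task_part = amp[:, None] * reg[None, :]
    drift = config.drift_amplitude * np.cos(
        2 * np.pi * t / (2 * design.total_duration_s) + rng.uniform(0, 2 * np.pi, (n_regions, 1))
    )
    noise = rng.normal(0.0, config.noise_sd, size=(n_regions, n_t)) if config.noise_sd else 0.0
    data = latent + task_part + drift + noise

    motion, outliers = _simulate_motion(rng, n_t)
    nuisance = pd.DataFrame(
        rng.standard_normal((n_t, 2)) * 0.5, columns=["wm_signal", "csf_signal"]
    )
    names = regions["name"].to_numpy()
    where = np.flatnonzero(names == config.seed_region)
    if len(where):
        seed_idx = int(where[0])
        seed_mean_r = float(np.delete(C[seed_idx], seed_idx).mean())
    else:
        seed_mean_r = float("nan")
    series = RoiTimeSeries(
        data=data,
        tr_s=design.tr_s,
        region_labels=list(names),
        subject_id=subject_id,
        prepped=False,
    )
    return SubjectData(series, motion, nuisance, outliers, seed_mean_r)


def simulate_cohort(
    config: CohortConfig,
    design: TaskDesign,
    regions: pd.DataFrame | None = None,
) -> Cohort:
    """Simulate the full cohort: one subject per configured slot.

    Per-subject seeds are spawned deterministically from the master seed,
    so any subject can be regenerated independently and the whole cohort
    is byte-reproducible.
    """
    if regions is None:
        regions = default_region_table()
    master = np.random.SeedSequence(config.seed)
    n_total = sum(config.group_sizes.values())
    subject_seeds = master.spawn(n_total + 1)
    meta_rng = np.random.default_rng(subject_seeds[-1])

    subjects: dict[str, SubjectData] = {}
    rows = []
    idx = 0
    for group in config.group_sizes:
        for _ in range(config.group_sizes[group]):
            sid = f"sub-{idx:03d}"
            sdata = simulate_subject(group, design, regions, config, subject_seeds[idx], sid)
            subjects[sid] = sdata
            age = float(np.clip(meta_rng.normal(config.age_mean, config.age_sd), 16, 65))
            sex = "male" if meta_rng.random() < 0.5 else "female"
            edu = float(np.clip(meta_rng.normal(config.education_mean, config.education_sd), 6, 22))
            moca = float(np.clip(meta_rng.normal(config.moca_mean[group], config.moca_sd), 10, 30))
            scores = {}
            for score, (a, b, sd) in config.score_model.items():
                scores[score] = float(
                    max(0.0, a + b * sdata.seed_mean_r + meta_rng.normal(0.0, sd))
                )
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age": age,
                    "sex": sex,
                    "education": edu,
                    "moca": moca,
                    **scores,
                    "seed_mean_r": sdata.seed_mean_r,
                    "li": np.nan,
                    "dominance": "",
                }
            )
            idx += 1
    table = pd.DataFrame(rows).set_index("subject_id", drop=False)
    table.index.name = None
    return Cohort(subjects=subjects, table=table, regions=regions, design=design, config=config)
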