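"""Plain-text file formats for cohorts, matrices and reports.

Everything the pipeline reads or writes is TSV/CSV/JSON with a small
``# key: value`` provenance header (seed, TR, subject id, config hash),
so that artifacts are diffable and a write-then-read round trip
reproduces values to full precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortConfig, SubjectData
from .connectivity import ConnectivityMatrix
from .design import TaskDesign, make_design
from .timeseries import RoiTimeSeries

__all__ = [
    "write_header",
    "read_header",
    "write_timeseries",
    "read_timeseries",
    "write_matrix",
    "read_matrix",
    "write_cohort",
    "load_cohort",
    "write_json",
]

FLOAT_FMT = "%.17g"


def write_header(path: Path, meta: dict, frame: pd.DataFrame, sep: str = "\t", **to_csv) -> None:
    with open(path, "w") as fh:
        for key in meta:
            fh.write(f"# {key}: {meta[key]}\n")
        frame.to_csv(fh, sep=sep, **to_csv)


def read_header(path: Path, sep: str = "\t", **read_csv) -> tuple[dict, pd.DataFrame]:
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" not in body:
                raise ValueError(f"{path}:{lineno}: malformed header line {line!r}")
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
            n_header = lineno
    frame = pd.read_csv(
        path, sep=sep, skiprows=n_header, float_precision="round_trip", **read_csv
    )
    return meta, frame


def write_timeseries(path: Path, series: RoiTimeSeries) -> None:
    meta = {
        "format": "vfnet-timeseries",
        "subject_id": series.subject_id,
        "tr_s": repr(series.tr_s),
        "prepped": str(series.prepped).lower(),
    }
    write_header(Path(path), meta, series.to_frame(), index=False, float_format=FLOAT_FMT)


def read_timeseries(path: Path) -> RoiTimeSeries:
    meta, frame = read_header(Path(path))
    if meta.get("format") != "vfnet-timeseries":
        raise ValueError(f"{path}: not a vfnet time-series file")
    return RoiTimeSeries(
        data=frame.to_numpy(dtype=float).T,
        tr_s=float(meta["tr_s"]),
        region_labels=list(frame.columns),
        subject_id=meta.get("subject_id", ""),
        prepped=meta.get("prepped") == "true",
    )


def write_matrix(path: Path, matrix: ConnectivityMatrix) -> None:
    meta = {"format": "vfnet-connectivity", "subject_id": matrix.subject_id}
    write_header(Path(path), meta, matrix.to_frame(), index=True, float_format=FLOAT_FMT)


def read_matrix(path: Path) -> ConnectivityMatrix:
    meta, frame = read_header(Path(path), index_col=0)
    if meta.get("format") != "vfnet-connectivity":
        raise ValueError(f"{path}: not a vfnet connectivity file")
    return ConnectivityMatrix(
        frame.to_numpy(dtype=float), list(frame.columns), meta.get("subject_id", "")
    )


def config_hash(config: CohortConfig) -> str:
    blob = json.dumps(
        {k: repr(v) for k, v in sorted(vars(config).items())}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_cohort(cohort: Cohort, directory: Path) -> None:
    """Write a cohort as regions.csv, subjects.csv, design.json + per-subject TSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.regions.to_csv(directory / "regions.csv", index=False)
    cohort.table.to_csv(directory / "subjects.csv", index=False, float_format=FLOAT_FMT)
    d = cohort.design
    write_json(
        directory / "design.json",
        {
            "n_blocks": d.n_blocks,
            "rest_duration_s": d.rest_duration_s,
            "task_duration_s": d.task_duration_s,
            "tr_s": d.tr_s,
        },
    )
    for sid, sdata in cohort.subjects.items():
        write_timeseries(directory / f"{sid}_timeseries.tsv", sdata.series)
        meta = {"format": "vfnet-confounds", "subject_id": sid}
        write_header(
            directory / f"{sid}_motion.tsv",
            meta,
            sdata.motion,
            index=False,
            float_format=FLOAT_FMT,
        )
        write_header(
            directory / f"{sid}_nuisance.tsv",
            meta,
            sdata.nuisance.assign(outlier_gt=sdata.outlier_frames.astype(int)),
            index=False,
            float_format=FLOAT_FMT,
        )


def load_cohort(directory: Path, config: CohortConfig | None = None) -> Cohort:
    directory = Path(directory)
    regions = pd.read_csv(directory / "regions.csv")
    table = pd.read_csv(directory / "subjects.csv")
    required = {"subject_id", "group", "age", "sex", "education", "moca"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"subjects.csv is missing column(s): {sorted(missing)}")
    table = table.set_index("subject_id", drop=False)
    table.index.name = None
    with open(directory / "design.json") as fh:
        dj = json.load(fh)
    design = make_design(dj["n_blocks"], dj["rest_duration_s"], dj["task_duration_s"], dj["tr_s"])
    subjects: dict[str, SubjectData] = {}
    for sid in table["subject_id"]:
        series = read_timeseries(directory / f"{sid}_timeseries.tsv")
        if series.n_regions != len(regions):
            raise ValueError(
                f"{sid}: series has {series.n_regions} regions, table has {len(regions)}"
            )
        _, motion = read_header(directory / f"{sid}_motion.tsv")
        _, nuis = read_header(directory / f"{sid}_nuisance.tsv")
        outliers = nuis.pop("outlier_gt").to_numpy(dtype=bool)
        subjects[sid] = SubjectData(
            series=series,
            motion=motion,
            nuisance=nuis,
            outlier_frames=outliers,
            seed_mean_r=float(table.loc[sid, "seed_mean_r"])
            if "seed_mean_r" in table.columns
            else float("nan"),
        )
    return Cohort(
        subjects=subjects,
        table=table,
        regions=regions,
        design=design,
        config=config or CohortConfig(),
    )


def write_json(path: Path, payload: dict) -> None:
    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
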