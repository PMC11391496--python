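"""End-to-end pipeline driver.

Chains every stage on a cohort: simulate (or load) -> denoise ->
connectivity -> degree-centrality AUC -> consensus community / affinity
-> task GLM / laterality -> covariate-adjusted group statistics with FDR
-> hippocampal-sclerosis classification. All stage parameters default to
the study's stated settings (0.009-0.10 Hz band, densities 5-40% in 1%
steps, 100 community optimisations, alpha = 0.05, repeated 70/30 splits
x 100), and all randomness flows from the single master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import community as com
from . import connectivity as conn
from . import graph, groupstats, io, prep, taskglm
from .cohort import Cohort, CohortConfig, simulate_cohort
from .design import make_design

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline settings; the defaults reproduce the study's stated values."""

    cohort_dir: str | None = None
    output_dir: str = "vfnet_out"
    simulate: bool = True
    seed: int = 0
    # denoising
    low_hz: float = 0.009
    high_hz: float = 0.10
    z_thresh: float = 5.0
    motion_thresh_mm: float = 0.9
    # graph metrics
    density_min: float = 0.05
    density_max: float = 0.40
    density_step: float = 0.01
    # community
    community_runs: int = 100
    gamma: float = 1.0
    community_cortices: tuple[str, ...] = ("left-frontal", "left-temporal")
    # statistics
    alpha: float = 0.05
    covariates: tuple[str, ...] = ("age", "sex", "education", "moca")
    # laterality
    li_mask: str = "frontal"
    li_threshold: float = 2.0
    # classification
    classify_groups: tuple[str, str] = ("TLE-HS", "TLE-NHS")
    p_enter: float = 0.05
    hidden_units: int = 4
    train_frac: float = 0.7
    repetitions: int = 100
    max_classifier_features: int = 30
    # stage toggles
    with_community: bool = True
    with_classification: bool = True
    # nested generator configuration (flat mapping of CohortConfig overrides)
    cohort: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        cohort_raw = raw.get("cohort", {}) or {}
        known_cohort = {f.name for f in dataclasses.fields(CohortConfig)}
        unknown_cohort = set(cohort_raw) - known_cohort
        if unknown_cohort:
            raise ValueError(f"unknown cohort key(s): {sorted(unknown_cohort)}")
        return cls(**raw)

    def density_grid(self) -> np.ndarray:
        n = int(round((self.density_max - self.density_min) / self.density_step)) + 1
        return np.round(self.density_min + self.density_step * np.arange(n), 10)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(**{**self.cohort, "seed": self.seed})

    def hash(self) -> str:
        """Provenance hash over the analysis settings (not filesystem paths)."""
        payload = {
            k: repr(v)
            for k, v in sorted(dataclasses.asdict(self).items())
            if k not in ("output_dir", "cohort_dir")
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _derive_seed(master: int, *tags) -> int:
    """Stable per-stage/per-subject seed derivation from the master seed."""
    blob = repr((master, *tags)).encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:4], "little")


class _StageLog:
    """Structured, timestamp-free log: one line per stage with output hashes."""

    def __init__(self) -> None:
        self.lines: list[str] = []

    def stage(self, name: str, params: dict, outputs: list[Path]) -> None:
        hashes = []
        for p in outputs:
            digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:12]
            hashes.append(f"{Path(p).name}:{digest}")
        par = " ".join(f"{k}={v}" for k, v in params.items())
        self.lines.append(f"stage={name} {par} outputs=[{' '.join(hashes)}]")
        logger.info("completed stage %s", name)

    def write(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the result bundle also written to disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog()
    meta = {"config_hash": config.hash(), "seed": config.seed}

    # ---- stage 1: cohort -------------------------------------------------
    if config.simulate:
        cohort = simulate_cohort(config.cohort_config(), make_design())
    else:
        if config.cohort_dir is None:
            raise FileNotFoundError("no cohort_dir given and simulate is off")
        cohort = io.load_cohort(config.cohort_dir, config.cohort_config())
    table = cohort.table.copy()
    regions = cohort.regions
    rois = list(regions.loc[regions["is_roi"], "name"])
    log.stage("cohort", {"n_subjects": len(table), "simulate": config.simulate}, [])

    # ---- stage 2: denoising ---------------------------------------------
    prepped = {
        sid: prep.prep_subject(
            s.series,
            s.motion,
            cohort.design,
            s.nuisance,
            config.z_thresh,
            config.motion_thresh_mm,
            config.low_hz,
            config.high_hz,
        )
        for sid, s in cohort.subjects.items()
    }
    log.stage("prep", {"band": f"{config.low_hz}-{config.high_hz}Hz"}, [])

    # ---- stage 3: connectivity and edge features -------------------------
    matrices = {sid: conn.correlation_matrix(series) for sid, series in prepped.items()}
    edges = conn.extract_edge_features(matrices, rois)
    edges = edges.loc[table["subject_id"]]
    edge_path = out / "edge_features.csv"
    io.write_header(edge_path, {**meta, "stage": "connectivity"}, edges, sep=",", index=True,
                    float_format=io.FLOAT_FMT)
    log.stage("connectivity", {"n_edges": edges.shape[1]}, [edge_path])

    # ---- stage 4: degree centrality AUC ----------------------------------
    grid = config.density_grid()
    dc_rows = {}
    for sid, m in matrices.items():
        curve = graph.degree_curves(m, grid)
        dc_rows[sid] = dict(zip(curve.region_labels, curve.auc))
    dc_auc_all = pd.DataFrame.from_dict(dc_rows, orient="index").loc[table["subject_id"]]
    dc_auc_roi = dc_auc_all[rois]
    dc_path = out / "dc_auc.csv"
    io.write_header(dc_path, {**meta, "stage": "graphmetrics", "densities": len(grid)},
                    dc_auc_roi, sep=",", index=True, float_format=io.FLOAT_FMT)
    log.stage("graphmetrics", {"densities": len(grid)}, [dc_path])

    # ---- stage 5: community / affinity -----------------------------------
    affinity_wide = None
    if config.with_community:
        sub_mask = regions["cortex"].isin(config.community_cortices).to_numpy()
        sub_names = list(regions.loc[sub_mask, "name"])
        cortex_members = {
            c: list(regions.loc[regions["cortex"] == c, "name"])
            for c in config.community_cortices
        }
        rows = []
        for idx, sid in enumerate(table["subject_id"]):
            W = matrices[sid].values[np.ix_(sub_mask, sub_mask)]
            W = np.clip(W, 0.0, None)  # negative correlations are not communities
            P = com.consensus_coassignment(
                W,
                runs=config.community_runs,
                master_seed=_derive_seed(config.seed, "community", idx),
                gamma=config.gamma,
                region_labels=sub_names,
            )
            for roi in rois:
                for cortex, members in cortex_members.items():
                    score = com.affinity(P, roi, members, cortex)
                    rows.append(
                        {"subject_id": sid, "region": roi, "cortex": cortex,
                         "affinity": score.value}
                    )
        affinity_long = pd.DataFrame(rows)
        affinity_wide = affinity_long.pivot_table(
            index="subject_id", columns=["region", "cortex"], values="affinity", sort=False
        )
        affinity_wide.columns = [f"{r}@{c}" for r, c in affinity_wide.columns]
        affinity_wide = affinity_wide.loc[table["subject_id"]]
        aff_path = out / "affinity.csv"
        io.write_header(aff_path, {**meta, "stage": "community",
                                   "runs": config.community_runs},
                        affinity_wide, sep=",", index=True, float_format=io.FLOAT_FMT)
        log.stage("community", {"runs": config.community_runs}, [aff_path])

    # ---- stage 6: task GLM and laterality --------------------------------
    # activation stream: motion/outlier/nuisance regression only — the task
    # effect must stay in the signal here, unlike in the connectivity stream
    table["li"] = np.nan
    table["dominance"] = pd.Series("", index=table.index, dtype=object)
    betas = {}
    for sid in table["subject_id"]:
        s = cohort.subjects[sid]
        flags = prep.detect_outlier_frames(
            s.series, s.motion, config.z_thresh, config.motion_thresh_mm
        )
        confounds = prep.build_confound_table(s.motion, flags, design=None,
                                              nuisance=s.nuisance)
        glm_series = prep.regress_confounds(s.series, confounds)
        glm = taskglm.fit_glm(glm_series, cohort.design)
        betas[sid] = glm["beta"]
        li = taskglm.laterality_index(
            glm["t"], regions, config.li_mask, config.li_threshold
        )
        table.loc[sid, "li"] = li.li
        table.loc[sid, "dominance"] = li.dominance
    beta_table = pd.DataFrame(betas).T.loc[table["subject_id"]]
    table_path = out / "subjects.csv"
    io.write_header(table_path, {**meta, "stage": "taskglm"}, table, sep=",", index=False,
                    float_format=io.FLOAT_FMT)
    log.stage("taskglm", {"mask": config.li_mask, "threshold": config.li_threshold},
              [table_path])

    # ---- stage 7: group statistics ---------------------------------------
    groups = table["group"]
    cov = groupstats.encode_covariates(table, config.covariates)
    families = {
        "edges": edges,
        "dc_auc": dc_auc_roi.rename(columns=lambda c: f"dc:{c}"),
        "activation": beta_table.rename(columns=lambda c: f"act:{c}"),
    }
    if affinity_wide is not None:
        families["affinity"] = affinity_wide
    stat_results = {}
    stat_paths = []
    for family, feats in families.items():
        res = groupstats.group_comparison(feats, groups, cov, config.alpha)
        stat_results[family] = res
        om_path = out / f"stats_{family}.csv"
        io.write_header(om_path, {**meta, "family": family, "alpha": config.alpha},
                        res["omnibus"], sep=",", index=True, float_format="%.10g")
        ph_path = out / f"posthoc_{family}.csv"
        io.write_header(ph_path, {**meta, "family": family}, res["posthoc"], sep=",",
                        index=False, float_format="%.10g")
        stat_paths += [om_path, ph_path]

    # HC-standardised scores and partial correlations
    hc_ids = table.loc[table["group"] == "HC", "subject_id"]
    score_cols = [c for c in ("vfc", "vfp", "vfs") if c in table.columns]
    for c in score_cols:
        table[f"{c}_z"] = groupstats.standardize_scores(table[c], hc_ids)
    corr_rows = []
    for g in sorted(groups.unique()):
        sub = table[table["group"] == g]
        cov_g = cov.loc[sub.index]
        cov_g = cov_g.loc[:, cov_g.std() > 0]
        for other in ("vfp", "vfs"):
            if "vfc" in sub.columns and other in sub.columns:
                try:
                    r, p = groupstats.partial_correlation(
                        sub["vfc_z"], sub[f"{other}_z"], cov_g
                    )
                except ValueError as exc:  # group too small for the covariate set
                    logger.warning("skipping correlation in %s: %s", g, exc)
                    continue
                corr_rows.append({"group": g, "x": "vfc", "y": other, "r": r, "p": p})
    # language scores against the significant edge features, across all subjects
    sig_edges = list(stat_results["edges"]["omnibus"].query("reject").index)[:20]
    for feat in sig_edges:
        for score in score_cols:
            r, p = groupstats.partial_correlation(edges[feat], table[score + "_z"], cov)
            corr_rows.append({"group": "all", "x": feat, "y": score, "r": r, "p": p})
    corr = pd.DataFrame(corr_rows)
    if len(corr):
        corr["q"] = np.nan
        for key, idx in corr.groupby("x").groups.items():
            corr.loc[idx, "q"] = groupstats.fdr_bh(corr.loc[idx, "p"], config.alpha)[0]
    corr_path = out / "correlations.csv"
    io.write_header(corr_path, {**meta, "stage": "correlations"}, corr, sep=",", index=False,
                    float_format="%.10g")
    log.stage("groupstats", {"alpha": config.alpha,
                             "families": ",".join(families)}, stat_paths + [corr_path])

    # ---- stage 8: classification -----------------------------------------
    classification = None
    if config.with_classification:
        g_a, g_b = config.classify_groups
        mask = groups.isin([g_a, g_b]).to_numpy()
        labels = (groups[mask] == g_a).astype(int).to_numpy()
        # candidate features: FDR-surviving functional statistics (+ scores)
        candidates = []
        for family, feats in families.items():
            surv = stat_results[family]["omnibus"].query("reject")
            ranked = surv.sort_values(["q", "p"]).index
            candidates.append(feats.loc[table["subject_id"], ranked])
        feat_all = pd.concat(candidates, axis=1)
        feat_all = feat_all.iloc[:, : config.max_classifier_features]
        feat_all = pd.concat(
            [feat_all.reset_index(drop=True),
             table[score_cols].reset_index(drop=True)], axis=1
        )
        feat_ab = feat_all[mask].reset_index(drop=True)
        stepwise = clf.ForwardStepwiseLogistic(p_enter=config.p_enter)
        stepwise.fit(feat_ab, labels)
        insample_auc = clf.roc_auc(stepwise.decision_function(feat_ab), labels)
        nn = clf.StepwiseNN(p_enter=config.p_enter, hidden_units=config.hidden_units,
                            random_state=_derive_seed(config.seed, "nn"))
        split = clf.evaluate_repeated_split(
            feat_ab, labels, nn, config.train_frac, config.repetitions,
            master_seed=_derive_seed(config.seed, "splits"),
        )
        classification = {
            "groups": [g_a, g_b],
            "n_candidates": int(feat_all.shape[1]),
            "selected_features": stepwise.selected_features_,
            "selection_path": [
                {"feature": s.feature, "statistic": s.statistic, "p": s.p}
                for s in stepwise.steps_
            ],
            "separated": bool(stepwise.separated_),
            "logistic_insample_auc": insample_auc,
            "nn_split_mean_auc": split.mean_auc,
            "nn_split_ci95": list(split.ci95),
            "repetitions": split.repetitions,
        }
        clf_path = out / "classification.json"
        io.write_json(clf_path, {**meta, **classification})
        log.stage("classify", {"reps": config.repetitions}, [clf_path])

    # ---- summary ----------------------------------------------------------
    summary = {
        **meta,
        "n_subjects": int(len(table)),
        "n_regions": int(len(regions)),
        "rois": rois,
        "n_edge_features": int(edges.shape[1]),
        "n_densities": int(len(grid)),
        "significant_edges": int(stat_results["edges"]["omnibus"]["reject"].sum()),
        "significant_dc_auc": int(stat_results["dc_auc"]["omnibus"]["reject"].sum()),
        "dominance_counts": {
            g: table.loc[table["group"] == g, "dominance"].value_counts().to_dict()
            for g in sorted(groups.unique())
        },
    }
    if affinity_wide is not None:
        summary["significant_affinity"] = int(
            stat_results["affinity"]["omnibus"]["reject"].sum()
        )
    if classification is not None:
        summary["classification"] = classification
    io.write_json(out / "summary.json", summary)
    log.stage("summary", {}, [out / "summary.json"])
    log.write(out / "pipeline.log")

    return {
        "cohort": cohort,
        "table": table,
        "edges": edges,
        "dc_auc": dc_auc_roi,
        "affinity": affinity_wide,
        "stats": stat_results,
        "correlations": corr,
        "classification": classification,
        "summary": summary,
    }
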