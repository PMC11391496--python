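"""Covariate-adjusted group comparison, FDR control, HC-standardisation,
and partial correlation.

The omnibus test per feature is a one-way ANCOVA: the feature is
regressed on group indicators plus the covariates (age, sex indicator,
education, MoCA), and the group block is F-tested against the reduced
model with covariates only. With no covariates this is exactly one-way
ANOVA. Post hoc pairwise comparisons contrast the adjusted group means
from the full model. Multiplicity is controlled per declared family by
Benjamini-Hochberg FDR at alpha = 0.05.

All linear algebra is vectorised across feature columns so that
mass-univariate families (hundreds of edges) and Monte-Carlo calibration
stay cheap; agreement with the reference implementations (statsmodels
OLS/ANOVA) is checked in the test suite.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ancova",
    "posthoc_pairwise",
    "group_comparison",
    "fdr_bh",
    "standardize_scores",
    "partial_correlation",
    "encode_covariates",
]

DEFAULT_ALPHA = 0.05
DEFAULT_COVARIATES = ("age", "sex", "education", "moca")


def encode_covariates(table: pd.DataFrame, columns=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Numeric covariate matrix; the sex column becomes a 0/1 indicator (male = 1)."""
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    cov = table.loc[:, list(columns)].copy()
    if "sex" in cov.columns and cov["sex"].dtype == object:
        cov["sex"] = (cov["sex"] == "male").astype(float)
    return cov.astype(float)


def _design(groups: pd.Series, covariates: pd.DataFrame | None):
    """Full/reduced design matrices for the group-block F test."""
    groups = pd.Series(groups).astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs n >= 2")
    n = len(groups)
    dummies = np.column_stack([(groups == g).to_numpy(float) for g in levels[1:]])
    parts = [np.ones((n, 1))]
    names = ["intercept"]
    if covariates is not None and covariates.shape[1] > 0:
        C = covariates.to_numpy(dtype=float)
        if C.shape[0] != n:
            raise ValueError("covariate table length mismatch")
        keep: list[int] = []
        base = np.ones((n, 1))
        for j in range(C.shape[1]):
            cand = np.column_stack([base, C[:, keep + [j]]])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                keep.append(j)
            else:
                logger.warning("dropping collinear covariate %r", covariates.columns[j])
        C = C[:, keep]
        parts.append(C)
        names += [covariates.columns[k] for k in keep]
    X_red = np.column_stack(parts)
    X_full = np.column_stack([X_red[:, :1], dummies, X_red[:, 1:]])
    names_full = ["intercept"] + [f"group[{g}]" for g in levels[1:]] + names[1:]
    return X_full, X_red, levels, names_full


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid**2).sum(axis=0), beta


def ancova(
    feature: pd.Series | pd.DataFrame | np.ndarray,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Omnibus group F test adjusting for covariates; vectorised over features.

    Returns a table with one row per feature: ``F``, ``p`` and the
    adjusted mean per group (fitted value at the covariate means). A
    feature with zero residual variation in both models is reported as
    F = 0, p = 1 by convention.
    """
    Y = np.atleast_2d(np.asarray(feature, dtype=float).T).T
    if isinstance(feature, pd.DataFrame):
        feat_names = list(feature.columns)
    elif isinstance(feature, pd.Series):
        feat_names = [feature.name or "feature"]
    else:
        feat_names = [f"f{i}" for i in range(Y.shape[1])]
    X_full, X_red, levels, names_full = _design(groups, covariates)
    n, p_full = X_full.shape
    df1 = len(levels) - 1
    df2 = n - p_full
    if df2 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    rss_f, beta_f = _rss(X_full, Y)
    rss_r, _ = _rss(X_red, Y)
    # a feature with no residual variation in either model is null by convention
    degenerate = rss_r <= 1e-12 * np.maximum(1.0, (Y**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    bad = degenerate | ~np.isfinite(F)
    F = np.where(bad, 0.0, F)
    p = np.where(bad, 1.0, stats.f.sf(F, df1, df2))
    # adjusted means: fitted value per group at the covariate means
    cov_part = np.zeros(Y.shape[1])
    if X_full.shape[1] > 1 + df1:
        cov_means = X_full[:, 1 + df1 :].mean(axis=0)
        cov_part = cov_means @ beta_f[1 + df1 :]
    out = pd.DataFrame({"F": F, "p": p}, index=feat_names)
    for gi, g in enumerate(levels):
        mean_g = beta_f[0] + cov_part + (beta_f[gi] if gi >= 1 else 0.0)
        out[f"adjmean[{g}]"] = mean_g
    out.attrs["df"] = (df1, df2)
    out.attrs["levels"] = levels
    return out


def posthoc_pairwise(
    feature: pd.Series | pd.DataFrame | np.ndarray,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise contrasts of adjusted means from the full ANCOVA model.

    One row per (feature, pair): adjusted mean difference (a - b), t with
    the full-model residual dof, and a two-sided p. With exactly two
    groups the pairwise p equals the omnibus p (F = t^2).
    """
    Y = np.atleast_2d(np.asarray(feature, dtype=float).T).T
    feat_names = (
        list(feature.columns)
        if isinstance(feature, pd.DataFrame)
        else [getattr(feature, "name", None) or "feature"]
        if Y.shape[1] == 1
        else [f"f{i}" for i in range(Y.shape[1])]
    )
    X, _, levels, _ = _design(groups, covariates)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    for a, b in pairs:
        if a not in levels or b not in levels:
            raise ValueError(f"unknown pair ({a!r}, {b!r}); groups: {levels}")
    n, p_dim = X.shape
    dof = n - p_dim
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)

    def dummy_vec(g: str) -> np.ndarray:
        v = np.zeros(p_dim)
        gi = levels.index(g)
        if gi >= 1:
            v[gi] = 1.0
        return v

    rows = []
    for a, b in pairs:
        c = dummy_vec(a) - dummy_vec(b)
        diff = c @ beta
        se = np.sqrt(sigma2 * (c @ xtx_inv @ c))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = diff / se
        p = 2 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), dof)
        p = np.where(np.isfinite(t), p, 1.0)
        t = np.where(np.isfinite(t), t, 0.0)
        for fi, fname in enumerate(feat_names):
            rows.append(
                {
                    "feature": fname,
                    "group_a": a,
                    "group_b": b,
                    "diff": diff[fi],
                    "t": t[fi],
                    "p": p[fi],
                }
            )
    return pd.DataFrame(rows)


def fdr_bh(pvalues, alpha: float = DEFAULT_ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q-values, rejection flags at q < alpha)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha


def group_comparison(
    features: pd.DataFrame,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = DEFAULT_ALPHA,
    posthoc_on: str = "fdr",
) -> dict[str, pd.DataFrame]:
    """One FDR family of features: omnibus ANCOVA + BH, then post hoc pairs.

    ``posthoc_on``: ``"fdr"`` (default) restricts post hoc tests to
    features whose omnibus q survives alpha; ``"all"`` tests every
    feature. Pairwise p-values are themselves BH-corrected across the
    tested features within each pair.
    """
    omnibus = ancova(features, groups, covariates)
    omnibus["q"], omnibus["reject"] = fdr_bh(omnibus["p"], alpha)
    if posthoc_on == "all":
        selected = list(features.columns)
    elif posthoc_on == "fdr":
        selected = list(omnibus.index[omnibus["reject"]])
    else:
        raise ValueError("posthoc_on must be 'fdr' or 'all'")
    if selected:
        ph = posthoc_pairwise(features[selected], groups, covariates)
        qs = np.full(len(ph), np.nan)
        for (_, _), idx in ph.groupby(["group_a", "group_b"]).groups.items():
            qs[np.asarray(idx)] = fdr_bh(ph.loc[idx, "p"], alpha)[0]
        ph["q"] = qs
        ph["reject"] = ph["q"] < alpha
    else:
        ph = pd.DataFrame(
            columns=["feature", "group_a", "group_b", "diff", "t", "p", "q", "reject"]
        )
    return {"omnibus": omnibus, "posthoc": ph}


def standardize_scores(scores: pd.Series, reference_ids) -> pd.Series:
    """z-score every subject against the reference (healthy-control) subjects.

    z = (x - mean_ref) / sd_ref with the n-1 SD denominator.
    """
    ref = scores.loc[reference_ids]
    sd = ref.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("reference SD is zero; cannot standardise")
    return (scores - ref.mean()) / sd


def partial_correlation(
    x, y, covariates: pd.DataFrame | np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after removing the covariates by OLS.

    Returns (r, p) with p from the t distribution at n - 2 - k degrees of
    freedom. With no covariates this is plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        k = 0
        rx, ry = x - x.mean(), y - y.mean()
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        k = C.shape[1]
        if n <= k + 3:
            raise ValueError("need n > number of covariates + 3")
        X = np.column_stack([np.ones(n), C])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("degenerate residuals; correlation undefined")
    r = float(np.dot(rx, ry) / (n * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    dof = n - 2 - k
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(dof / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), dof)) if abs(r) < 1 else 0.0
    return r, p
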