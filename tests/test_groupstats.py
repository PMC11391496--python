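"""Covariate-adjusted group statistics, FDR, standardisation, partial correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import null_covariates
from vfnet.groupstats import (
    ancova,
    encode_covariates,
    fdr_bh,
    group_comparison,
    partial_correlation,
    posthoc_pairwise,
    standardize_scores,
)


def _groups(sizes=(10, 10, 10)):
    return pd.Series(
        np.repeat([f"g{i}" for i in range(len(sizes))], sizes).tolist()
    )


class TestAncova:
    def test_no_covariates_equals_anova_oracle(self, rng):
        g = _groups((12, 15, 9))
        y = pd.Series(rng.normal(0, 1, len(g)) + (g == "g1") * 0.8)
        res = ancova(y, g)
        F_oracle, p_oracle = stats.f_oneway(y[g == "g0"], y[g == "g1"], y[g == "g2"])
        assert res["F"].iloc[0] == pytest.approx(F_oracle, abs=1e-8)
        assert res["p"].iloc[0] == pytest.approx(p_oracle, abs=1e-8)

    def test_matches_statsmodels_with_covariates(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        g = _groups((10, 11, 12))
        cov = null_covariates(rng, len(g))
        y = rng.normal(0, 1, len(g)) + 0.05 * cov["age"] + (g == "g2") * 0.5
        res = ancova(pd.Series(y), g, cov)
        df = cov.assign(y=y, group=g.values)
        fit = smf.ols("y ~ C(group) + age + sex + education + moca", df).fit()
        tab = anova_lm(
            smf.ols("y ~ age + sex + education + moca", df).fit(), fit
        )
        assert res["F"].iloc[0] == pytest.approx(tab["F"].iloc[1], abs=1e-8)
        assert res["p"].iloc[0] == pytest.approx(tab["Pr(>F)"].iloc[1], abs=1e-8)

    def test_constant_feature_reported_as_null(self):
        g = _groups((5, 5))
        res = ancova(pd.Series(np.ones(10)), g)
        assert res["F"].iloc[0] == 0.0 and res["p"].iloc[0] == 1.0

    def test_null_rejection_rate_calibrated(self, rng):
        """Monte-Carlo: omnibus test rejects ~5% under the null."""
        g = _groups((10, 10, 10))
        reps = 400
        Y = pd.DataFrame(rng.normal(0, 1, (len(g), reps)))
        cov = null_covariates(rng, len(g))
        res = ancova(Y, g, cov)
        rate = (res["p"] < 0.05).mean()
        assert 0.025 < rate < 0.075

    def test_collinear_covariate_dropped(self, rng):
        g = _groups((8, 8))
        y = pd.Series(rng.normal(0, 1, 16))
        cov = pd.DataFrame({"a": rng.normal(0, 1, 16)})
        cov["b"] = 2 * cov["a"]
        res = ancova(y, g, cov)
        assert np.isfinite(res["F"].iloc[0])

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            ancova(pd.Series([1.0, 2.0, 3.0]), pd.Series(["a", "a", "b"]))


class TestPosthoc:
    def test_two_groups_pairwise_equals_omnibus(self, rng):
        g = _groups((12, 12))
        y = pd.Series(rng.normal(0, 1, 24) + (g == "g1") * 0.7)
        cov = null_covariates(rng, 24)
        om = ancova(y, g, cov)
        ph = posthoc_pairwise(y, g, cov)
        assert ph["t"].iloc[0] ** 2 == pytest.approx(om["F"].iloc[0], abs=1e-8)
        assert ph["p"].iloc[0] == pytest.approx(om["p"].iloc[0], abs=1e-8)

    def test_pair_order_flips_sign_same_p(self, rng):
        g = _groups((10, 10, 10))
        y = pd.Series(rng.normal(0, 1, 30) + (g == "g0") * 1.0)
        a = posthoc_pairwise(y, g, pairs=[("g0", "g1")])
        b = posthoc_pairwise(y, g, pairs=[("g1", "g0")])
        assert a["diff"].iloc[0] == pytest.approx(-b["diff"].iloc[0])
        assert a["p"].iloc[0] == pytest.approx(b["p"].iloc[0])

    def test_large_shift_always_detected(self, rng):
        hits = 0
        for rep in range(30):
            r = np.random.default_rng(rep)
            g = _groups((30, 30))
            y = pd.Series(r.normal(0, 1, 60) + (g == "g1") * 2.0)  # 2 SD shift
            ph = posthoc_pairwise(y, g)
            hits += ph["p"].iloc[0] < 0.001
        assert hits / 30 > 0.95

    def test_unknown_pair_rejected(self, rng):
        g = _groups((5, 5))
        with pytest.raises(ValueError, match="unknown pair"):
            posthoc_pairwise(pd.Series(rng.normal(0, 1, 10)), g, pairs=[("g0", "gX")])


class TestFdr:
    def test_step_up_enumeration_example(self):
        q, reject = fdr_bh([0.01, 0.02, 0.03, 0.5], alpha=0.05)
        assert reject.sum() == 3
        assert reject.tolist() == [True, True, True, False]

    def test_all_ones_no_rejection(self):
        q, reject = fdr_bh(np.ones(10), alpha=0.05)
        assert not reject.any() and (q == 1).all()

    def test_single_small_p(self):
        q, reject = fdr_bh([0.04], alpha=0.05)
        assert reject[0] and q[0] == pytest.approx(0.04)

    def test_empty_input(self):
        q, reject = fdr_bh([], alpha=0.05)
        assert len(q) == 0 and len(reject) == 0

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(0, 1, 50)
        q, _ = fdr_bh(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestStandardize:
    def test_reference_moments(self, rng):
        scores = pd.Series(rng.normal(20, 4, 40), index=[f"s{i}" for i in range(40)])
        hc = [f"s{i}" for i in range(15)]
        z = standardize_scores(scores, hc)
        assert z.loc[hc].mean() == pytest.approx(0.0, abs=1e-12)
        assert z.loc[hc].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        one_above = scores.loc[hc].mean() + scores.loc[hc].std(ddof=1)
        assert (one_above - scores.loc[hc].mean()) / scores.loc[hc].std(ddof=1) == 1.0

    def test_zero_reference_sd_rejected(self):
        s = pd.Series([1.0, 1.0, 5.0], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            standardize_scores(s, ["a", "b"])


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x = rng.normal(0, 1, 60)
        y = x + rng.normal(0, 1, 60)
        r, p = partial_correlation(x, y)
        r_o, p_o = stats.pearsonr(x, y)
        assert r == pytest.approx(r_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-8)

    def test_shared_covariate_removed(self, rng):
        z = rng.normal(0, 1, 500)
        x = z + rng.normal(0, 1, 500)
        y = z + rng.normal(0, 1, 500)
        r, _ = partial_correlation(x, y, z)
        assert abs(r) < 0.1

    def test_first_order_closed_form(self, rng):
        x, y, z = rng.normal(0, 1, (3, 200))
        x = x + 0.5 * z
        y = y - 0.3 * z + 0.2 * x
        r, _ = partial_correlation(x, y, z)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        oracle = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation([1, 2, 3], [1, 2, 3], np.ones((3, 2)))


def test_group_comparison_family_pipeline(rng):
    g = _groups((15, 15, 15))
    cov = null_covariates(rng, 45)
    feats = pd.DataFrame(rng.normal(0, 1, (45, 20)),
                         columns=[f"e{i}" for i in range(20)])
    feats["e0"] += (g == "g0") * 2.0  # one real effect
    res = group_comparison(feats, g, cov, alpha=0.05)
    om = res["omnibus"]
    assert om.loc["e0", "reject"]
    assert (om["q"] >= om["p"] - 1e-12).all()
    # post hoc rows exist only for FDR-surviving features
    assert set(res["posthoc"]["feature"]) == set(om.index[om["reject"]])


def test_encode_covariates_sex_indicator():
    t = pd.DataFrame({"age": [30, 40], "sex": ["male", "female"],
                      "education": [12, 16], "moca": [27, 28]})
    cov = encode_covariates(t)
    assert cov["sex"].tolist() == [1.0, 0.0]
    with pytest.raises(ValueError, match="missing covariate"):
        encode_covariates(t.drop(columns=["moca"]))
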