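"""Robust linear factor models and pairwise rank-sum comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from manateebci import (
    RankDeficientError,
    fit_robust_linear,
    pairwise_wilcoxon,
)


def scores_frame(values, groups, **extra_cols):
    frame = pd.DataFrame({"score": values, "location": groups})
    frame["model"] = "bci1"
    for k, v in extra_cols.items():
        frame[k] = v
    return frame


def enumeration_p(x, y):
    """Oracle: exact two-sided rank-sum p by enumerating every assignment
    of the pooled values to the first group."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx, n = len(x), len(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for comb in itertools.combinations(range(n), nx):
        us.append(ranks[list(comb)].sum() - nx * (nx + 1) / 2)
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestPairwiseWilcoxon:
    def test_identical_groups_give_adjusted_p_one(self):
        frame = scores_frame([1, 2, 3, 4] * 2, ["a"] * 4 + ["b"] * 4)
        pw = pairwise_wilcoxon(frame, group_by="location")
        assert pw.adjusted_p.loc["a", "b"] == 1.0

    def test_fully_separated_small_groups_exact_p(self):
        frame = scores_frame([1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
                             ["a"] * 5 + ["b"] * 5)
        pw = pairwise_wilcoxon(frame, group_by="location", adjust="none")
        assert pw.raw_p.loc["a", "b"] == pytest.approx(2 / 252)
        assert pw.pair_methods[("a", "b")] == "exact"

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for n1, n2 in [(2, 5), (3, 3), (4, 6), (5, 7), (7, 7)]:
            x = rng.normal(size=n1)
            y = rng.normal(loc=0.8, size=n2)
            frame = scores_frame(np.concatenate([x, y]),
                                 ["a"] * n1 + ["b"] * n2)
            pw = pairwise_wilcoxon(frame, group_by="location", adjust="none")
            assert pw.raw_p.loc["a", "b"] == pytest.approx(
                enumeration_p(x, y), abs=1e-12)

    def test_bonferroni_is_m_times_raw_capped(self):
        rng = np.random.default_rng(1)
        groups = [g for g in "abcdefg" for _ in range(8)]
        frame = scores_frame(rng.normal(size=len(groups)), groups)
        pw = pairwise_wilcoxon(frame, group_by="location")
        assert pw.n_pairs == 21  # 7 localities -> 21 pairs
        expected = (pw.raw_p * 21).clip(upper=1.0)
        off_diag = ~np.eye(7, dtype=bool)
        assert np.allclose(pw.adjusted_p.values[off_diag],
                           expected.values[off_diag])
        assert (pw.adjusted_p.values >= pw.raw_p.values - 1e-15).all()

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        groups = ["a"] * 15 + ["b"] * 20 + ["c"] * 12
        vals = rng.normal(size=len(groups))
        p1 = pairwise_wilcoxon(scores_frame(vals, groups),
                               group_by="location").raw_p
        p2 = pairwise_wilcoxon(scores_frame(np.exp(3 * vals), groups),
                               group_by="location").raw_p
        assert np.allclose(p1.values, p2.values, equal_nan=True)

    def test_exact_and_normal_paths_agree_at_n10(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(loc=0.5, size=10)
            exact = stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact").pvalue
            approx = stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method="asymptotic",
                                        use_continuity=True).pvalue
            assert abs(exact - approx) < 0.01

    def test_small_group_excluded_with_warning(self):
        frame = scores_frame([1, 2, 3, 4, 5, 9], ["a"] * 3 + ["b"] * 2 + ["c"])
        with pytest.warns(UserWarning, match="c"):
            pw = pairwise_wilcoxon(frame, group_by="location")
        assert pw.groups == ["a", "b"]

    def test_matrices_symmetric(self):
        rng = np.random.default_rng(2)
        groups = ["a"] * 12 + ["b"] * 14 + ["c"] * 9
        pw = pairwise_wilcoxon(scores_frame(rng.normal(size=len(groups)),
                                            groups), group_by="location")
        assert np.allclose(pw.raw_p.values, pw.raw_p.values.T)
        assert np.allclose(pw.adjusted_p.values, pw.adjusted_p.values.T)


class TestRobustLinearFit:
    @staticmethod
    def synth_scores(rng, n=400, habitat_effect=-0.07, sex_effect=0.0,
                     sigma=0.05):
        habitat = rng.choice(["coastal", "riverine"], size=n)
        sex = rng.choice(["F", "M"], size=n)
        score = (0.76 + habitat_effect * (habitat == "riverine")
                 + sex_effect * (sex == "M") + rng.normal(0, sigma, n))
        return pd.DataFrame({"score": score, "habitat": habitat, "sex": sex,
                             "condition_group": "ideal", "model": "bci1"})

    def test_recovers_habitat_effect_and_null_sex_effect(self):
        rng = np.random.default_rng(12)
        res = fit_robust_linear(self.synth_scores(rng),
                                terms=("habitat", "sex"))
        h = res.params["habitat[riverine]"]
        assert abs(h - (-0.07)) < 2 * res.bse["habitat[riverine]"]
        s = res.params["sex[M]"]
        assert abs(s) < 2 * res.bse["sex[M]"]

    def test_matches_ols_on_clean_gaussian_data(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        frame = self.synth_scores(rng)
        res = fit_robust_linear(frame, terms=("habitat", "sex"))
        X = np.column_stack([
            np.ones(len(frame)),
            (frame["habitat"] == "riverine").astype(float),
            (frame["sex"] == "M").astype(float)])
        ols = sm.OLS(frame["score"].to_numpy(), X).fit()
        for i, name in enumerate(res.params.index):
            combined = np.hypot(res.bse[name], ols.bse[i])
            assert abs(res.params[name] - ols.params[i]) < 2 * combined

    def test_thin_group_offset_negative_and_significant(self):
        rng = np.random.default_rng(9)
        n = 300
        group = rng.choice(["ideal", "thin", "obese"], size=n,
                           p=[0.8, 0.1, 0.1])
        score = 0.76 - 0.06 * (group == "thin") + rng.normal(0, 0.05, n)
        frame = pd.DataFrame({"score": score, "condition_group": group,
                              "habitat": rng.choice(["coastal", "riverine"], n),
                              "model": "bci1"})
        res = fit_robust_linear(frame, terms=("habitat", "field_condition"))
        assert res.model.reference_levels["field_condition"] == "ideal"
        assert res.params["field_condition[thin]"] < 0
        assert res.pvalues["field_condition[thin]"] < 0.05

    def test_identical_scores_degenerate_without_division_error(self):
        frame = pd.DataFrame({
            "score": 0.76, "habitat": ["coastal", "riverine"] * 10,
            "sex": ["F", "F", "M", "M"] * 5, "condition_group": "ideal",
            "model": "bci1"}, index=range(20))
        res = fit_robust_linear(frame, terms=("habitat", "sex"))
        assert res.scale == 0.0
        assert np.allclose(res.params[1:], 0.0, atol=1e-12)
        assert res.pvalues.isna().all()

    def test_aliased_terms_raise_named_rank_deficiency(self):
        rng = np.random.default_rng(4)
        n = 60
        habitat = rng.choice(["coastal", "riverine"], size=n)
        country = np.where(habitat == "coastal", "Belize", "Colombia")
        frame = pd.DataFrame({"score": rng.normal(0.7, 0.05, n),
                              "habitat": habitat, "country": country,
                              "condition_group": "ideal", "model": "bci1"})
        with pytest.raises(RankDeficientError):
            fit_robust_linear(frame, terms=("country", "habitat"))

    def test_seeded_fit_reproducible(self):
        rng = np.random.default_rng(6)
        frame = self.synth_scores(rng, n=150)
        a = fit_robust_linear(frame, seed=123)
        b = fit_robust_linear(frame, seed=123)
        assert np.array_equal(a.params.to_numpy(), b.params.to_numpy())

    def test_resists_outlier_contamination(self):
        rng = np.random.default_rng(15)
        frame = self.synth_scores(rng, n=300)
        contaminated = frame.copy()
        idx = rng.choice(300, size=30, replace=False)
        contaminated.loc[idx, "score"] += 1.0  # gross shift
        clean = fit_robust_linear(frame, terms=("habitat", "sex"))
        dirty = fit_robust_linear(contaminated, terms=("habitat", "sex"))
        assert abs(dirty.params["habitat[riverine]"]
                   - clean.params["habitat[riverine]"]) < 0.02
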