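"""Univariate statistics: ANOVA decomposition, ranking, mixed regressions."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mycotraits.lmm import fit_lmm, indicator_matrix
from mycotraits.stats import (TRAITS, all_pairwise_tests, factorial_anova,
                              pairwise_trait_regression, rank_transform,
                              taxonomy_variance, trait_matrix)


class TestRankTransform:
    def test_tie_convention(self):
        assert rank_transform([3.1, 2.0, 2.0, 10]).tolist() == \
            [3.0, 1.5, 1.5, 4.0]

    def test_increasing_is_identity(self):
        assert rank_transform([0.1, 0.5, 2.0, 7.0]).tolist() == \
            [1.0, 2.0, 3.0, 4.0]

    def test_missing_preserved(self):
        out = rank_transform([5.0, np.nan, 1.0])
        assert np.isnan(out[1]) and out[0] == 2.0 and out[2] == 1.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            rank_transform([np.nan, np.nan])

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=2,
                    max_size=30, unique=True))
    @settings(max_examples=100, deadline=None)
    def test_idempotent_without_ties(self, values):
        once = rank_transform(values)
        assert rank_transform(once).tolist() == once.tolist()


def _anova_oracle(y, a, b):
    """Independent least-squares oracle: sequential orthogonal projections
    (exact for balanced layouts)."""
    def proj(M):
        q, _ = np.linalg.qr(M)
        return q @ q.T
    n = len(y)
    P1 = proj(np.ones((n, 1)))
    PA = proj(indicator_matrix(a))
    PB = proj(indicator_matrix(b))
    cells = pd.factorize(pd.Series(a).astype(str) + "|"
                         + pd.Series(b).astype(str))[0]
    PAB = proj(indicator_matrix(cells))
    ss = {
        "A": y @ (PA - P1) @ y,
        "B": y @ (PB - P1) @ y,
        "AB": y @ (PAB - PA - PB + P1) @ y,
        "resid": y @ (np.eye(n) - PAB) @ y,
    }
    na, nb = len(np.unique(a)), len(np.unique(b))
    df = {"A": na - 1, "B": nb - 1, "AB": (na - 1) * (nb - 1),
          "resid": n - na * nb}
    ms = {k: ss[k] / df[k] for k in ss}
    f = {k: ms[k] / ms["resid"] for k in ("A", "B", "AB")}
    return ss, df, f


class TestFactorialAnova:
    def test_study_design_dfs(self, default_derived):
        """The balanced 15 x 3 x 2 layout gives term dfs 2/14/28 and
        residual df 45."""
        tab = factorial_anova(default_derived.traits, "growth_yield_m_per_g")
        assert tab.loc["moisture_whc", "df"] == 2
        assert tab.loc["isolate_id", "df"] == 14
        assert tab.loc["moisture_whc x isolate_id", "df"] == 28
        assert tab.loc["residual", "df"] == 45
        assert tab["df"].sum() == 90 - 1

    @pytest.mark.parametrize("seed,na,nb,reps", [
        (0, 2, 2, 2), (1, 2, 2, 2), (2, 3, 4, 2), (3, 5, 2, 3),
    ])
    def test_matches_projection_oracle(self, seed, na, nb, reps):
        rng = np.random.default_rng(seed)
        a = np.repeat(np.arange(na), nb * reps)
        b = np.tile(np.repeat(np.arange(nb), reps), na)
        y = rng.standard_normal(len(a))
        data = pd.DataFrame({"y": y, "A": a, "B": b})
        tab = factorial_anova(data, "y", "A", "B")
        ss, df, f = _anova_oracle(y, a, b)
        assert tab.loc["A", "sum_sq"] == pytest.approx(ss["A"], abs=1e-10)
        assert tab.loc["B", "sum_sq"] == pytest.approx(ss["B"], abs=1e-10)
        assert tab.loc["A x B", "sum_sq"] == pytest.approx(ss["AB"],
                                                           abs=1e-10)
        assert tab.loc["residual", "sum_sq"] == pytest.approx(ss["resid"],
                                                              abs=1e-10)
        assert tab.loc["A", "F"] == pytest.approx(f["A"], rel=1e-10)
        assert tab.loc["A x B", "F"] == pytest.approx(f["AB"], rel=1e-10)

    def test_ss_decomposition_exact(self, default_derived):
        tab = factorial_anova(default_derived.traits, "activity_NAG")
        y = default_derived.traits["activity_NAG"].dropna()
        total = ((y - y.mean()) ** 2).sum()
        assert tab["sum_sq"].sum() == pytest.approx(total, rel=1e-8)

    def test_constant_response_degenerate(self):
        data = pd.DataFrame({"y": 3.0, "A": [0, 0, 1, 1] * 2,
                             "B": [0, 1, 0, 1] * 2})
        tab = factorial_anova(data, "y", "A", "B")
        assert (tab.loc[tab.index != "residual", "sum_sq"]
                < 1e-10).all()
        assert tab.loc[tab.index != "residual", "F"].isna().all()

    def test_single_level_factor_dropped(self):
        data = pd.DataFrame({"y": np.arange(6.0), "A": [0] * 6,
                             "B": [0, 0, 1, 1, 2, 2]})
        with pytest.warns(UserWarning, match="single level"):
            tab = factorial_anova(data, "y", "A", "B")
        assert "A" not in tab.index


class TestPairwiseRegression:
    def test_exact_affine_relationship_recovered(self, default_experiment):
        tax = default_experiment.taxonomy
        rng = np.random.default_rng(4)
        rows = []
        for iso in tax["isolate_id"]:
            for m in (0.04, 0.27, 0.50):
                x = rng.normal()
                rows.append({"isolate_id": iso, "moisture_whc": m,
                             "x": x, "y": 2.0 + 3.0 * x + 0.5 * m})
        data = pd.DataFrame(rows)
        res = pairwise_trait_regression(data, "y", "x", tax,
                                        rank_yield=False)
        assert res.slope == pytest.approx(3.0, rel=1e-6)
        assert res.pvalue < 1e-10

    def test_swap_symmetry_of_sign(self, default_experiment,
                                   default_derived):
        data = trait_matrix(default_derived.traits, default_derived.mai)
        tax = default_experiment.taxonomy
        fwd = pairwise_trait_regression(data, "BG", "CBH", tax)
        rev = pairwise_trait_regression(data, "CBH", "BG", tax)
        assert fwd.slope != rev.slope
        assert np.sign(fwd.tvalue) == np.sign(rev.tvalue)

    def test_rank_regression_monotone_invariant(self, default_experiment,
                                                default_derived):
        """Any strictly increasing transform of growth yield leaves its
        ranked regressions identical."""
        data = trait_matrix(default_derived.traits, default_derived.mai)
        tax = default_experiment.taxonomy
        base = pairwise_trait_regression(data, "BG", "growth_yield", tax,
                                         rank_yield=True)
        warped = data.copy()
        warped["growth_yield"] = np.exp(warped["growth_yield"] / 200.0)
        res = pairwise_trait_regression(warped, "BG", "growth_yield", tax,
                                        rank_yield=True)
        assert res.tvalue == pytest.approx(base.tvalue, rel=1e-9)
        assert res.pvalue == pytest.approx(base.pvalue, rel=1e-9)

    def test_sign_consistency(self, default_experiment, default_derived):
        data = trait_matrix(default_derived.traits, default_derived.mai)
        res = pairwise_trait_regression(data, "NAG", "BG",
                                        default_experiment.taxonomy)
        assert np.sign(res.tvalue) == np.sign(res.slope)


class TestAllPairwise:
    def test_fifteen_pairs(self, default_experiment, default_derived):
        out = all_pairwise_tests(default_derived.traits,
                                 default_derived.mai,
                                 default_experiment.taxonomy)
        assert len(out) == 15
        assert set(zip(out["trait_a"], out["trait_b"])) == {
            (a, b) for i, a in enumerate(TRAITS) for b in TRAITS[i + 1:]}

    def test_missing_trait_reported_untested(self, default_experiment,
                                             default_derived):
        traits = default_derived.traits.copy()
        traits["activity_BX"] = np.nan
        out = all_pairwise_tests(traits, default_derived.mai,
                                 default_experiment.taxonomy)
        bx = out[(out["trait_a"] == "BX") | (out["trait_b"] == "BX")]
        assert len(bx) == 5
        assert bx["p"].isna().all()
        assert (bx["model"] == "untested: trait missing").all()


class TestTaxonomyVariance:
    def test_pure_noise_has_no_taxonomic_signal(self, default_experiment):
        tax = default_experiment.taxonomy
        rng = np.random.default_rng(12)
        v = pd.Series(rng.standard_normal(15),
                      index=tax["isolate_id"])
        out = taxonomy_variance(v, tax).set_index("rank")
        assert out.loc["residual", "share_parsimonious"] == \
            pytest.approx(1.0, abs=0.35)
        assert (out.drop("residual")["p"].dropna() > 0.01).all()

    def test_shares_sum_to_one(self, default_experiment, default_derived):
        tax = default_experiment.taxonomy
        v = default_derived.mai.set_index("isolate_id")["mai_percent"]
        out = taxonomy_variance(v, tax)
        assert out["share"].sum() == pytest.approx(1.0, abs=1e-6)
        assert (out["share"] >= 0).all()

    def test_family_signal_recovered(self, default_experiment):
        tax = default_experiment.taxonomy
        fam_codes = pd.factorize(tax["family"])[0]
        rng = np.random.default_rng(3)
        eff = rng.standard_normal(fam_codes.max() + 1)
        v = pd.Series(eff[fam_codes] + 0.02 * rng.standard_normal(15),
                      index=tax["isolate_id"])
        out = taxonomy_variance(v, tax).set_index("rank")
        assert out.loc["family", "share_parsimonious"] > 0.8
        assert out.loc["family", "p"] < 0.05


def test_lmm_matches_statsmodels_mixedlm():
    """Cross-check the internal REML engine against statsmodels MixedLM
    on a single-grouping random-intercept model."""
    import statsmodels.formula.api as smf
    rng = np.random.default_rng(8)
    groups = np.repeat(np.arange(10), 4)
    u = rng.standard_normal(10)
    x = rng.standard_normal(40)
    y = 1.0 + 0.7 * x + u[groups] + 0.5 * rng.standard_normal(40)
    X = np.column_stack([np.ones(40), x])
    vc = fit_lmm(y, X, [indicator_matrix(groups)], reml=True)
    V = vc.theta[0] * np.eye(40) + vc.theta[1] * (
        indicator_matrix(groups) @ indicator_matrix(groups).T)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    se = np.sqrt(np.linalg.inv(X.T @ Vi @ X)[1, 1])

    df = pd.DataFrame({"y": y, "x": x, "g": groups})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sm_fit = smf.mixedlm("y ~ x", df, groups="g").fit(reml=True)
    assert beta[1] == pytest.approx(sm_fit.params["x"], rel=1e-4)
    assert se == pytest.approx(sm_fit.bse["x"], rel=1e-2)
    assert vc.theta[1] == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]),
                                        rel=1e-2)
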