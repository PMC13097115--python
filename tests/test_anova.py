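"""Unit and property tests for the Box-Cox / two-way ANOVA / LSD / FDR engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import balanced_design
from lipokine import anova
from lipokine.errors import DegenerateVarianceError, DesignError, DomainError

# ---------------------------------------------------------------------------
# fixture dataset: 2 obs/cell, 8 printed numbers
# ---------------------------------------------------------------------------
FIXTURE_VALUES = np.array([3.1, 4.9, 10.2, 12.8, 5.5, 6.5, 7.3, 9.7])
# order matches balanced_design(2): NoDx-White, Dx-White, NoDx-AA, Dx-AA


def brute_force_anova(y, race, disease):
    """Independent cell-means oracle for the balanced 2x2 decomposition."""
    cells = {}
    for r in ("White", "AA"):
        for d in ("NoDx", "Dx"):
            cells[(r, d)] = y[(race == r) & (disease == d)]
    n = len(next(iter(cells.values())))
    grand = y.mean()
    cm = {k: v.mean() for k, v in cells.items()}
    r_mean = {r: np.mean([cm[(r, "NoDx")], cm[(r, "Dx")]]) for r in ("White", "AA")}
    d_mean = {d: np.mean([cm[("White", d)], cm[("AA", d)]]) for d in ("NoDx", "Dx")}
    ss_race = 2 * n * sum((r_mean[r] - grand) ** 2 for r in r_mean)
    ss_dis = 2 * n * sum((d_mean[d] - grand) ** 2 for d in d_mean)
    ss_int = n * sum(
        (cm[(r, d)] - r_mean[r] - d_mean[d] + grand) ** 2 for r in r_mean for d in d_mean
    )
    ss_err = sum(((v - cm[k]) ** 2).sum() for k, v in cells.items())
    mse = ss_err / (4 * (n - 1))
    return {
        "ss_race": ss_race, "ss_disease": ss_dis, "ss_interaction": ss_int,
        "ss_error": ss_err, "mse": mse,
        "f_race": ss_race / mse, "f_disease": ss_dis / mse, "f_interaction": ss_int / mse,
        "omnibus_f": ((ss_race + ss_dis + ss_int) / 3) / mse,
        "cell_means": cm, "n": n,
    }


class TestBoxCox:
    def test_lambda_zero_is_log(self):
        fit = anova.BoxCoxFit(lambda_=0.0, shift=0.0, loglik=0.0, applied=True)
        out = anova.boxcox_transform(np.array([1.0, 2.0, 4.0]), fit)
        assert np.allclose(out, [0.0, np.log(2), np.log(4)])

    def test_lambda_one_is_affine(self):
        fit = anova.BoxCoxFit(lambda_=1.0, shift=0.0, loglik=0.0, applied=True)
        y = np.array([0.5, 3.0, 7.25])
        assert np.allclose(anova.boxcox_transform(y, fit), y - 1.0)

    def test_grid_oracle_lognormal(self):
        # 500 draws of exp(N(0,1)): lambda should be near 0, matching a
        # brute-force scipy-llf grid maximization at step 0.001
        rng = np.random.default_rng(7)
        y = np.exp(rng.standard_normal(500))
        fit = anova.boxcox_fit(y)
        assert -0.3 <= fit.lambda_ <= 0.3
        grid = np.arange(-1.0, 1.0, 0.001)
        ll = np.array([stats.boxcox_llf(l, y) for l in grid])
        lam_grid = grid[np.argmax(ll)]
        assert fit.lambda_ == pytest.approx(lam_grid, abs=0.001)

    def test_loglik_matches_scipy(self):
        rng = np.random.default_rng(3)
        y = np.exp(rng.standard_normal(60) * 0.4 + 2.0)
        for lam in (-1.7, -0.3, 0.0, 0.4, 2.1):
            assert anova.boxcox_profile_llf(lam, y)[0] == pytest.approx(
                stats.boxcox_llf(lam, y), rel=1e-10
            )

    def test_constant_input_skipped(self):
        fit = anova.boxcox_fit([2.0, 2.0, 2.0, 2.0])
        assert not fit.applied

    def test_too_few_values(self):
        with pytest.raises(DomainError):
            anova.boxcox_fit([1.0, 2.0])

    def test_nonpositive_values_shifted(self):
        y = np.array([-1.0, 0.0, 2.0, 5.0, 9.0])
        fit = anova.boxcox_fit(y)
        assert fit.applied and fit.shift > 1.0
        out = anova.boxcox_transform(y, fit)
        assert np.all(np.isfinite(out))

    def test_monotone_for_any_lambda(self):
        rng = np.random.default_rng(11)
        y = np.sort(rng.uniform(0.1, 50.0, size=30))
        for _ in range(5):
            sample = rng.uniform(0.1, 50, size=40)
            fit = anova.boxcox_fit(sample)
            out = anova.boxcox_transform(y, fit)
            assert np.all(np.diff(out) > 0), f"not increasing at lambda={fit.lambda_}"


class TestTwowayAnova:
    def test_additive_cell_means_zero_interaction(self):
        race, disease = balanced_design(3)
        means = {"NoDx-White": 10.0, "Dx-White": 12.0, "NoDx-AA": 20.0, "Dx-AA": 22.0}
        group = [f"{d}-{r}" for d, r in zip(disease, race)]
        y = np.array([means[g] for g in group]) + np.tile([0.3, -0.3, 0.0], 4)
        rec = anova.twoway_anova(y, race, disease)
        assert rec.ss_interaction == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_degenerate(self):
        race, disease = balanced_design(3)
        with pytest.raises(DegenerateVarianceError):
            anova.twoway_anova(np.full(12, 7.0), race, disease)

    def test_empty_cell(self):
        race, disease = balanced_design(3)
        race = np.where(race == "AA", "White", race)  # collapse to one race
        with pytest.raises(DesignError):
            anova.twoway_anova(np.arange(12.0), race, disease)

    def test_unbalanced_rejected(self):
        race, disease = balanced_design(3)
        with pytest.raises(DesignError):
            anova.twoway_anova(np.arange(11.0), race[:11], disease[:11])

    def test_fixture_matches_oracle(self):
        race, disease = balanced_design(2)
        rec = anova.twoway_anova(FIXTURE_VALUES, race, disease)
        oracle = brute_force_anova(FIXTURE_VALUES, race, disease)
        for key in ("ss_race", "ss_disease", "ss_interaction", "ss_error",
                    "f_race", "f_disease", "f_interaction", "omnibus_f", "mse"):
            assert getattr(rec, key) == pytest.approx(oracle[key], abs=1e-10, rel=1e-10)

    def test_statsmodels_cross_check(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(5)
        race, disease = balanced_design(6)
        y = rng.normal(size=24) + (race == "AA") * 1.2 + (disease == "Dx") * 0.5
        rec = anova.twoway_anova(y, race, disease)
        df = pd.DataFrame({"y": y, "race": race, "disease": disease})
        table = sm.stats.anova_lm(ols("y ~ C(race) * C(disease)", data=df).fit(), typ=2)
        assert rec.ss_race == pytest.approx(table.loc["C(race)", "sum_sq"], rel=1e-9)
        assert rec.ss_disease == pytest.approx(table.loc["C(disease)", "sum_sq"], rel=1e-9)
        assert rec.ss_interaction == pytest.approx(
            table.loc["C(race):C(disease)", "sum_sq"], rel=1e-9
        )
        assert rec.p_race == pytest.approx(table.loc["C(race)", "PR(>F)"], rel=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_ss_decomposition_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        race, disease = balanced_design(n)
        y = rng.normal(scale=rng.uniform(0.5, 5.0), size=4 * n) + rng.uniform(-10, 10)
        rec = anova.twoway_anova(y, race, disease)
        total = rec.ss_race + rec.ss_disease + rec.ss_interaction + rec.ss_error
        assert total == pytest.approx(rec.ss_total, rel=1e-8)


class TestProtectedLsd:
    def test_equal_means_t_zero_p_one(self):
        race, disease = balanced_design(4)
        rng = np.random.default_rng(2)
        noise = rng.normal(size=4)
        y = np.concatenate([noise] * 4)  # identical cells, nonzero within-cell spread
        rec = anova.twoway_anova(y, race, disease)
        comps = anova.protected_lsd(rec)
        for c in comps:
            assert c.t == pytest.approx(0.0, abs=1e-12)
            assert c.p_raw == pytest.approx(1.0)

    def test_gate_definition(self):
        race, disease = balanced_design(5)
        rng = np.random.default_rng(8)
        y = rng.normal(size=20)
        rec = anova.twoway_anova(y, race, disease)
        rec.omnibus_p = 0.20
        comps = anova.protected_lsd(rec)
        assert all(not c.protected for c in comps)
        rec.omnibus_p = 0.01
        assert all(c.protected for c in anova.protected_lsd(rec))

    def test_formula_oracle(self):
        race, disease = balanced_design(2)
        rec = anova.twoway_anova(FIXTURE_VALUES, race, disease)
        oracle = brute_force_anova(FIXTURE_VALUES, race, disease)
        comps = anova.protected_lsd(rec)
        for c in comps:
            d0, r0 = c.pair[0].split("-")
            d1, r1 = c.pair[1].split("-")
            diff = oracle["cell_means"][(r0, d0)] - oracle["cell_means"][(r1, d1)]
            t = diff / np.sqrt(oracle["mse"] * 2 / oracle["n"])
            p = 2 * stats.t.sf(abs(t), 4 * (oracle["n"] - 1))
            assert c.t == pytest.approx(t, abs=1e-10)
            assert c.p_raw == pytest.approx(p, abs=1e-10)

    def test_only_four_prespecified_pairs(self):
        race, disease = balanced_design(3)
        rng = np.random.default_rng(9)
        rec = anova.twoway_anova(rng.normal(size=12), race, disease)
        comps = anova.protected_lsd(rec)
        assert [c.pair for c in comps] == list(anova.CONTRAST_PAIRS)
        assert all(c.p_fdr >= c.p_raw - 1e-15 for c in comps)

    def test_mismatched_n_rejected(self):
        race, disease = balanced_design(3)
        rng = np.random.default_rng(10)
        rec = anova.twoway_anova(rng.normal(size=12), race, disease)
        with pytest.raises(DesignError):
            anova.protected_lsd(rec, n_per_cell=5)


class TestFdrAdjust:
    def test_hand_example(self):
        out = anova.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert anova.fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(anova.fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range(self):
        with pytest.raises(DomainError):
            anova.fdr_adjust([0.5, 1.5])
        with pytest.raises(DomainError):
            anova.fdr_adjust([-0.1])

    def test_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(anova.fdr_adjust(p), expected, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_properties(self, p):
        out = anova.fdr_adjust(p)
        assert np.all(out >= np.asarray(p) - 1e-15)
        assert np.all(out <= 1.0 + 1e-15)


class TestAnalyzePanel:
    def test_panel_output_shape(self, small_cohort):
        cohort, _ = small_cohort
        res = anova.analyze_panel(cohort, "lipid")
        assert len(res) == 12
        assert {"p_race_fdr", "p_disease_fdr", "p_interaction_fdr"} <= set(res.columns)
        # planted clusters 1 (race) and 2 (disease) should surface
        sig = anova.significant_analytes(res)
        assert len(sig) >= 6

    def test_boxcox_never(self, small_cohort):
        cohort, _ = small_cohort
        res = anova.analyze_panel(cohort, "lipid", boxcox="never")
        assert not res["boxcox_applied"].any()
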