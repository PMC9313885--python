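import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from neophobia import (
    SchemaError,
    arcsine_sqrt,
    binomial_glm_lr,
    flag_outliers,
    lmm_velocity,
    pearson_chi2,
    pearson_chi2_2x2,
    weighted_ancova,
    weighted_t_test,
)


def make_obs_table(rng, n_per_cell=10, sd=0.3, effects=None):
    """Balanced 2-treatment x 3-age observation table with positive weights."""
    rows = []
    effects = effects or {}
    for t in ("enrichment", "no_enrichment"):
        for a in (7, 14, 21):
            mu = 0.8 + effects.get((t, a), 0.0)
            for _ in range(n_per_cell):
                rows.append(
                    {
                        "treatment": t,
                        "age_dpf": a,
                        "y": rng.normal(mu, sd),
                        "weight": rng.uniform(20, 200),
                    }
                )
    return pd.DataFrame(rows)


class TestArcsineSqrt:
    def test_reference_points(self):
        assert arcsine_sqrt(0.0) == 0.0
        assert arcsine_sqrt(1.0) == pytest.approx(np.pi / 2)
        assert arcsine_sqrt(0.5) == pytest.approx(np.pi / 4)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            arcsine_sqrt(1.2)


class TestWeightedAncova:
    def test_equal_weights_reduce_to_ols_anova(self, rng):
        """With unit weights the sequential F table must match statsmodels."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        tbl = make_obs_table(rng)
        tbl["weight"] = 1.0
        res = weighted_ancova(tbl, "y", weights="weight")
        fit = ols("y ~ age_dpf * C(treatment)", data=tbl).fit()
        oracle = sm.stats.anova_lm(fit, typ=1)
        for ours, theirs in zip(
            res.terms, ["age_dpf", "C(treatment)", "age_dpf:C(treatment)"]
        ):
            assert res[ours].statistic == pytest.approx(
                oracle.loc[theirs, "F"], rel=1e-9
            )
            assert res[ours].p == pytest.approx(oracle.loc[theirs, "PR(>F)"], rel=1e-9)

    def test_invariance_to_weight_rescaling(self, rng):
        tbl = make_obs_table(rng)
        a = weighted_ancova(tbl, "y")
        tbl2 = tbl.assign(weight=tbl["weight"] * 37.5)
        b = weighted_ancova(tbl2, "y")
        for t in a.terms:
            assert a[t].statistic == pytest.approx(b[t].statistic, rel=1e-10)

    def test_row_splitting_with_half_weights_changes_nothing_in_estimates(self, rng):
        """Duplicating every observation at half weight leaves coefficients'
        F ratios unchanged up to the doubled residual df."""
        tbl = make_obs_table(rng, n_per_cell=6)
        doubled = pd.concat([tbl, tbl]).assign(
            weight=lambda d: d["weight"].to_numpy() / 2.0
        )
        a = weighted_ancova(tbl, "y")
        b = weighted_ancova(doubled, "y")
        # identical weighted normal equations -> identical sums of squares
        assert b.extra["rss"] == pytest.approx(a.extra["rss"], rel=1e-9)

    def test_aliased_term_raises_rank_error_naming_it(self, rng):
        tbl = make_obs_table(rng)
        tbl["dup"] = tbl["age_dpf"]
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            weighted_ancova(tbl, "y", terms=("age_dpf", "dup"))

    def test_pooled_analysis_accepts_an_experiment_factor(self, rng):
        """Pooling two experiments adds an experiment factor to the model."""
        from neophobia.stats import POOLED_TERMS

        a = make_obs_table(rng).assign(experiment="object")
        b = make_obs_table(rng).assign(experiment="odor")
        tbl = pd.concat([a, b], ignore_index=True)
        res = weighted_ancova(tbl, "y", terms=POOLED_TERMS)
        assert set(res.terms) == set(POOLED_TERMS)
        assert res.extra["df_resid"] == len(tbl) - 7

    def test_nonpositive_weights_rejected(self, rng):
        tbl = make_obs_table(rng)
        tbl.loc[0, "weight"] = 0.0
        with pytest.raises(SchemaError):
            weighted_ancova(tbl, "y")


class TestWeightedTTest:
    def test_equal_weights_match_pooled_two_sample_t(self, rng):
        tbl = make_obs_table(rng).assign(weight=1.0)
        res = weighted_t_test(tbl, "y", "treatment")
        a = tbl.loc[tbl.treatment == "enrichment", "y"]
        b = tbl.loc[tbl.treatment == "no_enrichment", "y"]
        t, p = sps.ttest_ind(b, a, equal_var=True)
        assert res.tests[0].statistic == pytest.approx(t, rel=1e-10)
        assert res.tests[0].p == pytest.approx(p, rel=1e-10)

    def test_t_squared_equals_one_way_weighted_f(self, rng):
        tbl = make_obs_table(rng)
        t_res = weighted_t_test(tbl, "y", "treatment")
        f_res = weighted_ancova(tbl, "y", terms=("treatment",))
        assert t_res.tests[0].statistic ** 2 == pytest.approx(
            f_res["treatment"].statistic, rel=1e-10
        )

    def test_identical_groups_give_t_zero_p_one(self):
        tbl = pd.DataFrame(
            {
                "y": [1.0, 2.0, 3.0] * 2,
                "g": ["a"] * 3 + ["b"] * 3,
                "weight": [1.0] * 6,
            }
        )
        res = weighted_t_test(tbl, "y", "g")
        assert res.tests[0].statistic == pytest.approx(0.0, abs=1e-12)
        assert res.tests[0].p == pytest.approx(1.0)

    def test_requires_two_groups(self, rng):
        tbl = make_obs_table(rng)
        with pytest.raises(SchemaError):
            weighted_t_test(tbl, "y", "age_dpf")


def make_velocity_table(rng, n_per_cell=6, sigma_b=0.5, sigma_w=0.2, sector_gap=-0.4):
    rows = []
    k = 0
    for t in ("enrichment", "no_enrichment"):
        for a in (7, 14, 21):
            for _ in range(n_per_cell):
                b = rng.normal(0.0, sigma_b)
                base = 1.8 + 0.01 * a + (0.1 if t == "enrichment" else 0.0)
                for sector, off in (("stimulus", sector_gap), ("empty", 0.0)):
                    rows.append(
                        {
                            "subject_id": f"s{k:03d}",
                            "sector": sector,
                            "velocity": float(
                                np.exp(base + off + b + rng.normal(0, sigma_w))
                            ),
                            "treatment": t,
                            "age_dpf": a,
                        }
                    )
                k += 1
    return pd.DataFrame(rows)


class TestVelocityLmm:
    def test_structure_errors(self, rng):
        tbl = make_velocity_table(rng)
        with pytest.raises(SchemaError):
            lmm_velocity(tbl.iloc[1:])  # one subject lost a row
        bad = tbl.copy()
        bad.loc[bad.index[0], "velocity"] = -1.0
        with pytest.raises(ValueError):
            lmm_velocity(bad)

    def test_equal_sector_values_give_zero_sector_f(self, rng):
        tbl = make_velocity_table(rng, sigma_w=0.0, sector_gap=0.0)
        res = lmm_velocity(tbl)
        assert res["sector"].statistic == pytest.approx(0.0, abs=1e-9)

    def test_variance_components_match_mixedlm_reml(self, rng):
        import statsmodels.formula.api as smf

        tbl = make_velocity_table(rng, n_per_cell=10)
        res = lmm_velocity(tbl)
        tbl["log_v"] = np.log(tbl["velocity"])
        m = smf.mixedlm(
            "log_v ~ C(sector) * C(treatment) * age_dpf", tbl, groups=tbl["subject_id"]
        ).fit(reml=True)
        assert res.extra["sigma2_within"] == pytest.approx(m.scale, rel=1e-3)
        assert res.extra["sigma2_between"] == pytest.approx(
            float(m.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-6
        )

    def test_within_terms_match_anova_on_differences(self, rng):
        """The sector-involving F tests equal a sequential OLS ANOVA of the
        per-subject velocity differences — an independent statsmodels route."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        tbl = make_velocity_table(rng, n_per_cell=8)
        res = lmm_velocity(tbl)
        tbl["log_v"] = np.log(tbl["velocity"])
        wide = tbl.pivot_table(
            index=["subject_id", "treatment", "age_dpf"],
            columns="sector",
            values="log_v",
        ).reset_index()
        wide["d"] = wide["stimulus"] - wide["empty"]
        fit = ols("d ~ age_dpf * C(treatment)", data=wide).fit()
        oracle = sm.stats.anova_lm(fit, typ=1)
        assert res["sector:age_dpf"].statistic == pytest.approx(
            oracle.loc["age_dpf", "F"], rel=1e-9
        )
        assert res["sector:treatment"].statistic == pytest.approx(
            oracle.loc["C(treatment)", "F"], rel=1e-9
        )
        assert res["sector:age_dpf:treatment"].statistic == pytest.approx(
            oracle.loc["age_dpf:C(treatment)", "F"], rel=1e-9
        )

    def test_matches_lmer_f_table_on_balanced_data(self, rng, tmp_path):
        """Cross-check F statistics and df against R lme4/lmerTest (REML)."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        tbl = make_velocity_table(rng, n_per_cell=8)
        res = lmm_velocity(tbl)
        csv = tmp_path / "v.csv"
        tbl.assign(log_v=np.log(tbl["velocity"])).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            d$sector <- factor(d$sector); d$treatment <- factor(d$treatment)
            m <- lmer(log_v ~ sector * treatment * age_dpf + (1 | subject_id), data = d)
            a <- anova(m, type = 1)
            cat(jsonlite::toJSON(data.frame(term = rownames(a), F = a$`F value`,
                df_den = a$DenDF), digits = 12))
            """
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        oracle = {
            row["term"]: row for row in json.loads(out.stdout[out.stdout.index("[") :])
        }
        pairs = {
            "sector": "sector",
            "treatment": "treatment",
            "age_dpf": "age_dpf",
            "sector:treatment": "sector:treatment",
            "sector:age_dpf": "sector:age_dpf",
            "treatment:age_dpf": "age_dpf:treatment",
            "sector:treatment:age_dpf": "sector:age_dpf:treatment",
        }
        for r_term, our_term in pairs.items():
            ours = res[our_term]
            assert ours.statistic == pytest.approx(
                oracle[r_term]["F"], rel=1e-6
            ), r_term
            assert ours.df_den == pytest.approx(oracle[r_term]["df_den"], abs=0.51)


class TestPearsonChi2:
    def test_nonchooser_contrast_between_experiments(self):
        res = pearson_chi2_2x2([[21, 99], [4, 116]])
        t = res.tests[0]
        assert t.statistic == pytest.approx(12.904, abs=5e-4)
        assert t.df_num == 1 and t.p < 0.001

    def test_identical_proportions_give_zero(self):
        assert pearson_chi2_2x2([[10, 90], [10, 90]]).tests[0].statistic == 0.0

    def test_matches_scipy_without_continuity_correction(self, rng):
        for _ in range(25):
            tab = rng.integers(1, 40, (2, 2))
            ours = pearson_chi2_2x2(tab).tests[0]
            chi2, p, df, _ = sps.chi2_contingency(tab, correction=False)
            assert ours.statistic == pytest.approx(chi2, rel=1e-12)
            assert ours.p == pytest.approx(p, rel=1e-12)

    def test_symmetric_under_row_and_column_permutation(self):
        a = pearson_chi2_2x2([[21, 99], [4, 116]]).tests[0].statistic
        b = pearson_chi2_2x2([[4, 116], [21, 99]]).tests[0].statistic
        c = pearson_chi2_2x2([[99, 21], [116, 4]]).tests[0].statistic
        assert a == pytest.approx(b) == pytest.approx(c)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(ValueError):
            pearson_chi2_2x2([[0, 0], [5, 5]])

    def test_three_by_two_table_supported(self):
        res = pearson_chi2([[14, 26], [4, 36], [3, 37]])
        assert res.tests[0].df_num == 2


class TestBinomialGlm:
    def test_equal_proportions_give_zero_statistic(self):
        factors = pd.DataFrame({"age_dpf": ["7", "14", "21"]})
        res = binomial_glm_lr([8, 8, 8], [40, 40, 40], factors)
        assert res.tests[0].statistic == pytest.approx(0.0, abs=1e-8)

    def test_single_group_gives_df_zero(self):
        res = binomial_glm_lr([5], [40], pd.DataFrame({"age_dpf": ["7"]}), terms=())
        assert res.tests[0].statistic == 0.0 and res.tests[0].df_num == 0

    def test_age_factor_lr_matches_saturated_closed_form(self):
        """Nonchooser counts by age; oracle is the grouped-binomial deviance
        drop computed directly from the log-likelihood."""
        y = np.array([14.0, 4.0, 3.0])
        n = np.array([40.0, 40.0, 40.0])
        p_g = y / n
        p_bar = y.sum() / n.sum()

        def term(a, b):
            out = np.zeros_like(a)
            nz = a > 0
            out[nz] = a[nz] * np.log(b[nz])
            return out.sum()

        lr = 2 * (
            term(y, p_g / p_bar) + term(n - y, (1 - p_g) / (1 - p_bar))
        )
        factors = pd.DataFrame({"age_dpf": ["07", "14", "21"]})
        res = binomial_glm_lr(y, n, factors)
        assert res.tests[0].statistic == pytest.approx(lr, rel=1e-8)
        assert res.tests[0].df_num == 2

    def test_separation_reports_boundary_fit(self):
        factors = pd.DataFrame({"age_dpf": ["7", "14"]})
        res = binomial_glm_lr([0, 10], [20, 20], factors)
        assert np.isfinite(res.tests[0].statistic)
        assert res.tests[0].statistic > 0


class TestOutlierFlags:
    def test_large_residual_flagged(self):
        e = np.zeros(50)
        e[:49] = np.random.default_rng(0).normal(0, 1, 49)
        e[49] = 10 * e[:49].std()
        flags = flag_outliers(e, df_model=2)
        assert flags[49]
        assert flags.sum() == 1

    def test_equal_residuals_flag_nothing(self):
        assert not flag_outliers(np.ones(20), df_model=1).any()

    def test_standard_normal_rarely_flagged(self):
        e = np.random.default_rng(3).normal(0, 1, 100)
        assert flag_outliers(e, df_model=3).sum() <= 1
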