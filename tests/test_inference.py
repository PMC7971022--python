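"""Inference layer: descriptives, ANOVA against a sum-of-squares oracle,
mixed-model behaviour (OLS limit, effect recovery), contrasts, weekly series."""

import numpy as np
import pandas as pd
import pytest

from wearmob.config import default_synthetic_config
from wearmob.inference import (
    ModelSpec,
    describe_cohort,
    fit_mixed,
    level_contrasts,
    level_means,
    severity_group,
    weekly_series,
)
from wearmob.synthetic import simulate_cohort, truth_analysis_table

from conftest import small_config


# ---------------------------------------------------------------------------
# cohort descriptives


class TestDescribeCohort:
    def _roster(self):
        return pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(6)],
                "site": "Cyprus",
                "age_years": [8.0, 9.0, 10.0, 11.0, 7.0, 9.0],
                "gender": ["M", "F", "M", "M", "F", "M"],
                "wheezing": [1, 1, 1, 0, 0, 0],
                "preventive_medication": [0, 1, 1, 1, 0, 0],
                "unscheduled_visits": [0, 0, 1, 1, 0, 0],
                "er_visits": [0, 0, 1, 0, 0, 0],
            }
        )

    def test_severity_groups_match_hand_tally(self):
        out = describe_cohort(self._roster()).iloc[0]
        # criteria counts per participant: 1, 2, 4, 2, 0, 0 -> sev 1,2,3,2 + 2 ineligible
        assert out["n"] == 4
        assert out["n_ineligible"] == 2
        assert out["severity1_n"] == 1
        assert out["severity2_n"] == 2
        assert out["severity3_n"] == 1
        assert out["male_n"] == 3
        assert out["age_mean"] == pytest.approx(np.mean([8, 9, 10, 11]))

    def test_severity_definition(self):
        assert severity_group(1) == 1  # diagnosis + one criterion
        assert severity_group(2) == 2  # diagnosis + two criteria
        assert severity_group(5) == 3  # three or more
        with pytest.raises(ValueError):
            severity_group(0)

    def test_synthetic_roster_counts_match_brute_force(self, small_cohort):
        parts = small_cohort.participants
        out = describe_cohort(parts)
        for _, row in out.iterrows():
            grp = parts[parts["site"] == row["site"]]
            crit = grp[["wheezing", "preventive_medication", "unscheduled_visits", "er_visits"]].sum(axis=1)
            assert row["n"] == int((crit > 0).sum())
            assert row["severity3_n"] == int((crit[crit > 0] >= 3).sum())


# ---------------------------------------------------------------------------
# unadjusted level means / ANOVA


def anova_f_oracle(groups):
    """One-way ANOVA F from first-principles sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def _toy_table():
    rng = np.random.default_rng(8)
    rows = []
    for lvl, mu in [(0, 10.0), (1, 12.0), (3, 15.0)]:
        for i in range(30):
            rows.append(
                {"site": "Cyprus", "level": lvl, "fraction_home": rng.normal(mu, 1.0)}
            )
    return pd.DataFrame(rows)


class TestLevelMeans:
    def test_anova_matches_sum_of_squares_oracle(self):
        df = _toy_table()
        out = level_means(df, "fraction_home")
        groups = [g["fraction_home"].to_numpy() for _, g in df.groupby("level")]
        assert out["anova_F"].iloc[0] == pytest.approx(anova_f_oracle(groups), rel=1e-10)

    def test_identical_observations_give_capped_p(self):
        df = pd.DataFrame(
            {"level": [0] * 5 + [1] * 5 + [2] * 5, "fraction_home": 0.5, "site": "x"}
        )
        out = level_means(df, "fraction_home")
        assert (out["p_vs_baseline"].dropna() == 1.0).all()
        assert (out["p_vs_previous"].dropna() == 1.0).all()

    def test_ci_is_normal_theory(self):
        df = _toy_table()
        out = level_means(df, "fraction_home").set_index("level")
        g = df[df["level"] == 0]["fraction_home"]
        half = 1.959963984540054 * g.std(ddof=1) / np.sqrt(len(g))
        assert out.loc[0, "ci95_high"] - out.loc[0, "mean"] == pytest.approx(half)

    def test_single_level_rejected(self):
        df = pd.DataFrame({"level": [0] * 5, "fraction_home": 0.5})
        with pytest.raises(ValueError, match="two intervention levels"):
            level_means(df, "fraction_home")

    def test_severity_stratified_summaries_reuse_level_means(self):
        """Stratified output is the plain summary computed within each stratum."""
        df = _toy_table()
        df["severity"] = np.tile([1, 2], len(df) // 2)
        strat = level_means(df, "fraction_home", stratum_col="severity")
        for sev, grp in df.groupby("severity"):
            want = level_means(grp, "fraction_home")
            got = strat[strat["severity"] == sev].drop(columns="severity").reset_index(drop=True)
            pd.testing.assert_frame_equal(got, want)

    def test_recovers_generator_truth_at_zero_effect_noise(self):
        """Cyprus-like generator: per-level pooled means sit within Monte-Carlo
        error of the means of the emitted daily truth."""
        cfg = small_config(seed=31, n=20, weeks=12)
        cohort = simulate_cohort(cfg, daily_only=True)
        tab = truth_analysis_table(cohort)
        cy = tab[tab["site"] == "Cyprus"]
        out = level_means(cy, "fraction_home", site="Cyprus").set_index("level")
        for lvl, grp in cy.groupby("level"):
            assert out.loc[lvl, "mean"] == pytest.approx(grp["fraction_home"].mean())
            # 3-sigma Monte-Carlo band around the configured expectation
            site = cfg.sites[0]
            shift = 0.0 if lvl == 0 else site.level_home_fraction_shift[lvl - 1]
            wk = grp["weekend"].mean()
            wk_delta = (
                site.weekend_home_delta_baseline
                if lvl == 0
                else site.weekend_home_delta_lockdown
            )
            expect = site.baseline_home_fraction + shift + wk * wk_delta
            se = grp["fraction_home"].std(ddof=1) / np.sqrt(len(grp))
            assert abs(out.loc[lvl, "mean"] - expect) < 3.5 * se + 0.01


# ---------------------------------------------------------------------------
# mixed model


def ols_oracle(X, y):
    """Plain least-squares coefficients via the normal equations (lstsq)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


class TestMixedModel:
    def test_ols_limit_with_variance_pinned_at_zero(self):
        """With the random-intercept variance fixed to 0 on independent data the
        mixed fit must reproduce ordinary least squares to 4 decimals."""
        cfg = small_config(seed=17, n=12, weeks=12, participant_sd_home=0.0)
        tab = truth_analysis_table(simulate_cohort(cfg, daily_only=True))
        tab = tab[tab["site"] == "Cyprus"]
        fit = fit_mixed(tab, "fraction_home", fix_zero_group_variance=True)
        terms = fit.terms.set_index("term")
        X = np.column_stack(
            [np.ones(len(tab))]
            + [
                (tab["level"] == k).astype(float) if isinstance(k, int) else tab[k].astype(float)
                for k in [1, 2, 3, "male", "age_years", "weekend", "temp_c",
                          "rh_pct", "sin_t", "cos_t", "wk_lvl1", "wk_lvl2", "wk_lvl3"]
            ]
        )
        beta = ols_oracle(X, tab["fraction_home"].to_numpy())
        got = terms["coef"].reindex(
            ["Intercept", "level_1", "level_2", "level_3", "male", "age_years",
             "weekend", "temp_c", "rh_pct", "sin_t", "cos_t",
             "wk_lvl1", "wk_lvl2", "wk_lvl3"]
        ).to_numpy()
        np.testing.assert_allclose(got, beta, atol=1e-4)
        assert fit.group_var == 0.0

    def test_unconstrained_reml_collapses_near_ols_on_independent_data(self):
        """With no true between-participant variance the free REML fit should
        drive the intercept variance to ~0 and land near the OLS solution."""
        cfg = small_config(seed=19, n=15, weeks=12, participant_sd_home=0.0)
        tab = truth_analysis_table(simulate_cohort(cfg, daily_only=True))
        tab = tab[tab["site"] == "Cyprus"]
        free = fit_mixed(tab, "fraction_home")
        pinned = fit_mixed(tab, "fraction_home", fix_zero_group_variance=True)
        assert free.group_var < 0.05 * free.resid_var
        a = free.terms.set_index("term")["coef"]
        b = pinned.terms.set_index("term")["coef"]
        np.testing.assert_allclose(a.to_numpy(), b.reindex(a.index).to_numpy(), atol=2e-3)

    def test_recovers_configured_effects(self):
        cfg = small_config(seed=23, n=25, weeks=12)
        tab = truth_analysis_table(simulate_cohort(cfg, daily_only=True))
        site = cfg.sites[0]
        fit = fit_mixed(tab[tab["site"] == "Cyprus"], "fraction_home")
        for k in (1, 2, 3):
            truth = site.level_home_fraction_shift[k - 1]
            row = fit.terms.set_index("term").loc[f"level_{k}"]
            assert abs(row["coef"] - truth) < 4 * row["se"] + 0.02

    def test_variance_components_nonnegative(self, small_cohort):
        tab = truth_analysis_table(small_cohort)
        fit = fit_mixed(tab[tab["site"] == "Cyprus"], "total_steps")
        assert fit.group_var >= 0 and fit.resid_var > 0
        assert fit.converged
        assert fit.n_participants == 4

    def test_collinear_terms_named(self):
        cfg = small_config(seed=2, n=6, weeks=4)
        tab = truth_analysis_table(simulate_cohort(cfg, daily_only=True))
        tab = tab[tab["site"] == "Cyprus"].copy()
        tab["dupe"] = tab["weekend"] * 1.0
        spec = ModelSpec(outcome="fraction_home", extra_terms=["dupe"])
        with pytest.raises(ValueError, match="dupe"):
            fit_mixed(tab, spec)

    def test_requires_multiple_participants(self):
        df = pd.DataFrame(
            {
                "participant_id": "P1",
                "site": "x",
                "level": [0, 1],
                "male": 0,
                "age_years": 9.0,
                "year_2020": [0, 1],
                "weekend": 0,
                "temp_c": 15.0,
                "rh_pct": 60.0,
                "sin_t": 0.0,
                "cos_t": 1.0,
                "wk_lvl1": 0,
                "wk_lvl2": 0,
                "wk_lvl3": 0,
                "fraction_home": [0.4, 0.9],
            }
        )
        with pytest.raises(ValueError, match="participants"):
            fit_mixed(df, "fraction_home")

    def test_harmonic_terms_do_not_move_level_effects(self):
        """The generator has no seasonal signal, so dropping the harmonic pair
        shifts the level coefficients by less than Monte-Carlo error."""
        cfg = small_config(seed=41, n=20, weeks=12)
        tab = truth_analysis_table(simulate_cohort(cfg, daily_only=True))
        tab = tab[tab["site"] == "Cyprus"]
        with_h = fit_mixed(tab, ModelSpec(outcome="fraction_home", include_harmonics=True))
        without = fit_mixed(tab, ModelSpec(outcome="fraction_home", include_harmonics=False))
        for k in (1, 2, 3):
            a = with_h.terms.set_index("term").loc[f"level_{k}"]
            b = without.terms.set_index("term").loc[f"level_{k}"]
            assert abs(a["coef"] - b["coef"]) < 2 * a["se"]


# ---------------------------------------------------------------------------
# contrasts


@pytest.fixture(scope="module")
def contrast_fit():
    cfg = small_config(seed=53, n=15, weeks=12)
    tab = truth_analysis_table(simulate_cohort(cfg, daily_only=True))
    return fit_mixed(tab[tab["site"] == "Cyprus"], "fraction_home")


class TestContrasts:

    def test_estimates_are_coefficient_differences(self, contrast_fit):
        out = level_contrasts(contrast_fit).set_index("comparison")
        c = contrast_fit.terms.set_index("term")["coef"]
        assert out.loc["level1_vs_level0", "estimate"] == pytest.approx(c["level_1"])
        assert out.loc["level2_vs_level1", "estimate"] == pytest.approx(
            c["level_2"] - c["level_1"]
        )
        assert out.loc["level3_vs_level2", "estimate"] == pytest.approx(
            c["level_3"] - c["level_2"]
        )

    def test_bonferroni_capped_at_one(self, contrast_fit):
        out = level_contrasts(contrast_fit)
        assert (out["p_adjusted"] <= 1.0).all()
        np.testing.assert_allclose(
            out["p_adjusted"],
            np.minimum(1.0, out["p_unadjusted"] * len(out)),
        )

    def test_unknown_adjustment_rejected(self, contrast_fit):
        with pytest.raises(ValueError, match="adjustment"):
            level_contrasts(contrast_fit, adjustment="fdr")


def test_equal_level2_level3_effects_usually_non_significant():
    """Simulate equal level-2/level-3 effects: the 3-vs-2 contrast should be
    non-significant in the clear majority of replicates."""
    hits = 0
    n_rep = 20
    for r in range(n_rep):
        cfg = small_config(seed=100 + r, n=15, weeks=12)
        for s in cfg.sites:
            s.level_home_fraction_shift = (0.3, 0.45, 0.45)
        tab = truth_analysis_table(simulate_cohort(cfg, daily_only=True))
        fit = fit_mixed(tab[tab["site"] == "Cyprus"], "fraction_home")
        out = level_contrasts(fit).set_index("comparison")
        if out.loc["level3_vs_level2", "p_adjusted"] > 0.05:
            hits += 1
    assert hits >= int(0.9 * n_rep)


# ---------------------------------------------------------------------------
# weekly series


class TestWeeklySeries:
    def test_week_anchoring(self):
        df = pd.DataFrame(
            {
                "site": "Cyprus",
                "year": 2020,
                "date": pd.to_datetime(
                    ["2020-02-03", "2020-02-09", "2020-02-10", "2020-02-16"]
                ),
                "fraction_home": [0.1, 0.2, 0.3, 0.5],
                "total_steps": 1000,
            }
        )
        out = weekly_series(df).set_index("week")
        assert out.loc[1, "fraction_home_mean"] == pytest.approx(0.15)  # Feb 3-9
        assert out.loc[2, "fraction_home_mean"] == pytest.approx(0.4)  # Feb 10-16

    def test_constant_input_constant_series(self):
        df = pd.DataFrame(
            {
                "site": "Cyprus",
                "year": 2020,
                "date": pd.date_range("2020-02-03", periods=28, freq="D"),
                "fraction_home": 0.44,
                "total_steps": 9000,
            }
        )
        out = weekly_series(df)
        assert (out["fraction_home_mean"] == 0.44).all()
        assert len(out) == 4

    def test_2019_series_flat_relative_to_2020_level_shifts(self):
        """A restriction-free 2019 window shows far less between-week variance
        than the 2020 window with its configured level shifts."""
        cfg = small_config(seed=61, n=10, weeks=12, n_prior=10)
        tab = truth_analysis_table(simulate_cohort(cfg, daily_only=True))
        wk = weekly_series(tab[tab["site"] == "Cyprus"])
        v2019 = wk[wk["year"] == 2019]["fraction_home_mean"].var(ddof=1)
        v2020 = wk[wk["year"] == 2020]["fraction_home_mean"].var(ddof=1)
        assert v2020 > 5 * v2019
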