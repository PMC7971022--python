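"""Statistical analysis of the daily compliance outcomes.

Three layers, mirroring how longitudinal wearable studies are usually
reported:

* unadjusted: per-intervention-level means of the pooled participant-days
  with normal-theory 95% CIs, a one-way ANOVA across levels, and pairwise
  level comparisons with Bonferroni adjustment (capped at 1);
* adjusted: a linear mixed model per outcome with a participant random
  intercept (REML), fixed effects for intervention level (categorical,
  level 0 reference), gender, age, study year, weekend, temperature,
  humidity, one sine/cosine harmonic pair, and weekend-by-level
  interactions; inference is Wald with normal critical values, matching the
  symmetric CIs such studies print;
* contrasts: Wald contrasts of each level against baseline and against the
  previous level, Bonferroni-adjusted over the contrast family.

The unadjusted ANOVA deliberately treats participant-days as independent
observations — that is what "unadjusted" means here; clustering is handled
only by the mixed model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

logger = logging.getLogger(__name__)

__all__ = [
    "describe_cohort",
    "level_means",
    "ModelSpec",
    "FitResult",
    "fit_mixed",
    "level_contrasts",
    "weekly_series",
]

_Z95 = stats.norm.ppf(0.975)
ELIGIBILITY_FLAGS = [
    "wheezing",
    "preventive_medication",
    "unscheduled_visits",
    "er_visits",
]


# ---------------------------------------------------------------------------
# cohort descriptives


def describe_cohort(participants: pd.DataFrame) -> pd.DataFrame:
    """Demographics and asthma-severity groups per site.

    Severity counts the eligibility criteria met beyond the physician
    diagnosis: 1 criterion -> severity 1, 2 -> severity 2, >= 3 -> severity 3.
    Participants with no criterion beyond the diagnosis do not meet the
    eligibility definition; they are excluded from the table and counted in
    the ``n_ineligible`` row.
    """
    rows = []
    for site, grp in participants.groupby("site"):
        n_crit = grp[ELIGIBILITY_FLAGS].sum(axis=1)
        ineligible = n_crit == 0
        if ineligible.any():
            logger.warning(
                "%s: excluding %d participant(s) with no eligibility "
                "criterion beyond diagnosis", site, int(ineligible.sum()),
            )
        g = grp[~ineligible]
        nc = n_crit[~ineligible]
        severity = np.minimum(nc, 3)
        n = len(g)
        rows.append(
            {
                "site": site,
                "n": n,
                "n_ineligible": int(ineligible.sum()),
                "male_n": int((g["gender"] == "M").sum()),
                "male_pct": 100.0 * (g["gender"] == "M").mean(),
                "age_mean": g["age_years"].mean(),
                "age_sd": g["age_years"].std(ddof=1),
                **{
                    f"{f}_n": int(g[f].sum())
                    for f in ELIGIBILITY_FLAGS
                    if f in g
                },
                **{
                    f"severity{k}_n": int((severity == k).sum())
                    for k in (1, 2, 3)
                },
                **{
                    f"severity{k}_pct": 100.0 * float((severity == k).mean())
                    for k in (1, 2, 3)
                },
            }
        )
    return pd.DataFrame(rows)


def severity_group(n_criteria_beyond_diagnosis: int) -> int:
    """Asthma severity from the count of criteria beyond the diagnosis."""
    if n_criteria_beyond_diagnosis < 1:
        raise ValueError("eligibility requires at least one criterion beyond diagnosis")
    return min(n_criteria_beyond_diagnosis, 3)


# ---------------------------------------------------------------------------
# unadjusted per-level summaries


def level_means(
    analysis: pd.DataFrame,
    outcome: str,
    site: str | None = None,
    stratum_col: str | None = None,
) -> pd.DataFrame:
    """Observed per-level means with 95% CIs, ANOVA and Bonferroni pairwise tests.

    Pools participant-days within each level. ``stratum_col`` (e.g. an
    asthma-severity column) repeats the summary within each stratum.
    """
    df = analysis if site is None else analysis[analysis["site"] == site]
    if stratum_col is not None:
        parts = []
        for stratum, grp in df.groupby(stratum_col):
            if grp["level"].nunique() < 2 or not len(grp):
                logger.warning("stratum %s=%r omitted (insufficient data)", stratum_col, stratum)
                continue
            sub = level_means(grp, outcome, site=None)
            sub.insert(0, stratum_col, stratum)
            parts.append(sub)
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()

    levels = sorted(df["level"].unique())
    if len(levels) < 2:
        raise ValueError("need data for at least two intervention levels")
    by_level = {lvl: df.loc[df["level"] == lvl, outcome].dropna().to_numpy() for lvl in levels}
    f_stat, anova_p = stats.f_oneway(*by_level.values())
    m = len(levels) * (len(levels) - 1) // 2  # Bonferroni family: all level pairs

    rows = []
    for i, lvl in enumerate(levels):
        x = by_level[lvl]
        n = len(x)
        mean = x.mean()
        half = _Z95 * x.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        p_base = _bonferroni_t(by_level[levels[0]], x, m) if lvl != levels[0] else np.nan
        p_prev = _bonferroni_t(by_level[levels[i - 1]], x, m) if i > 0 else np.nan
        rows.append(
            {
                "site": site if site is not None else "all",
                "outcome": outcome,
                "level": lvl,
                "n": n,
                "mean": mean,
                "ci95_low": mean - half,
                "ci95_high": mean + half,
                "p_vs_baseline": p_base,
                "p_vs_previous": p_prev,
                "anova_F": f_stat,
                "anova_p": anova_p,
            }
        )
    return pd.DataFrame(rows)


def _bonferroni_t(a: np.ndarray, b: np.ndarray, m: int) -> float:
    """Pooled-variance two-sample t-test p-value, Bonferroni x m, capped at 1."""
    if np.allclose(a.var(ddof=0) + b.var(ddof=0), 0.0) and np.isclose(a.mean(), b.mean()):
        return 1.0
    _, p = stats.ttest_ind(a, b, equal_var=True)
    return float(min(1.0, m * p))


# ---------------------------------------------------------------------------
# adjusted mixed model


@dataclass
class ModelSpec:
    """Fixed/random structure of the adjusted model (level 0 is reference)."""

    outcome: str
    include_harmonics: bool = True
    include_interactions: bool = True
    extra_terms: list[str] = field(default_factory=list)
    method: str = "REML"

    def design_columns(self, df: pd.DataFrame) -> list[str]:
        levels = sorted(set(df["level"].unique()) - {0})
        cols = [f"level_{k}" for k in levels]
        cols += ["male", "age_years", "year_2020", "weekend", "temp_c", "rh_pct"]
        if self.include_harmonics:
            cols += ["sin_t", "cos_t"]
        if self.include_interactions:
            cols += [f"wk_lvl{k}" for k in levels]
        cols += list(self.extra_terms)
        return cols


@dataclass
class FitResult:
    """Estimated fixed effects (Wald CIs/p-values) and variance components."""

    outcome: str
    terms: pd.DataFrame  # term, coef, se, ci95_low, ci95_high, pvalue
    group_var: float
    resid_var: float
    n_obs: int
    n_participants: int
    converged: bool
    method: str
    cov_fe: pd.DataFrame  # fixed-effect covariance, for contrasts

    def coef(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "coef"])


def _build_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    d = df.copy()
    for k in sorted(set(d["level"].unique()) - {0}):
        d[f"level_{k}"] = (d["level"] == k).astype(float)
    cols = spec.design_columns(d)
    needed = cols + [spec.outcome, "participant_id"]
    missing_cols = [c for c in needed if c not in d.columns]
    if missing_cols:
        raise ValueError(f"analysis table lacks columns {missing_cols}")
    complete = d[needed].notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.warning("dropping %d rows with missing outcome/covariates", n_drop)
    d = d[complete]
    X = d[cols].astype(float)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        logger.warning("dropping constant design columns %s", constant)
        X = X.drop(columns=constant)
    X.insert(0, "Intercept", 1.0)
    _check_rank(X)
    return X, d[spec.outcome].astype(float), d["participant_id"]


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank == X.shape[1]:
        return
    # name the dependent columns for the error message
    bad, kept = [], []
    for c in X.columns:
        trial = X[kept + [c]].to_numpy()
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(c)
        else:
            bad.append(c)
    raise ValueError(f"rank-deficient design; collinear terms: {bad}")


def _wald_table(names, coefs, ses) -> pd.DataFrame:
    coefs, ses = np.asarray(coefs, float), np.asarray(ses, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(coefs / ses))
    return pd.DataFrame(
        {
            "term": list(names),
            "coef": coefs,
            "se": ses,
            "ci95_low": coefs - _Z95 * ses,
            "ci95_high": coefs + _Z95 * ses,
            "pvalue": p,
        }
    )


def fit_mixed(
    analysis: pd.DataFrame,
    spec: ModelSpec | str,
    fix_zero_group_variance: bool = False,
) -> FitResult:
    """REML fit of the random-intercept mixed model for one outcome.

    ``fix_zero_group_variance=True`` pins the random-intercept variance at
    zero (the model then coincides with ordinary least squares) — useful for
    diagnostics on independent data.
    """
    if isinstance(spec, str):
        spec = ModelSpec(outcome=spec)
    if analysis["participant_id"].nunique() < 2 or len(analysis) < 2:
        raise ValueError("need >= 2 observations from >= 2 participants")
    X, y, groups = _build_design(analysis, spec)

    reml = spec.method.upper() == "REML"
    if fix_zero_group_variance:
        # tau^2 = 0 makes the marginal covariance sigma^2*I: the REML mixed
        # fit coincides exactly with ordinary least squares, so fit that.
        import statsmodels.api as sm

        res = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        fe = pd.Series(res.params, index=X.columns)
        se = pd.Series(res.bse, index=X.columns)
        terms = _wald_table(X.columns, fe.values, se.values)
        return FitResult(
            outcome=spec.outcome,
            terms=terms,
            group_var=0.0,
            resid_var=float(res.mse_resid),
            n_obs=int(len(y)),
            n_participants=int(groups.nunique()),
            converged=True,
            method=spec.method,
            cov_fe=pd.DataFrame(
                np.asarray(res.cov_params()), index=X.columns, columns=X.columns
            ),
        )

    import warnings as _w

    def _ok(cand) -> bool:
        if not bool(getattr(cand, "converged", False)):
            return False
        if not np.isfinite(cand.fe_params).all():
            return False
        diag = np.diag(np.asarray(cand.cov_params()))[: len(cand.fe_params)]
        return bool(np.isfinite(diag).all() and (diag >= 0).all())

    model = MixedLM(y.to_numpy(), X.to_numpy(), groups=groups.to_numpy())
    res = None
    for method in (None, "powell", "cg", "nm"):
        try:
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                kwargs = {} if method is None else {"method": method, "maxiter": 2000}
                cand = model.fit(reml=reml, **kwargs)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if _ok(cand):
            res = cand
            break
    if res is None:
        raise RuntimeError("mixed model failed to converge")
    converged = True
    group_var = float(np.asarray(res.cov_re).ravel()[0])
    if group_var <= 1e-10:
        logger.warning("random-intercept variance at boundary (0)")

    fe = pd.Series(res.fe_params, index=X.columns)
    with np.errstate(invalid="ignore"):  # boundary fits can yield a non-PSD vcov
        se = pd.Series(np.sqrt(np.diag(res.cov_params()))[: len(fe)], index=X.columns)
    terms = _wald_table(X.columns, fe.values, se.values)
    cov_fe = pd.DataFrame(
        np.asarray(res.cov_params())[: len(fe), : len(fe)], index=X.columns, columns=X.columns
    )
    return FitResult(
        outcome=spec.outcome,
        terms=terms,
        group_var=group_var,
        resid_var=float(res.scale),
        n_obs=int(len(y)),
        n_participants=int(groups.nunique()),
        converged=converged,
        method=spec.method,
        cov_fe=cov_fe,
    )


# ---------------------------------------------------------------------------
# contrasts


def level_contrasts(fit: FitResult, adjustment: str = "bonferroni") -> pd.DataFrame:
    """Wald contrasts: each level vs baseline and vs the previous level.

    The Bonferroni multiplier is the number of contrasts emitted; adjusted
    p-values are capped at 1.
    """
    level_terms = [t for t in fit.terms["term"] if t.startswith("level_")]
    levels = sorted(int(t.split("_")[1]) for t in level_terms)
    if not levels:
        raise ValueError("fit has no level terms to contrast")
    pairs = [(k, 0) for k in levels] + [
        (b, a) for a, b in zip(levels, levels[1:])
    ]
    coef = fit.terms.set_index("term")["coef"]
    rows = []
    for hi, lo in pairs:
        c = pd.Series(0.0, index=fit.cov_fe.index)
        c[f"level_{hi}"] = 1.0
        if lo != 0:
            c[f"level_{lo}"] = -1.0
        est = float((coef.reindex(c.index).fillna(0.0) * c).sum())
        var = float(c.values @ fit.cov_fe.values @ c.values)
        se = np.sqrt(var)
        if se == 0.0:
            p = 1.0 if est == 0.0 else 0.0
        else:
            p = float(2.0 * stats.norm.sf(abs(est) / se))
        rows.append(
            {
                "outcome": fit.outcome,
                "comparison": f"level{hi}_vs_level{lo}",
                "estimate": est,
                "se": se,
                "p_unadjusted": p,
            }
        )
    out = pd.DataFrame(rows)
    if adjustment == "bonferroni":
        out["p_adjusted"] = np.minimum(1.0, out["p_unadjusted"] * len(out))
    elif adjustment in ("none", None):
        out["p_adjusted"] = out["p_unadjusted"]
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    out["adjustment"] = adjustment
    return out


# ---------------------------------------------------------------------------
# weekly series


def weekly_series(analysis: pd.DataFrame, anchor_month_day: tuple[int, int] = (2, 3)) -> pd.DataFrame:
    """Weekly means of both outcomes per site and study year.

    Study weeks are 7-day blocks anchored at the window start (Feb 3 by
    default): Feb 3-9 is week 1, Feb 10-16 week 2, and so on.
    """
    df = analysis.copy()
    df["date"] = pd.to_datetime(df["date"])
    anchors = df["date"].dt.year.map(
        lambda y: pd.Timestamp(y, anchor_month_day[0], anchor_month_day[1])
    )
    df["week"] = ((df["date"] - anchors).dt.days // 7) + 1
    out = (
        df.groupby(["site", "year", "week"])
        .agg(
            fraction_home_mean=("fraction_home", "mean"),
            steps_mean=("total_steps", "mean"),
            n_days=("fraction_home", "size"),
        )
        .reset_index()
    )
    return out
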