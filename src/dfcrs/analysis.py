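"""Longitudinal and categorical analysis of trial cohort tables.

Mirrors the source trial's statistical pipeline:

* baseline group comparisons — chi-square for categorical covariates; for
  continuous covariates a Shapiro-Wilk normality gate chooses one-way ANOVA
  (all groups normal) or Kruskal-Wallis;
* a random-intercept linear mixed model for THI with fixed effects for
  follow-up time (days), treatment arm, gender, age, tinnitus location and
  course;
* a 3-category multinomial logistic model of the subjective outcome
  (reference: worsened) with bidirectional stepwise covariate selection
  scored by AICc (AIC/BIC selectable), odds ratios with Wald intervals;
* paired two-tailed t tests between all timepoint pairs per scale;
* outcome percentages from category counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .simulate import Cohort, SCALE_COLUMNS, TIMEPOINT_LABELS

__all__ = [
    "LMMResult",
    "MultinomialResult",
    "baseline_tests",
    "fit_thi_lmm",
    "fit_outcome_multinomial",
    "timepoint_contrasts",
    "outcome_proportions",
]

OUTCOME_LEVELS = ("worsened", "relief", "disappeared")

DEFAULT_LMM_FIXED = ("day", "arm", "gender", "age_years", "location",
                     "course_months")

DEFAULT_OUTCOME_CANDIDATES = ("daily_listen_hours", "gender", "age_years",
                              "course_months", "status", "severity_grade")


# ---------------------------------------------------------------------------
# Baseline comparisons
# ---------------------------------------------------------------------------

def baseline_tests(
    cohort: Cohort,
    group_col: str = "arm",
    covariates: tuple[str, ...] | None = None,
    shapiro_alpha: float = 0.05,
    force_categorical: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Test per-covariate group differences at baseline.

    Categorical covariates get a chi-square test of the contingency table;
    continuous covariates go through a Shapiro-Wilk gate (per group, at
    ``shapiro_alpha``): ANOVA when every group passes, Kruskal-Wallis
    otherwise. Constant covariates yield a degenerate-test warning row.
    """
    t0 = cohort.long[cohort.long["timepoint"] == TIMEPOINT_LABELS[0]]
    base = cohort.subjects.merge(
        t0[["subject_id", *[c for c in SCALE_COLUMNS if c in t0.columns]]],
        on="subject_id", how="left",
    )
    groups = [g for _, g in base.groupby(group_col)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("baseline_tests needs >= 2 nonempty groups")
    if covariates is None:
        covariates = tuple(
            c for c in base.columns
            if c not in ("subject_id", group_col, "outcome")
        )
    rows = []
    for cov in covariates:
        col = base[cov]
        if col.nunique(dropna=True) <= 1:
            rows.append({"covariate": cov, "test": "degenerate",
                         "statistic": float("nan"), "p": float("nan"),
                         "note": "constant covariate; no test performed"})
            continue
        categorical = (cov in force_categorical
                       or not pd.api.types.is_numeric_dtype(col))
        if categorical:
            table = pd.crosstab(base[cov], base[group_col])
            stat, p, _, _ = stats.chi2_contingency(table.values)
            rows.append({"covariate": cov, "test": "chi_square",
                         "statistic": float(stat), "p": float(p), "note": ""})
        else:
            samples = [g[cov].dropna().to_numpy(float) for g in groups]
            normal = all(
                len(s) >= 3 and stats.shapiro(s).pvalue > shapiro_alpha
                for s in samples
            )
            if normal:
                stat, p = stats.f_oneway(*samples)
                test = "anova"
            else:
                stat, p = stats.kruskal(*samples)
                test = "kruskal_wallis"
            rows.append({"covariate": cov, "test": test,
                         "statistic": float(stat), "p": float(p),
                         "note": f"shapiro gate at alpha={shapiro_alpha}"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    """Fixed-effect table plus variance components of a random-intercept fit."""

    table: pd.DataFrame  # term, estimate, se, t, df, p
    var_intercept: float
    var_resid: float
    converged: bool
    singular: bool
    df_method: str
    reference_levels: dict[str, str] = field(default_factory=dict)

    def estimate(self, term_substring: str) -> float:
        hit = self.table[self.table["term"].str.contains(term_substring,
                                                         regex=False)]
        if len(hit) != 1:
            raise KeyError(
                f"{term_substring!r} matches {len(hit)} terms: "
                f"{list(self.table['term'])}"
            )
        return float(hit["estimate"].iloc[0])


def fit_thi_lmm(
    cohort: Cohort,
    fixed: tuple[str, ...] = DEFAULT_LMM_FIXED,
    outcome_col: str = "thi",
    reml: bool = True,
) -> LMMResult:
    """Random-intercept linear mixed model for a longitudinal scale score.

    Sign convention: improvement over follow-up yields negative time and
    DFCRS-group estimates (UM and male and unilateral are reference levels).
    Degrees of freedom use a containment-style rule — between-subject terms:
    n_subjects - n_between_params; within-subject terms: n_obs - n_subjects
    - n_within_params — flagged in ``df_method``; a singular fit (zero
    random-intercept variance) is flagged, not silenced.
    """
    data = cohort.merged()
    refs = {"arm": "UM", "gender": "male", "location": "unilateral"}
    terms = []
    for cov in fixed:
        if cov in refs:
            terms.append(f"C({cov}, Treatment('{refs[cov]}'))")
        elif not pd.api.types.is_numeric_dtype(data[cov]):
            terms.append(f"C({cov})")
        else:
            terms.append(cov)
    formula = f"{outcome_col} ~ " + " + ".join(terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["subject_id"])
        fit = model.fit(reml=reml)

    n_obs = len(data)
    n_subj = data["subject_id"].nunique()
    within_covs = {
        cov for cov in fixed
        if data.groupby("subject_id")[cov].nunique().max() > 1
    }
    names = list(fit.fe_params.index)
    is_within = [any(cov in nm for cov in within_covs) for nm in names]
    n_within = sum(is_within)
    n_between = len(names) - n_within
    df_within = max(n_obs - n_subj - n_within, 1)
    df_between = max(n_subj - n_between, 1)

    rows = []
    for nm, w in zip(names, is_within):
        est = float(fit.fe_params[nm])
        se = float(fit.bse_fe[nm])
        t = est / se if se > 0 else float("nan")
        df = df_within if w else df_between
        p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else float("nan")
        rows.append({"term": nm, "estimate": est, "se": se, "t": t,
                     "df": df, "p": p})
    var_int = float(np.asarray(fit.cov_re).ravel()[0])
    return LMMResult(
        table=pd.DataFrame(rows),
        var_intercept=var_int,
        var_resid=float(fit.scale),
        converged=bool(fit.converged),
        singular=var_int <= 1e-8 * float(fit.scale),
        df_method="containment",
        reference_levels=refs,
    )


# ---------------------------------------------------------------------------
# Multinomial outcome model with stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class MultinomialResult:
    """Stepwise-selected multinomial logit: odds ratios vs the reference."""

    reference: str
    table: pd.DataFrame  # category, term, odds_ratio, ci_low, ci_high, p
    selected: tuple[str, ...]
    criterion: str
    criterion_value: float
    converged: bool
    separation_flag: bool

    def odds_ratio(self, category: str, term_substring: str) -> float:
        sub = self.table[(self.table["category"] == category)
                         & self.table["term"].str.contains(term_substring,
                                                           regex=False)]
        if len(sub) != 1:
            raise KeyError(f"no unique OR for {category}/{term_substring}")
        return float(sub["odds_ratio"].iloc[0])


def _design(data: pd.DataFrame, covs: tuple[str, ...]):
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for cov in covs:
        col = data[cov]
        if pd.api.types.is_numeric_dtype(col):
            X[cov] = col.astype(float)
        else:
            ref = {"gender": "male", "status": "continued",
                   "severity_grade": "I"}.get(cov)
            levels = sorted(col.unique())
            if ref in levels:
                levels = [ref] + [l for l in levels if l != ref]
            for lev in levels[1:]:
                X[f"{cov}[{lev}]"] = (col == lev).astype(float)
    return X


def _fit_mnlogit(y_codes: np.ndarray, X: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(y_codes, X)
        fit = model.fit(method="newton", maxiter=200, disp=0)
    return fit


def _criterion_value(fit, name: str) -> float:
    k = fit.params.size
    n = fit.nobs
    if name == "aic":
        return float(fit.aic)
    if name == "bic":
        return float(fit.bic)
    if name == "aicc":
        if n - k - 1 <= 0:
            return float("inf")
        return float(fit.aic + 2.0 * k * (k + 1) / (n - k - 1))
    raise ValueError(f"unknown criterion {name!r} (use aic/bic/aicc)")


def fit_outcome_multinomial(
    cohort: Cohort,
    candidate_covariates: tuple[str, ...] = DEFAULT_OUTCOME_CANDIDATES,
    criterion: str = "aicc",
    stepwise: bool = True,
) -> MultinomialResult:
    """Model the 3-category subjective outcome (reference: worsened).

    Bidirectional stepwise search from the intercept-only model, scored by
    ``criterion``; the winning covariate set is refit and reported as odds
    ratios with 95% Wald intervals. Quasi-separation (a huge coefficient) is
    flagged, not hidden.
    """
    subj = cohort.subjects
    data = subj[subj["outcome"].isin(OUTCOME_LEVELS)].copy()
    observed = [l for l in OUTCOME_LEVELS if (data["outcome"] == l).any()]
    if len(observed) < 3:
        raise ValueError(
            f"outcome has only {len(observed)} observed level(s): {observed}; "
            "a 3-category model needs all of worsened/relief/disappeared"
        )
    y = pd.Categorical(data["outcome"], categories=OUTCOME_LEVELS).codes

    def try_fit(covs: tuple[str, ...]):
        X = _design(data, covs)
        try:
            fit = _fit_mnlogit(y, X)
        except Exception:
            return None, float("inf")
        if not np.all(np.isfinite(fit.params.values)):
            return None, float("inf")
        return fit, _criterion_value(fit, criterion)

    selected: tuple[str, ...] = ()
    best_fit, best_val = try_fit(selected)
    if stepwise:
        improved = True
        while improved:
            improved = False
            moves = [selected + (c,) for c in candidate_covariates
                     if c not in selected]
            moves += [tuple(s for s in selected if s != c) for c in selected]
            for cand in moves:
                fit, val = try_fit(cand)
                if val < best_val - 1e-9:
                    best_fit, best_val, selected = fit, val, cand
                    improved = True
    else:
        selected = tuple(candidate_covariates)
        best_fit, best_val = try_fit(selected)
    if best_fit is None:
        raise RuntimeError("multinomial fit failed for every candidate model")

    params = best_fit.params  # (k_exog, J-1); columns = non-reference cats
    with warnings.catch_warnings():
        # near-separation gives a singular Hessian: bse come out NaN and the
        # intervals infinite; that is reported, flagged, not silenced
        warnings.simplefilter("ignore", RuntimeWarning)
        bse = best_fit.bse
        pvals = best_fit.pvalues
    z = stats.norm.ppf(0.975)
    rows = []
    old_err = np.seterr(over="ignore")  # huge Wald bounds become inf, kept as-is
    for j, cat in enumerate(OUTCOME_LEVELS[1:]):
        for term in params.index:
            b = float(params.iloc[:, j][term])
            s = float(np.asarray(bse)[list(params.index).index(term), j])
            rows.append({
                "category": cat, "term": term,
                "odds_ratio": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * s)),
                "ci_high": float(np.exp(b + z * s)),
                "p": float(np.asarray(pvals)[list(params.index).index(term), j]),
            })
    np.seterr(**old_err)
    table = pd.DataFrame(rows)
    separation = bool(np.any(np.abs(params.values) > 20.0))
    return MultinomialResult(
        reference=OUTCOME_LEVELS[0],
        table=table,
        selected=selected,
        criterion=criterion,
        criterion_value=float(best_val),
        converged=bool(best_fit.mle_retvals.get("converged", True)),
        separation_flag=separation,
    )


# ---------------------------------------------------------------------------
# Timepoint contrasts and outcome proportions
# ---------------------------------------------------------------------------

def timepoint_contrasts(cohort: Cohort, scale: str = "thi") -> pd.DataFrame:
    """Paired two-tailed t tests between every pair of the four visits.

    Subjects missing either visit of a pair are dropped listwise for that
    pair; the per-pair n is reported. Identical paired scores give t=0, p=1.
    """
    if scale not in cohort.long.columns:
        raise ValueError(f"scale {scale!r} not in cohort")
    wide = cohort.long.pivot_table(index="subject_id", columns="timepoint",
                                   values=scale, aggfunc="first")
    rows = []
    present = [t for t in TIMEPOINT_LABELS if t in wide.columns]
    for a, b in itertools.combinations(present, 2):
        pair = wide[[a, b]].dropna()
        n = len(pair)
        if n < 2:
            rows.append({"scale": scale, "timepoint_a": a, "timepoint_b": b,
                         "n": n, "mean_diff": float("nan"),
                         "t": float("nan"), "p": float("nan"),
                         "note": "fewer than 2 complete pairs"})
            continue
        diff = pair[a].to_numpy(float) - pair[b].to_numpy(float)
        if np.allclose(diff.std(ddof=1), 0.0) and np.allclose(diff.mean(), 0.0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_rel(pair[a], pair[b])
        rows.append({"scale": scale, "timepoint_a": a, "timepoint_b": b,
                     "n": n, "mean_diff": float(diff.mean()),
                     "t": float(t_stat), "p": float(p), "note": ""})
    return pd.DataFrame(rows)


def outcome_proportions(
    outcome_counts: dict[str, int],
    combine: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, float]:
    """Percentages 100*count/total, one decimal; supports combined categories.

    ``combine`` maps a new name to the categories whose counts are pooled
    (e.g. relief-or-disappeared).
    """
    if any(c < 0 for c in outcome_counts.values()):
        raise ValueError("counts must be nonnegative")
    total = sum(outcome_counts.values())
    if total == 0:
        raise ValueError("zero total count")
    pct = {k: round(100.0 * v / total, 1) for k, v in outcome_counts.items()}
    for name, cats in (combine or {}).items():
        missing = [c for c in cats if c not in outcome_counts]
        if missing:
            raise KeyError(f"unknown categories in combine: {missing}")
        pct[name] = round(100.0 * sum(outcome_counts[c] for c in cats) / total, 1)
    return pct
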