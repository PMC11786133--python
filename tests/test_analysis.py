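"""Analysis pipeline against brute-force oracles and simulations.

The oracles here are deliberately library-free re-derivations: the paired t
statistic from its textbook formula, the Yates-corrected 2x2 chi-square in
closed form, and a multinomial-logit maximum likelihood found by direct
Newton iteration on the log-likelihood written out in this file.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dfcrs.analysis import (
    baseline_tests,
    fit_outcome_multinomial,
    fit_thi_lmm,
    outcome_proportions,
    timepoint_contrasts,
)
from dfcrs.simulate import Cohort, SimulationConfig, generate_cohort


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def paired_t_oracle(a, b):
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), d = a - b."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return t, p


def chi2_2x2_yates_oracle(a, b, c, d):
    """Closed-form Yates-corrected chi-square for a 2x2 table [[a,b],[c,d]]."""
    n = a + b + c + d
    num = n * (abs(a * d - b * c) - n / 2.0) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    stat = num / den
    return stat, stats.chi2.sf(stat, 1)


def multinomial_mle_oracle(y, x, n_iter=200):
    """Direct Newton maximisation of the 3-category logit likelihood with
    design (1, x); categories coded 0 (reference), 1, 2. Returns the flat
    parameter vector (a1, b1, a2, b2)."""
    X = np.column_stack([np.ones_like(x, dtype=float), x])
    k = X.shape[1]
    beta = np.zeros(2 * k)

    def probs(beta):
        eta = np.column_stack([X @ beta[:k], X @ beta[k:]])
        e = np.exp(eta)
        denom = 1.0 + e.sum(axis=1)
        return np.column_stack([e[:, 0] / denom, e[:, 1] / denom])

    Y = np.column_stack([y == 1, y == 2]).astype(float)
    for _ in range(n_iter):
        P = probs(beta)
        grad = np.concatenate([X.T @ (Y[:, 0] - P[:, 0]),
                               X.T @ (Y[:, 1] - P[:, 1])])
        H = np.zeros((2 * k, 2 * k))
        for j in range(2):
            for l in range(2):
                w = P[:, j] * ((j == l) - P[:, l])
                H[j * k:(j + 1) * k, l * k:(l + 1) * k] = -(X * w[:, None]).T @ X
        step = np.linalg.solve(H, grad)
        beta = beta - step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


# ---------------------------------------------------------------------------
# oracle-equivalence tests on hand-sized fixtures
# ---------------------------------------------------------------------------

PAIRED_T0 = [62.0, 48.0, 55.0, 70.0, 41.0]
PAIRED_T3 = [30.0, 36.0, 20.0, 52.0, 39.0]


def paired_fixture_cohort():
    rows = []
    for i, (a, b) in enumerate(zip(PAIRED_T0, PAIRED_T3)):
        rows.append({"subject_id": f"S{i}", "timepoint": "T0", "day": 0.0,
                     "thi": a})
        rows.append({"subject_id": f"S{i}", "timepoint": "T3", "day": 90.0,
                     "thi": b})
    subjects = pd.DataFrame({"subject_id": [f"S{i}" for i in range(5)],
                             "arm": ["DFCRS"] * 5, "outcome": [""] * 5})
    return Cohort(subjects=subjects, long=pd.DataFrame(rows))


def test_paired_t_matches_textbook_oracle():
    res = timepoint_contrasts(paired_fixture_cohort(), "thi")
    row = res[(res.timepoint_a == "T0") & (res.timepoint_b == "T3")].iloc[0]
    t_ref, p_ref = paired_t_oracle(PAIRED_T0, PAIRED_T3)
    assert row["t"] == pytest.approx(t_ref, abs=1e-6)
    assert row["p"] == pytest.approx(p_ref, abs=1e-6)
    assert row["n"] == 5


def test_identical_scores_give_t0_p1(tiny_cohort_frame):
    cohort = tiny_cohort_frame
    flat = cohort.long.copy()
    flat["thi"] = 30.0
    res = timepoint_contrasts(Cohort(cohort.subjects, flat), "thi")
    assert (res["t"] == 0.0).all() and (res["p"] == 1.0).all()


def test_chi_square_matches_closed_form_oracle():
    # binary covariate through the categorical path of baseline_tests
    subjects = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(40)],
        "arm": ["DFCRS"] * 22 + ["UM"] * 18,
        "smoker": (["yes"] * 15 + ["no"] * 7) + (["yes"] * 5 + ["no"] * 13),
        "outcome": [""] * 40,
    })
    long = pd.DataFrame({"subject_id": subjects.subject_id, "timepoint": "T0",
                         "day": 0.0, "thi": 50.0})
    res = baseline_tests(Cohort(subjects, long), covariates=("smoker",))
    row = res[res.covariate == "smoker"].iloc[0]
    stat_ref, p_ref = chi2_2x2_yates_oracle(7, 15, 13, 5)
    assert row["statistic"] == pytest.approx(stat_ref, abs=1e-6)
    assert row["p"] == pytest.approx(p_ref, abs=1e-6)


def test_multinomial_fit_matches_newton_oracle():
    hours = np.array([0.8, 1.2, 1.6, 1.9, 2.1, 2.4, 2.6, 2.9, 3.2, 3.6])
    y = np.array([0, 0, 1, 0, 1, 1, 2, 1, 2, 1])
    subjects = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(10)],
        "arm": ["DFCRS"] * 10,
        "daily_listen_hours": hours,
        "outcome": np.array(["worsened", "relief", "disappeared"])[y],
    })
    long = pd.DataFrame({"subject_id": subjects.subject_id, "timepoint": "T0",
                         "day": 0.0, "thi": 50.0})
    res = fit_outcome_multinomial(
        Cohort(subjects, long),
        candidate_covariates=("daily_listen_hours",),
        stepwise=False,
    )
    beta = multinomial_mle_oracle(y, hours)
    a1, b1, a2, b2 = beta
    assert res.odds_ratio("relief", "daily_listen_hours") == \
        pytest.approx(math.exp(b1), abs=1e-6 * max(1, math.exp(b1)))
    assert res.odds_ratio("disappeared", "daily_listen_hours") == \
        pytest.approx(math.exp(b2), abs=1e-6 * max(1, math.exp(b2)))
    intercepts = res.table[res.table.term == "Intercept"]
    got = {r.category: math.log(r.odds_ratio) for r in intercepts.itertuples()}
    assert got["relief"] == pytest.approx(a1, abs=1e-6)
    assert got["disappeared"] == pytest.approx(a2, abs=1e-6)


# ---------------------------------------------------------------------------
# baseline test dispatch
# ---------------------------------------------------------------------------

def test_identical_groups_balanced_categorical_p_near_one():
    subjects = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(40)],
        "arm": ["DFCRS"] * 20 + ["UM"] * 20,
        "gender": ["male", "female"] * 20,
        "outcome": [""] * 40,
    })
    long = pd.DataFrame({"subject_id": subjects.subject_id, "timepoint": "T0",
                         "day": 0.0, "thi": 50.0})
    res = baseline_tests(Cohort(subjects, long), covariates=("gender",))
    assert res.iloc[0]["p"] > 0.99


def test_large_location_shift_detected_by_kruskal_wallis():
    rng = np.random.default_rng(21)
    # lognormal covariate fails the normality gate; big shift between arms
    vals = np.concatenate([np.exp(rng.normal(0, 1, 60)),
                           np.exp(rng.normal(2, 1, 60))])
    subjects = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(120)],
        "arm": ["DFCRS"] * 60 + ["UM"] * 60,
        "course_months": vals,
        "outcome": [""] * 120,
    })
    long = pd.DataFrame({"subject_id": subjects.subject_id, "timepoint": "T0",
                         "day": 0.0, "thi": 50.0})
    res = baseline_tests(Cohort(subjects, long), covariates=("course_months",))
    row = res.iloc[0]
    assert row["test"] == "kruskal_wallis"
    assert row["p"] < 1e-3


def test_constant_covariate_degenerate_row(tiny_cohort_frame):
    res = baseline_tests(tiny_cohort_frame, covariates=("status",))
    assert res.iloc[0]["test"] == "degenerate"


# ---------------------------------------------------------------------------
# LMM behaviour on simulations
# ---------------------------------------------------------------------------

def test_noise_free_cohort_recovers_slope_exactly():
    cfg = SimulationConfig(sd_intercept=1e-4, sd_resid=1e-4)
    cohort = generate_cohort(cfg, seed=10)
    res = fit_thi_lmm(cohort)
    assert res.estimate("day") == pytest.approx(cfg.beta_time, abs=1e-3)
    assert res.estimate("DFCRS") == pytest.approx(cfg.beta_group, abs=1e-2)


def test_permuted_arm_labels_rarely_significant():
    rng = np.random.default_rng(31)
    n_sig = 0
    n_rep = 30
    for s in range(n_rep):
        cohort = generate_cohort(SimulationConfig(), seed=400 + s)
        cohort.subjects["arm"] = rng.permutation(cohort.subjects["arm"].values)
        res = fit_thi_lmm(cohort)
        p = res.table.loc[res.table.term.str.contains("DFCRS"), "p"].iloc[0]
        n_sig += p < 0.05
    assert n_sig <= 0.10 * n_rep + 1  # >=90% nonsignificant under the null


def test_lmm_result_flags_present(default_cohort):
    res = fit_thi_lmm(default_cohort)
    assert res.converged
    assert res.df_method == "containment"
    assert res.var_intercept > 0 and res.var_resid > 0
    assert res.table["p"].between(0, 1).all()
    # improvement convention: time and DFCRS estimates come out negative
    assert res.estimate("day") < 0 and res.estimate("DFCRS") < 0


# ---------------------------------------------------------------------------
# multinomial selection behaviour
# ---------------------------------------------------------------------------

def test_stepwise_recovers_dose_response_sign(default_cohort):
    res = fit_outcome_multinomial(default_cohort)
    assert "daily_listen_hours" in res.selected
    assert res.odds_ratio("relief", "daily_listen_hours") > 1
    assert res.odds_ratio("disappeared", "daily_listen_hours") > 1


def test_pure_noise_covariate_usually_excluded():
    excluded = 0
    n_rep = 7
    for s in range(n_rep):
        cohort = generate_cohort(SimulationConfig(), seed=600 + s)
        rng = np.random.default_rng(s)
        cohort.subjects["noise_cov"] = rng.standard_normal(len(cohort.subjects))
        res = fit_outcome_multinomial(
            cohort,
            candidate_covariates=("daily_listen_hours", "severity_grade",
                                  "noise_cov"),
        )
        excluded += "noise_cov" not in res.selected
    assert excluded > n_rep / 2


def test_two_level_outcome_rejected(default_cohort):
    subj = default_cohort.subjects.copy()
    subj.loc[subj.outcome == "disappeared", "outcome"] = "relief"
    broken = Cohort(subj, default_cohort.long)
    with pytest.raises(ValueError, match="level"):
        fit_outcome_multinomial(broken)


def test_refit_on_selected_set_identical(default_cohort):
    res = fit_outcome_multinomial(default_cohort)
    refit = fit_outcome_multinomial(
        default_cohort, candidate_covariates=res.selected, stepwise=False
    )
    merged = res.table.merge(refit.table, on=["category", "term"],
                             suffixes=("_sel", "_refit"))
    assert len(merged) == len(res.table)
    np.testing.assert_allclose(merged["odds_ratio_sel"],
                               merged["odds_ratio_refit"], rtol=1e-6)


# ---------------------------------------------------------------------------
# outcome proportions
# ---------------------------------------------------------------------------

class TestOutcomeProportions:
    def test_reported_trial_split(self):
        pct = outcome_proportions(
            {"relief": 93, "disappeared": 6, "worsened": 8},
            combine={"relief_or_disappeared": ("relief", "disappeared")},
        )
        assert pct["relief"] == 86.9
        assert pct["disappeared"] == 5.6
        assert pct["worsened"] == 7.5
        assert pct["relief_or_disappeared"] == 92.5

    def test_single_category_is_100(self):
        assert outcome_proportions({"relief": 12})["relief"] == 100.0

    def test_rounding_keeps_total_near_100(self):
        pct = outcome_proportions({"a": 1, "b": 1, "c": 1})
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.2)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            outcome_proportions({"relief": 0})

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            outcome_proportions({"relief": -1})


def test_t0_vs_t3_power_in_dfcrs_arm(default_cohort):
    dfcrs_ids = default_cohort.subjects.loc[
        default_cohort.subjects.arm == "DFCRS", "subject_id"
    ]
    sub = Cohort(
        subjects=default_cohort.subjects[
            default_cohort.subjects.subject_id.isin(dfcrs_ids)
        ],
        long=default_cohort.long[
            default_cohort.long.subject_id.isin(dfcrs_ids)
        ],
    )
    res = timepoint_contrasts(sub, "thi")
    row = res[(res.timepoint_a == "T0") & (res.timepoint_b == "T3")].iloc[0]
    assert row["p"] < 1e-3
    assert row["mean_diff"] > 0  # THI declines over treatment
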