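import warnings

import numpy as np
import pandas as pd
import pytest

from pathprs.association_models import (
    emm_pairwise_contrasts,
    fit_biomarker_models,
    fit_extended_models,
    fit_ols,
    fit_stage_model,
    plot_scores_by_stage,
)
from pathprs.errors import CollinearityError, ValidationError
from pathprs.prs_engine import (
    align_effect_alleles,
    compute_all_scores,
    impute_missing_dosage,
)
from pathprs.variant_qc import apply_variant_qc

from oracles import ols_normal_equations


def scores_from(sim):
    matrix, weights, cohort, truth = sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered, _ = apply_variant_qc(matrix)
        al = impute_missing_dosage(align_effect_alleles(weights, filtered))
        return compute_all_scores(al, weights), cohort, truth


# ---------------------------------------------------------------------------
# OLS core
# ---------------------------------------------------------------------------

def test_perfect_fit_recovers_unit_coefficient():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(20), rng.normal(size=20), rng.normal(size=20)])
    y = X[:, 1].copy()
    res = fit_ols(y, X, ["intercept", "x1", "x2"])
    assert res.estimate("x1") == pytest.approx(1.0, abs=1e-12)
    assert res.estimate("intercept") == pytest.approx(0.0, abs=1e-12)
    assert res.r_squared == pytest.approx(1.0)


def test_simple_regression_matches_closed_form():
    """n=6 toy: slope = S_xy / S_xx, intercept = ybar - slope * xbar."""
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.array([1.1, 1.9, 3.2, 3.8, 5.1, 5.8])
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    intercept = y.mean() - slope * x.mean()
    res = fit_ols(y, np.column_stack([np.ones(6), x]), ["intercept", "x"])
    assert res.estimate("x") == pytest.approx(slope, rel=1e-14)
    assert res.estimate("intercept") == pytest.approx(intercept, rel=1e-14)
    assert res.df_resid == 4


def test_row_permutation_leaves_fit_unchanged():
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
    y = rng.normal(size=30)
    perm = rng.permutation(30)
    a = fit_ols(y, X)
    b = fit_ols(y[perm], X[perm])
    pd.testing.assert_frame_equal(a.params, b.params, atol=1e-12, rtol=0)


def test_ols_matches_normal_equations_and_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(7)
    for _ in range(20):
        n, p = 40, 4
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        mine = fit_ols(y, X)
        beta, se, df = ols_normal_equations(y, X)
        np.testing.assert_allclose(mine.params["estimate"], beta, rtol=1e-10)
        np.testing.assert_allclose(mine.params["se"], se, rtol=1e-10)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(mine.params["estimate"], ref.params, rtol=1e-9)
        np.testing.assert_allclose(mine.params["p_value"], ref.pvalues, rtol=1e-8)
        ci = ref.conf_int(0.05)
        np.testing.assert_allclose(mine.params["ci_low"], ci[:, 0], rtol=1e-8)


def test_rank_deficiency_names_collinear_column():
    X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
    with pytest.raises(CollinearityError, match="x2"):
        fit_ols(np.random.default_rng(0).normal(size=10), X)


def test_underdetermined_fit_rejected():
    with pytest.raises(ValidationError, match="n=2"):
        fit_ols(np.zeros(2), np.eye(2) + 1)


# ---------------------------------------------------------------------------
# stage model
# ---------------------------------------------------------------------------

def test_stage_model_recovers_planted_intermediate_shift():
    """On a large liability-simulated cohort the intermediate-vs-none
    coefficient must cover the planted PRS shift."""
    from pathprs.synthetic_cohort import SimulationConfig, simulate_cohort

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = simulate_cohort(SimulationConfig(n_samples=5500, seed=99))
    scores, cohort, truth = scores_from(sim)
    res = fit_stage_model(cohort, scores)
    planted = truth.stage_shift["intermediate"]
    row = res.params.set_index("term").loc["stage_intermediate"]
    assert row["ci_low"] - 0.02 <= planted <= row["ci_high"] + 0.02
    # ordering of planted shifts mirrors the stage severity ordering
    assert truth.stage_shift["early"] < planted < truth.stage_shift["late"]


def test_stage_model_requires_reference_group(study_scale_sim):
    scores, cohort, _ = scores_from(study_scale_sim)
    no_controls = cohort[cohort["stage"].astype(str) != "none"]
    with pytest.raises(ValidationError, match="reference"):
        fit_stage_model(no_controls, scores)


def test_age_negation_negates_age_coefficient(study_scale_sim):
    scores, cohort, _ = scores_from(study_scale_sim)
    res = fit_stage_model(cohort, scores)
    flipped = cohort.assign(age=-cohort["age"])
    res2 = fit_stage_model(flipped, scores)
    assert res2.estimate("age") == pytest.approx(-res.estimate("age"), rel=1e-10)
    assert res2.estimate("stage_intermediate") == pytest.approx(
        res.estimate("stage_intermediate"), rel=1e-10
    )


# ---------------------------------------------------------------------------
# biomarker models
# ---------------------------------------------------------------------------

def test_biomarker_family_is_six_scores_by_four_models(large_intermediate_sim):
    scores, cohort, _ = scores_from(large_intermediate_sim)
    fits = fit_biomarker_models(cohort, scores)
    assert len(fits) == 24
    joint = [f for f in fits if f.model_id.startswith("model4")]
    assert all(
        {"irora", "crora"} <= set(f.params["term"]) for f in joint
    )  # one combined atrophy fit


def test_planted_rpd_effects_detected(large_intermediate_sim):
    scores, cohort, _ = scores_from(large_intermediate_sim)
    fits = {f.model_id: f for f in fit_biomarker_models(cohort, scores)}
    ah = fits["model1:rpd:ah_prs"]
    e = fits["model1:rpd:e_prs"]
    cr = fits["model4:irora+crora:ah_prs"]
    assert ah.estimate("rpd") > 0 and ah.p_value("rpd") < 0.05
    assert e.estimate("rpd") > 0 and e.p_value("rpd") < 0.05
    assert cr.estimate("crora") > 0 and cr.p_value("crora") < 0.05


def test_constant_biomarker_column_fails_alone(large_intermediate_sim):
    scores, cohort, _ = scores_from(large_intermediate_sim)
    broken = cohort.copy()
    broken["pa"] = pd.array([False] * len(broken), dtype="boolean")
    with pytest.warns(UserWarning, match="model2"):
        fits = fit_biomarker_models(broken, scores, score_names=["global_prs"])
    ids = {f.model_id for f in fits}
    assert "model2:pa:global_prs" not in ids and len(fits) == 3


def test_extended_models_and_atrophy_degeneracy(large_intermediate_sim):
    scores, cohort, _ = scores_from(large_intermediate_sim)
    res_a = fit_extended_models(cohort, scores, "global_prs", include_atrophy=False)
    assert {"rpd", "pa", "hrf"} <= set(res_a.params["term"])
    no_atrophy = cohort.copy()
    no_atrophy["irora"] = pd.array([False] * len(cohort), dtype="boolean")
    no_atrophy["crora"] = pd.array([False] * len(cohort), dtype="boolean")
    res_a2 = fit_extended_models(no_atrophy, scores, "global_prs", False)
    np.testing.assert_allclose(
        res_a2.params["estimate"], res_a.params["estimate"], rtol=1e-12
    )
    with pytest.raises(CollinearityError):
        fit_extended_models(no_atrophy, scores, "global_prs", include_atrophy=True)


# ---------------------------------------------------------------------------
# estimated marginal means
# ---------------------------------------------------------------------------

def test_contrast_to_reference_equals_dummy_coefficient(study_scale_sim):
    scores, cohort, _ = scores_from(study_scale_sim)
    res = fit_stage_model(cohort, scores)
    contrasts = {(c.group_a, c.group_b): c for c in emm_pairwise_contrasts(res, cohort)}
    c = contrasts[("none", "early")]
    assert -c.difference == pytest.approx(res.estimate("stage_early"), rel=1e-12)
    assert c.se == pytest.approx(
        res.params.set_index("term").loc["stage_early", "se"], rel=1e-12
    )
    c2 = contrasts[("intermediate", "late")]
    assert c2.difference == pytest.approx(
        res.estimate("stage_intermediate") - res.estimate("stage_late"), rel=1e-12
    )


def test_contrasts_telescope_to_zero(study_scale_sim):
    scores, cohort, _ = scores_from(study_scale_sim)
    res = fit_stage_model(cohort, scores)
    cs = {(c.group_a, c.group_b): c.difference for c in emm_pairwise_contrasts(res, cohort)}
    total = cs[("none", "early")] + cs[("early", "intermediate")] - cs[("none", "intermediate")]
    assert total == pytest.approx(0.0, abs=1e-12)
    assert len(cs) == 6  # four stages -> six pairs


def test_re_referencing_leaves_contrasts_invariant(study_scale_sim):
    scores, cohort, _ = scores_from(study_scale_sim)
    base = fit_stage_model(cohort, scores, reference="none")
    alt = fit_stage_model(cohort, scores, reference="early")
    c1 = {
        frozenset((c.group_a, c.group_b)): abs(c.difference)
        for c in emm_pairwise_contrasts(base, cohort)
    }
    c2 = {
        frozenset((c.group_a, c.group_b)): abs(c.difference)
        for c in emm_pairwise_contrasts(alt, cohort)
    }
    assert set(c1) == set(c2)
    for k in c1:
        assert c1[k] == pytest.approx(c2[k], abs=1e-10)


# ---------------------------------------------------------------------------
# figure
# ---------------------------------------------------------------------------

def test_box_plot_written_for_multi_and_single_stage(tmp_path, study_scale_sim):
    scores, cohort, _ = scores_from(study_scale_sim)
    out = tmp_path / "plot.png"
    plot_scores_by_stage(scores, cohort, out)
    assert out.stat().st_size > 0
    single = cohort[cohort["stage"].astype(str) == "intermediate"]
    plot_scores_by_stage(scores, single, tmp_path / "one.png")
    with pytest.raises(ValidationError):
        plot_scores_by_stage(scores, cohort.iloc[0:0], tmp_path / "none.png")
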