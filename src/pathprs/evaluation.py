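"""Simulation studies over the pipeline: planted-effect recovery, prevalence
calibration, and frequentist calibration (type-I error, CI coverage) of the
least-squares core.

Each routine re-runs the package end to end on freshly simulated cohorts —
nothing is memoized — so the numbers it returns are always recomputed from
the study conditions in :class:`~pathprs.synthetic_cohort.SimulationConfig`.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .association_models import fit_biomarker_models, fit_ols
from .prs_engine import (
    align_effect_alleles,
    compute_all_scores,
    impute_missing_dosage,
)
from .synthetic_cohort import SimulationConfig, simulate_cohort
from .variant_qc import apply_variant_qc

#: (model_id prefix, term) pairs carrying a planted effect under the default
#: simulation conditions.
PLANTED_TERMS = [
    ("model1:rpd:ah_prs", "rpd"),
    ("model1:rpd:e_prs", "rpd"),
    ("model4:irora+crora:ah_prs", "crora"),
]

#: (model_id, term) pairs that are genuinely null under the defaults: no
#: planted coefficient links that score to that biomarker.
NULL_TERMS = (
    [("model1:rpd:c_prs", "rpd"), ("model1:rpd:l_prs", "rpd")]
    + [(f"model4:irora+crora:{s}", "crora") for s in ("c_prs", "l_prs", "e_prs")]
    + [
        (f"model{m}:{b}:{s}", b)
        for m, b in ((2, "pa"), (3, "hrf"))
        for s in ("global_prs", "ah_prs", "c_ah_prs", "c_prs", "e_prs", "l_prs")
    ]
    + [
        (f"model4:irora+crora:{s}", "irora")
        for s in ("global_prs", "ah_prs", "c_ah_prs", "c_prs", "e_prs", "l_prs")
    ]
)


def _scores_for(sim):
    matrix, weights, cohort, truth = sim
    filtered, _ = apply_variant_qc(matrix)
    aligned = impute_missing_dosage(align_effect_alleles(weights, filtered))
    return compute_all_scores(aligned, weights), cohort


def recovery_study(
    n_reps: int = 200, n_samples: int = 4000, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Planted-effect recovery across replicate intermediate-AMD cohorts.

    Each replicate simulates ``n_samples`` intermediate-stage participants
    under the default planted effects (RPD on AH + ECM scores, cRORA on
    AH), runs QC -> scoring -> the biomarker model family, and records
    whether each planted term is positive and significant and whether each
    null term crosses alpha. Returns per-term recovery rates and the
    pooled null significance rate.
    """
    hits = {key: 0 for key, _ in PLANTED_TERMS}
    null_sig = 0
    null_total = 0
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            cfg = SimulationConfig(
                n_samples=n_samples, stage_mode="intermediate_only", seed=rep_seed
            )
            scores, cohort = _scores_for(simulate_cohort(cfg))
            fits = {f.model_id: f for f in fit_biomarker_models(cohort, scores)}
            for model_id, term in PLANTED_TERMS:
                f = fits[model_id]
                if f.estimate(term) > 0 and f.p_value(term) < alpha:
                    hits[model_id] += 1
            for model_id, term in NULL_TERMS:
                null_total += 1
                if fits[model_id].p_value(term) < alpha:
                    null_sig += 1
    return {
        "rpd_ah_recovery": hits["model1:rpd:ah_prs"] / n_reps,
        "rpd_e_recovery": hits["model1:rpd:e_prs"] / n_reps,
        "crora_ah_recovery": hits["model4:irora+crora:ah_prs"] / n_reps,
        "null_significance_rate": null_sig / null_total,
        "n_reps": n_reps,
        "n_null_terms": null_total,
    }


def prevalence_calibration(n_samples: int = 20_000, seed: int = 0) -> dict:
    """Observed biomarker prevalences in one large intermediate-only cohort
    (targets are the profile prevalences; the iRORA group is reported after
    the combined atrophy recoding)."""
    cfg = SimulationConfig(
        n_samples=n_samples, stage_mode="intermediate_only", seed=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, _, cohort, _ = simulate_cohort(cfg)
    return {
        b: float(cohort[b].mean()) for b in ("rpd", "pa", "hrf", "irora", "crora")
    }


def ols_calibration(
    n_reps: int = 2000, n: int = 200, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Type-I error and 95% CI coverage of the biomarker t-test.

    Refits the biomarker-model design (intercept + flag + age + sex) on
    Gaussian responses: under the null (flag coefficient 0) the rejection
    rate estimates the size of the test; under a nonzero coefficient the
    CI coverage of the true value is recorded. Both should sit at their
    nominal levels by t-theory; this measures the implementation.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    covered = 0
    true_beta = np.array([0.1, 0.0, -0.002, 0.03])  # null flag term
    true_beta_cov = np.array([0.1, 0.08, -0.002, 0.03])
    names = ["intercept", "flag", "age", "sex_male"]
    for _ in range(n_reps):
        X = np.column_stack(
            [
                np.ones(n),
                rng.random(n) < 0.25,
                rng.normal(71.5, 7.0, size=n),
                rng.random(n) < 0.35,
            ]
        ).astype(float)
        y0 = X @ true_beta + rng.normal(0, 0.4, size=n)
        res = fit_ols(y0, X, names)
        if res.p_value("flag") < alpha:
            rejections += 1
        y1 = X @ true_beta_cov + rng.normal(0, 0.4, size=n)
        res1 = fit_ols(y1, X, names)
        row = res1.params.set_index("term").loc["flag"]
        if row["ci_low"] <= true_beta_cov[1] <= row["ci_high"]:
            covered += 1
    return {
        "type1_error": rejections / n_reps,
        "ci_coverage": covered / n_reps,
        "n_reps": n_reps,
    }


def hwe_exhaustive_deviation(oracle, max_total: int = 60) -> float:
    """Max |implementation - oracle| HWE P over every genotype-count triple
    with total <= ``max_total``. ``oracle`` is an independent
    (a, b, c) -> P function."""
    from .variant_qc import hwe_exact_test

    worst = 0.0
    for n in range(1, max_total + 1):
        for b in range(0, n + 1):
            for a in range(0, n - b + 1):
                c = n - b - a
                diff = abs(hwe_exact_test(a, b, c) - oracle(a, b, c))
                if diff > worst:
                    worst = diff
    return worst
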