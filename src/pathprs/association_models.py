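"""Multivariable linear models linking PRS to AMD stage and structural
biomarkers, plus estimated-marginal-means stage contrasts.

Modelling direction follows the descriptive design: the PRS (global or
pathway-specific) is the *dependent* variable and stage / biomarker flags
are independent variables, always adjusted for age and sex. Reference
categories are fixed: the no-AMD control group for stage and female for
sex. P values come from the t distribution with residual degrees of
freedom and are never adjusted for multiple comparisons.

The least-squares core is implemented here directly (QR decomposition,
covariance sigma^2 (X'X)^-1) so that every downstream number is traceable
to one code path; external model libraries are used only as independent
oracles in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, ValidationError
from .io_formats import STAGE_LEVELS

BIOMARKER_MODELS: dict[int, tuple[str, ...]] = {
    1: ("rpd",),
    2: ("pa",),
    3: ("hrf",),
    4: ("irora", "crora"),  # combined atrophy model, reference = neither
}

ALL_SCORES = ["global_prs", "ah_prs", "c_ah_prs", "c_prs", "e_prs", "l_prs"]


@dataclass
class ModelResult:
    """One fitted linear model: per-term estimates and inference plus the
    coefficient covariance needed for linear contrasts."""

    model_id: str
    params: pd.DataFrame = field(repr=False)  # term, estimate, se, t, p, CI
    n: int = 0
    df_resid: int = 0
    r_squared: float = np.nan
    cov: np.ndarray = field(default=None, repr=False)

    def estimate(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "estimate"])

    def p_value(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "p_value"])

    def term_index(self, term: str) -> int:
        return list(self.params["term"]).index(term)


@dataclass(frozen=True)
class ContrastResult:
    """Difference of adjusted (marginal) means between two groups."""

    group_a: str
    group_b: str
    difference: float
    se: float
    t: float
    p_value: float


def fit_ols(
    response: np.ndarray,
    design: np.ndarray,
    term_names: list[str] | None = None,
    model_id: str = "ols",
) -> ModelResult:
    """Ordinary least squares via QR with classical (homoskedastic)
    standard errors; 95% CIs use t_{0.975, n-p}.

    Raises :class:`CollinearityError` naming suspect columns for rank
    deficient designs and :class:`ValidationError` when n <= p.
    """
    y = np.asarray(response, dtype=float).ravel()
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape[0] != n:
        raise ValidationError(f"fit_ols: y has {y.shape[0]} rows, X has {n}")
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]
    if n <= p:
        raise ValidationError(f"fit_ols[{model_id}]: n={n} <= p={p}")
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise ValidationError(f"fit_ols[{model_id}]: non-finite values in y or X")

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    bad = diag <= np.finfo(float).eps * n * scale
    if bad.any():
        names = [term_names[j] for j in np.flatnonzero(bad)]
        raise CollinearityError(
            f"fit_ols[{model_id}]: rank-deficient design; "
            f"collinear/constant column(s): {names}"
        )
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    Rinv = np.linalg.solve(R, np.eye(p))
    cov = sigma2 * (Rinv @ Rinv.T)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    tcrit = stats.t.ppf(0.975, df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    params = pd.DataFrame(
        {
            "term": term_names,
            "estimate": beta,
            "se": se,
            "t": tvals,
            "p_value": pvals,
            "ci_low": beta - tcrit * se,
            "ci_high": beta + tcrit * se,
        }
    )
    return ModelResult(
        model_id=model_id, params=params, n=n, df_resid=df, r_squared=r2, cov=cov
    )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _merge(cohort: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    data = cohort.merge(scores, on="sample_id", how="inner", validate="1:1")
    if data.empty:
        raise ValidationError("no overlapping sample_id between cohort and scores")
    return data


def _age_sex_columns(data: pd.DataFrame) -> tuple[list[np.ndarray], list[str]]:
    sex_male = (data["sex"].astype(str) == "male").astype(float).to_numpy()
    return (
        [data["age"].to_numpy(dtype=float), sex_male],
        ["age", "sex_male"],
    )


def fit_stage_model(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    score_name: str = "global_prs",
    reference: str = "none",
) -> ModelResult:
    """PRS ~ stage dummies + age + sex, reference stage = no-AMD control."""
    data = _merge(cohort, scores)
    present = set(data["stage"].astype(str))
    if reference not in present:
        raise ValidationError(
            f"stage model: reference stage {reference!r} absent from cohort"
        )
    if len(present) < 2:
        raise ValidationError("stage model: need >= 2 stages")
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for stage in STAGE_LEVELS:
        if stage == reference or stage not in present:
            continue
        cols.append((data["stage"].astype(str) == stage).astype(float).to_numpy())
        names.append(f"stage_{stage}")
    extra, extra_names = _age_sex_columns(data)
    cols += extra
    names += extra_names
    return fit_ols(
        data[score_name].to_numpy(dtype=float),
        np.column_stack(cols),
        names,
        model_id=f"stage:{score_name}",
    )


def _intermediate_with_biomarkers(
    cohort: pd.DataFrame, biomarkers: tuple[str, ...]
) -> pd.DataFrame:
    sub = cohort[cohort["stage"].astype(str) == "intermediate"]
    mask = np.ones(len(sub), dtype=bool)
    for b in biomarkers:
        mask &= sub[b].notna().to_numpy()
    sub = sub[mask]
    if sub.empty:
        raise ValidationError("no intermediate-stage samples with biomarker data")
    return sub


def _fit_flag_model(
    data: pd.DataFrame, score_name: str, flags: tuple[str, ...], model_id: str
) -> ModelResult:
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for b in flags:
        col = data[b].astype(float).to_numpy()
        cols.append(col)
        names.append(b)
    extra, extra_names = _age_sex_columns(data)
    cols += extra
    names += extra_names
    return fit_ols(
        data[score_name].to_numpy(dtype=float),
        np.column_stack(cols),
        names,
        model_id=model_id,
    )


def fit_biomarker_models(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    score_names: list[str] | None = None,
) -> list[ModelResult]:
    """The per-biomarker model family on the intermediate-AMD subgroup.

    For each score, four models: 1 RPD, 2 PA, 3 HRF, and 4 the combined
    atrophy model with iRORA and cRORA dummies in one fit (reference =
    neither lesion). A model whose biomarker column is constant in the
    analysis subset fails alone, with a warning; the rest still run.
    """
    score_names = score_names or ALL_SCORES
    results: list[ModelResult] = []
    for score_name in score_names:
        for model_no, flags in BIOMARKER_MODELS.items():
            model_id = f"model{model_no}:{'+'.join(flags)}:{score_name}"
            try:
                sub = _intermediate_with_biomarkers(cohort, flags)
                data = _merge(sub, scores)
                results.append(_fit_flag_model(data, score_name, flags, model_id))
            except CollinearityError as exc:
                warnings.warn(f"{model_id} skipped: {exc}")
    if not results:
        raise ValidationError("all biomarker models failed")
    return results


def fit_extended_models(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    score_name: str = "global_prs",
    include_atrophy: bool = False,
) -> ModelResult:
    """Extended multi-biomarker model: RPD + PA + HRF (+ iRORA + cRORA when
    ``include_atrophy``) + age + sex on the intermediate subgroup."""
    flags: tuple[str, ...] = ("rpd", "pa", "hrf")
    if include_atrophy:
        flags = flags + ("irora", "crora")
    sub = _intermediate_with_biomarkers(cohort, flags)
    data = _merge(sub, scores)
    variant = "B" if include_atrophy else "A"
    return _fit_flag_model(
        data, score_name, flags, model_id=f"extended{variant}:{score_name}"
    )


# ---------------------------------------------------------------------------
# estimated marginal means
# ---------------------------------------------------------------------------

def emm_pairwise_contrasts(
    stage_model: ModelResult, cohort: pd.DataFrame
) -> list[ContrastResult]:
    """Pairwise differences of stage-adjusted mean PRS.

    Each stage's adjusted mean is the model prediction at that stage with
    age at the cohort mean and sex at its observed proportion; because the
    covariate part is shared, every pairwise difference reduces to a
    linear contrast on the stage-dummy coefficients, with variance
    L Cov(beta) L'. P values are unadjusted. Stages absent from the fit are
    skipped with a warning.
    """
    terms = list(stage_model.params["term"])
    stage_terms = {t.removeprefix("stage_"): t for t in terms if t.startswith("stage_")}
    fitted_stages = [s for s in STAGE_LEVELS if s in stage_terms]
    reference = [
        s
        for s in STAGE_LEVELS
        if s not in stage_terms and s in set(cohort["stage"].astype(str))
    ]
    groups = (reference[:1] if reference else []) + fitted_stages
    skipped = [s for s in STAGE_LEVELS if s not in groups]
    for s in skipped:
        warnings.warn(f"EMM contrasts: stage {s!r} absent from fit; skipped")

    p = len(terms)

    def stage_vector(stage: str) -> np.ndarray:
        v = np.zeros(p)
        if stage in stage_terms:
            v[terms.index(stage_terms[stage])] = 1.0
        return v

    beta = stage_model.params["estimate"].to_numpy()
    out: list[ContrastResult] = []
    for a, b in combinations(groups, 2):
        L = stage_vector(a) - stage_vector(b)
        diff = float(L @ beta)
        var = float(L @ stage_model.cov @ L)
        se = float(np.sqrt(var))
        t = diff / se
        pval = 2.0 * float(stats.t.sf(abs(t), stage_model.df_resid))
        out.append(ContrastResult(a, b, diff, se, t, pval))
    return out


def contrasts_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": c.group_a,
                "group_b": c.group_b,
                "difference": c.difference,
                "se": c.se,
                "t": c.t,
                "p_value": c.p_value,
            }
            for c in contrasts
        ]
    )


# ---------------------------------------------------------------------------
# figure
# ---------------------------------------------------------------------------

def plot_scores_by_stage(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    path,
    score_name: str = "global_prs",
    seed: int = 0,
) -> None:
    """Box plot of a score by AMD stage with one jittered dot per sample."""
    import matplotlib.pyplot as plt

    data = _merge(cohort, scores)
    stages = [s for s in STAGE_LEVELS if (data["stage"].astype(str) == s).any()]
    if not stages:
        raise ValidationError("plot_scores_by_stage: empty cohort")
    groups = [
        data.loc[data["stage"].astype(str) == s, score_name].to_numpy()
        for s in stages
    ]
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(groups, tick_labels=stages, showfliers=False)
    for i, g in enumerate(groups, start=1):
        ax.scatter(
            i + rng.uniform(-0.12, 0.12, size=g.size),
            g,
            s=8,
            alpha=0.5,
            color="tab:blue",
            edgecolors="none",
        )
    ax.set_xlabel("AMD stage")
    ax.set_ylabel(score_name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
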