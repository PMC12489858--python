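"""Synthetic genotype/phenotype cohorts with known planted structure.

The generator emulates the statistical shape of a European multicenter AMD
cohort profile (see :mod:`pathprs.cohort_profile`): ~50 independent
biallelic score SNPs in Hardy-Weinberg proportions with meta-analysis-scale
effect weights, an age/sex structure matching the profile, AMD stages
assigned by ordered thresholds on a liability combining the true global PRS
with age, and structural biomarkers drawn — in the intermediate-AMD group
only — from logistic models on the true pathway scores with intercepts
calibrated to the profile prevalences. QC decoy SNPs (low imputation R2,
high missingness, HWE violation, rare) are injected so the QC filters have
known targets, and every planted quantity is returned in a TruthRecord for
parameter-recovery testing.

No linkage disequilibrium is simulated: the additive score model treats
loci independently, matching the assumption behind fixed per-SNP weights.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from . import cohort_profile as profile
from .errors import CalibrationError, ValidationError
from .io_formats import (
    BIOMARKERS,
    GenotypeMatrix,
    VariantMeta,
    WEIGHT_COLUMNS,
    enforce_atrophy_coding,
    write_phenotypes,
    write_scoring_file,
)

PATHWAY_GENES = {
    "complement": ["CFH", "C3", "CFB/C2", "CFI"],
    "ecm": [
        "ADAM19",
        "ADAMTS9-AS2",
        "COL4A3",
        "COL8A1",
        "MMP9",
        "SYN3/TIMP3",
        "VEGF-A",
    ],
    "lipid": ["ABCA1", "APOE", "CETP", "LIPC"],
    "arms2_htra1": ["ARMS2/HTRA1"],
}

_DECOY_RULES = ("low_r2", "high_missing", "hwe_violation", "rare")
_DECOY_VERDICT = {
    "low_r2": "fail_r2",
    "high_missing": "fail_callrate",
    "hwe_violation": "fail_hwe",
    "rare": "fail_maf",
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the reference cohort profile: 50 score SNPs split
    across pathways (complement 8, ECM 9, lipid 6, ARMS2/HTRA1 2, untagged
    25), effect-allele frequencies uniform on [0.05, 0.5], per-pathway
    weight scales chosen so the simulated score SDs match the profile's,
    age ~ N(71.5, 6.98) truncated to [55, 86], P(male) = 0.349, stage
    prevalences from the profile stage sizes, and biomarker prevalence
    targets from the profile. ``biomarker_effects`` are logistic
    coefficients of each biomarker on the *true* pathway scores; the
    defaults plant RPD on AH + ECM and cRORA on AH, chosen by a power
    calculation for recovery at n = 4000 (see the methods note), with the
    remaining biomarkers null.
    """

    n_samples: int = 556
    snps_per_pathway: dict = field(
        default_factory=lambda: {
            "complement": 8,
            "ecm": 9,
            "lipid": 6,
            "arms2_htra1": 2,
            "untagged": 25,
        }
    )
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    age_mean: float = profile.AGE_MEAN
    age_sd: float = profile.AGE_SD
    age_range: tuple[float, float] = (profile.AGE_MIN, profile.AGE_MAX)
    p_male: float = 0.349
    stage_mode: str = "liability"  # or "intermediate_only"
    stage_prevalences: dict = field(default_factory=profile.stage_prevalences)
    #: liability weight on standardized age (older -> later stage)
    age_liability_weight: float = 0.25
    #: liability weight on the standardized true global PRS; None calibrates
    #: it so the intermediate-vs-none PRS shift matches the profile's 0.405
    genetic_liability_weight: float | None = None
    biomarker_targets: dict = field(
        default_factory=lambda: dict(profile.BIOMARKER_PREVALENCE)
    )
    biomarker_effects: dict = field(
        default_factory=lambda: {
            "rpd": {"arms2_htra1": 1.0, "ecm": 2.0},
            "pa": {},
            "hrf": {},
            "irora": {},
            "crora": {"arms2_htra1": 1.5},
        }
    )
    qc_contamination: dict = field(
        default_factory=lambda: {
            "low_r2": 0.06,
            "high_missing": 0.06,
            "hwe_violation": 0.06,
            "rare": 0.06,
        }
    )
    missing_rate: float = 0.01
    hard_call_jitter_sd: float = 0.0  # dosage noise around hard calls
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("allele_freq_range must satisfy 0 < lo <= hi <= 0.5")
        if any(v < 0 for v in self.snps_per_pathway.values()):
            raise ValidationError("snps_per_pathway counts must be >= 0")
        for d in (self.qc_contamination, self.biomarker_targets):
            if any(not 0 <= v <= 1 for v in d.values()):
                raise ValidationError("fractions/probabilities must lie in [0,1]")
        if self.stage_mode not in ("liability", "intermediate_only"):
            raise ValidationError(f"unknown stage_mode {self.stage_mode!r}")


@dataclass
class TruthRecord:
    """Planted ground truth for a simulated cohort."""

    variant_freq: dict = field(default_factory=dict)
    variant_beta: dict = field(default_factory=dict)
    variant_pathway: dict = field(default_factory=dict)
    decoy_verdicts: dict = field(default_factory=dict)
    sigma_global: float = np.nan
    stage_shift: dict = field(default_factory=dict)
    biomarker_effects: dict = field(default_factory=dict)
    biomarker_intercepts: dict = field(default_factory=dict)
    true_scores: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def clean_ids(self) -> list[str]:
        return [v for v in self.variant_beta if v not in self.decoy_verdicts]

    def to_json(self, path) -> None:
        d = asdict(self)
        scores = d.pop("true_scores")
        if scores is not None:
            d["true_scores"] = self.true_scores.to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=float)


def _beta_scales(snps: dict) -> dict:
    """Per-pathway per-SNP weight magnitudes solving
    n_p * beta^2 * E[2pq] = target score variance for the profile SDs."""
    e2pq = 0.365  # E[2p(1-p)] for p ~ U(0.05, 0.5)
    scales = {}
    resid_var = profile.GLOBAL_PRS_SD_IAMD**2
    for pw, sd in profile.PATHWAY_PRS_SD.items():
        n = snps.get(pw, 0)
        scales[pw] = np.sqrt(sd**2 / (n * e2pq)) if n else 0.0
        resid_var -= sd**2 if n else 0.0
    n_un = snps.get("untagged", 0)
    scales["untagged"] = np.sqrt(max(resid_var, 0.0) / (n_un * e2pq)) if n_un else 0.0
    return scales


def simulate_genotypes(
    config: SimulationConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    """Draw HWE genotypes for the score SNPs plus QC decoys.

    Score SNPs are iid Binomial(2, p) per variant; the ARMS2/HTRA1 weights
    are forced positive (high-effect risk locus), the rest carry random
    signs. Decoy SNPs are injected per ``qc_contamination`` with the defect
    their label announces.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_samples
    n_score = sum(config.snps_per_pathway.values())
    if n < 1 or n_score < 1:
        raise ValidationError("need >= 1 sample and >= 1 score SNP")
    scales = _beta_scales(config.snps_per_pathway)
    lo, hi = config.allele_freq_range

    truth = TruthRecord(biomarker_effects=dict(config.biomarker_effects))
    variants: list[VariantMeta] = []
    columns: list[np.ndarray] = []
    wrows: list[dict] = []
    counter = 0

    def add_variant(pathway, gene, p, beta, r2, genotypes, decoy_rule=None):
        nonlocal counter
        counter += 1
        vid = f"rs{1000000 + counter}"
        chrom = str((counter - 1) % 22 + 1)
        ref, alt = ("A", "G") if counter % 2 else ("C", "T")  # never strand-ambiguous
        variants.append(
            VariantMeta(
                variant_id=vid,
                chrom=chrom,
                pos=10_000 + 100 * counter,
                ref_allele=ref,
                alt_allele=alt,
                imputation_r2=r2,
            )
        )
        columns.append(genotypes)
        wrows.append(
            {
                "variant_id": vid,
                "chrom": chrom,
                "pos": 10_000 + 100 * counter,
                "effect_allele": alt,
                "other_allele": ref,
                "effect_weight": beta,
                "gene_label": gene,
                "pathway": pathway if pathway != "untagged" else "",
            }
        )
        truth.variant_freq[vid] = float(p)
        truth.variant_beta[vid] = float(beta)
        truth.variant_pathway[vid] = pathway
        if decoy_rule:
            truth.decoy_verdicts[vid] = _DECOY_VERDICT[decoy_rule]

    def clean_column(p):
        g = rng.binomial(2, p, size=n).astype(float)
        if config.hard_call_jitter_sd > 0:
            g = np.clip(g + rng.normal(0, config.hard_call_jitter_sd, size=n), 0, 2)
        if config.missing_rate > 0:
            g[rng.random(n) < config.missing_rate] = np.nan
        return g

    for pathway, count in config.snps_per_pathway.items():
        genes = PATHWAY_GENES.get(pathway, [])
        for i in range(count):
            p = rng.uniform(lo, hi)
            sign = 1.0 if pathway == "arms2_htra1" else rng.choice([-1.0, 1.0])
            beta = sign * scales[pathway] * rng.uniform(0.7, 1.3)
            gene = genes[i % len(genes)] if genes else f"LOCUS{counter + 1}"
            add_variant(pathway, gene, p, beta, rng.uniform(0.85, 1.0), clean_column(p))

    for rule in _DECOY_RULES:
        n_decoys = int(round(config.qc_contamination.get(rule, 0.0) * n_score))
        for i in range(n_decoys):
            gene = f"QCFAIL_{rule.upper()}_{i + 1}"
            beta = rng.choice([-1.0, 1.0]) * scales["untagged"] * rng.uniform(0.7, 1.3)
            if rule == "low_r2":
                p = rng.uniform(lo, hi)
                add_variant("untagged", gene, p, beta, rng.uniform(0.05, 0.25),
                            clean_column(p), rule)
            elif rule == "high_missing":
                p = rng.uniform(lo, hi)
                g = rng.binomial(2, p, size=n).astype(float)
                g[rng.random(n) < rng.uniform(0.15, 0.25)] = np.nan
                add_variant("untagged", gene, p, beta, rng.uniform(0.85, 1.0), g, rule)
            elif rule == "hwe_violation":
                # strong heterozygote excess at p = 0.5 (HWE expects 0.5 het)
                g = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.175, 0.65, 0.175])
                add_variant("untagged", gene, 0.5, beta, rng.uniform(0.85, 1.0), g, rule)
            elif rule == "rare":
                p = rng.uniform(0.001, 0.004)
                g = rng.binomial(2, p, size=n).astype(float)
                add_variant("untagged", gene, p, beta, rng.uniform(0.85, 1.0), g, rule)

    samples = [f"S{i + 1:05d}" for i in range(n)]
    matrix = GenotypeMatrix(
        samples=samples, variants=variants, dosages=np.column_stack(columns)
    )
    weights = pd.DataFrame(wrows, columns=WEIGHT_COLUMNS)
    sigma2 = sum(
        truth.variant_beta[v] ** 2
        * 2
        * truth.variant_freq[v]
        * (1 - truth.variant_freq[v])
        for v in truth.clean_ids
    )
    truth.sigma_global = float(np.sqrt(sigma2))
    return matrix, weights, truth


def _true_scores(matrix: GenotypeMatrix, truth: TruthRecord) -> pd.DataFrame:
    """Per-sample true pathway scores over the clean (non-decoy) SNPs,
    with missing genotypes mean-imputed from the true frequency."""
    ids = matrix.variant_ids()
    out = {"sample_id": list(matrix.samples)}
    total = np.zeros(matrix.n_samples)
    for pw in ("complement", "ecm", "lipid", "arms2_htra1", "untagged"):
        acc = np.zeros(matrix.n_samples)
        for vid in truth.clean_ids:
            if truth.variant_pathway[vid] != pw:
                continue
            j = ids.index(vid)
            col = matrix.dosages[:, j].copy()
            col[np.isnan(col)] = 2 * truth.variant_freq[vid]
            acc += truth.variant_beta[vid] * col
        out[pw] = acc
        total += acc
    out["global"] = total
    return pd.DataFrame(out)


def _stage_band_means(prevalences: dict) -> dict:
    """Mean of a standard normal truncated to each stage's liability band."""
    order = [s for s in profile.STAGES if prevalences.get(s, 0) > 0]
    cum = np.cumsum([prevalences[s] for s in order])
    cum = cum / cum[-1]
    edges = np.concatenate([[-np.inf], stats.norm.ppf(np.clip(cum[:-1], 1e-12, 1)),
                            [np.inf]])
    means = {}
    for i, s in enumerate(order):
        lo, hi = edges[i], edges[i + 1]
        mass = stats.norm.cdf(hi) - stats.norm.cdf(lo)
        means[s] = float((stats.norm.pdf(lo) - stats.norm.pdf(hi)) / mass)
    return means


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Solve mean(expit(alpha + eta)) = target for alpha."""
    lo, hi = -30.0, 30.0
    f = lambda a: float(np.mean(expit(a + eta))) - target
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise CalibrationError(
            f"target prevalence {target:.3f} unreachable; achievable range "
            f"[{flo + target:.4f}, {fhi + target:.4f}]"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def simulate_phenotypes(
    matrix: GenotypeMatrix,
    weights: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
    truth: TruthRecord | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate ages, sex, AMD stage, and structural biomarkers.

    Stage comes from ordered thresholds on a liability
    ``a * z(global PRS) + b * z(age) + noise`` with thresholds at the
    profile stage prevalences, so the per-stage PRS means are ordered
    none < early < intermediate < late by construction. Biomarkers are
    drawn only for intermediate-stage samples from logistic models on the
    true pathway scores, intercept-calibrated to the profile prevalences;
    the combined atrophy coding (iRORA group excludes cRORA carriers) is
    enforced on output.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    if truth is None:
        truth = TruthRecord(
            variant_freq={},
            variant_beta=dict(
                zip(weights["variant_id"], weights["effect_weight"].astype(float))
            ),
            variant_pathway={
                vid: (pw if pw else "untagged")
                for vid, pw in zip(weights["variant_id"], weights["pathway"])
            },
            biomarker_effects=dict(config.biomarker_effects),
        )
        ids = set(matrix.variant_ids())
        for j, vid in enumerate(matrix.variant_ids()):
            col = matrix.dosages[:, j]
            truth.variant_freq[vid] = float(np.nanmean(col) / 2)
        truth.variant_beta = {
            v: b for v, b in truth.variant_beta.items() if v in ids
        }
    n = matrix.n_samples

    a_lo = (config.age_range[0] - config.age_mean) / config.age_sd
    a_hi = (config.age_range[1] - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a_lo, a_hi, loc=config.age_mean, scale=config.age_sd, size=n,
        random_state=rng,
    )
    sex = np.where(rng.random(n) < config.p_male, "male", "female")

    scores = _true_scores(matrix, truth)
    truth.true_scores = scores
    g = scores["global"].to_numpy()

    if config.stage_mode == "intermediate_only":
        stage = np.full(n, "intermediate", dtype=object)
        truth.stage_shift = {}
    else:
        band = _stage_band_means(config.stage_prevalences)
        a = config.genetic_liability_weight
        if a is None:
            delta_m = band["intermediate"] - band["none"]
            a = profile.IAMD_STAGE_SHIFT / (delta_m * truth.sigma_global)
        b = config.age_liability_weight
        if a**2 + b**2 >= 1:
            raise ValidationError("liability weights imply non-positive noise variance")
        gz = (g - g.mean()) / g.std(ddof=0)
        az = (age - age.mean()) / age.std(ddof=0)
        liab = a * gz + b * az + np.sqrt(1 - a**2 - b**2) * rng.standard_normal(n)
        order = [s for s in profile.STAGES if config.stage_prevalences.get(s, 0) > 0]
        cum = np.cumsum([config.stage_prevalences[s] for s in order])
        cuts = stats.norm.ppf(np.clip(cum[:-1] / cum[-1], 1e-12, 1 - 1e-12))
        stage = np.asarray(order, dtype=object)[np.searchsorted(cuts, liab)]
        sigma_emp = float(g.std(ddof=0))
        truth.stage_shift = {
            s: float(a * (band[s] - band["none"]) * sigma_emp) for s in order
        }

    cohort = pd.DataFrame(
        {
            "sample_id": list(matrix.samples),
            "age": age,
            "sex": pd.Categorical(sex, categories=["female", "male"]),
            "stage": pd.Categorical(
                stage, categories=list(profile.STAGES), ordered=True
            ),
        }
    )
    inter = cohort["stage"].astype(str) == "intermediate"
    for b_name in BIOMARKERS:
        flags = pd.array([pd.NA] * n, dtype="boolean")
        if inter.any():
            effects = config.biomarker_effects.get(b_name, {})
            eta = np.zeros(int(inter.sum()))
            for pw, coef in effects.items():
                eta += coef * scores.loc[inter.to_numpy(), pw].to_numpy()
            target = config.biomarker_targets[b_name]
            alpha = (
                float(logit(target)) if not effects.keys()
                else _calibrate_intercept(eta, target)
            )
            truth.biomarker_intercepts[b_name] = alpha
            draws = rng.random(eta.size) < expit(alpha + eta)
            flags[inter.to_numpy()] = draws
        cohort[b_name] = flags
    cohort = enforce_atrophy_coding(cohort)
    return cohort, truth


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Full bundle: genotypes, weight table, phenotype cohort, truth."""
    base = config.seed if seed is None else seed
    matrix, weights, truth = simulate_genotypes(config, seed=base)
    cohort, truth = simulate_phenotypes(
        matrix, weights, config, seed=base + 1, truth=truth
    )
    return matrix, weights, cohort, truth


# ---------------------------------------------------------------------------
# fixture output
# ---------------------------------------------------------------------------

def _format_record(meta: VariantMeta, dosages: np.ndarray) -> str:
    r2 = "." if np.isnan(meta.imputation_r2) else f"R2={meta.imputation_r2:.4f}"
    fields = [
        meta.chrom,
        str(meta.pos),
        meta.variant_id,
        meta.ref_allele,
        meta.alt_allele,
        ".",
        "PASS",
        r2,
        "GT:DS",
    ]
    for d in dosages:
        if np.isnan(d):
            fields.append("./.:.")
        else:
            g = int(round(d))
            gt = ("0/0", "0/1", "1/1")[g] if abs(d - g) < 1e-9 and g in (0, 1, 2) \
                else "./."
            fields.append(f"{gt}:{d:g}")
    return "\t".join(fields)


def write_genotypes_vcf(matrix: GenotypeMatrix, path) -> None:
    """Emit an uncompressed VCFv4.2 with GT and DS per sample and the
    imputation R2 in INFO."""
    chroms = []
    for v in matrix.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=pathprs-synthetic",
        '##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">',
    ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    order = sorted(
        range(matrix.n_variants),
        key=lambda j: (chroms.index(matrix.variants[j].chrom), matrix.variants[j].pos),
    )
    for j in order:
        lines.append(_format_record(matrix.variants[j], matrix.dosages[:, j]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_fixture(
    matrix: GenotypeMatrix,
    weights: pd.DataFrame,
    cohort: pd.DataFrame,
    out_dir,
    truth: TruthRecord | None = None,
) -> dict:
    """Write genotypes.vcf + weights.tsv + phenotypes.csv (+ truth.json)
    readable by :mod:`pathprs.io_formats`."""
    from pathlib import Path

    if list(matrix.samples) != list(cohort["sample_id"]):
        raise ValidationError("write_fixture: sample ids differ between objects")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.vcf",
        "weights": out / "weights.tsv",
        "phenotypes": out / "phenotypes.csv",
    }
    write_genotypes_vcf(matrix, paths["genotypes"])
    write_scoring_file(weights, paths["weights"])
    write_phenotypes(cohort, paths["phenotypes"])
    if truth is not None:
        paths["truth"] = out / "truth.json"
        truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def profile_cohort() -> pd.DataFrame:
    """Deterministic cohort reproducing the reference profile counts
    (stage sizes, sex counts, biomarker counts) for descriptive
    recomputation; ages are placeholders at the profile mean."""
    rows = []
    i = 0
    for stage in profile.STAGES:
        n = profile.STAGE_N[stage]
        n_male = profile.MALE_N[stage]
        for k in range(n):
            i += 1
            row = {
                "sample_id": f"P{i:04d}",
                "age": profile.AGE_MEAN,
                "sex": "male" if k < n_male else "female",
                "stage": stage,
            }
            for b in BIOMARKERS:
                row[b] = pd.NA
            if stage == "intermediate":
                for b in ("rpd", "pa", "hrf"):
                    row[b] = k < profile.BIOMARKER_N[b]
                row["crora"] = k < profile.BIOMARKER_N["crora"]
                row["irora"] = (
                    profile.BIOMARKER_N["crora"]
                    <= k
                    < profile.BIOMARKER_N["crora"] + profile.BIOMARKER_N["irora"]
                )
            rows.append(row)
    cohort = pd.DataFrame(rows)
    cohort["sex"] = pd.Categorical(cohort["sex"], categories=["female", "male"])
    cohort["stage"] = pd.Categorical(
        cohort["stage"], categories=list(profile.STAGES), ordered=True
    )
    for b in BIOMARKERS:
        cohort[b] = pd.array(cohort[b], dtype="boolean")
    return cohort
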