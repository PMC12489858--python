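# Methods

## Scope and model

`pathprs` implements a genotype-phenotype analysis for age-related macular
degeneration (AMD): variant-level QC of imputed genotypes, computation of a
global polygenic risk score (PRS) and five pathway-specific scores (psPRS),
and multivariable linear models relating those scores to AMD stage and to
structural retinal biomarkers in the intermediate-AMD (iAMD) subgroup. A
synthetic-cohort generator with planted, recoverable effects makes the whole
pipeline testable without access to individual-level study data.

### Scores

For sample *s*, a score is the raw weighted dosage sum

    PRS(s) = Σ_i β_i · d_{s,i}

where `d` is the effect-allele dosage in [0, 2] and `β_i` a fixed published
per-variant weight. Scores are deliberately **not** averaged, centered or
standardized, so cohort means can be negative when weights are signed. The
global PRS sums every QC-surviving weight; each psPRS restricts the sum to
variants whose assigned gene belongs to one pathway:

| score    | pathway gene set |
|----------|------------------|
| C-PRS    | complement: *C3*, *CFB/C2*, *CFH*, *CFI* |
| AH-PRS   | *ARMS2/HTRA1* |
| C+AH-PRS | complement ∪ *ARMS2/HTRA1* |
| E-PRS    | extracellular matrix: *ADAM19*, *ADAMTS9-AS2*, *COL4A3*, *COL8A1*, *MMP9*, *SYN3/TIMP3*, *VEGF-A* |
| L-PRS    | lipid: *ABCA1*, *APOE*, *CETP*, *LIPC* |

The two matrix-metalloproteinase loci (*ADAM19*, *MMP9*) are assigned to the
extracellular-matrix set. Complement and *ARMS2/HTRA1* are disjoint, so
C+AH-PRS = C-PRS + AH-PRS holds samplewise (a tested invariant). Gene→pathway
assignment travels in the scoring file (with the registry as fallback)
because published score SNP lists vary by array content; unknown pathway
strings fold into `other` and contribute only to the global score.

### Effect-allele alignment

Weights reference an effect allele, VCF dosages count ALT copies. Alignment
per variant: effect==ALT keeps the dosage, effect==REF flips it
(d ← 2 − d), a match only after base complement is accepted and tagged
`strand_complemented`. A/T and C/G SNPs cannot be strand-resolved without
frequency heuristics and are excluded by default (`--ambiguity-policy keep`
overrides). Missing dosages are mean-imputed per variant (2 × effect-allele
frequency from the observed entries), configurable off by omitting the
imputation step.

### Variant QC

Four filters with defaults R² ≥ 0.3, call rate ≥ 90 %, MAF ≥ 1 %, HWE exact
P ≥ 1e-6, applied in the fixed order R² → call rate → MAF → HWE so the
recorded verdict of a multiply-failing variant is deterministic; the
surviving set is order-independent. A variant without an R² annotation is
treated as directly genotyped and passes the R² rule (flag
`assume_genotyped`, default on). HWE needs discrete genotypes: dosages
within 0.1 of {0, 1, 2} are hard-called, others are excluded from the HWE
test only — call rate is computed from raw missingness so the two filters
stay independent. The HWE sample set defaults to all samples (the package
targets single-ancestry cohorts; a subset can be passed).

### HWE exact test

Implemented from scratch as the two-sided conditional test on the
heterozygote count: given n diploid samples and the minor-allele count, each
admissible heterozygote count h (same parity) has probability

    P(h) ∝ n! 2^h / (n_AA! h! n_BB!)

computed by a ratio recurrence started at the modal count for numerical
stability; the P value sums P(h) over all h with P(h) ≤ P(h_obs). A mid-P
variant (half weight on the observed configuration) sits behind
`--hwe-midp`. Tie handling: a configuration is included when its probability
is ≤ (1 + 1e-9) × the observed one. The factor guards against the float
representation of exactly tied masses (symmetric configurations); genuinely
distinct probability masses at the sample sizes involved differ by far more
than 1e-9 relative, so the tolerance cannot flip a non-tie. The test suite
checks exhaustive agreement with an independent log-factorial enumeration
for every genotype triple with total ≤ 60 at 1e-12.

### Association models

Direction of modelling is descriptive, not causal: the PRS is the
*dependent* variable, stage or biomarker flags the independent variables,
always adjusted for age (years) and sex, with fixed reference categories
(no-AMD controls; female). Families:

- **stage model** — score ~ early + intermediate + late + age + sex;
- **biomarker models** (iAMD subgroup only) — per score, model 1 RPD,
  2 PA, 3 HRF, 4 iRORA + cRORA jointly in one fit (reference: neither
  lesion), because the atrophy groups are mutually exclusive by coding
  (the iRORA group excludes cRORA carriers — a row claiming both is
  repaired to the cRORA group on input);
- **extended models** — variant A: RPD + PA + HRF; variant B adds
  iRORA + cRORA.

The least-squares core is written here (QR solve; covariance
σ̂²(XᵀX)⁻¹ with σ̂² = RSS/(n−p)); P values use the t distribution with
residual df, CIs are estimate ± t₀.₉₇₅,df × SE. No multiplicity adjustment
anywhere, by design: the analyses are exploratory and every P value is
reported unadjusted. Rank-deficient designs raise an error naming the
offending columns; in the biomarker family a constant-column model fails
alone and the remaining models still run.

**EMM contrasts.** Adjusted stage means are model predictions with age at
the cohort mean and sex at its observed proportion. Because the covariate
part is shared, each pairwise difference collapses to a linear contrast on
the stage-dummy coefficients with variance LΣ̂Lᵀ — so contrast(stage, ref)
equals that stage's coefficient exactly, and the contrasts are invariant to
re-referencing the stage factor (tested to 1e-10). Proportional (observed)
sex weighting is the convention here; equal weighting would change nothing
for the differences, only for the reported adjusted means.

## Synthetic cohort generator

The generator's defaults are the study conditions of a European multicenter
AMD cohort profile (`pathprs.cohort_profile`): 556 participants split
none/early/intermediate/late = 46/33/404/73; age ~ N(71.5, 6.98²) truncated
to [55, 86]; P(male) = 0.349; iAMD biomarker prevalences RPD 23.8 %, PA
47.8 %, HRF 46.8 %, iRORA 8.7 %, cRORA 7.2 %.

- **Genotypes.** ~50 score SNPs, iid Binomial(2, p) with p ~ U(0.05, 0.5)
  (HWE, no LD), split complement 8 / ECM 9 / lipid 6 / ARMS2-HTRA1 2 /
  untagged 25. Per-pathway weight magnitudes solve
  n_pathway · β² · E[2p(1−p)] = (target score SD)² against the profile's
  per-score SDs (AH 0.226, C 0.183, E 0.126, L 0.110, global 0.425), so
  simulated score spreads match the reported ones; ARMS2/HTRA1 weights are
  forced positive (the canonical high-effect risk locus), other signs are
  random. Decoy SNPs (3 each by default) carry exactly the defect their
  truth label announces: R² ~ U(0.05, 0.25); missingness 15–25 %;
  heterozygote excess (genotype probabilities 0.175/0.65/0.175); or
  p ~ U(0.001, 0.004).
- **Stage.** Ordered thresholds on a liability
  a·z(global PRS) + b·z(age) + √(1−a²−b²)·ε at the profile stage
  prevalences. b = 0.25 plants age-stage confounding (older → later stage)
  so the age adjustment is non-trivial; a is calibrated so the implied
  intermediate-vs-none PRS shift equals the profile's headline 0.405
  (a ≈ 0.51). One liability scale cannot match every stage's reported
  shift simultaneously — the late-stage planted shift comes out larger
  than the profile's — but the required ordering
  none < early < intermediate < late holds by construction, and the
  analytic planted shifts (truncated-normal band means × a × σ_PRS) are
  stored in the truth record.
- **Biomarkers.** Drawn only for intermediate-stage samples from logistic
  models on the *true* pathway scores, with intercepts root-solved so the
  marginal prevalence hits its target exactly in expectation. Planted
  coefficients: RPD ~ 1.0·AH + 2.0·E; cRORA ~ 1.5·AH; PA, HRF, iRORA
  intercept-only (null). The magnitudes were fixed once by a power
  calculation: a logistic slope γ on a score with variance σ² shifts the
  carrier/non-carrier score means by ≈ 0.8·γ·σ², and at n = 4000
  intermediate samples each planted term then exceeds 5 standard errors
  (≥ 99 % power), while leaving every null term at its nominal size.
  After drawing, the combined atrophy coding is enforced, which deflates
  the recorded iRORA-group prevalence slightly below the raw 8.7 % target
  (≈ 8.1 % expected) — within the calibration tolerance.

What the generator does *not* emulate: linkage disequilibrium, population
structure, family relatedness, imputation dosage noise (dosages are integer
hard calls unless `hard_call_jitter_sd` is set), genotype-calling batch
effects, and the biomarker direction of generation. The last point matters
for interpretation: effects are planted as biomarker-given-score
(logistic) while the analysis fits score-given-biomarker (linear), so
recovery tests assert sign and significance of planted terms, never
numeric equality of coefficients. Passing tests therefore show that the
pipeline detects pathway-specific structure of realistic size under clean
conditions — not that it would survive LD-confounded or stratified real
data.

## Problem sizes and numerical choices

- Recovery study: 200 replicate intermediate-only cohorts of n = 4000
  (the scale at which the planted effects are comfortably detectable);
  prevalence calibration at n = 20 000; t-test size and CI coverage over
  2000 refits at n = 200. The exhaustive HWE cross-check covers all
  genotype triples with total ≤ 60 (~40 000 cases).
- Degenerate inputs fail loudly: empty matrices, all-missing dosage
  columns, missing reference stage, constant design columns, empty result
  lists and unreachable prevalence targets all raise typed errors rather
  than returning silent defaults.
- All randomness flows through `numpy.random.default_rng` seeded from a
  single integer; identical seeds give bit-identical cohorts and
  byte-identical pipeline CSVs (tested).
- CSV outputs keep full float precision; the text renderings round to 3
  significant figures and percentages to one decimal.

## Known limitations

- The scoring file is a required input: published AMD score SNP lists
  differ by genotyping array, so the package validates pathway labels
  rather than hard-coding rsIDs. The shipped generator emulates, not
  reproduces, any specific published weight set.
- No sample-level QC (relatedness, heterozygosity, ancestry PCs) and no
  LD-aware scoring (clumping, P-value thresholding, posterior
  re-weighting); weights are taken as fixed.
- The stage generator's single liability scale ties all stage shifts to
  one parameter (see above).
- Strand-ambiguous SNPs are dropped rather than frequency-resolved.
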