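# pathprs

Pathway-partitioned polygenic risk scores (PRS) for age-related macular
degeneration (AMD), and their association with structural retinal
biomarkers in intermediate AMD (iAMD).

AMD risk is strongly genetic, but single global risk scores blur
mechanistically distinct pathways — complement activation, extracellular
matrix (ECM) remodeling, lipid metabolism, and the *ARMS2/HTRA1* locus.
`pathprs` is for statistical geneticists and ophthalmic researchers who
want to ask which of those pathways a given structural phenotype (reticular
pseudodrusen [RPD], pigmentary abnormalities [PA], hyper-reflective foci
[HRF], incomplete/complete RPE and outer retinal atrophy [iRORA/cRORA])
loads on.

The core quantities are raw, non-averaged weighted dosage sums

    PRS(s) = Σ_i β_i · d_{s,i}

over imputed effect-allele dosages `d ∈ [0, 2]`, computed globally and
restricted to pathway gene sets (C-PRS, AH-PRS, C+AH-PRS, E-PRS, L-PRS),
after variant QC (imputation R² ≥ 0.3, call rate ≥ 90 %, MAF ≥ 1 %,
Hardy-Weinberg exact P ≥ 1e-6 — the HWE exact test is implemented from
scratch and checked exhaustively against an enumeration oracle). Scores are
then modelled descriptively: score ~ stage (or biomarker flags) + age +
sex by ordinary least squares on a self-implemented core, with
estimated-marginal-means pairwise stage contrasts. All P values are
unadjusted, by design.

A synthetic-cohort generator (`pathprs.synthetic_cohort`) emulates a
European multicenter AMD cohort profile — stage sizes 46/33/404/73, age
71.5 ± 7 years truncated to [55, 86], 34.9 % male, iAMD biomarker
prevalences 23.8/47.8/46.8/8.7/7.2 % — with planted, recoverable
pathway-specific effects (RPD on AH + ECM scores, cRORA on AH) and QC decoy
variants, so the full pipeline is testable end to end. See
`docs/methods.md` for the model, calibration and limitations.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
cohort and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py   # fixture: VCF + weights + phenotypes
python analysis/02_qc_and_score.py      # variant QC + six scores
python analysis/03_descriptives.py      # per-stage table + box plot
python analysis/04_stage_associations.py
python analysis/05_biomarker_associations.py
```

`02` reports the QC outcome — every planted decoy is caught by the filter
its defect targets:

```
QC: 50/62 variants pass; failures: {'fail_r2': 3, 'fail_callrate': 3, 'fail_maf': 3, 'fail_hwe': 3}
```

`04` fits global PRS ~ stage + age + sex on the 556-sample cohort
(reference: no-AMD controls, female) and prints:

```
stage model (n=556, R2=0.287):
  intercept             1.287e-01 [-1.814e-01,  4.387e-01]  P=0.415
  stage_early           9.926e-02 [-4.666e-02,  2.452e-01]  P=0.182
  stage_intermediate    4.180e-01 [ 3.221e-01,  5.139e-01]  P=1.1e-16
  stage_late            8.388e-01 [ 7.176e-01,  9.600e-01]  P=1.66e-36
  age                  -1.053e-02 [-1.486e-02, -6.200e-03]  P=2.29e-06
  sex_male             -3.049e-02 [-8.962e-02,  2.863e-02]  P=0.311
planted intermediate shift 0.397, recovered 0.418
```

The intermediate and late coefficients are the PRS elevations of those
stages over controls at equal age and sex; the planted intermediate shift
(0.397, calibrated to the profile's headline 0.405) lies inside the fitted
95 % CI. `05` fits the 24 biomarker models on the iAMD subgroup; at study
scale (n ≈ 400) the strongest planted signal is the cRORA-AH association:

```
  model4:irora+crora:ah_prs        crora:  7.238e-02 (P=0.00472)
```

The subtler RPD effects need larger cohorts — the acceptance study
(below) shows they are recovered in ≥ 99 % of replicates at n = 4000.

The same steps are available as a CLI (`pathprs simulate|qc|score|
associate|run`), e.g.:

```sh
pathprs simulate --seed 1 --n-samples 556 --out-dir fixture/
pathprs score fixture/genotypes.vcf fixture/weights.tsv --out scores.csv
```

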