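"""Simulate the study-scale cohort fixture.

Generates 556 participants under the default study conditions (stage
prevalences, age/sex structure, planted pathway-biomarker effects, QC decoy
SNPs) and writes the raw inputs every later step consumes:
results/fixture/{genotypes.vcf, weights.tsv, phenotypes.csv, truth.json}.
"""

import warnings
from pathlib import Path

from pathprs.synthetic_cohort import SimulationConfig, simulate_cohort, write_fixture

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "fixture"


def main() -> None:
    cfg = SimulationConfig(n_samples=556, seed=SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, weights, cohort, truth = simulate_cohort(cfg)
    paths = write_fixture(matrix, weights, cohort, OUT, truth)
    print(f"simulated {matrix.n_samples} samples x {matrix.n_variants} variants "
          f"({len(truth.decoy_verdicts)} QC decoys, seed {SEED})")
    print("stage counts:", cohort["stage"].value_counts().to_dict())
    print("planted stage shifts (global PRS vs none):",
          {k: round(v, 3) for k, v in truth.stage_shift.items()})
    for name, p in paths.items():
        print(f"  {name}: {p}")


if __name__ == "__main__":
    main()
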