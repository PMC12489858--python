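"""Descriptive tables and the PRS-by-stage figure.

Summarizes the simulated cohort per AMD stage (n, age, sex, score means)
and the biomarker prevalences in the intermediate group, and draws the box
plot of the global PRS by stage. Writes results/descriptives.csv and
results/prs_by_stage.png.
"""

from pathlib import Path

import pandas as pd

from pathprs.association_models import plot_scores_by_stage
from pathprs.io_formats import read_phenotypes
from pathprs.pipeline import describe_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_phenotypes(ROOT / "fixture" / "phenotypes.csv")
    scores = pd.read_csv(ROOT / "scores.csv")
    desc = describe_cohort(cohort, scores)
    desc.to_csv(ROOT / "descriptives.csv", index=False)
    show = desc.set_index("stage")
    print("per-stage composition:")
    for stage in show.index:
        row = show.loc[stage]
        print(f"  {stage}: n={int(row['n'])}, age {row['age_mean']:.1f} +/- "
              f"{row['age_sd']:.2f}, male {row['pct_male']}%, "
              f"global PRS {row.get('global_prs_mean', float('nan')):.3f}")
    inter = show.loc["intermediate"]
    print("iAMD biomarker prevalences:",
          {b: f"{inter[f'pct_{b}']}%" for b in ("rpd", "pa", "hrf", "irora", "crora")})
    plot_scores_by_stage(scores, cohort, ROOT / "prs_by_stage.png")
    print(f"figure: {ROOT / 'prs_by_stage.png'}")


if __name__ == "__main__":
    main()
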