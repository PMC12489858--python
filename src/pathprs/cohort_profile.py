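"""Reference profile of the European multicenter AMD cohort the synthetic
generator emulates.

These counts and moments are the study conditions for every simulation:
stage sizes, sex composition, age distribution, structural-biomarker
prevalences in the intermediate-AMD (iAMD) group, and the per-stage mean of
the global polygenic risk score. They are inputs to the generator and to the
worked descriptive examples, not fitted quantities.
"""

from __future__ import annotations

STAGES = ("none", "early", "intermediate", "late")

# Participants per AMD stage (total 556).
STAGE_N = {"none": 46, "early": 33, "intermediate": 404, "late": 73}

# Male participants per stage.
MALE_N = {"none": 18, "early": 7, "intermediate": 141, "late": 29}

# Age (years) in the iAMD group; range bounds are the overall observed range.
AGE_MEAN = 71.5
AGE_SD = 6.98
AGE_MIN = 55.0
AGE_MAX = 86.0

# Structural-biomarker counts among the 404 iAMD study eyes.
IAMD_N = 404
BIOMARKER_N = {"rpd": 96, "pa": 193, "hrf": 189, "irora": 35, "crora": 29}

BIOMARKER_PREVALENCE = {k: v / IAMD_N for k, v in BIOMARKER_N.items()}

# Global PRS mean +/- SD per stage (non-averaged score sums).
GLOBAL_PRS_MEAN = {
    "none": -0.207,
    "early": -0.0474,
    "intermediate": 0.187,
    "late": 0.258,
}
GLOBAL_PRS_SD = {
    "none": 0.557,
    "early": 0.417,
    "intermediate": 0.425,
    "late": 0.382,
}

# Pathway score SDs in the iAMD group, used to scale simulated effect weights.
PATHWAY_PRS_SD = {
    "arms2_htra1": 0.226,
    "complement": 0.183,
    "ecm": 0.126,
    "lipid": 0.110,
}
GLOBAL_PRS_SD_IAMD = 0.425

# Headline stage effect: iAMD-vs-control shift of the global PRS after
# age/sex adjustment.
IAMD_STAGE_SHIFT = 0.405


def stage_prevalences() -> dict[str, float]:
    total = sum(STAGE_N.values())
    return {s: STAGE_N[s] / total for s in STAGES}
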