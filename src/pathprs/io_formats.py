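"""External representations: genotype VCF, PRS scoring files, phenotype CSV,
and model-result tables.

In-memory containers
--------------------
``GenotypeMatrix``
    samples x variants dosage matrix (effect counted on the ALT allele),
    NaN for missing, with per-variant metadata including the imputation R2.
``WeightTable`` / ``CohortTable`` / score matrices
    plain :class:`pandas.DataFrame` objects with fixed column schemas,
    produced and validated by the readers below.

The scoring file is a PGS-Catalog-style tab-separated table extended with a
gene label and a pathway column; the pathway vocabulary is
{complement, ecm, lipid, arms2_htra1, other} and unknown strings fold into
``other`` with a warning. Gene labels alone are enough to assign a pathway
for the canonical AMD loci (e.g. ``ARMS2/HTRA1``, ``MMP9``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

VALID_ALLELES = {"A", "C", "G", "T"}

PATHWAYS = ("complement", "ecm", "lipid", "arms2_htra1")

#: Gene label -> pathway, following the canonical grouping of AMD risk loci
#: by the biological process of the nearest gene product. ADAM19 and MMP9
#: are matrix metalloproteinases and belong to the extracellular-matrix set.
GENE_PATHWAY = {
    "C3": "complement",
    "CFB/C2": "complement",
    "CFH": "complement",
    "CFI": "complement",
    "ADAM19": "ecm",
    "ADAMTS9-AS2": "ecm",
    "COL4A3": "ecm",
    "COL8A1": "ecm",
    "MMP9": "ecm",
    "SYN3/TIMP3": "ecm",
    "VEGF-A": "ecm",
    "ABCA1": "lipid",
    "APOE": "lipid",
    "CETP": "lipid",
    "LIPC": "lipid",
    "ARMS2/HTRA1": "arms2_htra1",
}

_PATHWAY_ALIASES = {
    "complement": "complement",
    "ecm": "ecm",
    "extracellular matrix": "ecm",
    "lipid": "lipid",
    "lipid metabolism": "lipid",
    "arms2_htra1": "arms2_htra1",
    "arms2/htra1": "arms2_htra1",
    "other": "other",
    "": "",
}

WEIGHT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "effect_weight",
    "gene_label",
    "pathway",
]

PHENOTYPE_COLUMNS = [
    "sample_id",
    "age",
    "sex",
    "stage",
    "rpd",
    "pa",
    "hrf",
    "irora",
    "crora",
]

STAGE_LEVELS = ("none", "early", "intermediate", "late")
SEX_LEVELS = ("female", "male")
BIOMARKERS = ("rpd", "pa", "hrf", "irora", "crora")


@dataclass(frozen=True)
class VariantMeta:
    """Metadata for one biallelic variant.

    ``imputation_r2`` is the per-variant imputation quality (NaN when the
    variant is genotyped rather than imputed, or simply unannotated).
    """

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    imputation_r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.variant_id}: pos must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"{self.variant_id}: ref == alt allele")
        for a in (self.ref_allele, self.alt_allele):
            if a not in VALID_ALLELES:
                raise ValidationError(f"{self.variant_id}: invalid allele {a!r}")
        if not math.isnan(self.imputation_r2) and not 0 <= self.imputation_r2 <= 1:
            raise ValidationError(
                f"{self.variant_id}: imputation R2 {self.imputation_r2} outside [0,1]"
            )


@dataclass
class GenotypeMatrix:
    """Samples x variants ALT-allele dosage matrix (NaN = missing)."""

    samples: list[str]
    variants: list[VariantMeta]
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate variant_id in GenotypeMatrix")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValidationError(f"{bad} dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def subset_variants(self, keep: list[int]) -> "GenotypeMatrix":
        """New matrix restricted to the given variant indices (order kept)."""
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in keep],
            dosages=self.dosages[:, keep].copy(),
        )


# ---------------------------------------------------------------------------
# scoring file
# ---------------------------------------------------------------------------

def normalize_pathway(value: str, gene_label: str = "") -> str:
    """Map a raw pathway string (or, failing that, a gene label) onto the
    controlled vocabulary. Unknown non-empty strings fold to ``other``."""
    key = str(value).strip().lower() if value is not None else ""
    if key in ("nan", "none"):
        key = ""
    if key in _PATHWAY_ALIASES:
        tag = _PATHWAY_ALIASES[key]
    else:
        warnings.warn(
            f"unknown pathway label {value!r}; keeping variant as 'other'",
            stacklevel=3,
        )
        return "other"
    if tag == "":
        # derive from the gene label where the canonical map knows it
        tag = GENE_PATHWAY.get(str(gene_label).strip(), "")
    return tag


def read_scoring_file(path) -> pd.DataFrame:
    """Read a tab-separated scoring table into a WeightTable DataFrame.

    Mandatory columns: ``variant_id``, ``effect_allele``, ``effect_weight``.
    Optional: ``chrom``, ``pos``, ``other_allele``, ``gene_label``,
    ``pathway``. Betas are parsed as floats; a non-numeric weight raises a
    row-level :class:`FormatError` with its line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("variant_id", "effect_allele", "effect_weight"):
        if col not in df.columns:
            raise FormatError(f"scoring file {path}: missing mandatory column {col!r}")
    for col in WEIGHT_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    betas = []
    for i, raw in enumerate(df["effect_weight"]):
        try:
            betas.append(float(raw))
        except ValueError:
            # +2: header line plus 1-based numbering
            raise FormatError(
                f"scoring file {path}, line {i + 2}: non-numeric effect_weight {raw!r}"
            ) from None
    out = pd.DataFrame(
        {
            "variant_id": df["variant_id"].astype(str),
            "chrom": df["chrom"].astype(str),
            "pos": pd.to_numeric(df["pos"], errors="coerce").astype("Int64"),
            "effect_allele": df["effect_allele"].str.upper(),
            "other_allele": df["other_allele"].str.upper(),
            "effect_weight": np.array(betas, dtype=float),
            "gene_label": df["gene_label"].astype(str),
        }
    )
    out["pathway"] = [
        normalize_pathway(p, g) for p, g in zip(df["pathway"], df["gene_label"])
    ]
    _validate_weight_table(out, path)
    return out


def _validate_weight_table(wt: pd.DataFrame, origin="WeightTable") -> None:
    if wt["variant_id"].duplicated().any():
        dup = wt.loc[wt["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValidationError(f"{origin}: duplicate variant_id {dup!r}")
    if not np.isfinite(wt["effect_weight"]).all():
        raise ValidationError(f"{origin}: non-finite effect_weight")
    same = wt["other_allele"].ne("") & (wt["effect_allele"] == wt["other_allele"])
    if same.any():
        vid = wt.loc[same, "variant_id"].iloc[0]
        raise ValidationError(f"{origin}: effect == other allele for {vid}")


def write_scoring_file(weights: pd.DataFrame, path) -> None:
    """Write a WeightTable back to the tab-separated layout (round-trips
    through :func:`read_scoring_file` with betas preserved exactly)."""
    out = weights.copy()
    out["effect_weight"] = [repr(float(b)) for b in out["effect_weight"]]
    out.to_csv(path, sep="\t", index=False, columns=WEIGHT_COLUMNS)


# ---------------------------------------------------------------------------
# genotype VCF
# ---------------------------------------------------------------------------

def read_genotypes(
    path,
    field_preference: tuple[str, ...] = ("DS", "GT"),
    r2_key: str = "R2",
    multiallelic_policy: str = "error",
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Dosages come from the first available field in ``field_preference``
    per record: ``DS`` (imputed ALT dosage) or ``GT`` (hard-call ALT allele
    count). Missing genotypes stay NaN. Multi-allelic records are rejected
    (``error``) or dropped (``skip``) — the downstream score expects
    biallelic loci. Variant order follows file order.
    """
    from cyvcf2 import VCF

    if multiallelic_policy not in ("error", "skip"):
        raise ValidationError(f"unknown multiallelic_policy {multiallelic_policy!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantMeta] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            if multiallelic_policy == "error":
                raise ValidationError(
                    f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                    f"({rec.REF}->{','.join(rec.ALT)}); biallelic input required"
                )
            warnings.warn(f"skipping multi-allelic record {rec.CHROM}:{rec.POS}")
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        r2 = rec.INFO.get(r2_key)
        meta = VariantMeta(
            variant_id=vid,
            chrom=str(rec.CHROM),
            pos=int(rec.POS),
            ref_allele=rec.REF.upper(),
            alt_allele=rec.ALT[0].upper(),
            imputation_r2=float(r2) if r2 is not None else float("nan"),
        )
        col = None
        for fieldname in field_preference:
            if fieldname == "DS":
                ds = rec.format("DS")
                if ds is not None:
                    col = np.asarray(ds, dtype=float).reshape(len(samples))
                    col = np.where((col < 0) | (col > 2), np.nan, col)
                    break
            elif fieldname == "GT":
                gts = rec.genotypes
                if gts is not None:
                    col = np.array(
                        [
                            np.nan
                            if g[0] < 0 or g[1] < 0
                            else float(g[0]) + float(g[1])
                            for g in gts
                        ]
                    )
                    break
            else:
                raise ValidationError(f"unknown genotype field {fieldname!r}")
        if col is None:
            raise FormatError(
                f"record {vid}: none of the fields {field_preference} present"
            )
        variants.append(meta)
        columns.append(col)
    if not variants:
        raise FormatError(f"VCF {path}: no usable biallelic records")
    dosages = np.column_stack(columns)
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


# ---------------------------------------------------------------------------
# phenotype CSV
# ---------------------------------------------------------------------------

def _parse_flag(value) -> object:
    """0/1/true/false/yes/no -> pandas boolean; blank -> NA."""
    s = str(value).strip().lower()
    if s in ("", "na", "nan", "none"):
        return pd.NA
    if s in ("1", "1.0", "true", "t", "yes"):
        return True
    if s in ("0", "0.0", "false", "f", "no"):
        return False
    raise ValidationError(f"unparseable boolean flag {value!r}")


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype CSV into a CohortTable DataFrame.

    Stage and sex labels are case-folded against their controlled
    vocabularies. The combined atrophy coding is enforced: a row claiming
    both iRORA and cRORA is repaired to the cRORA group (irora=False,
    crora=True) with a warning, because cRORA presence defines that group.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"phenotype CSV {path}: missing columns {missing}")
    if raw["sample_id"].duplicated().any():
        dup = raw.loc[raw["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"phenotype CSV {path}: duplicate sample_id {dup!r}")

    stage = raw["stage"].str.strip().str.lower()
    bad_stage = ~stage.isin(STAGE_LEVELS)
    if bad_stage.any():
        raise ValidationError(
            f"phenotype CSV {path}: unknown stage label "
            f"{raw.loc[bad_stage, 'stage'].iloc[0]!r}"
        )
    sex = raw["sex"].str.strip().str.lower()
    bad_sex = ~sex.isin(SEX_LEVELS)
    if bad_sex.any():
        raise ValidationError(
            f"phenotype CSV {path}: unknown sex label "
            f"{raw.loc[bad_sex, 'sex'].iloc[0]!r}"
        )
    cohort = pd.DataFrame(
        {
            "sample_id": raw["sample_id"],
            "age": pd.to_numeric(raw["age"]),
            "sex": pd.Categorical(sex, categories=SEX_LEVELS),
            "stage": pd.Categorical(stage, categories=STAGE_LEVELS, ordered=True),
        }
    )
    if (cohort["age"] <= 0).any():
        raise ValidationError(f"phenotype CSV {path}: non-positive age")
    for b in BIOMARKERS:
        cohort[b] = pd.array([_parse_flag(v) for v in raw[b]], dtype="boolean")
    return enforce_atrophy_coding(cohort)


def enforce_atrophy_coding(cohort: pd.DataFrame) -> pd.DataFrame:
    """Repair irora=True & crora=True rows to the cRORA group, warning once."""
    both = (cohort["irora"] == True) & (cohort["crora"] == True)  # noqa: E712
    if both.any():
        warnings.warn(
            f"{int(both.sum())} sample(s) flagged both iRORA and cRORA; "
            "recoded to the cRORA group (irora=False, crora=True)"
        )
        cohort = cohort.copy()
        cohort.loc[both, "irora"] = False
    return cohort


def write_phenotypes(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    for b in BIOMARKERS:
        out[b] = out[b].astype("Int64")
    out.to_csv(path, index=False, columns=PHENOTYPE_COLUMNS)


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["model", "predictor", "estimate", "ci_low", "ci_high", "p_value"]


def results_frame(model_results) -> pd.DataFrame:
    """Flatten a list of ModelResult objects into a tidy results table."""
    rows = []
    for res in model_results:
        for _, r in res.params.iterrows():
            rows.append(
                {
                    "model": res.model_id,
                    "predictor": r["term"],
                    "estimate": r["estimate"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "p_value": r["p_value"],
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(model_results, path, format: str = "csv") -> None:
    """Write fitted-model tables (CSV keeps full precision; ``text`` renders
    aligned blocks, one per model). An empty result list is an error."""
    results = list(model_results)
    if not results:
        raise ValidationError("write_results: empty result list")
    table = results_frame(results)
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "text":
        blocks = []
        for model, sub in table.groupby("model", sort=False):
            lines = [f"== {model} =="]
            for _, r in sub.iterrows():
                lines.append(
                    f"  {r['predictor']:<22} {r['estimate']: .3e} "
                    f"[{r['ci_low']: .3e}, {r['ci_high']: .3e}]  P={r['p_value']:.3g}"
                )
            blocks.append("\n".join(lines))
        with open(path, "w") as fh:
            fh.write("\n\n".join(blocks) + "\n")
    else:
        raise ValidationError(f"unknown results format {format!r}")
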