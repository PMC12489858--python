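"""Effect-allele alignment and polygenic score computation.

Scores are raw, non-averaged weighted dosage sums: score(s) = sum_i beta_i
* d_{s,i}, with d the effect-allele dosage. No centering, no division by
the variant count, no standardization — cohort means can therefore be
negative when the weight set carries signed betas.

Six scores are produced: the global PRS over every surviving weight, and
five pathway-specific scores (psPRS) restricted to variants whose assigned
gene belongs to one pathway: complement (C-PRS), ARMS2/HTRA1 (AH-PRS),
their union (C+AH-PRS), extracellular matrix (E-PRS) and lipid metabolism
(L-PRS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ScoreUndefinedError, ValidationError
from .io_formats import GENE_PATHWAY, GenotypeMatrix

_COMPLEMENT_BASE = {"A": "T", "T": "A", "C": "G", "G": "C"}

SCORE_COLUMNS = ["global_prs", "ah_prs", "c_prs", "c_ah_prs", "e_prs", "l_prs"]

#: score column -> set of pathway tags it sums over (None = all variants)
SCORE_PATHWAYS: dict[str, set[str] | None] = {
    "global_prs": None,
    "ah_prs": {"arms2_htra1"},
    "c_prs": {"complement"},
    "c_ah_prs": {"complement", "arms2_htra1"},
    "e_prs": {"ecm"},
    "l_prs": {"lipid"},
}


@dataclass(frozen=True)
class PathwayRegistry:
    """Gene-label -> pathway registry backing the psPRS definitions.

    The default mapping groups the canonical AMD risk loci by the
    biological process of the nearest gene product; every gene label maps
    to at most one pathway, and complement and ARMS2/HTRA1 are disjoint so
    C+AH-PRS = C-PRS + AH-PRS holds samplewise.
    """

    gene_pathway: dict[str, str] = field(default_factory=lambda: dict(GENE_PATHWAY))

    def pathway_of(self, gene_label: str) -> str:
        return self.gene_pathway.get(str(gene_label).strip(), "")

    def genes_in(self, pathway: str) -> set[str]:
        return {g for g, p in self.gene_pathway.items() if p == pathway}


@dataclass
class AlignedDosage:
    """Effect-allele dosages plus per-variant alignment bookkeeping.

    ``table`` has one row per weight-table variant found in the genotype
    matrix, with columns variant_id, effect_weight, gene_label, pathway,
    action (as_is | flipped | strand_complemented | excluded_ambiguous |
    unmatched). ``dosages`` holds the samples x variants effect-allele
    dosage matrix for the scoreable (as_is/flipped/strand_complemented)
    variants, column order matching ``scoreable_ids``.
    """

    samples: list[str]
    table: pd.DataFrame = field(repr=False)
    dosages: np.ndarray = field(repr=False)

    @property
    def scoreable(self) -> pd.DataFrame:
        return self.table[
            self.table["action"].isin(("as_is", "flipped", "strand_complemented"))
        ]

    @property
    def scoreable_ids(self) -> list[str]:
        return list(self.scoreable["variant_id"])


def _is_ambiguous(a1: str, a2: str) -> bool:
    return a2 == _COMPLEMENT_BASE.get(a1, "?")


def align_effect_alleles(
    weights: pd.DataFrame,
    matrix: GenotypeMatrix,
    ambiguity_policy: str = "exclude",
) -> AlignedDosage:
    """Reorient ALT dosages onto each weight's effect allele.

    effect==ALT keeps the dosage; effect==REF flips it (d <- 2-d); if the
    alleles only match after strand complement the variant is marked
    ``strand_complemented`` (with the flip applied when needed). A/T and
    C/G SNPs cannot be strand-resolved and are excluded under the default
    policy. Weights whose alleles match neither orientation are
    ``unmatched`` and contribute to no score.
    """
    if ambiguity_policy not in ("exclude", "keep"):
        raise ValidationError(f"unknown ambiguity_policy {ambiguity_policy!r}")
    by_id = {v.variant_id: j for j, v in enumerate(matrix.variants)}
    shared = [vid for vid in weights["variant_id"] if vid in by_id]
    if not shared:
        raise ValidationError(
            "no overlapping variant_id between weights and genotypes; "
            "scores are undefined"
        )
    n_absent = len(weights) - len(shared)
    if n_absent:
        warnings.warn(f"{n_absent} weight(s) absent from the genotype matrix")

    rows = []
    cols = []
    widx = weights.set_index("variant_id")
    for vid in shared:
        w = widx.loc[vid]
        j = by_id[vid]
        meta = matrix.variants[j]
        eff, oth = str(w["effect_allele"]), str(w["other_allele"])
        ref, alt = meta.ref_allele, meta.alt_allele
        ambiguous = oth != "" and _is_ambiguous(eff, oth)
        action, flip = _match_alleles(eff, oth, ref, alt)
        if ambiguous and ambiguity_policy == "exclude" and action != "unmatched":
            action = "excluded_ambiguous"
        rows.append(
            {
                "variant_id": vid,
                "effect_weight": float(w["effect_weight"]),
                "gene_label": str(w["gene_label"]),
                "pathway": str(w["pathway"]),
                "action": action,
            }
        )
        if action in ("as_is", "flipped", "strand_complemented"):
            d = matrix.dosages[:, j]
            cols.append(2.0 - d if flip else d.copy())
    if rows and not cols:
        raise ValidationError("no scoreable variants after alignment")
    for r in rows:
        if r["action"] == "unmatched":
            warnings.warn(f"{r['variant_id']}: alleles unmatched; excluded from scores")
    dosages = np.column_stack(cols) if cols else np.empty((matrix.n_samples, 0))
    return AlignedDosage(
        samples=list(matrix.samples), table=pd.DataFrame(rows), dosages=dosages
    )


def _match_alleles(eff: str, oth: str, ref: str, alt: str) -> tuple[str, bool]:
    """Return (action, flip). ``flip`` means effect allele sits on REF."""
    if eff == alt and (oth in ("", ref)):
        return "as_is", False
    if eff == ref and (oth in ("", alt)):
        return "flipped", True
    ceff = _COMPLEMENT_BASE.get(eff, "?")
    coth = _COMPLEMENT_BASE.get(oth, "") if oth else ""
    if ceff == alt and (coth in ("", ref)):
        return "strand_complemented", False
    if ceff == ref and (coth in ("", alt)):
        return "strand_complemented", True
    return "unmatched", False


def impute_missing_dosage(aligned: AlignedDosage) -> AlignedDosage:
    """Replace missing aligned dosages by the per-variant mean dosage
    (2 x effect-allele frequency from the non-missing entries). A variant
    with no observed dosage at all is dropped with a warning."""
    dos = aligned.dosages.copy()
    keep = []
    scoreable_ids = aligned.scoreable_ids
    for k, vid in enumerate(scoreable_ids):
        col = dos[:, k]
        miss = np.isnan(col)
        if miss.all():
            warnings.warn(f"{vid}: all dosages missing; variant dropped")
            continue
        if miss.any():
            col[miss] = col[~miss].mean()
        keep.append(k)
    kept_ids = {scoreable_ids[k] for k in keep}
    table = aligned.table[
        ~aligned.table["action"].isin(("as_is", "flipped", "strand_complemented"))
        | aligned.table["variant_id"].isin(kept_ids)
    ].reset_index(drop=True)
    return AlignedDosage(
        samples=list(aligned.samples), table=table, dosages=dos[:, keep]
    )


def compute_score(
    aligned: AlignedDosage, weights: pd.DataFrame, variant_subset: list[str]
) -> np.ndarray:
    """Non-averaged weighted dosage sum over ``variant_subset``."""
    if not variant_subset:
        raise ScoreUndefinedError("compute_score: empty variant subset")
    ids = aligned.scoreable_ids
    pos = {vid: k for k, vid in enumerate(ids)}
    missing = [v for v in variant_subset if v not in pos]
    if missing:
        raise ValidationError(f"variants not scoreable/aligned: {missing}")
    cols = [pos[v] for v in variant_subset]
    betas = (
        weights.set_index("variant_id")
        .loc[variant_subset, "effect_weight"]
        .to_numpy(dtype=float)
    )
    return aligned.dosages[:, cols] @ betas


def compute_all_scores(
    aligned: AlignedDosage,
    weights: pd.DataFrame,
    registry: PathwayRegistry | None = None,
) -> pd.DataFrame:
    """ScoreMatrix: global plus the five pathway scores per sample.

    The global score sums every scoreable weight (pathway-tagged or not);
    each psPRS is restricted to variants whose gene label resolves to that
    pathway in the registry. A pathway with zero surviving variants makes
    its score undefined and raises.
    """
    registry = registry or PathwayRegistry()
    sc = aligned.scoreable
    # resolve each variant's pathway: scoring-file tag, else registry lookup
    resolved = [
        p if p in ("complement", "ecm", "lipid", "arms2_htra1")
        else registry.pathway_of(g)
        for p, g in zip(sc["pathway"], sc["gene_label"])
    ]
    out = {"sample_id": list(aligned.samples)}
    for score_name, pathways in SCORE_PATHWAYS.items():
        if pathways is None:
            subset = list(sc["variant_id"])
        else:
            subset = [
                vid for vid, p in zip(sc["variant_id"], resolved) if p in pathways
            ]
        if not subset:
            raise ScoreUndefinedError(
                f"score {score_name}: no surviving variants for "
                f"pathway(s) {sorted(pathways) if pathways else 'global'}"
            )
        out[score_name] = compute_score(aligned, weights, subset)
    return pd.DataFrame(out)
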