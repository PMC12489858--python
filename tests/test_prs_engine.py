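import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathprs.errors import ScoreUndefinedError, ValidationError
from pathprs.io_formats import GenotypeMatrix, VariantMeta
from pathprs.prs_engine import (
    PathwayRegistry,
    SCORE_COLUMNS,
    align_effect_alleles,
    compute_all_scores,
    compute_score,
    impute_missing_dosage,
)

from conftest import toy_weights


def matrix_of(variant_specs, dosages):
    """variant_specs: list of (vid, ref, alt)."""
    variants = [
        VariantMeta(vid, "1", 100 + j, ref, alt)
        for j, (vid, ref, alt) in enumerate(variant_specs)
    ]
    d = np.asarray(dosages, dtype=float)
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(d.shape[0])], variants=variants, dosages=d
    )


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def test_effect_on_alt_kept_as_is():
    m = matrix_of([("rs1", "G", "A")], [[1.2]])
    w = toy_weights([("rs1", "A", "G", 0.5, "CFH", "complement")])
    al = align_effect_alleles(w, m)
    assert al.table["action"].iloc[0] == "as_is"
    assert al.dosages[0, 0] == pytest.approx(1.2)


def test_effect_on_ref_flips_dosage():
    m = matrix_of([("rs1", "G", "A")], [[1.2]])
    w = toy_weights([("rs1", "G", "A", 0.5, "CFH", "complement")])
    al = align_effect_alleles(w, m)
    assert al.table["action"].iloc[0] == "flipped"
    assert al.dosages[0, 0] == pytest.approx(0.8)


def test_strand_complement_resolves_non_ambiguous_pair():
    # effect T/other C complements to A/G == alt/ref
    m = matrix_of([("rs1", "G", "A")], [[1.5]])
    w = toy_weights([("rs1", "T", "C", 0.5, "CFH", "complement")])
    al = align_effect_alleles(w, m)
    assert al.table["action"].iloc[0] == "strand_complemented"
    assert al.dosages[0, 0] == pytest.approx(1.5)


def test_ambiguous_at_snp_excluded_by_default_kept_on_request():
    m = matrix_of([("rs1", "T", "A"), ("rs2", "G", "A")], [[1.0, 1.0]])
    w = toy_weights(
        [("rs1", "A", "T", 0.5, "CFH", "complement"),
         ("rs2", "A", "G", 0.2, "C3", "complement")]
    )
    al = align_effect_alleles(w, m, ambiguity_policy="exclude")
    actions = dict(zip(al.table["variant_id"], al.table["action"]))
    assert actions["rs1"] == "excluded_ambiguous" and actions["rs2"] == "as_is"
    al_keep = align_effect_alleles(w, m, ambiguity_policy="keep")
    assert set(al_keep.scoreable_ids) == {"rs1", "rs2"}


def test_irreconcilable_alleles_marked_unmatched():
    m = matrix_of([("rs1", "G", "A"), ("rs2", "C", "A")], [[1.0, 1.0]])
    w = toy_weights(
        [("rs1", "C", "G", 0.5, "CFH", "complement"),
         ("rs2", "A", "C", 0.2, "C3", "complement")]
    )
    with pytest.warns(UserWarning, match="unmatched"):
        al = align_effect_alleles(w, m)
    actions = dict(zip(al.table["variant_id"], al.table["action"]))
    assert actions["rs1"] == "unmatched"
    assert al.scoreable_ids == ["rs2"]


def test_zero_overlap_is_hard_error():
    m = matrix_of([("rs9", "G", "A")], [[1.0]])
    w = toy_weights([("rs1", "A", "G", 0.5, "CFH", "complement")])
    with pytest.raises(ValidationError, match="no overlapping"):
        align_effect_alleles(w, m)


# ---------------------------------------------------------------------------
# missing-dosage imputation
# ---------------------------------------------------------------------------

def test_missing_dosage_imputed_with_mean():
    m = matrix_of([("rs1", "G", "A")], [[0.0], [2.0], [np.nan]])
    w = toy_weights([("rs1", "A", "G", 1.0, "CFH", "complement")])
    al = impute_missing_dosage(align_effect_alleles(w, m))
    assert al.dosages[:, 0].tolist() == [0.0, 2.0, 1.0]


def test_complete_column_unchanged_and_all_missing_dropped():
    m = matrix_of(
        [("rs1", "G", "A"), ("rs2", "C", "T")],
        [[1.0, np.nan], [2.0, np.nan]],
    )
    w = toy_weights(
        [("rs1", "A", "G", 1.0, "CFH", "complement"),
         ("rs2", "T", "C", 1.0, "C3", "complement")]
    )
    with pytest.warns(UserWarning, match="dropped"):
        al = impute_missing_dosage(align_effect_alleles(w, m))
    assert al.scoreable_ids == ["rs1"]
    assert al.dosages[:, 0].tolist() == [1.0, 2.0]


# ---------------------------------------------------------------------------
# score sums
# ---------------------------------------------------------------------------

def _aligned_three_variants(dosages):
    m = matrix_of(
        [("rs1", "G", "A"), ("rs2", "C", "T"), ("rs3", "G", "A")], dosages
    )
    w = toy_weights(
        [
            ("rs1", "A", "G", 0.4, "ARMS2/HTRA1", "arms2_htra1"),
            ("rs2", "T", "C", -0.2, "CFH", "complement"),
            ("rs3", "A", "G", 0.1, "LOC1", ""),
        ]
    )
    return align_effect_alleles(w, m), w


def test_score_is_hand_computed_weighted_sum():
    """beta=(0.4,-0.2,0.1), dosages (2,1,0) -> 0.8 - 0.2 + 0 = 0.6."""
    al, w = _aligned_three_variants([[2.0, 1.0, 0.0]])
    s = compute_score(al, w, ["rs1", "rs2", "rs3"])
    assert s[0] == pytest.approx(0.6)


def test_single_variant_score_scales_with_dosage():
    m = matrix_of([("rs1", "G", "A")], [[0.0], [1.0], [2.0]])
    w = toy_weights([("rs1", "A", "G", 0.5, "CFH", "complement")])
    al = align_effect_alleles(w, m)
    assert compute_score(al, w, ["rs1"]).tolist() == [0.0, 0.5, 1.0]


def test_null_weights_give_zero_scores():
    al, w = _aligned_three_variants([[2.0, 1.0, 0.0]])
    w0 = w.assign(effect_weight=0.0)
    assert compute_score(al, w0, ["rs1", "rs2", "rs3"]).tolist() == [0.0]


def test_empty_subset_rejected():
    al, w = _aligned_three_variants([[2.0, 1.0, 0.0]])
    with pytest.raises(ScoreUndefinedError):
        compute_score(al, w, [])


def test_all_scores_additivity_and_zero_dosage():
    al, w = _aligned_three_variants([[0.0, 0.0, 0.0], [2.0, 1.0, 1.0]])
    with pytest.raises(ScoreUndefinedError, match="e_prs"):
        compute_all_scores(al, w)  # no ECM/lipid variants in this toy set


def test_score_matrix_matches_brute_force_per_pathway_sums(study_scale_sim):
    """ScoreMatrix equals a direct re-summation over each pathway's
    variants on a simulated fixture."""
    matrix, weights, _, truth = study_scale_sim
    al = align_effect_alleles(weights, matrix)
    al = impute_missing_dosage(al)
    scores = compute_all_scores(al, weights)
    assert list(scores["sample_id"]) == matrix.samples  # sample order kept
    sc = al.scoreable
    pos = {vid: k for k, vid in enumerate(al.scoreable_ids)}
    for col, pathways in [
        ("c_prs", {"complement"}),
        ("ah_prs", {"arms2_htra1"}),
        ("e_prs", {"ecm"}),
        ("l_prs", {"lipid"}),
    ]:
        expected = np.zeros(matrix.n_samples)
        for vid, pw, beta in zip(
            sc["variant_id"], sc["pathway"], sc["effect_weight"]
        ):
            if pw in pathways:
                expected += beta * al.dosages[:, pos[vid]]
        np.testing.assert_allclose(scores[col].to_numpy(), expected, rtol=1e-12)
    np.testing.assert_allclose(
        scores["c_ah_prs"], scores["c_prs"] + scores["ah_prs"], rtol=1e-12
    )


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_scoring_invariants_on_random_fixtures(seed):
    """Linearity in beta, allele-flip invariance, and C+AH additivity."""
    rng = np.random.default_rng(seed)
    n, m = 12, 8
    pathways = ["complement", "arms2_htra1", "ecm", "lipid"] * 2
    genes = ["CFH", "ARMS2/HTRA1", "MMP9", "APOE"] * 2
    dosages = rng.integers(0, 3, size=(n, m)).astype(float)
    specs = [(f"rs{j}", "G", "A") for j in range(m)]
    matrix = matrix_of(specs, dosages)
    w = toy_weights(
        [
            (f"rs{j}", "A", "G", float(rng.normal(0, 0.3)), genes[j], pathways[j])
            for j in range(m)
        ]
    )
    base = compute_all_scores(align_effect_alleles(w, matrix), w)

    # linearity: doubling every beta doubles every score exactly
    w2 = w.assign(effect_weight=w["effect_weight"] * 2)
    doubled = compute_all_scores(align_effect_alleles(w2, matrix), w2)
    for col in SCORE_COLUMNS:
        np.testing.assert_array_equal(doubled[col], 2 * base[col])

    # allele-encoding invariance: swap ref/alt labels and dosages d <- 2-d
    flipped_specs = [(f"rs{j}", "A", "G") for j in range(m)]
    flipped = matrix_of(flipped_specs, 2.0 - dosages)
    refit = compute_all_scores(align_effect_alleles(w, flipped), w)
    for col in SCORE_COLUMNS:
        np.testing.assert_allclose(refit[col], base[col], atol=1e-12)

    # disjoint-set additivity
    np.testing.assert_allclose(
        base["c_ah_prs"], base["c_prs"] + base["ah_prs"], atol=1e-12
    )


def test_global_decomposes_into_pathways_plus_untagged(study_scale_sim):
    matrix, weights, _, _ = study_scale_sim
    al = impute_missing_dosage(align_effect_alleles(weights, matrix))
    scores = compute_all_scores(al, weights)
    sc = al.scoreable
    pos = {vid: k for k, vid in enumerate(al.scoreable_ids)}
    untagged = np.zeros(matrix.n_samples)
    for vid, pw, beta in zip(sc["variant_id"], sc["pathway"], sc["effect_weight"]):
        if pw not in ("complement", "ecm", "lipid", "arms2_htra1"):
            untagged += beta * al.dosages[:, pos[vid]]
    total = (
        scores["c_prs"] + scores["ah_prs"] + scores["e_prs"] + scores["l_prs"]
        + untagged
    )
    np.testing.assert_allclose(scores["global_prs"], total, rtol=1e-10)


def test_registry_defaults_are_disjoint():
    reg = PathwayRegistry()
    assert not (reg.genes_in("complement") & reg.genes_in("arms2_htra1"))
    for gene, pw in reg.gene_pathway.items():
        assert pw in ("complement", "ecm", "lipid", "arms2_htra1")
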