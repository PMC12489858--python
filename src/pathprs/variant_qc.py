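"""Variant-level quality control.

Four filters, applied in a fixed order so failure attribution is
deterministic: imputation R2 >= 0.3, genotype call rate >= 90%, minor
allele frequency >= 1%, and Hardy-Weinberg equilibrium exact-test
P >= 1e-6. The surviving variant set does not depend on the order; only the
recorded verdict of a multiply-failing variant does.

The HWE exact test is the two-sided conditional test on the heterozygote
count: given the sample size and allele counts, every admissible
heterozygote count (same parity as the observed one) has a conditional
probability under random mating, and the P value sums the probabilities of
all counts no more probable than the observed one. A mid-P variant (half
weight on the observed configuration) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .io_formats import GenotypeMatrix


@dataclass(frozen=True)
class QCThresholds:
    """Variant QC cut-offs (defaults are the standard imputation-pipeline
    values: R2 0.3, MAF 1%, missingness 10%, HWE P 1e-6)."""

    r2_min: float = 0.3
    maf_min: float = 0.01
    missing_max: float = 0.10
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("r2_min", "maf_min", "missing_max", "hwe_p_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"threshold {name}={v} outside [0,1]")


#: Fixed failure-attribution order.
VERDICT_ORDER = ("fail_r2", "fail_callrate", "fail_maf", "fail_hwe")


@dataclass
class QCReport:
    """Per-variant QC statistics and verdicts, plus per-class counts."""

    table: pd.DataFrame = field(repr=False)

    @property
    def counts(self) -> dict[str, int]:
        c = {"pass": 0, **{v: 0 for v in VERDICT_ORDER}}
        c.update(self.table["verdict"].value_counts().to_dict())
        return c

    @property
    def n_pass(self) -> int:
        return int((self.table["verdict"] == "pass").sum())


def compute_maf(dosage_column: np.ndarray) -> float:
    """Minor allele frequency from a dosage column: p-hat = mean/2 over
    non-missing entries, folded to min(p, 1-p)."""
    col = np.asarray(dosage_column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise UndefinedStatisticError("MAF undefined: all dosages missing")
    p = float(obs.mean()) / 2.0
    return min(p, 1.0 - p)


def hard_calls_from_dosage(
    dosage_column: np.ndarray, hard_call_tolerance: float = 0.1
) -> tuple[int, int, int]:
    """Discretize dosages to genotype counts (hom-ref, het, hom-alt).

    A dosage within ``hard_call_tolerance`` of 0, 1 or 2 maps to that
    genotype; anything else (including missing) is uncallable and excluded.
    """
    if not 0 < hard_call_tolerance < 0.5:
        raise ValidationError("hard_call_tolerance must lie in (0, 0.5)")
    col = np.asarray(dosage_column, dtype=float)
    col = col[~np.isnan(col)]
    counts = []
    for g in (0.0, 1.0, 2.0):
        counts.append(int((np.abs(col - g) <= hard_call_tolerance).sum()))
    return tuple(counts)  # type: ignore[return-value]


def _hwe_het_distribution(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given ``n``
    diploid samples and ``n_rare`` copies of the rarer allele.

    Uses the stable ratio recurrence starting at the modal count:
    P(h-2)/P(h) = h(h-1) / (4 (n_r+1)(n_c+1)) where n_r, n_c are the
    homozygote counts implied by h-2. Returns (het counts, probabilities).
    """
    if n_rare == 0:
        return np.array([0]), np.array([1.0])
    h_max = min(n_rare, 2 * n - n_rare)
    h_min = n_rare % 2
    hs = np.arange(h_min, h_max + 1, 2)
    # start near the mode of the distribution
    mid = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if mid % 2 != n_rare % 2:
        mid += 1 if mid < h_max else -1
    mid = min(max(mid, h_min), h_max)
    probs = {mid: 1.0}
    h = mid
    while h - 2 >= h_min:  # downward
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mid
    while h + 2 <= h_max:  # upward (inverse ratio)
        hom_r = (n_rare - h - 2) // 2
        hom_c = n - (h + 2) - hom_r
        probs[h + 2] = probs[h] * 4.0 * (hom_r + 1) * (hom_c + 1) / ((h + 2) * (h + 1))
        h += 2
    p = np.array([probs[int(x)] for x in hs])
    p /= p.sum()
    return hs, p


#: Relative tolerance for "no more probable than observed" in the two-sided
#: sum; guards against the float representation of exactly-tied masses.
_TIE_RTOL = 1e-9


def hwe_exact_test(
    n_hom_ref: int, n_het: int, n_hom_alt: int, midp: bool = False
) -> float:
    """Two-sided Hardy-Weinberg exact test P value from genotype counts.

    Sums the conditional probabilities of all heterozygote counts whose
    probability does not exceed the observed count's. Returns P in (0, 1].
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    for c in counts:
        if int(c) != c or c < 0:
            raise ValidationError(f"genotype counts must be non-negative ints: {counts}")
    n = int(n_hom_ref + n_het + n_hom_alt)
    if n < 1:
        raise ValidationError("total genotype count must be >= 1")
    n_alt = 2 * n_hom_alt + n_het
    n_rare = min(n_alt, 2 * n - n_alt)
    hs, probs = _hwe_het_distribution(n, n_rare)
    p_obs = probs[hs == n_het][0]
    mask = probs <= p_obs * (1.0 + _TIE_RTOL)
    p = float(probs[mask].sum())
    if midp:
        p -= 0.5 * float(p_obs)
    return min(max(p, np.nextafter(0, 1)), 1.0)


def apply_variant_qc(
    matrix: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    assume_genotyped: bool = True,
    hard_call_tolerance: float = 0.1,
    hwe_midp: bool = False,
    hwe_samples: list[str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter a genotype matrix and account for every variant in a report.

    A variant's verdict is the first failing rule in the fixed order
    R2 -> call rate -> MAF -> HWE. A missing imputation R2 passes the R2
    rule when ``assume_genotyped`` is on (the variant is then treated as
    directly genotyped). ``hwe_samples`` optionally restricts the HWE test
    to a sample subset; call rate and MAF always use all samples.
    """
    if matrix.n_variants == 0:
        raise ValidationError("apply_variant_qc: empty matrix")
    if hwe_samples is not None:
        idx = [matrix.samples.index(s) for s in hwe_samples]
        hwe_dos = matrix.dosages[idx, :]
    else:
        hwe_dos = matrix.dosages

    rows = []
    keep: list[int] = []
    for j, meta in enumerate(matrix.variants):
        col = matrix.dosages[:, j]
        n_missing = int(np.isnan(col).sum())
        call_rate = 1.0 - n_missing / matrix.n_samples
        maf = compute_maf(col) if n_missing < matrix.n_samples else np.nan
        gt_counts = hard_calls_from_dosage(hwe_dos[:, j], hard_call_tolerance)
        hwe_p = (
            hwe_exact_test(*gt_counts, midp=hwe_midp)
            if sum(gt_counts) >= 1
            else np.nan
        )
        r2 = meta.imputation_r2
        verdict = "pass"
        if not np.isnan(r2):
            if r2 < thresholds.r2_min:
                verdict = "fail_r2"
        elif not assume_genotyped:
            verdict = "fail_r2"
        if verdict == "pass" and call_rate < 1.0 - thresholds.missing_max:
            verdict = "fail_callrate"
        if verdict == "pass" and (np.isnan(maf) or maf < thresholds.maf_min):
            verdict = "fail_maf"
        if verdict == "pass" and (np.isnan(hwe_p) or hwe_p < thresholds.hwe_p_min):
            verdict = "fail_hwe"
        rows.append(
            {
                "variant_id": meta.variant_id,
                "maf": maf,
                "call_rate": call_rate,
                "hwe_p": hwe_p,
                "imputation_r2": r2,
                "verdict": verdict,
            }
        )
        if verdict == "pass":
            keep.append(j)
    report = QCReport(table=pd.DataFrame(rows))
    return matrix.subset_variants(keep), report
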