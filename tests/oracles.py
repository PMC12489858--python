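"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: the HWE oracle
enumerates the conditional distribution through log-factorials instead of
the production ratio recurrence, and the OLS oracle solves the normal
equations by explicit matrix inversion.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def hwe_enumeration_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided HWE exact P by full enumeration of admissible
    heterozygote counts, probabilities from the closed-form conditional
    distribution P(h | n, nA) = n! 2^h nA! nB! / (nAA! h! nBB! (2n)!)."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_alt + n_het
    n_rare = min(n_a, 2 * n - n_a)
    hs = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    n_rr = (n_rare - hs) // 2
    n_cc = n - hs - n_rr
    logp = (
        gammaln(n + 1)
        - gammaln(n_rr + 1)
        - gammaln(hs + 1)
        - gammaln(n_cc + 1)
        + hs * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hs == n_het][0]
    return float(min(probs[probs <= p_obs * (1.0 + 1e-9)].sum(), 1.0))


def hwe_het_probabilities(n: int, n_rare: int) -> np.ndarray:
    """Full conditional het-count distribution (for self-check sums)."""
    hs = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    n_rr = (n_rare - hs) // 2
    n_cc = n - hs - n_rr
    logp = (
        gammaln(n + 1)
        - gammaln(n_rr + 1)
        - gammaln(hs + 1)
        - gammaln(n_cc + 1)
        + hs * np.log(2.0)
    )
    probs = np.exp(logp - logp.max())
    return probs / probs.sum()


def ols_normal_equations(y: np.ndarray, X: np.ndarray):
    """OLS through explicit (X'X)^-1: returns (beta, se, df)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    return beta, se, n - p
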