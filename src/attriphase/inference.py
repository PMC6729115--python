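"""Shared inference machinery for adjacent-question comparisons.

Both model-based detectors reduce to the same pipeline: a vector of K
per-question coefficients with a covariance matrix, successive-difference
contrasts (question q+1 minus question q), two-sided Wald tests, and
Benjamini–Hochberg adjustment of the K-1 raw p-values evaluated at the 5%
level.  Comparisons whose variance is zero or undefined (e.g. a question at
which no one, or everyone, dropped out) are flagged non-estimable, treated
as not significant, and excluded from the BH family size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "successive_difference_contrasts",
    "wald_pvalues",
    "bh_adjust",
    "contrast_results",
]


def successive_difference_contrasts(K: int) -> np.ndarray:
    """(K-1) x K matrix whose row j encodes coefficient j+2 minus j+1."""
    if K < 2:
        raise ValueError("need at least 2 coefficients for adjacent contrasts")
    C = np.zeros((K - 1, K))
    idx = np.arange(K - 1)
    C[idx, idx] = -1.0
    C[idx, idx + 1] = 1.0
    return C


def wald_pvalues(
    coefficients: np.ndarray,
    covariance: np.ndarray,
    contrasts: np.ndarray,
    estimable: np.ndarray | None = None,
):
    """Two-sided z tests of each contrast row.

    Returns ``(estimate, se, z, p, estimable)`` arrays; entries touching a
    non-estimable coefficient or with zero/non-finite contrast variance are
    NaN with ``estimable=False``.
    """
    beta = np.asarray(coefficients, dtype=float)
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    C = np.asarray(contrasts, dtype=float)
    if C.shape[1] != beta.shape[0] or cov.shape != (beta.shape[0],) * 2:
        raise ValueError("contrasts, coefficients and covariance are not conformable")
    # NaN coefficients / covariance rows mark non-estimable positions;
    # zero-fill so they do not leak into contrasts that never touch them
    # (0 * NaN = NaN otherwise), and exclude any contrast that does touch one
    est = C @ np.nan_to_num(beta)
    var = np.einsum("ij,jk,ik->i", C, np.nan_to_num(cov), C)
    touches_nan = (C != 0) @ (np.isnan(beta) | np.isnan(np.diag(cov)))
    ok = np.isfinite(est) & (var > 0) & ~touches_nan
    if estimable is not None:
        ok &= (C != 0) @ ~np.asarray(estimable, dtype=bool) == 0
    se = np.where(ok, np.sqrt(np.where(var > 0, var, np.nan)), np.nan)
    z = est / se
    p = 2 * stats.norm.sf(np.abs(z))
    est = np.where(ok, est, np.nan)
    z = np.where(ok, z, np.nan)
    p = np.where(ok, p, np.nan)
    return est, se, z, p, ok


def bh_adjust(raw_p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    NaN entries (non-estimable comparisons) are passed through as NaN and do
    not count toward the family size m.
    """
    p = np.asarray(raw_p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def contrast_results(
    coefficients: np.ndarray,
    covariance: np.ndarray,
    alpha: float = 0.05,
    estimable: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full adjacent-comparison table for K per-question coefficients.

    Columns: ``q_lo, q_hi, estimate, se, z, p_raw, p_adj, significant,
    estimable`` — one row per adjacent pair (q, q+1).
    """
    K = len(coefficients)
    C = successive_difference_contrasts(K)
    est, se, z, p, ok = wald_pvalues(coefficients, covariance, C, estimable)
    p_adj = bh_adjust(p)
    sig = ok & (p_adj < alpha)
    return pd.DataFrame(
        {
            "q_lo": np.arange(1, K),
            "q_hi": np.arange(2, K + 1),
            "estimate": est,
            "se": se,
            "z": z,
            "p_raw": p,
            "p_adj": p_adj,
            "significant": sig,
            "estimable": ok,
        }
    )
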