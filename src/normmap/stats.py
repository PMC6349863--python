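"""Vectorized pooled two-sample t — the work-horse of every mass-univariate map.

Kept in one place because the lesion-frequency comparison, the W-score
contrasts and the permutation engine all need the identical statistic.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def pooled_two_sample_t(
    A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled-variance two-sample t per column; positive t means A > B.

    Returns (t, two-sided p, df) with df = n_A + n_B - 2. Columns with zero
    pooled variance give t = 0 (p = 1) when the means are equal and signed
    infinity (p = 0) otherwise.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    df = na + nb - 2
    diff = A.mean(axis=0) - B.mean(axis=0)
    ssa = ((A - A.mean(axis=0)) ** 2).sum(axis=0)
    ssb = ((B - B.mean(axis=0)) ** 2).sum(axis=0)
    pooled_var = (ssa + ssb) / df
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero = se == 0
    t[zero & (diff == 0)] = 0.0
    t[zero & (diff > 0)] = np.inf
    t[zero & (diff < 0)] = -np.inf
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p[np.isinf(t)] = 0.0
    return t, p, df


def t_from_sums(
    s_a: np.ndarray,
    ss_a: np.ndarray,
    na: int,
    s_tot: np.ndarray,
    ss_tot: np.ndarray,
    n_tot: int,
) -> np.ndarray:
    """Pooled t per column from group-A sums and whole-sample sums.

    Lets the permutation engine evaluate thousands of relabellings with one
    matrix product: s_a/ss_a are (n_perm, L) sums of values/squares over the
    permuted A labels.
    """
    nb = n_tot - na
    s_b = s_tot - s_a
    ss_b = ss_tot - ss_a
    mean_a = s_a / na
    mean_b = s_b / nb
    ssa = ss_a - na * mean_a**2
    ssb = ss_b - nb * mean_b**2
    df = n_tot - 2
    pooled_var = (ssa + ssb) / df
    # numerical floor: tiny negative SS from cancellation clipped to 0
    pooled_var = np.clip(pooled_var, 0.0, None)
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t[(se == 0) & (diff == 0)] = 0.0
    t[(se == 0) & (diff > 0)] = np.inf
    t[(se == 0) & (diff < 0)] = -np.inf
    return t
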