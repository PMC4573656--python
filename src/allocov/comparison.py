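"""Statistical comparison of covariance matrices and residual variances.

Box's M test checks equality of k covariance matrices estimated from
samples of known sizes, via the likelihood-ratio statistic

    M = (sum over i of (n_i - 1)) ln|S_pooled| - sum (n_i - 1) ln|S_i|

with the pooled matrix the (n_i - 1)-weighted average.  The chi-square
approximation applies the standard Box (1949) small-sample correction
factor; the reference distribution has p(p+1)(k-1)/2 degrees of freedom.
An F-ratio test compares two residual variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import InputError

__all__ = ["MTestResult", "box_m_test", "f_ratio_test", "cov_to_corr"]


@dataclass(frozen=True)
class MTestResult:
    M: float
    chi2: float
    df: int
    p_value: float


def box_m_test(matrices: Sequence[np.ndarray],
               group_sizes: Sequence[int]) -> MTestResult:
    """Box's M test of equality of k covariance matrices.

    Parameters
    ----------
    matrices : k covariance matrices, all p x p, positive definite.
    group_sizes : sample sizes n_i the matrices were estimated from
        (each must exceed p).
    """
    mats = [np.asarray(m, dtype=float) for m in matrices]
    k = len(mats)
    if k < 2:
        raise InputError("need at least 2 matrices to compare")
    p = mats[0].shape[0]
    if any(m.shape != (p, p) for m in mats):
        raise InputError("all matrices must have the same square shape")
    ns = [int(n) for n in group_sizes]
    if len(ns) != k:
        raise InputError("one group size per matrix required")
    if any(n <= p for n in ns):
        raise InputError(f"every group size must exceed p={p}")

    dof = [n - 1 for n in ns]
    total = sum(dof)
    pooled = sum(d * m for d, m in zip(dof, mats)) / total
    logdets = []
    for m in mats + [pooled]:
        sign, logdet = np.linalg.slogdet(m)
        if sign <= 0:
            raise InputError("matrix with non-positive determinant; M undefined")
        logdets.append(logdet)
    M = total * logdets[-1] - sum(d * ld for d, ld in zip(dof, logdets[:-1]))
    # Box's small-sample scaling of the chi-square approximation
    c = (sum(1.0 / d for d in dof) - 1.0 / total) \
        * (2 * p**2 + 3 * p - 1) / (6.0 * (p + 1) * (k - 1))
    chi2 = M * (1.0 - c)
    df = p * (p + 1) * (k - 1) // 2
    p_value = float(stats.chi2.sf(chi2, df))
    return MTestResult(M=float(M), chi2=float(chi2), df=df, p_value=p_value)


def f_ratio_test(var1: float, df1: int, var2: float, df2: int) -> float:
    """Two-sided p-value for equality of two variances under the F distribution."""
    if not (var1 > 0 and var2 > 0):
        raise InputError("variances must be positive")
    if df1 < 1 or df2 < 1:
        raise InputError("degrees of freedom must be >= 1")
    ratio = var1 / var2
    p = 2.0 * min(stats.f.sf(ratio, df1, df2), stats.f.cdf(ratio, df1, df2))
    return float(min(p, 1.0))


def cov_to_corr(matrix: np.ndarray) -> np.ndarray:
    """Correlation matrix of a covariance matrix; diagonal exactly one."""
    m = np.asarray(matrix, dtype=float)
    d = np.diag(m)
    if np.any(d <= 0):
        raise InputError("covariance matrix must have a positive diagonal")
    s = np.sqrt(d)
    corr = m / np.outer(s, s)
    np.fill_diagonal(corr, 1.0)
    return corr
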