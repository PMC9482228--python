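"""Goodness-of-normalization measures and paired comparison.

RMSE measures how well *absolute* volumes are recovered; rRMSE is
scale-free and measures how well *relative* volume changes are
recovered, which also makes it applicable to PQN quotients (no absolute
volume exists for PQN, so no RMSE is defined for it).  Population
(n-denominator) standard deviations are used throughout.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

from .pqn import QuotientVector

__all__ = ["rmse", "rrmse", "scaled_errors", "paired_compare", "CompareResult"]

_LOG_EPS = 1e-8


def _pair(a, b):
    a = np.asarray(a, float)
    b = b.q if isinstance(b, QuotientVector) else np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("inputs must be equal-length 1-D vectors, length >= 2")
    return a, b


def rmse(V_true, V_fit) -> float:
    """Population standard deviation of the residuals V_true - V_fit."""
    a, b = _pair(V_true, V_fit)
    return float(np.std(a - b))


def rrmse(V_true, V_fit) -> float:
    """std/mean of the ratio V_true / V_fit (population std).

    Scale-free: any positive rescaling of ``V_fit`` leaves it unchanged,
    so PQN quotients can be evaluated without absolute volumes.
    """
    a, b = _pair(V_true, V_fit)
    if np.any(b <= 0):
        raise ValueError("fitted values must be strictly positive")
    r = a / b
    return float(np.std(r) / np.mean(r))


def scaled_errors(q, V_true, *, absolute: bool = True):
    """Mean- and standard-scaled error of quotients against true volumes.

    Both are computed in log space (``T = log10(x + 1e-8)``).  The
    per-time-point residual is ``ZT(q)_i - ZT(V)_i`` with mean scaling
    (centering) or standard scaling; the standard-scaled residual is
    multiplied by ``Std(T(V))`` so the two error sizes are comparable
    (otherwise the scaling with the smaller spread would win trivially).

    With ``absolute=True`` (default) the summed absolute residuals are
    returned -- centering makes the signed sums vanish identically, so
    the error *size* is the meaningful quantity; ``absolute=False``
    returns the signed sums (both exactly 0, kept for completeness).
    Returns ``(mean_scaled, standard_scaled)``.
    """
    qv, V = _pair(q if not isinstance(q, QuotientVector) else q.q, V_true)
    tq = np.log10(qv + _LOG_EPS)
    tV = np.log10(V + _LOG_EPS)
    mean_resid = (tq - tq.mean()) - (tV - tV.mean())
    sq, sV = tq.std(), tV.std()
    if sq == 0 or sV == 0:
        raise ValueError("standard scaling undefined for constant series")
    std_resid = ((tq - tq.mean()) / sq - (tV - tV.mean()) / sV) * sV
    if absolute:
        return float(np.abs(mean_resid).sum()), float(np.abs(std_resid).sum())
    return float(mean_resid.sum()), float(std_resid.sum())


class CompareResult(NamedTuple):
    statistic: float
    pvalue: float
    stars: str
    degenerate: bool = False


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def paired_compare(a, b, alternative: str = "two-sided") -> CompareResult:
    """Wilcoxon signed-rank comparison of paired per-replicate metrics.

    Zero differences are discarded (classical Wilcoxon); the exact null
    distribution is used for n <= 25 pairs, the normal approximation
    otherwise.  ``alternative='one-sided'`` (alias ``'less'``) tests
    whether ``a`` is stochastically smaller than ``b``.  Stars mark
    p <= 0.05 / 0.01 / 0.001.  If every pair is tied the test is
    degenerate and NaN is returned with the ``degenerate`` flag set.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be paired equal-length vectors")
    if alternative == "one-sided":
        alternative = "less"
    d = a - b
    nz = np.count_nonzero(d)
    if nz == 0:
        return CompareResult(np.nan, np.nan, "", degenerate=True)
    method = "exact" if nz <= 25 else "approx"
    res = stats.wilcoxon(a, b, alternative=alternative,
                         zero_method="wilcox", method=method)
    return CompareResult(float(res.statistic), float(res.pvalue),
                         _stars(float(res.pvalue)))
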