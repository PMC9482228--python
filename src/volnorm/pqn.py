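"""Probabilistic quotient normalization (PQN).

PQN estimates a per-sample dilution factor as the median of abundance
ratios to a reference profile.  For a time series with roughly constant
median metabolite concentration, the quotient ``Q(t)`` is proportional to
the (unknown) sample volume ``V(t)`` relative to a reference volume:
``Q(t) = V(t) / V_ref``.  PQN is scale-free: it recovers relative volume
changes but not absolute volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["QuotientVector", "reference_profile", "pqn_quotients", "PQNNormalizer"]


@dataclass
class QuotientVector:
    """PQN quotients for one time series.

    Attributes
    ----------
    q : ndarray, shape (n_time_points,)
        Dilution quotient per time point; distributes around 1.
    reference : ndarray, shape (n_metabolites,)
        Metabolite-wise reference profile (medians over time).
    """

    q: np.ndarray
    reference: np.ndarray

    def __len__(self):
        return len(self.q)


def _validate_masses(M) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[None, :]
    if M.ndim != 2 or M.size == 0:
        raise ValueError("mass matrix must be a non-empty 2-D array")
    if np.any(~np.isfinite(M)):
        raise ValueError("mass matrix contains missing or non-finite values; "
                         "PQN requires complete data")
    if np.any(M <= 0):
        raise ValueError("mass matrix must be strictly positive "
                         "(quotients are undefined otherwise)")
    return M


def reference_profile(M, kind: str = "median") -> np.ndarray:
    """Per-metabolite reference masses.

    The default (and the choice used throughout this package) is the
    metabolite-wise median over all time points, which minimizes the
    influence of experimental errors.  ``kind='first'`` uses the first
    sample instead, ``kind='mean'`` the metabolite-wise mean.
    """
    M = _validate_masses(M)
    if kind == "median":
        return np.median(M, axis=0)
    if kind == "mean":
        return M.mean(axis=0)
    if kind == "first":
        return M[0].copy()
    raise ValueError(f"unknown reference kind {kind!r}")


def pqn_quotients(M, reference: str | np.ndarray = "median") -> QuotientVector:
    """Compute Q(t) = median_j { M_j(t) / M_ref_j } for each time point."""
    M = _validate_masses(M)
    if isinstance(reference, str):
        ref = reference_profile(M, reference)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (M.shape[1],) or np.any(ref <= 0):
            raise ValueError("reference must be strictly positive, one entry "
                             "per metabolite")
    q = np.median(M / ref[None, :], axis=1)
    return QuotientVector(q=q, reference=ref)


class PQNNormalizer(BaseEstimator, TransformerMixin):
    """Probabilistic quotient normalization as a transformer.

    ``fit`` learns the reference profile and the quotient per sample of
    the fitted matrix; ``transform`` divides each row by its quotient
    relative to the learned reference, removing the (relative) size
    effect.

    Parameters
    ----------
    reference : {'median', 'mean', 'first'}, default='median'
        Reference-profile choice; the metabolite-wise median is the
        conventional, robust default.

    Attributes
    ----------
    reference_ : ndarray, shape (n_features,)
        Learned reference profile.
    quotients_ : ndarray, shape (n_samples,)
        Dilution quotient of each fitted sample (proportional to the
        relative sample volume).
    """

    def __init__(self, reference: str = "median"):
        self.reference = reference

    def fit(self, X, y=None):
        qv = pqn_quotients(X, self.reference)
        self.reference_ = qv.reference
        self.quotients_ = qv.q
        self.n_features_in_ = len(qv.reference)
        return self

    def transform(self, X):
        if not hasattr(self, "reference_"):
            raise AttributeError("PQNNormalizer is not fitted yet")
        X = _validate_masses(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        q = np.median(X / self.reference_[None, :], axis=1)
        return X / q[:, None]
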