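"""Pharmacokinetic (PKM) and combined (MIX) normalization models.

Both models jointly fit per-time-point sample volumes ``V(t)`` and the
kinetic parameters of the modelled metabolites so that modelled
concentration x volume matches the measured abundances.  The MIX model
adds a second objective term that biases the fitted volumes toward the
(scale-free) PQN quotient vector, weighted by ``lambda = 1/(ell + 1)``
where ``ell`` is the number of kinetically modelled metabolites.

The objective is

    L_PKM = sum_ij L[ lambda (T(M_ij) - T(C_ij V_i))^2 ]
    L_PQN = sum_i  L[ (1-lambda) (ZT(V)_i - ZT(Q)_i)^2 Var(T(V)) ]

with transform ``T`` (identity or log10), scaling ``Z`` (standard or
mean) and robust loss ``L`` (Cauchy or linear, optionally on the maximum
of absolute and relative residuals).  Optimization is bounded
trust-region nonlinear least squares restarted from ``n_starts`` random
initial points drawn uniformly within the bounds (Monte-Carlo
multistart); the best start by final loss wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .kinetics import (
    DEFAULT_LOWER,
    DEFAULT_UPPER,
    PARAM_NAMES,
    KineticParams,
    SubnetworkParams,
    bateman_array,
    subnetwork_concentrations,
)
from .pqn import QuotientVector, pqn_quotients

__all__ = [
    "transform",
    "scale",
    "lambda_weight",
    "loss_pkm",
    "loss_pqn",
    "FitResult",
    "PKMNormalizer",
    "MIXNormalizer",
    "fit",
]

#: additive guard inside log10 (the size of optimizer precision)
_LOG_EPS = 1e-8
#: guard for the denominator of the relative residual in max_* losses
_REL_GUARD = 1e-12

SUBNET_PARAM_NAMES = ("k1p", "k2p", "k3p", "k4p", "c0")


# ---------------------------------------------------------------------------
# building blocks


def transform(x, kind: str = "none") -> np.ndarray:
    """Transform measured data before loss calculation.

    ``'none'`` is the identity; ``'log10'`` is ``log10(x + 1e-8)`` --
    appropriate when the measurement error is multiplicative.  Negative
    input under log10 is rejected.
    """
    x = np.asarray(x, dtype=float)
    if kind == "none":
        return x
    if kind == "log10":
        if np.any(x < 0):
            raise ValueError("log10 transform requires non-negative input")
        return np.log10(x + _LOG_EPS)
    raise ValueError(f"unknown transform {kind!r}")


def scale(x, kind: str = "standard", transform_kind: str = "log10") -> np.ndarray:
    """Scale a (transformed) series.

    ``'standard'``: ``(x - mean) / std`` with the population std.
    ``'mean'``: ``x - mean`` if the data were log-transformed else
    ``x / mean`` (centering is the log-space analogue of dividing).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("scaling requires at least 2 values")
    if kind == "standard":
        s = x.std()
        if s == 0:
            raise ValueError("cannot standard-scale a constant series")
        return (x - x.mean()) / s
    if kind == "mean":
        if transform_kind == "log10":
            return x - x.mean()
        return x / x.mean()
    raise ValueError(f"unknown scaling {kind!r}")


def lambda_weight(ell: int) -> float:
    """Weight of the PKM term: lambda = 1 / (ell + 1).

    Balances the two loss terms by the number of fitted data points per
    term rather than by the number of metabolites.
    """
    if ell < 1:
        raise ValueError("ell must be >= 1")
    return 1.0 / (ell + 1)


def _rho(z, loss: str):
    if loss in ("cauchy", "max_cauchy"):
        return np.log1p(z)
    if loss in ("linear", "max_linear"):
        return z
    raise ValueError(f"unknown loss {loss!r}")


def _weighted_residuals(M, CV, lam, transform_kind, loss):
    """sqrt(lambda) * r with r per the loss's residual definition."""
    tM = transform(M, transform_kind)
    tCV = transform(CV, transform_kind)
    r = tM - tCV
    if loss.startswith("max_"):
        denom = np.where(np.abs(tM) < _REL_GUARD, 1.0, tM)
        r = np.maximum(np.abs(r), np.abs(r / denom))
    return np.sqrt(lam) * r


def loss_pkm(M, C, V, *, lam: float = 1.0, transform_kind: str = "none",
             loss: str = "max_cauchy") -> float:
    """Pharmacokinetic loss term over all modelled entries."""
    M = np.asarray(M, dtype=float)
    C = np.asarray(C, dtype=float)
    V = np.asarray(V, dtype=float)
    if M.shape != C.shape or V.shape != (M.shape[0],):
        raise ValueError("shape mismatch between M, C and V")
    f = _weighted_residuals(M, C * V[:, None], lam, transform_kind, loss)
    return float(np.sum(_rho(f**2, loss)))


def _pqn_residuals(V, q, lam, transform_kind, scaling):
    """sqrt(1-lambda) * (ZT(V) - ZT(q)) * Std(T(V)), stabilized.

    ``Var(T(V))`` is recomputed from the current V iterate; multiplying
    the standard-scaled difference by ``Std(T(V))`` keeps the term
    informative (otherwise a shrunken V trivially wins) and makes the
    degenerate constant-V case vanish smoothly instead of dividing by
    zero.
    """
    tV = transform(V, transform_kind)
    tq = transform(q, transform_kind)
    sV = tV.std()
    if scaling == "standard":
        sq = tq.std()
        if sq == 0:
            raise ValueError("PQN quotient vector is constant")
        zq = (tq - tq.mean()) / sq
        # (zV - zq) * sV  with zV*sV expanded to avoid 0/0 at constant V
        diff = (tV - tV.mean()) - zq * sV
    elif scaling == "mean":
        zV = scale(tV, "mean", transform_kind)
        zq = scale(tq, "mean", transform_kind)
        diff = (zV - zq) * sV
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return np.sqrt(1.0 - lam) * diff


def loss_pqn(V, q, *, lam: float, transform_kind: str = "log10",
             scaling: str = "standard", loss: str = "cauchy") -> float:
    """Quotient-matching loss term of the MIX model."""
    V = np.asarray(V, dtype=float)
    q = q.q if isinstance(q, QuotientVector) else np.asarray(q, dtype=float)
    if V.shape != q.shape or V.size < 2:
        raise ValueError("V and q must have equal length >= 2")
    if lam >= 1.0:
        return 0.0
    f = _pqn_residuals(V, q, lam, transform_kind, scaling)
    return float(np.sum(_rho(f**2, loss)))


# ---------------------------------------------------------------------------
# fit result


@dataclass
class FitResult:
    """Outcome of a Monte-Carlo multistart fit."""

    V: np.ndarray
    kinetic_params: list
    loss: float
    start_losses: np.ndarray
    best_start: int
    seed: object = None
    size_effect_detected: bool = True
    n_starts_failed: int = 0


# ---------------------------------------------------------------------------
# estimators


class _PharmacokineticFitter(BaseEstimator):
    """Shared machinery of PKM and MIX normalization estimators."""

    # subclasses override
    _is_mix = False

    def __init__(self, ell=4, kinetic_model="bateman", loss="max_cauchy",
                 transform="none", scaling="standard", lam=None,
                 v_bounds=(0.05, 4.0), kinetic_bounds=None, known_params=None,
                 n_starts=100, random_state=None, prescale=False,
                 tol=1e-8, max_nfev=None):
        self.ell = ell
        self.kinetic_model = kinetic_model
        self.loss = loss
        self.transform = transform
        self.scaling = scaling
        self.lam = lam
        self.v_bounds = v_bounds
        self.kinetic_bounds = kinetic_bounds
        self.known_params = known_params
        self.n_starts = n_starts
        self.random_state = random_state
        self.prescale = prescale
        self.tol = tol
        self.max_nfev = max_nfev

    # -- parameter bookkeeping ------------------------------------------------

    def _kinetic_layout(self):
        """Free/fixed layout of the kinetic part of the parameter vector.

        Returns (names, lower, upper, fixed_values, free_mask) where the
        arrays are flat over all kinetic parameters of the model.
        """
        known = self.known_params or {}
        if self.kinetic_model == "bateman":
            lo, hi = self.kinetic_bounds or (DEFAULT_LOWER, DEFAULT_UPPER)
            lo = np.tile(np.asarray(lo, float), self.ell)
            hi = np.tile(np.asarray(hi, float), self.ell)
            n = 5 * self.ell
            values = np.full(n, np.nan)
            free = np.ones(n, bool)
            for j, fixes in known.items():
                if not (0 <= int(j) < self.ell):
                    raise ValueError(f"known_params key {j} outside modelled "
                                     f"metabolites 0..{self.ell - 1}")
                for name, val in fixes.items():
                    k = 5 * int(j) + PARAM_NAMES.index(name)
                    values[k] = float(val)
                    free[k] = False
            return lo, hi, values, free
        if self.kinetic_model == "subnetwork":
            if self.ell != 2:
                raise ValueError("subnetwork kinetics model exactly 2 "
                                 "metabolites (ell=2)")
            lo, hi = self.kinetic_bounds or ((0, 0, 0, 0, 0), (3, 3, 3, 3, 5))
            lo = np.asarray(lo, float)
            hi = np.asarray(hi, float)
            values = np.full(5, np.nan)
            free = np.ones(5, bool)
            for name, val in known.items():
                k = SUBNET_PARAM_NAMES.index(name)
                values[k] = float(val)
                free[k] = False
            return lo, hi, values, free
        raise ValueError(f"unknown kinetic model {self.kinetic_model!r}")

    def _concentrations(self, t, kin_flat):
        if self.kinetic_model == "bateman":
            return bateman_array(t, kin_flat.reshape(self.ell, 5))
        p = SubnetworkParams(*kin_flat)
        caf, met = subnetwork_concentrations(t, p)
        return np.column_stack([caf, met])

    # -- fitting --------------------------------------------------------------

    def fit(self, X, y=None, *, t=None, q=None):
        """Fit volumes and kinetic parameters to a mass matrix.

        Parameters
        ----------
        X : array-like, shape (n_time_points, n_metabolites)
            Measured abundances; the first ``ell`` columns are the
            kinetically modelled metabolites.
        t : array-like, optional
            Sampling times in hours.  Defaults to ``n_time_points``
            equidistant points on [0, 15].
        q : QuotientVector or array, optional (MIX only)
            PQN quotients; computed from all columns of ``X`` if absent.
        """
        M = np.asarray(X, dtype=float)
        if M.ndim != 2:
            raise ValueError("X must be 2-D (time x metabolites)")
        n_t, n_m = M.shape
        min_ell = 1 if self._is_mix else 2
        if not (min_ell <= self.ell <= n_m):
            raise ValueError(
                f"need {min_ell} <= ell <= n_metabolites, got ell={self.ell} "
                f"with {n_m} metabolites")
        if t is None:
            t = np.linspace(0.0, 15.0, n_t)
        t = np.asarray(t, dtype=float)
        if t.shape != (n_t,):
            raise ValueError("t must match the number of rows of X")
        v_lo, v_hi = self.v_bounds
        if not v_lo < v_hi:
            raise ValueError("V_lower must be < V_upper")

        if self._is_mix:
            lam = lambda_weight(self.ell) if self.lam is None else float(self.lam)
            if not 0.0 <= lam <= 1.0:
                raise ValueError("lambda must be in [0, 1]")
            if q is None:
                q = pqn_quotients(M)
            q_arr = q.q if isinstance(q, QuotientVector) else np.asarray(q, float)
            if q_arr.shape != (n_t,):
                raise ValueError("q must have one quotient per time point")
        else:
            lam, q_arr = 1.0, None

        factors = M.max(axis=0) if self.prescale else np.ones(n_m)
        Mw = M / factors
        M_ell = Mw[:, : self.ell]

        k_lo, k_hi, k_values, k_free = self._kinetic_layout()
        bad = ~k_free & ((k_values < k_lo) | (k_values > k_hi))
        if np.any(bad):
            raise ValueError("fixed kinetic values lie outside their bounds")
        n_kin_free = int(k_free.sum())
        lower = np.concatenate([k_lo[k_free], np.full(n_t, v_lo)])
        upper = np.concatenate([k_hi[k_free], np.full(n_t, v_hi)])
        n_free = n_kin_free + n_t

        use_pqn_term = self._is_mix and lam < 1.0

        def residuals(x):
            kin = k_values.copy()
            kin[k_free] = x[:n_kin_free]
            V = x[n_kin_free:]
            C = self._concentrations(t, kin)
            f = _weighted_residuals(M_ell, C * V[:, None], lam,
                                    self.transform, self.loss).ravel()
            if use_pqn_term:
                f = np.concatenate([
                    f, _pqn_residuals(V, q_arr, lam, self.transform,
                                      self.scaling)])
            return f

        def spec_loss(x):
            kin = k_values.copy()
            kin[k_free] = x[:n_kin_free]
            V = x[n_kin_free:]
            C = self._concentrations(t, kin)
            total = loss_pkm(M_ell, C, V, lam=lam,
                             transform_kind=self.transform, loss=self.loss)
            if use_pqn_term:
                total += loss_pqn(V, q_arr, lam=lam,
                                  transform_kind=self.transform,
                                  scaling=self.scaling, loss=self.loss)
            return total

        ls_loss = "cauchy" if self.loss in ("cauchy", "max_cauchy") else "linear"
        jac_sparsity, tr_solver = self._sparsity(n_t, n_kin_free, k_free,
                                                 use_pqn_term)

        ss = np.random.SeedSequence(self.random_state)
        children = ss.spawn(self.n_starts)
        start_losses = np.full(self.n_starts, np.inf)
        best = None
        best_loss = np.inf
        n_failed = 0
        diagnostics = []
        for i, child in enumerate(children):
            rng = np.random.default_rng(child)
            x0 = rng.uniform(lower, upper)
            try:
                res = least_squares(
                    residuals, x0, bounds=(lower, upper), method="trf",
                    loss=ls_loss, xtol=self.tol, ftol=self.tol, gtol=self.tol,
                    max_nfev=self.max_nfev, jac_sparsity=jac_sparsity,
                    tr_solver=tr_solver)
            except Exception as exc:  # pragma: no cover - optimizer hiccup
                n_failed += 1
                diagnostics.append((i, repr(exc)))
                continue
            start_losses[i] = spec_loss(res.x)
            if start_losses[i] < best_loss:  # strict: ties keep lowest index
                best_loss = start_losses[i]
                best = res
        if best is None:
            raise RuntimeError(
                f"all {self.n_starts} optimization starts failed: "
                f"{diagnostics[:3]}")

        kin = k_values.copy()
        kin[k_free] = best.x[:n_kin_free]
        V = best.x[n_kin_free:]

        self.t_ = t
        self.V_ = V
        self.loss_ = best_loss
        self.start_losses_ = start_losses
        self.best_start_ = int(np.argmin(np.where(np.isfinite(start_losses),
                                                  start_losses, np.inf)))
        self.lambda_ = lam
        self.column_scale_ = factors
        self.quotients_ = q_arr
        self.n_features_in_ = n_m
        self.kinetic_params_ = self._package_params(kin, k_lo, k_hi, k_free,
                                                    factors)
        # Var(V) ~ 0 means the model saw no size effect -- a warning, not
        # an error: it tells the analyst size effects may not matter here.
        rel_spread = V.std() / max(V.mean(), 1e-300)
        self.size_effect_detected_ = bool(rel_spread > 1e-6)
        if not self.size_effect_detected_:
            warnings.warn("fitted volumes are (near-)constant: no size "
                          "effect detected", UserWarning, stacklevel=2)
        self.fit_result_ = FitResult(
            V=V, kinetic_params=self.kinetic_params_, loss=best_loss,
            start_losses=start_losses, best_start=self.best_start_,
            seed=self.random_state,
            size_effect_detected=self.size_effect_detected_,
            n_starts_failed=n_failed)
        return self

    def _sparsity(self, n_t, n_kin_free, k_free, use_pqn_term):
        """Jacobian sparsity pattern: residual (i, j) touches only
        metabolite j's free parameters and V_i; PQN rows touch all V."""
        n_free = n_kin_free + n_t
        if self.kinetic_model != "bateman" or n_free < 80:
            return None, "exact"
        rows = self.ell * n_t + (n_t if use_pqn_term else 0)
        S = sparse.lil_matrix((rows, n_free), dtype=np.uint8)
        # map each flat kinetic index to its position among free params
        free_pos = np.cumsum(k_free) - 1
        for j in range(self.ell):
            cols = [free_pos[5 * j + k] for k in range(5) if k_free[5 * j + k]]
            for i in range(n_t):
                r = i * self.ell + j
                S[r, cols] = 1
                S[r, n_kin_free + i] = 1
        if use_pqn_term:
            S[self.ell * n_t:, n_kin_free:] = 1
        return S.tocsr(), "lsmr"

    def _package_params(self, kin, k_lo, k_hi, k_free, factors):
        if self.kinetic_model == "subnetwork":
            return [SubnetworkParams(*kin)]
        out = []
        for j in range(self.ell):
            sl = slice(5 * j, 5 * j + 5)
            vals, lo, hi = kin[sl].copy(), k_lo[sl].copy(), k_hi[sl].copy()
            fac = factors[j]
            if fac != 1.0:  # fold the unit-max pre-scaling back into c0, d
                for k in (2, 4):
                    vals[k] *= fac
                    lo[k] *= fac
                    hi[k] *= fac
            out.append(KineticParams(*vals, lower=tuple(lo), upper=tuple(hi),
                                     fixed=tuple(~k_free[sl])))
        return out

    # -- post-fit accessors ---------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "V_"):
            raise AttributeError(f"{type(self).__name__} is not fitted yet")

    def predict_concentrations(self, t=None) -> np.ndarray:
        """Modelled concentration curves of the ``ell`` fitted metabolites."""
        self._check_fitted()
        t = self.t_ if t is None else np.asarray(t, float)
        if self.kinetic_model == "subnetwork":
            caf, met = subnetwork_concentrations(t, self.kinetic_params_[0])
            return np.column_stack([caf, met])
        kin = np.stack([p.values for p in self.kinetic_params_])
        return bateman_array(t, kin)

    def transform_volumes(self, X) -> np.ndarray:
        """Concentration estimates M / V for every metabolite column."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        return X / self.V_[:, None]


class PKMNormalizer(_PharmacokineticFitter):
    """Pharmacokinetic normalization (PKM).

    Fits kinetic concentration curves through the first ``ell``
    metabolite columns together with the per-time-point volumes, using
    only those columns (``lambda = 1``; no quotient term).  Requires
    ``ell >= 2`` so the system stays overdetermined.  Estimates
    *absolute* volumes within ``v_bounds``.

    Defaults follow the reference configuration: no transform and the
    ``max_cauchy`` loss (Cauchy loss on the maximum of absolute and
    relative residuals).
    """

    _is_mix = False

    def __init__(self, ell=4, kinetic_model="bateman", loss="max_cauchy",
                 transform="none", scaling="standard", lam=None,
                 v_bounds=(0.05, 4.0), kinetic_bounds=None, known_params=None,
                 n_starts=100, random_state=None, prescale=False,
                 tol=1e-8, max_nfev=None):
        super().__init__(ell=ell, kinetic_model=kinetic_model, loss=loss,
                         transform=transform, scaling=scaling, lam=lam,
                         v_bounds=v_bounds, kinetic_bounds=kinetic_bounds,
                         known_params=known_params, n_starts=n_starts,
                         random_state=random_state, prescale=prescale,
                         tol=tol, max_nfev=max_nfev)


class MIXNormalizer(_PharmacokineticFitter):
    """Combined PKM + PQN normalization (MIX).

    The PKM term fits kinetics and volumes through the first ``ell``
    columns; the PQN term pulls the fitted volume profile toward the
    quotient vector computed from *all* columns, so untargeted
    metabolites inform the fit without being modelled.  ``lam=None``
    uses ``lambda = 1/(ell+1)``; at ``lam=1`` the model reduces exactly
    to PKM.

    Defaults follow the reference configuration: log10 transform,
    Cauchy loss, standard scaling.
    """

    _is_mix = True

    def __init__(self, ell=4, kinetic_model="bateman", loss="cauchy",
                 transform="log10", scaling="standard", lam=None,
                 v_bounds=(0.05, 4.0), kinetic_bounds=None, known_params=None,
                 n_starts=100, random_state=None, prescale=False,
                 tol=1e-8, max_nfev=None):
        super().__init__(ell=ell, kinetic_model=kinetic_model, loss=loss,
                         transform=transform, scaling=scaling, lam=lam,
                         v_bounds=v_bounds, kinetic_bounds=kinetic_bounds,
                         known_params=known_params, n_starts=n_starts,
                         random_state=random_state, prescale=prescale,
                         tol=tol, max_nfev=max_nfev)


def fit(M, *, model: str = "mix", t=None, q=None, **kwargs) -> FitResult:
    """Convenience wrapper: fit a PKM or MIX model and return its result."""
    cls = {"pkm": PKMNormalizer, "mix": MIXNormalizer}[model]
    est = cls(**kwargs)
    est.fit(M, t=t, q=q)
    return est.fit_result_
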