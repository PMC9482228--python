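"""Concentration-curve models.

Two kinetic models are provided:

* the modified Bateman function -- the classical one-compartment
  absorption/elimination curve extended with a ``lag`` (absorption start
  time) and a baseline offset ``d``;
* the closed-form solution of a first-order mass-action subnetwork
  (absorption -> caffeine -> one degradation metabolite, with elimination
  from both pools), the shape used when a known two-metabolite pathway is
  modelled jointly.

Both are pure, vectorized functions over time; they are consumed by the
normalization models and by the synthetic-data generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticParams",
    "SubnetworkParams",
    "bateman_concentration",
    "subnetwork_concentrations",
]

#: below this |k_e - k_a| the analytic k_a == k_e limit of the Bateman
#: function is used (removes the pole without constraining an optimizer)
_RATE_EQ_TOL = 1e-9

# default fitting bounds: (k_a, k_e, c_0, lag, d) in (1/h, 1/h, conc, h, conc)
DEFAULT_LOWER = (0.0, 0.0, 0.0, 0.0, 0.0)
DEFAULT_UPPER = (3.0, 3.0, 5.0, 15.0, 3.0)

PARAM_NAMES = ("k_a", "k_e", "c_0", "lag", "d")


@dataclass
class KineticParams:
    """Parameters of the modified Bateman function.

    Attributes
    ----------
    k_a, k_e : float
        Absorption and elimination rate constants (1/h, >= 0).
    c_0 : float
        Amount absorbed over the volume of distribution (concentration
        units, >= 0).
    lag : float
        Absorption start time (h, >= 0): shifts the curve along t.
    d : float
        Baseline offset (concentration units, >= 0).
    lower, upper : tuple of float
        Per-parameter bounds in ``(k_a, k_e, c_0, lag, d)`` order.
    fixed : tuple of bool
        Per-parameter flags; fixed parameters are held at their value
        during fitting.
    """

    k_a: float
    k_e: float
    c_0: float
    lag: float = 0.0
    d: float = 0.0
    lower: tuple = DEFAULT_LOWER
    upper: tuple = DEFAULT_UPPER
    fixed: tuple = (False,) * 5

    def __post_init__(self):
        vals = self.values
        if not np.all(np.isfinite(vals)):
            raise ValueError("kinetic parameters must be finite")
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != (5,) or hi.shape != (5,):
            raise ValueError("bounds must have 5 elements")
        if np.any(lo > hi):
            raise ValueError("lower bounds must not exceed upper bounds")
        if np.any(vals < lo - 1e-12) or np.any(vals > hi + 1e-12):
            raise ValueError(
                f"parameters {vals} outside declared bounds [{lo}, {hi}]"
            )

    @property
    def values(self) -> np.ndarray:
        return np.array([self.k_a, self.k_e, self.c_0, self.lag, self.d])

    def replace(self, **kwargs) -> "KineticParams":
        d = {n: getattr(self, n) for n in PARAM_NAMES}
        d.update(lower=self.lower, upper=self.upper, fixed=self.fixed)
        d.update(kwargs)
        return KineticParams(**d)


@dataclass
class SubnetworkParams:
    """First-order rate constants of the two-metabolite cascade.

    The cascade is ``A --k1'--> Caf --k2'--> M`` with additional
    elimination ``Caf --k3'-->`` and ``M --k4'-->`` and ``A(0) = c0``.
    The derived identities ``k_a^caf = k1'`` and ``k_e^caf = k2' + k3'``
    hold exactly.
    """

    k1p: float
    k2p: float
    k3p: float
    k4p: float
    c0: float = 1.0

    def __post_init__(self):
        vals = [self.k1p, self.k2p, self.k3p, self.k4p, self.c0]
        if not np.all(np.isfinite(vals)):
            raise ValueError("subnetwork parameters must be finite")
        if min(vals) < 0:
            raise ValueError("subnetwork rates and c0 must be non-negative")

    @property
    def k_a_caf(self) -> float:
        return self.k1p

    @property
    def k_e_caf(self) -> float:
        return self.k2p + self.k3p


def _bateman_core(t, k_a, k_e, c_0, lag):
    """Two-exponential core b(t); analytic limit near k_a == k_e."""
    tau = t - lag
    if abs(k_e - k_a) < _RATE_EQ_TOL:
        return c_0 * k_a * tau * np.exp(-k_a * tau)
    return (
        c_0
        * k_a
        / (k_e - k_a)
        * (np.exp(-k_a * tau) - np.exp(-k_e * tau))
    )


def bateman_concentration(t, p: KineticParams) -> np.ndarray:
    """Evaluate the modified Bateman function F(t).

    ``F(t) = b(t) + d`` where the core ``b(t)`` is clamped to zero from
    below, so ``F(t) = d`` wherever ``b(t) < 0`` (in particular for all
    ``t < lag``).  Defined for all real ``t``; vectorized over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    b = _bateman_core(t, p.k_a, p.k_e, p.c_0, p.lag)
    return np.where(b >= 0.0, b + p.d, p.d)


def bateman_array(t, params: np.ndarray) -> np.ndarray:
    """Vectorized Bateman evaluation for many metabolites at once.

    ``params`` has shape (n_metabolites, 5) with columns
    ``(k_a, k_e, c_0, lag, d)``; returns shape (len(t), n_metabolites).
    Used in the optimizer's inner loop, hence no per-call validation.
    """
    t = np.asarray(t, dtype=float)[:, None]
    k_a, k_e, c_0, lag, d = (params[:, i][None, :] for i in range(5))
    tau = t - lag
    dk = k_e - k_a
    near = np.abs(dk) < _RATE_EQ_TOL
    # guard the pole, then overwrite the near-equal columns with the limit
    dk_safe = np.where(near, 1.0, dk)
    b = c_0 * k_a / dk_safe * (np.exp(-k_a * tau) - np.exp(-k_e * tau))
    b_lim = c_0 * k_a * tau * np.exp(-k_a * tau)
    b = np.where(near, b_lim, b)
    return np.where(b >= 0.0, b + d, d)


def _expdiff(t, ka, kb):
    """(e^{-ka t} - e^{-kb t})/(kb - ka) with the kb -> ka limit."""
    if abs(kb - ka) < _RATE_EQ_TOL:
        kb = ka + _RATE_EQ_TOL  # measure-zero coincidence: tiny perturbation
    return (np.exp(-ka * t) - np.exp(-kb * t)) / (kb - ka)


def subnetwork_concentrations(t, p: SubnetworkParams):
    """Closed-form concentrations of the first-order cascade.

    Solves ``dA/dt = -k1' A``, ``dCaf/dt = k1' A - (k2'+k3') Caf``,
    ``dM/dt = k2' Caf - k4' M`` with ``A(0) = c0``, ``Caf(0) = M(0) = 0``
    and returns ``(C_caffeine, C_metabolite)`` evaluated at ``t``.

    Coinciding eigenvalues (equal effective rates) are handled by the
    analytic limit of the relevant exponential difference.  Non-negative
    for all ``t >= 0``.
    """
    t = np.asarray(t, dtype=float)
    k1, ke = p.k1p, p.k2p + p.k3p
    caf = p.c0 * k1 * _expdiff(t, k1, ke)
    return caf, _subnet_metabolite(t, p)


def _subnet_metabolite(t, p: SubnetworkParams):
    """M(t) of the cascade via partial fractions on the Caf input."""
    k1, ke, k4 = p.k1p, p.k2p + p.k3p, p.k4p
    if abs(ke - k1) < _RATE_EQ_TOL:
        ke = k1 + _RATE_EQ_TOL
    amp = p.c0 * k1 * p.k2p / (ke - k1)
    return amp * (_expdiff(t, k1, k4) - _expdiff(t, ke, k4))
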