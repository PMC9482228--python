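"""Synthetic benchmark data generators.

Each generator builds a mass time-series matrix ``M = diag(C V) eps``
from known ground truth: a concentration matrix ``C`` (first four
columns are a fixed caffeine-like toy model), per-time-point sample
volumes ``V`` drawn from a truncated log-normal, and multiplicative
measurement error ``eps`` with 20 % coefficient of variation.  The three
flavours differ in how the untargeted concentration columns are made:

* **v1** -- modified Bateman curves with kinetic parameters drawn
  uniformly within the fitting bounds (everything is describable by the
  kinetic model);
* **v2** -- per-time-point log-normal draws whose mean/SD are themselves
  sampled from log-normal meta-distributions (nothing is describable);
* **v3** -- columns resampled without replacement from a ground-truth
  concentration matrix emulating PQN-normalized real sweat data (a
  mixture of both behaviours).

``apply_noise_fraction`` converts a fraction of untargeted columns into
volume-independent contamination (their masses ignore ``V``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import DEFAULT_LOWER, DEFAULT_UPPER, KineticParams, bateman_array

__all__ = [
    "SyntheticDataset",
    "TOY_PARAMS",
    "toy_base_concentrations",
    "toy_known_params",
    "sample_volumes",
    "sample_epsilon",
    "simulate_v1",
    "simulate_v2",
    "simulate_v3",
    "v3_ground_truth",
    "apply_noise_fraction",
]

N_TARGETED = 4

#: caffeine-like toy kinetics (caffeine + three degradation products):
#: fast shared absorption, slower product formation, small baselines.
#: All parameters lie within the default fitting bounds.
TOY_PARAMS = (
    KineticParams(k_a=1.5, k_e=0.12, c_0=4.0, lag=0.0, d=0.02),
    KineticParams(k_a=0.6, k_e=0.10, c_0=1.5, lag=0.0, d=0.1),
    KineticParams(k_a=0.4, k_e=0.08, c_0=0.8, lag=0.0, d=0.05),
    KineticParams(k_a=0.3, k_e=0.06, c_0=0.5, lag=0.0, d=0.05),
)

#: truncated log-normal volume distribution: untruncated median 0.3 uL,
#: geometric SD 2.5, truncated to the physiological range [0.05, 4] uL
VOLUME_LOG_MU = float(np.log(0.3))
VOLUME_LOG_SIGMA = float(np.log(2.5))
VOLUME_BOUNDS = (0.05, 4.0)

#: multiplicative error: Normal(1, 0.20), truncated at 0.01 for positivity
ERROR_CV = 0.20
_ERROR_FLOOR = 0.01

#: v2 meta-distribution defaults: log-normal hyperparameters of the
#: populations of per-metabolite means and standard deviations,
#: emulating untargeted sweat feature statistics (median mean ~1 in
#: arbitrary concentration units, median SD ~0.5, both spanning roughly
#: an order of magnitude)
META_DISTRIBUTIONS = {
    "mean_log_mu": 0.0,
    "mean_log_sigma": 1.0,
    "sd_log_mu": -0.7,
    "sd_log_sigma": 0.8,
}

_V3_FIXTURE_SEED = 719  # fixed: the shipped ground truth is one matrix


@dataclass
class SyntheticDataset:
    """Ground truth plus generated masses for one benchmark replicate.

    ``noise_mask[j]`` is True for metabolites whose signal is
    volume-independent contamination; targeted columns are never noise.
    """

    t: np.ndarray
    C: np.ndarray
    V: np.ndarray
    epsilon: np.ndarray
    noise_mask: np.ndarray
    M: np.ndarray
    seed: object = None
    n_targeted: int = N_TARGETED
    info: dict = field(default_factory=dict)

    @property
    def n_metabolites(self) -> int:
        return self.C.shape[1]

    @property
    def noise_fraction(self) -> float:
        return float(self.noise_mask.mean())

    def recompute_masses(self) -> np.ndarray:
        """M from the stored components (the defining identity)."""
        return compute_masses(self.C, self.V, self.epsilon, self.noise_mask)


def compute_masses(C, V, epsilon, noise_mask=None) -> np.ndarray:
    """M = diag(C V) eps columnwise; noise columns get no volume factor."""
    C = np.asarray(C, float)
    V = np.asarray(V, float)
    epsilon = np.asarray(epsilon, float)
    if noise_mask is None:
        noise_mask = np.zeros(C.shape[1], bool)
    vol = np.where(noise_mask[None, :], 1.0, V[:, None])
    return C * vol * epsilon


def default_time_grid(n_timepoints: int = 20, t_max: float = 15.0) -> np.ndarray:
    """Equidistant sampling grid on [0, t_max] hours."""
    return np.linspace(0.0, t_max, n_timepoints)


def toy_base_concentrations(t=None) -> np.ndarray:
    """Concentration curves of the four caffeine-like toy metabolites."""
    if t is None:
        t = default_time_grid()
    params = np.stack([p.values for p in TOY_PARAMS])
    return bateman_array(np.asarray(t, float), params)


def toy_known_params() -> dict:
    """Fixed-parameter map for minimal models: the four targeted
    metabolites have known c_0, lag and d (only rates are fitted)."""
    return {j: {"c_0": p.c_0, "lag": p.lag, "d": p.d}
            for j, p in enumerate(TOY_PARAMS)}


def _rng(seed):
    return np.random.default_rng(seed)


def sample_volumes(n: int, seed=None, *, log_mu=VOLUME_LOG_MU,
                   log_sigma=VOLUME_LOG_SIGMA, bounds=VOLUME_BOUNDS) -> np.ndarray:
    """Truncated log-normal sweat volumes (uL), by rejection sampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    lo, hi = bounds
    out = np.empty(0)
    while out.size < n:
        draw = rng.lognormal(log_mu, log_sigma, size=2 * n)
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:n]


def sample_epsilon(shape, seed=None, *, cv=ERROR_CV) -> np.ndarray:
    """Multiplicative error draws: Normal(1, cv) truncated at 0.01."""
    rng = _rng(seed)
    eps = rng.normal(1.0, cv, size=shape)
    bad = eps < _ERROR_FLOOR
    while np.any(bad):
        eps[bad] = rng.normal(1.0, cv, size=int(bad.sum()))
        bad = eps < _ERROR_FLOOR
    return eps


def _assemble(t, C, seed_entropy, rng, volumes, epsilon,
              info=None) -> SyntheticDataset:
    n_t, n_m = C.shape
    V = sample_volumes(n_t, rng) if volumes is None else np.asarray(volumes, float)
    eps = (sample_epsilon((n_t, n_m), rng) if epsilon is None
           else np.broadcast_to(np.asarray(epsilon, float), (n_t, n_m)).copy())
    mask = np.zeros(n_m, bool)
    M = compute_masses(C, V, eps, mask)
    return SyntheticDataset(t=t, C=C, V=V, epsilon=eps, noise_mask=mask,
                            M=M, seed=seed_entropy, info=info or {})


def simulate_v1(n_metabolites: int = 60, n_timepoints: int = 20, seed=None,
                *, volumes=None, epsilon=None) -> SyntheticDataset:
    """Kinetic simulation: untargeted columns are Bateman curves with
    parameters drawn uniformly within the fitting bounds."""
    if n_metabolites < N_TARGETED:
        raise ValueError(f"need at least {N_TARGETED} metabolites")
    rng = _rng(seed)
    t = default_time_grid(n_timepoints)
    n_extra = n_metabolites - N_TARGETED
    lo = np.asarray(DEFAULT_LOWER)
    hi = np.asarray(DEFAULT_UPPER)
    params = rng.uniform(lo, hi, size=(n_extra, 5))
    C = np.hstack([toy_base_concentrations(t), bateman_array(t, params)]
                  ) if n_extra else toy_base_concentrations(t)
    return _assemble(t, C, seed, rng, volumes, epsilon,
                     info={"kinetic_params": params})


def simulate_v2(n_metabolites: int = 60, n_timepoints: int = 20, seed=None,
                *, meta_distributions=None, volumes=None,
                epsilon=None) -> SyntheticDataset:
    """Random simulation: untargeted columns are i.i.d. log-normal draws
    whose mean/SD come from log-normal meta-distributions -- time series
    no kinetic function can describe."""
    if n_metabolites < N_TARGETED:
        raise ValueError(f"need at least {N_TARGETED} metabolites")
    meta = dict(META_DISTRIBUTIONS, **(meta_distributions or {}))
    rng = _rng(seed)
    t = default_time_grid(n_timepoints)
    n_extra = n_metabolites - N_TARGETED
    cols = [toy_base_concentrations(t)]
    if n_extra:
        m = rng.lognormal(meta["mean_log_mu"], meta["mean_log_sigma"], n_extra)
        s = rng.lognormal(meta["sd_log_mu"], meta["sd_log_sigma"], n_extra)
        # log-normal with arithmetic mean m and SD s
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2
        draws = rng.lognormal(mu[None, :], np.sqrt(sigma2)[None, :],
                              size=(n_timepoints, n_extra))
        cols.append(draws)
    return _assemble(t, np.hstack(cols), seed, rng, volumes, epsilon)


def v3_ground_truth(n_metabolites: int = 100, n_timepoints: int = 20,
                    seed: int = _V3_FIXTURE_SEED) -> np.ndarray:
    """Synthetic stand-in for a PQN-normalized real sweat concentration
    matrix: a deterministic half/half mixture of Bateman-shaped and
    random log-normal profiles (real data contains both behaviours).
    Regenerated on demand from a fixed seed, so every call returns the
    same matrix unless ``seed`` is overridden."""
    rng = _rng(seed)
    t = default_time_grid(n_timepoints)
    n_kinetic = n_metabolites // 2
    params = rng.uniform(DEFAULT_LOWER, DEFAULT_UPPER, size=(n_kinetic, 5))
    kinetic = bateman_array(t, params)
    n_random = n_metabolites - n_kinetic
    m = rng.lognormal(META_DISTRIBUTIONS["mean_log_mu"],
                      META_DISTRIBUTIONS["mean_log_sigma"], n_random)
    s = rng.lognormal(META_DISTRIBUTIONS["sd_log_mu"],
                      META_DISTRIBUTIONS["sd_log_sigma"], n_random)
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2
    random_cols = rng.lognormal(mu[None, :], np.sqrt(sigma2)[None, :],
                                size=(n_timepoints, n_random))
    gt = np.hstack([kinetic, random_cols])
    order = rng.permutation(n_metabolites)
    return gt[:, order]


def simulate_v3(ground_truth=None, n_metabolites: int = 60,
                n_timepoints: int = 20, seed=None, *, columns=None,
                volumes=None, epsilon=None) -> SyntheticDataset:
    """Resampling simulation: untargeted columns are drawn without
    replacement from a ground-truth concentration matrix."""
    if n_metabolites < N_TARGETED:
        raise ValueError(f"need at least {N_TARGETED} metabolites")
    rng = _rng(seed)
    gt = (v3_ground_truth(n_timepoints=n_timepoints) if ground_truth is None
          else np.asarray(ground_truth, float))
    if gt.shape[0] != n_timepoints:
        raise ValueError("ground truth row count must equal n_timepoints")
    n_extra = n_metabolites - N_TARGETED
    if n_extra > gt.shape[1]:
        raise ValueError(
            f"requested {n_extra} untargeted columns but ground truth has "
            f"only {gt.shape[1]}")
    t = default_time_grid(n_timepoints)
    if columns is None:
        columns = rng.choice(gt.shape[1], size=n_extra, replace=False)
    C = np.hstack([toy_base_concentrations(t), gt[:, columns]])
    return _assemble(t, C, seed, rng, volumes, epsilon)


def apply_noise_fraction(ds: SyntheticDataset, f_n: float,
                         seed=None) -> SyntheticDataset:
    """Flag round(f_n * n_metabolites) untargeted columns as noise and
    regenerate their masses without the volume factor.

    Targeted metabolites are never flagged: with a known kinetic model
    one can be confident their signal is not contamination.  ``f_n`` is
    limited to [0, 0.95].
    """
    if not 0.0 <= f_n <= 0.95:
        raise ValueError("f_n must be in [0, 0.95]")
    n_m = ds.n_metabolites
    n_noise = int(round(f_n * n_m))
    if n_noise == 0:
        return replace(ds)
    n_untargeted = n_m - ds.n_targeted
    if n_noise > n_untargeted:
        raise ValueError(
            f"f_n={f_n} would require {n_noise} noise columns but only "
            f"{n_untargeted} untargeted columns exist")
    rng = _rng(ds.seed if seed is None else seed)
    idx = rng.choice(np.arange(ds.n_targeted, n_m), size=n_noise,
                     replace=False)
    mask = ds.noise_mask.copy()
    mask[idx] = True
    M = compute_masses(ds.C, ds.V, ds.epsilon, mask)
    return replace(ds, noise_mask=mask, M=M)
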