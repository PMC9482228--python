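"""Benchmark orchestrator: the simulation x model experiment grid.

For every grid cell (simulation version, n_metabolites, noise fraction)
it generates replicate datasets, fits the requested normalization
models and collects RMSE / rRMSE per replicate, with a reproducible
seed hierarchy: master seed -> per-cell seed -> per-replicate seed ->
per-fit seed.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic
from .metrics import paired_compare, rmse, rrmse
from .models import MIXNormalizer, PKMNormalizer
from .pqn import pqn_quotients

__all__ = ["BenchmarkGrid", "run_benchmark", "pairwise_comparisons"]

MODELS = ("pqn", "pkm_minimal", "pkm_full", "mix_minimal", "mix_full")
_SIMULATORS = {"v1": synthetic.simulate_v1, "v2": synthetic.simulate_v2}


@dataclass
class BenchmarkGrid:
    """Fully enumerated experiment grid."""

    versions: tuple = ("v1",)
    n_metabolites: tuple = (4, 10, 20, 40, 60)
    noise_fractions: tuple = (0.0,)
    replicates: int = 100
    models: tuple = ("pqn", "pkm_minimal", "mix_minimal")
    master_seed: int = 0
    n_starts: int = 100
    n_timepoints: int = 20
    error_free: bool = False  # epsilon forced to 1 (recovery experiments)

    def __post_init__(self):
        unknown = set(self.models) - set(MODELS)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")
        unknown = set(self.versions) - {"v1", "v2", "v3"}
        if unknown:
            raise ValueError(f"unknown simulation versions {sorted(unknown)}")

    def cells(self):
        for v in self.versions:
            for n in self.n_metabolites:
                for f_n in self.noise_fractions:
                    yield v, n, f_n


def _make_dataset(version, n_met, f_n, n_t, seed, error_free):
    eps = 1.0 if error_free else None
    if version == "v3":
        ds = synthetic.simulate_v3(n_metabolites=n_met, n_timepoints=n_t,
                                   seed=seed, epsilon=eps)
    else:
        ds = _SIMULATORS[version](n_metabolites=n_met, n_timepoints=n_t,
                                  seed=seed, epsilon=eps)
    if f_n > 0:
        ds = synthetic.apply_noise_fraction(ds, f_n, seed=seed + 1)
    return ds


def _make_estimator(model, n_met, n_starts, seed):
    known = synthetic.toy_known_params()
    common = dict(n_starts=n_starts, random_state=seed)
    if model == "pkm_minimal":
        return PKMNormalizer(ell=4, known_params=known, **common)
    if model == "pkm_full":
        return PKMNormalizer(ell=n_met, known_params=known, **common)
    if model == "mix_minimal":
        return MIXNormalizer(ell=4, known_params=known, **common)
    if model == "mix_full":
        return MIXNormalizer(ell=n_met, known_params=known, **common)
    raise ValueError(model)


def fit_one(model, ds, n_starts=100, seed=None):
    """Fit one model to one dataset; returns (rmse, rrmse, seconds).

    PQN yields quotients only, so its RMSE is NaN (no absolute volume
    scale exists for it).
    """
    t0 = time.perf_counter()
    if model == "pqn":
        q = pqn_quotients(ds.M)
        return np.nan, rrmse(ds.V, q.q), time.perf_counter() - t0
    est = _make_estimator(model, ds.n_metabolites, n_starts, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        est.fit(ds.M, t=ds.t)
    return (rmse(ds.V, est.V_), rrmse(ds.V, est.V_),
            time.perf_counter() - t0)


def run_benchmark(grid: BenchmarkGrid, progress=None) -> pd.DataFrame:
    """Run the grid; returns a tidy frame of per-replicate metrics.

    Partial failures are recorded (NaN metrics, ``error`` column) and
    the run continues.
    """
    rows = []
    master = np.random.SeedSequence(grid.master_seed)
    for cell_idx, (version, n_met, f_n) in enumerate(grid.cells()):
        cell_rng = np.random.default_rng(
            np.random.SeedSequence(grid.master_seed, spawn_key=(cell_idx,)))
        # pre-drawn, so per-replicate seeds do not depend on model order
        data_seeds = cell_rng.integers(2**31 - 2, size=grid.replicates)
        fit_seeds = cell_rng.integers(2**31 - 2,
                                      size=(grid.replicates, len(grid.models)))
        for rep in range(grid.replicates):
            ds = _make_dataset(version, n_met, f_n, grid.n_timepoints,
                               int(data_seeds[rep]), grid.error_free)
            for m_idx, model in enumerate(grid.models):
                err = ""
                try:
                    r, rr, secs = fit_one(model, ds, grid.n_starts,
                                          int(fit_seeds[rep, m_idx]))
                except Exception as exc:
                    r = rr = secs = np.nan
                    err = repr(exc)
                rows.append(dict(version=version, n_metabolites=n_met,
                                 noise_fraction=f_n, replicate=rep,
                                 model=model, rmse=r, rrmse=rr,
                                 seconds=secs, error=err))
            if progress is not None:
                progress(version, n_met, f_n, rep)
    return pd.DataFrame(rows)


def pairwise_comparisons(results: pd.DataFrame, metric: str = "rrmse",
                         alternative: str = "two-sided") -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests between all model pairs, per cell."""
    out = []
    keys = ["version", "n_metabolites", "noise_fraction"]
    for cell, sub in results.groupby(keys):
        wide = sub.pivot(index="replicate", columns="model", values=metric)
        models = [m for m in wide.columns if wide[m].notna().all()]
        for i, a in enumerate(models):
            for b in models[i + 1:]:
                res = paired_compare(wide[a], wide[b], alternative)
                out.append(dict(zip(keys, cell), model_a=a, model_b=b,
                                pvalue=res.pvalue, stars=res.stars,
                                degenerate=res.degenerate))
    return pd.DataFrame(out)
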