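"""Tabular readers/writers and flat configuration files.

Mass time-series matrices travel as TSV/CSV with a leading ``time``
column (hours) and one column per metabolite.  Every result file
carries the seed and a config hash so it can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["MassTimeSeries", "read_mass_matrix", "write_mass_matrix",
           "read_config", "write_config", "config_hash", "write_results"]


@dataclass
class MassTimeSeries:
    """Measured abundance matrix with time stamps and metabolite labels.

    The first ``n_targeted`` columns are the kinetically modelled
    (targeted) metabolites; the rest are untargeted features.
    """

    t: np.ndarray
    M: np.ndarray
    metabolites: list
    n_targeted: int = 4

    @property
    def targeted(self) -> np.ndarray:
        return self.M[:, : self.n_targeted]

    @property
    def untargeted(self) -> np.ndarray:
        return self.M[:, self.n_targeted:]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_mass_matrix(path, n_targeted: int = 4) -> MassTimeSeries:
    """Read a time x metabolite abundance table.

    Errors on non-numeric cells, missing values and duplicate time
    stamps (PQN and the fitters require complete, well-ordered data).
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"{path}: empty series (need a time column and at "
                         "least one metabolite)")
    tcol = df.columns[0]
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from None
    if values.isna().any().any():
        raise ValueError(f"{path}: missing values are not supported")
    t = values[tcol].to_numpy()
    if len(np.unique(t)) != len(t):
        raise ValueError(f"{path}: duplicate time stamps")
    M = values.drop(columns=tcol).to_numpy()
    return MassTimeSeries(t=t, M=M, metabolites=list(df.columns[1:]),
                          n_targeted=n_targeted)


def write_mass_matrix(path, ts: MassTimeSeries) -> None:
    df = pd.DataFrame(ts.M, columns=ts.metabolites)
    df.insert(0, "time", ts.t)
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key-value mapping")
    return cfg


def write_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(out_dir, *, V, t, kinetic_params=None, loss=None,
                  config=None, seed=None) -> Path:
    """Write fitted volumes (TSV) plus a JSON manifest with provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time": t, "V_fit": V}).to_csv(
        out_dir / "volumes.tsv", sep="\t", index=False)
    manifest = {
        "seed": seed,
        "loss": loss,
        "config": config or {},
        "config_hash": config_hash(config or {}),
    }
    if kinetic_params is not None:
        manifest["kinetic_params"] = [
            {k: float(v) for k, v in zip(
                ("k_a", "k_e", "c_0", "lag", "d"), p.values)}
            if hasattr(p, "values") else vars(p)
            for p in kinetic_params]
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out_dir
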