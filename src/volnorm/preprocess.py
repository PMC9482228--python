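"""LC-MS feature-table pre-filtering.

Operates on exported alignment tables (one row per feature with m/z,
retention time, per-sample abundances and blank abundances) and applies,
per time series, three exclusion rules before normalization:

1. retention-time rule: features eluting after ``rt_max`` are removed
   (late eluters are predominantly background);
2. blank rule: features whose *minimum* sample abundance is below
   ``blank_factor`` x the *maximum* blank abundance are removed, except
   listed spike-ins / internal standards;
3. isomer rule (applied last, on survivors): of any pair closer than
   ``isomer_dm`` in m/z *and* ``isomer_drt`` in retention time, the
   member with the lower maximum sample abundance is removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["filter_features", "read_feature_table"]

REQUIRED_COLUMNS = ("feature_id", "mz", "rt")


def read_feature_table(path) -> pd.DataFrame:
    """Read a TSV/CSV alignment export with feature_id, mz, rt columns."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table lacks required columns {missing}")
    return df


def _validate(df, sample_cols, blank_cols):
    for c in REQUIRED_COLUMNS:
        if c not in df.columns:
            raise ValueError(f"missing column {c!r}")
    if df.empty:
        return
    if (df["mz"] <= 0).any():
        raise ValueError("m/z values must be positive")
    if (df["rt"] < 0).any():
        raise ValueError("retention times must be non-negative")
    for c in list(sample_cols) + list(blank_cols or []):
        if (df[c] < 0).any():
            raise ValueError(f"abundances in {c!r} must be non-negative")


def filter_features(df: pd.DataFrame, sample_cols, blank_cols=None, *,
                    rt_max: float = 5.5, blank_factor: float = 5.0,
                    isomer_dm: float = 0.001, isomer_drt: float = 0.5,
                    spike_in_ids=()):
    """Apply the three exclusion rules to one time series' feature table.

    Returns ``(filtered, removal_log)`` where the log records one row
    per removed feature with the rule that removed it.  The operation is
    idempotent: filtering a filtered table changes nothing.
    """
    _validate(df, sample_cols, blank_cols)
    removed = []  # (feature_id, rule)
    if df.empty:
        return df.copy(), pd.DataFrame(columns=["feature_id", "rule"])
    spike_in_ids = set(spike_in_ids)

    keep = pd.Series(True, index=df.index)

    late = df["rt"] > rt_max
    for fid in df.loc[late, "feature_id"]:
        removed.append((fid, "retention_time"))
    keep &= ~late

    if blank_factor is not None:
        if not blank_cols:
            raise ValueError("blank columns required when the blank rule "
                             "is active")
        min_sample = df[list(sample_cols)].min(axis=1)
        max_blank = df[list(blank_cols)].max(axis=1)
        below = (min_sample < blank_factor * max_blank) & \
            ~df["feature_id"].isin(spike_in_ids)
        for fid in df.loc[below & keep, "feature_id"]:
            removed.append((fid, "blank"))
        keep &= ~below

    # isomer deduplication on the survivors: keep the better-quantified
    # (higher maximum sample abundance) member of each close pair
    surv = df[keep].copy()
    surv["_maxab"] = surv[list(sample_cols)].max(axis=1)
    surv = surv.sort_values("_maxab", ascending=False, kind="stable")
    kept_mz, kept_rt, kept_idx = [], [], []
    for idx, row in surv.iterrows():
        clash = any(
            abs(row["mz"] - m) < isomer_dm and abs(row["rt"] - r) < isomer_drt
            for m, r in zip(kept_mz, kept_rt))
        if clash:
            removed.append((row["feature_id"], "isomer"))
        else:
            kept_mz.append(row["mz"])
            kept_rt.append(row["rt"])
            kept_idx.append(idx)

    filtered = df.loc[sorted(kept_idx)].copy()
    log = pd.DataFrame(removed, columns=["feature_id", "rule"])
    return filtered, log
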