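"""CSV schemas, provenance-stamped writers, and schema validation."""

from __future__ import annotations

from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd

from .panels import CURVE_COLUMNS, DistanceSeries, SchemaError

try:
    PACKAGE_VERSION = version("gpcrbias")
except PackageNotFoundError:  # running from a source tree
    PACKAGE_VERSION = "0+unknown"


def write_csv(df: pd.DataFrame, path: str, config_hash: str = "") -> None:
    """Write a CSV with provenance comment lines (version + config hash)."""
    with open(path, "w") as fh:
        fh.write(f"# gpcrbias {PACKAGE_VERSION}\n")
        if config_hash:
            fh.write(f"# config_hash {config_hash}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str) -> pd.DataFrame:
    """Read a CSV, skipping provenance comment lines."""
    return pd.read_csv(path, comment="#")


def validate_curves(df: pd.DataFrame) -> list[str]:
    """Row-level validation of the curves schema; returns error messages.

    Row numbers refer to data rows (1-based, excluding header/comments).
    """
    errors = []
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        return [f"missing columns: {sorted(missing)}"]
    conc = pd.to_numeric(df["concentration_M"], errors="coerce")
    resp = pd.to_numeric(df["response"], errors="coerce")
    for i in df.index[conc.isna() | (conc <= 0)]:
        errors.append(f"row {i + 1}: concentration_M must be a positive number "
                      f"(got {df.loc[i, 'concentration_M']!r})")
    for i in df.index[resp.isna() | ~np.isfinite(resp.fillna(np.inf))]:
        errors.append(f"row {i + 1}: response must be a finite number "
                      f"(got {df.loc[i, 'response']!r})")
    return errors


def distance_series_to_frame(runs: list[DistanceSeries]) -> pd.DataFrame:
    """Distance CSV schema: run, time_ns, one column per residue:oxygen (A)."""
    frames = []
    for run in runs:
        cols = {"run": run.run_id, "time_ns": run.time_ns}
        for res in run.residues:
            arr = run.distances[res]
            for j in range(arr.shape[1]):
                cols[f"{res}:O{j + 1}"] = arr[:, j]
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def distance_series_from_frame(df: pd.DataFrame) -> list[DistanceSeries]:
    """Parse the distance CSV schema back into per-run series."""
    if "run" not in df.columns or "time_ns" not in df.columns:
        raise SchemaError("distance table needs 'run' and 'time_ns' columns")
    dist_cols = [c for c in df.columns if ":" in c]
    if not dist_cols:
        raise SchemaError("no 'RESIDUE:OXYGEN' distance columns found")
    residues: dict[str, list[str]] = {}
    for c in dist_cols:
        res = c.split(":", 1)[0]
        residues.setdefault(res, []).append(c)
    runs = []
    for run_id, sub in df.groupby("run", sort=True):
        sub = sub.sort_values("time_ns")
        dists = {res: sub[cols].to_numpy(dtype=float)
                 for res, cols in residues.items()}
        runs.append(DistanceSeries(str(run_id), sub["time_ns"].to_numpy(dtype=float),
                                   dists))
    return runs
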