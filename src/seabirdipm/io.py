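"""Delimited-text I/O and run manifests.

All tabular inputs and outputs are comma-separated UTF-8 text with a
header row; empty cells encode missing values.  The counts file has
columns ``year, females, chicks_f`` plus optional replicate columns
``rep1..repK`` (all on the female scale); the survival file
``year, age_class, estimate, ci_low, ci_high``; the covariate file one
column per covariate term.  Every pipeline output directory receives a
``manifest.json`` recording the config snapshot, input checksums, seeds
and package version, so a run can be reconstructed exactly.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import COLUMNS, CovariateMatrix
from .inference import ModelData

__all__ = [
    "read_counts",
    "read_survival",
    "read_covariates",
    "write_covariates",
    "load_model_data",
    "write_manifest",
    "MalformedInputError",
]


class MalformedInputError(ValueError):
    """A cell in an input table could not be parsed; names row and column."""


def _read_numeric_csv(path, required, int_cols=()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise MalformedInputError(f"{path.name}: missing column {col!r}")
    out = {}
    for col in df.columns:
        if col == "age_class":
            out[col] = df[col]
            continue
        vals = []
        for row, cell in enumerate(df[col], start=2):  # header is line 1
            cell = cell.strip()
            if cell == "":
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError as exc:
                raise MalformedInputError(
                    f"{path.name}: non-numeric cell {cell!r} at row {row}, column {col!r}"
                ) from exc
        arr = np.asarray(vals)
        if col in int_cols:
            if np.isnan(arr).any():
                raise MalformedInputError(f"{path.name}: empty cell in column {col!r}")
            arr = arr.astype(int)
        out[col] = arr
    return pd.DataFrame(out)


def read_counts(path) -> pd.DataFrame:
    """Counts file: year, females, chicks_f [, rep1..repK]."""
    return _read_numeric_csv(path, ("year", "females", "chicks_f"), int_cols=("year",))


def read_survival(path) -> pd.DataFrame:
    """Survival file: year, age_class, estimate, ci_low, ci_high."""
    df = _read_numeric_csv(
        path, ("year", "age_class", "estimate", "ci_low", "ci_high"), int_cols=("year",)
    )
    bad = ~df["age_class"].isin(["fledgling", "older"])
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise MalformedInputError(
            f"{Path(path).name}: unknown age_class at row {row} (use fledgling/older)"
        )
    return df


def read_covariates(path) -> CovariateMatrix:
    """Covariate file: year plus standardized covariate columns; an
    optional sidecar ``<name>.scalers.json`` restores the raw-scale
    (mean, sd) pairs."""
    df = _read_numeric_csv(path, ("year",), int_cols=("year",))
    scalers = {}
    sidecar = Path(path).with_suffix(".scalers.json")
    if sidecar.exists():
        scalers = {k: tuple(v) for k, v in json.loads(sidecar.read_text()).items()}
    return CovariateMatrix.from_frame(df, scalers=scalers)


def write_covariates(cov: CovariateMatrix, path) -> None:
    path = Path(path)
    cov.to_frame().to_csv(path, index=False)
    if cov.scalers:
        path.with_suffix(".scalers.json").write_text(
            json.dumps({k: list(v) for k, v in cov.scalers.items()}, indent=1)
        )


def load_model_data(counts_path, covariates_path, survival_path=None) -> ModelData:
    """Assemble aligned model data from the three input tables."""
    counts = read_counts(counts_path)
    cov = read_covariates(covariates_path)
    years = counts["year"].to_numpy()
    if not np.array_equal(np.sort(years), years):
        raise MalformedInputError("counts file years must be sorted")

    rep_cols = [c for c in counts.columns if c.startswith("rep")]
    replicates: dict[int, list[float]] = {}
    for _, row in counts.iterrows():
        reps = [row[c] for c in rep_cols if not np.isnan(row[c])]
        if len(reps) >= 2:
            replicates[int(row["year"])] = reps

    T = len(years)
    surv = {
        name: np.full(T, np.nan)
        for name in ("est_f", "lo_f", "hi_f", "est_a", "lo_a", "hi_a")
    }
    if survival_path is not None:
        sdf = read_survival(survival_path)
        year_pos = {int(y): i for i, y in enumerate(years)}
        for _, row in sdf.iterrows():
            i = year_pos.get(int(row["year"]))
            if i is None:
                raise MalformedInputError(
                    f"survival year {int(row['year'])} not in the counts series"
                )
            sfx = "f" if row["age_class"] == "fledgling" else "a"
            surv[f"est_{sfx}"][i] = row["estimate"]
            surv[f"lo_{sfx}"][i] = row["ci_low"]
            surv[f"hi_{sfx}"][i] = row["ci_high"]

    return ModelData(
        years=years,
        obs_females=counts["females"].to_numpy(),
        obs_chicks_f=counts["chicks_f"].to_numpy(),
        cov=cov,
        replicates=replicates,
        surv_est_f=surv["est_f"], surv_lo_f=surv["lo_f"], surv_hi_f=surv["hi_f"],
        surv_est_a=surv["est_a"], surv_lo_a=surv["lo_a"], surv_hi_a=surv["hi_a"],
    )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir, config: dict, inputs=(), seeds=()) -> Path:
    """Write the run manifest (exactly one per output directory)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "seeds": list(seeds),
        "inputs": {str(p): _checksum(Path(p)) for p in inputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
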