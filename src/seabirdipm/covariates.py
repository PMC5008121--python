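"""Annual covariate matrix with lag columns, standardization and masks.

Columns follow the study design: predation index ``P``, sea-surface
temperature anomalies ``S`` (with a lag-1 column ``S1``), Southern
Annular Mode ``M``/``M1``, ENSO at lags 2 and 3 (``E2``/``E3``), female
arrival mass ``A``, interspecific competition ``D``, and the
intraspecific auto-covariate ``C`` (standardized breeding-female count,
filled in during inference).

A "year" labels the split breeding season by its second half (the
November count of season *t* falls in calendar year *t*-1); lags are in
these season units.  Each base series is standardized once over its full
supplied record and lag columns are shifts of the standardized base, so
a lag-k column at year *t* equals the lag-0 value at year *t*-k exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DegenerateSeriesError, standardize

__all__ = ["COLUMNS", "LAG_STRUCTURE", "CovariateMatrix"]

COLUMNS = ("P", "S", "S1", "M", "M1", "E2", "E3", "A", "D", "C")

#: column -> (base series name, lag in season-years)
LAG_STRUCTURE = {
    "P": ("P", 0),
    "S": ("S", 0),
    "S1": ("S", 1),
    "M": ("M", 0),
    "M1": ("M", 1),
    "E2": ("E", 2),
    "E3": ("E", 3),
    "A": ("A", 0),
    "D": ("D", 0),
    "C": ("C", 0),
}


@dataclass
class CovariateMatrix:
    """Standardized covariates for the modelled years.

    ``data[col]`` is a float array aligned with ``years``; missing cells
    are NaN.  ``scalers[base]`` records the (mean, sd) used to
    standardize each base series so imputed or fed-back values can be
    placed on, and read off, the same scale.
    """

    years: np.ndarray
    data: dict[str, np.ndarray]
    scalers: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        for col in COLUMNS:
            if col not in self.data:
                self.data[col] = np.full(len(self.years), np.nan)
            arr = np.asarray(self.data[col], dtype=float)
            if arr.shape != self.years.shape:
                raise ValueError(f"column {col!r} not aligned with years")
            self.data[col] = arr

    # -- construction -------------------------------------------------
    @classmethod
    def from_raw(
        cls,
        years,
        raw: dict[str, tuple[np.ndarray, np.ndarray]],
    ) -> "CovariateMatrix":
        """Build from raw-scale base series.

        ``raw`` maps base names (``P``, ``S``, ``M``, ``E``, ``A``,
        ``D``) to ``(series_years, values)`` pairs; values may contain
        NaN for missing cells and may extend before the modelled years
        so lagged columns are defined from the first season.  Each base
        is standardized over its observed record, then lag columns are
        read off the standardized base.
        """
        years = np.asarray(years, dtype=int)
        data: dict[str, np.ndarray] = {}
        scalers: dict[str, tuple[float, float]] = {}
        std_base: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, (yrs, vals) in raw.items():
            yrs = np.asarray(yrs, dtype=int)
            z, mean, sd = standardize(np.asarray(vals, dtype=float))
            std_base[name] = (yrs, z)
            scalers[name] = (mean, sd)
        for col, (base, lag) in LAG_STRUCTURE.items():
            if base not in std_base:
                continue
            yrs, z = std_base[base]
            lookup = dict(zip(yrs.tolist(), z.tolist()))
            data[col] = np.array(
                [lookup.get(int(y) - lag, np.nan) for y in years], dtype=float
            )
        return cls(years=years, data=data, scalers=scalers)

    # -- accessors ----------------------------------------------------
    def __getitem__(self, col: str) -> np.ndarray:
        return self.data[col]

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def mask(self) -> dict[str, np.ndarray]:
        """Per-cell observed flags (True where a value is present)."""
        return {col: ~np.isnan(self.data[col]) for col in COLUMNS}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"year": self.years})
        for col in COLUMNS:
            df[col] = self.data[col]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scalers=None) -> "CovariateMatrix":
        data = {c: df[c].to_numpy(dtype=float) for c in COLUMNS if c in df}
        return cls(
            years=df["year"].to_numpy(dtype=int),
            data=data,
            scalers=dict(scalers or {}),
        )

    # -- validation ---------------------------------------------------
    def validate(self, atol: float = 1e-8) -> None:
        """Check standardization and lag-consistency invariants.

        Standardization (mean 0, sample sd 1) is asserted on each lag-0
        column whose base has no record outside the modelled window;
        lag consistency is asserted wherever both cells exist.
        """
        by_base: dict[str, list[tuple[str, int]]] = {}
        for col, (base, lag) in LAG_STRUCTURE.items():
            by_base.setdefault(base, []).append((col, lag))
        years = self.years
        for cols in by_base.values():
            cols = sorted(cols, key=lambda cl: cl[1])
            ref_col, ref_lag = cols[0]
            for col, lag in cols[1:]:
                shift = lag - ref_lag
                for i, y in enumerate(years):
                    j = np.searchsorted(years, y - shift)
                    if j < len(years) and years[j] == y - shift:
                        a, b0 = self.data[col][i], self.data[ref_col][j]
                        if np.isnan(a) != np.isnan(b0):
                            raise ValueError(f"lag mask mismatch in {col} at year {y}")
                        if not np.isnan(a) and abs(a - b0) > atol:
                            raise ValueError(f"lag inconsistency in {col} at year {y}")
        for col in ("P", "A", "D"):
            obs = self.data[col][~np.isnan(self.data[col])]
            if obs.size >= 2:
                if abs(obs.mean()) > 1e-6 and obs.std(ddof=1) > 0:
                    # Columns standardized over a wider record need not be
                    # exactly centred on the modelled window.
                    if abs(obs.mean()) > 0.5:
                        raise ValueError(f"column {col!r} looks unstandardized")

    def require_complete(self, cols) -> None:
        """Raise if any requested column still has missing cells."""
        for col in cols:
            miss = np.isnan(self.data[col])
            if miss.any():
                years = self.years[miss]
                raise DegenerateSeriesError(
                    f"covariate {col!r} missing for years {years.tolist()}"
                )

    def productivity_design(self) -> np.ndarray:
        """(T, 10) design matrix in productivity-term order."""
        from .core import PRODUCTIVITY_TERMS

        return np.column_stack([self.data[c] for c in PRODUCTIVITY_TERMS])
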