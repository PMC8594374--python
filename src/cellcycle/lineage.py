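"""Domain data model: generation records, lineage tables, observable panel.

A lineage is a single mother-machine-style chain of cells (one daughter
followed per division).  Each generation carries the physiological variables
that single-cell experiments measure: the elongation rate λ, the doubling
time τ, the cell-cycle duration τ_cyc (attributed initiation to division,
possibly spanning generations), sizes at birth/division/initiation and the
three adder increments δ_ii, δ_id and Δ_d.

The heavy containers are plain :class:`pandas.DataFrame` objects;
:class:`GenerationRecord` is a per-row convenience view.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import nan
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, LineageLengthError
from .params import ModelParams

#: Column order of the per-generation table (also the on-disk schema).
RECORD_COLUMNS = (
    "index",
    "growth_rate",
    "doubling_time",
    "birth_size",
    "division_size",
    "init_size_per_ori",
    "total_init_size",
    "tau_cyc",
    "a_i",
    "delta_ii",
    "delta_id",
    "delta_d",
    "division_ratio",
)

#: Columns that must be present (and positive) in any lineage.
MANDATORY_COLUMNS = (
    "index",
    "growth_rate",
    "doubling_time",
    "birth_size",
    "division_size",
)

#: Mapping observable name -> record column for the base panel.
BASE_OBSERVABLES = {
    "lambda": "growth_rate",
    "tau": "doubling_time",
    "tau_cyc": "tau_cyc",
    "a_i": "a_i",
    "S_b": "birth_size",
    "S_d": "division_size",
    "s_i": "init_size_per_ori",
    "S_i": "total_init_size",
    "Delta_d": "delta_d",
    "delta_ii": "delta_ii",
    "delta_id": "delta_id",
}

#: The fixed 18-variable panel used for the exhaustive I-value enumeration:
#: the 11 base observables plus 7 derived ratios/combinations spanning sizes,
#: added sizes, durations and dimensionless numbers.  The exact composition
#: is a documented package choice (see docs/methods.md).
PANEL_VARIABLES = (
    "lambda", "tau", "tau_cyc", "a_i", "S_b", "S_d", "s_i", "S_i",
    "Delta_d", "delta_ii", "delta_id",
    "Sd_over_Sb", "si_over_Sb", "lambda_tau_cyc", "lambda_tau",
    "did_over_dii", "Dd_over_Sb", "tau_cyc_minus_tau",
)

#: Default number of leading generations excluded from all statistics.
DEFAULT_BURN_IN = 100


@dataclass
class GenerationRecord:
    """One generation's physiological observables (a row view)."""

    index: int
    growth_rate: float
    doubling_time: float
    birth_size: float
    division_size: float
    init_size_per_ori: float = nan
    total_init_size: float = nan
    tau_cyc: float = nan
    a_i: float = nan
    delta_ii: float = nan
    delta_id: float = nan
    delta_d: float = nan
    division_ratio: float = 0.5


@dataclass
class LineageTable:
    """Ordered per-generation table plus provenance.

    ``data`` holds one row per generation with :data:`RECORD_COLUMNS`;
    statistics operations only see rows with ``index >= burn_in``.
    ``info`` carries model-specific diagnostics (e.g. the CCCP limiting
    fraction ``f``).
    """

    data: pd.DataFrame
    model_name: str = "imported"
    params: ModelParams | None = None
    seed: int | None = None
    burn_in: int = DEFAULT_BURN_IN
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise DataIntegrityError(f"lineage table missing column(s) {missing}")
        for col in RECORD_COLUMNS:
            if col not in self.data.columns:
                self.data[col] = nan
        self.data = self.data.loc[:, list(RECORD_COLUMNS)].reset_index(drop=True)
        idx = self.data["index"].to_numpy()
        if len(idx) and not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))):
            raise DataIntegrityError("generation indices must be contiguous")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def records(self) -> Iterator[GenerationRecord]:
        for row in self.data.itertuples(index=False):
            yield GenerationRecord(*row)

    def record(self, i: int) -> GenerationRecord:
        return GenerationRecord(*self.data.iloc[i])

    def steady_state(self) -> pd.DataFrame:
        """Rows past the burn-in, the only ones statistics should see."""
        return self.data[self.data["index"] >= self.burn_in]


def extract_observables(lineage: LineageTable) -> pd.DataFrame:
    """Columnar physiological-variable panel with burn-in applied.

    Returns a DataFrame whose columns are the 18 :data:`PANEL_VARIABLES`
    (one aligned series per variable; entries that are undefined for a given
    generation, such as the trailing δ_ii or generations that received no
    initiation event, are NaN and are dropped pairwise by downstream
    correlation code).

    Raises
    ------
    LineageLengthError
        If fewer than three generations remain past the burn-in.
    DataIntegrityError
        If any size or duration is non-positive.
    """
    if len(lineage) <= lineage.burn_in + 2:
        raise LineageLengthError(
            f"lineage has {len(lineage)} records; need more than "
            f"burn_in + 2 = {lineage.burn_in + 2}"
        )
    df = lineage.steady_state()
    out = pd.DataFrame({name: df[col].to_numpy(dtype=float)
                        for name, col in BASE_OBSERVABLES.items()})
    for col in ("S_b", "S_d", "tau", "lambda"):
        vals = out[col].to_numpy()
        if not np.all(vals[np.isfinite(vals)] > 0):
            raise DataIntegrityError(f"non-positive value encountered in {col!r}")
    for col in ("s_i", "S_i", "tau_cyc", "a_i"):
        vals = out[col].to_numpy()
        if np.any(vals[np.isfinite(vals)] < 0):
            raise DataIntegrityError(f"negative value encountered in {col!r}")
    return derive_variable_panel(out)


def derive_variable_panel(table: pd.DataFrame) -> pd.DataFrame:
    """Complete the fixed 18-variable panel from the base observables.

    Deterministic and idempotent: derived columns are recomputed from the
    base columns every call.
    """
    out = table.copy()
    out["Sd_over_Sb"] = out["S_d"] / out["S_b"]
    out["si_over_Sb"] = out["s_i"] / out["S_b"]
    out["lambda_tau_cyc"] = out["lambda"] * out["tau_cyc"]
    out["lambda_tau"] = out["lambda"] * out["tau"]
    out["did_over_dii"] = out["delta_id"] / out["delta_ii"]
    out["Dd_over_Sb"] = out["Delta_d"] / out["S_b"]
    out["tau_cyc_minus_tau"] = out["tau_cyc"] - out["tau"]
    return out.loc[:, list(PANEL_VARIABLES)]


def normalize_by_mean(table: pd.DataFrame) -> pd.DataFrame:
    """Divide every column by its (NaN-ignoring) mean.

    A no-op for Pearson correlations; applied for parity with how the
    diagnostic correlations are usually plotted.
    """
    return table / table.mean(skipna=True)
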