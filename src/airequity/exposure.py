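"""Grid-to-tract exposure aggregation and scenario deltas.

Concentration fields are 2-D annual-mean PM2.5 arrays (micrograms per cubic
metre), indexed row-major and 0-based.  Tract exposure changes follow the
positive-equals-reduction sign convention: ``delta_c = reference - scenario``,
so an air-quality improvement is a positive number.  Reporting layers that
want the concentration-change sign (negative for an improvement) negate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationField",
    "TractRecord",
    "TractExposure",
    "aggregate_to_tracts",
    "scenario_delta",
    "population_weighted_mean",
]

#: Canonical columns of a tract table.
TRACT_COLUMNS = [
    "tract_id",
    "county_id",
    "population",
    "incidence_per_person_year",
    "vulnerability_score",
]

#: Canonical columns of a tract-to-cell weight mapping.
WEIGHT_COLUMNS = ["tract_id", "row", "col", "weight"]

WEIGHT_SUM_TOL = 1e-6


@dataclass(frozen=True)
class ConcentrationField:
    """A gridded annual-mean PM2.5 field (ug/m3), row-major and 0-based.

    Parameters
    ----------
    values
        2-D array of cell values.  Must be finite everywhere.
    is_delta
        If True this is a change field (reductions); values may be any sign.
        Baseline (absolute) fields must be non-negative.
    """

    values: np.ndarray
    is_delta: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"concentration field must be 2-D, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("concentration field contains non-finite values")
        if not self.is_delta and np.any(arr < 0):
            raise ValueError("baseline concentration field has negative values")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcentrationField):
            return NotImplemented
        return self.is_delta == other.is_delta and np.array_equal(
            self.values, other.values
        )


@dataclass(frozen=True)
class TractRecord:
    """One census tract: population (projected), baseline mortality incidence
    (per person-year) and a 0-100 vulnerability screening score."""

    tract_id: str
    county_id: str
    population: float
    incidence: float
    vulnerability_score: float

    def __post_init__(self) -> None:
        if not self.population > 0:
            raise ValueError(f"tract {self.tract_id}: population must be > 0")
        if self.incidence < 0:
            raise ValueError(f"tract {self.tract_id}: incidence must be >= 0")
        if not 0.0 <= self.vulnerability_score <= 100.0:
            raise ValueError(
                f"tract {self.tract_id}: vulnerability score must be in [0, 100]"
            )


@dataclass(frozen=True)
class TractExposure:
    """Per-tract concentration change; positive means a reduction."""

    tract_id: str
    delta_c: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_c):
            raise ValueError(f"tract {self.tract_id}: delta_c not finite")


def tracts_to_frame(records: list[TractRecord]) -> pd.DataFrame:
    """Build a canonical tract table from records."""
    return pd.DataFrame(
        {
            "tract_id": [r.tract_id for r in records],
            "county_id": [r.county_id for r in records],
            "population": [r.population for r in records],
            "incidence_per_person_year": [r.incidence for r in records],
            "vulnerability_score": [r.vulnerability_score for r in records],
        }
    )


def validate_tracts(tracts: pd.DataFrame) -> pd.DataFrame:
    """Validate a tract table against the canonical schema and invariants."""
    missing = [c for c in TRACT_COLUMNS if c not in tracts.columns]
    if missing:
        raise ValueError(f"tract table missing columns: {missing}")
    if tracts["tract_id"].duplicated().any():
        dups = tracts.loc[tracts["tract_id"].duplicated(), "tract_id"].tolist()
        raise ValueError(f"duplicate tract_id values: {dups}")
    if not (tracts["population"] > 0).all():
        raise ValueError("tract populations must all be > 0")
    if not (tracts["incidence_per_person_year"] >= 0).all():
        raise ValueError("tract incidence must be >= 0")
    score = tracts["vulnerability_score"]
    if not ((score >= 0) & (score <= 100)).all():
        raise ValueError("vulnerability scores must lie in [0, 100]")
    return tracts


def aggregate_to_tracts(field: ConcentrationField, weights: pd.DataFrame) -> pd.Series:
    """Aggregate a gridded field to tracts with an explicit weight mapping.

    Parameters
    ----------
    field
        Gridded concentration (or concentration-change) field.
    weights
        Long-format mapping with columns ``tract_id, row, col, weight``.
        Weights for each tract must sum to 1 within ``1e-6``, and every
        (row, col) must index into the grid.

    Returns
    -------
    pandas.Series
        Tract value ``sum(weight * cell value)``, indexed by ``tract_id``.
    """
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    nrows, ncols = field.shape
    rows = weights["row"].to_numpy(dtype=int)
    cols = weights["col"].to_numpy(dtype=int)
    bad = (rows < 0) | (rows >= nrows) | (cols < 0) | (cols >= ncols)
    if bad.any():
        bad_tracts = sorted(set(weights.loc[bad, "tract_id"].astype(str)))
        raise IndexError(
            f"weight cells out of range for grid {field.shape} in tracts: {bad_tracts}"
        )
    sums = weights.groupby("tract_id")["weight"].sum()
    off = sums[(sums - 1.0).abs() > WEIGHT_SUM_TOL]
    if not off.empty:
        detail = ", ".join(f"{t}={v:.6f}" for t, v in off.items())
        raise ValueError(f"tract weights do not sum to 1: {detail}")
    contrib = weights["weight"].to_numpy() * field.values[rows, cols]
    out = (
        pd.Series(contrib, index=weights["tract_id"].to_numpy())
        .groupby(level=0)
        .sum()
        .sort_index()
    )
    out.index.name = "tract_id"
    out.name = "value"
    return out


def scenario_delta(reference: pd.Series, scenario: pd.Series) -> pd.Series:
    """Per-tract concentration reduction ``reference - scenario``.

    Positive values are improvements; local worsening is preserved as a
    negative delta, never clipped.  Both inputs must cover the same tracts.
    """
    ref_ids = set(reference.index)
    scen_ids = set(scenario.index)
    if ref_ids != scen_ids:
        diff = sorted(map(str, ref_ids.symmetric_difference(scen_ids)))
        raise ValueError(f"tract sets differ between reference and scenario: {diff}")
    delta = (reference - scenario.reindex(reference.index)).sort_index()
    delta.name = "delta_c"
    return delta


def population_weighted_mean(values: pd.Series, tracts: pd.DataFrame) -> float:
    """Population-weighted mean of per-tract values: sum(pop*v)/sum(pop)."""
    if len(tracts) == 0:
        raise ValueError("cannot take a population-weighted mean of zero tracts")
    validate_tracts(tracts)
    pop = pd.Series(
        tracts["population"].to_numpy(dtype=float),
        index=tracts["tract_id"].to_numpy(),
    )
    aligned = values.reindex(pop.index)
    if aligned.isna().any():
        missing = sorted(map(str, aligned[aligned.isna()].index))
        raise ValueError(f"values missing for tracts: {missing}")
    return float(np.average(aligned.to_numpy(dtype=float), weights=pop.to_numpy()))
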