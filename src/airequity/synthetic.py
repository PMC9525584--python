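"""Synthetic study regions for desk-scale pipeline testing.

Generates a complete region — tract table, gridded baseline PM2.5 field,
per-scenario reduction fields, tract-to-cell weights and scenario costs —
with the statistical structure the downstream analysis assumes:

* tract populations log-normal;
* baseline incidence truncated-normal, floored at 10% of the mean;
* vulnerability scores spanning [0, 100] exactly (a random permutation of
  an even grid of scores), so the top quartile is flagged disadvantaged;
* concentration fields are smoothed white noise (Gaussian kernel, width
  ``smoothing_length`` cells) — no atmospheric physics;
* a tunable Spearman rank-correlation ``benefit_vulnerability_rho`` between
  a tract's vulnerability score and its per-capita concentration reduction.

Vulnerability-benefit coupling mechanism
----------------------------------------
Tract-level reductions are first aggregated from the smoothed random field,
then *reassigned* across tracts: a latent Gaussian variable
``a*z(score) + sqrt(1-a^2)*noise`` with ``a = 2*sin(pi*rho/6)`` (the exact
bivariate-normal inversion of Spearman's rho) ranks the tracts, and the
sorted reduction values are dealt out in that rank order.  Grid cells owned
exclusively by a tract are then shifted by a constant so the tract's
aggregated value matches its reassigned target; tracts that share a cell
with another tract keep the approximate value.  This preserves the field's
spatial texture while hitting the target rank-correlation closely.

Randomness
----------
A single integer seed governs everything.  Sub-streams are spawned from
``numpy.random.SeedSequence(seed)`` in a fixed order (populations,
incidence, scores, tract centers, baseline field, then one per scenario in
sorted-name order), so adding a scenario never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from airequity.exposure import (
    ConcentrationField,
    aggregate_to_tracts,
    validate_tracts,
)

__all__ = [
    "ScenarioSpec",
    "SyntheticRegionSpec",
    "SyntheticRegion",
    "generate_region",
    "write_region",
    "read_region",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One synthetic mitigation scenario.

    ``delta_mean``/``delta_sd`` set the scale of the gridded reduction field
    (ug/m3); ``rho`` overrides the region-level vulnerability-benefit
    rank-correlation target; ``cost`` is the economy-wide incremental annual
    cost (2018 USD/yr).
    """

    delta_mean: float = 0.65
    delta_sd: float = 0.2
    rho: float | None = None
    cost: float = 1.0e10

    def __post_init__(self) -> None:
        # coerce: YAML 1.1 parses bare exponents like "1.0e8" as strings
        for name in ("delta_mean", "delta_sd", "cost"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if self.rho is not None:
            object.__setattr__(self, "rho", float(self.rho))
            if not -1.0 <= self.rho <= 1.0:
                raise ValueError("scenario rho must lie in [-1, 1]")
        if not math.isfinite(self.cost):
            raise ValueError("scenario cost must be finite")


@dataclass(frozen=True)
class SyntheticRegionSpec:
    """Parameters of a synthetic study region."""

    n_tracts: int = 200
    n_counties: int = 8
    grid_rows: int = 30
    grid_cols: int = 30
    pop_log_mean: float = 8.3  # exp(8.3) ~ 4000 people per tract
    pop_log_sd: float = 0.5
    incidence_mean: float = 0.008  # all-cause deaths per person-year
    incidence_sd: float = 0.002
    benefit_vulnerability_rho: float = 0.5
    smoothing_length: float = 3.0
    baseline_mean: float = 10.0
    baseline_sd: float = 2.0
    seed: int = 0
    scenarios: dict[str, ScenarioSpec] | None = None

    def __post_init__(self) -> None:
        if self.n_tracts < 1:
            raise ValueError("n_tracts must be a positive integer")
        if self.n_counties < 1:
            raise ValueError("n_counties must be a positive integer")
        if self.n_counties > self.n_tracts:
            raise ValueError("n_counties must not exceed n_tracts")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid_rows and grid_cols must be >= 1")
        if not -1.0 <= self.benefit_vulnerability_rho <= 1.0:
            raise ValueError("benefit_vulnerability_rho must lie in [-1, 1]")
        if not self.incidence_mean > 0:
            raise ValueError("incidence_mean must be > 0")
        if self.incidence_sd < 0:
            raise ValueError("incidence_sd must be >= 0")
        if self.smoothing_length < 0:
            raise ValueError("smoothing_length must be >= 0")
        if not self.baseline_mean >= 0:
            raise ValueError("baseline_mean must be >= 0")

    def resolved_scenarios(self) -> dict[str, ScenarioSpec]:
        if self.scenarios is not None:
            if not self.scenarios:
                raise ValueError("scenarios mapping must not be empty")
            return dict(self.scenarios)
        return {"scenario": ScenarioSpec(rho=self.benefit_vulnerability_rho)}


@dataclass
class SyntheticRegion:
    """A generated region: tracts, fields, weights, costs and metadata."""

    tracts: pd.DataFrame
    baseline_field: ConcentrationField
    scenario_deltas: dict[str, ConcentrationField]
    scenario_costs: dict[str, float]
    weights: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticRegion):
            return NotImplemented
        return (
            self.tracts.equals(other.tracts)
            and self.baseline_field == other.baseline_field
            and set(self.scenario_deltas) == set(other.scenario_deltas)
            and all(
                self.scenario_deltas[k] == other.scenario_deltas[k]
                for k in self.scenario_deltas
            )
            and self.scenario_costs == other.scenario_costs
            and self.weights.equals(other.weights)
        )


def _smooth_unit_field(
    rng: np.random.Generator, rows: int, cols: int, sigma: float
) -> np.ndarray:
    """Gaussian-smoothed white noise, standardized to mean 0 / sd 1."""
    raw = rng.standard_normal((rows, cols))
    if sigma > 0 and (rows > 1 or cols > 1):
        raw = gaussian_filter(raw, sigma=sigma, mode="reflect")
    sd = raw.std()
    if sd == 0:  # degenerate 1x1 grid or fully flat smooth
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def _tract_cells(
    centers: np.ndarray, rows: int, cols: int
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Assign grid cells to tracts by nearest tract center (cell centres at
    integer + 0.5).  Every tract keeps >= 1 cell: tracts owning no cell fall
    back to the single cell containing their center, shared with its owner.

    Returns the long-format weight table (uniform weights per tract, last
    weight adjusted so the sum is exactly 1.0) and each tract's exclusively
    owned flat cell indices (empty for fallback tracts).
    """
    n = centers.shape[0]
    rr, cc = np.meshgrid(np.arange(rows) + 0.5, np.arange(cols) + 0.5, indexing="ij")
    cell_xy = np.column_stack([rr.ravel(), cc.ravel()])
    # nearest center per cell; ties resolved to the lowest tract index
    d2 = (
        (cell_xy[:, None, 0] - centers[None, :, 0]) ** 2
        + (cell_xy[:, None, 1] - centers[None, :, 1]) ** 2
    )
    owner = np.argmin(d2, axis=1)

    owned: list[np.ndarray] = [np.flatnonzero(owner == i) for i in range(n)]
    recs = []
    for i in range(n):
        cells = owned[i]
        if cells.size == 0:
            r = min(int(centers[i, 0]), rows - 1)
            c = min(int(centers[i, 1]), cols - 1)
            cells = np.array([r * cols + c])
        k = cells.size
        w = np.full(k, 1.0 / k)
        w[-1] = 1.0 - w[:-1].sum()
        for flat, wj in zip(cells, w):
            recs.append((i, flat // cols, flat % cols, wj))
    weights = pd.DataFrame(recs, columns=["tract_idx", "row", "col", "weight"])
    return weights, owned


def _couple_to_scores(
    values: np.ndarray,
    scores: np.ndarray,
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reassign sorted values across tracts so Spearman(score, value) ~= rho.

    Uses the exact bivariate-normal relation rho_s = (6/pi)*asin(a/2): the
    latent ranking variable is ``a*z + sqrt(1-a^2)*eps`` with z the normal
    quantile of the score rank and a = 2*sin(pi*rho/6).
    """
    n = values.size
    if n < 2:
        return values.copy()
    a = 2.0 * math.sin(math.pi * rho / 6.0)
    score_rank = stats.rankdata(scores, method="ordinal") - 1
    z = stats.norm.ppf((score_rank + 0.5) / n)
    latent = a * z + math.sqrt(max(0.0, 1.0 - a * a)) * rng.standard_normal(n)
    latent_rank = stats.rankdata(latent, method="ordinal") - 1
    return np.sort(values)[latent_rank.astype(int)]


def generate_region(spec: SyntheticRegionSpec) -> SyntheticRegion:
    """Generate a synthetic region; bitwise deterministic for a fixed seed."""
    scenarios = spec.resolved_scenarios()
    scen_names = sorted(scenarios)
    ss = np.random.SeedSequence(spec.seed)
    streams = ss.spawn(5 + len(scen_names))
    rng_pop, rng_inc, rng_score, rng_center, rng_base = (
        np.random.default_rng(s) for s in streams[:5]
    )

    n = spec.n_tracts
    population = rng_pop.lognormal(spec.pop_log_mean, spec.pop_log_sd, n)

    floor = 0.1 * spec.incidence_mean
    if spec.incidence_sd > 0:
        a = (floor - spec.incidence_mean) / spec.incidence_sd
        incidence = stats.truncnorm.rvs(
            a, np.inf, loc=spec.incidence_mean, scale=spec.incidence_sd,
            size=n, random_state=rng_inc,
        )
    else:
        incidence = np.full(n, spec.incidence_mean)

    if n > 1:
        scores = (100.0 * rng_score.permutation(n)) / (n - 1)
    else:
        scores = np.array([50.0])

    centers = np.column_stack(
        [
            rng_center.uniform(0, spec.grid_rows, n),
            rng_center.uniform(0, spec.grid_cols, n),
        ]
    )
    weights, owned = _tract_cells(centers, spec.grid_rows, spec.grid_cols)

    # counties: spatially contiguous-ish chunks of the center ordering
    order = np.lexsort((centers[:, 1], centers[:, 0]))
    county_of = np.empty(n, dtype=int)
    for k, chunk in enumerate(np.array_split(order, spec.n_counties)):
        county_of[chunk] = k

    tract_ids = np.array([f"T{i:05d}" for i in range(n)])
    tracts = pd.DataFrame(
        {
            "tract_id": tract_ids,
            "county_id": [f"C{k:03d}" for k in county_of],
            "population": population,
            "incidence_per_person_year": incidence,
            "vulnerability_score": scores,
        }
    )
    validate_tracts(tracts)

    base = _smooth_unit_field(
        rng_base, spec.grid_rows, spec.grid_cols, spec.smoothing_length
    )
    baseline = ConcentrationField(
        np.clip(spec.baseline_mean + spec.baseline_sd * base, 0.0, None)
    )

    wtab = weights.assign(tract_id=tract_ids[weights["tract_idx"].to_numpy()])[
        ["tract_id", "row", "col", "weight"]
    ]

    scenario_deltas: dict[str, ConcentrationField] = {}
    scenario_costs: dict[str, float] = {}
    for name, stream in zip(scen_names, streams[5:]):
        scen = scenarios[name]
        rng_s = np.random.default_rng(stream)
        rho = spec.benefit_vulnerability_rho if scen.rho is None else scen.rho
        grid = scen.delta_mean + scen.delta_sd * _smooth_unit_field(
            rng_s, spec.grid_rows, spec.grid_cols, spec.smoothing_length
        )
        tract_vals = aggregate_to_tracts(
            ConcentrationField(grid, is_delta=True), wtab
        ).reindex(tract_ids).to_numpy()
        targets = _couple_to_scores(tract_vals, scores, rho, rng_s)
        # shift exclusively-owned cells so aggregates hit the targets
        flat = grid.ravel().copy()
        for i in range(n):
            if owned[i].size:
                flat[owned[i]] += targets[i] - tract_vals[i]
        scenario_deltas[name] = ConcentrationField(
            flat.reshape(spec.grid_rows, spec.grid_cols), is_delta=True
        )
        scenario_costs[name] = scen.cost

    return SyntheticRegion(
        tracts=tracts,
        baseline_field=baseline,
        scenario_deltas=scenario_deltas,
        scenario_costs=scenario_costs,
        weights=wtab.reset_index(drop=True),
        metadata={
            "seed": spec.seed,
            "kernel": "gaussian",
            "smoothing_length": spec.smoothing_length,
            "benefit_vulnerability_rho": spec.benefit_vulnerability_rho,
            "scenario_rho": {
                name: (
                    spec.benefit_vulnerability_rho
                    if scenarios[name].rho is None
                    else scenarios[name].rho
                )
                for name in scen_names
            },
            "substreams": [
                "populations",
                "incidence",
                "scores",
                "centers",
                "baseline",
                *[f"scenario:{s}" for s in scen_names],
            ],
        },
    )


def write_region(region: SyntheticRegion, directory) -> dict:
    """Write a region to disk as the pipeline's canonical inputs.

    Emits ``tracts.csv``, ``weights.csv``, ``baseline_pm25.csv``, one
    ``delta_<scenario>.csv`` per scenario, and a ready-to-run
    ``config.yaml``.  Values are written at 17 significant digits so
    read-back reproduces the region exactly.  Returns the manifest mapping
    logical names to paths (also stored as ``manifest.json``).
    """
    from airequity import fileio  # deferred: fileio imports this module's types

    return fileio.write_region_files(region, directory)


def read_region(directory) -> SyntheticRegion:
    """Read back a region written by :func:`write_region`."""
    from airequity import fileio

    return fileio.read_region_files(directory)
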