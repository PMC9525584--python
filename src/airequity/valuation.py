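"""Monetization, cost allocation and net-benefit summaries.

Avoided deaths are valued at a single value of a statistical life (VSL,
default $9.7M in 2018 dollars).  Economy-wide incremental mitigation costs
are allocated equally per capita, so a tract's cost is its population share
of the total.  A tract has a "net benefit" when its cost per life saved is
strictly less than the VSL; tracts with zero or negative avoided deaths get
an infinite cost per life (and hence no net benefit) rather than being
dropped, keeping population shares well defined.

All dollar amounts are a single-year snapshot in 2018$; there is no
discounting or inflation machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from airequity.exposure import validate_tracts

__all__ = [
    "ValuationConfig",
    "monetize",
    "allocate_costs",
    "cost_per_life",
    "tract_valuation",
    "net_benefit_summary",
]

DEFAULT_VSL = 9.7e6  # USD per avoided death, 2018$


@dataclass(frozen=True)
class ValuationConfig:
    """VSL and per-scenario economy-wide incremental annual costs (2018$)."""

    vsl: float = DEFAULT_VSL
    scenario_costs: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.vsl > 0:
            raise ValueError("VSL must be > 0")
        for name, cost in self.scenario_costs.items():
            if not math.isfinite(cost):
                raise ValueError(f"scenario {name}: cost must be finite")


def monetize(avoided_deaths, vsl: float = DEFAULT_VSL):
    """Monetary value of avoided deaths: exact product with the VSL (USD/yr)."""
    if not vsl > 0:
        raise ValueError("VSL must be > 0")
    out = np.asarray(avoided_deaths, dtype=float) * vsl
    if out.ndim == 0:
        return float(out)
    return out


def allocate_costs(total_cost: float, tracts: pd.DataFrame) -> pd.Series:
    """Equal per-capita allocation of an economy-wide cost to tracts.

    Per-capita cost is ``total_cost / sum(population)``; each tract bears
    per-capita times its own population, so allocated costs conserve the
    total exactly up to float rounding.
    """
    validate_tracts(tracts)
    total_pop = float(tracts["population"].sum())
    if not total_pop > 0:
        raise ValueError("total population must be > 0 to allocate costs")
    per_capita = total_cost / total_pop
    out = pd.Series(
        per_capita * tracts["population"].to_numpy(dtype=float),
        index=tracts["tract_id"].to_numpy(),
        name="allocated_cost_usd",
    ).sort_index()
    out.index.name = "tract_id"
    return out


def cost_per_life(tract_cost: float, avoided_deaths: float) -> float:
    """Cost per life saved; ``inf`` sentinel when no deaths are avoided."""
    if tract_cost < 0:
        raise ValueError("tract cost must be >= 0")
    if avoided_deaths <= 0:
        return math.inf
    return tract_cost / avoided_deaths


def tract_valuation(
    impacts: pd.DataFrame,
    tracts: pd.DataFrame,
    total_cost: float,
    vsl: float = DEFAULT_VSL,
) -> pd.DataFrame:
    """Per-tract benefit, allocated cost, cost per life and net-benefit flag.

    Parameters
    ----------
    impacts
        Health impact table with ``tract_id`` and ``avoided_deaths`` columns.
    tracts
        Canonical tract table.
    total_cost
        Scenario economy-wide incremental annual cost (USD/yr).
    vsl
        Value of a statistical life (USD).

    Returns
    -------
    pandas.DataFrame
        Columns ``tract_id, avoided_deaths, benefit_usd, allocated_cost_usd,
        cost_per_life, net_benefit`` sorted by tract_id.  ``net_benefit`` is
        the strict comparison ``cost_per_life < vsl``.
    """
    costs = allocate_costs(total_cost, tracts)
    df = impacts.sort_values("tract_id").reset_index(drop=True)
    deaths = df["avoided_deaths"].to_numpy(dtype=float)
    alloc = costs.reindex(df["tract_id"]).to_numpy(dtype=float)
    cpl = np.full_like(alloc, np.inf)
    np.divide(alloc, deaths, out=cpl, where=deaths > 0)
    return pd.DataFrame(
        {
            "tract_id": df["tract_id"],
            "avoided_deaths": deaths,
            "benefit_usd": monetize(deaths, vsl),
            "allocated_cost_usd": alloc,
            "cost_per_life": cpl,
            "net_benefit": cpl < vsl,
        }
    )


def net_benefit_summary(
    valuations: pd.DataFrame,
    tracts: pd.DataFrame,
    dac_flags: pd.Series,
) -> dict:
    """Summarize net-benefit incidence and statewide totals.

    Population shares weight each qualifying tract by its population (the
    alternative - counting only people in qualifying tracts - is identical
    here because whole tracts qualify or not).

    Returns a dict with keys ``pop_share_net_benefit``,
    ``tract_share_net_benefit``, ``dac_share_net_benefit`` (percent, 0-100;
    the DAC share is NaN when there are no DAC tracts),
    ``total_benefit_usd``, ``total_cost_usd``, ``net_benefit_usd``.
    """
    validate_tracts(tracts)
    df = valuations.merge(
        tracts[["tract_id", "population"]], on="tract_id", validate="one_to_one"
    )
    if len(df) != len(tracts):
        raise ValueError("valuation and tract tables do not cover the same tracts")
    dac = dac_flags.reindex(df["tract_id"]).to_numpy(dtype=bool)
    nb = df["net_benefit"].to_numpy(dtype=bool)
    pop = df["population"].to_numpy(dtype=float)

    pop_share = 100.0 * float(pop[nb].sum() / pop.sum())
    tract_share = 100.0 * float(nb.mean())
    n_dac = int(dac.sum())
    dac_share = 100.0 * float(nb[dac].mean()) if n_dac else float("nan")
    total_benefit = float(df["benefit_usd"].sum())
    total_cost = float(df["allocated_cost_usd"].sum())
    return {
        "pop_share_net_benefit": pop_share,
        "tract_share_net_benefit": tract_share,
        "dac_share_net_benefit": dac_share,
        "n_dac_tracts": n_dac,
        "total_benefit_usd": total_benefit,
        "total_cost_usd": total_cost,
        "net_benefit_usd": total_benefit - total_cost,
    }
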