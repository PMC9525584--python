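"""Lorenz-curve / Suits-Index equity assessment of benefit distributions.

Tracts are ordered by ascending vulnerability score (ties broken by
tract_id, for determinism); the Lorenz curve plots cumulative benefit share
against cumulative population share.  The Suits Index is

    S = (K - L) / K,    K = 0.5,

with L the trapezoid area under the piecewise-linear discrete curve.  A
curve below the proportionality line (benefits concentrated in high-score,
disadvantaged tracts) gives S > 0; S = 0 is exact proportionality.  For
nonnegative benefits S lies in [-1, 1].  Negative tract benefits are kept
as signed increments (the curve can locally decrease); the [-1, 1] bound
then no longer applies and results carry a warning flag.

County decomposition renormalizes population and benefit shares within each
county, so a county's index measures within-county progressivity only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from airequity.exposure import validate_tracts

__all__ = [
    "DAC_THRESHOLD",
    "LorenzCurve",
    "SuitsResult",
    "DispersityResult",
    "classify_dac",
    "lorenz_curve",
    "suits_index",
    "suits_for_tracts",
    "suits_by_county",
    "scenario_delta_equity",
    "dispersity",
]

#: Vulnerability score at or above which a tract is a disadvantaged community.
DAC_THRESHOLD = 75.0


def classify_dac(score) -> bool | np.ndarray:
    """True iff the vulnerability score is >= 75 (top-quartile screening rank)."""
    arr = np.asarray(score, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("vulnerability scores must lie in [0, 100]")
    out = arr >= DAC_THRESHOLD
    if out.ndim == 0:
        return bool(out)
    return out


@dataclass(frozen=True)
class LorenzCurve:
    """Discrete Lorenz curve: (cumulative population, cumulative benefit).

    ``points`` is an (n+1, 2) array starting at (0, 0) and ending at (1, 1)
    up to rounding; x is nondecreasing.  ``has_negative`` flags negative
    benefit increments (curve may locally decrease in y).
    """

    points: np.ndarray
    ordering_key: str = "vulnerability_score, ties by tract_id"
    has_negative: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("curve needs an (n+1, 2) array of points")
        if not np.allclose(pts[0], [0.0, 0.0]):
            raise ValueError("curve must start at (0, 0)")
        if abs(pts[-1, 0] - 1.0) > 1e-9 or abs(pts[-1, 1] - 1.0) > 1e-9:
            raise ValueError("curve must end at (1, 1)")
        if np.any(np.diff(pts[:, 0]) < -1e-12):
            raise ValueError("cumulative population must be nondecreasing")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class SuitsResult:
    """Suits Index for a tract subset (statewide or one county)."""

    suits_index: float | None
    scope: str
    n_tracts: int
    total_benefit: float
    warning: str | None = None


@dataclass(frozen=True)
class DispersityResult:
    """Population standard deviation of min-max normalized tract benefits."""

    sigma: float


def _align_benefits(tracts: pd.DataFrame, benefits: pd.Series) -> pd.DataFrame:
    validate_tracts(tracts)
    df = tracts.copy()
    b = benefits.reindex(df["tract_id"])
    if b.isna().any():
        missing = sorted(map(str, b[b.isna()].index))
        raise ValueError(f"benefits missing for tracts: {missing}")
    df["benefit"] = b.to_numpy(dtype=float)
    return df


def lorenz_curve(tracts: pd.DataFrame, benefits: pd.Series) -> LorenzCurve:
    """Lorenz curve of benefits ordered by ascending vulnerability score.

    ``benefits`` is indexed by tract_id (deaths/yr or USD/yr; the curve is
    scale invariant).  Raises if the total benefit is zero, where the curve
    is undefined.
    """
    if len(tracts) == 0:
        raise ValueError("lorenz_curve requires at least one tract")
    df = _align_benefits(tracts, benefits)
    # sort before any summation so results are bitwise independent of the
    # input row order (cumulative float sums are order-sensitive)
    df = df.sort_values(["vulnerability_score", "tract_id"], kind="mergesort")
    x = np.concatenate(
        [[0.0], np.cumsum(df["population"].to_numpy(dtype=float))]
    )
    y = np.concatenate([[0.0], np.cumsum(df["benefit"].to_numpy(dtype=float))])
    if y[-1] == 0:
        raise ValueError("total benefit is zero; Lorenz curve undefined")
    x /= x[-1]
    y /= y[-1]
    x[-1] = 1.0
    y[-1] = 1.0
    neg = bool((df["benefit"].to_numpy() < 0).any())
    return LorenzCurve(points=np.column_stack([x, y]), has_negative=neg)


def suits_index(
    curve: LorenzCurve, scope: str = "state", total_benefit: float = float("nan")
) -> SuitsResult:
    """Suits Index S = (K - L)/K with K = 0.5 and L the trapezoid area.

    Positive S means benefits are concentrated in high-score (disadvantaged)
    tracts.  When the curve has negative increments the documented [-1, 1]
    bound does not apply and the result carries a warning.
    """
    pts = curve.points
    L = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    K = 0.5
    s = (K - L) / K
    warning = None
    if curve.has_negative:
        warning = "negative benefit increments: Suits Index may fall outside [-1, 1]"
    return SuitsResult(
        suits_index=s,
        scope=scope,
        n_tracts=pts.shape[0] - 1,
        total_benefit=total_benefit,
        warning=warning,
    )


def suits_for_tracts(
    tracts: pd.DataFrame, benefits: pd.Series, scope: str = "state"
) -> SuitsResult:
    """Convenience wrapper: Lorenz curve plus Suits Index for one tract set."""
    df = _align_benefits(tracts, benefits)
    ordered = df.sort_values(["vulnerability_score", "tract_id"], kind="mergesort")
    total = float(np.cumsum(ordered["benefit"].to_numpy(dtype=float))[-1])
    if total == 0:
        return SuitsResult(
            suits_index=None,
            scope=scope,
            n_tracts=len(df),
            total_benefit=0.0,
            warning="zero total benefit: Suits Index undefined",
        )
    curve = lorenz_curve(tracts, benefits)
    return suits_index(curve, scope=scope, total_benefit=total)


def suits_by_county(tracts: pd.DataFrame, benefits: pd.Series) -> list[SuitsResult]:
    """Within-county Suits Index for every county, sorted by county id.

    Shares are renormalized inside each county, so a county's index is
    independent of how its total benefit compares with its population share.
    Counties with zero total benefit get a null index and a warning flag.
    """
    validate_tracts(tracts)
    if tracts["county_id"].isna().any():
        raise ValueError("every tract needs a county id")
    out = []
    for county, sub in tracts.groupby("county_id", sort=True):
        out.append(
            suits_for_tracts(sub, benefits.reindex(sub["tract_id"]), scope=str(county))
        )
    return out


def scenario_delta_equity(
    results_a: pd.DataFrame, results_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-county differences A - B in avoided deaths and Suits Index.

    Inputs are frames indexed by county id with columns ``avoided_deaths``
    and ``suits_index``.  A negative Suits delta means scenario B allocates
    benefits more towards disadvantaged communities than scenario A.
    """
    a_ids = set(results_a.index)
    b_ids = set(results_b.index)
    if a_ids != b_ids:
        diff = sorted(map(str, a_ids.symmetric_difference(b_ids)))
        raise ValueError(f"county sets differ between scenarios: {diff}")
    b = results_b.reindex(results_a.index)
    out = pd.DataFrame(
        {
            "delta_avoided_deaths": results_a["avoided_deaths"] - b["avoided_deaths"],
            "delta_suits_index": results_a["suits_index"] - b["suits_index"],
        },
        index=results_a.index,
    ).sort_index()
    out.index.name = "county_id"
    return out


def dispersity(benefits: pd.Series | np.ndarray) -> DispersityResult:
    """Spread of min-max normalized tract benefits.

    Benefits are rescaled to [0, 1] by (b - min)/(max - min) and the
    population (divisor n) standard deviation returned.  Constant benefits
    normalize to an all-zero vector, giving sigma = 0.  Scale and shift
    invariant by construction.
    """
    arr = np.asarray(benefits, dtype=float)
    if arr.size < 2:
        raise ValueError("dispersity requires at least two tracts")
    if not np.all(np.isfinite(arr)):
        raise ValueError("benefits contain non-finite values")
    span = arr.max() - arr.min()
    if span == 0:
        return DispersityResult(sigma=0.0)
    norm = (arr - arr.min()) / span
    return DispersityResult(sigma=float(norm.std(ddof=0)))
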