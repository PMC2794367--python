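"""Direct age-standardisation, proportions, moving averages, rate contrasts.

The directly standardised rate over age bands s with standard weights w_s,
observed deaths d_s and person-years n_s is

    rate = 1e5 * sum_s w_s * d_s / n_s

with the usual Poisson variance approximation

    var  = 1e5**2 * sum_s w_s**2 * d_s / n_s**2 .

Proportions use the Wilson score interval, which behaves well in the sparse
cells that arise when a method is still rare in a stratum.  Rate contrasts
use normal-approximation intervals on the difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IncompleteStrataError, InvalidArgumentError
from .graph import AreaGraph
from .standards import StandardPopulation

PER = 100_000.0


@dataclass(frozen=True)
class StandardisedRate:
    rate: float       # per 100,000 person-years
    variance: float   # on the same (per 100,000) scale

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(self.variance)
        return (self.rate - half, self.rate + half)


def direct_standardised_rate(
    deaths_by_band,
    pyears_by_band,
    standard: StandardPopulation,
) -> StandardisedRate:
    """Directly age-standardised rate per 100,000 with Poisson variance.

    ``deaths_by_band`` / ``pyears_by_band`` are mappings or Series indexed
    by age band.  Every band with positive standard weight must have
    positive person-years; bands with zero weight may be absent.
    """
    d = pd.Series(deaths_by_band, dtype=float)
    n = pd.Series(pyears_by_band, dtype=float)
    rate = 0.0
    var = 0.0
    for band, w in standard.weights.items():
        if w == 0:
            continue
        if band not in n.index or n.get(band, 0.0) <= 0:
            raise IncompleteStrataError(
                f"band {band!r} has standard weight {w:.4g} but no person-years"
            )
        db = float(d.get(band, 0.0))
        if db < 0:
            raise InvalidArgumentError(f"negative deaths in band {band!r}")
        nb = float(n[band])
        rate += w * db / nb
        var += w * w * db / (nb * nb)
    return StandardisedRate(rate=PER * rate, variance=PER * PER * var)


def proportion_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float, float]:
    """Proportion k/n with a Wilson score interval.

    Returns (proportion, lower, upper) on the 0-1 scale.
    """
    if n <= 0:
        raise InvalidArgumentError("n must be > 0")
    if not 0 <= k <= n:
        raise InvalidArgumentError("need 0 <= k <= n")
    z = stats.norm.ppf(0.5 + level / 2)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if k == 0 else max(0.0, centre - half)   # boundary cases are exact
    hi = 1.0 if k == n else min(1.0, centre + half)
    return (p, lo, hi)


def moving_average(series: pd.Series, window: int = 3) -> pd.DataFrame:
    """Centred moving average over consecutive years.

    Endpoints use a shrinking window (only the years that exist) and are
    flagged in the ``partial`` column.  The index must be consecutive
    integer years.
    """
    if window < 1:
        raise InvalidArgumentError("window must be >= 1")
    if len(series) < window:
        raise InvalidArgumentError("window longer than series")
    years = np.asarray(series.index, dtype=int)
    if len(years) > 1 and not np.all(np.diff(years) == 1):
        raise InvalidArgumentError("series years must be consecutive")
    half = (window - 1) // 2
    upper = window - 1 - half
    vals = series.to_numpy(dtype=float)
    out, partial = [], []
    for i in range(len(vals)):
        lo, hi = max(0, i - half), min(len(vals), i + upper + 1)
        out.append(vals[lo:hi].mean())
        partial.append(hi - lo < window)
    return pd.DataFrame({"value": out, "partial": partial}, index=series.index)


def rate_difference_ci(
    rate_a: float, var_a: float, rate_b: float, var_b: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Difference rate_a - rate_b with a normal-approximation CI."""
    if var_a < 0 or var_b < 0:
        raise InvalidArgumentError("variances must be >= 0")
    z = stats.norm.ppf(0.5 + level / 2)
    diff = rate_a - rate_b
    half = z * np.sqrt(var_a + var_b)
    return (diff, diff - half, diff + half)


# ---------------------------------------------------------------------------
# Table-1-style summary: rates and new-method proportions by sex x level x period
# ---------------------------------------------------------------------------

def table1(
    counts: pd.DataFrame,
    graph: AreaGraph,
    periods: list[tuple[int, int]],
    standard: StandardPopulation,
) -> pd.DataFrame:
    """Per sex x urbanisation level x period: standardised all-method and
    new-method rates, and new-method proportions with Wilson CIs.

    ``periods`` is a list of inclusive (start_year, end_year) tuples.
    """
    levels = graph.subset_levels()
    level_of = dict(zip(graph.area_ids, levels))
    missing = set(counts["area_id"]) - set(graph.area_ids)
    if missing:
        raise InvalidArgumentError(f"areas without urbanisation level: {sorted(missing)[:5]}")
    df = counts.copy()
    df["level"] = df["area_id"].map(level_of)
    rows = []
    for start, end in periods:
        sub = df[(df["year"] >= start) & (df["year"] <= end)]
        for sex in sorted(sub["sex"].unique()):
            ssub = sub[sub["sex"] == sex]
            for level in sorted(ssub["level"].unique()):
                cell = ssub[ssub["level"] == level]
                pooled = cell.groupby("age_band")[["deaths", "person_years"]].sum()
                # person-years are duplicated across the method rows of a stratum
                py = (
                    cell.drop_duplicates(subset=["area_id", "year", "sex", "age_band"])
                    .groupby("age_band")["person_years"].sum()
                )
                all_rate = direct_standardised_rate(pooled["deaths"], py, standard)
                cb = cell[cell["method"] == "charcoal"].groupby("age_band")["deaths"].sum()
                cb_rate = direct_standardised_rate(cb, py, standard)
                k = int(cb.sum())
                n = int(pooled["deaths"].sum())
                if n > 0:
                    p, lo, hi = proportion_ci(k, n)
                else:
                    p = lo = hi = np.nan
                rows.append({
                    "period": f"{start}-{end}", "sex": sex, "level": int(level),
                    "rate_all": all_rate.rate, "var_all": all_rate.variance,
                    "rate_charcoal": cb_rate.rate, "var_charcoal": cb_rate.variance,
                    "deaths_charcoal": k, "deaths_all": n,
                    "prop_charcoal": p, "prop_lo": lo, "prop_hi": hi,
                })
    return pd.DataFrame(rows)
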