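"""Indirect standardisation: expected deaths and raw SMRs per area.

Expected deaths in area i are obtained by applying national sex- and
age-specific rates (pooled over the analysis period) to the area's
person-years in the same strata:

    E_i = sum_s rate_s * pyears_{i,s}

and SMR_i = O_i / E_i.  When the reference rates are computed from the same
counts, sum_i E_i equals sum_i O_i (closure), so the E-weighted mean SMR is 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError


def national_reference_rates(
    counts: pd.DataFrame, period: tuple[int, int], method: str | None = None
) -> pd.DataFrame:
    """Pooled deaths/person-years per sex x age band over an inclusive period.

    Returns a DataFrame indexed by (sex, age_band) with columns
    ``deaths, person_years, rate`` (rate per person-year).
    """
    start, end = period
    sub = counts[(counts["year"] >= start) & (counts["year"] <= end)]
    if sub.empty:
        raise InvalidArgumentError(f"no data in period {start}-{end}")
    if method is not None:
        deaths = sub[sub["method"] == method].groupby(["sex", "age_band"])["deaths"].sum()
    else:
        deaths = sub.groupby(["sex", "age_band"])["deaths"].sum()
    py = (
        sub.drop_duplicates(subset=["area_id", "year", "sex", "age_band"])
        .groupby(["sex", "age_band"])["person_years"].sum()
    )
    out = pd.DataFrame({"deaths": deaths.reindex(py.index, fill_value=0), "person_years": py})
    out["rate"] = out["deaths"] / out["person_years"]
    return out


def expected_deaths(
    counts: pd.DataFrame,
    reference: pd.DataFrame,
    period: tuple[int, int],
) -> pd.DataFrame:
    """Expected deaths per area x sex: E_i = sum_s rate_s * pyears_{i,s}.

    Areas whose person-years are all zero in the covered strata receive
    E = 0 and are flagged for exclusion downstream (with a warning).
    """
    start, end = period
    sub = counts[(counts["year"] >= start) & (counts["year"] <= end)]
    py = (
        sub.drop_duplicates(subset=["area_id", "year", "sex", "age_band"])
        .groupby(["area_id", "sex", "age_band"])["person_years"].sum()
        .reset_index()
    )
    rate = reference["rate"]
    missing = [
        key for key in py.set_index(["sex", "age_band"]).index.unique()
        if key not in rate.index
    ]
    if missing:
        raise InvalidArgumentError(f"strata missing from reference rates: {missing[:5]}")
    py["expected"] = py["person_years"] * rate.loc[
        pd.MultiIndex.from_frame(py[["sex", "age_band"]])
    ].to_numpy()
    E = py.groupby(["area_id", "sex"])["expected"].sum().reset_index()
    zero = E["expected"] <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} area/sex cell(s) with zero expected deaths; excluded")
    return E.rename(columns={"expected": "E"})


def observed_deaths(
    counts: pd.DataFrame, period: tuple[int, int], method: str | None = None
) -> pd.DataFrame:
    start, end = period
    sub = counts[(counts["year"] >= start) & (counts["year"] <= end)]
    if method is not None:
        sub = sub[sub["method"] == method]
    O = sub.groupby(["area_id", "sex"])["deaths"].sum().reset_index()
    return O.rename(columns={"deaths": "O"})


def compute_smr(O: pd.DataFrame, E: pd.DataFrame) -> pd.DataFrame:
    """Join observed and expected deaths and compute raw SMRs.

    Areas with E <= 0 are dropped (no population at risk in the covered
    strata); areas with O = 0 are retained with SMR 0.
    """
    tab = E.merge(O, on=["area_id", "sex"], how="left")
    tab["O"] = tab["O"].fillna(0).astype(int)
    dropped = tab["E"] <= 0
    if dropped.any():
        warnings.warn(f"dropping {int(dropped.sum())} cell(s) with E <= 0")
        tab = tab[~dropped].copy()
    tab["smr_raw"] = tab["O"] / tab["E"]
    return tab.reset_index(drop=True)[["area_id", "sex", "O", "E", "smr_raw"]]


def smr_table(
    counts: pd.DataFrame,
    period: tuple[int, int],
    sex: str,
    method: str = "charcoal",
) -> pd.DataFrame:
    """One-call SMR table for a sex and method group over an analysis period.

    Reference rates are sex- and age-specific national rates for the same
    method group, pooled over the period from the counts themselves, so the
    closure property sum(E) == sum(O) holds by construction.
    """
    ref = national_reference_rates(counts, period, method=method)
    scounts = counts[counts["sex"] == sex]
    E = expected_deaths(scounts, ref, period)
    O = observed_deaths(scounts, period, method=method)
    tab = compute_smr(O, E)
    total_E = tab["E"].sum()
    if total_E > 0:
        # guard against stratum misalignment: closure must hold
        closure = tab["O"].sum() / total_E
        if not np.isfinite(closure):
            raise InvalidArgumentError("non-finite SMR closure")
    return tab
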