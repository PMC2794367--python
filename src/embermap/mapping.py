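"""Choropleth classification of SMRs and urban-rural secular trends.

SMRs are classed into five categories symmetric on the log scale around a
middle class of 0.9-1.1 (shown white on maps); one log-step of r = 1.1/0.9
on each side gives the outer breaks 0.9^2/1.1 ~ 0.736 and 1.1^2/0.9 ~ 1.344.
Classes below the middle are blue, above are red (divergent 5-class
red-blue scheme).  The classification, not the plot, is the source of
truth; plotting is a thin consumer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .graph import AreaGraph
from .io_formats import write_geojson
from .rates import direct_standardised_rate, moving_average, rate_difference_ci
from .standards import StandardPopulation

# 5-class divergent red-blue (dark blue .. white .. dark red)
COLOUR_TOKENS = (
    ("dark_blue", "#0571b0"),
    ("light_blue", "#92c5de"),
    ("white", "#f7f7f7"),
    ("light_red", "#f4a582"),
    ("dark_red", "#ca0020"),
)
NO_DATA_TOKEN = ("no_data", "#bdbdbd")


@dataclass(frozen=True)
class MapBreaks:
    """Break points c1 < c2 < c3 < c4 bounding the five classes.

    Log-symmetry requires c1*c4 == c2*c3; the middle class [c2, c3] is
    closed at both ends, the others half-open.
    """
    c1: float
    c2: float = 0.9
    c3: float = 1.1
    c4: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "c4", self.c4 or self.c2 * self.c3 / self.c1)
        if not (0 < self.c1 < self.c2 < self.c3 < self.c4):
            raise InvalidArgumentError("breaks must satisfy 0 < c1 < c2 < c3 < c4")
        if abs(self.c1 * self.c4 - self.c2 * self.c3) > 1e-9:
            raise InvalidArgumentError("breaks are not symmetric on the log scale")


def default_breaks(middle: tuple[float, float] = (0.9, 1.1)) -> MapBreaks:
    lo, hi = middle
    r = hi / lo
    return MapBreaks(c1=lo / r, c2=lo, c3=hi, c4=hi * r)


def classify_smr(values, breaks: MapBreaks | None = None) -> pd.DataFrame:
    """Assign each positive SMR to one of five classes (1 = lowest).

    Intervals: [0,c1), [c1,c2), [c2,c3], (c3,c4], (c4,inf).
    """
    x = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise InvalidArgumentError("SMRs must be positive and finite")
    b = breaks or default_breaks()
    cls = np.full(x.shape, 3, dtype=int)
    cls[x < b.c1] = 1
    cls[(x >= b.c1) & (x < b.c2)] = 2
    cls[(x > b.c3) & (x <= b.c4)] = 4
    cls[x > b.c4] = 5
    names = np.array([t[0] for t in COLOUR_TOKENS])
    hexes = np.array([t[1] for t in COLOUR_TOKENS])
    return pd.DataFrame({
        "smr": x,
        "class": cls,
        "colour": names[cls - 1],
        "hex": hexes[cls - 1],
    })


def export_choropleth(
    classification: pd.DataFrame,
    graph: AreaGraph,
    path,
    image_path=None,
) -> None:
    """Write the classified map as GeoJSON (plus an optional PNG).

    ``classification`` must carry an ``area_id`` column; areas of the graph
    absent from it are emitted with the no-data token.  Without polygon
    geometry, a CSV is written instead with a warning.
    """
    if "area_id" not in classification.columns:
        raise InvalidArgumentError("classification needs an area_id column")
    cls = classification.set_index("area_id")
    rows = []
    for a in graph.area_ids:
        if a in cls.index:
            r = cls.loc[a]
            rows.append({"area_id": a, "smr": float(r["smr"]), "class": int(r["class"]),
                         "colour": r["colour"], "hex": r["hex"]})
        else:
            rows.append({"area_id": a, "smr": None, "class": None,
                         "colour": NO_DATA_TOKEN[0], "hex": NO_DATA_TOKEN[1]})
    props = pd.DataFrame(rows)
    if graph.polygons is None:
        warnings.warn("graph has no geometry; writing CSV instead of GeoJSON")
        props.to_csv(str(path).rsplit(".", 1)[0] + ".csv", index=False)
        return
    write_geojson(graph, props, path)
    if image_path is not None:
        _plot_choropleth(graph, props, image_path)


def _plot_choropleth(graph: AreaGraph, props: pd.DataFrame, image_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon

    fig, ax = plt.subplots(figsize=(6, 6))
    lut = props.set_index("area_id")["hex"]
    for a in graph.area_ids:
        ring = graph.polygons[a][0]
        ax.add_patch(MplPolygon(ring, closed=True, facecolor=lut[a],
                                edgecolor="0.6", linewidth=0.2))
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(image_path, dpi=150, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# urban / rural secular trends
# ---------------------------------------------------------------------------

def urban_rural_trends(
    counts: pd.DataFrame,
    graph: AreaGraph,
    standard: StandardPopulation,
    window: int = 3,
) -> pd.DataFrame:
    """Sex-specific standardised-rate series for urban vs rural areas.

    For each sex x {urban, rural} x {overall, charcoal, non_charcoal} the
    yearly directly standardised rate is computed and smoothed with a
    centred ``window``-year moving average (shrinking at the endpoints).
    Returns a long DataFrame with columns sex, stratum, method_group, year,
    rate, variance, rate_smooth, partial.
    """
    levels = graph.subset_levels()
    urban_of = {a: (lv in graph.URBAN_LEVELS) for a, lv in zip(graph.area_ids, levels)}
    df = counts.copy()
    df["stratum"] = df["area_id"].map(urban_of).map({True: "urban", False: "rural"})
    if df["stratum"].isna().any():
        raise InvalidArgumentError("some areas lack an urbanisation level")
    out = []
    for sex in sorted(df["sex"].unique()):
        for stratum in ("urban", "rural"):
            cell = df[(df["sex"] == sex) & (df["stratum"] == stratum)]
            for group, sel in (
                ("overall", cell),
                ("charcoal", cell[cell["method"] == "charcoal"]),
                ("non_charcoal", cell[cell["method"] == "non_charcoal"]),
            ):
                yearly = {}
                for year, ysub in sel.groupby("year"):
                    d = ysub.groupby("age_band")["deaths"].sum()
                    n = (
                        cell[cell["year"] == year]
                        .drop_duplicates(subset=["area_id", "age_band"])
                        .groupby("age_band")["person_years"].sum()
                    )
                    sr = direct_standardised_rate(d, n, standard)
                    yearly[year] = (sr.rate, sr.variance)
                years = sorted(yearly)
                series = pd.Series({y: yearly[y][0] for y in years})
                sm = moving_average(series, window=window)
                for y in years:
                    out.append({
                        "sex": sex, "stratum": stratum, "method_group": group,
                        "year": y, "rate": yearly[y][0], "variance": yearly[y][1],
                        "rate_smooth": sm.loc[y, "value"],
                        "partial": bool(sm.loc[y, "partial"]),
                    })
    return pd.DataFrame(out)


def rural_urban_differences(
    counts: pd.DataFrame,
    graph: AreaGraph,
    standard: StandardPopulation,
    periods: list[tuple[int, int]],
    method_group: str = "overall",
    level: float = 0.95,
) -> pd.DataFrame:
    """Rural minus urban standardised-rate difference per sex and period.

    Rates are computed on the pooled person-years of each inclusive period
    (the scale on which headline contrasts such as the peak rural excess
    are usually reported), with normal-approximation CIs.
    """
    levels = graph.subset_levels()
    urban_of = {a: (lv in graph.URBAN_LEVELS) for a, lv in zip(graph.area_ids, levels)}
    df = counts.copy()
    df["stratum"] = df["area_id"].map(urban_of).map({True: "urban", False: "rural"})
    if method_group != "overall":
        df = df[df["method"] == method_group]
    rows = []
    for start, end in periods:
        sub = df[(df["year"] >= start) & (df["year"] <= end)]
        for sex in sorted(sub["sex"].unique()):
            cell = sub[sub["sex"] == sex]
            res = {}
            for stratum in ("rural", "urban"):
                s = cell[cell["stratum"] == stratum]
                d = s.groupby("age_band")["deaths"].sum()
                n = (
                    s.drop_duplicates(subset=["area_id", "year", "age_band"])
                    .groupby("age_band")["person_years"].sum()
                )
                res[stratum] = direct_standardised_rate(d, n, standard)
            diff, lo, hi = rate_difference_ci(
                res["rural"].rate, res["rural"].variance,
                res["urban"].rate, res["urban"].variance, level=level,
            )
            rows.append({
                "period": f"{start}-{end}", "sex": sex,
                "rate_rural": res["rural"].rate, "rate_urban": res["urban"].rate,
                "difference": diff, "diff_lo": lo, "diff_hi": hi,
            })
    return pd.DataFrame(rows)
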