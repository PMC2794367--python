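"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
- stratified counts: CSV with columns
  ``area_id, year, sex, age_band, method, deaths, person_years``
- adjacency: GAL neighbour-list files (the contiguity format of the GeoDa
  ecosystem) plus a companion attribute CSV (``area_id, urban_level,
  population``)
- maps: GeoJSON FeatureCollections with per-area properties
- configs: YAML

Parsers validate and reject rather than coerce: duplicate keys, negative
deaths, non-positive person-years and dangling neighbour ids are errors.
Asymmetric GAL adjacency and self-loops are repaired with a warning since
hand-edited neighbour files commonly contain them.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .errors import ParseError, SchemaError
from .graph import AreaGraph

COUNT_COLUMNS = ["area_id", "year", "sex", "age_band", "method", "deaths", "person_years"]
KEY_COLUMNS = ["area_id", "year", "sex", "age_band", "method"]
METHODS = ("charcoal", "non_charcoal")
SEXES = ("male", "female")


# ---------------------------------------------------------------------------
# stratified counts
# ---------------------------------------------------------------------------

def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a stratified-counts table, returning a normalised copy."""
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    df = df[COUNT_COLUMNS].copy()
    df["area_id"] = df["area_id"].astype(str)
    df["year"] = df["year"].astype(int)
    bad_method = ~df["method"].isin(METHODS)
    if bad_method.any():
        row = df.index[bad_method][0]
        raise SchemaError(f"row {row}: method must be one of {METHODS}")
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        row = df.index[bad_sex][0]
        raise SchemaError(f"row {row}: sex must be one of {SEXES}")
    deaths = pd.to_numeric(df["deaths"], errors="coerce")
    if deaths.isna().any() or (deaths < 0).any() or (deaths % 1 != 0).any():
        row = df.index[deaths.isna() | (deaths < 0) | (deaths % 1 != 0)][0]
        raise SchemaError(f"row {row}: deaths must be a non-negative integer")
    df["deaths"] = deaths.astype(int)
    py = pd.to_numeric(df["person_years"], errors="coerce")
    if py.isna().any() or (py <= 0).any():
        row = df.index[py.isna() | (py <= 0)][0]
        raise SchemaError(f"row {row}: person_years must be > 0")
    df["person_years"] = py.astype(float)
    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        row = df.index[dup][0]
        raise SchemaError(f"row {row}: duplicate stratum key {tuple(df.loc[row, KEY_COLUMNS])}")
    return df.reset_index(drop=True)


def read_counts(path) -> pd.DataFrame:
    """Read and validate a stratified mortality counts CSV."""
    df = pd.read_csv(path, comment="#")
    return validate_counts(df)


def write_counts(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    df = validate_counts(df)
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# GAL adjacency
# ---------------------------------------------------------------------------

def read_gal(path) -> dict[str, list[str]]:
    """Parse a GAL neighbour file into symmetric neighbour lists.

    The header line carries the area count (possibly as the second of four
    tokens, GeoDa style).  Each area contributes an ``id degree`` line and a
    line of neighbour ids.  Ids are kept as opaque strings; whether they are
    0- or 1-based integers is irrelevant because all joins are by id.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ParseError("empty GAL file")
    header = lines[0].split()
    try:
        n = int(header[1]) if len(header) >= 2 else int(header[0])
    except ValueError as e:
        raise ParseError(f"bad GAL header: {lines[0]!r}") from e
    nb: dict[str, list[str]] = {}
    pos = 1
    for _ in range(n):
        if pos >= len(lines):
            raise ParseError("truncated GAL file")
        head = lines[pos].split()
        if len(head) != 2:
            raise ParseError(f"bad GAL record header: {lines[pos]!r}")
        area, deg = head[0], int(head[1])
        pos += 1
        if deg > 0:
            if pos >= len(lines):
                raise ParseError(f"missing neighbour line for area {area!r}")
            neigh = lines[pos].split()
            pos += 1
        else:
            neigh = []
        if len(neigh) != deg:
            raise ParseError(f"area {area!r}: declared degree {deg}, got {len(neigh)} neighbours")
        nb[area] = neigh
    # dangling ids are an error; self-loops and asymmetries are repaired
    for a, lst in nb.items():
        for b in lst:
            if b not in nb:
                raise ParseError(f"area {a!r} lists unknown neighbour {b!r}")
    cleaned: dict[str, list[str]] = {}
    for a, lst in nb.items():
        if a in lst:
            warnings.warn(f"GAL: area {a!r} listed itself; self-loop removed")
            lst = [b for b in lst if b != a]
        cleaned[a] = sorted(set(lst))
    for a in list(cleaned):
        for b in cleaned[a]:
            if a not in cleaned[b]:
                warnings.warn(f"GAL: asymmetric pair ({a!r}, {b!r}); symmetrised")
                cleaned[b] = sorted(set(cleaned[b]) | {a})
    return cleaned


def write_gal(neighbours: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(neighbours)}\n")
        for a in neighbours:
            lst = neighbours[a]
            fh.write(f"{a} {len(lst)}\n")
            if lst:
                fh.write(" ".join(lst) + "\n")


def read_graph(gal_path, attrs_path=None) -> AreaGraph:
    """Assemble an AreaGraph from a GAL file and optional attribute CSV."""
    nb = read_gal(gal_path)
    urban = pop = None
    if attrs_path is not None:
        attrs = pd.read_csv(attrs_path, comment="#")
        if "area_id" not in attrs.columns:
            raise SchemaError("attribute table needs an area_id column")
        attrs["area_id"] = attrs["area_id"].astype(str)
        attrs = attrs.set_index("area_id")
        if "urban_level" in attrs.columns:
            urban = attrs["urban_level"].astype(int).to_dict()
        if "population" in attrs.columns:
            pop = attrs["population"].astype(float).to_dict()
    return AreaGraph(list(nb), nb, urban_level=urban, population=pop)


def write_graph(graph: AreaGraph, gal_path, attrs_path=None) -> None:
    write_gal({a: graph.neighbours[a] for a in graph.area_ids}, gal_path)
    if attrs_path is not None:
        rec = {"area_id": graph.area_ids}
        if graph.urban_level is not None:
            rec["urban_level"] = [graph.urban_level[a] for a in graph.area_ids]
        if graph.population is not None:
            rec["population"] = [graph.population[a] for a in graph.area_ids]
        pd.DataFrame(rec).to_csv(attrs_path, index=False)


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

def write_geojson(graph: AreaGraph, properties: pd.DataFrame | None, path) -> None:
    """Write area polygons (if present) with per-area properties."""
    if graph.polygons is None:
        raise SchemaError("graph has no polygon geometry")
    props = {}
    if properties is not None:
        p = properties.copy()
        if "area_id" in p.columns:
            p = p.set_index("area_id")
        props = {str(k): {c: _json_safe(v) for c, v in row.items()} for k, row in p.iterrows()}
    features = []
    for a in graph.area_ids:
        feat = {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": graph.polygons[a]},
            "properties": {"area_id": a, **props.get(a, {})},
        }
        features.append(feat)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path) -> tuple[dict[str, list], pd.DataFrame]:
    """Read polygons and the property table back from a GeoJSON file."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ParseError("expected a GeoJSON FeatureCollection")
    polys, rows = {}, []
    for feat in gj["features"]:
        props = dict(feat.get("properties", {}))
        aid = str(props.pop("area_id"))
        polys[aid] = feat["geometry"]["coordinates"]
        rows.append({"area_id": aid, **props})
    return polys, pd.DataFrame(rows)


def _json_safe(v):
    if pd.isna(v):
        return None
    if hasattr(v, "item"):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# YAML configs and result tables
# ---------------------------------------------------------------------------

def read_yaml(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a YAML mapping")
    return cfg


def write_results(tables: dict[str, pd.DataFrame], out_dir, header_comment: str | None = None) -> list[Path]:
    """Write a dict of DataFrames as CSVs with stable column order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False)
        written.append(path)
    return written
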