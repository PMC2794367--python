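"""Area contiguity graph: neighbour lists, urbanisation levels, populations.

The graph is the home of the spatial weights w_ij used by Moran's I and by
the intrinsic CAR prior.  Weights are binary contiguity (areas sharing a
border) and may be row-standardised on demand; area identifiers are opaque
strings and every join in the pipeline goes through them, never through
file order.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import InvalidArgumentError


class AreaGraph:
    """Symmetric contiguity graph over small areas.

    Parameters
    ----------
    area_ids : sequence of str
        Unique area identifiers.
    neighbours : mapping id -> iterable of ids
        Contiguity lists.  Must be symmetric and free of self-loops.
    urban_level : mapping id -> int, optional
        Ordinal urbanisation level, 1 (most urban) .. 7 (most rural).
    population : mapping id -> float, optional
        Total resident population (used by the synthetic generator).
    polygons : mapping id -> GeoJSON-style polygon coordinates, optional
    """

    URBAN_LEVELS = (1, 2, 3)  # levels classed as urban; 4-7 are rural

    def __init__(
        self,
        area_ids: Sequence[str],
        neighbours: Mapping[str, Iterable[str]],
        urban_level: Mapping[str, int] | None = None,
        population: Mapping[str, float] | None = None,
        polygons: Mapping[str, list] | None = None,
    ):
        self.area_ids = [str(a) for a in area_ids]
        if len(set(self.area_ids)) != len(self.area_ids):
            raise InvalidArgumentError("duplicate area ids")
        self._index = {a: i for i, a in enumerate(self.area_ids)}
        nb: dict[str, list[str]] = {}
        for a in self.area_ids:
            lst = [str(b) for b in neighbours.get(a, [])]
            for b in lst:
                if b not in self._index:
                    raise InvalidArgumentError(f"neighbour {b!r} of {a!r} is not an area")
                if b == a:
                    raise InvalidArgumentError(f"area {a!r} lists itself as a neighbour")
            nb[a] = sorted(set(lst))
        for a, lst in nb.items():
            for b in lst:
                if a not in nb[b]:
                    raise InvalidArgumentError(f"asymmetric adjacency: {a!r} -> {b!r}")
        self.neighbours = nb
        self.urban_level = dict(urban_level) if urban_level is not None else None
        self.population = dict(population) if population is not None else None
        self.polygons = dict(polygons) if polygons is not None else None
        iso = self.isolates()
        if iso:
            warnings.warn(f"{len(iso)} isolated area(s) with no neighbours: {iso[:5]}...")

    # -- basic queries ----------------------------------------------------
    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def index_of(self, area_id: str) -> int:
        return self._index[area_id]

    def isolates(self) -> list[str]:
        return [a for a in self.area_ids if not self.neighbours[a]]

    def degree(self) -> np.ndarray:
        return np.array([len(self.neighbours[a]) for a in self.area_ids])

    def neighbour_indices(self) -> list[np.ndarray]:
        """Neighbour lists as integer index arrays, in ``area_ids`` order."""
        return [
            np.array([self._index[b] for b in self.neighbours[a]], dtype=int)
            for a in self.area_ids
        ]

    def is_urban(self, area_id: str) -> bool:
        if self.urban_level is None:
            raise InvalidArgumentError("graph has no urbanisation levels")
        return self.urban_level[area_id] in self.URBAN_LEVELS

    # -- matrices ---------------------------------------------------------
    def weight_matrix(self, style: str = "binary") -> sp.csr_matrix:
        """Spatial weights W as sparse CSR.

        style='binary' gives w_ij in {0,1}; style='row' row-standardises so
        each non-isolated row sums to 1.
        """
        rows, cols = [], []
        for a in self.area_ids:
            i = self._index[a]
            for b in self.neighbours[a]:
                rows.append(i)
                cols.append(self._index[b])
        data = np.ones(len(rows))
        W = sp.csr_matrix((data, (rows, cols)), shape=(self.n_areas, self.n_areas))
        if style == "row":
            deg = np.asarray(W.sum(axis=1)).ravel()
            inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
            W = sp.diags(inv) @ W
            W = sp.csr_matrix(W)
        elif style != "binary":
            raise InvalidArgumentError(f"unknown weight style {style!r}")
        return W

    def laplacian(self) -> sp.csr_matrix:
        A = self.weight_matrix("binary")
        return sp.csr_matrix(sp.diags(self.degree().astype(float)) - A)

    def connected_components(self) -> tuple[int, np.ndarray]:
        return sp.csgraph.connected_components(self.weight_matrix("binary"), directed=False)

    # -- misc -------------------------------------------------------------
    def subset_levels(self) -> np.ndarray:
        """Urbanisation level per area, in ``area_ids`` order."""
        if self.urban_level is None:
            raise InvalidArgumentError("graph has no urbanisation levels")
        return np.array([self.urban_level[a] for a in self.area_ids], dtype=int)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AreaGraph(n_areas={self.n_areas}, edges={int(self.degree().sum()) // 2})"
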