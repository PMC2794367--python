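"""Synthetic registry generator: lattices, risk surfaces, epidemic counts.

Emulates the statistical structure of a national township-level mortality
registry during the emergence of a new suicide method:

- a rook-contiguity lattice of small areas with an urbanisation gradient
  (ordinal levels 1 = most urban .. 7 = most rural, spatially clustered)
  and log-normal populations concentrated in urban areas;
- a spatially autocorrelated log-relative-risk surface u (proper CAR) plus
  unstructured noise v;
- stratified Poisson death counts by area x year x sex x 5-y age band x
  method group.  The new method's rate is zero before an onset year and
  then follows an urbanisation-level-specific logistic adoption curve
  (urban areas plateau higher and earlier); rates for the established
  methods are constant over time with a persistent multiplicative excess
  in rural areas.

Counts are Poisson(person_years x rate); the per-area relative risk
exp(u_i + v_i) multiplies the new-method rate so that downstream smoothing
and autocorrelation stages have a recoverable spatial signal.  One master
seed is split into independent streams per sub-generator, so enabling or
adding strata does not perturb earlier draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import InvalidArgumentError
from .graph import AreaGraph
from .standards import get_standard

AGE_BANDS_15PLUS = (
    "15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
    "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85+",
)

# adult age composition of the simulated population (fractions of 15+)
_AGE_FRACTIONS = np.array(
    [0.10, 0.10, 0.105, 0.105, 0.10, 0.095, 0.085, 0.075, 0.06,
     0.05, 0.045, 0.04, 0.03, 0.02, 0.01]
)
# relative age profile of established-method suicide risk (rises with age)
_AGE_PROFILE_BASE = np.array(
    [0.3, 0.7, 1.0, 1.1, 1.1, 1.1, 1.1, 1.1, 1.1, 1.2, 1.4, 1.7, 2.1, 2.6, 3.0]
)
# the new method concentrates in working ages
_AGE_PROFILE_NEW = np.array(
    [0.4, 1.2, 1.8, 2.0, 1.9, 1.6, 1.2, 0.8, 0.5, 0.35, 0.25, 0.15, 0.1, 0.05, 0.05]
)

# area-count fraction per urbanisation level 1..7 (level 5 deliberately small)
_LEVEL_AREA_FRACTIONS = np.array([0.08, 0.12, 0.15, 0.20, 0.04, 0.20, 0.21])
# mean resident population (15+) per area by level; urban areas are larger so
# levels 1-3 carry roughly three quarters of the population
_LEVEL_MEAN_POP = np.array([90_000, 60_000, 40_000, 15_000, 9_000, 11_000, 9_000])


@dataclass
class AdoptionCurve:
    """Logistic adoption of the new method for one urbanisation level.

    The age-standardised new-method rate t years into the epidemic is
    plateau / (1 + exp(-steepness * (year - midpoint))).
    """
    plateau: float      # asymptotic age-standardised rate per 100,000
    midpoint: float     # calendar year of half-plateau
    steepness: float    # per-year logistic slope

    def rate(self, year, onset_year) -> np.ndarray:
        year = np.asarray(year, dtype=float)
        r = self.plateau / (1.0 + np.exp(-self.steepness * (year - self.midpoint)))
        return np.where(year < onset_year, 0.0, r)


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic registry scenario.

    Rates are age-standardised rates per 100,000 person-years; the age
    profiles internally rescale them across bands so that the directly
    standardised rate of the simulated stratum rates equals the configured
    value.
    """
    n_areas: int
    years: tuple[int, int] = (1991, 2007)
    age_bands: tuple[str, ...] = AGE_BANDS_15PLUS
    sexes: tuple[str, ...] = ("male", "female")
    baseline_rates: dict = field(default_factory=lambda: {"male": 25.0, "female": 12.0})
    adoption_onset_year: int = 1999
    adoption_params: dict = None  # level -> AdoptionCurve (male scale)
    female_adoption_scale: float = 0.37
    sigma_u: float = 0.3
    sigma_v: float = 0.1
    rural_excess: float = 1.3
    seed: int = 0

    def __post_init__(self):
        if self.n_areas < 2:
            raise InvalidArgumentError("n_areas must be >= 2")
        if self.years[0] > self.years[1]:
            raise InvalidArgumentError("year range reversed")
        if self.sigma_u < 0 or self.sigma_v < 0:
            raise InvalidArgumentError("sigma_u, sigma_v must be >= 0")
        if self.rural_excess < 0:
            raise InvalidArgumentError("rural_excess must be >= 0")
        if any(r < 0 for r in self.baseline_rates.values()):
            raise InvalidArgumentError("baseline rates must be >= 0")
        if self.adoption_onset_year < self.years[0]:
            # onset past the final year is the degenerate "no epidemic" case,
            # but an onset before the series starts is a config error
            raise InvalidArgumentError("adoption_onset_year precedes the year range")
        if self.adoption_params is None:
            self.adoption_params = default_adoption_params()
        bad = [lv for lv, c in self.adoption_params.items() if c.plateau < 0]
        if bad:
            raise InvalidArgumentError(f"negative plateau for level(s) {bad}")


def default_adoption_params(
    targets: dict[int, float] | None = None,
    target_period: tuple[int, int] = (2005, 2007),
    midpoints: dict[int, float] | None = None,
    steepness: float = 1.0,
    onset_year: int = 1999,
) -> dict[int, AdoptionCurve]:
    """Adoption curves calibrated so the mean logistic rate over
    ``target_period`` hits per-level target rates.

    The default targets are the male new-method age-standardised rates by
    urbanisation level observed late in a mature epidemic (roughly 11 per
    100,000 in the most urban stratum falling to 7 in the most rural), with
    urban levels reaching their midpoint a year earlier than rural ones.
    """
    if targets is None:
        targets = {1: 11.4, 2: 10.9, 3: 11.3, 4: 9.4, 5: 7.9, 6: 8.1, 7: 7.3}
    if midpoints is None:
        midpoints = {lv: (2002.5 if lv <= 3 else 2003.5) for lv in targets}
    curves = {}
    yrs = np.arange(target_period[0], target_period[1] + 1, dtype=float)
    for lv, tgt in targets.items():
        mid = midpoints[lv]
        frac = float(np.mean(1.0 / (1.0 + np.exp(-steepness * (yrs - mid)))))
        curves[lv] = AdoptionCurve(plateau=tgt / frac, midpoint=mid, steepness=steepness)
    return curves


# ---------------------------------------------------------------------------
# lattice
# ---------------------------------------------------------------------------

def generate_lattice(n_rows: int, n_cols: int, seed: int = 0) -> AreaGraph:
    """Rook-contiguity grid of areas with clustered urbanisation levels.

    Urbanisation is a smooth spatial score (distance from a randomly placed
    urban core, plus correlated noise) quantised to levels 1..7 with fixed
    area shares; populations are log-normal with urban areas larger.  Grid
    cells carry unit-square polygons so maps can be drawn.
    """
    if n_rows < 1 or n_cols < 1:
        raise InvalidArgumentError("grid dimensions must be >= 1")
    n = n_rows * n_cols
    master = np.random.SeedSequence(seed)
    rng_core, rng_noise, rng_pop = (np.random.default_rng(s) for s in master.spawn(3))
    ids = [f"A{r:03d}{c:03d}" for r in range(n_rows) for c in range(n_cols)]
    nb: dict[str, list[str]] = {a: [] for a in ids}
    for r in range(n_rows):
        for c in range(n_cols):
            a = f"A{r:03d}{c:03d}"
            if r + 1 < n_rows:
                nb[a].append(f"A{r + 1:03d}{c:03d}")
                nb[f"A{r + 1:03d}{c:03d}"].append(a)
            if c + 1 < n_cols:
                nb[a].append(f"A{r:03d}{c + 1:03d}")
                nb[f"A{r:03d}{c + 1:03d}"].append(a)
    # urbanisation score: proximity to an urban core + smooth noise
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    core = (rng_core.uniform(0, max(n_rows - 1, 1)), rng_core.uniform(0, max(n_cols - 1, 1)))
    scale = max(n_rows, n_cols, 2)
    dist = np.sqrt((rr - core[0]) ** 2 + (cc - core[1]) ** 2) / scale
    noise = rng_noise.standard_normal((n_rows, n_cols))
    noise = _smooth_grid(noise)
    score = (-dist + 0.25 * noise).ravel()  # higher = more urban
    order = np.argsort(-score, kind="stable")
    levels = np.empty(n, dtype=int)
    bounds = np.round(np.cumsum(_LEVEL_AREA_FRACTIONS) * n).astype(int)
    start = 0
    for lv, stop in enumerate(bounds, start=1):
        stop = max(stop, start)
        levels[order[start:stop]] = lv
        start = stop
    levels[order[start:]] = 7
    mean_pop = _LEVEL_MEAN_POP[levels - 1]
    sigma = 0.5
    pop = rng_pop.lognormal(mean=np.log(mean_pop) - sigma ** 2 / 2, sigma=sigma)
    polygons = {
        f"A{r:03d}{c:03d}": [[[c, -r], [c + 1, -r], [c + 1, -r - 1], [c, -r - 1], [c, -r]]]
        for r in range(n_rows) for c in range(n_cols)
    }
    return AreaGraph(
        ids,
        {a: sorted(set(v)) for a, v in nb.items()},
        urban_level=dict(zip(ids, (int(x) for x in levels))),
        population=dict(zip(ids, pop)),
        polygons=polygons,
    )


def _smooth_grid(z: np.ndarray, passes: int = 4) -> np.ndarray:
    """Cheap separable box smoothing with edge replication."""
    for _ in range(passes):
        zp = np.pad(z, 1, mode="edge")
        z = (zp[:-2, 1:-1] + zp[2:, 1:-1] + zp[1:-1, :-2] + zp[1:-1, 2:] + zp[1:-1, 1:-1]) / 5.0
    return z


# ---------------------------------------------------------------------------
# risk surface
# ---------------------------------------------------------------------------

def simulate_risk_surface(
    graph: AreaGraph, sigma_u: float, sigma_v: float, seed=0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a log-relative-risk surface eta = u + v.

    u comes from a proper CAR (precision proportional to the graph
    Laplacian plus a small ridge, 1e-6), handled per connected component,
    centred to mean zero and rescaled to empirical SD ``sigma_u``; v is iid
    Normal(0, sigma_v^2).  Returns (eta, u, v).
    """
    if sigma_u < 0 or sigma_v < 0:
        raise InvalidArgumentError("sigmas must be >= 0")
    n = graph.n_areas
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_u, rng_v = (np.random.default_rng(s) for s in master.spawn(2))
    u = np.zeros(n)
    if sigma_u > 0 and n > 1:
        L = graph.laplacian().toarray()
        ncomp, labels = graph.connected_components()
        if ncomp > 1:
            warnings.warn(f"graph has {ncomp} components; CAR drawn per component")
        for comp in range(ncomp):
            idx = np.flatnonzero(labels == comp)
            if len(idx) < 2:
                continue
            Q = L[np.ix_(idx, idx)] + 1e-6 * np.eye(len(idx))
            # draw x ~ N(0, Q^{-1}) via the Cholesky factor of Q
            R = np.linalg.cholesky(Q)
            x = np.linalg.solve(R.T, rng_u.standard_normal(len(idx)))
            u[idx] = x - x.mean()
        sd = u.std()
        if sd > 0:
            u *= sigma_u / sd
        u -= u.mean()
    v = sigma_v * rng_v.standard_normal(n) if sigma_v > 0 else np.zeros(n)
    return u + v, u, v


# ---------------------------------------------------------------------------
# epidemic simulation
# ---------------------------------------------------------------------------

def _band_rates(standardised_rate: float, profile: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-band rates with the given shape whose directly standardised rate
    (under ``weights``) equals ``standardised_rate`` (per 100,000)."""
    norm = float(weights @ profile)
    return standardised_rate * profile / norm


def simulate_epidemic(config: ScenarioConfig, graph: AreaGraph):
    """Simulate stratified death counts for a scenario on a graph.

    Returns (counts, truth): ``counts`` is a stratified-counts DataFrame
    and ``truth`` a per-area DataFrame with the simulated u, v and relative
    risk theta = exp(u + v) applied to the new-method rates.
    """
    if graph.n_areas != config.n_areas:
        raise InvalidArgumentError(
            f"config.n_areas={config.n_areas} but graph has {graph.n_areas}"
        )
    levels = graph.subset_levels()
    missing_lv = sorted(set(levels) - set(config.adoption_params))
    if missing_lv:
        raise InvalidArgumentError(f"no adoption curve for level(s) {missing_lv}")
    master = np.random.SeedSequence(config.seed)
    s_surface, s_counts = master.spawn(2)
    eta, u, v = simulate_risk_surface(graph, config.sigma_u, config.sigma_v, seed=s_surface)
    theta = np.exp(eta)
    rng = np.random.default_rng(s_counts)

    bands = list(config.age_bands)
    std_all = get_standard("segi")
    if not set(bands) <= set(std_all.bands):
        raise InvalidArgumentError("age bands must be drawn from the standard set")
    std = std_all.restrict(bands)
    w = std.weights.to_numpy()
    pos = [AGE_BANDS_15PLUS.index(b) for b in bands]
    agefrac = _AGE_FRACTIONS[pos]
    agefrac = agefrac / agefrac.sum()
    profile_base = _AGE_PROFILE_BASE[pos]
    profile_new = _AGE_PROFILE_NEW[pos]

    years = np.arange(config.years[0], config.years[1] + 1)
    n_y, n_a, n_b = len(years), graph.n_areas, len(bands)
    pop = np.array([graph.population[a] for a in graph.area_ids], dtype=float)
    rural = levels >= 4
    # person-years: the population splits evenly by sex and by the fixed
    # adult age composition; constant over calendar years
    py = pop[:, None] * agefrac[None, :] / len(config.sexes)  # (areas, bands)

    frames = []
    for sex in config.sexes:
        base = config.baseline_rates[sex]
        sex_scale = 1.0 if sex == "male" else config.female_adoption_scale
        nc_band = _band_rates(base, profile_base, w)          # per 1e5
        cb_band_unit = _band_rates(1.0, profile_new, w)       # shape for 1 per 1e5
        lam = np.zeros((8, n_y))
        for lv, curve in config.adoption_params.items():
            lam[lv] = sex_scale * curve.rate(years, config.adoption_onset_year)
        nc_rate = nc_band[None, :] * np.where(rural, config.rural_excess, 1.0)[:, None]
        mu_nc = np.broadcast_to(py * nc_rate / 1e5, (n_y, n_a, n_b))
        mu_cb = (
            lam[levels, :].T[:, :, None] * cb_band_unit[None, None, :]
            * theta[None, :, None] * py[None, :, :] / 1e5
        )
        d_nc = rng.poisson(mu_nc)
        d_cb = rng.poisson(mu_cb)
        year_col = np.repeat(years, n_a * n_b)
        area_col = np.tile(np.repeat(np.array(graph.area_ids, dtype=object), n_b), n_y)
        band_col = np.tile(np.array(bands, dtype=object), n_y * n_a)
        py_col = np.broadcast_to(py, (n_y, n_a, n_b)).ravel()
        for method, d in (("charcoal", d_cb), ("non_charcoal", d_nc)):
            frames.append(pd.DataFrame({
                "area_id": area_col, "year": year_col, "sex": sex,
                "age_band": band_col, "method": method,
                "deaths": d.ravel(), "person_years": py_col,
            }))
    counts = pd.concat(frames, ignore_index=True)[
        ["area_id", "year", "sex", "age_band", "method", "deaths", "person_years"]
    ]
    truth = pd.DataFrame({
        "area_id": graph.area_ids,
        "u": u, "v": v, "theta": theta,
        "urban_level": levels,
    })
    return counts, truth
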