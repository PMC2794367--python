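"""Bayesian hierarchical Poisson smoothing of SMRs (global / local / convolution).

Model
-----
For area i with observed deaths O_i and expected deaths E_i,

    O_i ~ Poisson(E_i * theta_i),   log theta_i = alpha + u_i + v_i

where v_i ~ Normal(0, 1/tau_v) is the unstructured ("global") heterogeneity
component and u follows the intrinsic conditional autoregressive (ICAR)
prior: u_i | u_{-i} ~ Normal(mean of neighbours' u, 1/(tau_u * n_i)) with
n_i the neighbour count.  The three variants keep only v (``global``), only
u (``local``), or both (``convolution``).  Priors: alpha improper flat,
tau_u, tau_v ~ Gamma(0.5, 0.0005) (vague, WinBUGS-era convention).

Sampler
-------
Custom MCMC: conjugate Gibbs updates for the precisions, adaptive
random-walk Metropolis for alpha and for each u_i, v_i.  The u updates are
vectorised over graph colour classes (no two areas in a class are
neighbours, so their full conditionals are mutually independent); the
v updates are fully vectorised because they are conditionally independent.
The ICAR prior is improper, so u is re-centred to mean zero after every
sweep with alpha absorbing the level.  Step sizes adapt toward 44%
acceptance during burn-in only, then freeze.  Isolated areas keep u_i = 0.

Everything is reproducible bit-for-bit given the seed and the iteration
schedule; chains use independent streams spawned from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .errors import InvalidArgumentError
from .graph import AreaGraph

VARIANTS = ("global", "local", "convolution")


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------

@dataclass
class BYMFit:
    """Posterior draws and metadata from one model fit.

    Draw arrays are shaped (chains, draws) for scalars and
    (chains, draws, n_areas) for effect vectors; u and v are identically
    zero for variants that omit them.
    """

    variant: str
    area_ids: list[str]
    O: np.ndarray
    E: np.ndarray
    alpha: np.ndarray
    u: np.ndarray
    v: np.ndarray
    tau_u: np.ndarray
    tau_v: np.ndarray
    seed: int | None = None
    isolates: list[str] = field(default_factory=list)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def theta_draws(self) -> np.ndarray:
        """theta_i = exp(alpha + u_i + v_i), shape (chains, draws, n)."""
        return np.exp(self.alpha[:, :, None] + self.u + self.v)

    def theta_summary(self, level: float = 0.95) -> pd.DataFrame:
        th = self.theta_draws().reshape(-1, self.n_areas)
        lo, hi = 50 * (1 - level), 50 * (1 + level)
        return pd.DataFrame({
            "area_id": self.area_ids,
            "smr_smooth": th.mean(axis=0),
            "smr_lo": np.percentile(th, lo, axis=0),
            "smr_hi": np.percentile(th, hi, axis=0),
        })


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(chains) -> float:
    """Brooks-Gelman potential scale reduction factor for a scalar parameter.

    ``chains`` is an (m, n) array of m >= 2 parallel chains of equal length
    n >= 10.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 chains of equal length")
    m, n = x.shape
    if n < 10:
        raise InvalidArgumentError("chains too short for R-hat")
    W = x.var(axis=1, ddof=1).mean()
    if W == 0:
        raise InvalidArgumentError("zero within-chain variance in all chains")
    B_over_n = x.mean(axis=1).var(ddof=1)
    v_hat = (n - 1) / n * W + B_over_n
    # Brooks & Gelman correction for sampling variability of the means
    r2 = (m + 1) / m * v_hat / W - (n - 1) / (m * n)
    return float(np.sqrt(max(r2, 0.0)))


def dic(fit: BYMFit) -> tuple[float, float, float]:
    """Deviance information criterion.

    Returns (Dbar, pD, DIC) where D(theta) = -2 sum_i log Poisson(O_i | E_i
    theta_i), Dbar is the posterior mean deviance, pD = Dbar - D(posterior
    mean of theta), and DIC = Dbar + pD.  pD can be negative on pathological
    fits and is reported as-is.
    """
    th = fit.theta_draws().reshape(-1, fit.n_areas)
    O, E = fit.O, fit.E
    const = gammaln(O + 1.0).sum()

    def deviance(theta2d):
        mu = E * theta2d
        return -2.0 * ((O * np.log(mu)).sum(axis=-1) - mu.sum(axis=-1) - const)

    dbar = float(deviance(th).mean())
    dhat = float(deviance(th.mean(axis=0)[None, :])[0])
    pd_ = dbar - dhat
    return dbar, pd_, dbar + pd_


def variance_partition(fit: BYMFit, method: str = "marginal", level: float = 0.95):
    """Share of total area variability attributed to the local (spatial)
    component, psi, with a credible interval.

    method='marginal' (default): per draw, psi = var(u)/(var(u)+var(v))
    using the empirical variances of the effect vectors.  method=
    'conditional': psi from the precision parameters, (1/tau_u)/((1/tau_u)+
    (1/tau_v)).  Returns (median, lo, hi).
    """
    if fit.variant != "convolution":
        raise InvalidArgumentError("variance partition requires a convolution fit")
    if method == "marginal":
        su2 = fit.u.var(axis=2)
        sv2 = fit.v.var(axis=2)
    elif method == "conditional":
        su2 = 1.0 / fit.tau_u
        sv2 = 1.0 / fit.tau_v
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    tot = su2 + sv2
    with np.errstate(invalid="ignore"):
        psi = np.where(tot > 0, su2 / np.where(tot > 0, tot, 1.0), 0.0).ravel()
    lo, hi = 50 * (1 - level), 50 * (1 + level)
    return float(np.median(psi)), float(np.percentile(psi, lo)), float(np.percentile(psi, hi))


def smoothed_smr_table(fit: BYMFit, smr_table: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Join posterior-mean SMRs (with credible intervals) onto the raw table."""
    summ = fit.theta_summary(level=level)
    if set(summ["area_id"]) != set(smr_table["area_id"]):
        raise InvalidArgumentError("area ids of fit and SMR table do not match")
    return smr_table.merge(summ, on="area_id", validate="one_to_one")


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def _colour_classes(graph: AreaGraph, active: np.ndarray) -> list[np.ndarray]:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_areas))
    for a in graph.area_ids:
        i = graph.index_of(a)
        for b in graph.neighbours[a]:
            g.add_edge(i, graph.index_of(b))
    colours = nx.coloring.greedy_color(g, strategy="largest_first")
    classes: dict[int, list[int]] = {}
    for node, c in colours.items():
        if active[node]:
            classes.setdefault(c, []).append(node)
    return [np.array(sorted(v), dtype=int) for _, v in sorted(classes.items())]


def icar_tau_posterior_params(u, laplacian, a: float, b: float, n_components: int):
    """Conjugate Gamma(shape, rate) parameters of tau_u | u under the ICAR prior.

    shape = a + (n_active - n_components)/2, rate = b + u'Lu/2, where the
    pairwise sum of squared neighbour differences u'Lu is taken over the
    edges and n_active counts areas with at least one neighbour.
    """
    u = np.asarray(u, dtype=float)
    ss = float(u @ (laplacian @ u))
    deg = laplacian.diagonal()
    n_active = int(np.sum(deg > 0))
    return a + 0.5 * (n_active - n_components), b + 0.5 * ss


def _run_chain(O, E, variant, graph, classes, class_rows, L, active, n_comp,
               iterations, burn_in, thin, a_u, b_u, a_v, b_v, rng):
    n = len(O)
    has_u = variant in ("local", "convolution")
    has_v = variant in ("global", "convolution")
    alpha = float(np.log(max(O.sum(), 0.5) / E.sum()) + 0.3 * rng.standard_normal())
    u = np.zeros(n)
    v = np.zeros(n)
    if has_u:
        u[active] = 0.05 * rng.standard_normal(active.sum())
        u[active] -= u[active].mean()
    if has_v:
        v = 0.05 * rng.standard_normal(n)
    tau_u = tau_v = 1.0
    step_u = np.full(n, 0.3)
    step_v = np.full(n, 0.3)
    step_a = 0.05
    acc_u = np.zeros(n)
    acc_v = np.zeros(n)
    acc_a = 0.0
    window = 50
    deg = L.diagonal()
    n_draws = (iterations - burn_in) // thin
    out = {
        "alpha": np.empty(n_draws),
        "u": np.zeros((n_draws, n)),
        "v": np.zeros((n_draws, n)),
        "tau_u": np.full(n_draws, np.nan),
        "tau_v": np.full(n_draws, np.nan),
    }
    A = graph.weight_matrix("binary")
    kept = 0
    for it in range(iterations):
        ev = np.exp(v)
        eu = np.exp(u)
        ea = np.exp(alpha)
        if has_u:
            for idx, A_rows in zip(classes, class_rows):
                du = step_u[idx] * rng.standard_normal(len(idx))
                u_old = u[idx]
                u_new = u_old + du
                s = A_rows @ u  # neighbour sums (never within-class)
                lam = E[idx] * ea * ev[idx]
                dlik = O[idx] * du - lam * (np.exp(u_new) - eu[idx])
                dpri = -0.5 * tau_u * (deg[idx] * (u_new ** 2 - u_old ** 2) - 2.0 * s * du)
                accept = np.log(rng.random(len(idx))) < dlik + dpri
                u[idx[accept]] = u_new[accept]
                eu[idx[accept]] = np.exp(u_new[accept])
                acc_u[idx] += accept
            # identifiability: re-centre u, alpha absorbs the level
            m = u[active].mean()
            u[active] -= m
            alpha += m
            ea = np.exp(alpha)
            eu = np.exp(u)
            shape, rate = (
                a_u + 0.5 * (int(active.sum()) - n_comp),
                b_u + 0.5 * float(u @ (L @ u)),
            )
            tau_u = rng.gamma(shape, 1.0 / rate)
        if has_v:
            dv = step_v * rng.standard_normal(n)
            v_new = v + dv
            lam = E * ea * eu
            dlik = O * dv - lam * (np.exp(v_new) - ev)
            dpri = -0.5 * tau_v * (v_new ** 2 - v ** 2)
            accept = np.log(rng.random(n)) < dlik + dpri
            v[accept] = v_new[accept]
            ev = np.exp(v)
            acc_v += accept
            tau_v = rng.gamma(a_v + 0.5 * n, 1.0 / (b_v + 0.5 * float(v @ v)))
        # alpha: flat prior random-walk
        da = step_a * rng.standard_normal()
        total = float((E * eu * ev).sum())
        dlik = O.sum() * da - total * (np.exp(alpha + da) - ea)
        if np.log(rng.random()) < dlik:
            alpha += da
            acc_a += 1
        # adaptation (burn-in only)
        if it < burn_in and (it + 1) % window == 0:
            if has_u:
                step_u *= np.exp(np.clip(acc_u / window - 0.44, -0.5, 0.5))
                np.clip(step_u, 1e-3, 10.0, out=step_u)
                acc_u[:] = 0
            if has_v:
                step_v *= np.exp(np.clip(acc_v / window - 0.44, -0.5, 0.5))
                np.clip(step_v, 1e-3, 10.0, out=step_v)
                acc_v[:] = 0
            step_a *= np.exp(np.clip(acc_a / window - 0.44, -0.5, 0.5))
            step_a = float(np.clip(step_a, 1e-4, 5.0))
            acc_a = 0.0
        if it >= burn_in and (it - burn_in) % thin == 0:
            out["alpha"][kept] = alpha
            out["u"][kept] = u
            out["v"][kept] = v
            out["tau_u"][kept] = tau_u if has_u else np.nan
            out["tau_v"][kept] = tau_v if has_v else np.nan
            kept += 1
    return out


class BYMModel(BaseEstimator):
    """Estimator-style interface to the hierarchical Poisson SMR smoother.

    Parameters
    ----------
    variant : 'global', 'local' or 'convolution'
        Which random-effect structure to include (unstructured only,
        ICAR only, or both).
    chains, iterations, burn_in, thin : MCMC schedule (iterations is the
        total per chain including burn-in).
    a_u, b_u, a_v, b_v : Gamma prior hyperparameters on the precisions.
    seed : master seed; chains run on streams spawned from it.

    Fitted attributes: ``fit_`` (BYMFit with all draws), ``theta_``
    (posterior-mean SMR per area), ``theta_ci_``, ``rhat_`` (dict),
    ``dic_`` (Dbar, pD, DIC), ``local_share_`` (convolution only),
    ``converged_``.
    """

    def __init__(self, variant: str = "convolution", chains: int = 4,
                 iterations: int = 5000, burn_in: int = 2500, thin: int = 1,
                 a_u: float = 0.5, b_u: float = 5e-4,
                 a_v: float = 0.5, b_v: float = 5e-4, seed: int = 0):
        self.variant = variant
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.a_u = a_u
        self.b_u = b_u
        self.a_v = a_v
        self.b_v = b_v
        self.seed = seed

    def _validate(self, smr_table: pd.DataFrame, graph: AreaGraph):
        if self.variant not in VARIANTS:
            raise InvalidArgumentError(f"variant must be one of {VARIANTS}")
        if self.chains < 2:
            raise InvalidArgumentError("need >= 2 chains for convergence diagnostics")
        if not (self.iterations > self.burn_in >= 0):
            raise InvalidArgumentError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise InvalidArgumentError("thin must be >= 1")
        missing = set(smr_table["area_id"]) - set(graph.area_ids)
        if missing:
            raise InvalidArgumentError(f"areas not in graph: {sorted(missing)[:5]}")
        tab = smr_table.set_index("area_id").loc[
            [a for a in graph.area_ids if a in set(smr_table["area_id"])]
        ].reset_index()
        if (tab["E"] <= 0).any():
            raise InvalidArgumentError("all expected counts must be > 0")
        return tab

    def fit(self, smr_table: pd.DataFrame, graph: AreaGraph) -> "BYMModel":
        """Run the sampler on an (area_id, O, E) table over a contiguity graph."""
        tab = self._validate(smr_table, graph)
        sub = graph
        if len(tab) != graph.n_areas:
            keep = set(tab["area_id"])
            sub = AreaGraph(
                [a for a in graph.area_ids if a in keep],
                {a: [b for b in graph.neighbours[a] if b in keep]
                 for a in graph.area_ids if a in keep},
                urban_level=graph.urban_level,
                population=graph.population,
            )
        O = tab["O"].to_numpy(dtype=float)
        E = tab["E"].to_numpy(dtype=float)
        deg = sub.degree()
        active = deg > 0
        if self.variant != "global" and not active.all():
            warnings.warn(
                f"{int((~active).sum())} isolated area(s): spatial effect fixed at 0"
            )
        L = sub.laplacian()
        ncomp_all, labels = sub.connected_components()
        n_comp = len({c for c in labels[active]})
        classes = _colour_classes(sub, active)
        A = sub.weight_matrix("binary")
        class_rows = [A[idx, :] for idx in classes]
        streams = np.random.SeedSequence(self.seed).spawn(self.chains)
        chain_out = [
            _run_chain(O, E, self.variant, sub, classes, class_rows, L, active,
                       n_comp, self.iterations, self.burn_in, self.thin,
                       self.a_u, self.b_u, self.a_v, self.b_v,
                       np.random.default_rng(s))
            for s in streams
        ]
        self.fit_ = BYMFit(
            variant=self.variant,
            area_ids=list(tab["area_id"]),
            O=O, E=E,
            alpha=np.stack([c["alpha"] for c in chain_out]),
            u=np.stack([c["u"] for c in chain_out]),
            v=np.stack([c["v"] for c in chain_out]),
            tau_u=np.stack([c["tau_u"] for c in chain_out]),
            tau_v=np.stack([c["tau_v"] for c in chain_out]),
            seed=self.seed,
            isolates=[a for a, act in zip(sub.area_ids, active) if not act],
        )
        summ = self.fit_.theta_summary()
        self.theta_ = summ["smr_smooth"].to_numpy()
        self.theta_ci_ = summ[["smr_lo", "smr_hi"]].to_numpy()
        self.rhat_ = self._rhats()
        self.dic_ = dic(self.fit_)
        if self.variant == "convolution":
            self.local_share_ = variance_partition(self.fit_)
        self.converged_ = all(r < 1.05 for r in self.rhat_.values())
        return self

    def _rhats(self) -> dict[str, float]:
        f = self.fit_
        out = {"alpha": gelman_rubin(f.alpha)}
        if f.variant in ("local", "convolution"):
            out["tau_u"] = gelman_rubin(f.tau_u)
        if f.variant in ("global", "convolution"):
            out["tau_v"] = gelman_rubin(f.tau_v)
        # a handful of area-level SMRs, deterministically chosen from the seed
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7]))
        th = f.theta_draws()
        for i in sorted(rng.choice(f.n_areas, size=min(5, f.n_areas), replace=False)):
            out[f"theta[{f.area_ids[i]}]"] = gelman_rubin(th[:, :, i])
        return out

    def smoothed_table(self, smr_table: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "fit_"):
            raise InvalidArgumentError("model is not fitted")
        return smoothed_smr_table(self.fit_, smr_table)


def fit(smr_table: pd.DataFrame, graph: AreaGraph, **kwargs) -> BYMFit:
    """Functional wrapper: fit a model and return the BYMFit draws object."""
    return BYMModel(**kwargs).fit(smr_table, graph).fit_
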