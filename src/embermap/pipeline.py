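"""End-to-end pipeline: simulate -> rates -> SMR -> BYM -> Moran -> maps -> trends.

Driven by a YAML config (or an equivalent dict).  A minimal config:

    simulate:
      grid: [20, 20]
      years: [1991, 2007]
    analysis:
      period: [1999, 2007]
      sexes: [male, female]
      method: charcoal
    bym:
      chains: 4
      iterations: 2000
      burn_in: 1000
    moran:
      permutations: 999
    seed: 7

Every stochastic stage draws its seed from the single top-level seed; the
manifest records versions, seeds and a SHA-256 per output file, so reruns
with the same config and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .bym import BYMModel
from .errors import SchemaError
from .graph import AreaGraph
from .io_formats import read_yaml, write_counts, write_graph
from .mapping import classify_smr, export_choropleth, rural_urban_differences, urban_rural_trends
from .moran import moran_test_rates
from .rates import table1
from .smr import smr_table
from .standards import get_standard
from .synthetic import ScenarioConfig, generate_lattice, simulate_epidemic

log = logging.getLogger("embermap")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config, out_dir, seed: int | None = None) -> Path:
    """Run the configured stages, writing outputs and a manifest.

    ``config`` is a path to a YAML file or a dict.  Returns the output
    directory.  A stage failure raises, after logging which stage failed.
    """
    cfg = read_yaml(config) if not isinstance(config, dict) else dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    if seed is None:
        seed = int(cfg.get("seed", 0))
    stage = "config"
    manifest = {"version": __version__, "seed": seed, "stages": [], "files": {}}
    try:
        # ---- simulate ----------------------------------------------------
        stage = "simulate"
        sim = cfg.get("simulate")
        if sim is None:
            raise SchemaError("config needs a 'simulate' block (external input mode "
                              "is driven through the library API)")
        if "grid" not in sim:
            raise SchemaError("simulate block needs 'grid: [rows, cols]'")
        rows, cols = sim["grid"]
        years = tuple(sim.get("years", (1991, 2007)))
        graph = generate_lattice(rows, cols, seed=seed)
        scen = ScenarioConfig(
            n_areas=graph.n_areas, years=years,
            adoption_onset_year=int(sim.get("adoption_onset_year", 1999)),
            sigma_u=float(sim.get("sigma_u", 0.3)),
            sigma_v=float(sim.get("sigma_v", 0.1)),
            rural_excess=float(sim.get("rural_excess", 1.3)),
            seed=seed,
        )
        counts, truth = simulate_epidemic(scen, graph)
        write_counts(counts, out / "counts.csv", header_comment=f"embermap {__version__} seed={seed}")
        write_graph(graph, out / "adjacency.gal", out / "areas.csv")
        truth.to_csv(out / "truth.csv", index=False)
        log.info("simulate: %d areas, %d rows of counts", graph.n_areas, len(counts))
        manifest["stages"].append("simulate")

        ana = cfg.get("analysis", {})
        period = tuple(ana.get("period", (1999, years[1])))
        sexes = ana.get("sexes", ["male", "female"])
        method = ana.get("method", "charcoal")
        standard = get_standard(ana.get("standard", "segi"), min_age_band="15-19")

        # ---- rates / table 1 --------------------------------------------
        stage = "rates"
        p0, p1 = period
        third = max(1, (p1 - p0 + 1) // 3)
        periods = [(p0, p0 + third - 1), (p0 + third, p0 + 2 * third - 1), (p0 + 2 * third, p1)]
        t1 = table1(counts, graph, periods, standard)
        t1.to_csv(out / "table1.csv", index=False)
        manifest["stages"].append("rates")

        # ---- per-sex SMR, BYM, Moran, maps -------------------------------
        bym_cfg = cfg.get("bym", {})
        moran_cfg = cfg.get("moran", {})
        summaries = {}
        for si, sex in enumerate(sexes):
            stage = f"smr[{sex}]"
            tab = smr_table(counts, period, sex, method=method)
            tab.to_csv(out / f"smr_{sex}.csv", index=False)

            stage = f"bym[{sex}]"
            fits = {}
            for variant in ("global", "local", "convolution"):
                model = BYMModel(
                    variant=variant,
                    chains=int(bym_cfg.get("chains", 4)),
                    iterations=int(bym_cfg.get("iterations", 2000)),
                    burn_in=int(bym_cfg.get("burn_in", 1000)),
                    seed=seed * 1000 + si * 10 + len(fits),
                )
                model.fit(tab, graph)
                fits[variant] = model
            conv = fits["convolution"]
            smoothed = conv.smoothed_table(tab)
            smoothed.to_csv(out / f"smr_smoothed_{sex}.csv", index=False)

            stage = f"moran[{sex}]"
            mres = moran_test_rates(
                tab["O"].to_numpy(), tab["E"].to_numpy(), graph,
                n_perm=int(moran_cfg.get("permutations", 999)),
                seed=seed * 100 + si,
            )

            stage = f"classify[{sex}]"
            cls = classify_smr(smoothed["smr_smooth"])
            cls.insert(0, "area_id", smoothed["area_id"])
            export_choropleth(cls, graph, out / f"map_{sex}.geojson",
                              image_path=out / f"map_{sex}.png")

            summaries[sex] = {
                "dic": {k: m.dic_[2] for k, m in fits.items()},
                "pD": {k: m.dic_[1] for k, m in fits.items()},
                "local_share": conv.local_share_,
                "rhat": conv.rhat_,
                "converged": bool(conv.converged_),
                "moran_I": mres.I, "moran_p": mres.p_value,
                "zero_count_fraction": float((tab["O"] == 0).mean()),
            }
            manifest["stages"] += [f"smr[{sex}]", f"bym[{sex}]", f"moran[{sex}]", f"classify[{sex}]"]

        # ---- trends ------------------------------------------------------
        stage = "trends"
        trends = urban_rural_trends(counts, graph, standard,
                                    window=int(cfg.get("trends", {}).get("window", 3)))
        trends.to_csv(out / "trends.csv", index=False)
        y0, y1 = years
        diff_periods = [(y, y + 2) for y in range(y0, y1 - 1, 3)]
        diffs = rural_urban_differences(counts, graph, standard, diff_periods)
        diffs.to_csv(out / "rural_urban_differences.csv", index=False)
        manifest["stages"].append("trends")

        with open(out / "summary.json", "w") as f:
            json.dump(summaries, f, indent=2, default=float)
        for p in sorted(out.iterdir()):
            if p.suffix in (".csv", ".gal", ".geojson", ".json") and p.name != "manifest.json":
                manifest["files"][p.name] = _sha256(p)
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2)
        log.info("pipeline complete: %s", out)
        return out
    except Exception:
        log.exception("stage %r failed; see %s", stage, out / "pipeline.log")
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
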