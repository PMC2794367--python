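# embermap

Small-area spatial–temporal analysis of the emergence of a new suicide
method.  When a novel method (such as carbon-monoxide poisoning by burning
barbecue charcoal) appears in a population, public-health surveillance
wants to know *where* it takes hold first, whether its incidence clusters
geographically, and how it reshapes long-standing urban–rural differences
in overall rates.  `embermap` packages the full analysis pipeline used for
this kind of question at the township scale, driven either by registry-style
input tables or by a built-in synthetic scenario generator that reproduces
the statistical structure of such an epidemic (urban-first logistic
adoption of the new method on top of stable, rurally elevated rates for
established methods).

It is aimed at epidemiologists and biostatisticians working with stratified
mortality counts (area × year × sex × 5-year age band × method group),
an area contiguity list, and an ordinal urbanisation index per area.

## What it computes

- **Directly age-standardised rates** per 100,000 person-years against the
  Segi (1960) or WHO (2000) world standard: rate = 10⁵ Σₛ wₛ dₛ/nₛ, with
  Poisson variance 10¹⁰ Σₛ wₛ² dₛ/nₛ²; method-share proportions with Wilson
  intervals; 3-year moving averages; rate differences with normal CIs.
- **SMRs by indirect standardisation**: Eᵢ = Σₛ rateₛ · pyearsᵢₛ from
  national sex/age-specific rates, SMRᵢ = Oᵢ/Eᵢ.
- **Bayesian hierarchical Poisson smoothing** (a from-scratch MCMC
  sampler): Oᵢ ~ Poisson(Eᵢθᵢ), log θᵢ = α + uᵢ + vᵢ with an intrinsic CAR
  prior on the spatially structured effect u and exchangeable normal v —
  the Besag–York–Mollié convolution model, plus global-only and local-only
  variants.  Reports smoothed SMRs with credible intervals, Gelman–Rubin
  R-hat over parallel chains, DIC for model comparison, and the posterior
  share ψ = var(u)/(var(u)+var(v)) of area variability attributable to the
  local (spatial) component.
- **Moran's I** with Assunção–Reis empirical-Bayes standardisation of
  small-count rates and one-sided permutation inference.
- **Choropleth classification** of SMRs into five classes symmetric on the
  log scale around a middle class of 0.9–1.1 (divergent blue–white–red),
  exported as GeoJSON/CSV/PNG.
- **Urban–rural secular trends**: sex-specific standardised-rate series for
  urban (levels 1–3) vs rural (levels 4–7) areas, by method group, with
  period-level rate differences.

## Worked example

```python
import embermap as em

graph = em.generate_lattice(10, 10, seed=1)               # 100 areas
cfg = em.ScenarioConfig(n_areas=100, seed=5)              # 1991-2007 epidemic
counts, truth = em.simulate_epidemic(cfg, graph)

tab = em.smr_table(counts, (1999, 2007), "male", method="charcoal")
model = em.BYMModel(variant="convolution", chains=4, iterations=4000,
                    burn_in=2000, seed=7).fit(tab, graph)
res = em.permutation_test(em.eb_adjusted_rates(tab.O, tab.E), graph,
                          n_perm=999, seed=11)
```

This prints (via the obvious `print` calls):

```
areas: 100, total O = 698, total E = 698.0
DIC = 439.2  (pD = 42.9)
local share psi = 1.00 (95% CrI 0.91-1.00)
Moran's I = 0.233, permutation p = 0.003
class counts: {1: 44, 2: 22, 3: 13, 4: 11, 5: 10}
```

Total expected deaths equal total observed by construction (the reference
rates are estimated from the same counts).  The convolution model
attributes essentially all area variability to the spatial component —
as it should, since this scenario's log-risk surface is dominated by a
spatially autocorrelated field — and the EB-adjusted Moran test rejects
spatial randomness (I = 0.23, p = 0.003 with 999 permutations).  The class
counts are the five map categories (1 = SMR below ≈0.74, 3 = white middle
class 0.9–1.1, 5 = above ≈1.34).

The same pipeline runs end to end from a shell:

```sh
embermap run --config demo.yaml --out results/demo --seed 7
```

writing counts, SMR tables, smoothed SMRs, GeoJSON maps, trend series and
a manifest of SHA-256 hashes (reruns with the same seed are bit-identical).

## Layout

```
src/embermap/
  synthetic.py   scenario generator (lattice, CAR risk surface, epidemic)
  io_formats.py  CSV counts, GAL adjacency, GeoJSON, YAML configs
  standards.py   Segi 1960 / WHO 2000 standard populations
  rates.py       direct standardisation, proportions, moving averages
  smr.py         expected deaths and raw SMRs
  bym.py         hierarchical Poisson smoothing (MCMC), DIC, R-hat, psi
  moran.py       Moran's I, EB adjustment, permutation test
  mapping.py     map classification, choropleth export, urban-rural trends
  pipeline.py    end-to-end runner with manifest
  cli.py         `embermap` command group
```

See `docs/methods.md` for the statistical details and design choices.
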