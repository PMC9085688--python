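# landgen

Landscape-genetic analysis of temperate forest herbs in agricultural
mosaics.

Forest herbs such as *Anemone nemorosa*, *Oxalis acetosella* and
*Polygonatum multiflorum* persist in small forest fragments embedded in
farmland, and their gene flow depends on animal vectors — pollinators,
wild boar, deer, birds — that must cross the agricultural matrix.
`landgen` asks how the composition and configuration of that matrix
shape the herbs' population genetic structure.  It provides, as one
tested pipeline:

* **Microsatellite statistics** (diploid and tetraploid): rarefied
  allelic richness *A*ᵣ, expected/observed heterozygosity *H*ₑ, *H*ₒ,
  inbreeding coefficient *F* = 1 − *H*ₒ/*H*ₑ within populations;
  Hedrick's standardized *G″*_ST and the shared-allele distance *D*_PS
  between population pairs; edge-to-edge distances and Hanski
  incidence-function connectivity *S*ᵢ = Σ exp(−α d)·Aᵇ.
* **Multi-scale landscape metrics** from vector land-use maps: percent
  cover (with decade-frequency crop weighting for oilseed rape, maize and
  cereals), relative length of linear elements, Shannon diversity, parcel
  edge density, green-settlement fraction — measured in circular buffers
  (125–2000 m) around populations and in rectangular strips (width:length
  1:7–2:3) between population pairs, including the decomposition of
  linear elements into components parallel and orthogonal to the
  gene-dispersal direction (the O:P conditioning ratio).
* **Mixed-model multimodel inference**: Box-Cox + standardization, linear
  mixed models with a landscape-window random intercept and, at the pair
  level, the MLPE correlation structure

      Σ = σ²_w Z_w Z_wᵀ + σ²_p A Aᵀ + σ²_e I

  (A = pair-incidence matrix, two unit entries per row); per-metric scale
  selection by AICc, an α = 0.15 likelihood-ratio screen, |r| ≥ 0.7
  collinearity reduction with principal-component composites, all-subsets
  selection (caps 4/9 terms), ΔAICc < 2 full model averaging with
  importance values, and the marginal/landscape R² decomposition.
* **A synthetic-data generator** producing 5 × 5 km landscape windows,
  populations and genotypes with known ground truth, so the whole
  pipeline is testable closed-loop without any downloads.

## Worked example

Simulate a four-window scenario, compute diversity tables, and run the
node-level analysis for *H*ₑ at two buffer scales:

```python
from landgen import (ScenarioConfig, generate_scenario, simulate_genotypes,
                     diversity_table, RunConfig, run_node, render_report)

cfg = ScenarioConfig(seed=7, n_windows=4, pops_per_window=6, n_parcels=40)
scen = generate_scenario(cfg)
gt = simulate_genotypes(scen["nodes"], cfg)
print(diversity_table(gt).head(4).to_string(index=False))

rc = RunConfig(buffer_distances=(250.0, 1000.0))
res = run_node(scen["windows"], gt, scen["nodes"], config=rc, responses=("He",))
print(render_report(res["results"]))
```

prints

```
window population       Ar       He       Ho         F  n_individuals  rarefaction_size
    W0       W0P0 5.833333 0.713462 0.733333 -0.027853             20                40
    W0       W0P1 6.166667 0.759188 0.750000  0.012102             20                40
    W0       W0P2 5.833333 0.695085 0.708333 -0.019059             20                40
    W0       W0P3 5.666667 0.708120 0.708333 -0.000302             20                40

== He ==
  size                         \   imp=1.00 beta=-0.126
  isolation                    /   imp=1.00 beta=+0.358
  FOREST_1000                  /   imp=0.80 beta=+0.492
  GRASS_1000                   \   imp=0.51 beta=-0.188
  Marginal R2  : 0.312
  Landscape R2 : 0.309
  % Landscape  : 98.9
```

Each diversity row gives a population's rarefied allelic richness (at a
common 40-gene-copy subsample), heterozygosities and inbreeding
coefficient.  The report lists every term with importance ≥ 0.5 in the
ΔAICc < 2 average model: here forest cover in the 1000 m buffer has a
positive effect (`/`) on expected heterozygosity with importance 0.80 and
a standardized coefficient of +0.49 SD, grassland a weaker negative one;
the landscape metrics explain 0.309 of the 0.312 marginal R² (98.9%),
i.e. almost all explained variation beyond population size and isolation
is attributable to landscape structure (the genotypes here carry no true
landscape signal at this effect size — importances near the 0.5 cutoff on
a 24-population scenario illustrate the method, not an inference).

The same analysis runs from the shell:

```sh
landgen simulate --seed 7 --out sim/
landgen popgen   --genotypes sim/genotypes.csv --nodes sim/nodes.csv --out sim/
landgen run-node --map sim/window_W0.geojson --map sim/window_W1.geojson \
                 --genotypes sim/genotypes.csv --nodes sim/nodes.csv --out sim/
```

Subcommands: `simulate`, `popgen`, `metrics-node`, `metrics-link`,
`run-node`, `run-link`, `report`.

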