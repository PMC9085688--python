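# Methods

`landgen` links the population genetic structure of slow-colonizing forest
herbs in fragmented agricultural landscapes to the composition and
configuration of the surrounding landscape matrix.  The analysis has two
levels.  At the **node level** the unit is a single population and the
responses are within-population diversity: rarefied allelic richness (Ar),
expected and observed heterozygosity (He, Ho) and the inbreeding
coefficient F = 1 − Ho/He.  At the **link level** the unit is a
within-window population pair and the responses are pairwise
differentiation: Hedrick's standardized G″ST and the shared-allele
distance D_PS.  Landscape structure is quantified in circular buffers
around populations (node level) and rectangular strips connecting
population-centre pairs (link level).

## Population genetic statistics

Allele frequencies are estimated from gene-copy counts.  Diploid records
contribute their two called alleles.  Tetraploid records scored without
dosage (only the set of distinct alleles is known) are expanded to equal
weights summing to four gene copies — unbiased under ignorance of dosage
and standard practice for partially heterozygous polyploid microsatellite
calls.

* **He** — Nei's gene diversity 1 − Σp², by default with the small-sample
  correction n/(n−1) applied at the gene-copy level; the uncorrected form
  is available via a flag.
* **Ho** — the fraction of individual-locus records carrying at least two
  distinct alleles, for both ploidies.  This definition avoids any
  dependence on unknown tetraploid dosage.
* **F** — 1 − Ho/He per population, undefined (NaN) where He = 0.
* **Ar** — hypergeometric rarefaction: the expected number of distinct
  alleles in a subsample of g gene copies,
  Ar = Σᵢ [1 − C(N−Nᵢ, g)/C(N, g)], averaged over loci.  The default g is
  the minimum per-locus gene count over all populations and loci of the
  table, which makes the statistic comparable across populations and
  deterministic on reruns.
* **D_PS** — 1 − (1/L) Σ_loci Σ_alleles min(p_A, p_B), computed on
  population allele-frequency vectors.  This population-level form of the
  "proportion of shared alleles" is simpler than averaging over individual
  pairs and identical in expectation for random-mating populations.
* **G″ST** — per locus, HS is the mean within-population gene diversity
  and HT the diversity of the pooled (mean) frequency vector.  HS and HT
  are averaged across loci first and the k = 2 standardization
  G″ST = k(HT−HS)/[(kHT−HS)(1−HS)] is applied once to the multilocus
  averages.  Negative estimates are reported, not clamped.  With
  `corrected=True` the Nei–Chesser sample-size-corrected estimators
  ĤS = 2ñ/(2ñ−1)·HS and ĤT = HT + ĤS/(2ñk) replace the plug-in values
  (ñ = harmonic mean individual count).  The correction matters in limit
  checks: the plug-in form carries a positive O(1/n) sampling bias, so
  near-identical populations score a small positive G″ST unless corrected.
* **Spatial determinants** — edge-to-edge distance is the minimum
  Euclidean distance between patch polygons (0 when touching); Hanski's
  incidence-function connectivity is Sᵢ = Σ_{j≠i} exp(−α·dᵢⱼ)·Aⱼᵇ with
  Aⱼ the neighbour's flowering-shoot count, summed within a landscape
  window.  The original parameterization is not printed in the source
  material, so α and b are configurable; the defaults α = 1/1000 m⁻¹
  (mean dispersal distance 1 km, mid-range for insect pollinators and
  mid-sized mammals) and b = 0.5 (sub-linear size weighting) are stated
  here once and not tuned.  The modelling layer consumes −Sᵢ as
  "isolation" so that larger values mean more isolated.

Population statistics average over scored loci only; pairs sharing fewer
than 3 scored loci are flagged missing.

## Landscape metrics

Inputs must be planar projected coordinates in meters (the analysis
operates inside 5 × 5 km windows; no geographic-CRS support).  Buffers are
discs approximated by 256-vertex polygons (radius error < 0.01%); buffer
radii default to 125, 250, 500, 1000 and 2000 m.  Strips are rectangles
whose long axis joins the two population centres, with width-to-length
ratios 1:7, 1:5, 1:3, 1:2 and 2:3.  Both are clipped to the window extent
and all denominators use the clipped area.

* **Percent cover** per land-use class (FOREST, GRASS, SEMNATGRASS,
  SEMNATVEG, ARABLE, ORCHARD, SETTLE, OTHER).  Crop-type covers (RAPE,
  MAIZE, CEREAL) weight each arable parcel's clipped area by the fraction
  of the years 2008–2017 the parcel grew that crop.  Frequency weighting
  (rather than majority classification) treats decade-scale crop dominance
  as a proportion and preserves RAPE + MAIZE + CEREAL ≤ ARABLE exactly.
* **Relative length** of linear elements (LWOOD hedgerows/tree lines,
  LWATER water courses, LFRINGE herbaceous fringes, LROAD roads): clipped
  length divided by zone area, m/ha.
* **Orientation decomposition** — every polyline is clipped to the zone;
  each connected clipped piece is one feature.  The reference direction is
  the strip axis (strips) or the direction from the feature's arc-length
  midpoint to the population centre (buffers).  A straight segment of
  length ℓ at angle θ to the reference contributes ℓ|cosθ| to the parallel
  and ℓ|sinθ| to the orthogonal total.  Whether the decomposition should
  be computed per feature or per segment, before or after clipping, is
  genuinely open; clipping first and taking the midpoint per clipped piece
  keeps the reference direction local to the part of the element that can
  actually influence movement through the zone.  A degenerate feature
  whose midpoint coincides with the centre is counted fully orthogonal and
  logged.  The orthogonal-to-parallel ratio O:P = (o + c)/(p + c) uses a
  1 m stabilizer c to avoid division by zero while preserving ordering;
  c is recorded in the output metadata.  In output tables these
  conditioning columns are named `OP_<class>_<scale>` — a plain-text
  rendering of the O:P ratio, suffixed with the scale of the zone it was
  measured in, because a conditioning variable is only meaningful at the
  scale of its metric.
* **Shannon diversity** −Σ p ln p over the 8 area-based classes present in
  the zone (the crop split is not used here).
* **Edge density** counts only internal boundaries between parcels of
  different land-use class, divided by zone area; the zone outline and the
  window border are excluded so a uniform landscape scores 0 at every
  scale.
* **PROPGREEN** is the area-weighted mean green fraction of settlement
  parcels in the zone (0 when no settlement is present).

## Transformations and mixed models

All responses and predictors are Box-Cox-transformed to symmetrize their
distributions and then centred and scaled, so coefficients are in SD
units.  Variables with non-positive values are shifted by |min| + 1% of
the range first; the exponent λ maximizes the profile log-likelihood over
[−3, 3].  Constant or non-finite columns are left untouched (they are
excluded from selection anyway).

The mixed model has marginal covariance

    Σ = σ²_w Z_w Z_wᵀ + σ²_p A Aᵀ + σ²_e I

where Z_w indicates the landscape window (random intercept) and A is the
pair-incidence matrix with two unit entries per row — the
maximum-likelihood population-effects (MLPE) structure that accounts for
the non-independence of pairs sharing a population.  A is absent at node
level.  The variance ratios γ = σ²/σ²_e are profiled out on the log scale
and optimized with analytic-gradient L-BFGS-B from three fixed starting
points, plus boundary candidates with each component pinned at zero;
convergence tolerance is 1e−12 on the scaled objective.  β is the GLS
solution at the optimum; the residual variance is profiled in closed form.
Regions where X′V⁻¹X becomes numerically singular (unbounded variance
ratios push the intercept into the random-effect span) are rejected
during optimization.  Everything is deterministic given the data.

Model selection uses ML likelihoods; final coefficient estimates come from
REML refits.  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting fixed
coefficients plus all variance parameters (window, MLPE population where
present, residual) — one consistent convention across node and link
models.  Likelihood-ratio tests compare nested ML fits against χ².
Marginal R² follows Nakagawa–Schielzeth:
var(Xβ) / (var(Xβ) + σ²_w + 2σ²_p + σ²_e); the MLPE component enters with
weight 2 because every pair row loads on exactly two population effects —
no published convention exists for MLPE, so the choice is stated here.

## Three-step selection and model averaging

1. **Scale selection.**  For each metric family, single-metric models are
   fitted at every candidate scale.  The model always carries the linear
   term and, for linear elements and settlement, the conditioning-variable
   interaction (O:P ratio or PROPGREEN at the same scale); a quadratic
   term and, at link level, a geographic-distance interaction are added
   only when they lower AICc.  The scale with the lowest AICc wins; ties
   (AICc equal to 9 decimals) break toward the smaller scale, then the
   simpler model, so reruns are reproducible.
2. **Screening and collinearity.**  A family survives only if a
   likelihood-ratio test of all its terms jointly against the basic model
   has p < 0.15.  Among the survivors, correlations |r| ≥ 0.7 are not
   tolerated: metrics belonging to a declared intrinsic group are merged
   into the standardized first principal-component score of the cluster
   (sign oriented to correlate positively with the first-named member);
   collinear metrics from different groups are resolved by keeping the one
   with the lower single-metric AICc.  The intrinsic grouping is supplied
   explicitly by the analyst (there is no algorithmic definition of
   "ecologically related"); by default all metrics form one group.
3. **All-subsets inference.**  All subsets of the surviving terms obeying
   marginality (a quadratic or interaction never enters without its main
   effects) and the term cap — 4 at node level, 9 at link level — are
   fitted by ML with the basic determinants always included.  Models
   within ΔAICc < 2 of the best are refit by REML and fully averaged:
   Akaike weights w = exp(−Δ/2)/Σexp(−Δ/2), a term absent from a
   component model contributing 0 to its average.  A term's importance is
   the summed weight of component models containing it; terms with
   importance ≥ 0.5 are reported.  Landscape R² is the marginal R² of the
   averaged model minus that of the basic model (population size +
   isolation, or distance only); it may be negative and is reported as-is.
   The averaged model's R² is evaluated on the single best component model
   containing all important terms, or on a dedicated REML refit with
   exactly those terms when no component model contains them all —
   averaging R² values across models with different random-effect
   estimates has no defined meaning.
   The crop-split and lumped-ARABLE variants are both run; the variant
   with the higher final marginal R² is reported (ties favour the more
   informative crop split).

Effect shapes in reports use the symbols /, \ (positive/negative linear),
∩, ∪ (unimodal with interior maximum/minimum), asymmetric variants /∩,
\∩, /∪ when the parabola vertex lies outside the central 50% of the
predictor range (a quantitative stand-in for a visual classification),
and X for an important interaction.

## Synthetic data

The generator emulates the study conditions so every stage has a
closed-loop test: 5 × 5 km windows (4 by default), up to six populations
per window at least 200 m apart inside forest parcels, flowering-shoot
counts log-uniform between 15 and 1.2 × 10⁷, per-year crop records for
2008–2017.  Land-use mosaics are Voronoi partitions of uniform random
points with classes assigned greedily toward target area fractions
(defaults: 50% arable, 18% grassland, 12% forest, 6% settlement, the rest
minor classes — an arable-dominated north-west European mosaic).  Linear
elements are random-walk chains of 250 m segments whose headings follow a
von Mises distribution with configurable concentration κ and mean angle,
giving controllable orientation anisotropy (κ = 0 is isotropic);
orientation is undirected (half the headings are flipped).  Default line
densities are 25 (LWOOD), 12 (LWATER), 4 (LFRINGE) and 15 (LROAD) m/ha.

Genotypes follow a Dirichlet hierarchy: per locus, ancestral frequencies
are symmetric Dirichlet(1) over A alleles; population i draws its
frequencies from Dirichlet(ancestral × (1−θᵢ)/θᵢ) with divergence
θᵢ = logistic(a + b·driverᵢ) for a configurable node-level driver;
individuals are i.i.d. draws of ploidy gene copies.  This is *not* a
coalescent or spatially explicit gene-flow simulation — it produces the
right first-order signal (driver→divergence monotonicity, θ→0 identity
limit) at negligible cost, but no linkage, drift trajectories, mutation
model or isolation-by-distance pattern; conclusions from passing tests
are about the statistics and the inference machinery, not about realism
of microsatellite evolution.  Responses for recovery studies are drawn
exactly from the mixed-model generative process (Xβ + window effects +
population effects + noise).

All generators are pure functions of (config, seed); each stage draws
from a named substream derived from (seed, stage tag, index), so changing
one stage's draws cannot shift another's.

## Study sizes used in validation

The recovery study uses 200 replicate link datasets of 120 pairs (all
pairs of 16 populations labelled across 4 windows) with β = 0.5 SD and
variance components (0.25, 0.25, 0.5); the selection-power study uses 100
replicates of 100 links with one true effect among 8 candidate families
at 3 candidate strip ratios each (linear terms; the power question
concerns the linear effect).  The pinned golden fixture is 2 windows ×
4 populations × 5 loci, digest-stored with values rounded to 10 decimals.

## Known limitations

* The MLPE k-counting and marginal-R² conventions are package choices
  (documented above); other software may count differently, shifting AICc
  by a constant within a comparison set (harmless) but changing absolute
  values.
* Tetraploid Ho is a presence-based definition and not comparable to
  dosage-aware heterozygosity.
* Collinearity handling needs the analyst's intrinsic grouping to
  distinguish composite-building from drop-one resolution; the default
  (one group) always builds composites.
* Edge density scales with parcel granularity of the input map; maps
  digitized at different resolutions are not comparable.
* The generator's Voronoi parcels have unrealistic shape statistics
  (convex cells) and its lines are not network-connected; both are
  irrelevant to the metrics tested but visible on plots.
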