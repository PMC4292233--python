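# Methods

`treeadapt` simulates the genetic adaptation of bud-burst phenology in an
individual-tree beech stand. This note documents the model components, the
parameter choices that matter, what the synthetic inputs do and do not
emulate, and the numerical conventions.

## Quantitative-genetic core

Each adaptive model parameter is a polygenic trait of `n_loci` unlinked
di-allelic loci. The machinery has three steps:

1. **Initial allele frequencies.** The equilibrium allele-frequency
   density is taken as φ(x) = Beta(θ, (k−1)θ) with θ = H/(1−H), where H is
   the trait heterozygosity and k the alleles per locus. This family is
   flat (φ ≡ 1) at k = 2, H = 0.5 and U-shaped for H < 0.5, the two
   qualitative anchors the model is built on; it is a reconstruction in
   the sense that only those properties, not a specific literature
   parameterization, constrain it. Per-locus "+"-frequencies are the
   quantiles of φ at mid-levels (i − ½)/n_loci — symmetric for symmetric
   φ, never exactly 0 or 1, assigned to loci in ascending order (loci are
   exchangeable afterwards).
2. **Allelic effects.** Raw effects of +1/−1 are affinely normalized using
   analytic Hardy–Weinberg moments: per-copy centering by p − q and
   division by σ = √(8·Σ p_l q_l), so the summed diploid deviate has mean
   exactly 0 and variance exactly 1. The per-allele magnitude is E = 1/σ;
   the allele-substitution effect is 2E at every locus, hence a 10-locus
   trait spans deviates −20E..+20E between the two extreme homozygotes.
3. **Values.** Genotypic value = trait mean + √Vg × deviate. Phenotype
   adds N(0, Ve), Ve = Vg(1−h²)/h², drawn once per individual at birth:
   the parameter is a fixed property of a tree, not re-drawn yearly.

Defaults for both adaptive traits: 10 loci, k = 2, H = 0.25, h² = 0.5.
Dominance, epistasis, mutation and linkage are excluded: the traits are
purely additive, gametes assort freely, and the simulated horizons (a few
centuries) are short relative to mutational input.

## Phenology and the frost rule

Bud burst follows a sequential chilling–forcing scheme. Chilling
accumulates from November 1 (1-based day-of-year on a 365-day calendar)
with a triangular response: 0 at or below −20 °C and at or above 12 °C,
peak 1 at 0.5 °C. Forcing, counted only after the chilling state reaches
the tree's S\*_c, follows r = tanh(0.1·(T − 0 °C)) above the base, a
saturating, strictly increasing response. Bud burst is the first day the
forcing state reaches the tree's S\*_f. These response shapes and
breakpoints are package choices, selected so that chilling remains
effective across the full range of synthetic European winters (seasonal
winter means from about −3 to −13 °C); all are configurable.

Daily mean temperature drives both accumulations; the daily minimum drives
frost: a minimum strictly below −2 °C (deciduous-broadleaf frost
hardiness) on any day after bud burst costs an adult that year's foliage
and flowers — no seed production and a 50% cut of the year's growth
increment — and kills a seedling with emerged leaves outright.

**Trait units and calibration.** S\*_c and S\*_f are in model-specific
chilling/forcing units, so their absolute scale is set by the response
functions. The defaults (S\*_c mean 90, Vg 25; S\*_f mean 28, Vg 2) were
calibrated once so the source (Dutch) population completes chilling in
midwinter and reaches mean bud burst near May 5 — the source population's
anchor — with a genetic bud-burst-date spread of about ±2 d (matching a
date-scale genetic variance of ~5 d²). Negative phenotypic values arising
from the environmental deviate are clipped to 0 when used.

## Stand, growth, mortality

Stands are generated from inventory-style statistics: round(density ×
area) trees, heights and diameters from zero-truncated normal laws with
the stated means and CVs, positions uniform (no spatial structure), one
uniform age. The default stand is the even-aged beech experiment: 581
trees/ha, height 18.6 m and dbh 18.5 cm (CV 0.1 each), age 40.

Growth is a deliberate surrogate for a full ecophysiological model. It
preserves the single property the eco-evolutionary results rest on — the
productivity value of a longer frost-free season: annual dbh increment =
0.6 cm × min(season/165 d, 1) × light, where season runs from bud burst to
a fixed senescence day (doy 280), and light = exp(−6·B) with B the basal
area (m²) of strictly taller trees within 8 m. Height follows
h = 1.8·dbh^0.8 (anchored to the 18.5 cm / 18.6 m inventory stand), never
shrinking. Trees at or above 5 m are adults (the management retention
height doubles as the stage boundary); recruits start at dbh 0.5 cm.

Mortality per year: frost deaths (above), suppression — trees whose
increment fell below half the canopy-median increment die with probability
0.4 — and a background 0.005. The suppression reference uses canopy
(≥ 5 m) trees when any exist so that a large regeneration bank cannot
neutralize self-thinning. These constants reconstruct an undocumented
mortality scheme and were chosen to give closed-canopy stands that
self-thin to inventory-like densities; they are config values.

## Reproduction and management

Adults whose flowers escaped frost set Poisson(0.01 × dbh²) seeds. Pollen
donors are drawn with probability ∝ exp(−distance/30 m), selfing excluded
by default; seeds disperse from the mother with an exponential 15 m
kernel, clipped to the plot. Each offspring gets one free-recombination
gamete per parent per trait and a fresh environmental deviate. Recruitment
is capped at 0.01 seedlings/m²/yr by genotype-blind random thinning — the
cap is density regulation, not selection (verified by a martingale test).
An optional immigrant-pollen hook is deliberately absent: the reconstructed
experiment runs closed populations.

Management implements FMA 4 (intensive even-aged forestry) fully: when
stand age — the mean age of trees at ≥ 50% of maximum height — first
reaches 60, trees at or above 5 m are cut back to the 50 largest-diameter
per hectare; retained small trees regenerate the stand; surviving seed
trees are removed ten years after the realized cut (the nominal "harvest
at stand age 70" re-expressed relative to the realized cut year, since
regeneration drags the recomputed stand age). After the final harvest the
plan state resets so the next even-aged generation is managed identically.
FMA 1 is a no-op; FMAs 2, 3 and 5 are configuration stubs.

## Weather

The generator works on a 365-day calendar. Daily mean temperature is a
skewed sinusoid (separate winter and summer amplitudes, mean-corrected)
plus AR(1) noise (ρ = 0.7, stationary sd 2.5 °C); the amplitudes are
solved so the 1st/99th percentiles of daily means match the site's stated
long-run extremes — the packaged interpretation of a site's [min, max]
summary. Minima and maxima sit ∓4 °C around the mean; radiation is a
non-negative seasonal shape scaled to the annual total with lognormal
noise; precipitation is wet-day (p = 0.5) exponential draws scaled to the
annual total. A warming offset shifts every day by exactly that amount;
no CO₂ forcing of any kind is represented. Seven European beech site
summaries ship as a TSV fixture.

Frost-selection scenarios add explicit late-frost events: with probability
1/interval per year, one day in a spring window (default doy 115–135,
chosen to straddle the population's bud-burst distribution so events
produce differential rather than all-or-none kills) has its minimum forced
to −5 °C. What the generator does *not* emulate: observed day-to-day
weather sequences, spatial correlation between sites, trends within a
scenario, or realistic winter means at maritime sites (matching stated
extreme daily means makes synthetic winters colder than observed
climatology — the chilling response breakpoints account for this).
Passing tests therefore demonstrate the model's internal selection logic
under controlled forcing, not a reproduction of any observed series.

## Simulation loop and experiments

Within a year: phenology → frost checks → growth under competition →
mortality → reproduction → management → bookkeeping. The order makes one
frost event cost survival (seedlings), fecundity and growth (adults) in
the same year. Replicate r uses seed base_seed + r with a fresh stand and
weather; a stand that loses its last tree is flagged extinct, ends
gracefully, and is excluded from cross-replicate means. The `selection`
switch, when off, disables *all* phenotype-dependent demography (frost
effects and the season-length growth coupling), giving genuinely neutral
dynamics — the reference point for drift tests.

The translocation experiment initializes every site with the identical
source architecture and differs only in climate; end-state trait means
feed ordinary least-squares clines (S\*_c on latitude, S\*_f on site mean
temperature) and a bud-burst response table comparing the first and last
25-year windows. The configured default horizon is 400 years with 5
replicates on 1 ha; the shipped tests and examples use shorter horizons
and fewer sites (50–150 years, 2–5 replicates), which preserve every
qualitative behaviour they assert while keeping runs at desk scale.

## Numerical conventions and limitations

- 365-day calendar throughout; leap days in read weather files are
  dropped and day-of-year re-counted.
- Bud burst uses cumulative-sum inversion (searchsorted); ties resolve to
  the earliest qualifying day; with S\*_f = 0 bud burst falls on the day
  chilling completes.
- The frost boundary is strict: a minimum of exactly −2 °C is harmless.
- Seeded `numpy.random.Generator` everywhere; identical config and seed
  give byte-identical outputs.
- The growth surrogate has no photosynthesis, water balance or carbon
  allocation; mixed-species stands, seed banks, masting, frost-hardiness
  dynamics and senescence phenology are out of scope.
- Trait units for S\*_c/S\*_f are internal to the chosen response
  functions; comparisons with published values in other unit systems
  require recalibration.
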