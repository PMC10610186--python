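# Methods

`mzosim` asks how latitudinal and elevational gradients of tree-community
phylogenetic diversity arise from the biogeographic history of lineages, and
contrasts two assembly processes:

* **Tropical niche conservatism (TNC)** — all lineages originate in the
  warm/wet tropical lowlands; colonization of climatically dissimilar regions
  (temperate zones, tropical highlands) is rare.  Predicts phylogenetic
  diversity *decreasing* with latitude and elevation.
* **Multiple zones of origin (MZO)** — lineages originate in both tropical and
  temperate lowlands and disperse preferentially between climatically similar
  regions (temperate zones and tropical highlands share a cold/seasonal
  climate).  Predicts phylogenetic diversity *increasing* with latitude and
  elevation, because highland and temperate communities mix deeply divergent
  lineages.

## Simulation model

Each replicate has three stages.

**1. Diversification.**  A constant-rate birth–death process, simulated
forward by the Gillespie algorithm: every extant lineage waits an exponential
time at rate λ+μ, then speciates with probability λ/(λ+μ) or dies.  Defaults
λ = 0.5, μ = 0.05 per lineage per My.  The simulation stops the first time the
extant count reaches the target N and the tree is cut at that instant (a
"simple stop": analyses condition on N, so the known small bias of this
stopping rule relative to fixed-age sampling is immaterial here).  Whole-clade
extinction triggers a retry with fresh draws (cap 100, then an error).
Extinct tips are pruned and unary nodes suppressed with lengths summed, so the
returned tree is ultrametric (checked to 1e-9 relative).  The pre-crown stem
is dropped; returned trees are crown trees.

**2. Region evolution.**  Species occupy one of four exclusive regions —
TrL, TrH, TeL, TeH (tropical/temperate × lowland/highland).  The region is a
discrete trait evolving along branches as a continuous-time Markov chain with
generator Q.  Allowed moves: TrL↔TeL and TrL↔TrH at `rate_dissimilar`
(cross-climate), TeL↔TeH and TrH↔TeH at `rate_similar` (within the
cold/seasonal class); TrH↔TeL is off by default (configurable).  Defaults
`rate_similar = 0.1`, `rate_dissimilar = 0.01` shifts per lineage per My — a
10:1 ratio that keeps cross-climate colonization rare while populating all
four pools.  These two values are the model's main free calibration: the
magnitudes (not the signs) of the simulated gradient slopes depend on them.
TNC roots the whole tree in TrL.  MZO simulates two independent clades of
round(0.75·N) and the remaining tips, joins them at a new root (the deeper
crown defines the join depth; the shallower clade's stem is extended so the
joined tree is ultrametric), and starts region evolution at TrL and TeL
respectively, with no state change on the artificial stems.

**3. Communities and gradients.**  Tips partition into four regional pools.
From each pool, 10 local communities are drawn, each an independent uniform
subset of round(0.10·pool) species (round-half-even, floored at 2 — MPD needs
a pair).  A pool under 20 species marks the replicate degenerate; the study
re-draws it with a fresh stream and counts the re-draw.  For each of the 40
communities, MPD (mean patristic distance over unordered pairs) is
standardized against a richness-matched null — uniform subsets of a shared
pool, by default the union of species over the 40 communities, equivalent to
a taxa-label shuffle of the community dataset's distance matrix (the
behaviour of the standard permutation implementation this metric comes
from).  Drawing nulls from each community's *own regional* pool would centre
every region at ses ≈ 0 by construction and erase the gradients, so it is
available only as an option.  Null draws are shared across equally rich
communities within a replicate, exactly as a matrix-permutation null shares
them; `mpd_ses` called standalone draws independent nulls.  The 40 ses
values are z-scored and regressed (simple OLS) on the latitude factor
(tropical = 0, temperate = 1) and on the elevation factor (lowland = 0,
highland = 1) separately, mirroring the two-panel design.  Slopes are in SD
units per factor level.

**Aggregation.**  Across replicates: mean slope, one-sample two-sided t vs 0,
and the fraction of replicates with two-sided p < 0.05 — reported both raw
and filtered to the scenario-predicted sign.  Scenario slope distributions
are compared with a two-sample Kolmogorov–Smirnov test.

**Randomness.**  One master seed per study; `numpy` `SeedSequence` spawning
gives every replicate (and every degenerate re-draw) an independent child
stream, so results are bit-reproducible for a given (config, seed) and
replicates are independently reproducible.

### Problem sizes

Default configuration is N = 10,000 tips and 1,000 replicates with 999 null
draws.  The shipped tests and the acceptance script run the studies at
N = 2,000 tips, 200 replicates and 199 nulls — sizes chosen so a full
two-scenario study completes in about a minute on one core while the
between-replicate spread of the slope estimates is already dominated by tree
stochasticity, not by the reduction.  Spot checks at N = 1,000 and N = 4,000
give the same slope pattern.

### Known behaviour at the default calibration

With `rate_similar/rate_dissimilar = 0.1/0.01` the mean slopes carry the
predicted signs (TNC negative, MZO positive on both gradients) and the
TNC/MZO slope distributions separate sharply (KS p ≪ 0.001).  The *fraction*
of individually significant replicates is 0.3–0.5 on most gradients (MZO
elevation ~0.8), and the MZO latitude slope is the weakest quantity: the
signal strength depends directly on the assumed transition rates, and the
between-replicate spread at these rates is wide because a handful of deep
colonization events dominate each replicate's pool structure.  Stronger and
more balanced mixing rates raise all four magnitudes; the defaults are kept
as stated rather than tuned to any particular outcome.

## Empirical pipeline

Inputs: a stems CSV (`plot_id, taxon, rank, dbh_cm`), a plot-metadata CSV
(`plot_id, lat, lon, elev_m, area_ha, mat_c, map_mm`) and a rooted newick
phylogeny whose tips include the inventory taxa (taxa identified only to
genus/family enter as their own terminal labels; no grafting is attempted and
unmatched taxa are reported, never silently dropped).  Filters: stems without
taxonomic identification and stems with DBH < 10 cm are removed, with
per-reason counts.  Plots retaining fewer than 2 matched taxa are excluded
and logged.  Polytomies are resolved uniformly at random over labelled
topologies with zero-length inserted edges; because zero-length insertion
preserves every patristic distance exactly, all resolutions give identical
MPD values and the resolution loop defaults to a single pass
(`n_resolutions` restores the multi-tree average for user-supplied
resolutions with nonzero lengths).  MPD_ses uses the network-wide matched
taxon list as the null pool so plot values are comparable.  Because plot
area affects MPD_ses, the values are first regressed on area and the
residuals carried forward.  Gradient fits are simple OLS of the residuals on
absolute latitude (signed latitude via a flag), elevation, or mean annual
temperature; slopes are reported raw and standardized (both variables
z-scored, i.e. the Pearson correlation).

**Vessel analysis.**  To ask whether temperate-origin species keep narrower
water-conducting vessels than tropical species of the same height, the model
is OLS of log10(vessel diameter, µm) on log10(height, m) plus a 0/1
temperate indicator (tropical = 0); the origin effect is reported as its
coefficient with F = t² and p.  A second view fits the pooled log–log
regression without origin and compares the residuals between origins with a
pooled-variance two-sample t-test (t reported as tropical − temperate, so
positive t means tropical vessels are wider at equal height).

## Synthetic-data generator

The generator emulates the *structure* of an Andean plot network so the
empirical pipeline is testable end to end without any external data: 245
plots, latitudes 7.1° N–27.8° S, elevations 150–3,511 m, areas
{0.25, 0.5, 1} ha (majority 1 ha), MAT linear in elevation (≈5.5 °C/km
lapse) and absolute latitude with noise, affinely rescaled to span
7.3–23.8 °C.  Plot communities are drawn from a simulated MZO scenario tree
(default 1,000 tips): each species is temperate-affiliated (member of the
temperate-origin clade) with probability

    w(plot) = 0.15 + 0.13 · [effect_lat · z(|lat|) + effect_elev · z(elev)]

and tropical otherwise; a w outside [0, 1] marks the requested effects
infeasible.  The intercept and gain were calibrated once, jointly: community
dispersion is non-monotonic in the clade mix (it peaks where a community
matches the pool's own mix), so plots must sit on the rising flank of that
curve for mixing to *increase* ses; with intercept 0.15 and gain 0.13 the
default targets (standardized slopes 0.24 latitude, 0.26 elevation)
reproduce themselves through the full pipeline at 245 plots (measured
+0.244 ± 0.022 and +0.277 ± 0.017 over 20 calibration seeds).  Richness scales with area^0.25
(~30 species/ha), stems per plot with area; DBH is 10 cm + lognormal because
the inventory protocol records only stems ≥ 10 cm (the DBH filter is
exercised on toy fixtures); 6.1% of stems are marked unidentified so the
identification filter retains 93.9%.  Every dataset ships a truth JSON
(effect sizes, signs, weight parameters) and recovery tests read only that
file.  The vessel generator draws log-uniform heights over 2–60 m and
log10 diameters a + b·log10 h + offset·I(temperate) + ε with defaults
a = 1.30, b = 0.45, σ = 0.10 and offset −0.08.

What the generator does **not** emulate: real taxonomic composition, spatial
autocorrelation, abundance structure, climate-layer extraction.  Passing
recovery tests therefore show that the pipeline detects the *mechanism* it
implements (deep-clade mixing along gradients) at realistic sample sizes —
not that any particular empirical dataset satisfies these assumptions.

## Numerical choices and edge cases

* Cophenetic distances are assembled per internal node over cross-child tip
  blocks (d(i,j) = depth_i + depth_j − 2·depth_MRCA), vectorized; exactness
  is cross-checked against a path-walk oracle and dendropy.
* MPD_ses with a zero-spread null (community = pool) is flagged degenerate
  with ses = 0; rank p is the one-sided high-tail quantile
  (1 + #{null ≥ obs})/(n_null + 1).
* z-scoring uses the n−1 denominator; zero variance raises an error rather
  than emitting NaNs.
* OLS p-values come from F(1, n−2) with F = t²; a constant predictor is an
  error.
* Community-size rounding is Python's round-half-even, floored at 2.
* The MZO join places the deeper crown directly at the root (zero-length
  stem); cross-clade distances are then exactly twice the deeper crown age.

## Limitations

* The transition-rate calibration is the dominant unknown; only slope signs
  and distribution separation are robust to it.
* Single-region states (no widespread ranges, no cladogenetic state change,
  no rate estimation from data).
* No fossilized birth–death, time-varying, or trait-dependent rates.
* The empirical module assumes pre-resolved taxon names and a user-supplied
  phylogeny; no name resolution or megatree grafting.
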