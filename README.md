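# mzosim

Simulations and analyses of latitudinal/elevational gradients in the
phylogenetic diversity of tree communities, contrasting two assembly
hypotheses:

* **TNC (tropical niche conservatism)** — lineages originate in the warm/wet
  tropical lowlands and rarely colonize colder zones; phylogenetic diversity
  should *decrease* with latitude and elevation.
* **MZO (multiple zones of origin)** — lineages originate in both tropical
  and temperate lowlands and disperse preferentially between climatically
  similar regions (temperate zones ↔ tropical highlands); phylogenetic
  diversity should *increase* with latitude and elevation.

The package is aimed at community phylogeneticists and biogeographers who
want to simulate these scenarios, measure diversity gradients with a
richness-controlled metric, and run the same measurement on plot-inventory
data.

## What it computes

Per scenario replicate: a birth–death phylogeny cut at N extant tips
(λ = 0.5, μ = 0.05 per lineage per My), a four-region biogeographic trait
(TrL/TrH/TeL/TeH) evolved along the tree as a continuous-time Markov chain
whose rates are faster between climatically similar regions, 10 local
communities per regional pool (random 10% subsets), and for each community
the standardized effect size of mean pairwise phylogenetic distance

    MPD_ses = (MPD_obs − mean MPD_null) / sd MPD_null,

with the null drawing equally rich communities from a shared species pool.
The 40 z-scored MPD_ses values are regressed (OLS) on latitude
(tropical = 0, temperate = 1) and elevation (lowland = 0, highland = 1);
slope distributions across replicates are summarized (mean, one-sample t,
fraction significant) and compared between scenarios with a two-sample
Kolmogorov–Smirnov test.

The empirical module applies the same metric to forest-inventory tables
(stems ≥ 10 cm DBH, identified taxa) against a user-supplied phylogeny,
residualizes plot-level MPD_ses on plot area, and regresses the residuals on
absolute latitude, elevation or mean annual temperature.  A companion model
tests whether temperate-origin species have narrower water-conducting
vessels than tropical species of the same height
(log10 diameter ~ log10 height + origin).  A synthetic-data generator
produces plot networks and vessel tables with known ground truth for
end-to-end testing.  See `docs/methods.md` for the full model description.

## Worked example

A reduced MZO study from the command line (50 replicates, 1,000-tip trees,
199 null draws):

```
$ mzo-sim study --model MZO --reps 50 --ntips 1000 --n-null 199 --seed 7 -o mzo_demo
...
"latitude":  { "mean_slope": 0.096, "t_stat": 0.78,  "t_p": 0.44,    "frac_significant": 0.32, ... }
"elevation": { "mean_slope": 0.802, "t_stat": 8.95,  "t_p": 7.1e-12, "frac_significant": 0.72, ... }
```

The mean elevation slope of +0.80 SD per factor level (t-test against zero,
p ≈ 7e-12, 72% of replicates individually significant and positive) says
that under the two-origin scenario highland communities are consistently
more phylogenetically dispersed than lowland ones; the latitude slope is
positive but weak at this reduced scale and transition-rate calibration.
`mzo_demo/replicates.csv` holds the per-replicate slopes and p-values.

The synthetic empirical pipeline, end to end:

```
$ mzo-sim synth network --seed 11 -o net
$ mzo-sim synth vessels --seed 11 -o net
$ mzo-sim empirical --stems net/stems.csv --meta net/meta.csv --tree net/tree.nwk \
      --vessels net/vessels.csv --n-null 199 --seed 1 -o out
abs_latitude: std slope +0.266 (F=18.47, p=2.5e-05, n=245)
elevation: std slope +0.302 (F=24.42, p=1.4e-06, n=245)
mat: std slope -0.346 (F=33.11, p=2.6e-08, n=245)
vessel origin term: coef -0.087 (F=63.11, p=4.1e-14); residual t=7.94 (p=4.3e-14)
```

The generator built this 245-plot network with true standardized slopes
+0.24 (latitude) and +0.26 (elevation) and a −0.08 log10 temperate vessel
offset; the pipeline recovers positive, significant gradient slopes of the
right size, an MAT slope of the opposite sign (MAT falls with elevation),
and a negative, significant origin coefficient.

## Layout

```
src/mzosim/
  trees.py           array-backed phylogenies, newick I/O (dendropy)
  treesim.py         birth-death simulation, extinct-lineage pruning
  biogeography.py    regions, transition models, scenario construction
  communities.py     regional pools, community sampling
  phylodiv.py        cophenetic distances, MPD, MPD_ses, polytomy resolution
  gradients.py       z-scoring, OLS, replicate studies, KS comparison
  empirical.py       inventory pipeline + vessel model
  synthetic_data.py  plot-network and vessel-table generators
  cli.py             `mzo-sim` command group
```
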