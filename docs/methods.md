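# Methods

## The four-segment estimator

The estimator treats one-time genetic sampling as a capture process.
Adults fall into four segments by what the reconstructed pedigree shows:
sampled-and-matched (linked), sampled-and-unmatched (unlinked),
unsampled-but-matched (inferred: a mate and a shared offspring were both
sampled, so the animal's existence and genotype are implied), and
unsampled-and-unmatched (invisible).  Under independence of sampling and
matching, the joint probability of being observed at all is
`1 − (1 − p_sampled)(1 − p_matched)`, and dividing the observed count by
it estimates the adult population, exactly as classical
capture–recapture divides a known sample by a capture probability.  The
marginals are estimated by conditional proportions: `p_sampled` from the
matched subset (linked vs inferred), `p_matched` from the sampled subset
(linked vs unlinked).

Conventions and edge rules:

* **Adults only are counted**; offspring of any age (calves included)
  create the matches.  The adult threshold is age ≥ 2 at the December
  census, configurable.  Moose in their second winter (census age 1)
  can already have bred, so a ≥1 cutoff is defensible; we measured both
  and kept 2 — a ≥1 threshold mixes in yearlings whose much lower
  matching probability violates the homogeneity assumption and produces
  a persistent negative bias.
* **Known-dead adults are excluded from every segment.**  In the
  simulation experiments the oracle death state plays that role, so
  segment counts contain only adults alive at the census; the residual
  positive bias of multi-year surveys then comes from live emigrants
  that the cumulative pedigree keeps tracking, not from ghosts.  In
  field use the flag is whatever mortality information the study has.
* `n_linked = 0` raises a typed error (the joint observation probability
  is zero); experiment loops record such iterations as failures rather
  than imputing.

## Bootstrap confidence intervals

Each marginal receives a Beta(1, 1) prior (configurable) updated to
`Beta(1 + n_linked, 1 + n_inferred)` for `p_sampled` and
`Beta(1 + n_linked, 1 + n_unlinked)` for `p_matched`.  Each bootstrap
trial draws both marginals from their posteriors, **redraws the four
segment counts** from the multinomial observation model of a population
of size `round(n_hat)` at the drawn marginals, pushes the redrawn counts
back through the estimator, and the interval is the percentile interval
of the resulting `n_hat*` sample (default 10,000 trials, 95% level).

Redrawing the counts is the one place this implementation goes beyond a
literal "bootstrap the joint probabilities": intervals built from the
posterior draws alone ignore the binomial noise of the counts entirely
and are badly anticonservative — under the estimator's own independence
model (N = 500, p = 0.6) their realized coverage is roughly half the
nominal level, whereas with count resampling it is on target.  The
probability-scale-only variant remains available
(`resample_counts=False`).

Even the calibrated interval under-covers in the full simulation
experiments at moderate sampling effort (the acceptance suite measures
this): the cow–calf sampling rule and age structure make sampling and
matching heterogeneous in ways the independence model cannot see, and a
percent-level bias against a narrow interval is enough to lose coverage.
We report this as a property of the method under these study conditions
rather than adjusting the interval to fit.

## The simulated moose population

An individual-based annual cycle starting at a December census:
winter survival → May birth pulse with mate assignment → aging →
yearling dispersal → summer survival, all Bernoulli per individual at
sex- and age-specific rates from a packaged table (northern New England
moose studies, senescence embedded as 1.6-fold mortality odds per year
after age 9, single calf per cow per year, reproduction ceasing after
age 14).  Sires are drawn uniformly among males older than 3 that were
alive at the previous census — the rut precedes the winter, so
candidacy is judged before winter mortality — and whose annual range
overlaps the dam's; a cow with no overlapping candidate skips that
birth (logged; a nearest-male policy could be swapped in).  Dead
animals are retained so the true pedigree is complete.

Two growth rates coexist, both inherited from the source schedule.  The
female projection matrix on census age classes (survival
`sw(a)·ss(a+1)`, terminal self-loop at the pooled 13+ class) has
dominant eigenvalue 1.003, and its stable age distribution reproduces
the packaged 659-animal starting structure.  Its fertility row is
`sw(a) · b(a) · 0.5 · c` with calf recruitment `c = 0.665` — first-summer
survival (0.70) times a 0.95 maternal-dependence factor — with `c`
calibrated so the matrix reproduces the schedule's published asymptotic
rate; the event-order dynamics of the simulator itself imply a slightly
higher asymptotic rate (≈1.011), which is what replicate runs realize.
The starting population places 659 founders at the printed per-class
counts (pooled classes split by within-class stable-age weights);
other sizes scale the stable distribution with largest-remainder
rounding.

## Synthetic spatial layer

Field home ranges would come from GPS-collar location clouds; no collar
data ship with this package, so it generates synthetic clouds instead:
isotropic bivariate-normal point sets around per-animal centroids —
50 annual points with spreads of 1.0 km (females) and 1.5 km (males),
and 30 winter points at 0.40/0.55 km around a winter centroid offset by
a 1-km normal.  Defaults give median annual 100% minimum-convex-polygon
(MCP) areas near 25 km² (F) and 55 km² (M) and winter ranges of a few
km², in line with the region's moose; they are free parameters, not
fitted quantities.  Calves share their mother's clouds until they
disperse at age 1 (uniform bearing, sex-specific truncated-normal
distance: 2.3 ± 0.4 km females, 9.3 ± 3.1 km males).

What the synthetic layer does **not** emulate: irregular and
habitat-driven range shapes, winter aggregation in favourable cover,
fine-scale utilization structure below the 1-km² grid, and
autocorrelated movement.  Spatial-sampling results (capture fractions,
effort thresholds, zone densities) are therefore qualitative, and the
tests hold them only to monotonicity, sign and ceiling checks rather
than point values.  Passing those tests says the estimator and designs
behave correctly on *a* realistic spatial population, not that
collar-driven numbers would be recovered.

## Sampling designs

Both designs run at the December census under demographic closure, and
an individual can enter the cumulative record only once.  Samples carry
identity, sex, parentage links and the calf/adult distinction only.

* **Population-based**: a simple random draw of
  `round_half_up(fraction × pool)` from the previously unsampled
  animals whose annual MCP intersects the study area.
* **Spatially based**: `n_cells` grid cells drawn without replacement
  with probability proportional to the number of animals whose annual
  MCP intersects each cell (scaled to the busiest cell); an animal
  whose winter MCP uses a drawn cell is detected by a Bernoulli trial
  at its winter-kernel utilization of that cell, scaled to 1 at its own
  busiest cell (Gaussian KDE, normal-reference bandwidth).  Previously
  drawn cells are excluded within a run (configurable), so each year
  surveys fresh ground.
* **Cow–calf rule** (both designs): sampling a cow adds her live
  dependent calf and vice versa — the pair travels together in snow.

## Experiments and problem sizes

Experiment defaults: a single 659-founder trajectory with a 20-year
pedigree burn-in and five survey censuses; 10–90% population-based
intensities or 10–200 surveyed cells; 50–100 sampling iterations per
treatment, with 2,000-trial bootstraps where intervals are scored.
Zone experiments partition the population's final extent into nine
equal rectangles (≈300 km² each; the extent exceeds the 1650-km² unit
because animals disperse outward) and survey 1–20% of
each zone's own 1-km² grid once.  Metrics: CV (sample sd / mean), SME
(mean scaled error), SRMSE (root mean squared scaled error), interval
coverage, and growth-rate error λ̂ − λ; SME/SRMSE denominators use the
true adult count inside the study area at the matching census, with the
extant-population truth also reported.

## Numerical choices

* One root seed; the simulator, each sampling iteration and each
  bootstrap consume independent child streams, so results do not depend
  on replay order.
* Utilization ties (two cells at the scaled maximum) break toward the
  lowest cell index; degenerate single-point clouds put utilization 1
  on the containing cell.
* Nominal sample sizes round half-up; integer allocations of fractional
  age structures use largest-remainder rounding.
* Grid cells are half-open `[x, x+1) × [y, y+1)`, indexed row-major
  from the lower-left corner; membership predicates use `intersects`,
  so a shared boundary counts.

## Known limitations

Parentage is taken as known and error-free — genotyping error and
pedigree-inference uncertainty are out of scope, as is any link from
genotypes to the pedigree.  Density dependence, twinning and
immigration are not modelled.  The interval's under-coverage at
moderate effort under heterogeneous sampling is inherent to the
independence assumption; multi-year cumulative pedigrees overestimate
discrete-area abundance by a few percent through emigration, a bias
that is small, predictable and correctable.
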