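# pedrecon

Abundance estimation for wildlife populations by **pedigree
reconstruction**, with a spatially explicit individual-based moose
(*Alces americanus*) population simulator for designing noninvasive
genetic surveys.

Pedigree reconstruction is a close-kin method: genotype animals once
(e.g. from winter scat), reconstruct parent–offspring relationships,
and let the pedigree reveal animals that were never sampled.  It suits
low-density, hard-to-observe species for which mark–recapture resighting
is impractical.  This package provides the estimator with bootstrap
confidence intervals, plus the simulation machinery to ask *how much
sampling — as a fraction of animals, or as area surveyed — an accurate
estimate requires*, and how local density changes that answer.

## The estimator

A pedigree built from one-time genetic samples partitions the adult
population into four segments:

| segment   | sampled? | matched to a sampled offspring?        |
|-----------|----------|----------------------------------------|
| linked    | yes      | yes                                    |
| unlinked  | yes      | no                                     |
| inferred  | no       | yes (mate and shared offspring sampled)|
| invisible | no       | no — must be estimated                 |

With marginal probabilities *p*<sub>sampled</sub> and
*p*<sub>matched</sub> assumed independent, an adult is observed with
probability 1 − (1 − *p*<sub>sampled</sub>)(1 − *p*<sub>matched</sub>),
and, writing *N*<sub>obs</sub> = *N*<sub>linked</sub> +
*N*<sub>unlinked</sub> + *N*<sub>inferred</sub>,

```
p_sampled = N_linked / (N_linked + N_inferred)      # P(sampled | matched)
p_matched = N_linked / (N_linked + N_unlinked)      # P(matched | sampled)
N_hat     = N_obs / (1 - (1 - p_sampled) * (1 - p_matched))
```

Uncertainty: each marginal gets a vague Beta prior updated by the
segment counts; a parametric bootstrap draws both marginals from their
posteriors, redraws the segment counts from the implied multinomial
observation model, re-estimates, and reports a percentile interval
(see `docs/methods.md` for why the counts are redrawn).

## Worked example

```python
from pedrecon import SegmentCounts, bootstrap_interval

counts = SegmentCounts(n_linked=60, n_unlinked=20, n_inferred=20, census_year=2024)
est = bootstrap_interval(counts, n_boot=10_000, seed=42)
```

prints, via the fields of `est`:

```
p_sampled    = 0.750
p_matched    = 0.750
n_hat        = 106.7
n_invisible  = 6.7
95% interval = (99.9, 114.5)
```

Sixty linked adults among eighty matched gives a 75% sampling
probability; sixty linked among eighty sampled gives a 75% matching
probability.  The 100 observed adults are therefore 93.75% of the adult
population, so about 6.7 further adults are invisible to the pedigree
and the point estimate is 106.7.

The same estimator drives the survey-design experiments.  A desk-scale
run — 659 moose at the stable age distribution, 20-year burn-in, then
five annual surveys at 50% and 90% population-based sampling:

```python
from pedrecon import simulate_study, run_objective1, summarize_results

study = simulate_study(seed=1)
res = run_objective1(study, intensities=[0.5, 0.9], iterations=20, seed=1,
                     n_boot=2000, ci_years={5})
print(summarize_results(res[res.year_index == 5], ["intensity", "year_index"]))
```

```
 intensity  year_index  truth    cv    sme  srmse  coverage
       0.5           5  431.0 0.008 -0.006  0.010      0.65
       0.9           5  431.0 0.002  0.036  0.037      0.00
```

By year 5 both efforts are precise (CV ≤ 0.8%); moderate sampling is
essentially unbiased against the 431 true in-area adults, while
exhaustive sampling *over*-estimates by ~3.6% because the cumulative
pedigree keeps tracking adults that emigrated from the study area —
which is also why its narrow intervals stop covering the in-area truth.

## Command line

```
pedrecon simulate   --config cfg.yaml --out runs/sim      # censuses + true pedigree
pedrecon estimate   --pedigree ped.txt --attributes att.txt --census-year 2024 \
                    --seed 1 --out estimate.csv
pedrecon experiment --objective 1 --out runs/obj1          # accuracy grid
```

Pedigrees are three-column text (`id sire dam`, `0`/`NA` = unknown
parent) with a companion attribute table — the same convention used by
common parentage-assignment tools.

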