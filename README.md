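# percmem

Reverse-correlation analysis of **perceptual memory of multistable
displays**, built around bistable kinetic-depth-effect (KDE) spheres.

When an ambiguous rotating sphere is shown intermittently with long
blanks, its onset perception is governed by a weak perceptual memory of
the previously dominant state. `percmem` implements the full analysis
chain for probing *when and how* that memory forms: interleaved sessions
of fully ambiguous **probes** (which read the memory out) and randomly
disambiguated **primes** (which perturb it), probe–prime–probe triplet
classification, classification-image style reverse correlation of the
disambiguation sequences, and hierarchical Bayesian models of the
recovered per-segment strengths. A synthetic observer with a known
temporal kernel makes every stage testable without human data.

The package is aimed at visual psychophysicists and computational
modelers who want a tested, reproducible desk-scale implementation of
this analysis — or a harness to validate their own.

## The analysis in brief

Each prime carries a random sequence of disambiguation strengths, one per
30 ms segment, drawn uniformly from {−1.0, −0.9, …, 1.0}. Sequences are
re-signed so positive = toward the direction reported on the leading
probe, and trials are classified by which percepts changed (prime,
trailing probe, both, neither). Averaging the sequences of trials with a
chosen outcome yields the effective temporal kernel of that outcome, with
97% percentile bootstrap intervals (2,000 iterations; two-stage
resampling for group estimates).

Smooth average sequences are modeled hierarchically. The linear model
uses correlated random intercepts and slopes over segment index
`Int`:

    Bias_i ~ Normal(α_P[i] + β_P[i]·(Int_i − 1), σ)

The additive model expresses the curve as six clamped cubic B-splines
with strictly positive per-participant scaling weights:

    Bias_i ~ Normal((B·w_spline)[Int_i] · w_P[i], σ),  log w_P ~ Normal(0, σ_P)

Dual-condition variants fit two selections (prime perception vs
perceptual memory) with independent, correlated (correlation ρ, LKJ(2)
prior) or identical spline weights, and are compared by PSIS-LOO ELPD
with softmax relative weights. Posteriors are summarized with 97%
percentile credible intervals and 97% HPDIs.

## Worked example

```python
import numpy as np
import percmem as pm

schedule = pm.DisambiguationSchedule.from_variant("onset_only")
observer = pm.ObserverParams()          # memory gain = 2 x perception gain
session = pm.simulate_session(observer, schedule, n_primes=10_000,
                              rng=np.random.default_rng(0))
triplets = pm.build_triplets(session)
est = pm.bootstrap_individual(triplets, "memory_changed",
                              pm.BootstrapConfig(seed=1))
template = pm.switch_template(observer.kernel)
print(len(triplets))
print(np.round(est.mean, 3))
print(round(float(np.corrcoef(est.mean, template)[0, 1]), 4))
```

prints

```
9642
[-0.297 -0.384 -0.281 -0.132 -0.05   0.006 -0.003 -0.007 -0.011  0.01 ]
0.9983
```

The memory-changing image is a moderate disambiguation *against* the
previously dominant state, strongest at the second 30 ms segment and
fading to fully ambiguous by 150 ms — the negated sensitivity kernel of
the generating observer, recovered at r = 0.998. Segments 6–10, where the
observer is insensitive, hover at zero.

The command-line surface mirrors the library
(`percmem simulate|revcorr|fit|compare|report`); a YAML config fixes the
schedule, observer, sample sizes and all seeds, and
`percmem simulate --config cfg.yaml --out run/ --full` regenerates a
whole run directory (trial log, estimate tables, model comparisons,
draws, run log) from the config alone.

## Layout

- `percmem.schedules` — disambiguation schedules, sequence grid, dot-size map
- `percmem.observer` — synthetic observer and session simulation
- `percmem.triplets` — triplet construction, outcome classes, bootstrap estimates
- `percmem.splines` — clamped cubic B-spline basis
- `percmem.models` — hierarchical linear/additive/dual fits, LOO comparison
- `percmem.sampler`, `percmem.intervals` — ensemble-MCMC driver, CI/HPDI
- `percmem.io`, `percmem.pipeline`, `percmem.cli` — formats, full runs, CLI

See `docs/methods.md` for the models, priors, observer design and known
limitations.
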