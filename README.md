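# wingcrypsis

Quantifying seasonal crypsis in the squinting bush brown butterfly
(*Bicyclus anynana*): calibrated wing-image colorimetry plus mixed-model
inference on background-choice behavior.

*B. anynana* is thermally polyphenic. Larvae reared at cool, dry-season
temperatures (Td = 19 °C) develop wings with small, dull pattern elements
that are cryptic against brown dry-season foliage; warm-reared (Td = 27 °C)
individuals develop large, contrasting marginal eyespots that deflect
predator strikes. This package implements, end to end, the two analyses
needed to ask whether appearance and behavior respond to the developmental
environment in a coordinated way:

1. **Wing colorimetry.** Scanned ventral hindwings are linearized through a
   gray-standard calibration, sampled along two contiguous landmark
   transects through the eyespot (mean linear RGB of 3×3-pixel squares),
   and converted to CIE-xyY. Two Euclidean distances in the CIE-xy
   chromaticity plane are computed per wing: *internal contrast*
   d(element, wing background) for the central band and each eyespot ring,
   and a *crypsis score*, the mean distance of all transect pixels to the
   brown assay patch HSB(25°, 60%, 50%) — an inverse proxy for background
   matching.
2. **Behavioral inference.** Cohorts of 20 same-sex butterflies are
   photographed 15 times at 4-minute intervals in a cage tiled with brown
   and green patches. Arrivals-to-brown vs arrivals-to-green (preference)
   and relocated vs stationary (activity) are binomial "two-vector"
   responses, modelled as

   logit P(brown) = β₀ + β_Td·[Td=19] + β_Ta·[Ta=19] + β_Sex·[F] + (two-way interactions) + u_cohort + u_timepoint

   with crossed gaussian random intercepts, fitted by maximum likelihood
   with a Laplace approximation. Minimum adequate models come from BIC
   backward elimination; p-values from likelihood-ratio tests and a
   parametric bootstrap (nsim = 999 by default); post-hoc contrasts use
   Tukey-style familywise adjustment with a compact letter display; each
   cell's pooled preference is also tested against a 1:1 ratio with an
   exact binomial test.

Raw wing scans and observation tables for this assay are not publicly
available, so the package includes a first-class synthetic-data module
that generates wing
images (brown field, central band, concentric eyespot) and cohort time
series with known ground truth, used by the test suite to verify the whole
pipeline against closed-form expectations.

## Worked example

```python
from wingcrypsis.pipeline import PipelineConfig, run_full_pipeline

cfg = PipelineConfig(out_dir="demo", seed=1, n_wings_per_cell=4, n_cohorts_per_cell=4)
run_full_pipeline(cfg)
print(open("demo/summary.txt").read())
```

prints

```
wingcrypsis run (seed 1, config 8c5822563f70bacc)

Preference model (selected by BIC): Td, Sex
BinomialMixedModel (binomial, ML-Laplace)
nobs = 440   llf = -667.8937   BIC = 1366.2214
converged = True   boundary = False

term                        coef        se       z
Intercept                -0.0499    0.1555   -0.32
Td[19]                    0.8086    0.1778    4.55
Sex[F]                    0.6706    0.1785    3.76

random intercept sd(cohort) = 0.4356
random intercept sd(timepoint) = 0.1497
...
Mean crypsis (distance to brown patch) by Td: Td; 19    0.0106; 27    0.0269
```

Read: dry-season development raises the log-odds of alighting on brown by
0.81 (the generator injected 0.8), females prefer brown more than males
(+0.67), and dry-season wings sit less than half as far from the brown
patch in chromaticity space (0.011 vs 0.027) — smaller crypsis score means
better background matching. The run directory also contains per-wing
scores, per-term χ² tests, post-hoc letters, and a manifest recording the
config hash and derived seeds; `wingcrypsis figures --results demo`
renders the four summary figures.

The same stages are available as a CLI for real data:

```sh
wingcrypsis calibrate --standards standards.csv --degree 1 --out curve.json
wingcrypsis score --images wings/ --annotations wings/ --curve curve.json --out scores.csv
wingcrypsis analyze preference --data cohorts.csv --nsim 999 --seed 1 --out results/
```

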