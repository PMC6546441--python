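# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the package's own validation design.

## Colorimetry

**Color space.** Images are assumed to be linear-reflectance RGB after
calibration. Conversion to CIE XYZ uses the sRGB primary matrix with D65
white point and the 2° standard observer; chromaticity is x = X/(X+Y+Z),
y = Y/(X+Y+Z). No device-specific scanner characterisation is available, and sRGB
is the de-facto assumption for consumer scanner output; the matrix is a
single module constant (`colorspace.SRGB_TO_XYZ`) so a measured
characterisation can be substituted. All scores are Euclidean distances in
the (x, y) plane only; relative luminance Y is carried but never enters a
distance, because chromaticity — not brightness — is the quantity the
scores are defined on.

**Transect sampling.** The two contiguous transect segments are polylines
through landmarks 0–2 and 2–4 (landmark 2 at the eyespot center),
rasterized 8-connected; the shared landmark is sampled once. Each sample
is the unweighted mean linear RGB of the 3×3 pixel square centred on the
transect pixel, so every landmark must sit ≥ 1 px from the border.
Coordinates are 0-based (row, col); element intervals on the transect are
half-open.

**Mean-then-convert.** Element colors average RGB over the element's
intervals first and convert to chromaticity second. Chromaticity is a
projective quantity and is numerically unstable near black; averaging in
RGB keeps dark-disc estimates well conditioned. The alternative
(convert-then-mean) is available via `element_mean_colors(...,
convert_first=True)`; on the synthetic wings the two differ negligibly
away from black.

**Degenerate black.** A pixel with X+Y+Z = 0 has no chromaticity; by
convention it carries the white-point (x, y) with Y = 0, is flagged, and
is excluded from crypsis-score means.

## Calibration

Per-channel monotone polynomial mapping raw scanner values (normalized by
255 or 65535) to linear reflectance, fitted by least squares to gray
standards; default degree 1 (the scanner is nominally linear), higher
degrees opt-in. If the unconstrained fit is non-monotone on [0, 1] it is
re-solved with the derivative constrained ≥ 0 on a 64-point grid (SLSQP);
a fit that still decreases anywhere on a 256-point grid is rejected.
Calibration is per-channel only — no cross-channel color matrix — because
linearization, not color correction, is the modelled step. At least
degree + 2 distinct reflectance levels per channel are required; constant
raw responses are rejected as degenerate.

## Mixed models

**Families and estimation.** Binomial-logit models for the two behavioral
responses; gaussian models for pigmentation scores. Estimation is maximum
likelihood throughout — never REML — so that likelihood-ratio tests and
BIC are comparable across fixed-effect structures. Random structure is
crossed independent intercepts for cohort and time point (the experimental
design crosses them; nothing is nested).

**Laplace approximation.** Random intercepts are integrated out by a
Laplace approximation around the joint mode of (β, b), using the spherical
parametrisation u_f = σ_f b_f, b_f ~ N(0, I), which makes σ_f = 0 an
ordinary point of the profiled objective (boundary fits need no special
casing; fitted σ < 10⁻⁴ is flagged as boundary). The inner mode is found
by penalised Newton iterations with step halving (gradient tolerance 10⁻⁷,
step tolerance 10⁻⁹); the largest random factor's diagonal Hessian block
is eliminated by a Schur complement, so a step costs O(n) in the number of
rows regardless of the number of cohorts. The outer problem — the σ's
(plus the residual variance for gaussian models) — is solved by bounded
L-BFGS-B (Nelder-Mead for gaussian) on the Laplace objective with the
inner state warm-started between evaluations. The Laplace log-determinant
uses the random-effect block only, with β profiled at the joint mode;
lme4's glmer instead keeps β in the outer optimisation, which is why
coefficients agree with glmer to ~10⁻² on tiny fixtures while variance
components and log-likelihoods agree to ~10⁻³ (see the frozen oracle test).
With no random terms the Newton iteration is exactly IRLS and reproduces a
single-level GLM/OLS fit to ≤ 10⁻⁶.

**Fixed-effect structure.** Treatment coding against the reference cell
Td = 27, Ta = 27, Sex = M, so a positive `Td[19]` coefficient means
dry-season development raises the response. The full starting model has
the three main effects and all two-way interactions; the three-way
interaction is excluded. Marginality is enforced: an interaction may only
appear (and a main effect may only be removed) consistently.

**Model selection.** Backward elimination by BIC
(−2·loglik + k·log n, k counting fixed coefficients plus variance
components): at each step the removable term whose removal lowers BIC most
is dropped; ties break toward the higher-order term, then alphabetically;
elimination stops when no removal lowers BIC. The trace records every
step's BIC and is strictly decreasing by construction.

**Tests.** LRT statistic 2·(ℓ_full − ℓ_reduced) against χ² with df = the
free-parameter difference. The parametric bootstrap simulates response
tables from the fitted reduced model — fresh random-intercept draws, then
binomial draws at the fitted probabilities — refits both models, and
reports the add-one p-value (1 + #{sim ≥ obs})/(nsim + 1), which is
guaranteed in [1/(nsim+1), 1]; failed refits are dropped and counted, and
more than 10 % failures is an error. Post-hoc contrasts are estimated
marginal means on the link scale (design rows averaged with equal weights
over non-grouping factors); the familywise adjustment refers each |z| to
the distribution of the maximum absolute component of a multivariate
normal with the contrasts' correlation matrix, evaluated by a seeded
Monte Carlo (40 000 shared draws; sharing the draws makes adjusted
p-values monotone and reproducible, and the two-group case falls back to
the exact z-test). The compact letter display uses the standard
insert-and-absorb algorithm. Cell-level 1:1 preference is an exact
two-sided binomial test on cohort-aggregated counts; such annotations
could equally be derived from per-cell model intercepts, and the exact
test is this package's choice of interpretation.

**Pigmentation models.** Default is no random term (no random grouping is
defined for per-individual wing scores), in which case the fit is OLS and per-term F tests are
classical partial F with residual df, computed by model comparison. The df
convention is isolated in `lmm_term_ftests` so a Satterthwaite-style
alternative could be substituted. A gaussian mixed model with random
intercepts is available through the same Laplace machinery (exact for the
gaussian family).

**Responses.** Time point 1 has no previous photo, so arrivals and
relocations are undefined there and those rows are excluded from both
responses. Rows with zero trials (no arrivals, or no perched individuals)
are dropped with a logged count, never imputed.

## Synthetic data

**Wings.** A stylized wing: uniform background field, a vertical central
band stripe, and a concentric eyespot (outer ring / dark disc / pale
focus) on a horizontal transect through its center. Geometry beyond
landmark and boundary placement is irrelevant to the pipeline, which only
reads colors along the transect. Default palettes (linear RGB) were chosen
once so that the dry-season (Td = 19) palette is "browner" in exactly the
directions the real wings show: every element sits closer in CIE-xy to its
own wing background (lower internal contrast) and the whole transect sits
closer to the brown assay patch (lower crypsis score) than its wet-season
counterpart; dry-season radii (3/6/10 px) are strictly smaller than
wet-season (5/10/16 px). Pixel noise is i.i.d. gaussian in linear RGB
(default sd 0.01, roughly 8-bit quantisation scale), clipped to [0, 1].
Ground-truth boundary intervals mark a transect index as belonging to an
element only when the full 3×3 neighbourhood lies inside it (a
conservative annotator), so noise-free neighbourhood means equal the
palette colors exactly — the basis of the machine-precision pipeline
tests. Elements too small to contain any interior sample, or radii
exceeding the image, raise a geometry error.

**Cohorts.** Cohorts of 20 individuals over 15 photos (the assay's
design), 8 cohorts per treatment × sex cell by default (16 per treatment).
At the first photo each individual perches on brown with the preference
probability; at each later photo each perched individual relocates with
the activity probability and movers re-choose brown vs green with the
preference probability, so arrivals are a subset of movers and occupancy
accounting is consistent by construction. Departure patches are uniform
over perched individuals (the assay protocol records arrivals, not
departures), and everyone stays perched between photos (the protocol is
ambiguous about off-patch individuals; an always-perched pool is the
simplest consistent reading). Effects are logit-linear with the treatment
coding above; defaults encode the study's qualitative structure —
preference: Td[19] +0.8, Sex[F] +0.6, Ta[19]:Sex[F] +0.4, intercept −0.3;
activity: males more active when reared or kept cool (Td[19] +0.4,
Ta[19] +0.5) with those effects cancelled in females (Td[19]:Sex[F] −0.4,
Ta[19]:Sex[F] −0.5), base activity set so ~5 of 20 individuals relocate
per photo. Random intercepts: sd 0.5 between cohorts, 0.2 between time
points, drawn independently per response; time-point intercepts are shared
across cohorts (crossed design). Magnitudes are plausible mid-size effects
on the logit scale chosen once for the generator; the real effect sizes
are unknowable without the raw data.

**Standards.** Emulated scanner response raw = reflectance^(1/γ) + noise,
clipped; γ = 2.2 mimics an uncorrected consumer device, γ = 1 a linear
one.

**Seeds.** One master seed is split into per-purpose substreams with
`numpy.random.SeedSequence.spawn`, recorded in the run manifest, so every
stage is independently reproducible.

**What the generator does not emulate.** Real wing morphology and scale
texture, specular and lighting artifacts, landmark placement error,
annotator disagreement about element limits, off-patch or flying
individuals, inter-individual preference heterogeneity within a cohort,
and temporal autocorrelation beyond the shared time-point intercept.
Passing tests therefore show that the measurement and inference machinery
is correct under the stated generative model, not that the biological
conclusions would survive those real-data complications.

## Validation design and problem sizes

The acceptance suite verifies, in order: the conversion constants and
assay-patch arithmetic; the metric axioms of the chromaticity distance on
10 000 random points; machine-precision (≤ 10⁻¹²) recovery of generator
targets and closed-form scores on noise-free wings, including a
geometry-only brute-force oracle for the crypsis score; equivalence of the
degenerate mixed models with statsmodels GLM (50 random datasets, 10⁻⁶)
and classical ANOVA; recovery of injected preference coefficients with
|mean bias| < 0.1 at 300 cohorts/cell over 100 replicates; calibration of
the add-one bootstrap p (200 replicates × nsim 199, Kolmogorov–Smirnov
distance from uniform < 0.1) and of the asymptotic LRT size (500
replicates, nominal 5 %); and sign recovery of every injected effect in
≥ 95 % of 50 end-to-end replicates at the study's own sample sizes. The
bootstrap-uniformity check runs on the no-random-term binomial model —
the simulate/refit/add-one path is the same code — which keeps its 80 000
refits to about a minute; the LRT size check uses the full
crossed-random-intercept model. Bootstrap draws elsewhere default to
nsim = 999.

## Known limitations

- The Laplace approximation is first-order; with very small cluster
  counts or trials per row, variance components carry the usual downward
  bias (the recovery tests quantify it at ~0.02–0.03 on the logit scale at
  the sizes used).
- Wald standard errors for fixed effects condition on the fitted σ's.
- Only two crossed random factors are supported (all this design needs).
- The Tukey-style adjustment is simulation-based (seeded), not the exact
  studentized-range distribution; with shared draws its p-values are
  reproducible and conservative within ~3·10⁻³ Monte-Carlo error.
- Compact letters depend on the significance pattern only; with
  non-transitive patterns multiple minimal letterings exist and the
  insert–absorb order picks one deterministically.
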