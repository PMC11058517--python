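# Methods

This note documents the models, numerical choices and known limitations of
`domus`, in the order the pipeline runs them.

## Recoding

Ethnographic Atlas codes are mapped to analysis categories by total
functions: every integer yields a category, `missing`, or — for wall
materials only — `excluded`. `excluded` covers wall codes outside the four
analysed classes (rare materials such as ice and snow); it removes the
society from wall-material models only, never from the other responses.
Political complexity (jurisdictional levels beyond the local community,
1–5) is stored ordinal and enters models as a numeric covariate by default;
this keeps the parameter count small and lets the temperature-harshness ×
political-complexity interaction be a single column. Column-name mapping
for differently labelled exports lives in the reader's `column_map`
argument, not in code.

## Climate summaries and Colwell's index

Colwell's P requires discretised states. The pipeline defaults to
`n_states = 10`, with temperature binned equal-width over the society's
observed range and precipitation binned equal-width on `log(1 + mm)`
(precipitation is right-skewed with exact zeros). Both are configurable;
the suite checks that the *ranking* of societies by P is robust to bin
count (Spearman r > 0.9 between 8 and 12 states on heterogeneous synthetic
series). Entropies use the `0·log 0 = 0` convention; tiny negative values
(> −1e−12) from floating-point cancellation are clipped to 0. A constant
series occupies a single state and has C = P = 1: a climate that never
changes is perfectly predictable. A state space of one column is rejected
(`log s = 0`).

## Box-Cox and varimax composites

Each environmental variable is Box-Cox transformed with λ maximising the
profile log-likelihood, located on a 101-point grid over [−5, 5] and
refined by bounded minimisation between the flanking grid points.
Variables containing zeros (precipitation, slope) are shifted by
`1 − min(x)` first; the shift and λ are recorded in the output. Constant
variables (e.g. P exactly 1 everywhere in a perfectly periodic synthetic
climate) are dropped from the PCA with a warning since they carry no
information.

PCA retains the top three axes of the standardized variables; the loadings
are rotated by normalised (Kaiser) varimax. Rotation indeterminacy is
resolved deterministically: SVD axes are first signed so their
largest-magnitude element is positive, then components are identified by
their loadings — the component loading most heavily (summed |loading|) on
temperature variables becomes *temperature harshness*, oriented so the
mean-temperature loading is negative (cold sites score high); the heaviest
on elevation/slope becomes *mountain dwelling*, oriented positive on
elevation; the remainder is *xeric harshness*, oriented negative on mean
precipitation. Scores are re-standardised to mean 0, SD 1. The input
variable set (8 variables: means, variances and P of temperature and
precipitation, elevation, slope) is the set of quantities the summaries
compute, and is configurable.

## Spatial statistics

Distances are haversine on a sphere of radius 6371.0088 km; all uses are
rank-based (nearest neighbours) or binned (correlogram classes), so the
sphere/ellipsoid distinction is immaterial. Neighbour ties are broken by
society-id lexicographic order, making the neighbour graph deterministic.
The borrowing fraction excludes neighbours with a missing trait from the
denominator (keeping the statistic in [0, 1] and maximising usable
societies); a flag switches to counting them as non-matches. The neighbour
graph is built once on all located societies, regardless of per-response
missingness.

Moran's I uses binary weights within each of 12 equal-width distance
classes spanning (0, max pairwise distance]; zero-distance pairs (duplicate
coordinates) fall in no class. Classes with fewer than 30 pairs are flagged
unreliable. For a categorical response the residual fed to the correlogram
is the Pearson residual of the indicator of each category,
`(1[y=j] − p_j)/sqrt(p_j(1−p_j))`, computed per category; screening uses
the category with the largest |I|. Permutation null bands (2.5th/97.5th
percentiles, seeded) are off by default and enabled per run.

## Mixed categorical models

The baseline-category logit fixes one reference category per response
(ground plan → rounded, floor level → ground, wall material → thick, roof
shape → sloped). Fixed-effect fits are exact Newton maximum likelihood with
step-halving; convergence requires max |score| < 1e−6 within 200
iterations. Perfect separation is detected as any fixed coefficient
exceeding 15 in absolute value during iteration; such fits are retained but
flagged non-converged and excluded from averaging, mirroring the treatment
of models that fail on insufficient response variation.

The random-effect structure is diagonal: one variance per non-reference
category, intercepts independent across categories and language families.
This is the minimal structure consistent with "a language-family random
effect" for a multinomial response and keeps K interpretable. Estimation is
joint penalised Newton over (β, u) for fixed variances, with the variances
maximising the Laplace approximation of the marginal likelihood

    ℓ(σ) ≈ ℓ(y | β̂, û) − ½ û'D⁻¹û − ½ log|D| − ½ log|H_uu + D⁻¹|,

optimised over log σ² by bounded scalar search (binary response) or
Nelder-Mead (multinomial), warm-starting the inner Newton between
evaluations. Boundary estimates (σ² → 0) are allowed, flagged, and reduce
exactly to the fixed-effect likelihood in the σ = 0 limit (verified to
1e−6 in the suite). Laplace rather than adaptive quadrature is a deliberate
trade: hundreds of nested-model fits must run at desk scale, and parameter
recovery on synthetic worlds (slope bias < 0.15, σ̂ within [0.6, 1.4] at
n = 1000, 30 families) validates the approximation at the group sizes the
analysis sees.

`K` counts all fixed coefficients including intercepts, (J−1)(q+1), plus
one variance per non-reference category when the random effect is present;
`n` is the number of societies. AICc is undefined for n ≤ K + 1 and such
fits drop out of averaging.

## Multimodel inference

Enumeration toggles every term of the full model — the three composites,
the social terms, the borrowing fraction, the interaction (only with both
mains present) and the random effect — so the relative importance of each,
including language family and borrowing, is defined. All candidates are fit
on one complete-case dataset per response (complete on every full-model
variable), so n is identical across fits. Weights are renormalised over
converged models only. Averaging is zero-method (shrinkage): a coefficient
absent from a model contributes zero with that model's weight, the
Burnham–Anderson default consistent with unbiased averaged estimates;
natural averaging over containing models is not implemented. Unconditional
standard errors combine within-model variance and between-model spread.
Averaged probabilities are the weight-blend of each model's fitted
probabilities (conditional on its estimated group intercepts); effect
profiles instead use the averaged coefficients at population level (u = 0),
with other covariates at 0 (composite means / reference categories) and
optional stratification by political complexity 1 vs 5.

## Synthetic worlds

The generator emulates the structure the analysis assumes, not real
geography: no continents or coastlines, flat family labels rather than
trees. Family seed points are uniform on the sphere; societies disperse
around their seed with a configurable clustering scale (default 700 km).
Spatially correlated fields (site climate effects, relief) use
kernel-weighted mixing of i.i.d. noise with a Gaussian kernel
(range 1500 km) rather than an exact Gaussian-process draw — O(n²) and
dependency-free, adequate at n ≤ 2000. Temperature is a latitudinal
gradient (27 °C at the equator, −0.55 °C per degree |lat|) plus site effect
plus a seasonal cosine whose amplitude grows with |latitude| (18 °C at the
poles, hemisphere-flipped phase); precipitation is the exponential of an
analogous field. Month-level noise scales with (1 − predictability knob)
and with |latitude| (high-latitude sites are less predictable), so knob = 1
yields exactly repeating years and Colwell P = 1 at every society. The
default climate record is 50 years.

House traits draw from a multinomial logit on the composites (computed from
the generated climate by the pipeline's own summarisers) and social traits,
plus family intercepts. Default coefficients are strong (|slope| ≥ ~1) and
follow the directions the comparative literature expects (angular plans
with political complexity and sedentism, elevated floors where warm/wet,
thick walls where cold/dry, fabric walls among nomads). Horizontal
transmission is a finite number of synchronous contagion rounds (default 2,
strength 1): each round every society redraws with an added
η · (neighbour share of each category) term — a finite-round approximation
of an autologistic field, recorded in the truth, not an exact sample from
one. Social prevalences default to polygyny 20/35/45 (none/occasional/
frequent), 25% nomadic, political complexity heavily weighted to acephalous
societies; 2% of house-trait codes are blanked to exercise complete-case
logic. All randomness flows from one integer seed through named substreams
(geography, climate, social, one per response, contagion, missingness)
spawned in a fixed order.

What passing tests on these worlds do *not* show: robustness to real-world
features the generator omits — coastlines and landmass masking, non-random
ethnographic sampling, correlated missingness, language families whose
internal phylogeny matters, or climate regimes (monsoons, ENSO) outside a
seasonal-cosine-plus-noise model.

## Problem sizes and numerical tolerances

The test suite and examples run the generator at 80–1000 societies and the
full multimodel pass with 3–5 toggled terms (16–64 candidate specifications
per response); these sizes were chosen so a complete desk run finishes in
minutes while keeping every qualitative contrast (recovery bands,
accuracy-vs-baseline ordering) comfortably clear of its threshold. The
outer variance search uses `var_tol` (default 1e−3 on log σ²; the examples
use 2e−2–3e−2): AICc differences are insensitive at this level. Candidate
fitting treats estimation errors (rank deficiency, single observed
category) as non-converged candidates rather than failures; a run aborts
only if *no* candidate converges.

## Known limitations

- The Laplace marginal likelihood is biased towards smaller σ for binary
  responses with small families; the recovery band accepts this.
- Relative importance inherits the usual caveat of summed Akaike weights:
  it measures evidence for inclusion, not effect size.
- Effect profiles from zero-method averaged coefficients shrink slopes of
  rarely selected terms towards zero by construction.
- The pipeline assumes one climate record per society; interpolation or
  raster extraction is out of scope (climate arrives as input columns or is
  synthesised).
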