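# Methods

This note documents the models, numerical conventions and design choices
behind `octarep`, and what the synthetic experiments do and do not show
about real OCTA data.

## Synthetic angiogram model

The simulator emulates the *structure* of a paired test–retest macular OCTA
study, not OCTA physics (no decorrelation modelling, projection artefacts
or slab segmentation — out of scope by design).

**Geometry.** Scans are 3×3 mm, rendered at 1024×1024 px by default
(2.9 µm/px). The device export resolution is a free parameter of the model;
1024 px was chosen so vessel skeleton densities land on the 10⁻⁸–10⁻⁷
scale typical of megapixel en-face scans, and it is configurable
(`image_size_px`).

**FAZ.** A roughly circular polygon (24 vertices, mean radius 0.25 mm,
±10 % radial irregularity) at the image centre. Vessel centrelines keep an
8 px standoff from the delineated border, so the rendered capillary ring
sits ~5 px outside it: the exact delineation contains only background,
while an outward excursion of a jittered delineation can clip vessel
signal — the mechanism that makes the emulated manual rater occasionally
catch a bright pixel, as a human with a free-hand tool does.

**Vessel tree.** Three generations of persistent random walks at decreasing
calibre (7, 5, 3 px ≈ 20, 15, 9 µm): radial arterioles seeded on the FAZ
rim, secondary branches, and a capillary generation spawned from random
parent vertices until the drawn length×width budget reaches the target
coverage (`target_vessel_fraction`, default 0.32 before overlap; realized
coverage is ~0.2–0.27). Walks terminate at the image border or the FAZ
standoff. Ground truth (`true_vessel_fraction`) is obtained by pixel-
counting the rendered mask, never from the budget.

**Age effect.** The coverage budget shrinks linearly with age
(`age_density_slope`, default 0.25 over the 20–75 y range), giving the
cohort a negative age–density correlation by construction. No age effect on
*repeatability* is simulated, which is exactly what the age-adjusted
regression should (and does) report.

**Pathology.** Capillary dropout: a fraction (`dropout_fraction`, default
0.25, rounded half up) of terminal segments is removed, lowering coverage
by roughly 10–20 % relative — a generic stand-in for the heterogeneous
maculopathies of a clinical sample.

**Rendering and noise.** Vessels at grey 110, background at 30; the deep
layer scales both by 0.6 (matching the empirically lower deep-layer
thresholds). Noise is multiplicative speckle: pixel = mean · (1 + s·(R−1))
with R Rayleigh-distributed with unit mean and `speckle_scale` s = 0.6;
s = 0 is the exact two-level limit used by recovery tests, s = 1 fully
developed speckle. The two acquisitions of a pair share the vessel mask and
differ only in the speckle realization.

**Manual rater.** Each delineation perturbs the FAZ vertices radially by
Gaussian jitter (`rater_jitter_px`, default 2 px), redrawn on
self-intersection. Per acquisition the rater measures twice; a third
delineation breaks disagreements ≥ 5 grey levels (median of three),
otherwise the two thresholds average with half-up rounding. The deep-layer
threshold reuses the superficial delineations on the deep image.

**Seeding.** One master seed; every per-eye, per-acquisition and per-rater
stream derives from `numpy.random.SeedSequence(master, spawn_key=(eye,
stream))`, so cohorts are element-wise reproducible and any single image
can be regenerated in isolation.

## Thresholding conventions

All automated algorithms consume the 256-bin grey histogram. Uniform
conventions: foreground is *strictly greater* than the threshold;
fractional computations floor to an integer level; argmin/argmax ties
resolve to the lowest level; single-level histograms return that level
flagged `degenerate` instead of raising.

- **Mean** — floor of the grey mean.
- **Percentile** — level whose cumulative fraction is closest to p = 0.5
  (configurable), searched over the populated range so degenerate
  histograms resolve to their own support.
- **Otsu** — maximizes between-class variance ω₀ω₁(μ₀−μ₁)² over all splits
  with both classes populated.
- **Huang** — minimizes Shannon-entropy fuzziness of memberships
  μ_T(g) = 1/(1+|g−m|/C), m the class mean, C the populated grey range.
  The Shannon form was chosen over Yager's measure as the more common
  published variant.
- **Moments** — Tsai's moment preservation: solve for the background
  fraction p₀ from the first three grey moments, return the level whose
  cumulative fraction is nearest p₀; invalid roots fall back to the mean
  threshold, flagged.
- **Li** — minimum cross entropy by fixed-point iteration
  t ← (μ₀−μ₁)/(ln μ₀ − ln μ₁), initialized at the grey mean, tolerance 0.5
  levels, cap 100 iterations. Because the continuous fixed point can sit a
  few levels off the discrete optimum, the returned level is refined by
  walking down the criterion basin (crossing plateaus from empty bins);
  tests verify the result attains the exhaustive 256-candidate optimum.
- **Manual** — maximum grey inside the FAZ mask; the two-measurement
  protocol above. The paper-gap decision of how two close measurements
  combine (rounded mean) is logged and auditable.

Oracle tests pin these criterion definitions, not bit-compatibility with
any particular desktop software's dialect of the same algorithms.

## Vessel metrics

VD defaults to the squared white-pixel fraction; whether the squaring in
the source formula is substantive or typographic cannot be settled, so both
conventions are implemented and every output row records which one was
used. VSD is n_skel/n_total². Skeletonization is Zhang–Suen thinning
(8-connectivity) with background padding stripped afterwards; tests
guarantee skeleton ⊆ foreground, idempotence, and preservation of the
8-connected component count.

## Statistics

- **Relative difference**: |m₂−m₁| / pair mean (symmetric; 0/0 ≡ 0). The
  pair-mean denominator is a recorded choice; a first-measurement
  denominator is the obvious alternative.
- **RC** = 1.96·√(Σ(m₂−m₁)²/n), exactly the printed formula.
- **ICC**: two-way random effects, absolute agreement, single measures —
  ICC(A,1) — from the two-way mean squares, CI by the McGraw–Wong
  F-distribution method. Negative estimates are reported as-is; zero-
  variance data are flagged undefined. The model choice mirrors the
  convention of mainstream statistics packages; no ICC model is dictated by
  the study design itself.
- **Friedman**: tie-corrected rank chi-square, implemented directly (scipy
  refuses k = 2) and cross-checked against scipy for k ≥ 3. Post-hocs are
  Wilcoxon signed-rank over all algorithm pairs, Holm–Bonferroni corrected
  as one family per metric/layer.
- **Mann-Whitney-U**: exact for tie-free groups of ≤ 8, otherwise the
  normal approximation with tie correction.
- **Age adjustment**: OLS of relative differences on age plus seven 0/1
  algorithm indicators with no separate intercept (the indicators span it);
  the 6-dummy+intercept parameterization is equivalent and recoverable from
  the coefficients. Rank-deficient designs fail loudly, naming the
  collinear columns.
- **Logistic ROC**: label ~ intercept + metric + age by ML on internally
  standardized predictors (VSD lives at 10⁻⁷–10⁻⁸; fitting raw would
  overflow any fixed separation guard). Complete/quasi-separation (perfect
  fit or |standardized β| > 10⁴) triggers a ridge-penalized refit
  (λ = 10⁻⁴ on non-intercept terms), flagged in the output. ROC is the
  empirical curve over probability cutpoints with ties counted ½; AUC
  equals the normalized tie-aware rank statistic (tested exactly). The 95%
  CI uses the Hanley–McNeil exponential approximation truncated to [0, 1];
  paired AUCs are compared with DeLong's covariance-aware z-test.
- **Power**: Monte-Carlo power of the Friedman test for independent normal
  per-algorithm values with given means/SDs.

## Problem sizes

Unit tests run on 128–256 px cohorts of 4–6 eyes; the acceptance suite and
`scripts/acceptance.py` use the full default conditions (26 eyes, 1024 px,
104 images, 728 measurement rows), 1000-replicate calibration/coverage
simulations, and a 10000-replicate power simulation — the same replicate
count as the study being emulated.

## What passing tests do and do not show

The simulator reproduces the *mechanisms* that differentiate the
approaches: a max-statistic manual threshold with rater variability versus
histogram statistics over a million pixels; group separation via true
coverage loss; an age trend in density but not in repeatability. It does
not reproduce OCTA's spatially correlated speckle, projection and motion
artefacts, segmentation errors, or heterogeneous pathology morphology.
Passing the headline checks therefore shows the pipeline's statistics
respond correctly to known ground truth — not that any clinical effect size
is reproduced. Two in-simulation behaviors worth noting: with strong group
separation at n = 26 the in-sample age-adjusted AUCs of the informative
algorithms saturate at 1.0, and the Percentile algorithm's VSD in the
deep layer is chance-level (its median threshold sits inside the background
mode, so the skeleton is noise-dominated) — an extreme form of the
inconsistency that makes Percentile the one algorithm practitioners are
advised against. ROC is in-sample by design (no train/test split), matching
the study design it emulates; AUCs are optimistic in the usual way.

## Known limitations

- Terminal-segment dropout is a single pathology mechanism; real
  maculopathies alter calibre, tortuosity and perfusion heterogeneously.
- Speckle is pixel-independent; real OCTA noise is spatially correlated,
  which would widen all repeatability bands.
- Two eyes of one subject are treated as independent (as in the emulated
  design); `subject_id` is recorded so clustered analyses can be added.
- The Hanley–McNeil CI and the chi-square Friedman p are approximations;
  both are calibration-tested at the sizes used here, not asymptotically
  exact.
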