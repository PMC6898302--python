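# Methods

## The model

`nflmd` treats the peripapillary NFL thickness of each of 16 equal 22.5°
sectors as a noisy linear read-out of local nerve-fiber survival `s ∈ [0, 1]`:

    t = f + s · (N − f),

where `N` is the normative reference thickness and `f` the floor — the
residual glial/scar tissue left in end-stage damage, below which no
further thinning occurs. Inverting this relation on a decibel scale gives
the sector loss

    NFL_dB = 10 · log10( (t − f) / (N − f) ),

which is 0 dB at the reference and −∞ at the floor; it is clamped at
−12.8 dB because measurement noise dominates once `t` approaches `f`
(the clamp corresponds to roughly 5% residual survival at a 5% sector
test-retest CV; lowering it would extend dynamic range at the cost of
reproducibility). Sector losses are aggregated with visual-field-area
weights into the weighted logarithmic average NFL_WLA, and a
zero-intercept quadratic (`0.864·x − 0.075·x²`) removes the residual
curvature between NFL_WLA and VF_MD. The zero intercept encodes the prior
that an average-normal thickness profile corresponds to an average-normal
field. The quadratic is strictly increasing on the operating range
[−12.8, +3] dB; the constructor rejects coefficient pairs that are not.

## Normative reference and floor

Each sector (plus the overall and inferior-quadrant summaries) has an
affine normative model `N = a + b_age·age + b_AL·AL` quoted at reference
covariates age 50 y and axial length 23.6 mm; the 18-row coefficient
table ships as versioned JSON (`data/normative_coefficients.json`) and
can be overridden per analysis. Two covariate conventions appear in
practice and agree up to the floor term; this package resolves them as:

* the dB transform uses the raw measured thickness against the
  covariate-specific reference `N(age, AL)` and a floor adjusted for
  axial length only (its age term is pinned at the reference age, since
  the residual glial tissue is not expected to follow the age decline of
  the axon population);
* `adjust_to_reference` separately maps measured thickness to the
  reference covariates, for cutoff computation on a common scale.

The floor fraction (default 0.45) is estimated from end-stage eyes
(VF_MD < −12 dB, selection applied by the caller): each eye's worst
sector *as a fraction of its covariate-specific reference* is taken as
fully damaged, and the worst-sector residual fractions are pooled by
unweighted mean across eyes (median available). Keeping the severity gate
outside the estimator makes it testable standalone.

## Weights

Weights are the number of 24-2 test points (52 after excluding the blind
spot) whose bundles traverse each sector, following a modified
Garway-Heath scheme whose six disc sectors are split into eight at the
horizontal (maculopapillary axis temporally, horizontal midline nasally).
The canonical 16-sector scheme ships as constants
(`data/vf_area_weights.json`). Its anchor is the inferior-most
inferotemporal sector at 7.64 — the value implied by the focal-loss
worked example (−12.8 dB × w/52 through the quadratic = −1.89 dB); the
superior mirror carries a comparable weight and the remaining mass
follows the modified Garway-Heath allocation (arcuate sectors heavy,
temporal moderate, nasal light), summing to exactly 52.
`interpolate_weights` is the derivation path when only eight-sector
counts are available: counts are spread over the 22.5° sectors
proportionally to arc overlap (uniform density within each zone), which
conserves the total; it is verified against a 0.1°-grid counting oracle.

Sector labels are stored in right-eye orientation with 0° at the temporal
horizontal; left-eye profiles are mirrored across the horizontal at
ingest so superotemporal/inferotemporal semantics stay anatomically
consistent (the instruments' export convention is not standardised, so
the package fixes one).

## Calibration

`fit_calibration` refits the quadratic by least squares with the
intercept pinned at zero and grouped 5-fold cross-validation: folds
partition participants, not eyes, because fellow eyes are correlated;
fold assignment is a seeded permutation. Out-of-fold predictions are
pooled and returned next to the all-data fit. The shipped default
coefficients are the published all-participant values.

## Diagnostics and staging

Cutoffs sit 1.65 / 2.33 SD below the normal-group mean (targeting 95% /
99% specificity under normality). dB parameters are near-normal only on
the linear scale, so their cutoffs are computed on `10^(x/10)` and mapped
back; thickness parameters are computed natively. Normality is assumed;
a Kolmogorov–Smirnov utility reports but never gates. Staging uses the
modified Hodapp-Parrish-Anderson thresholds (≥ −6 inclusive, < −6,
< −12 dB); staging agreement is scored by F1 with the mild (stage 0–1)
class positive by default — with the typical strong class imbalance the
mild class is the majority and this is the convention that makes the
statistic informative; the orientation is configurable. The two-level
NFL_MD staging splits at −6 dB with a secondary split at −12 dB.

## Agreement, reproducibility, inference

* Stage-stratified differences: per-eye mean over visits, then averaged
  within stage; the per-stage SD pools visit-level differences about the
  stage mean by root mean square. Bland-Altman bias is the mean of
  per-eye differences with limits at ±1.96 SD.
* Reproducibility: per-eye OLS of the parameter on visit time; residual
  variance with the regression denominator n − 2 (the df-correct choice);
  eyes pooled by RMS.
* Repeatability: ICC(2,1) — two-way random effects, absolute agreement,
  single measurement (computed via pingouin, verified against an ANOVA
  mean-squares oracle in the tests).
* Correlations and comparisons: point estimates are plain Pearson /
  Spearman; interval estimates and between-parameter comparisons use a
  percentile bootstrap that resamples participants (clusters), since both
  eyes of a participant may be enrolled. This model-free clustering
  replaces mixed-effects/GEE machinery; the paired-sensitivity comparison
  keeps the exact McNemar test.
* AROC is the Mann–Whitney probability with half credit for ties (lower
  value = more diseased), invariant under monotone transforms;
  sensitivities are case fractions below each cutoff.
* Every stochastic routine takes an explicit seed (default 20191206).

## Synthetic cohorts

`simulate_cohort` draws participants (1–2 eyes each) with age ≈ N(60,
9.5²) y and axial length ≈ N(24, 1.3²) mm, an eye-level lognormal size
factor with CV 0.085 shared across sectors, hidden per-sector survival
per group (normals ≡ 1; pre-perimetric: shallow narrow arcuate dips;
perimetric: diffuse plus deep/wide focal loss spanning early to severe
stages), measured thickness = floor + survival·(healthy − floor) times
mean-one lognormal noise with CV 0.05, and VF_MD as the VF-area-weighted
decibel survival plus N(0, 0.7²) dB test-retest noise. Visits add a
linear dB/year progression trend (default −0.3 dB/y for glaucoma eyes)
and fresh noise. QC fields are mostly clean with a 3% injected failure
rate to exercise the filters.

Because VF generation uses the same log-survival/VF-area aggregation the
NFL_MD transform assumes, structure-function coupling is log-linear *by
construction*. That is deliberate: it makes parameter-recovery tests
meaningful (the generator's truth is the estimator's target), but it
means passing tests demonstrate internal consistency of the pipeline,
not that real psychophysics obeys the model. Real VF point noise,
eccentricity effects, media opacity, and segmentation error are not
emulated. `simulate_end_stage_eyes` is the dedicated floor experiment:
the worst sector sits exactly at the floor; with 2% measurement noise the
pooled estimator recovers the generating fraction to well within one
percentage point (n = 200).

## Numerical choices and problem sizes

dB values are reported to 2 decimals in output tables; internal
arithmetic is full precision. The weight-sum and scheme validations use a
1e-9 tolerance. Covariates outside 18–100 y / 18–30 mm warn rather than
error (clinical data contain outliers); a non-positive predicted
reference is an error. Visit selection takes the earliest k visits with
complete paired data (strict calendar consecutiveness is not enforced);
when several scans exist per visit one is picked by seeded RNG.
Monte-Carlo sizes in the tests (200 end-stage eyes, 500 visit series,
10,000 simulated normals for cutoff specificity, 40 replications for
bootstrap-CI coverage) were chosen to keep the default suite fast on a
single CPU while leaving comfortable statistical margins.

## Known limitations

* The canonical weight vector is a reconstruction anchored to the
  published worked example, not a transcription of instrument output;
  analyses sensitive to individual nasal/temporal weights should derive
  their own scheme via `interpolate_weights`.
* Published clinical reference values that depend on the original study
  data (cutoffs of −1.23/−1.78 dB, group correlations 0.68/0.55,
  reproducibility 0.35 vs 0.69 dB) are context, not reproduction targets:
  the package's synthetic cohorts are not that population. Refitting the
  normative table from a user's normal cohort is supported as a generic
  least-squares utility.
* NFL_MD saturates near −23 dB by construction (clamp through the
  quadratic) and therefore under-reports severity in advanced disease
  relative to perimetry, whose pointwise floor is far deeper; the index
  is strongest for early detection and progression monitoring.
* A 5% uniform diffuse loss reads −0.22 dB without the floor term
  (`diffuse_loss_db`) but −0.37 dB through the floor-subtracted pipeline;
  both are exposed because both readings are in circulation, and the
  difference is exactly the floor subtraction.
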