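# Methods

## The decision tree

Grading follows the 2016 ASE/EACVI two-step structure, adapted so each
criterion can be evaluated from either modality's measurements.

**Routing.** Subjects with depressed EF (below the modality's EF
threshold: echo < 50 %, 4D flow < 55 %) or known structural myocardial
disease enter the grading step directly; everyone else passes through
the diagnosis step first. The modality-specific routing threshold keeps
the bias-adjustment principle consistent: an echo EF of 49 % and the
equivalent 4D EF of 54 % route the same subject the same way.

**Diagnosis step.** Four criteria: average E/e′ > 14; reduced e′
(septal e′ < 7 cm/s *or* lateral e′ < 10 cm/s — one criterion, not
two); elevated pulmonary arterial pressure (echo: TR > 2.8 m/s; 4D:
*t*ᵥₒᵣₜₑₓ > 15 %); enlarged left atrium (LAVI above the modality's
threshold). A criterion whose measurement is missing is *unavailable*,
not negative — for echo this happens when no tricuspid regurgitant jet
is detectable; the 4D arm always has all four (a single acquisition
yields every parameter). The verdict is a majority over available
criteria: more than half positive → dysfunction, exactly half →
indeterminate, fewer → normal; fewer than two available criteria is an
error.

**Grading step.** E/A ≤ 0.8 with E ≤ 50 cm/s → grade I (impaired
relaxation); E/A ≥ 2.0 → grade III (restrictive filling); otherwise the
three-criterion block (E/e′, pulmonary pressure, left atrium): ≥ 2
positive → grade II, ≥ 2 negative → grade I, an even split with one
unavailable (or < 2 available) → indeterminate. E/A ≤ 0.8 with
E > 50 cm/s proceeds to the three-criterion block. Subjects who reached
grading through a dysfunction diagnosis receive at least grade I;
subjects routed by depressed EF or myocardial disease may end
indeterminate — we do not force a grade on them.

**Ties.** All comparisons are strict, exactly as the thresholds are
quoted ("E/e′ > 14", "septal e′ < 7"): a value equal to a cutoff is on
the non-positive side. This makes grading deterministic at boundaries;
the complementary shortcut branches use ≤ / ≥ accordingly. An undefined
E/A (absent or zero A peak, e.g. fused filling) raises a diagnostic
error rather than guessing; missing values are explicit nulls
throughout, never sentinels, and units are fixed per field (velocities
in cm/s except TR in m/s; no implicit conversion).

## Cutoff calibration (rule 1: bias adjustment)

Paired differences are summarised Bland–Altman style with bias =
mean(echo − 4D) and 95 % limits of agreement at bias ± 1.96·SD (the
classical multiplier, not a t quantile). The zero-bias test is a
one-sample t-test when the differences pass Shapiro–Wilk normality at
α = 0.05, otherwise the Wilcoxon signed-rank test. An echo threshold x
transfers to the 4D scale as x − bias. The default policy adjusts only
the volumetric parameters (EF, LAVI) and keeps every velocity threshold
at its echo value; an `auto` policy instead adjusts whatever parameter
shows a significant bias (α = 0.05). Proportional (regression-based)
bias is out of scope: the transfer assumes a constant offset.

## Vortex surrogate (rule 2: segmented model)

pTR = 4·TR² converts the regurgitant velocity to a pressure gradient
(simplified Bernoulli). *t*ᵥₒᵣₜₑₓ is modelled as zero up to a breakpoint
pTR₀ and linear with non-negative slope above. Fitting profiles the
breakpoint: for fixed pTR₀ the slope is the closed-form least-squares
solution on the excess pressures max(0, pTR − pTR₀), with flat-segment
points contributing their squared *t*ᵥₒᵣₜₑₓ to the objective (they are
included, not down-weighted). The breakpoint is searched on a 200-point
grid over the observed pTR range and refined by golden-section search in
the bracket around the best grid point; the refinement tolerance is
1e−9 mmHg so the result is grid-independent and noiseless data recover
the generating parameters to machine-level accuracy (the objective is
piecewise smooth and V-shaped at the optimum, so the cost of the tight
tolerance is ~60 extra scalar evaluations). A negative unconstrained
slope is clamped to zero and flagged. Fit quality is reported as
R = √(1 − SSE/SST).

Subjects without detectable TR are excluded from the fit (they carry no
pTR value); plotting-style exports may show them at pTR = 0 but they
never enter the objective. The grading cutoff is the model prediction at
pTR(TR cutoff); its 95 % CI is a subject-level nonparametric percentile
bootstrap (default 2000 resamples, seeded, refitting per resample) —
the CI construction is a package choice, as no standard exists for this
derived quantity; degenerate resamples (all points on the flat segment)
are dropped. For grading, the pipeline rounds the transferred cutoff to
integer percent, matching how thresholds are quoted clinically.

## Agreement statistics

Cross-classification uses the five ordered categories with
indeterminate placed between normal and grade I. Weighted kappa uses
disagreement weights v_ij = |i−j|/(k−1) (linear, the default) or its
square (quadratic): κ = 1 − Σv·p_ij / Σv·p_i·q_j. Linear weights are the
default because, on the published 94-subject table, they reproduce the
reported κ = 0.84 whereas quadratic weights give ≈ 0.94. The CI is the
large-sample (Fleiss–Cohen–Everitt) variance with a normal
approximation, reported to 2 dp — on the published table this yields
(0.78, 0.91), matching the printed interval. Directional disagreement
uses the Bowker symmetry statistic Σ_{i<j} (n_ij − n_ji)²/(n_ij + n_ji)
with category pairs containing no discordant subjects excluded from the
degrees of freedom (this convention, not the fixed k(k−1)/2, reproduces
the reported p = 0.53 on 3 df); no discordant pairs at all returns p = 1
by convention. Binary accuracies carry exact two-sided 95 %
Clopper–Pearson intervals (Beta quantiles), reported as rounded
percentages. Interobserver reliability of continuous parameters uses
ICC(A,1) — two-way model, single measure, absolute agreement — from the
ANOVA mean squares, with the standard F-based CI (Satterthwaite df);
it is cross-checked against pingouin in the tests. Correlation strength
labels: |r| > 0.90 "very high", 0.70–0.90 "high".

## Synthetic cohorts

The generator emulates the validation study's *parameter-level*
structure; it simulates no velocity fields, vortices, or imaging
physics, and its grade-conditional distributions are plausible
constructions, not published per-grade data (only EF is anchored to the
reported per-grade pattern). Consequently, passing tests demonstrate
that the pipeline recovers what the generator embeds — biases,
correlations, the vortex relationship, grade margins — not that it
would reproduce any particular patient cohort.

Per subject: a latent parameter vector (EF, LAVI, E, A, septal/lateral
e′, TR) is drawn from its grade-conditional normal distribution
(truncated to physical bounds); both arms observe latent + independent
noise, the 4D arm shifted by the configured bias (echo − 4D convention:
EF −5 %, LAVI −13 mL/m², velocities 0). The noise SD per parameter is
sd(L)·√(1/r − 1), where sd(L) is the analytic cohort-level latent SD
(law of total variance over the grade mixture), so the realised echo/4D
correlation matches the configured target (defaults: EF 0.75, LAVI
0.80, E 0.87, A 0.85, septal e′ 0.80, lateral e′ 0.86). *t*ᵥₒᵣₜₑₓ is the
segmented model at the latent pTR plus a Gaussian residual (SD 2
percentage points), floored at 0; because the between-grade spread of
*t*ᵥₒᵣₜₑₓ dominates this residual, refits on default cohorts show
R ≈ 0.99. TR is masked as echocardiographically undetectable with a
per-grade probability calibrated so the realised cohort fraction is
~27 % (the raw probabilities differ because rejection sampling
conditions some grades against undetectable draws — an indeterminate
outcome needs an even criterion split, impossible over three available
criteria). The latent vector is rejection-sampled (cap 1000 draws)
until the *noisy echo arm* grades to the intended category under echo
cutoffs, so echo grade margins (default 51/9/13/13/8) are exact by
construction; a configuration that cannot realise a grade fails loudly.
Indeterminate subjects are produced by targeting an exact two-of-four
positive split (enlarged LA + reduced septal e′). Myocardial-disease
probabilities per grade (0.05/0/0.70/0.80/0.90) give ~31 structural-
disease subjects per cohort. The `zero_noise()` configuration sets
r = 1, removes the vortex residual, and makes all TR detectable — the
idealisation under which both arms must grade identically.

Everything is reproducible: one `numpy` Generator seeded at the top,
per-stage seeds split by SHA-256 in the pipeline, and CSV output at
fixed 4-decimal precision so equal seeds give byte-identical artifacts.

## Problem sizes and defaults

Tests and the demo run on 94-subject cohorts (the study size);
estimator-recovery checks use a 10× cohort (940) where sampling noise
would otherwise dominate (observed: bias within ±0.5, r within ±0.05 of
target). The noisy segmented-fit recovery check uses n = 69 points
(the detectable-TR subset size) with noise SD 2 over 200 replicates;
bootstrap defaults to 2000 resamples, reduced in tests where the CI
itself is not under scrutiny.

## Known limitations

- The generator's joint correlation structure *within* a modality
  (E with e′, LAVI with grade, …) arises implicitly from the
  grade-conditional means; it is not calibrated to data.
- Constant-bias transfer only; proportional bias would require a
  regression calibration that is deliberately out of scope.
- The kappa CI method and the surrogate-cutoff CI method are package
  choices (asymptotic normal; percentile bootstrap); other constructions
  are defensible and will differ in the second decimal.
- Special-population rules of the 2016 guideline (atrial fibrillation,
  mitral stenosis, rhythm irregularity) are not implemented; records of
  such patients are outside the tree's domain.
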