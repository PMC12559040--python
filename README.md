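# diaflow

Echo-equivalent grading of left ventricular (LV) diastolic dysfunction
from 4D flow MRI parameters, together with the full method-comparison
machinery needed to validate such grading against transthoracic
echocardiography.

## The problem

Echocardiography is the recommended method for grading LV diastolic
dysfunction, via the multiparametric, threshold-based 2016 ASE/EACVI
algorithm. 4D flow MRI measures the same hemodynamic quantities — LV
ejection fraction (EF), maximal left atrial volume index (LAVI),
transmitral early/late diastolic peak velocities (E, A), septal and
lateral early diastolic myocardial peak velocities (e′), and their
ratios E/A and E/e′ — from a single acquisition. Two obstacles prevent
simply reusing the echocardiographic thresholds:

1. **Volumetric biases.** MRI-derived EF and LAVI differ systematically
   from echo. With bias defined as mean(echo − 4D), the echo thresholds
   transfer to the 4D scale by subtraction: EF 50 % − (−5) = **55 %**,
   LAVI 34 mL/m² − (−13) = **47 mL/m²**. Velocity parameters show no
   significant bias and keep their echo cutoffs (E > 50 cm/s,
   0.8 < E/A < 2.0, septal e′ < 7 cm/s, lateral e′ < 10 cm/s, E/e′ > 14).
2. **No tricuspid-regurgitation velocity.** The echocardiographic marker
   of elevated pulmonary arterial pressure, the tricuspid regurgitant
   peak velocity TR > 2.8 m/s, has no direct 4D-flow counterpart.
   Instead, the duration of vortical blood flow along the main pulmonary
   artery, *t*ᵥₒᵣₜₑₓ (% of the cardiac interval), serves as a surrogate:
   with the peak tricuspid pressure gradient pTR = 4·TR² (mmHg, simplified
   Bernoulli), *t*ᵥₒᵣₜₑₓ follows a segmented linear ("hockey-stick") model

   *t*ᵥₒᵣₜₑₓ(pTR) = slope · max(0, pTR − pTR₀),

   fitted at pTR₀ = 18.4 mmHg and slope = 1.19 %/mmHg, which maps
   TR = 2.8 m/s (pTR = 31.4 mmHg) to *t*ᵥₒᵣₜₑₓ = 15 %.

The package implements the adapted decision tree (diagnosis by a
four-criterion majority over the *available* criteria, then grading into
grade I / II / III or indeterminate), both cutoff-selection rules
(Bland–Altman bias adjustment; segmented-model cutoff transfer with a
subject-level bootstrap CI), and the agreement statistics used to compare
two graders on the five ordered categories
(normal < indeterminate < I < II < III): Cohen's linearly weighted kappa
with an asymptotic CI, the Bowker symmetry (McNemar-type) test,
exact Clopper–Pearson accuracy intervals, and the two-way single-measure
absolute-agreement intraclass correlation ICC(A,1). A synthetic-cohort
generator reproduces the validation study's statistical structure
(grade mixture 51/9/13/13/8, the volumetric biases, inter-modality
correlations 0.75–0.92, the segmented vortex relationship, and ~27 %
echocardiographically undetectable TR) so the whole pipeline is testable
without patient data.

## Worked example

```bash
$ diaflow run-all --simulate --seed 42 --out-dir demo
4D cutoffs: EF < 55.0 %, LAVI > 46.4 mL/m^2, t_vortex > 15 %
segmented fit: pTR0 = 18.7 mmHg, slope = 1.21 %/mmHg, R = 0.99
weighted kappa = 0.88 (0.82, 0.95); symmetry p = 0.20; 13 of 94 discordant
artifacts written to demo
```

A simulated 94-subject cohort is calibrated (the generator's true biases
are −5 % EF and −13 mL/m² LAVI, so the recovered 4D cutoffs land near
55 and 47), the vortex model is refitted (truth: 18.4 mmHg, 1.19 %/mmHg),
both arms are graded, and their 5×5 cross-classification is summarised:
here the two modalities agree almost perfectly (κ = 0.88) with no
directional over- or under-grading (symmetry p = 0.20). The `demo/`
directory holds the cohort CSV, adjusted-cutoff YAML, vortex-fit JSON,
per-subject grades with criterion-level audit columns, the agreement
report (including which criterion caused each discordance), and a run
log with seed and config hash.

The built-in published cross-classification is also available directly:

```bash
$ diaflow agree --table4 --format markdown
| 4D flow \ echo | 0 | indet | 1 | 2 | 3 |
|---|---|---|---|---|---|
| 0 | 44 | 6 | 0 | 0 | 0 |
| indet | 7 | 3 | 0 | 0 | 0 |
| 1 | 0 | 0 | 12 | 4 | 0 |
| 2 | 0 | 0 | 1 | 8 | 2 |
| 3 | 0 | 0 | 0 | 1 | 6 |

weighted kappa (linear): 0.84 (0.78, 0.91)
symmetry: chi2 = 2.21, df = 3, p = 0.53
discordant: 21 of 94
```

Individual stages are exposed as `simulate`, `calibrate`, `fit-vortex`,
`grade` and `agree` subcommands, and everything is importable as a
library (`diaflow.grade_subject`, `diaflow.fit_segmented`,
`diaflow.weighted_kappa`, ...).

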