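# Methods

## Model

`subtypegan` discovers latent disease subtypes from regional brain-volume
(ROI) tables by learning how a cognitively normal (CN) reference
population is transformed into a patient population, rather than by
clustering patients directly. Three small fully-connected networks are
trained jointly:

* a **mapping** f : X × Z → Y that takes a CN feature vector x (R ROIs)
  concatenated with a one-hot subtype code z of dimension M (each position
  sampled with probability 1/M, independently of x) and produces a
  synthetic patient-like vector y′ = f(x, z);
* a **clustering function** g : Y → Δ(M) that maps any patient-like
  vector to a point on the M-simplex (linear layers + softmax head);
* a **discriminator** D : Y → (0, 1) that scores whether a vector comes
  from the real patient sample or from f.

The training objective is

L(D, f, g) = L_GAN(D, f) + μ·L_change(f) + λ·L_cluster(f, g),

minimized over (f, g) and maximized over D in alternating steps, where

* L_GAN is the usual cross-entropy adversarial loss
  E[log D(y)] + E[log(1 − D(f(x, z)))] (the generator descends the
  non-saturating form −E[log D(y′)]); a variant that uses
  E[1 − log D(y′)] for the fake term is available via
  `HyperParams.gan_form="printed"` — for the generator the two coincide up
  to an additive constant, so the switch only changes the discriminator's
  fake-sample objective;
* L_change(f) = E‖f(x, z) − x‖₁ keeps the learned transformations sparse:
  disease should alter a subset of regions, not re-draw the whole brain;
* L_cluster(f, g) = E[ℓ_ce(z, g(f(x, z)))] (cross-entropy) forces the M
  transformations to remain mutually distinguishable, which is exactly
  what makes g a usable inverse on *real* patient data: after training,
  g(y) is read as the vector of pattern pseudo-probabilities of patient y.

Lipschitz continuity of D is enforced by clipping every D weight to
[−c, c] after each update (optionally also f and g via `clip_fg`).
Probabilities are clipped to [1e-12, 1] before logarithms. Argmax ties
resolve to the lowest pattern index.

### Assumptions

The model assumes (i) patients are CN-like vectors plus a disease
transformation, so any variation present in the CN group (age, sex, head
size, scanner noise) is, by construction, not a subtype; (ii) subtypes
are expressed as distinct, reproducible multivariate displacement
patterns; (iii) inputs are on a common scale — the preprocessing below is
part of the method, not an optional convenience.

## Preprocessing

Per ROI, ordinary least squares of volume on (age, sex) is fit on CN rows
only (≥ 10 required; a constant covariate gets a zero coefficient).
Every row — CN and patient, cross-sectional and longitudinal — is then
residualized by subtracting covariate *deviations from the CN means*,
value′ = value − β_age(age − mean_age) − β_sex(sex − mean_sex), which
preserves the CN-referenced intercept. Each ROI is finally mapped to
1 + 0.1·(value − μ)/σ with μ, σ the CN mean and sample SD (ddof = 1) of
the residualized values, so the CN block has mean 1 and SD 0.1 exactly
and "1.0" always reads as "typical CN volume". The residualization is
deliberately *not* the zero-mean residual: subtracting the full fitted
value would destroy that interpretation.

## Training defaults and their calibration

| parameter | default | meaning |
|---|---|---|
| μ (`mu`) | 0.1 | weight of the L1 change loss (per data-scale unit) |
| λ (`lam`) | 1.0 | weight of the cluster cross-entropy |
| `lr_g` / `lr_d` | 5e-4 / 1e-3 | Adam (β₁ = 0.5, β₂ = 0.999) |
| batch size | 25 | per group per iteration |
| `d_steps` | 1 | discriminator updates per generator update |
| `clip_c` | 0.1 | weight-clip radius on D |
| `max_iters` | 6000 | generator iterations |
| plateau window / tol | 1000 / 1e-3 | stop when the change and cluster moving averages both stall |
| collapse threshold | 5% | smallest dominant-assignment share below which a run restarts (seed + 1, ≤ 3 restarts) |

Hidden widths taper (f: R/2–R/4–R/2, g: R/2–R/4, D: R/4–R/16), leaky-ReLU
slope 0.2. Inputs are internally standardized per ROI by the CN mean/SD
(stored on the model); all reported losses stay on the data scale.

Two of these numbers deserve justification. **μ** must be small enough
that applying a genuine disease displacement is worth its L1 price: the
discriminator's per-feature gradient is bounded by the weight clip, so a
large μ (e.g. 5) freezes f near the identity and no subtype structure is
ever imprinted — recovery on ground-truth cohorts collapses to ARI
≈ 0.2–0.5. With μ = 0.1 the mapping reproduces planted 15-ROI atrophy
masks essentially exactly. **The discriminator must stay ahead of the
generator**: with equal learning rates and one D step, modes occasionally
mix late in training on some seeds; giving D twice the generator's
learning rate (equivalently, extra `d_steps`) removes the bulk of that
instability, with median recovery ARI at 1.0 and only rare low-ARI
seeds. These defaults were fixed by calibration on the synthetic
recovery harness and are not data-derived constants; all are exposed in
`HyperParams`.

Seeded runs are bitwise reproducible on a given platform: all randomness
flows through one `numpy` generator per training attempt, and the
networks are plain NumPy with hand-written backprop.

## Model selection and consensus

The number of patterns M is chosen by repeated holdout stability: per
candidate M, each of `folds` models trains on a random 80% of the
discovery rows (CN and patient subsampled jointly, unstratified), labels
*all* discovery patients, and the mean pairwise adjusted Rand index (ARI)
across fold labelings is the stability score; the highest mean wins, ties
to the smaller M. Evaluating every fold on the full patient set keeps the
pairwise ARIs comparable. A permutation test
(`permutation_reproducibility_test`) re-draws the CN/patient split at
fixed group sizes to calibrate the stability score against chance; this
protocol is this package's own reconstruction of a
stability-significance check.

The final output is a consensus of (by default) 30 independently seeded
models: the model whose hard labeling best agrees with the rest (highest
mean pairwise ARI) becomes the template; every other model's pattern
columns are permuted onto it by maximizing the contingency-table overlap
(exhaustive over M! permutations for M ≤ 8, lexicographic tie-break;
Hungarian assignment beyond); the aligned probability matrices are
averaged. The mean of simplex points is a simplex point, so consensus
rows still sum to 1.

## Synthetic cohorts

The generator emulates the structure of a 145-region volumetric atlas
(119 gray-matter, 20 white-matter, 6 ventricle ROIs). Every subject's
volumes are baseline_mean ⊙ global_scale ⊙ (1 + age slope + sex offset +
low-rank correlated noise + iid noise); patients additionally have the
ROIs of their subtype's mask multiplied by (1 − a), with a drawn per
subject from Uniform[0.1, 0.3] by default (ventricle ROIs in a mask are
multiplied by (1 + a), since disease appears there as enlargement). The
default masks are three disjoint random 15-ROI gray-matter sets.
Structural draws (baseline means, masks, noise loadings) use a separate
`structure_seed`, so different `seed` values give sampling replicates of
one fixed population. Defaults: 300 CN, 400 patients, age slope
−0.4%/year, sex offset 4%, global-scale log-SD 0.1 (the dominant shared
confound), rank-5 correlated noise at 3%, iid noise 5%, ages uniform on
[55, 85].

The longitudinal generator routes each patient down one of two
progression pathways (early atrophy in mask 1 or mask 2; 70/30 mix by
default), with a per-subject lognormal progression speed (median 6%
atrophy/year). Early-mask atrophy grows linearly in time up to a cap;
past a late-onset threshold the other mask starts accumulating too,
emulating a shared advanced stage. Ground truth records subtype, applied
atrophy, pathway, and a per-visit stage (1 → 2 → 3).

What the generator does **not** emulate: site/scanner batch effects,
longitudinal measurement drift, missing visits, diagnosis label noise,
non-linear age effects, spatially structured (atlas-topological)
correlation, or mixed/overlapping subtypes (a convex-mixture option
exists but is off by default). Passing the recovery suite therefore shows
the machinery is correct and confound-resistant in the stated regime — it
is not evidence about any particular clinical population.

## Progression analysis

A subject's dominant pattern is the argmax pattern when its probability
strictly exceeds 0.5; otherwise the subject is unassigned and excluded
from survival analyses. Conversion to a target pattern is the first visit
at which the target's probability strictly exceeds the threshold —
between-visit times are not interpolated; non-converters are censored at
the last visit; competing targets become distinct event types. Analyses
with a source-pattern origin (e.g. "from P1") filter at baseline on
source probability > 0.7.

Kaplan–Meier, Aalen–Johansen (competing risks), the log-rank test and Cox
proportional-hazards fitting are delegated to `lifelines`; Harrell's C
uses `lifelines.utils.concordance_index` with the risk sign flipped to
its convention (ties in risk count 0.5). The repeated-CV evaluator runs
100 random two-fold splits by default, fits Cox on one half, scores the
other by its partial hazard (the composite risk score) and reports all
200 validation C values; non-convergent fits are recorded as missing.
Fixed-horizon discrimination treats "converted by year X" as a binary
outcome (subjects censored before X are excluded at that horizon),
reports the AUC of the baseline probability, and locates the operating
threshold where TPR + FPR = 1 (sensitivity = specificity) by linear
interpolation along the ROC curve.

## Numerical and scale choices

* Acceptance-scale problem sizes — 300 CN / 400 patients, 3 subtypes,
  3–6 training seeds, 4 holdout folds, 6000 iterations — are the
  package's chosen desk-scale defaults; larger budgets only help.
* Simplex tolerance 1e-6 on probability rows; ε = 1e-12 before logs.
* The stability pipeline records collapsed folds as missing rather than
  failing the whole selection.
* Degenerate inputs are refused loudly: < 10 CN rows, zero-variance ROIs
  (numerically constant counts as constant), mismatched ROI names,
  unsorted visit times, event tables with no comparable pairs.

## Known limitations

* With M above the true subtype count, the surplus pattern can either
  collapse (triggering restarts) or stably split one subtype; stability
  selection can therefore be close between the true K and K + 1 on very
  clean synthetic data — noise-free clusters are *too* easy to split
  reproducibly.
* Weight clipping is a blunt Lipschitz device; the clip radius interacts
  with μ (see calibration above).
* The consensus aligns hard labelings; when two models disagree strongly
  the permutation may be ambiguous, which the jackknife-over-models
  diagnostic surfaces.
* Training cost grows with R through the network widths; the default
  architecture targets atlas-scale inputs (R ≈ 100–300), not voxel-level
  data.
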