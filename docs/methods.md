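# Methods

`neuroxai` benchmarks explanation (attribution) methods for deep-learning
mental-state decoding.  Real benchmarks of this kind rest on trial-level
BOLD maps from task fMRI; this package replaces the data with a synthetic
generator whose ground truth is known by construction, so that every stage
— decoding, attribution, aggregation, and the three evaluation axes — can
be tested end-to-end on one CPU.

## Synthetic volumetric data

Each dataset lives on a voxel grid (default 16×16×16) inside an ellipsoidal
"brain" mask inscribed in the grid.  Every mental state c of the C classes
(default 4) is assigned a planted spatial pattern

    w_c = Σ_j s_j · A_j · G(μ_j, σ),   σ = FWHM / 2.355,

a sum of isotropic Gaussian blobs (default 3 per class, FWHM 4 voxels,
peak amplitude 1) at seeded random in-mask centers.  A configurable
fraction of blobs (default 25%) carries negative sign, emulating
de-activations, so attribution methods face voxels whose association with
the state is negative.  In addition, `redundant_cluster_count` extra blobs
(default 2) duplicate the signal of an existing blob at a spatially
disjoint location (centers at least 1.5 FWHM apart): the duplicate shares
the base blob's sign and its per-subject amplitude factor, so the two
clusters are perfectly correlated and a decoder can rely on either copy.
This planted redundancy is what lets explanation faithfulness and
ground-truth alignment dissociate — a faithful explanation highlights the
copy the model actually uses, an aligned explanation highlights both.

A trial for subject s and class c is

    x = w_c^(s) + ε,

where `w_c^(s)` perturbs each blob-group amplitude by `1 + N(0, subject_sd)`
(default 0.1) and rigidly jitters all blob centers by up to one voxel
(the jitter is part of the subject effect and vanishes at `subject_sd = 0`,
so the noise-free limit reproduces the class patterns exactly), and ε is
Gaussian noise smoothed to FWHM 2 voxels and rescaled to sd 0.5 — the
smooth, spatially correlated noise floor that trial-level beta maps
exhibit.  Defaults: 12 subjects, 24 trials per class per subject, two
runs per subject, a subject-wise 20% test split.  The spatial covariance
of real beta-map noise is not well characterised; the smooth-Gaussian
choice is a modeling decision and is exposed in the configuration.

The generator's `support_mask` is the set of voxels above half of the
pattern's peak |weight| — the FWHM convention for the extent of a Gaussian
blob.  What passing tests show about real data is limited accordingly: the
generator has no haemodynamics, no physiological artefacts, no
inter-regional correlation beyond the planted clusters, and its
class-conditional means are exactly the planted patterns.

## Decoder

A 3D-CNN: `n_conv_layers` (default 3) stride-2 convolutions with
"same" zero padding (chosen so a 16³ grid survives four layers; the
padding scheme is otherwise a free choice), batch normalization applied to
the linear convolution outputs before the ReLU, optional dropout on the
convolution outputs, then a dense softmax layer on the flattened feature
maps.  Training minimises cross-entropy with Adam (β₁, β₂, ε at standard
defaults) and evaluates once per epoch on a random 10% validation split.
Early stopping fires when the evaluation loss has been worse than its
previous best for three consecutive evaluations, or when the sd of the
last 10 evaluation losses is at most 0.01 — never before epoch 10 nor
after epoch 100.  The parameters of the best-evaluation-loss epoch are
restored afterwards (disabled via `restore_best=False` for the deliberate
overfitting used by the data-randomization check).

Hyper-parameter selection scores each configuration of the grid (layers
{3,4} × kernels {4,8,16,32} × kernel size {3,5} × batch {32,64} × learning
rate {3e-4, 1e-3} × dropout {0, .25, .5}; 192 points, with a reduced
8-point subset for desk scale) by stratified 3-fold cross-validation:

    λ = ε_V + (ε_V − ε_T),

the mean validation error plus the generalization gap; lowest λ wins.
Final fits are an ensemble of 10 runs differing in seed and train/validation
split; the best-evaluation-loss run is the primary model.

The network stack is implemented directly on numpy with explicit
forward/backward kernels.  This keeps the backward pass open: the
attribution rules below (guided ReLU masking, DeepLift multipliers, LRP
redistribution) are non-standard backward passes, and installing them in
an explicit stack avoids framework graph surgery.

## Attribution methods

All methods run on the evaluation-mode network with batch normalization
folded into the adjacent convolution (canonization), so each layer is
affine followed by ReLU.  The attribution target is the pre-softmax logit
of the trial's true class by default (`target_output="probability"` is
available for the gradient family): probabilities saturate under softmax
and flatten gradients.  Dropout is always disabled.  Relevance maps are
zeroed outside the brain mask, and each map records its in-mask sum (a
nuisance covariate during aggregation).

* **Gradient** — |∂f/∂x| per voxel.
* **SmoothGrad** — mean of |∇f(x+ν)| over K=50 draws ν~N(0, σ²), σ=1
  (in input units; trial values are O(1)).  The averaged-absolute reading
  is the default; `smoothgrad_absolute=False` averages signed gradients.
* **InputXGradient** — ∇f(x) ∘ x, signed.
* **Guided Backpropagation** — backward pass whose ReLU rule zeroes the
  signal where the top-down gradient is negative *and* where the forward
  pre-activation was negative (the canonical rule); `guided_literal=True`
  keeps only the gradient-sign mask.
* **Guided GradCam** — GradCam pools ∂f/∂Aᵏ over positions of the last
  convolution's feature maps into weights αₖ, forms ReLU(Σₖ αₖAᵏ) on the
  coarse grid, trilinearly upsamples to the input grid, and multiplies with
  the Guided Backpropagation map.
* **Integrated Gradients** — midpoint Riemann sum (64 steps by default,
  256 in the completeness audits) of (x−b) ∘ ∫∇f(b+α(x−b))dα for two
  baselines, the all-zero volume and the dataset mean, averaged 0.5/0.5.
* **DeepLift** — multipliers propagated by the linear rule through
  convolutions and the dense layer and by the rescale rule
  m = Δσ(a)/Δa at ReLUs (gradient substituted where |Δa| < 1e-7);
  relevance is Δx ∘ m.  DeepLift SHAP averages DeepLift over K=50
  seeded references drawn from the training data.
* **LRP** — backward decomposition seeded with f(x): LRP-0 at the dense
  output layer, LRP-γ (γ=0.25) at every convolution, denominators
  stabilized by ε=1e-6·sign and excluding the bias so that layer sums stay
  equal to f(x) (conservation is exact on bias-free networks and audited
  per layer in the tests).

Sign conventions: Gradient, SmoothGrad, Guided Backprop and Guided GradCam
return non-negative (ReLU-clamped) maps where their definitions imply it;
the reference-based methods and LRP return signed maps.  No global absolute
value is imposed.

## Two-stage GLM

Subject stage: independent OLS per voxel on the subject's trial volumes
with one indicator per class and (when present) run indicators as nuisance;
the per-class map is the one-vs-rest contrast (target class minus the mean
of the others).  Group stage: subject maps are smoothed with a Gaussian
kernel (FWHM 1.5 voxels, the synthetic-grid stand-in for 5 mm) and fitted
across subjects with class indicators of interest and subject indicators
as nuisance — the paired t-test across subjects — and t statistics are
mapped to Z through the Student-t CDF.  Nuisance indicators are centered
(one redundant level dropped) so interest coefficients stay interpretable
as adjusted means.  Aggregating attribution maps uses the same two stages
with two extra nuisance terms at the subject stage: model-training-run
indicators and the centered per-map relevance sum.  Both stages share the
same smoothing FWHM (whether the second stage of an attribution
aggregation should be smoothed differently is under-determined; one knob
controls both).

## Evaluation axes

**Alignment.**  KSG k-nearest-neighbour mutual information (k=3, Chebyshev
balls, ψ-based estimator) between the in-mask voxel vectors of an
attribution map and a reference map — the planted ground-truth pattern, or
the group-level GLM Z map of the training subjects.  Seeded jitter at
1e-10·sd breaks ties; negative estimates are clipped to 0 for reporting
with the raw value available.  Full-mask vectors are used by default, with
optional seeded voxel subsampling.  Pearson r is reported as a secondary
linear metric.

**Faithfulness.**  The occlusion grid runs from 0 to 0.5 in steps of 0.025
(21 points; only the endpoints are canonical, the step is a resolution
choice).  At rate ρ the ⌈ρ·N_mask⌉ voxels with the highest relevance
(signed ranking, most-positive evidence first, ties broken by voxel index;
absolute ranking available) are set to zero and test accuracy is
re-evaluated.  The critical rate is the first grid point with accuracy at
or below 1/C; runs that never cross are recorded as censored at 0.5.
Below-chance accuracies are retained — occlusion can bias the model toward
systematically wrong states.

**Sanity checks.**  Attributions of the trained model are compared (per
trial, mean KSG MI over trials, computed per model run) against those of
(a) an architecture twin with freshly initialised weights and (b) a twin
trained for a fixed long period on label-shuffled data until it memorizes
(300 epochs at desk scale, with the memorization asserted: training
accuracy above 90% and held-out accuracy within 10 points of chance — the
held-out guard uses the test trials, whose sample size supports the bound,
with a binomial-noise floor for very small samples).  Lower MI means
stronger model/data sensitivity.  The self-comparison MI is reported as
the ceiling, and a `relevance = input` control map is flagged insensitive.

**Method comparison.**  Scores are modelled as `score ~ 1 + method` with
DeepLift the unmodelled baseline; each coefficient (a mean difference)
gets a 94% bias-corrected bootstrap percentile interval with expanded
percentile levels (Student-t quantiles scaled by √(n/(n−1))) to correct
the small-sample narrowness of percentile intervals; null coverage is
calibrated to the low-90s in the tests.  A method differs meaningfully
from the baseline if its interval excludes 0.  (A posterior-HDI fit could
replace the bootstrap behind the same interface; the interval contract —
94%, excludes zero — is the fixed part.)

## Problem sizes and numerical choices

The shipped defaults are sized for a single CPU: the full benchmark
(dataset generation, 10 training runs, nine methods, 21-point occlusion
curves, sanity checks) completes in roughly a quarter hour, with
attribution and occlusion computed on a 96-trial subset of the test split
and sanity-check MI on 24 trials.  The acceptance script defaults to a
5-run ensemble and 64 attributed trials.  Sum-rule audits run on bias-free
toy networks (8³ grids), where completeness and conservation are exact up
to the LRP stabilizer; tolerances are 1e-3 relative (1e-4 for DeepLift).
Degenerate cases are handled explicitly: zero-residual voxels flag t as
degenerate (±∞), constant MI inputs return 0 with a warning, occlusion
ties break by voxel index, and all stochastic components (noise draws,
reference sampling, bootstrap, tie jitter) are seeded.

## Known limitations

* The generator's class-conditional means are exactly the planted blobs;
  real decoding problems have distributed, partially overlapping signal.
* Group-level aggregation needs ≥3 subjects; the default 12-subject/20%
  split leaves 2 test subjects, so run-level alignment uses subject-level
  aggregated maps and the pooled group stage is emitted only when the test
  split has 3+ subjects.
* Attribution methods are implemented for the package's own CNN stack, not
  for arbitrary architectures (no skip connections, no pooling layers).
* The comparison statistic assumes exchangeable per-run/per-subject scores;
  with 10 runs its intervals are calibrated only to a few percent.
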