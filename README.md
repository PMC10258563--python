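# neuroxai

Benchmarking explanation (attribution) methods for deep-learning
mental-state decoding — on synthetic volumetric data with a known ground
truth.

## The problem

3D convolutional networks decode mental states (which task condition a
person was in) from trial-level voxelwise brain activation maps, and
attribution methods are then used to ask *which voxels the decoder relied
on*.  But attribution methods disagree, and there is no single notion of a
"good" explanation: a map can align well with where the signal truly is,
yet describe the model's decision process poorly — especially when brain
activity is spatially redundant and the model only needs a subset of the
informative voxels.

`neuroxai` turns this benchmark into a reusable, fully testable pipeline.
A synthetic generator plants smooth per-class activation patterns
(including negatively associated regions and deliberately redundant
duplicate clusters) inside a brain-like mask, adds per-subject random
effects and smooth noise, and hands every downstream stage a ground truth
it can be scored against.  The pipeline then:

1. trains an ensemble of 3D-CNN decoders (stride-2 convolutions + batch
   norm + dense softmax; early stopping; hyper-parameter selection by
   `λ = ε_V + (ε_V − ε_T)` over 3-fold CV);
2. computes nine attribution methods from their formulas — Gradient,
   SmoothGrad (K=50, σ=1), InputXGradient, Guided Backpropagation, Guided
   GradCam, Integrated Gradients (dual zero/data-mean baselines), DeepLift,
   DeepLift SHAP (K=50), and LRP (LRP-0 dense / LRP-γ conv, γ=0.25);
3. aggregates attribution maps with a two-stage voxelwise GLM (model-run
   and attribution-sum nuisance regressors at the subject stage, paired
   random-effects group stage);
4. scores each method on three axes: **alignment** with reference maps by
   Kraskov–Stögbauer–Grassberger mutual information (k=3), **faithfulness**
   by the occlusion rate at which decoding accuracy first drops to chance,
   and **sanity** via model- and data-randomization checks; methods are
   compared against a DeepLift baseline with 94% bootstrap intervals.

The central design point is that the attribution rules (guided ReLU
masking, DeepLift multipliers, LRP redistribution) are non-standard
backward passes, so the CNN stack is implemented directly on numpy with
explicit forward/backward kernels — sum rules like DeepLift's
summation-to-delta and LRP's layerwise conservation are then exact and
auditable.  See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from neuroxai import (SyntheticConfig, generate_dataset, DecoderConfig,
                      train_ensemble, evaluate, AttributionParams,
                      attribute_batch, faithfulness_curve)
from neuroxai.synthetic import stack_trials

dataset, patterns = generate_dataset(SyntheticConfig(seed=11))
X, y, *_ = stack_trials(dataset.train)
models = train_ensemble(DecoderConfig(seed=42), (X, y), n_runs=3)
primary = next(m for m in models if m.is_primary)
print("test accuracy:", evaluate(primary, dataset.test)[0])

params = AttributionParams(seed=5)
params.reference_data = X
for method in ("deeplift", "gradient"):
    attrs = attribute_batch(primary, dataset.test[:96], method, params)
    curve = faithfulness_curve(primary, dataset.test[:96], attrs)
    print(method, "critical occlusion rate:",
          curve.critical_rate if not curve.censored else ">=0.5")
```

prints

```
test accuracy: 1.0
deeplift critical occlusion rate: 0.025
gradient critical occlusion rate: >=0.5
```

i.e. the decoder reads every held-out-subject trial correctly; zeroing
just the top 2.5% of voxels ranked by DeepLift already drives it to chance
(the explanation found the voxels the model uses), while removing up to
half the brain by Gradient ranking never does.  At the same time the
gradient-family maps align *better* with the planted ground truth — the
faithfulness/alignment dissociation that planted redundancy produces, and
the integration tests assert.

The same pipeline is scriptable from the shell:

```bash
neuroxai write-config config.yaml
neuroxai run --config config.yaml --seed 7 --out bench_out
# stages: generate | train | attribute | evaluate | report (resumable)
```

which leaves tidy CSV tables (`alignment_runs.csv`, `critical_rates.csv`,
`sanity.csv`), NIfTI reference/attribution maps, and a `summary.md` check
matrix under `bench_out/results/`.

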