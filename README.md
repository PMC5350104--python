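# glidernet

Tools for studying how selectivity for *multipoint spatial correlations* —
the higher-order image statistics that distinguish corners, contours and
textures from noise — can arise in early visual cortex, and how it relates
to motion tuning.

Neurons in macaque V2 (and some in V1) respond selectively to binary
textures whose only structure is a specific third- or fourth-order spatial
correlation (maximum-entropy "glider" textures: *white/black triangle*,
*even/odd*, *wye/foot*, plus unstructured *random*).  A feedforward
linear–nonlinear (LN) cascade fitted to such responses reproduces the
training set but fails to generalize to fresh texture examples.  A small
recurrent network — 256 inputs (one per check), two hidden layers of
sigmoid units with full within-layer recurrence, trained by
backpropagation through time to reproduce the five-bin response time
course — does generalize, and its hidden units spontaneously develop speed
and direction tuning that is correlated with their four-point texture
selectivity.

Because the original recordings are not publicly deposited, the package
ships a first-class **surrogate population generator**: Poisson-spiking
model neurons with area/layer-dependent class gains (even-preferring on
average in "V2 supragranular"), per-example sensitivity through local
glider statistics, and transient/sustained temporal kernels.  All
quantitative results here are computed on this surrogate data.

## What is in the box

| module | contents |
| --- | --- |
| `glidernet.textures` | maximum-entropy glider textures (Markov recurrence), Gaussian blur, oriented-noise and moving-noise probes, ensemble statistics |
| `glidernet.surrogates` | surrogate neurons, population simulation, target normalization, split-half consistency |
| `glidernet.ln` | `LinearNonlinearModel` → `LNResults`: STA/STC moments, iSTAC filter selection, histogram-ratio nonlinearities |
| `glidernet.network` | `RecurrentFormAnalysis` → `RFAMResults`: Nguyen–Widrow init, Elman forward dynamics, exact BPTT, SGD(+momentum) training |
| `glidernet.probing` | tuning curves and the TTI/TSI/OSI/SSI/DSI selectivity battery |
| `glidernet.analysis` | PCA of response dynamics, convex-hull overlap, ridge-regression similarity, form–motion correlations, counterfactual target swap |
| `glidernet.pipeline` | one-config orchestration of the whole chain |
| `glidernet.cli` | `glidernet stimgen / simneurons / fitln / trainrfam / probe / analyze / run-all` |

## Worked example

```python
import numpy as np
from glidernet.pipeline import (
    PipelineConfig, generate_class_ensembles, flatten_stimuli,
    build_targets, fit_rfampa, tuning_curve_correlation,
)

# 200 textures per class, blurred (sigma = 2 checks) and flattened
grids = generate_class_ensembles(200, master_seed=1, stream="train")
stimuli, labels = flatten_stimuli(grids)

# surrogate V2 supragranular population average as the training target
targets, _, _, classes = build_targets(grids, {("V2", "supra"): 32}, 1)
print(np.round(targets.values.mean(axis=1), 3))
# [0.282 0.267 0.306 0.602 0.083 0.266 0.292]   <- class-mean target curve
#  random  w_tri  b_tri  even   odd   wye  foot

# train a single-output recurrent network (30+30 hidden units)
res = fit_rfampa(stimuli, labels, targets.values, classes,
                 n_epochs=2_000_000, learning_rate=0.02, momentum=0.95, seed=11)
print(res.summary())

# generalization: tuning curve on textures never seen in training
r, model_curve, target_curve = tuning_curve_correlation(
    res, targets.values, classes, n_examples=1000, master_seed=1)
print(round(r, 2))
```

The target curve shows the surrogate population average preferring *even*
textures (0.60) and suppressing *odd* (0.08) relative to *random* (0.28).
The final correlation measures whether the trained network reproduces that
preference pattern on fresh texture examples — the generalization that the
LN baseline lacks.

The full chain (LN baseline, probing, population analyses, counterfactual
control) runs from one config:

```bash
glidernet run-all --smoke --out-dir scratch/smoke   # tiny end-to-end check
```

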