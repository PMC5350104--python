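# Methods

This note documents the models implemented in `glidernet`, the choices made
where the published description left the design open, and what the
surrogate-data experiments can and cannot establish.

## Glider textures

A texture class is defined by a *glider* — a set of (row, col) check
offsets — and a target parity for the product of the covered checks in
±1 coding.  Generation uses a Markov recurrence: a check is *determined*
when it is the raster-last member of a complete glider placement, in which
case its value is forced by the parity of the other members; all other
checks are i.i.d. uniform.  Because the raster-last offset of a glider is
unique, each check is determined by at most one placement, the fill is
consistent for any glider shape, and every complete placement satisfies the
constraint exactly.  This realises the maximum-entropy ensemble with the
prescribed correlation: all statistics of lower order vanish on average
(verified by Monte-Carlo in the test suite at 10,000 textures, 4-SE bands).

Exact glider coordinates for the named classes are not published; the
defaults are the natural representatives with the right order and saliency
structure — 2×2 block for even/odd, L-triangle `{(0,0),(0,1),(1,0)}` with
parity +1 (white) / −1 (black), wye `{(0,0),(0,2),(1,1),(2,1)}`, foot
`{(0,0),(0,1),(0,2),(1,0)}` — and any published variant can be substituted
through `GliderSpec`.

Stimuli are blurred with a 2-D Gaussian (σ = 2 checks, reflect padding to
avoid border luminance gradients) and mapped affinely from ±1 to [0, 1].
Blur before remapping and remapping `(x+1)/2` are assumptions; both are
affine so they only fix the input scale.  Oriented probes replicate 16
binary values along y and rotate by one of 18 angles (10° spacing, bilinear
resampling).  Moving probes crop a 16×16 window from an 80×80 blurred-noise
canvas — large enough that at the fastest translation speed (16 checks per
40 ms bin) consecutive windows are disjoint, so speed 16 is not aliased to
speed 0.  The trajectory is centred (`(t−2)·speed`), rotations resample
bilinearly about the window centre with mid-grey fill.  The rotation speed
grid has the ten values 0–128°/bin.

## Surrogate neurons

The recordings the original analyses used are not deposited, so the package
defines an explicit generative model with the minimal structure the
downstream analyses need.  For neuron *n* and texture *x*:

    rate(t) = r0 · k(t) · max(0, 1 + Σ_c g_c ψ_c(x)),
    k(t)    = a·exp(−(t−1)/τ) + (1−a),        t = 1…5 (40 ms bins)
    ψ_c(x)  = (1−s)·[class(x)=c] + s·p_c·ĝ_c(x | rf window)

with counts Poisson(rate·0.04 s).  `ĝ_c` is the empirical glider statistic
of class *c* inside an 8×8 receptive-field window at a per-neuron random
position, and `p_c` the class parity, so ψ_c = 1 exactly on textures of
class *c* and averages 0 on random textures.  The window statistic creates
within-class response variance (consistency < 1, as in cortex); it also
implies that an even-preferring population responds *below* baseline to odd
textures (ĝ_even = −1 on odd), i.e. even preference and odd suppression are
two sides of one coin.

Population defaults (frozen): gain scale 0.40 in V2 supragranular with
even-gain mean +0.45; scales 0.06–0.15 elsewhere; non-salient classes (wye,
foot) at 0.25× the scale; baseline rates lognormal around 20 spikes/s;
transient fraction uniform in [0, 1]; decay constant τ uniform in [0.5, 3]
bins; example sensitivity s = 0.35.  With these gains the split-half
consistency of the V2-supragranular population average at 1024
examples/class saturates near 1.0 — comfortably in the high-consistency
regime the analyses require (the tests assert > 0.8), but higher than
cortex, where the class signal is far smaller relative to trial noise.
Weakening the gains tenfold would match the cortical consistency value but
would leave too little class signal for desk-scale network training to
demonstrate anything; the gains are frozen as stated and this mismatch is
a known realism limit of the surrogate.  Normalization of target patterns
subtracts
the global minimum rate and divides by the range, so targets span [0, 1]
with one affine map shared across neurons, conditions and bins
(trial-averaged extremes).

What the surrogate does **not** emulate: spike-time structure within bins,
adaptation across trials, the initial 40 ms descending transient, laminar
differences in temporal kernels, and any retinotopic structure beyond the
single receptive-field window.  Results on surrogate data therefore
establish that the pipeline recovers the properties *built into the
generator*, not properties of cortex.

## LN baseline

Spike-triggered moments are rate-weighted stimulus means/covariances.
Filters are selected greedily in whitened coordinates (Cholesky whitening
of the raw covariance, ridge 1e−6·trace/d on the diagonal) to maximise the
Gaussian KL divergence between spike-triggered and raw ensembles; the
candidate pool is the whitened-STC eigenvectors plus the whitened STA.
Information increments are non-increasing up to the orthogonalization of
the candidate pool (tested at 1e−3).  Nonlinearities divide the
rate-weighted by the raw histogram of the filter projection over ±4 SD
(25 equal-width bins — the bin count is not published), which equals the
mean rate conditioned on the binned projection; empty bins are filled by
linear interpolation and out-of-range projections clamp to the edge bins.
Prediction sums the per-filter nonlinearity outputs (separability
assumption).  Tuning performance is the correlation of class-mean tuning
curves; Spearman is the default for the LN model and Pearson for the
recurrent model, matching the two conventions used for each.

## Recurrent network

Four layers: 256 inputs (one per check), two hidden layers fully connected
feedforward with all-to-all within-layer recurrence, feedforward outputs.
Every unit is logistic: y = σ(Σ w·input + b).  At step t a hidden layer
receives the current feedforward drive and its own outputs from step t−1;
state is reset to zero (output coding) between trials.  Outputs are sigmoid
units, matching the uniform unit equation and the [0, 1] targets.
Initialization is Nguyen–Widrow: each unit's combined incoming weight
vector (feedforward + recurrent) is rescaled to 0.7·n^(1/fan_in) and biases
are spread evenly over the same range.  The full-scale architecture
(256→100→100→123) has 68,223 trainable parameters.

Training presents one uniformly drawn pattern per epoch, computes the
summed squared error of the five output steps, and backpropagates the exact
gradient through the unrolled network (verified against central finite
differences for every weight group including both recurrent matrices).
The optimiser is stochastic gradient descent with optional classical
momentum and gradient-norm clipping at 10 (a divergence guard; disable by
setting `clip_norm=None`).  The original toolbox's training
hyperparameters are not recoverable; they are free configuration here.
The package defaults for the scaled experiments are learning rate 0.02 and
momentum 0.95: with single-pattern updates the class-discriminative
gradient component is orders of magnitude smaller than per-example
gradient noise, and momentum (averaging ≈1/(1−m) consecutive pattern
gradients) is what lets a desk-scale network find the class rule rather
than memorize the training examples.  A numba-compiled inner loop
implements exactly the same arithmetic as the numpy reference path (their
equality is asserted in the tests); the numpy path remains the reference
for gradient checks and for sequence (non-static) inputs.

### Scaled desk conditions

The published experiment used 100+100 hidden units, 1024 examples per
class and five million epochs.  The package's scaled conditions — chosen
as the smallest configuration in which the qualitative phenomena are
reproducible and used throughout the tests and the acceptance script —
are 30+30 hidden units, 200 training examples per class, two million
epochs per training, 1000 fresh test examples per class for held-out
tuning, 10,000 probe examples per condition for the selectivity tables
(see *Probing and indices* for why), and three replicate trainings per
question.

Two phenomena behave differently at this scale, and the acceptance script
reports whatever values are actually attained:

* **Held-out tuning.**  The even-class preference is learned and
  generalizes (the even–random output gap on fresh textures grows steadily
  through training), but the target's strong *odd suppression* is not
  recovered.  Even-vs-odd after σ=2 blur is a *signed* fourth-order
  distinction; unsigned "structure" features — the ones a small network
  finds first — respond to both classes alike.  This caps the scaled
  held-out tuning-curve correlation well below the full-scale value, and
  neither more epochs, other learning rates/momenta, more examples per
  class, nor doubling the hidden layers changed the plateau in our runs.
* **Form–motion association.**  The correlation between even-texture
  selectivity and translational speed selectivity across first-layer units
  emerges in many trainings but its *sign* varies from seed to seed at
  this scale: an even detector can rely on recurrent build-up under static
  input (which moving noise disrupts, giving a negative speed index) or on
  transient drive (positive), and which solution gradient descent finds is
  seed-dependent with 30-unit layers.  When the link is present it
  collapses for that specific pair under retraining on swapped
  (black-triangle ↔ even) targets.  The *blanket* version of the control claim — that every
  texture-index × motion-index correlation is weak in the swapped network
  — does not hold with 30-unit layers: with so few units the selectivity
  indices share global gain modes and some pair is always strongly
  correlated.  This appears to be a small-population statistic artifact
  rather than a property of the computation; establishing the blanket
  claim would need the full-scale network.

## Probing and indices

A unit's response to a condition is its sigmoid output averaged over the
five time steps and over the condition's examples.  TTI is the absolute
Michelson contrast |(x−r)/(x+r)|; TSI the signed difference x−r; OSI the
largest-magnitude signed deviation of the 18 orientation responses from
their grand mean; SSIt/SSIr the largest-magnitude signed deviation of any
speed from the stationary condition; DSIt/DSIr the largest
across-direction response range at the preferred or anti-preferred speed
(the "largest difference between directions" is read as the range; ties in
preferred speed break toward the lower speed).  All motion conditions of
one probe share one set of noise canvases so that condition contrasts are
not confounded by canvas sampling noise, and all hidden layers share one
forward pass per probe stimulus (`selectivity_tables`).

Probe ensemble size matters more than it may appear: because probe noise is
shared across units, it does not average out in *cross-unit* statistics —
at 1,000 examples per condition the correlation between two selectivity
indices across 30 units can swing by ±0.7 between probe seeds.  The
acceptance analyses therefore probe with 10,000 examples per condition,
where this jitter drops to roughly ±0.15; smaller counts remain available
for interactive use.

## Population analyses

Dynamics PCA stacks max-normalized five-point time courses of hidden units
and neurons (neural courses advanced by their 40 ms onset delay; hidden
units have no afferent delay), mean-centres the time points, and reports
variance fractions and PC1/PC2 projections.  Centering is an assumption
and is fixed here.  Hull overlap is exact polygon clipping (area of
intersection over the area of the first hull).  Ridge similarity
standardizes source unit responses, fits each target neuron with an
unpenalized-intercept ridge solution (λ = 0.2), and averages the Pearson
correlation between fit and target over neurons; standardization makes the
penalty scale-meaningful.  The counterfactual control exchanges the target
curves of the black-triangle and even classes and retrains; a form–motion
correlation that survives this swap would be an artifact of the
architecture rather than a consequence of the trained response structure.

## Determinism

Every stimulus, surrogate draw and training run derives from one master
seed through named `SeedSequence` streams; the same configuration
reproduces reports bit-for-bit.  Per-trial surrogate counts are a pure
function of (neuron id, texture seed, repeat seed).
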