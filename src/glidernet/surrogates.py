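"""Surrogate V1/V2 neurons: a generative stand-in for cortical recordings.

The electrophysiological recordings that motivate this package are not
publicly deposited, so every analysis here runs on a *surrogate population*:
an explicit generative model of binned spike counts with the structural
features the downstream analyses rely on --

* class-selective gain (strongest, and even-preferring on average, in the
  "V2 supragranular" subpopulation),
* per-example response variability through local glider statistics inside a
  per-neuron receptive-field window,
* diverse transient/sustained temporal kernels, and
* Poisson count noise.

For a neuron with baseline rate :math:`r_0`, temporal kernel
:math:`k(t) = a e^{-(t-1)/\\tau} + (1-a)` over the five 40 ms bins, and
class gains :math:`g_c`, the expected rate to a texture is

.. math:: r(t) = r_0 \\, k(t) \\, \\max(0,\\; 1 + \\sum_c g_c \\psi_c),

where :math:`\\psi_c` mixes the class label with the texture's own local
glider statistic, :math:`\\psi_c = (1-s)\\,[\\text{class}=c] + s\\,p_c
\\hat g_c(\\text{rf window})` with :math:`p_c` the class parity (so that
:math:`\\psi_c = 1` exactly on textures of class *c* and averages 0 on random
textures).  Spike counts per bin are Poisson with mean ``rate * 0.04 s``.

Counts are a deterministic function of (neuron, texture seed, repeat seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .textures import (
    CORRELATED_CLASSES,
    GLIDER_LIBRARY,
    GRID_SIZE,
    N_FRAMES,
    BinaryTexture,
    glider_products,
)

__all__ = [
    "SurrogateNeuron",
    "ResponseRecord",
    "TargetPatterns",
    "BIN_SECONDS",
    "expected_rates",
    "simulate_response",
    "simulate_population",
    "make_population",
    "normalize_targets",
    "consistency",
    "population_average",
    "class_mean_targets",
]

BIN_SECONDS = 0.04
DEFAULT_RF_SIZE = 8

# Gain-magnitude scales per (area, layer); V2 supragranular is the strongly
# tuned subpopulation, V1 the weakest.  Frozen defaults of the generator.
GAIN_SCALES: dict[tuple[str, str], float] = {
    ("V1", "supra"): 0.10,
    ("V1", "gran"): 0.06,
    ("V1", "infra"): 0.08,
    ("V2", "supra"): 0.40,
    ("V2", "gran"): 0.15,
    ("V2", "infra"): 0.12,
}
# Mean even-class gain per (area, layer): the V2 supragranular population is
# even-preferring on average; elsewhere gains are zero-mean.
EVEN_GAIN_MEAN: dict[tuple[str, str], float] = {
    ("V1", "supra"): 0.0,
    ("V1", "gran"): 0.0,
    ("V1", "infra"): 0.0,
    ("V2", "supra"): 0.45,
    ("V2", "gran"): 0.05,
    ("V2", "infra"): 0.05,
}
# Non-salient four-point classes (wye, foot) carry much weaker tuning.
NON_SALIENT_FACTOR = 0.25


@dataclass(frozen=True)
class SurrogateNeuron:
    """Generative parameters for one simulated cell."""

    neuron_id: int
    baseline_rate: float  # spikes/s
    class_gains: dict[str, float]  # six non-random classes
    example_sensitivity: float  # weight on local glider stats vs class label
    transient_amp: float  # fraction of the rate that decays
    tau: float  # decay constant, bins
    area: str = "V2"
    layer: str = "supra"
    rf_corner: tuple[int, int] = (4, 4)
    rf_size: int = DEFAULT_RF_SIZE

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if not 0.0 <= self.transient_amp <= 1.0:
            raise ValueError("transient_amp must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def temporal_kernel(self) -> np.ndarray:
        t = np.arange(1, N_FRAMES + 1, dtype=np.float64)
        return self.transient_amp * np.exp(-(t - 1) / self.tau) + (
            1.0 - self.transient_amp
        )


@dataclass(frozen=True)
class ResponseRecord:
    """Spike counts in five 40 ms bins for one (neuron, texture, repeat)."""

    counts: np.ndarray
    neuron_id: int
    texture_id: int
    repeat_index: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_FRAMES,) or (c < 0).any() or not np.issubdtype(
            c.dtype, np.integer
        ):
            raise ValueError("counts must be five non-negative integers")


@dataclass(frozen=True)
class TargetPatterns:
    """Normalized firing rates in [0, 1] with the shared affine constants."""

    values: np.ndarray  # (..., n_bins), global min 0 and max 1
    rate_min: float
    rate_max: float


def _class_feature(
    neuron: SurrogateNeuron, grid: np.ndarray, class_name: str
) -> np.ndarray:
    """psi_c for every texture in ``grid`` (stacked) for one class c."""
    grids = np.asarray(grid)
    if grids.ndim == 2:
        grids = grids[None]
    r0, c0 = neuron.rf_corner
    window = grids[:, r0 : r0 + neuron.rf_size, c0 : c0 + neuron.rf_size]
    s = neuron.example_sensitivity
    psi = np.zeros((grids.shape[0], len(CORRELATED_CLASSES)))
    for k, c in enumerate(CORRELATED_CLASSES):
        spec = GLIDER_LIBRARY[c]
        stat = glider_products(window, spec) * spec.parity
        indicator = 1.0 if class_name == c else 0.0
        psi[:, k] = (1.0 - s) * indicator + s * stat
    return psi


def expected_rates(
    neuron: SurrogateNeuron,
    texture: BinaryTexture | np.ndarray,
    class_name: str | None = None,
) -> np.ndarray:
    """Closed-form expected rate (spikes/s) per bin; shape (n, 5) or (5,)."""
    if isinstance(texture, BinaryTexture):
        grids = texture.grid[None]
        class_name = texture.class_name
        squeeze = True
    else:
        grids = np.asarray(texture)
        squeeze = grids.ndim == 2
        if squeeze:
            grids = grids[None]
        if class_name is None:
            raise ValueError("class_name is required for raw grids")
    psi = _class_feature(neuron, grids, class_name)
    gains = np.array([neuron.class_gains.get(c, 0.0) for c in CORRELATED_CLASSES])
    drive = np.maximum(0.0, 1.0 + psi @ gains)
    rates = neuron.baseline_rate * drive[:, None] * neuron.temporal_kernel()[None, :]
    return rates[0] if squeeze else rates


def _response_rng(
    neuron_id: int, texture_seed: int, repeat_seed: int
) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(neuron_id) % 2**31, int(texture_seed) % 2**31, int(repeat_seed) % 2**31]
        )
    )


def simulate_response(
    neuron: SurrogateNeuron, texture: BinaryTexture, repeat_seed: int
) -> ResponseRecord:
    """Draw Poisson counts for one trial; deterministic in its arguments."""
    rates = expected_rates(neuron, texture)
    rng = _response_rng(neuron.neuron_id, texture.seed, repeat_seed)
    counts = rng.poisson(rates * BIN_SECONDS).astype(np.int64)
    return ResponseRecord(
        counts=counts,
        neuron_id=neuron.neuron_id,
        texture_id=texture.seed,
        repeat_index=int(repeat_seed),
    )


def simulate_population(
    neurons: list[SurrogateNeuron],
    grids_by_class: dict[str, np.ndarray],
    n_repeats: int = 2,
    seed: int = 0,
    poisson: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Simulate the full recording block.

    Returns ``(responses, class_names)`` where ``responses`` has shape
    ``(n_neurons, n_classes, n_examples, n_repeats, 5)`` and holds spike
    counts (or expected counts if ``poisson=False``).  All classes must have
    the same number of examples.
    """
    class_names = list(grids_by_class)
    n_examples = {g.shape[0] for g in grids_by_class.values()}
    if len(n_examples) != 1:
        raise ValueError("all classes must contain the same number of examples")
    n_ex = n_examples.pop()
    out = np.empty(
        (len(neurons), len(class_names), n_ex, n_repeats, N_FRAMES), dtype=np.float64
    )
    rng = np.random.default_rng(seed)
    for i, neuron in enumerate(neurons):
        for j, cname in enumerate(class_names):
            rates = expected_rates(neuron, grids_by_class[cname], cname)  # (n_ex, 5)
            mean_counts = rates * BIN_SECONDS
            if poisson:
                out[i, j] = rng.poisson(
                    np.broadcast_to(mean_counts[:, None, :], (n_ex, n_repeats, N_FRAMES))
                )
            else:
                out[i, j] = mean_counts[:, None, :]
    return out, class_names


def make_population(
    n_per_area_layer: dict[tuple[str, str], int],
    seed: int = 0,
    example_sensitivity: float = 0.35,
) -> list[SurrogateNeuron]:
    """Draw a surrogate population with area/layer-dependent tuning scales.

    Gain magnitudes are normal with scale :data:`GAIN_SCALES` (largest in V2
    supragranular, smallest in V1); the even-class gain has a positive mean
    in V2 supragranular so that its population average is even-preferring.
    Temporal kernels span transient (``transient_amp`` near 1), sustained
    (near 0) and mixed dynamics.  Same seed, same population.
    """
    rng = np.random.default_rng(seed)
    neurons: list[SurrogateNeuron] = []
    nid = 0
    for (area, layer), count in n_per_area_layer.items():
        if count < 0:
            raise ValueError("neuron counts must be non-negative")
        if (area, layer) not in GAIN_SCALES:
            raise KeyError(f"unknown area/layer {(area, layer)!r}")
        scale = GAIN_SCALES[(area, layer)]
        even_mu = EVEN_GAIN_MEAN[(area, layer)]
        for _ in range(count):
            gains = {}
            for c in CORRELATED_CLASSES:
                s = scale * (NON_SALIENT_FACTOR if c in ("wye", "foot") else 1.0)
                mu = even_mu if c == "even" else 0.0
                gains[c] = float(rng.normal(mu, s))
            corner = tuple(rng.integers(0, GRID_SIZE - DEFAULT_RF_SIZE + 1, size=2))
            neurons.append(
                SurrogateNeuron(
                    neuron_id=nid,
                    baseline_rate=float(rng.lognormal(np.log(20.0), 0.4)),
                    class_gains=gains,
                    example_sensitivity=example_sensitivity,
                    transient_amp=float(rng.uniform(0.0, 1.0)),
                    tau=float(rng.uniform(0.5, 3.0)),
                    area=area,
                    layer=layer,
                    rf_corner=(int(corner[0]), int(corner[1])),
                )
            )
            nid += 1
    return neurons


def normalize_targets(rates: np.ndarray) -> TargetPatterns:
    """Map firing rates to [0, 1] with one affine transform shared by all.

    The global minimum over all bins, conditions and neurons maps to 0 and
    the global maximum to 1; rank orders within any neuron are untouched.
    """
    rates = np.asarray(rates, dtype=np.float64)
    lo, hi = float(rates.min()), float(rates.max())
    if hi - lo <= 0:
        raise ValueError("degenerate normalization: all target rates are equal")
    return TargetPatterns(values=(rates - lo) / (hi - lo), rate_min=lo, rate_max=hi)


def consistency(
    per_example_responses: np.ndarray,
    n_splits: int = 5000,
    split_seed: int = 0,
) -> float:
    """Mean split-half correlation of the class tuning curve.

    ``per_example_responses`` has shape ``(n_classes, n_examples, ...)``;
    trailing axes (repeats, bins) are averaged first.  For each of
    ``n_splits`` random 50/50 splits of the examples, the per-class mean
    response is computed on each half and the Pearson correlation between
    the two tuning curves recorded; the mean over splits is returned.
    """
    resp = np.asarray(per_example_responses, dtype=np.float64)
    if resp.ndim > 2:
        resp = resp.reshape(resp.shape[0], resp.shape[1], -1).mean(axis=2)
    n_classes, n_ex = resp.shape
    if n_ex < 2:
        raise ValueError("need at least 2 examples per class")
    half = n_ex // 2
    rng = np.random.default_rng(split_seed)
    rs = np.empty(n_splits)
    for k in range(n_splits):
        perm = rng.permutation(n_ex)
        a = resp[:, perm[:half]].mean(axis=1)
        b = resp[:, perm[half:]].mean(axis=1)
        with np.errstate(invalid="ignore"):
            rs[k] = np.corrcoef(a, b)[0, 1]
    return float(np.nanmean(rs))


def population_average(
    responses: np.ndarray, subset: np.ndarray | list[int] | None = None
) -> TargetPatterns:
    """Normalized mean response of a neuron subset, per condition and bin.

    ``responses`` has shape ``(n_neurons, ..., n_bins)``; the mean over the
    subset is normalized with :func:`normalize_targets`.
    """
    responses = np.asarray(responses, dtype=np.float64)
    if subset is not None:
        subset = np.asarray(subset)
        if subset.size == 0:
            raise ValueError("empty neuron subset")
        responses = responses[subset]
    if responses.shape[0] == 0:
        raise ValueError("empty neuron subset")
    return normalize_targets(responses.mean(axis=0))


def class_mean_targets(
    responses: np.ndarray, subset: np.ndarray | list[int] | None = None
) -> TargetPatterns:
    """Class-mean population-average target curves for single-output training.

    ``responses`` has shape ``(n_neurons, n_classes, n_examples, n_repeats,
    n_bins)``.  Returns normalized targets of shape ``(n_classes, n_bins)``:
    the population- and example-mean time course per class.  During training
    every example of a class shares its class's curve as the target, so the
    network is asked for the tuning *rule*, not example-specific replay.
    """
    responses = np.asarray(responses, dtype=np.float64)
    if subset is not None:
        responses = responses[np.asarray(subset)]
    if responses.shape[0] == 0:
        raise ValueError("empty neuron subset")
    class_curves = responses.mean(axis=(0, 2, 3))  # (n_classes, n_bins)
    return normalize_targets(class_curves)
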