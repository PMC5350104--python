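"""Simulated tuning experiments and selectivity indices.

Trained network units (or surrogate neurons) are probed with large stimulus
ensembles: static MSCT textures, static oriented noise, and translating or
rotating noise.  The response of a unit to a condition is its sigmoid output
averaged over the five time steps and over the examples of that condition;
all selectivity indices are computed from these averaged responses.

Indices
-------
TTI
    texture tuning index, ``|(x - r) / (x + r)|`` -- the absolute Michelson
    contrast between the mean response to a class (x) and to random
    textures (r); in [0, 1] for non-negative responses.
TSI
    signed texture selectivity, ``x - r``.
OSI
    the deviation of any of the 18 orientation responses from the grand
    mean with the largest magnitude, sign preserved.
SSIt / SSIr
    the deviation of any translation/rotation speed response from the
    stationary response with the largest magnitude, sign preserved.
DSIt / DSIr
    at the preferred (largest across-direction mean) and anti-preferred
    speed, the largest range across directions; ties in the preferred speed
    break toward the lower speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import textures as tx
from .textures import (
    CLASS_NAMES,
    CORRELATED_CLASSES,
    GRID_SIZE,
    N_FRAMES,
    ORIENTATION_ANGLES,
    ROTATION_DIRECTIONS,
    ROTATION_SPEEDS,
    TRANSLATION_DIRECTIONS,
    TRANSLATION_SPEEDS,
)

__all__ = [
    "TuningCurve",
    "tuning_curve",
    "tti",
    "tsi",
    "osi",
    "ssi",
    "dsi",
    "network_responder",
    "surrogate_responder",
    "probe_textures",
    "probe_orientation",
    "probe_translation",
    "probe_rotation",
    "selectivity_table",
    "selectivity_tables",
]


@dataclass
class TuningCurve:
    """Mean response per condition with standard errors over examples."""

    labels: list
    means: np.ndarray
    sems: np.ndarray
    n_examples: int


def tuning_curve(responses_by_condition: dict) -> TuningCurve:
    """Time-and-example mean response per condition with standard error.

    Each value of ``responses_by_condition`` is an array of per-example
    (already time-averaged) responses; conditions may be probed with
    different example counts, the reported ``n_examples`` is the minimum.
    """
    labels = list(responses_by_condition)
    if not labels:
        raise ValueError("no conditions")
    means, sems, counts = [], [], []
    for lab in labels:
        r = np.asarray(responses_by_condition[lab], dtype=np.float64)
        if r.shape[0] == 0:
            raise ValueError(f"condition {lab!r} has no examples")
        means.append(r.mean(axis=0))
        sems.append(r.std(axis=0, ddof=1) / np.sqrt(r.shape[0]) if r.shape[0] > 1 else 0.0)
        counts.append(r.shape[0])
    return TuningCurve(
        labels=labels,
        means=np.asarray(means),
        sems=np.asarray(sems),
        n_examples=int(min(counts)),
    )


# ---------------------------------------------------------------------------
# selectivity indices


def tti(mean_class: float | np.ndarray, mean_random: float | np.ndarray) -> np.ndarray:
    """Absolute Michelson contrast |(x - r) / (x + r)|."""
    x = np.asarray(mean_class, dtype=np.float64)
    r = np.asarray(mean_random, dtype=np.float64)
    denom = x + r
    if np.any(denom == 0):
        raise ZeroDivisionError("TTI undefined: class + random response is zero")
    return np.abs((x - r) / denom)


def tsi(mean_class: float | np.ndarray, mean_random: float | np.ndarray) -> np.ndarray:
    """Signed selectivity x - r."""
    return np.asarray(mean_class, dtype=np.float64) - np.asarray(
        mean_random, dtype=np.float64
    )


def _largest_signed_deviation(deviations: np.ndarray) -> np.ndarray:
    """Per unit, the deviation with the largest magnitude, sign preserved."""
    dev = np.asarray(deviations, dtype=np.float64)
    idx = np.abs(dev).argmax(axis=0)
    return np.take_along_axis(dev, idx[None], axis=0)[0]


def osi(means_by_angle: np.ndarray) -> np.ndarray:
    """Largest signed deviation of any orientation from the grand mean.

    ``means_by_angle`` is (18,) or (18, n_units).
    """
    m = np.atleast_2d(np.asarray(means_by_angle, dtype=np.float64).T).T
    if m.shape[0] != len(ORIENTATION_ANGLES):
        raise ValueError(f"expected {len(ORIENTATION_ANGLES)} orientation conditions")
    out = _largest_signed_deviation(m - m.mean(axis=0, keepdims=True))
    return out if np.asarray(means_by_angle).ndim > 1 else out[0]


def ssi(means_by_speed: np.ndarray, stationary_index: int = 0) -> np.ndarray:
    """Largest signed deviation of any speed from the stationary condition.

    ``means_by_speed`` is (n_speeds,) or (n_speeds, n_units), with the
    stationary (speed 0) condition included at ``stationary_index``.
    """
    m = np.atleast_2d(np.asarray(means_by_speed, dtype=np.float64).T).T
    out = _largest_signed_deviation(m - m[stationary_index][None])
    return out if np.asarray(means_by_speed).ndim > 1 else out[0]


def dsi(means_by_speed_direction: np.ndarray) -> np.ndarray:
    """Direction selectivity from the full speed x direction response grid.

    ``means_by_speed_direction`` is (n_speeds, n_directions) or
    (n_speeds, n_directions, n_units).  The preferred (anti-preferred)
    speed maximises (minimises) the across-direction mean; argmax/argmin
    break ties toward the lower speed.  The index is the largest
    across-direction response range at either of those two speeds.
    """
    m = np.asarray(means_by_speed_direction, dtype=np.float64)
    squeeze = m.ndim == 2
    if squeeze:
        m = m[:, :, None]
    speed_mean = m.mean(axis=1)  # (n_speeds, n_units)
    pref = speed_mean.argmax(axis=0)
    anti = speed_mean.argmin(axis=0)
    ranges = m.max(axis=1) - m.min(axis=1)  # (n_speeds, n_units)
    units = np.arange(m.shape[2])
    out = np.maximum(ranges[pref, units], ranges[anti, units])
    return float(out[0]) if squeeze else out


# ---------------------------------------------------------------------------
# probe experiments


def network_responder(results, layer: str = "H1"):
    """Adapter: a trained network's time-averaged unit responses.

    Returns a callable mapping stimuli -- (B, 256) static patterns or
    (B, 5, 256) sequences -- to (B, n_units) responses.
    """

    def respond(stimuli: np.ndarray) -> np.ndarray:
        if layer.lower() in ("out", "output"):
            return results.predict(stimuli).mean(axis=1)
        return results.hidden_responses(stimuli, layer).mean(axis=1)

    return respond


def surrogate_responder(neurons):
    """Adapter: surrogate neurons' expected time-averaged rates on textures."""
    from .surrogates import expected_rates

    def respond_grids(grids: np.ndarray, class_name: str) -> np.ndarray:
        return np.column_stack(
            [expected_rates(n, grids, class_name).mean(axis=1) for n in neurons]
        )

    return respond_grids


def probe_textures(
    respond,
    n_examples: int = 1000,
    seed: int = 0,
    classes: tuple[str, ...] = CLASS_NAMES,
    sigma: float = tx.DEFAULT_BLUR_SIGMA,
    on_grids: bool = False,
) -> dict[str, np.ndarray]:
    """Per-example responses to fresh MSCT ensembles, by class.

    ``respond`` maps (B, 256) blurred flattened patterns to (B, n_units)
    responses, or, with ``on_grids=True``, maps ``(grids, class_name)`` to
    responses (for surrogate neurons).
    """
    if n_examples < 1:
        raise ValueError("n_examples must be >= 1")
    out = {}
    for c in classes:
        rng = tx.stimulus_seed(seed, f"probe/texture/{c}")
        grids = tx.generate_ensemble(c, n_examples, rng)
        if on_grids:
            out[c] = respond(grids, c)
        else:
            blurred = tx.blur_ensemble(grids, sigma).reshape(n_examples, -1)
            out[c] = respond(blurred)
    return out


def probe_orientation(
    respond,
    n_examples: int = 1000,
    seed: int = 0,
    sigma: float = tx.DEFAULT_BLUR_SIGMA,
) -> np.ndarray:
    """Mean response per orientation angle; (18, n_units)."""
    means = []
    for k, angle in enumerate(ORIENTATION_ANGLES):
        rng = tx.stimulus_seed(seed, "probe/orientation", k)
        frames = np.stack(
            [
                tx.oriented_noise(angle, rng, sigma).frames[0].ravel()
                for _ in range(n_examples)
            ]
        )
        means.append(respond(frames).mean(axis=0))
    return np.asarray(means)


def _bilinear_sample(canvases: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Sample (B, H, W) canvases at shared float coords (2, 16, 16)."""
    size = canvases.shape[1]
    r, c = coords
    r0 = np.clip(np.floor(r).astype(int), 0, size - 2)
    c0 = np.clip(np.floor(c).astype(int), 0, size - 2)
    fr = np.clip(r - r0, 0.0, 1.0)
    fc = np.clip(c - c0, 0.0, 1.0)
    v00 = canvases[:, r0, c0]
    v01 = canvases[:, r0, c0 + 1]
    v10 = canvases[:, r0 + 1, c0]
    v11 = canvases[:, r0 + 1, c0 + 1]
    return (
        v00 * (1 - fr) * (1 - fc)
        + v01 * (1 - fr) * fc
        + v10 * fr * (1 - fc)
        + v11 * fr * fc
    )


def _motion_frames(
    canvases: np.ndarray, kind: str, speed: float, direction: str
) -> np.ndarray:
    """Batched motion sequences from shared canvases; (B, 5, 256)."""
    B = canvases.shape[0]
    size = canvases.shape[1]
    frames = np.empty((B, N_FRAMES, GRID_SIZE, GRID_SIZE))
    for t in range(N_FRAMES):
        step = (t - (N_FRAMES - 1) / 2.0) * speed
        if kind == "translation":
            dr, dc = tx._DIRECTION_VECTORS[direction]
            coords = tx._window_coords(step * dr, step * dc, size)
        else:
            sign = 1.0 if direction == "cw" else -1.0
            coords = tx._rotated_coords(sign * step, size)
        frames[:, t] = _bilinear_sample(canvases, coords)
    return frames.reshape(B, N_FRAMES, GRID_SIZE * GRID_SIZE)


def _probe_motion(
    respond_seq,
    kind: str,
    speeds: tuple[float, ...],
    directions: tuple[str, ...],
    n_examples: int,
    seed: int,
    sigma: float,
) -> np.ndarray:
    rng = tx.stimulus_seed(seed, f"probe/{kind}")
    canvases = np.stack([tx.make_noise_canvas(rng, sigma) for _ in range(n_examples)])
    rows = []
    for speed in speeds:
        row = []
        for direction in directions:
            frames = _motion_frames(canvases, kind, speed, direction)
            row.append(respond_seq(frames).mean(axis=0))
        rows.append(row)
    return np.asarray(rows)  # (n_speeds, n_directions, n_units)


def probe_translation(
    respond_seq,
    n_examples: int = 1000,
    seed: int = 0,
    sigma: float = tx.DEFAULT_BLUR_SIGMA,
) -> np.ndarray:
    """Mean responses over the translation grid; (7 speeds, 4 dirs, n_units).

    All conditions share one set of noise canvases, so condition contrasts
    are not confounded by canvas sampling noise.
    """
    return _probe_motion(
        respond_seq, "translation", TRANSLATION_SPEEDS, TRANSLATION_DIRECTIONS,
        n_examples, seed, sigma,
    )


def probe_rotation(
    respond_seq,
    n_examples: int = 1000,
    seed: int = 0,
    sigma: float = tx.DEFAULT_BLUR_SIGMA,
) -> np.ndarray:
    """Mean responses over the rotation grid; (10 speeds, 2 dirs, n_units)."""
    return _probe_motion(
        respond_seq, "rotation", ROTATION_SPEEDS, ROTATION_DIRECTIONS,
        n_examples, seed, sigma,
    )


def selectivity_tables(
    results,
    layers: tuple[str, ...] = ("H1", "H2"),
    n_examples: int = 1000,
    seed: int = 0,
    include_orientation: bool = True,
) -> dict[str, pd.DataFrame]:
    """Selectivity indices for every unit of the requested hidden layers.

    All layers share one probe stimulus set and one forward pass per
    condition (the forward pass yields every layer's activity anyway), so
    probing both layers costs the same as probing one.  Each table has one
    row per unit with columns ``TSI_<class>``, ``TTI_<class>``, ``OSI``,
    ``SSIt``, ``SSIr``, ``DSIt``, ``DSIr``.
    """
    from .network import forward_batch

    layers = tuple(layers)
    sizes = {"H1": results.params.sizes[1], "H2": results.params.sizes[2]}

    def respond(stimuli: np.ndarray) -> np.ndarray:
        y1, y2, _ = forward_batch(results.params, stimuli)
        parts = {"H1": y1.mean(axis=1), "H2": y2.mean(axis=1)}
        return np.concatenate([parts[l.upper()] for l in layers], axis=1)

    tex = probe_textures(respond, n_examples=n_examples, seed=seed)
    random_mean = tex["random"].mean(axis=0)
    data = {}
    for c in CORRELATED_CLASSES:
        class_mean = tex[c].mean(axis=0)
        data[f"TSI_{c}"] = tsi(class_mean, random_mean)
        data[f"TTI_{c}"] = tti(class_mean, random_mean)
    if include_orientation:
        data["OSI"] = osi(probe_orientation(respond, n_examples=n_examples, seed=seed))
    trans = probe_translation(respond, n_examples=n_examples, seed=seed)
    rot = probe_rotation(respond, n_examples=n_examples, seed=seed)
    data["SSIt"] = ssi(trans.mean(axis=1))
    data["SSIr"] = ssi(rot.mean(axis=1))
    data["DSIt"] = dsi(trans)
    data["DSIr"] = dsi(rot)

    out = {}
    start = 0
    for layer in layers:
        stop = start + sizes[layer.upper()]
        df = pd.DataFrame({k: np.asarray(v)[start:stop] for k, v in data.items()})
        df.index.name = "unit"
        out[layer] = df
        start = stop
    return out


def selectivity_table(
    results,
    layer: str = "H1",
    n_examples: int = 1000,
    seed: int = 0,
    include_orientation: bool = True,
) -> pd.DataFrame:
    """All selectivity indices for every unit of one hidden layer.

    One row per unit with columns ``TSI_<class>``, ``TTI_<class>``, ``OSI``,
    ``SSIt``, ``SSIr``, ``DSIt``, ``DSIr``.
    """
    return selectivity_tables(
        results, (layer,), n_examples=n_examples, seed=seed,
        include_orientation=include_orientation,
    )[layer]
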