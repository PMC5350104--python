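"""Maximum-entropy binary textures with controlled multipoint correlations.

This module synthesises the stimulus families used throughout the package:

* **MSCT textures** (multipoint spatial correlation textures): 16 x 16 binary
  checkerboards in which exactly one third- or fourth-order spatial
  correlation is pinned to +1 or -1 while all lower-order statistics vanish
  on average.  Each class is defined by a *glider* -- a small set of check
  offsets -- together with a target parity for the product of the checks the
  glider covers.  Textures are generated with a Markov recurrence: checks
  that are not determined by any complete glider placement are drawn i.i.d.
  uniform, and the remaining checks are filled in raster order so that every
  complete placement satisfies the parity constraint.  This realises the
  maximum-entropy ensemble with the prescribed correlation.
* **Oriented noise**: one-dimensional binary noise replicated along y and
  rotated to one of 18 angles, used to probe orientation tuning.
* **Moving noise**: a 16 x 16 window translating or rotating over a larger
  blurred-noise canvas, used to probe speed and direction tuning.

Internally checks are coded as -1/+1 so that parity constraints are
multiplicative; stimuli are converted to luminance values in [0, 1] only
after the Gaussian low-pass filter (:func:`lowpass`).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "GliderSpec",
    "BinaryTexture",
    "StimulusSequence",
    "StatReport",
    "GLIDER_LIBRARY",
    "CLASS_NAMES",
    "CORRELATED_CLASSES",
    "TRANSLATION_SPEEDS",
    "ROTATION_SPEEDS",
    "TRANSLATION_DIRECTIONS",
    "ROTATION_DIRECTIONS",
    "ORIENTATION_ANGLES",
    "GRID_SIZE",
    "N_FRAMES",
    "DEFAULT_BLUR_SIGMA",
    "generate_texture",
    "generate_ensemble",
    "lowpass",
    "texture_sequence",
    "oriented_noise",
    "motion_sequence",
    "make_noise_canvas",
    "verify_statistics",
    "stimulus_seed",
]

GRID_SIZE = 16
N_FRAMES = 5
DEFAULT_BLUR_SIGMA = 2.0
CANVAS_SIZE = 80

TRANSLATION_SPEEDS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
ROTATION_SPEEDS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)
TRANSLATION_DIRECTIONS = ("up", "right", "down", "left")
ROTATION_DIRECTIONS = ("cw", "ccw")
ORIENTATION_ANGLES = tuple(float(a) for a in range(0, 180, 10))

# row/col displacement per bin for one check of speed
_DIRECTION_VECTORS = {
    "up": (-1.0, 0.0),
    "down": (1.0, 0.0),
    "right": (0.0, 1.0),
    "left": (0.0, -1.0),
}


@dataclass(frozen=True)
class GliderSpec:
    """One MSCT class: a set of check offsets and a target parity.

    ``offsets`` are (row, col) displacements; the product of the +/-1 checks
    over every complete placement of the glider equals ``parity``.  The
    ``random`` class has no constraint and its offsets/parity are ignored.
    """

    name: str
    offsets: tuple[tuple[int, int], ...]
    parity: int = 1

    def __post_init__(self) -> None:
        offs = tuple(tuple(o) for o in self.offsets)
        object.__setattr__(self, "offsets", offs)
        if self.name != "random":
            if len(set(offs)) != len(offs):
                raise ValueError("glider offsets must be distinct")
            if (0, 0) not in offs:
                raise ValueError("glider must contain the (0, 0) offset")
            if self.parity not in (-1, 1):
                raise ValueError("parity must be +1 or -1")

    @property
    def order(self) -> int:
        return len(self.offsets)


#: The seven texture classes.  The 2 x 2 block defines even/odd; the salient
#: three-point classes use an L-shaped triangle with white (+1) or black (-1)
#: parity; wye and foot are four-point gliders that are not perceptually
#: salient.  Any published variant can be substituted by building a
#: :class:`GliderSpec` with different offsets.
GLIDER_LIBRARY: dict[str, GliderSpec] = {
    "random": GliderSpec("random", ((0, 0),), 1),
    "white_triangle": GliderSpec("white_triangle", ((0, 0), (0, 1), (1, 0)), 1),
    "black_triangle": GliderSpec("black_triangle", ((0, 0), (0, 1), (1, 0)), -1),
    "even": GliderSpec("even", ((0, 0), (0, 1), (1, 0), (1, 1)), 1),
    "odd": GliderSpec("odd", ((0, 0), (0, 1), (1, 0), (1, 1)), -1),
    "wye": GliderSpec("wye", ((0, 0), (0, 2), (1, 1), (2, 1)), 1),
    "foot": GliderSpec("foot", ((0, 0), (0, 1), (0, 2), (1, 0)), 1),
}

CLASS_NAMES = tuple(GLIDER_LIBRARY)
CORRELATED_CLASSES = tuple(n for n in CLASS_NAMES if n != "random")


@dataclass(frozen=True)
class BinaryTexture:
    """A 16 x 16 array of -1/+1 checks with its generating class and seed."""

    grid: np.ndarray
    class_name: str
    seed: int

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=np.int8)
        if not np.isin(g, (-1, 1)).all():
            raise ValueError("texture checks must be -1 or +1")
        object.__setattr__(self, "grid", g)


@dataclass(frozen=True)
class StimulusSequence:
    """Five 40 ms frames of 16 x 16 luminance values in [0, 1]."""

    frames: np.ndarray
    kind: str  # static | translation | rotation | oriented
    speed: float = 0.0
    direction: str | None = None
    angle: float | None = None
    blur_sigma: float = DEFAULT_BLUR_SIGMA

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=np.float64)
        if f.shape != (N_FRAMES, GRID_SIZE, GRID_SIZE):
            raise ValueError(f"frames must be {(N_FRAMES, GRID_SIZE, GRID_SIZE)}")
        if f.min() < -1e-9 or f.max() > 1 + 1e-9:
            raise ValueError("frame values must lie in [0, 1]")
        object.__setattr__(self, "frames", f)


@dataclass
class StatReport:
    """Empirical first-, second- and glider-order statistics of an ensemble."""

    mean_stat: float
    mean_se: float
    pair_stats: dict[tuple[int, int], tuple[float, float]]
    glider_stats: dict[str, tuple[float, float]]
    n_textures: int
    class_name: str | None = None


def _resolve_spec(spec: GliderSpec | str) -> GliderSpec:
    if isinstance(spec, GliderSpec):
        return spec
    try:
        return GLIDER_LIBRARY[spec]
    except KeyError:
        raise KeyError(
            f"unknown texture class {spec!r}; known classes: {CLASS_NAMES}"
        ) from None


def stimulus_seed(master_seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Derive a per-stimulus generator from a master seed.

    Streams are named (e.g. ``"train/even"``); the (master, stream, index)
    triple feeds a :class:`numpy.random.SeedSequence`, so every stimulus in a
    pipeline is reachable from the master seed and independent of the order
    in which stimuli are generated.
    """
    digest = zlib.crc32(stream.encode("utf-8")) % (2**31)
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(digest), int(index)])
    )


def generate_ensemble(
    spec: GliderSpec | str,
    n: int,
    seed: int | np.random.Generator,
    size: int = GRID_SIZE,
) -> np.ndarray:
    """Generate ``n`` textures of one class as an ``(n, size, size)`` int8 array.

    The Markov recurrence fills checks in raster order.  A check is
    *determined* when it is the raster-last member of a complete glider
    placement; its value is then forced by the parity constraint.  All other
    checks are drawn i.i.d. uniform from {-1, +1}.  Because the raster-last
    offset of the glider is unique, each check is determined by at most one
    placement and the fill is consistent: every complete placement satisfies
    the constraint exactly.
    """
    spec = _resolve_spec(spec)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if spec.name == "random":
        return rng.choice(np.array([-1, 1], dtype=np.int8), size=(n, size, size))

    offs = np.array(spec.offsets, dtype=np.int64)
    # raster-last offset: the member filled last in raster order
    last_idx = np.lexsort((offs[:, 1], offs[:, 0]))[-1]
    last = offs[last_idx]
    others = np.delete(offs, last_idx, axis=0)
    rmin, cmin = offs.min(axis=0)
    rmax, cmax = offs.max(axis=0)

    grids = np.empty((n, size, size), dtype=np.int8)
    pm1 = np.array([-1, 1], dtype=np.int8)
    for i in range(size):
        for j in range(size):
            ar, ac = i - last[0], j - last[1]
            anchored = (
                ar + rmin >= 0 and ar + rmax < size and ac + cmin >= 0 and ac + cmax < size
            )
            if anchored:
                prod = np.full(n, spec.parity, dtype=np.int8)
                for dr, dc in others:
                    prod *= grids[:, ar + dr, ac + dc]
                grids[:, i, j] = prod
            else:
                grids[:, i, j] = rng.choice(pm1, size=n)
    return grids


def generate_texture(
    spec: GliderSpec | str, seed: int, size: int = GRID_SIZE
) -> BinaryTexture:
    """Generate a single texture; same (spec, seed) reproduces it exactly."""
    spec = _resolve_spec(spec)
    grid = generate_ensemble(spec, 1, seed, size=size)[0]
    return BinaryTexture(grid=grid, class_name=spec.name, seed=int(seed))


def lowpass(
    texture: BinaryTexture | np.ndarray,
    sigma: float = DEFAULT_BLUR_SIGMA,
    remap: bool = True,
) -> np.ndarray:
    """Gaussian low-pass filter of a -1/+1 grid, remapped to luminance [0, 1].

    Reflect padding at the border avoids the artifactual luminance gradient
    that zero padding would introduce.  With ``remap=False`` the smoothed
    grid is returned in the +/-1 coding (useful for linearity checks).
    """
    if sigma <= 0:
        raise ValueError("blur sigma must be positive")
    grid = texture.grid if isinstance(texture, BinaryTexture) else np.asarray(texture)
    smoothed = ndimage.gaussian_filter(grid.astype(np.float64), sigma, mode="reflect")
    if not remap:
        return smoothed
    return np.clip((smoothed + 1.0) / 2.0, 0.0, 1.0)


def blur_ensemble(grids: np.ndarray, sigma: float = DEFAULT_BLUR_SIGMA) -> np.ndarray:
    """Blur and remap a stack of textures; returns (n, size, size) in [0, 1]."""
    if sigma <= 0:
        raise ValueError("blur sigma must be positive")
    smoothed = ndimage.gaussian_filter(
        np.asarray(grids, dtype=np.float64), (0, sigma, sigma), mode="reflect"
    )
    return np.clip((smoothed + 1.0) / 2.0, 0.0, 1.0)


def texture_sequence(
    texture: BinaryTexture | np.ndarray, sigma: float = DEFAULT_BLUR_SIGMA
) -> StimulusSequence:
    """A static five-frame sequence: the blurred texture repeated per bin."""
    frame = lowpass(texture, sigma)
    frames = np.broadcast_to(frame, (N_FRAMES,) + frame.shape).copy()
    return StimulusSequence(frames=frames, kind="static", blur_sigma=sigma)


def oriented_noise(
    angle: float,
    seed: int | np.random.Generator,
    sigma: float = DEFAULT_BLUR_SIGMA,
) -> StimulusSequence:
    """Static oriented-noise probe.

    16 binary values are replicated along y (so at 0 degrees every column is
    constant), the pattern is rotated about the grid centre by ``angle``
    (bilinear resampling, mid-grey fill), blurred, and repeated over the five
    frames.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.choice(np.array([-1.0, 1.0]), size=GRID_SIZE)
    pattern = np.tile(noise, (GRID_SIZE, 1))  # pattern[y, x] = noise[x]
    if angle % 360 != 0:
        pattern = ndimage.rotate(
            pattern, angle, reshape=False, order=1, mode="constant", cval=0.0
        )
    frame = np.clip(
        (ndimage.gaussian_filter(pattern, sigma, mode="reflect") + 1.0) / 2.0, 0.0, 1.0
    )
    frames = np.broadcast_to(frame, (N_FRAMES, GRID_SIZE, GRID_SIZE)).copy()
    return StimulusSequence(
        frames=frames, kind="oriented", angle=float(angle), blur_sigma=sigma
    )


def make_noise_canvas(
    seed: int | np.random.Generator,
    sigma: float = DEFAULT_BLUR_SIGMA,
    size: int = CANVAS_SIZE,
) -> np.ndarray:
    """An 80 x 80 blurred binary-noise canvas in [0, 1] for motion probes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = rng.choice(np.array([-1.0, 1.0]), size=(size, size))
    return np.clip(
        (ndimage.gaussian_filter(grid, sigma, mode="reflect") + 1.0) / 2.0, 0.0, 1.0
    )


def _window_coords(offset_r: float, offset_c: float, size: int) -> np.ndarray:
    base = (size - GRID_SIZE) / 2.0
    rows = base + offset_r + np.arange(GRID_SIZE)
    cols = base + offset_c + np.arange(GRID_SIZE)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([rr, cc])


def _rotated_coords(angle_deg: float, size: int) -> np.ndarray:
    base = (size - GRID_SIZE) / 2.0
    centre = (size - 1) / 2.0
    rows = base + np.arange(GRID_SIZE) - centre
    cols = base + np.arange(GRID_SIZE) - centre
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    th = np.deg2rad(angle_deg)
    rot_r = np.cos(th) * rr - np.sin(th) * cc + centre
    rot_c = np.sin(th) * rr + np.cos(th) * cc + centre
    return np.stack([rot_r, rot_c])


def motion_sequence(
    kind: str,
    speed: float,
    direction: str,
    seed: int | np.random.Generator | None = None,
    sigma: float = DEFAULT_BLUR_SIGMA,
    canvas: np.ndarray | None = None,
) -> StimulusSequence:
    """Translating or rotating noise seen through a centred 16 x 16 window.

    The window samples a pre-blurred noise canvas (bilinear interpolation,
    out-of-canvas fill mid-grey).  Frame t (t = 0..4) is displaced by
    ``(t - 2) * speed`` checks (translation) or rotated by ``(t - 2) * speed``
    degrees (rotation), so the trajectory is centred on the canvas and at the
    fastest translation speed (16 checks/bin) consecutive windows sample
    disjoint canvas regions.  Speed 0 yields five identical frames.
    """
    if kind == "translation":
        if speed not in TRANSLATION_SPEEDS:
            raise ValueError(f"translation speed must be one of {TRANSLATION_SPEEDS}")
        if direction not in TRANSLATION_DIRECTIONS:
            raise ValueError(f"direction must be one of {TRANSLATION_DIRECTIONS}")
    elif kind == "rotation":
        if speed not in ROTATION_SPEEDS:
            raise ValueError(f"rotation speed must be one of {ROTATION_SPEEDS}")
        if direction not in ROTATION_DIRECTIONS:
            raise ValueError(f"direction must be one of {ROTATION_DIRECTIONS}")
    else:
        raise ValueError("kind must be 'translation' or 'rotation'")

    if canvas is None:
        if seed is None:
            raise ValueError("either a seed or a canvas is required")
        canvas = make_noise_canvas(seed, sigma)
    canvas = np.asarray(canvas, dtype=np.float64)
    size = canvas.shape[0]

    frames = np.empty((N_FRAMES, GRID_SIZE, GRID_SIZE))
    for t in range(N_FRAMES):
        step = (t - (N_FRAMES - 1) / 2.0) * speed
        if kind == "translation":
            dr, dc = _DIRECTION_VECTORS[direction]
            coords = _window_coords(step * dr, step * dc, size)
        else:
            sign = 1.0 if direction == "cw" else -1.0
            coords = _rotated_coords(sign * step, size)
        frames[t] = ndimage.map_coordinates(
            canvas, coords, order=1, mode="constant", cval=0.5
        )
    return StimulusSequence(
        frames=np.clip(frames, 0.0, 1.0),
        kind=kind,
        speed=float(speed),
        direction=direction,
        blur_sigma=sigma,
    )


_DEFAULT_PAIR_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1), (0, 2), (2, 0))


def glider_products(grids: np.ndarray, spec: GliderSpec | str) -> np.ndarray:
    """Per-texture mean glider product over all complete placements."""
    spec = _resolve_spec(spec)
    grids = np.asarray(grids)
    if grids.ndim == 2:
        grids = grids[None]
    offs = np.array(spec.offsets)
    rmin, cmin = offs.min(axis=0)
    rmax, cmax = offs.max(axis=0)
    h = grids.shape[1] - (rmax - rmin)
    w = grids.shape[2] - (cmax - cmin)
    prod = np.ones((grids.shape[0], h, w), dtype=np.float64)
    for dr, dc in offs - [rmin, cmin]:
        prod *= grids[:, dr : dr + h, dc : dc + w]
    return prod.reshape(grids.shape[0], -1).mean(axis=1)


def pair_correlation(grids: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Per-texture two-point correlation at a (row, col) offset."""
    grids = np.asarray(grids, dtype=np.float64)
    dr, dc = offset
    h, w = grids.shape[1] - abs(dr), grids.shape[2] - abs(dc)
    a = grids[:, max(dr, 0) : max(dr, 0) + h, max(dc, 0) : max(dc, 0) + w]
    b = grids[:, max(-dr, 0) : max(-dr, 0) + h, max(-dc, 0) : max(-dc, 0) + w]
    return (a * b).reshape(grids.shape[0], -1).mean(axis=1)


def verify_statistics(
    textures: np.ndarray | list[BinaryTexture],
    specs: list[GliderSpec | str] | None = None,
    pair_offsets: tuple[tuple[int, int], ...] = _DEFAULT_PAIR_OFFSETS,
) -> StatReport:
    """Empirical statistics of a single-class texture ensemble.

    Returns the ensemble mean check value, two-point correlations for a set
    of offsets, and the mean glider product for each requested glider, each
    with its standard error across textures.
    """
    class_name = None
    if isinstance(textures, (list, tuple)) and textures and isinstance(
        textures[0], BinaryTexture
    ):
        names = {t.class_name for t in textures}
        if len(names) > 1:
            raise ValueError(f"mixed texture classes in ensemble: {sorted(names)}")
        class_name = names.pop()
        grids = np.stack([t.grid for t in textures])
    else:
        grids = np.asarray(textures)
        if grids.ndim == 2:
            grids = grids[None]
    if grids.shape[0] == 0:
        raise ValueError("empty texture ensemble")
    n = grids.shape[0]

    per_tex_mean = grids.reshape(n, -1).mean(axis=1).astype(np.float64)

    def _mse(x: np.ndarray) -> tuple[float, float]:
        se = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        return float(x.mean()), se

    mean_stat, mean_se = _mse(per_tex_mean)
    pair_stats = {off: _mse(pair_correlation(grids, off)) for off in pair_offsets}
    glider_stats = {}
    if specs is None:
        specs = list(CORRELATED_CLASSES)
    for s in specs:
        s = _resolve_spec(s)
        if s.name == "random":
            continue
        glider_stats[s.name] = _mse(glider_products(grids, s))
    return StatReport(
        mean_stat=mean_stat,
        mean_se=mean_se,
        pair_stats=pair_stats,
        glider_stats=glider_stats,
        n_textures=n,
        class_name=class_name,
    )
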