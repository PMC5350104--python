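"""Population-level analyses of response dynamics and representations.

* :func:`dynamics_pca` embeds normalized five-point response time courses of
  model units and (surrogate) neurons in a common low-dimensional temporal
  basis.
* :func:`convex_hull_overlap` quantifies how much of one population's
  embedding falls inside another's.
* :func:`ridge_similarity` measures how well one unit set's condition x time
  response matrix linearly explains another's (ridge regression, Pearson
  correlation per target, averaged).
* :func:`form_motion_correlations` correlates texture selectivity with
  motion/orientation selectivity across units.
* :func:`counterfactual_swap` exchanges the target responses of two texture
  classes -- the control in which the link between form and motion tuning
  should disappear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint
from sklearn.linear_model import Ridge

from .surrogates import TargetPatterns

__all__ = [
    "DynamicsEmbedding",
    "SimilarityResult",
    "dynamics_pca",
    "convex_hull_overlap",
    "ridge_similarity",
    "form_motion_correlations",
    "counterfactual_swap",
]


@dataclass
class DynamicsEmbedding:
    """PCA of stacked, max-normalized response time courses."""

    components: np.ndarray  # (n_components, T), orthonormal rows
    variance_explained: np.ndarray  # fractions, sum to 1
    projections: np.ndarray  # (n_units, 2): coordinates on PC1/PC2
    scores: np.ndarray  # (n_units, n_components): all coordinates
    mean_course: np.ndarray  # (T,): the removed column means
    group_labels: np.ndarray | None = None


@dataclass
class SimilarityResult:
    """Ridge-regression mapping from source units to target neurons."""

    beta: np.ndarray  # (n_source, n_target)
    ridge_lambda: float
    r_mean: float
    r_per_target: np.ndarray
    pair: str = ""


def dynamics_pca(
    time_courses: np.ndarray,
    shift_bins: np.ndarray | int = 0,
    group_labels: np.ndarray | None = None,
) -> DynamicsEmbedding:
    """PCA of response time courses on a common temporal basis.

    ``time_courses`` is (n_units, T).  ``shift_bins`` aligns neural courses
    with model units (which have no afferent delay): each course is advanced
    by its shift (one bin = 40 ms onset delay for cortical responses, 0 for
    hidden units), padding with the final value.  Each course is then
    normalized by its maximum, the courses are stacked, time points are
    mean-centred, and PCA is computed; projections on the first two
    components are returned alongside the full decomposition.
    """
    courses = np.array(time_courses, dtype=np.float64)
    n_units, T = courses.shape
    shifts = np.broadcast_to(np.asarray(shift_bins, dtype=int), (n_units,))
    for i, s in enumerate(shifts):
        if s > 0:
            courses[i, : T - s] = courses[i, s:]
            courses[i, T - s :] = courses[i, T - s - 1]
    maxima = courses.max(axis=1)
    if (maxima <= 0).any():
        raise ValueError("every time course must have a positive maximum")
    courses /= maxima[:, None]

    mean_course = courses.mean(axis=0)
    centred = courses - mean_course
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    var = svals**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    scores = centred @ vt.T
    return DynamicsEmbedding(
        components=vt,
        variance_explained=frac,
        projections=scores[:, :2],
        scores=scores,
        mean_course=mean_course,
        group_labels=None if group_labels is None else np.asarray(group_labels),
    )


def convex_hull_overlap(projections_a: np.ndarray, projections_b: np.ndarray) -> float:
    """Fraction of hull(a)'s area covered by hull(b).

    Both inputs are (n, 2) point sets; each needs at least three
    non-collinear points.
    """
    hull_a = MultiPoint([tuple(p) for p in np.asarray(projections_a)]).convex_hull
    hull_b = MultiPoint([tuple(p) for p in np.asarray(projections_b)]).convex_hull
    if hull_a.geom_type != "Polygon" or hull_b.geom_type != "Polygon":
        raise ValueError("degenerate convex hull (need >= 3 non-collinear points)")
    return float(hull_a.intersection(hull_b).area / hull_a.area)


def ridge_similarity(
    r_source: np.ndarray,
    r_target: np.ndarray,
    ridge_lambda: float = 0.2,
    pair: str = "",
) -> SimilarityResult:
    """How well source-unit responses linearly explain target responses.

    ``r_source`` and ``r_target`` are condition x unit matrices with
    matching rows (e.g. 35 = 7 texture classes x 5 time bins).  Source
    columns are standardized so the penalty is scale-meaningful; the
    intercept is unpenalized.  Per target neuron the ridge solution
    ``(G'G + lambda I)^-1 G'y`` is fitted and the Pearson correlation
    between fit and target recorded; ``r_mean`` averages over targets.
    Zero-variance targets are excluded with a warning.
    """
    G = np.asarray(r_source, dtype=np.float64)
    Y = np.asarray(r_target, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    if G.shape[0] != Y.shape[0]:
        raise ValueError("source and target must have matching condition rows")
    sd = G.std(axis=0)
    sd[sd == 0] = 1.0
    Gz = (G - G.mean(axis=0)) / sd

    model = Ridge(alpha=ridge_lambda, fit_intercept=True)
    model.fit(Gz, Y)
    fit = model.predict(Gz)
    beta = np.atleast_2d(model.coef_).T  # (n_source, n_target)

    rs = np.full(Y.shape[1], np.nan)
    for j in range(Y.shape[1]):
        if Y[:, j].std() == 0 or fit[:, j].std() == 0:
            warnings.warn(f"target column {j} has zero variance; excluded")
            continue
        rs[j] = np.corrcoef(fit[:, j], Y[:, j])[0, 1]
    return SimilarityResult(
        beta=beta,
        ridge_lambda=ridge_lambda,
        r_mean=float(np.nanmean(rs)),
        r_per_target=rs,
        pair=pair,
    )


TEXTURE_INDEX_COLUMNS = [
    "TSI_white_triangle",
    "TSI_black_triangle",
    "TSI_even",
    "TSI_odd",
    "TSI_wye",
    "TSI_foot",
]
MOTION_INDEX_COLUMNS = ["OSI", "SSIt", "DSIt", "SSIr", "DSIr"]


def form_motion_correlations(
    indices: pd.DataFrame,
    texture_columns: list[str] | None = None,
    motion_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlations of texture vs motion/orientation indices.

    ``indices`` has one row per unit (a :func:`~glidernet.probing.
    selectivity_table`).  Returns a texture-class x motion-index matrix of
    across-unit correlations; constant columns give NaN entries with a
    warning.
    """
    tex_cols = texture_columns or [
        c for c in TEXTURE_INDEX_COLUMNS if c in indices.columns
    ]
    mot_cols = motion_columns or [c for c in MOTION_INDEX_COLUMNS if c in indices.columns]
    if len(indices) < 3:
        raise ValueError("need at least 3 units to correlate indices")
    out = pd.DataFrame(index=tex_cols, columns=mot_cols, dtype=float)
    for tc in tex_cols:
        for mc in mot_cols:
            x, y = indices[tc].to_numpy(), indices[mc].to_numpy()
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"constant index column in pair ({tc}, {mc})")
                out.loc[tc, mc] = np.nan
            else:
                out.loc[tc, mc] = float(np.corrcoef(x, y)[0, 1])
    return out


def counterfactual_swap(
    targets: TargetPatterns,
    class_names: list[str],
    class_a: str = "black_triangle",
    class_b: str = "even",
    class_axis: int = 0,
) -> TargetPatterns:
    """Exchange the target responses of two texture classes.

    Applied to class-resolved target patterns (class axis first by
    default); everything else is untouched, so applying the swap twice is
    the identity.
    """
    names = list(class_names)
    for c in (class_a, class_b):
        if c not in names:
            raise ValueError(f"class {c!r} not present in {names}")
    ia, ib = names.index(class_a), names.index(class_b)
    values = np.array(targets.values)
    sl_a = [slice(None)] * values.ndim
    sl_b = [slice(None)] * values.ndim
    sl_a[class_axis], sl_b[class_axis] = ia, ib
    values[tuple(sl_a)], values[tuple(sl_b)] = (
        values[tuple(sl_b)].copy(),
        values[tuple(sl_a)].copy(),
    )
    return replace(targets, values=values)
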