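"""Feedforward linear--nonlinear baseline with iSTAC filter selection.

The LN cascade filters the (flattened, blurred) stimulus with one or more
linear filters, passes each filter output through a static nonlinearity and
sums the results.  Filters are estimated from the spike-triggered average
and covariance: in whitened stimulus coordinates, an orthonormal subspace is
grown greedily to maximise the Gaussian Kullback-Leibler divergence between
the spike-triggered and raw stimulus ensembles (the iSTAC objective).  Each
nonlinearity is the ratio of the spike-triggered to the raw histogram of the
filter projection, over four standard deviations around the mean --
equivalently, the mean firing rate conditioned on the binned projection.

The model/results surface mirrors the recurrent model:
:class:`LinearNonlinearModel` holds the stimulus/rate data and ``fit()``
returns :class:`LNResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

__all__ = [
    "SpikeTriggeredMoments",
    "Nonlinearity",
    "spike_triggered_moments",
    "istac_filters",
    "estimate_nonlinearity",
    "ln_predict",
    "evaluate_tuning",
    "LinearNonlinearModel",
    "LNResults",
]

N_BINS_DEFAULT = 25
SD_RANGE = 4.0
COV_RIDGE = 1e-6


@dataclass
class SpikeTriggeredMoments:
    """Rate-weighted (spike-triggered) and raw stimulus moments."""

    sta: np.ndarray  # (d,)
    stc: np.ndarray  # (d, d), covariance about the STA
    raw_mean: np.ndarray  # (d,)
    raw_cov: np.ndarray  # (d, d)
    n_samples: int


@dataclass
class Nonlinearity:
    """Histogram-ratio rate lookup over a +/-4 SD projection range."""

    bin_centers: np.ndarray
    values: np.ndarray  # spikes/s (or response units); >= 0

    def __call__(self, projection: np.ndarray) -> np.ndarray:
        # linear interpolation between bin centres, clamped at the edges
        return np.interp(projection, self.bin_centers, self.values)


def spike_triggered_moments(
    stimuli: np.ndarray, rates: np.ndarray
) -> SpikeTriggeredMoments:
    """First and second moments of the stimulus, rate-weighted and raw.

    ``stimuli`` is (N, d); ``rates`` are the mean responses used as weights
    (non-negative).  Scaling all rates by a constant leaves the result
    unchanged.
    """
    stimuli = np.asarray(stimuli, dtype=np.float64)
    rates = np.asarray(rates, dtype=np.float64)
    if stimuli.shape[0] != rates.shape[0]:
        raise ValueError("stimuli and rates must have equal counts")
    if (rates < 0).any():
        raise ValueError("rates must be non-negative")
    total = rates.sum()
    if total <= 0:
        raise ValueError("degenerate ensemble: all rates are zero")
    w = rates / total
    sta = w @ stimuli
    centred_w = stimuli - sta
    stc = (centred_w * w[:, None]).T @ centred_w
    raw_mean = stimuli.mean(axis=0)
    centred = stimuli - raw_mean
    raw_cov = centred.T @ centred / stimuli.shape[0]
    return SpikeTriggeredMoments(
        sta=sta, stc=stc, raw_mean=raw_mean, raw_cov=raw_cov,
        n_samples=stimuli.shape[0],
    )


def _whiten(moments: SpikeTriggeredMoments) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cholesky whitening of the raw ensemble; returns (W, mu, Lam).

    W maps raw deviations to whitened coordinates; mu and Lam are the
    whitened spike-triggered mean and covariance.
    """
    d = moments.raw_cov.shape[0]
    cov = moments.raw_cov + COV_RIDGE * (np.trace(moments.raw_cov) / d) * np.eye(d)
    L = linalg.cholesky(cov, lower=True)
    W = linalg.solve_triangular(L, np.eye(d), lower=True)
    mu = W @ (moments.sta - moments.raw_mean)
    Lam = W @ moments.stc @ W.T
    Lam = (Lam + Lam.T) / 2.0
    return W, mu, Lam


def _kl_objective(B: np.ndarray, mu: np.ndarray, Lam: np.ndarray) -> float:
    """Gaussian KL divergence restricted to the subspace spanned by B."""
    M = B.T @ (Lam + np.outer(mu, mu)) @ B
    sign, logdet = np.linalg.slogdet(B.T @ Lam @ B)
    if sign <= 0:
        return -np.inf
    return 0.5 * (np.trace(M) - logdet - B.shape[1])


def istac_filters(
    moments: SpikeTriggeredMoments, n_filters: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedy selection of the maximally informative orthonormal subspace.

    The candidate pool is the eigenvectors of the whitened spike-triggered
    covariance plus the whitened STA direction.  Filters are grown one at a
    time, each step adding the candidate that maximises the KL objective of
    the enlarged subspace.

    Returns ``(filters, info, stimulus_filters)``: ``filters`` (k, d) are
    orthonormal in whitened coordinates, ``info`` the per-filter information
    increments (nats, non-negative and non-increasing), and
    ``stimulus_filters`` (k, d) the corresponding filters applied to raw
    stimulus deviations (for display and interpretation).
    """
    d = moments.raw_cov.shape[0]
    if n_filters > d:
        raise ValueError(f"n_filters ({n_filters}) exceeds dimension ({d})")
    W, mu, Lam = _whiten(moments)

    evals, evecs = np.linalg.eigh(Lam)
    candidates = [evecs[:, i] for i in range(d)]
    mu_norm = np.linalg.norm(mu)
    if mu_norm > 1e-12:
        candidates.append(mu / mu_norm)

    basis: list[np.ndarray] = []
    info: list[float] = []
    prev_obj = 0.0
    remaining = list(range(len(candidates)))
    for _ in range(n_filters):
        best_obj, best_i, best_vec = -np.inf, None, None
        for i in remaining:
            v = candidates[i].copy()
            for b in basis:
                v -= (b @ v) * b
            nrm = np.linalg.norm(v)
            if nrm < 1e-10:
                continue
            v /= nrm
            B = np.column_stack(basis + [v])
            obj = _kl_objective(B, mu, Lam)
            if obj > best_obj:
                best_obj, best_i, best_vec = obj, i, v
        if best_vec is None:
            break
        basis.append(best_vec)
        remaining.remove(best_i)
        info.append(max(0.0, best_obj - prev_obj))
        prev_obj = best_obj

    filters = np.array(basis)
    stimulus_filters = filters @ W  # act on raw stimulus deviations
    return filters, np.array(info), stimulus_filters


def estimate_nonlinearity(
    projections_raw: np.ndarray,
    rates: np.ndarray,
    n_bins: int = N_BINS_DEFAULT,
) -> Nonlinearity:
    """Ratio-of-histograms nonlinearity over +/-4 SD of the raw projections.

    Dividing the rate-weighted histogram by the raw histogram yields the
    mean rate conditioned on the binned projection value.  Empty raw bins
    are filled by linear interpolation; values outside the range clamp to
    the edge bins.
    """
    p = np.asarray(projections_raw, dtype=np.float64)
    rates = np.asarray(rates, dtype=np.float64)
    if rates.sum() <= 0:
        raise ValueError("degenerate ensemble: all rates are zero")
    mu, sd = p.mean(), p.std()
    if sd <= 0:
        raise ValueError("projection has zero variance")
    edges = np.linspace(mu - SD_RANGE * sd, mu + SD_RANGE * sd, n_bins + 1)
    idx = np.clip(np.digitize(p, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    rate_sums = np.bincount(idx, weights=rates, minlength=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    values = np.full(n_bins, np.nan)
    filled = counts > 0
    values[filled] = rate_sums[filled] / counts[filled]
    if not filled.all():
        values[~filled] = np.interp(centers[~filled], centers[filled], values[filled])
    return Nonlinearity(bin_centers=centers, values=np.maximum(values, 0.0))


def ln_predict(
    stimuli: np.ndarray,
    stimulus_filters: np.ndarray,
    nonlinearities: list[Nonlinearity],
    raw_mean: np.ndarray,
) -> np.ndarray:
    """Predicted rate: sum over filters of nonlinearity(projection).

    Assumes separability across filter dimensions -- each filter's
    nonlinearity is evaluated on its own projection and the outputs are
    summed.
    """
    stimuli = np.asarray(stimuli, dtype=np.float64)
    dev = stimuli - raw_mean
    out = np.zeros(stimuli.shape[0])
    for w, nl in zip(stimulus_filters, nonlinearities):
        out += nl(dev @ w)
    return out


def evaluate_tuning(
    predicted_rates: np.ndarray,
    target_rates: np.ndarray,
    class_labels: np.ndarray,
    method: str = "spearman",
) -> float:
    """Correlation between class-mean tuning curves of prediction and target.

    Class means are taken over examples for both rate vectors; the stated
    rank (Spearman) or linear (Pearson) correlation of the two tuning
    curves is returned.  Constant curves make the correlation undefined and
    raise.
    """
    predicted_rates = np.asarray(predicted_rates, dtype=np.float64)
    target_rates = np.asarray(target_rates, dtype=np.float64)
    labels = np.asarray(class_labels)
    classes = np.unique(labels)
    pred_curve = np.array([predicted_rates[labels == c].mean() for c in classes])
    if target_rates.shape == classes.shape:
        # a ready-made per-class tuning curve (e.g. measured on another set)
        targ_curve = target_rates
    else:
        targ_curve = np.array([target_rates[labels == c].mean() for c in classes])
    if np.ptp(pred_curve) == 0 or np.ptp(targ_curve) == 0:
        raise ValueError("constant tuning curve: correlation undefined")
    if method == "spearman":
        return float(stats.spearmanr(pred_curve, targ_curve).statistic)
    if method == "pearson":
        return float(stats.pearsonr(pred_curve, targ_curve).statistic)
    raise ValueError("method must be 'spearman' or 'pearson'")


class LinearNonlinearModel:
    """LN cascade fitted from stimuli and mean responses.

    Parameters
    ----------
    stimuli : ndarray, (N, d)
        Flattened (blurred) stimulus frames.
    rates : ndarray, (N,)
        Mean response of the neuron over the analysis window, >= 0.
    """

    def __init__(self, stimuli: np.ndarray, rates: np.ndarray):
        self.stimuli = np.asarray(stimuli, dtype=np.float64)
        self.rates = np.asarray(rates, dtype=np.float64)
        if self.stimuli.shape[0] != self.rates.shape[0]:
            raise ValueError("stimuli and rates must have equal counts")

    def fit(self, n_filters: int = 15, n_bins: int = N_BINS_DEFAULT) -> "LNResults":
        moments = spike_triggered_moments(self.stimuli, self.rates)
        filters, info, stim_filters = istac_filters(moments, n_filters)
        dev = self.stimuli - moments.raw_mean
        nonlinearities = [
            estimate_nonlinearity(dev @ w, self.rates, n_bins) for w in stim_filters
        ]
        return LNResults(self, moments, filters, info, stim_filters, nonlinearities)


class LNResults:
    """Fitted LN model: ranked filters, information values, nonlinearities."""

    def __init__(
        self,
        model: LinearNonlinearModel,
        moments: SpikeTriggeredMoments,
        filters: np.ndarray,
        info: np.ndarray,
        stimulus_filters: np.ndarray,
        nonlinearities: list[Nonlinearity],
    ):
        self.model = model
        self.moments = moments
        self.filters = filters  # orthonormal, whitened coordinates
        self.info = info
        self.stimulus_filters = stimulus_filters
        self.nonlinearities = nonlinearities
        self.mean_rate = float(model.rates.mean())

    def predict(self, stimuli: np.ndarray, n_filters: int | None = None) -> np.ndarray:
        k = len(self.nonlinearities) if n_filters is None else n_filters
        return ln_predict(
            stimuli,
            self.stimulus_filters[:k],
            self.nonlinearities[:k],
            self.moments.raw_mean,
        )

    def tuning_performance(
        self,
        stimuli: np.ndarray,
        target_rates: np.ndarray,
        class_labels: np.ndarray,
        n_filters: int | None = None,
        method: str = "spearman",
    ) -> float:
        pred = self.predict(stimuli, n_filters=n_filters)
        return evaluate_tuning(pred, target_rates, class_labels, method=method)

    def summary(self) -> str:
        lines = [
            "Linear-nonlinear (iSTAC) model",
            "=" * 42,
            f"Stimulus dimension     {self.model.stimuli.shape[1]}",
            f"Samples                {self.moments.n_samples}",
            f"Mean rate              {self.mean_rate:.3f}",
            f"Filters                {len(self.nonlinearities)}",
            "Information (nats) per filter:",
            "  " + ", ".join(f"{v:.4f}" for v in self.info),
        ]
        return "\n".join(lines)
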