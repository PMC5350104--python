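"""Two-stage locally recurrent network trained by backpropagation through time.

The architecture is a four-layer Elman-style network: 256 input units (one
per check of the 16 x 16 stimulus), two hidden layers fully connected in a
feedforward chain, each hidden layer also recurrently connected to all units
within its own layer, and a feedforward output layer.  Every unit computes a
weighted sum of its inputs plus a bias and passes it through the logistic
sigmoid.  At step t a hidden layer receives feedforward drive from the
current step and recurrent drive from its own outputs at step t - 1; the
recurrent state before the first step is zero (activity is reset between
trials).  Sequences are five 40 ms bins long.

Training is plain stochastic gradient descent: each epoch presents one
uniformly sampled pattern, computes the summed squared error of the five
output steps against the target, backpropagates the exact gradient through
the unrolled network, and takes a step.  The public surface follows the
model/results convention: :class:`RecurrentFormAnalysis` holds data and
architecture, ``fit()`` returns :class:`RFAMResults` with the trained
weights, the error trace and prediction helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .textures import GRID_SIZE, N_FRAMES

__all__ = [
    "NetworkParams",
    "ActivityTrace",
    "TrainConfig",
    "TrainingDiverged",
    "init_network",
    "forward",
    "forward_batch",
    "bptt_gradients",
    "train",
    "RecurrentFormAnalysis",
    "RFAMResults",
]

N_INPUT = GRID_SIZE * GRID_SIZE


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class NetworkParams:
    """All weights and biases; rows index the receiving unit."""

    w_in: np.ndarray  # (n1, n_in)
    w_h1h1: np.ndarray  # (n1, n1)
    b1: np.ndarray  # (n1,)
    w_h1h2: np.ndarray  # (n2, n1)
    w_h2h2: np.ndarray  # (n2, n2)
    b2: np.ndarray  # (n2,)
    w_out: np.ndarray  # (n_out, n2)
    b_out: np.ndarray  # (n_out,)

    _FIELDS = ("w_in", "w_h1h1", "b1", "w_h1h2", "w_h2h2", "b2", "w_out", "b_out")

    def __post_init__(self) -> None:
        n1, n_in = self.w_in.shape
        n2 = self.w_h1h2.shape[0]
        n_out = self.w_out.shape[0]
        expected = {
            "w_h1h1": (n1, n1),
            "b1": (n1,),
            "w_h1h2": (n2, n1),
            "w_h2h2": (n2, n2),
            "b2": (n2,),
            "w_out": (n_out, n2),
            "b_out": (n_out,),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        for name in self._FIELDS:
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def sizes(self) -> tuple[int, int, int, int]:
        return (self.w_in.shape[1], self.w_in.shape[0], self.w_h1h2.shape[0],
                self.w_out.shape[0])

    @property
    def n_params(self) -> int:
        return sum(getattr(self, f).size for f in self._FIELDS)

    def copy(self) -> "NetworkParams":
        return NetworkParams(**{f: getattr(self, f).copy() for f in self._FIELDS})

    def to_vector(self) -> np.ndarray:
        return np.concatenate([getattr(self, f).ravel() for f in self._FIELDS])

    def from_vector(self, vec: np.ndarray) -> "NetworkParams":
        out, i = {}, 0
        for f in self._FIELDS:
            arr = getattr(self, f)
            out[f] = vec[i : i + arr.size].reshape(arr.shape).copy()
            i += arr.size
        return NetworkParams(**out)


@dataclass
class ActivityTrace:
    """Unit outputs (and pre-activations) per layer per time step."""

    y1: np.ndarray  # (T, n1)
    y2: np.ndarray  # (T, n2)
    y_out: np.ndarray  # (T, n_out)
    x1: np.ndarray
    x2: np.ndarray
    x_out: np.ndarray


@dataclass
class TrainConfig:
    """Stochastic-gradient BPTT settings; one pattern per epoch."""

    n_epochs: int = 100_000
    learning_rate: float = 0.01
    momentum: float = 0.0  # classical momentum on the per-pattern gradient
    seed: int = 0
    clip_norm: float | None = 10.0
    trace_every: int | None = None  # default: ~200 probe evaluations per run
    probe_size: int = 64
    reset_between_trials: bool = True  # fixed: zero state each trial

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


class TrainingDiverged(RuntimeError):
    """Raised when the training error becomes non-finite."""

    def __init__(self, message: str, last_stable: NetworkParams | None = None):
        super().__init__(message)
        self.last_stable = last_stable


def init_network(
    n1: int = 100,
    n2: int = 100,
    n_out: int = 1,
    seed: int = 0,
    n_in: int = N_INPUT,
) -> NetworkParams:
    """Nguyen-Widrow initialization.

    Each unit's incoming weight vector (feedforward and recurrent inputs
    combined) points in a random direction and is rescaled to the magnitude
    ``0.7 * n_units ** (1 / fan_in)``; biases are spread evenly over the
    same range so the sigmoids' active regions tile the input space.
    """
    if min(n1, n2, n_out, n_in) < 1:
        raise ValueError("all layer sizes must be >= 1")
    rng = np.random.default_rng(seed)

    def nw_layer(n_units: int, fan_in: int) -> tuple[np.ndarray, np.ndarray]:
        beta = 0.7 * n_units ** (1.0 / fan_in)
        w = rng.uniform(-1.0, 1.0, size=(n_units, fan_in))
        w *= beta / np.linalg.norm(w, axis=1, keepdims=True)
        if n_units == 1:
            b = np.zeros(1)
        else:
            b = np.linspace(-beta, beta, n_units)[rng.permutation(n_units)]
        return w, b

    w1, b1 = nw_layer(n1, n_in + n1)
    w2, b2 = nw_layer(n2, n1 + n2)
    wo, bo = nw_layer(n_out, n2)
    return NetworkParams(
        w_in=w1[:, :n_in],
        w_h1h1=w1[:, n_in:],
        b1=b1,
        w_h1h2=w2[:, :n1],
        w_h2h2=w2[:, n1:],
        b2=b2,
        w_out=wo,
        b_out=bo,
    )


def _as_sequence(stimulus: np.ndarray) -> np.ndarray:
    """Accept a static (n_in,) pattern or a (T, n_in) sequence."""
    stimulus = np.asarray(stimulus, dtype=np.float64)
    if stimulus.ndim == 1:
        return np.broadcast_to(stimulus, (N_FRAMES, stimulus.size))
    return stimulus


def forward(params: NetworkParams, stimulus: np.ndarray) -> ActivityTrace:
    """Run the Elman dynamics for one stimulus sequence.

    ``stimulus`` is either a static flattened pattern of length 256 (repeated
    over the five bins) or an explicit (5, 256) sequence.  The recurrent
    state before step 1 is the zero vector.
    """
    static = np.asarray(stimulus).ndim == 1
    u = _as_sequence(stimulus)
    T = u.shape[0]
    n_in, n1, n2, n_out = params.sizes
    if u.shape[1] != n_in:
        raise ValueError(f"stimulus dimension {u.shape[1]} != input size {n_in}")
    y1 = np.zeros((T, n1))
    y2 = np.zeros((T, n2))
    yo = np.zeros((T, n_out))
    x1 = np.zeros((T, n1))
    x2 = np.zeros((T, n2))
    xo = np.zeros((T, n_out))
    prev1 = np.zeros(n1)
    prev2 = np.zeros(n2)
    ff1 = params.w_in @ u[0] + params.b1 if static else None
    for t in range(T):
        x1[t] = (
            ff1 + params.w_h1h1 @ prev1
            if static
            else params.w_in @ u[t] + params.w_h1h1 @ prev1 + params.b1
        )
        y1[t] = _sigmoid(x1[t])
        x2[t] = params.w_h1h2 @ y1[t] + params.w_h2h2 @ prev2 + params.b2
        y2[t] = _sigmoid(x2[t])
        xo[t] = params.w_out @ y2[t] + params.b_out
        yo[t] = _sigmoid(xo[t])
        prev1, prev2 = y1[t], y2[t]
    if not np.isfinite(yo).all():
        raise FloatingPointError("non-finite activations in forward pass")
    return ActivityTrace(y1=y1, y2=y2, y_out=yo, x1=x1, x2=x2, x_out=xo)


def forward_batch(
    params: NetworkParams, stimuli: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised forward pass over a batch.

    ``stimuli`` is (B, n_in) for static patterns or (B, T, n_in) for
    sequences.  Returns ``(y1, y2, y_out)`` each of shape (B, T, n).
    """
    stimuli = np.asarray(stimuli, dtype=np.float64)
    static = stimuli.ndim == 2
    B = stimuli.shape[0]
    T = N_FRAMES if static else stimuli.shape[1]
    n_in, n1, n2, n_out = params.sizes
    y1 = np.empty((B, T, n1))
    y2 = np.empty((B, T, n2))
    yo = np.empty((B, T, n_out))
    prev1 = np.zeros((B, n1))
    prev2 = np.zeros((B, n2))
    ff_static = stimuli @ params.w_in.T + params.b1 if static else None
    for t in range(T):
        ff = ff_static if static else stimuli[:, t] @ params.w_in.T + params.b1
        a1 = _sigmoid(ff + prev1 @ params.w_h1h1.T)
        a2 = _sigmoid(a1 @ params.w_h1h2.T + prev2 @ params.w_h2h2.T + params.b2)
        ao = _sigmoid(a2 @ params.w_out.T + params.b_out)
        y1[:, t], y2[:, t], yo[:, t] = a1, a2, ao
        prev1, prev2 = a1, a2
    return y1, y2, yo


def bptt_gradients(
    params: NetworkParams, stimulus: np.ndarray, target: np.ndarray
) -> tuple[dict[str, np.ndarray], float]:
    """Exact gradient of the summed squared error, unrolled through time.

    ``target`` has shape (T, n_out).  Returns a dict keyed like
    :class:`NetworkParams` fields plus the scalar error
    ``sum_t sum_o (y_out - target)**2``.
    """
    static = np.asarray(stimulus).ndim == 1
    u = _as_sequence(stimulus)
    target = np.asarray(target, dtype=np.float64)
    tr = forward(params, stimulus)
    T = u.shape[0]
    if target.shape != tr.y_out.shape:
        raise ValueError(f"target shape {target.shape} != output {tr.y_out.shape}")

    g = {f: np.zeros_like(getattr(params, f)) for f in NetworkParams._FIELDS}
    err = tr.y_out - target
    error = float((err**2).sum())

    d1_next = np.zeros(params.b1.size)
    d2_next = np.zeros(params.b2.size)
    d1_total = np.zeros(params.b1.size)
    for t in range(T - 1, -1, -1):
        do = 2.0 * err[t] * tr.y_out[t] * (1.0 - tr.y_out[t])
        g["w_out"] += np.outer(do, tr.y2[t])
        g["b_out"] += do
        e2 = params.w_out.T @ do + params.w_h2h2.T @ d2_next
        d2 = e2 * tr.y2[t] * (1.0 - tr.y2[t])
        g["w_h1h2"] += np.outer(d2, tr.y1[t])
        if t > 0:
            g["w_h2h2"] += np.outer(d2, tr.y2[t - 1])
        g["b2"] += d2
        e1 = params.w_h1h2.T @ d2 + params.w_h1h1.T @ d1_next
        d1 = e1 * tr.y1[t] * (1.0 - tr.y1[t])
        if static:
            d1_total += d1
        else:
            g["w_in"] += np.outer(d1, u[t])
        if t > 0:
            g["w_h1h1"] += np.outer(d1, tr.y1[t - 1])
        g["b1"] += d1
        d1_next, d2_next = d1, d2
    if static:
        g["w_in"] = np.outer(d1_total, u[0])
    return g, error


try:  # pragma: no cover - exercised indirectly through train()
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (a and callable(a[0])) else a[0]


@njit(cache=True, fastmath=False)
def _sgd_kernel(  # noqa: C901 - one flat loop for speed
    w_in, w_h1h1, b1, w_h1h2, w_h2h2, b2, w_out, b_out,
    v_w_in, v_w_h1h1, v_b1, v_w_h1h2, v_w_h2h2, v_b2, v_w_out, v_b_out,
    stimuli, targets, pattern_order, lr, momentum, clip_norm,
):
    """Static-stimulus SGD/BPTT inner loop (identical math to the numpy path).

    ``stimuli`` is (N, n_in); ``targets`` is (N, T, n_out).  Weights are
    updated in place, one uniformly drawn pattern per epoch (the draw order
    is precomputed).  Returns the last pattern error.
    """
    n_in = w_in.shape[1]
    n1 = b1.shape[0]
    n2 = b2.shape[0]
    n_out = b_out.shape[0]
    T = targets.shape[1]
    y1 = np.empty((T, n1))
    y2 = np.empty((T, n2))
    yo = np.empty((T, n_out))
    ff1 = np.empty(n1)
    g_w_h1h1 = np.empty((n1, n1))
    g_b1 = np.empty(n1)
    g_w_h1h2 = np.empty((n2, n1))
    g_w_h2h2 = np.empty((n2, n2))
    g_b2 = np.empty(n2)
    g_w_out = np.empty((n_out, n2))
    g_b_out = np.empty(n_out)
    d1 = np.empty(n1)
    d2 = np.empty(n2)
    do = np.empty(n_out)
    d1_next = np.empty(n1)
    d2_next = np.empty(n2)
    d1_total = np.empty(n1)
    e1 = np.empty(n1)
    e2 = np.empty(n2)
    err = 0.0
    for e in range(pattern_order.shape[0]):
        i = pattern_order[e]
        u = stimuli[i]
        tgt = targets[i]
        for a in range(n1):
            s = b1[a]
            for k in range(n_in):
                s += w_in[a, k] * u[k]
            ff1[a] = s
        # forward
        for t in range(T):
            for a in range(n1):
                s = ff1[a]
                if t > 0:
                    for k in range(n1):
                        s += w_h1h1[a, k] * y1[t - 1, k]
                y1[t, a] = 1.0 / (1.0 + np.exp(-s))
            for a in range(n2):
                s = b2[a]
                for k in range(n1):
                    s += w_h1h2[a, k] * y1[t, k]
                if t > 0:
                    for k in range(n2):
                        s += w_h2h2[a, k] * y2[t - 1, k]
                y2[t, a] = 1.0 / (1.0 + np.exp(-s))
            for a in range(n_out):
                s = b_out[a]
                for k in range(n2):
                    s += w_out[a, k] * y2[t, k]
                yo[t, a] = 1.0 / (1.0 + np.exp(-s))
        # backward
        g_w_h1h1[:, :] = 0.0
        g_b1[:] = 0.0
        g_w_h1h2[:, :] = 0.0
        g_w_h2h2[:, :] = 0.0
        g_b2[:] = 0.0
        g_w_out[:, :] = 0.0
        g_b_out[:] = 0.0
        d1_next[:] = 0.0
        d2_next[:] = 0.0
        d1_total[:] = 0.0
        err = 0.0
        for t in range(T - 1, -1, -1):
            for a in range(n_out):
                eo = yo[t, a] - tgt[t, a]
                err += eo * eo
                do[a] = 2.0 * eo * yo[t, a] * (1.0 - yo[t, a])
                for k in range(n2):
                    g_w_out[a, k] += do[a] * y2[t, k]
                g_b_out[a] += do[a]
            for a in range(n2):
                s = 0.0
                for k in range(n_out):
                    s += w_out[k, a] * do[k]
                for k in range(n2):
                    s += w_h2h2[k, a] * d2_next[k]
                e2[a] = s
            for a in range(n2):
                d2[a] = e2[a] * y2[t, a] * (1.0 - y2[t, a])
                for k in range(n1):
                    g_w_h1h2[a, k] += d2[a] * y1[t, k]
                if t > 0:
                    for k in range(n2):
                        g_w_h2h2[a, k] += d2[a] * y2[t - 1, k]
                g_b2[a] += d2[a]
            for a in range(n1):
                s = 0.0
                for k in range(n2):
                    s += w_h1h2[k, a] * d2[k]
                for k in range(n1):
                    s += w_h1h1[k, a] * d1_next[k]
                e1[a] = s
            for a in range(n1):
                d1[a] = e1[a] * y1[t, a] * (1.0 - y1[t, a])
                d1_total[a] += d1[a]
                if t > 0:
                    for k in range(n1):
                        g_w_h1h1[a, k] += d1[a] * y1[t - 1, k]
                g_b1[a] += d1[a]
            for a in range(n1):
                d1_next[a] = d1[a]
            for a in range(n2):
                d2_next[a] = d2[a]
        # gradient of w_in via the accumulated deltas (static input)
        scale = 1.0
        if clip_norm > 0.0:
            total = 0.0
            for a in range(n1):
                for k in range(n_in):
                    g = d1_total[a] * u[k]
                    total += g * g
            total += (
                np.sum(g_w_h1h1**2) + np.sum(g_b1**2) + np.sum(g_w_h1h2**2)
                + np.sum(g_w_h2h2**2) + np.sum(g_b2**2) + np.sum(g_w_out**2)
                + np.sum(g_b_out**2)
            )
            total = np.sqrt(total)
            if total > clip_norm:
                scale = clip_norm / total
        for a in range(n1):
            for k in range(n_in):
                v_w_in[a, k] = momentum * v_w_in[a, k] + scale * d1_total[a] * u[k]
                w_in[a, k] -= lr * v_w_in[a, k]
            for k in range(n1):
                v_w_h1h1[a, k] = momentum * v_w_h1h1[a, k] + scale * g_w_h1h1[a, k]
                w_h1h1[a, k] -= lr * v_w_h1h1[a, k]
            v_b1[a] = momentum * v_b1[a] + scale * g_b1[a]
            b1[a] -= lr * v_b1[a]
        for a in range(n2):
            for k in range(n1):
                v_w_h1h2[a, k] = momentum * v_w_h1h2[a, k] + scale * g_w_h1h2[a, k]
                w_h1h2[a, k] -= lr * v_w_h1h2[a, k]
            for k in range(n2):
                v_w_h2h2[a, k] = momentum * v_w_h2h2[a, k] + scale * g_w_h2h2[a, k]
                w_h2h2[a, k] -= lr * v_w_h2h2[a, k]
            v_b2[a] = momentum * v_b2[a] + scale * g_b2[a]
            b2[a] -= lr * v_b2[a]
        for a in range(n_out):
            for k in range(n2):
                v_w_out[a, k] = momentum * v_w_out[a, k] + scale * g_w_out[a, k]
                w_out[a, k] -= lr * v_w_out[a, k]
            v_b_out[a] = momentum * v_b_out[a] + scale * g_b_out[a]
            b_out[a] -= lr * v_b_out[a]
    return err


def _clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def _probe_error(params: NetworkParams, stimuli: np.ndarray, targets: np.ndarray) -> float:
    _, _, yo = forward_batch(params, stimuli)
    return float(((yo - targets) ** 2).sum(axis=(1, 2)).mean())


def train(
    params: NetworkParams,
    stimuli: np.ndarray,
    targets: np.ndarray,
    cfg: TrainConfig,
) -> tuple[NetworkParams, dict[str, np.ndarray]]:
    """Stochastic-gradient BPTT training.

    Each epoch samples one pattern uniformly, runs the network, and takes a
    gradient step on the summed squared error.  The error trace is evaluated
    on a fixed probe subset.  ``stimuli`` is (N, 256) for static patterns or
    (N, 5, 256); ``targets`` is (N, 5, n_out).

    Returns the trained parameters and a trace dict with ``epoch`` and
    ``probe_error`` arrays.
    """
    stimuli = np.ascontiguousarray(stimuli, dtype=np.float64)
    targets = np.ascontiguousarray(targets, dtype=np.float64)
    n_patterns = stimuli.shape[0]
    if targets.shape[0] != n_patterns:
        raise ValueError("stimuli and targets must be aligned")
    params = params.copy()
    rng = np.random.default_rng(cfg.seed)
    trace_every = cfg.trace_every or max(1, cfg.n_epochs // 200)
    probe_idx = rng.choice(n_patterns, size=min(cfg.probe_size, n_patterns), replace=False)
    probe_s, probe_t = stimuli[probe_idx], targets[probe_idx]
    pattern_order = rng.integers(n_patterns, size=cfg.n_epochs)
    static = stimuli.ndim == 2
    use_kernel = HAVE_NUMBA and static

    epochs, probe_errors = [], []
    last_stable = params.copy()
    lr = cfg.learning_rate
    clip = float(cfg.clip_norm) if cfg.clip_norm is not None else 0.0
    velocity = {f: np.zeros_like(getattr(params, f)) for f in NetworkParams._FIELDS}
    epoch = 0
    while epoch < cfg.n_epochs:
        chunk = min(trace_every - (epoch % trace_every) or trace_every,
                    cfg.n_epochs - epoch)
        order = pattern_order[epoch : epoch + chunk]
        if use_kernel:
            err = _sgd_kernel(
                params.w_in, params.w_h1h1, params.b1,
                params.w_h1h2, params.w_h2h2, params.b2,
                params.w_out, params.b_out,
                velocity["w_in"], velocity["w_h1h1"], velocity["b1"],
                velocity["w_h1h2"], velocity["w_h2h2"], velocity["b2"],
                velocity["w_out"], velocity["b_out"],
                stimuli, targets, order, lr, cfg.momentum, clip,
            )
            if not np.isfinite(err):
                raise TrainingDiverged(
                    f"non-finite training error near epoch {epoch}", last_stable
                )
        else:
            for i in order:
                grads, err = bptt_gradients(params, stimuli[i], targets[i])
                if not np.isfinite(err):
                    raise TrainingDiverged(
                        f"non-finite training error at epoch {epoch}", last_stable
                    )
                if cfg.clip_norm is not None:
                    _clip_gradients(grads, cfg.clip_norm)
                for f in NetworkParams._FIELDS:
                    velocity[f] *= cfg.momentum
                    velocity[f] += grads[f]
                    getattr(params, f)[...] -= lr * velocity[f]
        epoch += chunk
        pe = _probe_error(params, probe_s, probe_t)
        if not np.isfinite(pe):
            raise TrainingDiverged(
                f"non-finite probe error at epoch {epoch}", last_stable
            )
        epochs.append(epoch)
        probe_errors.append(pe)
        last_stable = params.copy()
    return params, {"epoch": np.array(epochs), "probe_error": np.array(probe_errors)}


class RecurrentFormAnalysis:
    """Recurrent network model of texture-evoked response dynamics.

    Parameters
    ----------
    stimuli : ndarray
        Training inputs, (N, 256) flattened blurred frames (static
        presentation) or (N, 5, 256) sequences.
    targets : ndarray
        Normalized target patterns in [0, 1], shape (N, 5, n_out) or, for a
        single output unit, (N, 5).
    n_hidden1, n_hidden2 : int
        Hidden layer sizes (100 and 100 for the full-scale architecture).
    """

    def __init__(
        self,
        stimuli: np.ndarray,
        targets: np.ndarray,
        n_hidden1: int = 100,
        n_hidden2: int = 100,
    ):
        self.stimuli = np.asarray(stimuli, dtype=np.float64)
        targets = np.asarray(targets, dtype=np.float64)
        if targets.ndim == 2:
            targets = targets[:, :, None]
        self.targets = targets
        self.n_hidden1 = int(n_hidden1)
        self.n_hidden2 = int(n_hidden2)
        self.n_output = targets.shape[2]
        if targets.min() < 0 or targets.max() > 1:
            raise ValueError("targets must be normalized to [0, 1]")

    def start_params(self, seed: int = 0) -> NetworkParams:
        return init_network(
            self.n_hidden1,
            self.n_hidden2,
            self.n_output,
            seed=seed,
            n_in=self.stimuli.shape[-1],
        )

    def fit(
        self,
        n_epochs: int = 100_000,
        learning_rate: float = 0.01,
        seed: int = 0,
        start_params: NetworkParams | None = None,
        **cfg_kwargs,
    ) -> "RFAMResults":
        cfg = TrainConfig(
            n_epochs=n_epochs, learning_rate=learning_rate, seed=seed, **cfg_kwargs
        )
        params = start_params if start_params is not None else self.start_params(seed)
        trained, trace = train(params, self.stimuli, self.targets, cfg)
        return RFAMResults(self, trained, trace, cfg)


class RFAMResults:
    """Fitted recurrent network: weights, error trace, prediction helpers."""

    def __init__(
        self,
        model: RecurrentFormAnalysis,
        params: NetworkParams,
        error_trace: dict[str, np.ndarray],
        config: TrainConfig,
    ):
        self.model = model
        self.params = params
        self.error_trace = error_trace
        self.config = config

    def predict(self, stimuli: np.ndarray) -> np.ndarray:
        """Output-unit time courses, (B, 5, n_out)."""
        _, _, yo = forward_batch(self.params, stimuli)
        return yo

    def hidden_responses(self, stimuli: np.ndarray, layer: str = "H1") -> np.ndarray:
        """Hidden-unit output time courses, (B, 5, n_units)."""
        y1, y2, _ = forward_batch(self.params, stimuli)
        if layer.upper() == "H1":
            return y1
        if layer.upper() == "H2":
            return y2
        raise ValueError("layer must be 'H1' or 'H2'")

    def summary(self) -> str:
        n_in, n1, n2, n_out = self.params.sizes
        tr = self.error_trace["probe_error"]
        lines = [
            "Recurrent form analysis network",
            "=" * 47,
            f"Architecture           {n_in} -> {n1} -> {n2} -> {n_out}",
            f"Recurrent layers       H1 ({n1}x{n1}), H2 ({n2}x{n2})",
            f"Trainable parameters   {self.params.n_params}",
            f"Training patterns      {self.model.stimuli.shape[0]}",
            f"Epochs                 {self.config.n_epochs}",
            f"Learning rate          {self.config.learning_rate}",
            f"Initial probe error    {tr[0]:.4f}" if tr.size else "",
            f"Final probe error      {tr[-1]:.4f}" if tr.size else "",
        ]
        return "\n".join(line for line in lines if line)
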