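"""A 4-24-2 multi-layer perceptron trained by stochastic back-propagation.

The network maps a 4-feature identification vector <c1, c2, deg(v1), deg(v2)>
to two outputs (y1, y2) in (0, 1), read as RNA-like / not-RNA-like evidence.
Architecture is fixed: 4 inputs, one hidden layer of 24 logistic units, 2
independent logistic outputs (not softmax: the two outputs need not sum to
one), with bias units on both layers.

Training minimizes the total squared error E = sum_i ||q_i - y(p_i)||^2 by
per-pattern gradient descent: each epoch presents every pattern once in a
freshly shuffled order and applies the exact gradient of that pattern's
squared error.  Weights start uniform in [-0.1, 0.1].  Patterns carry
integer multiplicities (a merge class seen with frequency w); by default
each pattern is replicated w times per epoch ("replicate"), or
equivalently presented once with a w-scaled gradient ("gradient").

Generalization is assessed by leave-v-out cross-validation: repeated random
splits holding out a complement (default 15% of the patterns), training on
the remainder and reporting the root-mean-square error of the complement
predictions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

logger = logging.getLogger(__name__)

__all__ = [
    "N_INPUT",
    "N_HIDDEN",
    "N_OUTPUT",
    "MLPParams",
    "TrainingConfig",
    "TrainingSet",
    "TrainResult",
    "CVRepetition",
    "CVReport",
    "init_params",
    "forward",
    "forward_batch",
    "total_error",
    "train",
    "cross_validate",
    "save_params",
    "load_params",
]

N_INPUT, N_HIDDEN, N_OUTPUT = 4, 24, 2


@dataclass
class MLPParams:
    """Weights of the 4-24-2 network (biases separate)."""

    w1: np.ndarray  # (4, 24) input -> hidden
    b1: np.ndarray  # (24,)
    w2: np.ndarray  # (24, 2) hidden -> output
    b2: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        shapes = (
            (self.w1, (N_INPUT, N_HIDDEN)),
            (self.b1, (N_HIDDEN,)),
            (self.w2, (N_HIDDEN, N_OUTPUT)),
            (self.b2, (N_OUTPUT,)),
        )
        for arr, shape in shapes:
            if arr.shape != shape:
                raise ValueError(f"weight shape {arr.shape} != expected {shape}")
        if not all(np.all(np.isfinite(a)) for a in (self.w1, self.b1, self.w2, self.b2)):
            raise ValueError("non-finite weights")

    def copy(self) -> "MLPParams":
        return MLPParams(self.w1.copy(), self.b1.copy(), self.w2.copy(), self.b2.copy())


@dataclass
class TrainingConfig:
    """Knobs of the back-propagation run.

    ``iterations`` counts full passes (epochs) over the pattern set;
    ``learning_rate`` is the fixed step size applied to each per-pattern
    gradient.  ``complement_fraction`` and ``repetitions`` parameterize
    leave-v-out cross-validation.
    """

    learning_rate: float = 0.05
    iterations: int = 10_000
    complement_fraction: float = 0.15
    repetitions: int = 5
    seed: int = 0
    weighting: str = "replicate"  # or "gradient"
    init_scale: float = 0.1
    record_every: int = 100

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.iterations < 1 or self.repetitions < 1:
            raise ValueError("iterations and repetitions must be positive")
        if not 0 < self.complement_fraction < 1:
            raise ValueError("complement_fraction must lie in (0, 1)")
        if self.weighting not in ("replicate", "gradient"):
            raise ValueError("weighting must be 'replicate' or 'gradient'")


@dataclass
class TrainingSet:
    """Weighted (pattern, target) pairs as arrays."""

    X: np.ndarray  # (N, 4) float
    Q: np.ndarray  # (N, 2) float, rows (1,0) or (0,1)
    weights: np.ndarray  # (N,) positive int

    @classmethod
    def from_vectors(cls, vectors) -> "TrainingSet":
        """Build from merge data vectors; vectors without a target are rejected."""
        rows, targets, wts = [], [], []
        for v in vectors:
            if v.target is None:
                raise ValueError(
                    f"vector for result {v.result_index or '?'} has no target; "
                    "unclassified results cannot train"
                )
            rows.append(v.features)
            targets.append(v.target)
            wts.append(v.weight)
        if not rows:
            raise ValueError("empty training set")
        return cls(
            np.asarray(rows, dtype=float),
            np.asarray(targets, dtype=float),
            np.asarray(wts, dtype=np.int64),
        )

    def __len__(self) -> int:
        return self.X.shape[0]

    def expanded(self) -> "TrainingSet":
        """Each pattern replicated by its multiplicity (weights become 1)."""
        idx = np.repeat(np.arange(len(self)), self.weights)
        return TrainingSet(self.X[idx], self.Q[idx], np.ones(len(idx), dtype=np.int64))

    def subset(self, idx) -> "TrainingSet":
        return TrainingSet(self.X[idx], self.Q[idx], self.weights[idx])


def init_params(rng: np.random.Generator, scale: float = 0.1) -> MLPParams:
    """Random weights close to zero, uniform in [-scale, scale]."""
    return MLPParams(
        rng.uniform(-scale, scale, (N_INPUT, N_HIDDEN)),
        rng.uniform(-scale, scale, N_HIDDEN),
        rng.uniform(-scale, scale, (N_HIDDEN, N_OUTPUT)),
        rng.uniform(-scale, scale, N_OUTPUT),
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(params: MLPParams, p) -> np.ndarray:
    """Network output for one 4-vector; both components in (0, 1)."""
    p = np.asarray(p, dtype=float)
    h = _sigmoid(p @ params.w1 + params.b1)
    return _sigmoid(h @ params.w2 + params.b2)


def forward_batch(params: MLPParams, X: np.ndarray) -> np.ndarray:
    H = _sigmoid(X @ params.w1 + params.b1)
    return _sigmoid(H @ params.w2 + params.b2)


def total_error(params: MLPParams, ts: TrainingSet) -> float:
    """Weighted total squared error E = sum_i w_i ||q_i - y(p_i)||^2."""
    Y = forward_batch(params, ts.X)
    return float(np.sum(ts.weights * np.sum((ts.Q - Y) ** 2, axis=1)))


@njit(cache=False)
def _epoch(w1, b1, w2, b2, X, Q, wts, order, lr):  # pragma: no cover - jitted
    for k in range(order.shape[0]):
        i = order[k]
        p = X[i]
        h = 1.0 / (1.0 + np.exp(-(p @ w1 + b1)))
        y = 1.0 / (1.0 + np.exp(-(h @ w2 + b2)))
        gy = 2.0 * wts[i] * (y - Q[i]) * y * (1.0 - y)
        gh = (w2 @ gy) * h * (1.0 - h)
        for j in range(w2.shape[0]):
            for r in range(w2.shape[1]):
                w2[j, r] -= lr * h[j] * gy[r]
        b2 -= lr * gy
        for j in range(w1.shape[0]):
            for r in range(w1.shape[1]):
                w1[j, r] -= lr * p[j] * gh[r]
        b1 -= lr * gh


@dataclass
class TrainResult:
    params: MLPParams
    errors: np.ndarray  # total E sampled every ``record_every`` epochs
    config: TrainingConfig
    final_error: float = field(init=False)

    def __post_init__(self) -> None:
        self.final_error = float(self.errors[-1])


def train(ts: TrainingSet, cfg: TrainingConfig) -> TrainResult:
    """Seeded back-propagation on the full set; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    params = init_params(rng, cfg.init_scale)
    work = ts.expanded() if cfg.weighting == "replicate" else ts
    wts = (
        np.ones(len(work))
        if cfg.weighting == "replicate"
        else work.weights.astype(float)
    )
    X = np.ascontiguousarray(work.X)
    Q = np.ascontiguousarray(work.Q)
    n = len(work)
    errors = []
    for epoch in range(cfg.iterations):
        order = rng.permutation(n)
        _epoch(params.w1, params.b1, params.w2, params.b2, X, Q, wts, order,
               cfg.learning_rate)
        if epoch % cfg.record_every == 0 or epoch == cfg.iterations - 1:
            e = total_error(params, work)
            if not np.isfinite(e):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (E not finite); "
                    "try a smaller learning_rate"
                )
            errors.append(e)
    if errors[-1] / wts.sum() > 0.05:
        logger.warning(
            "final training error %.4f is large for %d weighted patterns; "
            "the set may not be separable or needs more iterations",
            errors[-1], int(wts.sum()),
        )
    return TrainResult(params, np.asarray(errors), cfg)


@dataclass
class CVRepetition:
    rmse: float
    complement_size: int
    train_size: int
    final_error: float


@dataclass
class CVReport:
    repetitions: list[CVRepetition]

    @property
    def rmses(self) -> list[float]:
        return [r.rmse for r in self.repetitions]


def cross_validate(ts: TrainingSet, cfg: TrainingConfig) -> CVReport:
    """Leave-v-out cross-validation over the (expanded) pattern set.

    Each repetition holds out ``complement_fraction`` of the patterns,
    trains on the remainder and reports the complement RMSE
    sqrt(mean (q - y)^2) over all held-out components.  Partitions that
    would leave the training side without both classes are redrawn.
    """
    work = ts.expanded() if cfg.weighting == "replicate" else ts
    n = len(work)
    v = max(1, round(cfg.complement_fraction * n))
    if v >= n:
        raise ValueError("complement would swallow the whole set")
    rng = np.random.default_rng(cfg.seed)
    reps = []
    for _ in range(cfg.repetitions):
        for attempt in range(100):
            perm = rng.permutation(n)
            comp, tr = perm[:v], perm[v:]
            if len(np.unique(work.Q[tr], axis=0)) == 2:
                break
            logger.info("degenerate CV partition (single-class training set); redrawing")
        else:  # pragma: no cover - essentially impossible for real data
            raise RuntimeError("could not draw a two-class training partition")
        sub_cfg = TrainingConfig(
            **{**asdict(cfg), "seed": int(rng.integers(2**31)), "weighting": "gradient"}
        )
        res = train(work.subset(tr), sub_cfg)
        Y = forward_batch(res.params, work.X[comp])
        rmse = float(np.sqrt(np.mean((work.Q[comp] - Y) ** 2)))
        reps.append(CVRepetition(rmse, len(comp), len(tr), res.final_error))
    return CVReport(reps)


def save_params(params: MLPParams, path, config: TrainingConfig | None = None) -> None:
    """JSON weight snapshot; floats round-trip bit-exactly via repr."""
    payload = {
        "shape": [N_INPUT, N_HIDDEN, N_OUTPUT],
        "w1": params.w1.tolist(),
        "b1": params.b1.tolist(),
        "w2": params.w2.tolist(),
        "b2": params.b2.tolist(),
    }
    if config is not None:
        payload["config"] = asdict(config)
    Path(path).write_text(json.dumps(payload) + "\n")


def load_params(path) -> tuple[MLPParams, TrainingConfig | None]:
    payload = json.loads(Path(path).read_text())
    if payload.get("shape") != [N_INPUT, N_HIDDEN, N_OUTPUT]:
        raise ValueError(f"unexpected network shape {payload.get('shape')}")
    params = MLPParams(
        np.asarray(payload["w1"]),
        np.asarray(payload["b1"]),
        np.asarray(payload["w2"]),
        np.asarray(payload["b2"]),
    )
    cfg = TrainingConfig(**payload["config"]) if "config" in payload else None
    return params, cfg
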