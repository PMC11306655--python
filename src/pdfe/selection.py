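"""Neighborhood component analysis (NCA) feature weighting and the
iterative top-k selection loop (INCA).

NCA assigns each feature a nonnegative relevance weight by maximizing the
regularized expected leave-one-out classification mass of a soft-neighbor
model. With weighted Manhattan distance

    d_w(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr|,

reference probabilities are the softmax of -d_w / sigma over all other
samples,

    p_ij = exp(-d_w(x_i, x_j) / sigma) / sum_{l != i} exp(-d_w(x_i, x_l) / sigma),

the per-sample correct-neighbor mass is p_i = sum over same-class j of
p_ij, and the objective is

    xi(w) = sum_i p_i - lambda * sum_r w_r^2,

maximized by gradient ascent from the all-ones weight vector with an
adaptive step (a step that would decrease the objective is halved and
retried, so the accepted objective trace is non-decreasing). The analytic
gradient is

    d xi / d w_r = (2 w_r / sigma) * sum_{i != j} p_ij (p_i - [y_j = y_i]) |x_ir - x_jr|
                   - 2 lambda w_r.

The iterative selector (INCA) then sorts features by weight (descending,
ties to the lower column index), and for every subset size k in a loop
range (default 1..500) scores the top-k prefix by the stratified
cross-validated misclassification rate of a 1-NN Euclidean classifier,
using one fixed fold assignment for every k; the k with the smallest loss
wins, ties going to the smallest k.

The pairwise |x_ir - x_jr| accumulation never materializes the full
pairs-by-features array: it streams over fixed-size column blocks (JIT
kernels when numba is importable, blocked NumPy otherwise), keeping the
per-block working set in cache. Blocking only reorders exact partial sums,
so blocked and unblocked results agree to floating-point roundoff
(verified in tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, NumericalError, ValidationError

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

__all__ = [
    "NCAConfig",
    "NCAWeights",
    "SelectionResult",
    "nca_weights",
    "nca_objective_grad",
    "inca_select",
    "select_features",
]


@dataclass(frozen=True)
class NCAConfig:
    """Hyperparameters of the NCA weighting stage.

    sigma: softmax kernel width of the neighbor model. The default
        ("auto") uses the standard deviation of the initial (all-ones
        weight) pairwise distances, so the soft-neighbor probabilities
        start informative at any feature-space width. A fixed width such
        as 1 collapses to winner-take-all once distances grow with the
        feature count, and in that limit the gradient vanishes
        identically.
    lambda_reg: L2 weight penalty; None means 1/n_samples at fit time.
    max_iters: gradient-ascent iteration cap.
    learning_rate: initial step size; halved when a step would decrease the
        objective, grown 10% after each accepted step.
    standardize: center/scale columns first (zero-variance columns zeroed).
        On by default so the weighting reflects discrimination rather than
        raw feature scale.
    tol: relative objective improvement below which ascent stops early.
        The default (1e-4) is deliberately loose: the weights feed a
        ranking, and running deep into the saturated regime only lets the
        penalty erode the ordering of correlated informative features
        while chance-correlated noise stays inflated.
    chunk_size: feature columns per block in the pairwise-distance passes;
        results are independent of this value.
    seed: reserved for stochastic variants; the ascent itself is
        deterministic.
    """

    sigma: float | str = "auto"
    lambda_reg: float | None = None
    max_iters: int = 100
    learning_rate: float = 0.01
    standardize: bool = True
    tol: float = 1e-4
    chunk_size: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if isinstance(self.sigma, str):
            if self.sigma != "auto":
                raise ConfigurationError(
                    f"sigma must be a positive number or 'auto', got {self.sigma!r}"
                )
        elif self.sigma <= 0:
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma}")
        if self.lambda_reg is not None and self.lambda_reg < 0:
            raise ConfigurationError(
                f"lambda_reg must be >= 0, got {self.lambda_reg}"
            )
        if self.max_iters < 1:
            raise ConfigurationError(f"max_iters must be >= 1, got {self.max_iters}")
        if self.learning_rate <= 0:
            raise ConfigurationError(
                f"learning_rate must be > 0, got {self.learning_rate}"
            )
        if self.chunk_size < 1:
            raise ConfigurationError(f"chunk_size must be >= 1, got {self.chunk_size}")


@dataclass
class NCAWeights:
    weights: np.ndarray  # nonnegative, one per feature
    objective_trace: list[float]
    converged: bool


@dataclass
class SelectionResult:
    """Outcome of the INCA loop."""

    ranked_indices: np.ndarray  # all features, weight-descending
    k_min: int
    k_max: int
    ks: np.ndarray  # subset sizes actually evaluated
    losses: np.ndarray  # CV misclassification rate per k, aligned with ks
    chosen_k: int
    selected_indices: np.ndarray  # first chosen_k ranked indices
    loss_folds: int
    seed: int

    def to_json(self, path: str | Path, config_echo: dict | None = None) -> Path:
        payload = {
            "k_min": self.k_min,
            "k_max": self.k_max,
            "chosen_k": self.chosen_k,
            "selected_indices": [int(i) for i in self.selected_indices],
            "ranked_indices_head": [int(i) for i in self.ranked_indices[: self.k_max]],
            "ks": [int(k) for k in self.ks],
            "losses": [float(v) for v in self.losses],
            "loss_folds": self.loss_folds,
            "seed": self.seed,
            "config": config_echo or {},
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0, dtype=np.float64)
    sd = X.std(axis=0, dtype=np.float64)
    out = X.astype(X.dtype, copy=True)
    nz = sd > 0
    out[:, nz] = (X[:, nz] - mu[nz].astype(X.dtype)) / sd[nz].astype(X.dtype)
    out[:, ~nz] = 0
    return out


_BLOCK = 4096  # feature columns per cache block in the pairwise passes

if _HAVE_NUMBA:

    @njit(fastmath=True, cache=False)
    def _dw_pairs_jit(X, iu, ju, w2):  # pragma: no cover - exercised via wrapper
        n_pairs = iu.size
        p = X.shape[1]
        out = np.zeros(n_pairs, np.float64)
        for lo in range(0, p, _BLOCK):
            hi = min(lo + _BLOCK, p)
            for t in range(n_pairs):
                i = iu[t]
                j = ju[t]
                s = 0.0
                for r in range(lo, hi):
                    s += w2[r] * abs(X[i, r] - X[j, r])
                out[t] += s
        return out

    @njit(fastmath=True, cache=False)
    def _grad_pairs_jit(X, iu, ju, m):  # pragma: no cover - exercised via wrapper
        n_pairs = iu.size
        p = X.shape[1]
        out = np.zeros(p, np.float64)
        for lo in range(0, p, _BLOCK):
            hi = min(lo + _BLOCK, p)
            for t in range(n_pairs):
                i = iu[t]
                j = ju[t]
                mt = m[t]
                for r in range(lo, hi):
                    out[r] += mt * abs(X[i, r] - X[j, r])
        return out


def _pair_dist(Xs: np.ndarray, iu: np.ndarray, ju: np.ndarray,
               w2: np.ndarray, chunk: int = _BLOCK) -> np.ndarray:
    """sum_r w_r^2 |x_ir - x_jr| for every unordered pair, blocked over r."""
    w2 = np.ascontiguousarray(w2, dtype=np.float64)
    if _HAVE_NUMBA:
        return _dw_pairs_jit(Xs, iu, ju, w2)
    d = np.zeros(len(iu), dtype=np.float64)
    for lo in range(0, Xs.shape[1], chunk):
        hi = min(lo + chunk, Xs.shape[1])
        A = np.abs(Xs[iu, lo:hi] - Xs[ju, lo:hi])
        d += A.astype(np.float64) @ w2[lo:hi]
    return d


def _pair_weighted_sum(Xs: np.ndarray, iu: np.ndarray, ju: np.ndarray,
                       coeff: np.ndarray, chunk: int = _BLOCK) -> np.ndarray:
    """sum over pairs of coeff_pair * |x_ir - x_jr|, per feature r."""
    coeff = np.ascontiguousarray(coeff, dtype=np.float64)
    if _HAVE_NUMBA:
        return _grad_pairs_jit(Xs, iu, ju, coeff)
    g = np.empty(Xs.shape[1], dtype=np.float64)
    for lo in range(0, Xs.shape[1], chunk):
        hi = min(lo + chunk, Xs.shape[1])
        A = np.abs(Xs[iu, lo:hi] - Xs[ju, lo:hi])
        g[lo:hi] = coeff @ A.astype(np.float64)
    return g


def _soft_neighbors(n: int, iu: np.ndarray, ju: np.ndarray, d_pairs: np.ndarray,
                    sigma: float) -> np.ndarray:
    """Row-stochastic reference probabilities p_ij from pair distances."""
    D = np.zeros((n, n), dtype=np.float64)
    D[iu, ju] = d_pairs
    D[ju, iu] = d_pairs
    logits = -D / sigma
    np.fill_diagonal(logits, -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=1, keepdims=True)
    return P


def nca_objective_grad(
    Xs: np.ndarray, y: np.ndarray, w: np.ndarray, sigma: float, lam: float,
    chunk: int = 100_000,
) -> tuple[float, np.ndarray]:
    """Objective xi(w) and its analytic gradient at w (standardized X)."""
    n = Xs.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w2 = (w * w).astype(np.float64)
    d_pairs = _pair_dist(Xs, iu, ju, w2, chunk)
    P = _soft_neighbors(n, iu, ju, d_pairs, sigma)
    same = (y[:, None] == y[None, :]).astype(np.float64)
    np.fill_diagonal(same, 0.0)
    p_i = (P * same).sum(axis=1)
    obj = float(p_i.sum() - lam * w2.sum())
    # ordered-pair coefficient K_ij = p_ij (p_i - [y_j == y_i]); fold the two
    # orderings of each unordered pair together since |delta| is symmetric
    K = P * (p_i[:, None] - same)
    M = K[iu, ju] + K[ju, iu]
    g = _pair_weighted_sum(Xs, iu, ju, M, chunk)
    grad = (2.0 / sigma) * w * g - 2.0 * lam * w
    return obj, grad


def nca_weights(X: np.ndarray, y: np.ndarray, config: NCAConfig | None = None) -> NCAWeights:
    """Fit NCA feature weights by adaptive gradient ascent from all-ones."""
    config = config or NCAConfig()
    config.validate()
    X = np.asarray(X)
    y = np.asarray(y)
    n, p = X.shape
    if n < 2:
        raise ValidationError(f"need at least 2 samples, got {n}")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present to fit NCA weights")
    lam = config.lambda_reg if config.lambda_reg is not None else 1.0 / n
    Xs = _standardize(X) if config.standardize else X.astype(X.dtype, copy=True)

    n_pairs = n * (n - 1) // 2
    # keep each pairwise block under ~1.5 GB at float32
    chunk = min(config.chunk_size, max(1, int(3.5e8 / max(n_pairs, 1))))

    w = np.ones(p, dtype=np.float64)
    iu, ju = np.triu_indices(n, 1)
    same = (y[:, None] == y[None, :]).astype(np.float64)
    np.fill_diagonal(same, 0.0)

    d_init = _pair_dist(Xs, iu, ju, np.ones(p), chunk)
    if isinstance(config.sigma, str):  # "auto": width from the data
        sigma = float(d_init.std()) or float(d_init.mean()) or 1.0
    else:
        sigma = float(config.sigma)

    def finish(d_pairs: np.ndarray, w_vec: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        P = _soft_neighbors(n, iu, ju, d_pairs, sigma)
        p_i = (P * same).sum(axis=1)
        return float(p_i.sum() - lam * (w_vec * w_vec).sum()), P, p_i

    def objective_only(w_vec: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        w2 = (w_vec * w_vec).astype(np.float64)
        return finish(_pair_dist(Xs, iu, ju, w2, chunk), w_vec)

    obj, P, p_i = finish(d_init, w)
    if not np.isfinite(obj):
        raise NumericalError("non-finite NCA objective at initialization")
    trace = [obj]
    lr = config.learning_rate
    converged = False
    for it in range(config.max_iters):
        K = P * (p_i[:, None] - same)
        M = K[iu, ju] + K[ju, iu]
        g = _pair_weighted_sum(Xs, iu, ju, M, chunk)
        grad = (2.0 / sigma) * w * g - 2.0 * lam * w
        accepted = False
        for _ in range(25):
            w_new = w + lr * grad
            obj_new, P_new, p_i_new = objective_only(w_new)
            if not np.isfinite(obj_new):
                raise NumericalError(f"non-finite NCA objective at iteration {it}")
            if obj_new >= obj:
                accepted = True
                break
            lr *= 0.5
        if not accepted:
            converged = True
            break
        improvement = obj_new - obj
        w, obj, P, p_i = w_new, obj_new, P_new, p_i_new
        trace.append(obj)
        lr *= 1.1
        if improvement <= config.tol * max(1.0, abs(obj)):
            converged = True
            break
    return NCAWeights(weights=np.abs(w), objective_trace=trace, converged=converged)


def rank_features(weights: np.ndarray) -> np.ndarray:
    """Feature indices by weight descending, ties to the lower index."""
    return np.argsort(-np.asarray(weights), kind="stable")


def _fold_scale(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0, dtype=np.float64)
    sd = train.std(axis=0, dtype=np.float64)
    sd[sd == 0] = np.inf  # zero-variance column contributes nothing
    return mu, sd


def inca_select(
    X: np.ndarray,
    y: np.ndarray,
    weights: NCAWeights | np.ndarray,
    k_min: int = 1,
    k_max: int = 500,
    loss_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> SelectionResult:
    """Scan top-k prefixes of the weight ranking; keep the k with least loss.

    For each k in [k_min, min(k_max, n_features)] the loss is the pooled
    stratified ``loss_folds``-fold CV misclassification rate of the 1-NN
    Euclidean classifier on the top-k columns; the fold assignment is fixed
    by ``seed`` once and reused for every k. Per-fold standardization (on
    by default, matching the weighting stage) is fitted on the training
    rows only. Distances for all k come from one cumulative sum over the
    ranked feature axis, so the whole loop costs a single pass per fold.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    w = weights.weights if isinstance(weights, NCAWeights) else np.asarray(weights)
    n, p = X.shape
    if len(w) != p:
        raise ValidationError(f"weights length {len(w)} != n_features {p}")
    if not (1 <= k_min <= k_max):
        raise ConfigurationError(f"need 1 <= k_min <= k_max, got [{k_min}, {k_max}]")
    if n < loss_folds:
        raise ValidationError(
            f"n_samples={n} < loss_folds={loss_folds}; use fewer folds"
        )
    counts = np.bincount(y.astype(np.int64))
    if counts[counts > 0].min() < loss_folds:
        raise ValidationError(
            f"smallest class has {counts[counts > 0].min()} samples, fewer than "
            f"loss_folds={loss_folds}; use fewer folds"
        )

    ranked = rank_features(w)
    k_hi = min(k_max, p)
    if k_min > k_hi:
        raise ConfigurationError(f"k_min={k_min} exceeds n_features={p}")
    ks = np.arange(k_min, k_hi + 1)
    Xr = np.ascontiguousarray(X[:, ranked[:k_hi]], dtype=np.float64)

    errors = np.zeros(len(ks), dtype=np.int64)
    skf = StratifiedKFold(n_splits=loss_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(Xr, y):
        if standardize:
            mu, sd = _fold_scale(Xr[train_idx])
            tr = (Xr[train_idx] - mu) / sd
            te = (Xr[test_idx] - mu) / sd
        else:
            tr, te = Xr[train_idx], Xr[test_idx]
        # cumulative squared distance over the ranked feature axis
        sq = (te[:, None, :] - tr[None, :, :]) ** 2
        np.cumsum(sq, axis=2, out=sq)
        nn = sq[:, :, ks - 1].argmin(axis=1)  # (n_test, len(ks))
        preds = y[train_idx][nn]
        errors += (preds != y[test_idx][:, None]).sum(axis=0)

    losses = errors / n
    best = int(np.argmin(losses))  # first minimum -> smallest k
    chosen_k = int(ks[best])
    return SelectionResult(
        ranked_indices=ranked,
        k_min=k_min,
        k_max=k_max,
        ks=ks,
        losses=losses,
        chosen_k=chosen_k,
        selected_indices=ranked[:chosen_k].copy(),
        loss_folds=loss_folds,
        seed=seed,
    )


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    nca_config: NCAConfig | None = None,
    k_min: int = 1,
    k_max: int = 500,
    loss_folds: int = 10,
    seed: int = 0,
) -> tuple[NCAWeights, SelectionResult]:
    """Convenience wrapper: NCA weighting followed by the INCA loop.

    The loss CV inherits the weighting stage's standardize setting so both
    stages see features on the same scale.
    """
    nca_config = nca_config or NCAConfig()
    w = nca_weights(X, y, nca_config)
    res = inca_select(X, y, w, k_min=k_min, k_max=k_max,
                      loss_folds=loss_folds, seed=seed,
                      standardize=nca_config.standardize)
    return w, res
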