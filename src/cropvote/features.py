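"""Feature engineering: SVM importance, NGD correlation, Rising-Star ranking.

The stage runs, in order:

1. a linear SVM is trained in the primal (hinge loss, L2 penalty) by
   deterministic subgradient descent; the absolute weight |W_j| is the
   importance of feature j;
2. the top-m features by importance are kept for correlation analysis;
3. the pairwise Normalized Google Distance of the selected features is
   computed from occurrence counts — here, counts of above-median indicator
   events over the training samples (N = sample count), the data-driven
   analogue of web co-occurrence frequencies; low NGD means the features
   carry near-identical information;
4. redundant pairs (NGD below a threshold tau) are pruned greedily, keeping
   the higher-importance member;
5. each feature receives a Rising-Star score S = α·P + β·R combining its
   historical mean importance P over a sequence of chronological refits with
   its most recent importance R, and features are ranked by S descending.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Linear SVM (primal hinge loss, deterministic subgradient descent)
# ---------------------------------------------------------------------------


@dataclass
class LinearSVMModel:
    W: np.ndarray
    b: float
    C: float
    objective_value: float
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True


def svm_objective(W: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, C: float) -> float:
    """½‖W‖² + C·Σ max(0, 1 − y_i(W·x_i + b)) with y in {−1,+1}."""
    margins = y * (X @ W + b)
    hinge = np.maximum(0.0, 1.0 - margins)
    return 0.5 * float(W @ W) + C * float(hinge.sum())


def _smoothed_obj_grad(W, b, X, ys, C, mu):
    """Huberized-hinge objective and gradient (smoothing parameter mu)."""
    z = 1.0 - ys * (X @ W + b)
    quad = (z > 0) & (z < mu)
    lin = z >= mu
    val = 0.5 * W @ W + C * (np.sum(z[lin] - mu / 2) + np.sum(z[quad] ** 2 / (2 * mu)))
    dz = np.zeros_like(z)
    dz[lin] = 1.0
    dz[quad] = z[quad] / mu
    coef = -C * dz * ys
    return float(val), W + X.T @ coef, float(coef.sum())


_MU_SCHEDULE = (0.5, 0.1, 0.02, 4e-3, 8e-4, 1.6e-4, 3e-5, 6e-6, 1e-6)


def train_linear_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-10,
    seed: int = 0,
) -> LinearSVMModel:
    """Minimize the primal hinge objective deterministically.

    The nonsmooth hinge is annealed through a Huberized (quadratically
    smoothed) family with a decreasing smoothing parameter; each stage runs
    gradient descent with Armijo backtracking (``max_iter`` steps per
    stage). The best true-hinge iterate seen is retained and its running
    minimum reported as the trace, so the trace is non-increasing by
    construction. Labels in {0, 1} map to {−1, +1} internally; the seed only
    sets the tiny random initialization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise FeatureError("SVM input contains non-finite values")
    classes = np.unique(y)
    if len(classes) != 2:
        raise FeatureError("SVM needs exactly two classes")
    if set(classes) == {0.0, 1.0}:
        y = np.where(y > 0, 1.0, -1.0)
    elif set(classes) != {-1.0, 1.0}:
        raise FeatureError("labels must be {0,1} or {-1,+1}")

    n, F = X.shape
    rng = np.random.default_rng(seed)
    W = 0.01 * rng.standard_normal(F)
    b = 0.0
    best_obj = svm_objective(W, b, X, y, C)
    best_W, best_b = W.copy(), b
    trace = [best_obj]
    before_final = best_obj
    for stage, mu in enumerate(_MU_SCHEDULE):
        if stage == len(_MU_SCHEDULE) - 1:
            before_final = best_obj
        eta = 1.0
        val, g_W, g_b = _smoothed_obj_grad(W, b, X, y, C, mu)
        for _ in range(max_iter):
            g2 = g_W @ g_W + g_b * g_b
            while eta > 1e-16:
                W2, b2 = W - eta * g_W, b - eta * g_b
                v2, g2W, g2b = _smoothed_obj_grad(W2, b2, X, y, C, mu)
                if v2 <= val - 1e-4 * eta * g2:
                    break
                eta *= 0.5
            if eta <= 1e-16:
                break
            W, b, val, g_W, g_b = W2, b2, v2, g2W, g2b
            eta *= 1.3
            obj = svm_objective(W, b, X, y, C)
            if obj < best_obj:
                best_obj, best_W, best_b = obj, W.copy(), b
            trace.append(best_obj)
            if np.sqrt(g_W @ g_W + g_b * g_b) < tol * (1.0 + abs(val)):
                break
    # converged when the final (smallest-smoothing) stage no longer moves
    # the true hinge objective materially
    converged = (before_final - best_obj) <= 1e-4 * (1.0 + abs(best_obj))
    if not converged:
        logger.warning("SVM may not have converged; final objective %.6g", best_obj)
    return LinearSVMModel(W=best_W, b=float(best_b), C=C, objective_value=best_obj,
                          objective_trace=trace, converged=converged)


def feature_importance(model: LinearSVMModel) -> np.ndarray:
    """Importance of feature j is |W_j|."""
    return np.abs(model.W)


def select_top_m(importance: np.ndarray, m: int) -> list[int]:
    """Indices of the m most important features, importance-descending.

    Ties break toward the lower feature index.
    """
    importance = np.asarray(importance, dtype=float)
    if not (1 <= m <= len(importance)):
        raise FeatureError(f"m must be in [1, {len(importance)}], got {m}")
    order = np.lexsort((np.arange(len(importance)), -importance))
    return [int(i) for i in order[:m]]


# ---------------------------------------------------------------------------
# NGD correlation
# ---------------------------------------------------------------------------


@dataclass
class BinaryOccurrence:
    """Above-threshold indicator events and their (joint) counts."""

    indicators: np.ndarray  # samples × features, 0/1
    counts: np.ndarray  # per-feature event counts f(x_i)
    joint: np.ndarray  # pairwise joint counts f(x_i ∩ x_j)
    N: int

    def __post_init__(self) -> None:
        if (self.counts > self.N).any():
            raise FeatureError("event count exceeds sample count")
        if not np.allclose(self.joint, self.joint.T):
            raise FeatureError("joint counts must be symmetric")


def binarize_features(X: np.ndarray, thresholds: np.ndarray | None = None) -> BinaryOccurrence:
    """Turn numeric features into occurrence events: value > per-feature median.

    Custom thresholds may be supplied (e.g. training medians when binarizing
    held-out data). Counts and pairwise joint counts feed the NGD matrix.
    """
    X = np.asarray(X, dtype=float)
    if thresholds is None:
        thresholds = np.median(X, axis=0)
    ind = (X > thresholds).astype(float)
    joint = ind.T @ ind
    return BinaryOccurrence(
        indicators=ind.astype(int),
        counts=ind.sum(axis=0).astype(int),
        joint=joint.astype(int),
        N=X.shape[0],
    )


def ngd(f_i: int, f_j: int, f_ij: int, N: int) -> float:
    """Normalized Google Distance from occurrence counts.

    [max(log f_i, log f_j) − log f_ij] / [log N − min(log f_i, log f_j)].
    Base-independent. Degenerate cases map to finite sentinels: a zero joint
    or marginal count is maximally dissimilar (1.0); a feature occurring in
    every sample gives distance 0.0 only when the pair is literally
    identical, else 1.0.
    """
    if N < 1:
        raise FeatureError("N must be >= 1")
    if f_ij > min(f_i, f_j) or max(f_i, f_j) > N or min(f_i, f_j, f_ij) < 0:
        raise FeatureError("inconsistent occurrence counts")
    if f_i == 0 or f_j == 0 or f_ij == 0:
        return 1.0
    denom = np.log(N) - min(np.log(f_i), np.log(f_j))
    if denom == 0.0:
        return 0.0 if f_ij == f_i == f_j else 1.0
    num = max(np.log(f_i), np.log(f_j)) - np.log(f_ij)
    return float(num / denom)


def ngd_matrix(occ: BinaryOccurrence) -> np.ndarray:
    """Symmetric NGD matrix over the occurrence features; zero diagonal for
    non-degenerate (nonzero-count) features."""
    F = len(occ.counts)
    C = np.zeros((F, F))
    for i in range(F):
        C[i, i] = ngd(int(occ.counts[i]), int(occ.counts[i]), int(occ.joint[i, i]), occ.N)
        for j in range(i + 1, F):
            C[i, j] = C[j, i] = ngd(
                int(occ.counts[i]), int(occ.counts[j]), int(occ.joint[i, j]), occ.N
            )
    return C


def prune_redundant(C: np.ndarray, importance: np.ndarray, tau: float):
    """Drop the weaker member of each near-duplicate pair (NGD < tau).

    Pairs are scanned in ascending NGD order (most redundant first); a pair
    is skipped when either member is already gone. Importance ties drop the
    higher index. Returns (kept indices, drop log).
    """
    if not (0.0 <= tau <= 1.0):
        raise FeatureError("tau must be in [0, 1]")
    F = C.shape[0]
    pairs = [(C[i, j], i, j) for i in range(F) for j in range(i + 1, F) if C[i, j] < tau]
    pairs.sort()
    dropped: set[int] = set()
    log: list[dict] = []
    for c_ij, i, j in pairs:
        if i in dropped or j in dropped:
            continue
        if importance[i] > importance[j]:
            victim, keeper = j, i
        elif importance[j] > importance[i]:
            victim, keeper = i, j
        else:
            victim, keeper = max(i, j), min(i, j)
        dropped.add(victim)
        log.append({"dropped": victim, "kept": keeper, "ngd": float(c_ij)})
    kept = [i for i in range(F) if i not in dropped]
    return kept, log


# ---------------------------------------------------------------------------
# Rising-Star ranking
# ---------------------------------------------------------------------------


def rising_star_scores(weight_history: np.ndarray, alpha: float = 0.5, beta: float = 0.5) -> np.ndarray:
    """S_i = α·P_i + β·R_i.

    P_i is the mean absolute weight of feature i over the T historical model
    fits (rows of ``weight_history``); R_i is its absolute weight in the most
    recent fit (last row).
    """
    H = np.atleast_2d(np.asarray(weight_history, dtype=float))
    if H.size == 0:
        raise FeatureError("weight history is empty")
    if alpha < 0 or beta < 0 or alpha + beta == 0:
        raise FeatureError("alpha, beta must be nonnegative with alpha + beta > 0")
    A = np.abs(H)
    P = A.mean(axis=0)
    R = A[-1]
    return alpha * P + beta * R


def rank_features(scores: np.ndarray) -> list[int]:
    """Feature indices by score descending; ties toward the lower index."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise FeatureError("scores must be finite")
    order = np.lexsort((np.arange(len(scores)), -scores))
    return [int(i) for i in order]


# ---------------------------------------------------------------------------
# End-to-end report
# ---------------------------------------------------------------------------


@dataclass
class FeatureConfig:
    m: int | None = None  # top-m cut; None keeps all features
    tau: float = 0.1
    T: int = 5  # chronological refits for the weight history
    alpha: float = 0.5
    beta: float = 0.5
    svm_C: float = 1.0
    svm_max_iter: int = 200
    seed: int = 0


@dataclass
class FeatureReport:
    feature_names: list[str]
    importance: dict[str, float]
    selected_m: list[str]
    ngd: list[list[float]]  # over selected_m, in that order
    pruned: list[dict]
    kept: list[str]
    weight_history: list[list[float]]  # T × selected features
    scores: dict[str, float]
    ranked: list[str]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FeatureReport":
        return cls(**json.loads(text))


def feature_engineering(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    config: FeatureConfig | None = None,
    timestamps: np.ndarray | None = None,
) -> FeatureReport:
    """Run the full stage: SVM → top-m → NGD → prune → Rising-Star → rank.

    ``timestamps`` orders the samples chronologically for the T expanding
    refits behind the Rising-Star history (row order is used when absent).
    The ranked list covers the kept (post-pruning) features.
    """
    config = config or FeatureConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, F = X.shape
    names = feature_names if feature_names is not None else [f"f{i}" for i in range(F)]
    if len(names) != F:
        raise FeatureError("feature_names length mismatch")

    model = train_linear_svm(X, y, C=config.svm_C, max_iter=config.svm_max_iter, seed=config.seed)
    imp = feature_importance(model)
    m = config.m if config.m is not None else F
    selected = select_top_m(imp, m)

    occ = binarize_features(X[:, selected])
    C = ngd_matrix(occ)
    kept_local, drop_log = prune_redundant(C, imp[selected], config.tau)
    kept = [selected[i] for i in kept_local]
    pruned = [
        {
            "dropped": names[selected[e["dropped"]]],
            "kept": names[selected[e["kept"]]],
            "ngd": e["ngd"],
        }
        for e in drop_log
    ]

    history = _weight_history(X[:, kept], y, config, timestamps)
    scores = rising_star_scores(history, config.alpha, config.beta)
    ranked_local = rank_features(scores)
    ranked = [kept[i] for i in ranked_local]

    return FeatureReport(
        feature_names=list(names),
        importance={names[j]: float(imp[j]) for j in range(F)},
        selected_m=[names[j] for j in selected],
        ngd=C.tolist(),
        pruned=pruned,
        kept=[names[j] for j in kept],
        weight_history=history.tolist(),
        scores={names[kept[i]]: float(scores[i]) for i in range(len(kept))},
        ranked=[names[j] for j in ranked],
    )


def _weight_history(X: np.ndarray, y: np.ndarray, config: FeatureConfig,
                    timestamps: np.ndarray | None) -> np.ndarray:
    """T refits on chronologically expanding windows; rows are weight vectors.

    The earliest window holds the first 1/T of the samples, the last window
    is the full training set ("most recent model"). Windows too small to
    contain both classes inherit the previous row's weights.
    """
    n = len(y)
    order = np.argsort(timestamps, kind="stable") if timestamps is not None else np.arange(n)
    T = max(1, min(config.T, n))
    rows = []
    prev = np.zeros(X.shape[1])
    for t in range(1, T + 1):
        upto = int(round(n * t / T))
        idx = order[:max(upto, 2)]
        if len(np.unique(y[idx])) < 2:
            rows.append(prev.copy())
            continue
        model = train_linear_svm(
            X[idx], y[idx], C=config.svm_C, max_iter=config.svm_max_iter, seed=config.seed
        )
        prev = model.W
        rows.append(model.W.copy())
    return np.vstack(rows)
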