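"""ADASYN: adaptive synthetic oversampling of the minority class.

Implements the classic ADASYN scheme with full provenance. Given a numeric,
already-scaled training matrix with binary labels:

1. imbalance ratio r = N_maj / N_min;
2. for each minority sample, d_i = number of majority samples among its k
   nearest neighbors in the *whole* dataset (Euclidean, self excluded) and
   difficulty r_i = d_i / k — minority points deep in majority territory are
   the hardest;
3. G = N_maj − N_min synthetic samples are allocated proportionally to the
   normalized difficulties r̂_i = r_i / Σ r_j, with largest-remainder
   rounding so the counts sum to exactly G (uniform allocation when all
   difficulties are zero);
4. each synthetic row interpolates its parent towards a uniformly chosen one
   of the parent's k nearest *minority* neighbors:
   x_new = x_i + δ·(x_nn − x_i), δ ~ U(0, 1).

Neighbor searches for the difficulty measure span both classes (that is what
makes r_i a difficulty), while interpolation partners are restricted to the
minority class so synthetic rows stay inside minority territory. Distance
ties break toward the lower row index. Every synthetic row records
(parent index, neighbor index, δ) so it can be reconstructed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class BalanceError(ValueError):
    pass


@dataclass
class AdasynConfig:
    k: int = 5
    G_override: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise BalanceError("k must be >= 1")
        if self.G_override is not None and self.G_override < 0:
            raise BalanceError("G_override must be nonnegative")


@dataclass
class AdasynResult:
    X_balanced: np.ndarray
    y_balanced: np.ndarray
    provenance: list[tuple[int, int, float]]  # (parent row, neighbor row, delta)
    r: float
    d: np.ndarray  # per-minority majority-neighbor counts
    r_i: np.ndarray
    G_i: np.ndarray
    minority_label: int
    minority_indices: np.ndarray  # rows of X holding the minority class

    @property
    def n_synthetic(self) -> int:
        return len(self.provenance)


def imbalance_ratio(y: np.ndarray) -> float:
    """Majority count over minority count; >= 1. Errors on one class."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise BalanceError("imbalance ratio needs both classes present")
    if len(classes) > 2:
        raise BalanceError("binary labels expected")
    return float(counts.max() / counts.min())


def _knn_indices(X: np.ndarray, query: np.ndarray, k: int, exclude: int | None = None) -> np.ndarray:
    """Indices of the k nearest rows of X to `query` (ties: lower index)."""
    d2 = np.einsum("ij,ij->i", X - query, X - query)
    if exclude is not None:
        d2 = d2.copy()
        d2[exclude] = np.inf
    # stable sort on distance keeps lower indices first among exact ties
    order = np.argsort(d2, kind="stable")
    return order[:k]


def neighbor_difficulty(X: np.ndarray, y: np.ndarray, k: int, minority_label: int | None = None):
    """Per-minority-sample (d_i, r_i) from k-NN over the whole dataset.

    Returns (minority_indices, d, r_i).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise BalanceError("feature matrix must be fully numeric and finite (one-hot first)")
    if k >= len(X):
        raise BalanceError("k must be smaller than the number of samples")
    if minority_label is None:
        minority_label = _minority_label(y)
    minority_idx = np.flatnonzero(y == minority_label)
    d = np.empty(len(minority_idx), dtype=int)
    for j, i in enumerate(minority_idx):
        nn = _knn_indices(X, X[i], k, exclude=int(i))
        d[j] = int(np.sum(y[nn] != minority_label))
    return minority_idx, d, d / k


def allocate_counts(r_list: np.ndarray, G: int) -> np.ndarray:
    """Difficulty-proportional integer allocation summing exactly to G.

    Difficulties are normalized to a distribution; counts are rounded by the
    largest-remainder rule. All-zero difficulties allocate uniformly.
    """
    if G < 0:
        raise BalanceError("G must be nonnegative")
    r = np.asarray(r_list, dtype=float)
    if G == 0 or len(r) == 0:
        return np.zeros(len(r), dtype=int)
    total = r.sum()
    share = np.full(len(r), 1.0 / len(r)) if total == 0 else r / total
    exact = share * G
    counts = np.floor(exact).astype(int)
    remainder = G - counts.sum()
    if remainder > 0:
        frac = exact - counts
        # largest remainders first; ties toward lower index
        order = np.lexsort((np.arange(len(r)), -frac))
        counts[order[:remainder]] += 1
    return counts


def synthesize(
    X_min: np.ndarray,
    allocations: np.ndarray,
    k: int,
    seed: int,
    minority_rows: np.ndarray | None = None,
):
    """Interpolate synthetic minority rows; returns (rows, provenance).

    Provenance entries are (parent, neighbor, δ) where parent/neighbor are
    indices into the original matrix when ``minority_rows`` maps minority
    positions back to it, else positions within ``X_min``.
    """
    X_min = np.asarray(X_min, dtype=float)
    if len(X_min) < 2:
        raise BalanceError("interpolation needs at least 2 minority samples")
    if k >= len(X_min):
        raise BalanceError("k must be smaller than the minority count for synthesis")
    allocations = np.asarray(allocations, dtype=int)
    rng = np.random.default_rng(seed)
    rows = []
    provenance: list[tuple[int, int, float]] = []
    ident = np.arange(len(X_min)) if minority_rows is None else np.asarray(minority_rows)
    for pos, g in enumerate(allocations):
        if g <= 0:
            continue
        neighbors = _knn_indices(X_min, X_min[pos], k, exclude=pos)
        for _ in range(int(g)):
            nn = int(rng.integers(0, len(neighbors)))
            nn_pos = int(neighbors[nn])
            delta = float(rng.uniform(0.0, 1.0))
            rows.append(X_min[pos] + delta * (X_min[nn_pos] - X_min[pos]))
            provenance.append((int(ident[pos]), int(ident[nn_pos]), delta))
    X_new = np.vstack(rows) if rows else np.empty((0, X_min.shape[1]))
    return X_new, provenance


def adasyn_balance(X: np.ndarray, y: np.ndarray, config: AdasynConfig | None = None) -> AdasynResult:
    """Balance a binary training set by difficulty-weighted interpolation.

    Synthetic rows are appended after the untouched originals; by default
    exactly N_maj − N_min rows are generated so the classes end up equal.
    """
    config = config or AdasynConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    r = imbalance_ratio(y)
    minority_label = _minority_label(y)
    n_min = int(np.sum(y == minority_label))
    n_maj = len(y) - n_min
    G = (n_maj - n_min) if config.G_override is None else config.G_override

    if G == 0:
        return AdasynResult(
            X_balanced=X.copy(),
            y_balanced=y.copy(),
            provenance=[],
            r=r,
            d=np.zeros(n_min, dtype=int),
            r_i=np.zeros(n_min),
            G_i=np.zeros(n_min, dtype=int),
            minority_label=minority_label,
            minority_indices=np.flatnonzero(y == minority_label),
        )

    minority_idx, d, r_i = neighbor_difficulty(X, y, config.k, minority_label)
    G_i = allocate_counts(r_i, G)
    X_new, provenance = synthesize(
        X[minority_idx], G_i, config.k, config.seed, minority_rows=minority_idx
    )
    X_bal = np.vstack([X, X_new])
    y_bal = np.concatenate([y, np.full(len(X_new), minority_label, dtype=int)])
    return AdasynResult(
        X_balanced=X_bal,
        y_balanced=y_bal,
        provenance=provenance,
        r=r,
        d=d,
        r_i=r_i,
        G_i=G_i,
        minority_label=minority_label,
        minority_indices=minority_idx,
    )


def _minority_label(y: np.ndarray) -> int:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise BalanceError("binary labels expected with both classes present")
    if counts[0] == counts[1]:
        # convention: label 1 is the minority class on ties
        return 1 if 1 in classes else int(classes[0])
    return int(classes[np.argmin(counts)])
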