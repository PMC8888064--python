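"""Extreme learning machine: random hidden layer, closed-form output weights.

The hidden layer maps a P-dimensional feature vector x through L_h random
units h_i(x) = sigmoid(x·w_i + b_i), with w_i and b_i drawn once from a
continuous distribution (uniform on [−1, 1] here) and never trained.  With
H the m×L_h matrix of mapped training samples and T the m×M one-hot target
matrix, the output weights solve the least-squares objective ½‖Hβ − T‖²:

    β = H⁺ T                      (Moore–Penrose pseudoinverse), or
    β = (HᵀH + αI)⁻¹ Hᵀ T         (ridge/Tikhonov, α > 0)

Prediction is argmax over the columns of h(x)·β, ties going to the lowest
class index.  Features are z-scored column-wise (statistics from the
training split) before mapping by default — raw pixel-scale features would
saturate the sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElmModel",
    "one_hot",
    "init_hidden",
    "map_features",
    "solve_beta_pinv",
    "solve_beta_ridge",
    "fit",
    "predict",
    "decision_scores",
    "kfold_indices",
    "sweep_hidden_nodes",
]

DEFAULT_HIDDEN_NODES = 600
DEFAULT_ALPHA = 0.01
#: Hidden-node counts swept during model selection.
DEFAULT_CANDIDATES = (10, 100, 200, 400, 800, 1000, 2000)
#: Ridge levels swept when α is selected by cross-validation.  With a random
#: high-dimensional projection the right ridge level depends on how close L_h
#: is to the training-set size, so the pipeline picks it from data.
DEFAULT_ALPHA_CANDIDATES = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


@dataclass
class ElmModel:
    """Trained ELM: random hidden layer (W, b), ridge α and solved β."""

    W: np.ndarray  # L_h × P
    b: np.ndarray  # L_h
    alpha: float
    beta: np.ndarray | None  # L_h × M
    n_classes: int
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None

    @property
    def hidden_nodes(self) -> int:
        return self.W.shape[0]


def one_hot(label: int, n_classes: int = 3) -> np.ndarray:
    """Unit vector with a 1 at ``label``."""
    if not 0 <= label < n_classes:
        raise ValueError(f"label {label} outside [0, {n_classes})")
    v = np.zeros(n_classes)
    v[label] = 1.0
    return v


def _one_hot_matrix(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    T = np.zeros((labels.size, n_classes))
    T[np.arange(labels.size), labels] = 1.0
    return T


def init_hidden(P: int, L_h: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw hidden weights W (L_h×P) and biases b i.i.d. uniform on [−1, 1]."""
    if P < 1 or L_h < 1:
        raise ValueError("P and L_h must be >= 1")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(L_h, P))
    b = rng.uniform(-1.0, 1.0, size=L_h)
    return W, b


def map_features(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hidden-layer mapping H[n, i] = sigmoid(x_n·w_i + b_i)."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    Z = X @ W.T + b
    return 0.5 * (1.0 + np.tanh(0.5 * Z))


def solve_beta_pinv(H: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares output weights β = H⁺T."""
    H, T = np.asarray(H, dtype=float), np.asarray(T, dtype=float)
    if H.shape[0] != T.shape[0]:
        raise ValueError("H and T must have equal row counts")
    return np.linalg.pinv(H) @ T


def solve_beta_ridge(H: np.ndarray, T: np.ndarray, alpha: float) -> np.ndarray:
    """Ridge output weights β = (HᵀH + αI)⁻¹HᵀT."""
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    H, T = np.asarray(H, dtype=float), np.asarray(T, dtype=float)
    if H.shape[0] != T.shape[0]:
        raise ValueError("H and T must have equal row counts")
    L_h = H.shape[1]
    A = H.T @ H + alpha * np.eye(L_h)
    return np.linalg.solve(A, H.T @ T)


def fit(
    X: np.ndarray,
    labels: np.ndarray,
    hidden_nodes: int = DEFAULT_HIDDEN_NODES,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    n_classes: int = 3,
    standardize: bool = True,
) -> ElmModel:
    """Train an ELM on features X (N×P) and integer labels.

    α = 0 falls back to the pseudoinverse solve; α > 0 uses the ridge
    closed form.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if X.shape[0] != labels.size:
        raise ValueError("X rows and labels must align")
    mean = std = None
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        X = (X - mean) / std
    W, b = init_hidden(X.shape[1], hidden_nodes, seed)
    H = map_features(X, W, b)
    T = _one_hot_matrix(labels, n_classes)
    beta = solve_beta_pinv(H, T) if alpha == 0 else solve_beta_ridge(H, T, alpha)
    return ElmModel(
        W=W, b=b, alpha=alpha, beta=beta, n_classes=n_classes,
        feature_mean=mean, feature_std=std,
    )


def decision_scores(X: np.ndarray, model: ElmModel) -> np.ndarray:
    """Class scores h(x)·β for each row of X."""
    if model.beta is None:
        raise ValueError("model has no trained output weights")
    X = np.asarray(X, dtype=float)
    if model.feature_mean is not None:
        X = (X - model.feature_mean) / model.feature_std
    H = map_features(X, model.W, model.b)
    return H @ model.beta


def predict(X: np.ndarray, model: ElmModel) -> np.ndarray:
    """argmax of the class scores; ties break to the lowest class index."""
    return np.argmax(decision_scores(X, model), axis=1)


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Shuffle 0..n−1 and split into k folds whose sizes differ by ≤ 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def sweep_hidden_nodes(
    F: np.ndarray,
    labels: np.ndarray,
    candidates=DEFAULT_CANDIDATES,
    k: int = 4,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    n_classes: int = 3,
) -> tuple[list[tuple[int, float]], int]:
    """k-fold cross-validated accuracy for each hidden-node count.

    Returns the (L_h, mean accuracy) table and the best L_h (highest mean
    accuracy, first on ties).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes for model selection")
    F = np.asarray(F, dtype=float)
    folds = kfold_indices(F.shape[0], k, seed)
    table: list[tuple[int, float]] = []
    for L_h in candidates:
        accs = []
        for i, test_idx in enumerate(folds):
            train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
            model = fit(
                F[train_idx], labels[train_idx], hidden_nodes=L_h,
                alpha=alpha, seed=seed + i, n_classes=n_classes,
            )
            pred = predict(F[test_idx], model)
            accs.append(float(np.mean(pred == labels[test_idx])))
        table.append((L_h, float(np.mean(accs))))
    best = max(table, key=lambda row: row[1])[0]
    return table, best


def select_alpha(
    F: np.ndarray,
    labels: np.ndarray,
    hidden_nodes: int = DEFAULT_HIDDEN_NODES,
    candidates=DEFAULT_ALPHA_CANDIDATES,
    k: int = 4,
    seed: int = 0,
    n_classes: int = 3,
) -> tuple[list[tuple[float, float]], float]:
    """k-fold cross-validated accuracy over ridge levels at fixed L_h.

    Returns the (α, mean accuracy) table and the best α (first on ties).
    The hidden layer is redrawn per fold but the mapping is computed once
    per fold and reused across the α grid — only the closed-form solve
    changes with α.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    labels = np.asarray(labels, dtype=int)
    F = np.asarray(F, dtype=float)
    folds = kfold_indices(F.shape[0], k, seed)
    accs = {a: [] for a in candidates}
    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        Xtr, ytr = F[train_idx], labels[train_idx]
        mean = Xtr.mean(axis=0)
        std = Xtr.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        W, b = init_hidden(F.shape[1], hidden_nodes, seed + i)
        Htr = map_features((Xtr - mean) / std, W, b)
        Hte = map_features((F[test_idx] - mean) / std, W, b)
        T = _one_hot_matrix(ytr, n_classes)
        for a in candidates:
            beta = solve_beta_pinv(Htr, T) if a == 0 else solve_beta_ridge(Htr, T, a)
            pred = np.argmax(Hte @ beta, axis=1)
            accs[a].append(float(np.mean(pred == labels[test_idx])))
    table = [(float(a), float(np.mean(accs[a]))) for a in candidates]
    best = max(table, key=lambda row: row[1])[0]
    return table, best
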