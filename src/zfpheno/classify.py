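"""Phenotype classification: one-vs-one RBF-SVM, grid search, wrapper
descriptor selection, and the k-NN baseline.

The three-phenotype problem (hatched / unhatched / dead) is decomposed
one-against-one into k(k-1)/2 = 3 binary soft-margin SVMs with a Gaussian
kernel K(x_i, x_j) = exp(-gamma * ||x_i - x_j||^2).  Prediction is by
majority vote over the pairwise machines; a vote tie is resolved by the
largest summed signed decision value.  The two hyperparameters (C, gamma)
are tuned by a coarse log2 grid search (C in 2^-5..2^15, gamma in
2^-15..2^3, both step 2, 110 points) followed by a refined linear 31x31
grid spanning +-2 exponents around the coarse optimum, both scored by
stratified 10-fold cross-validation with the normalizer re-fit inside
each training split.  Wrapper descriptor selection runs the coarse search
for each of the 63 non-empty descriptor subsets and keeps the subset with
the best cross-validated accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .descriptors import (
    BLOCK_ORDER,
    EdgeConfig,
    GrayImage,
    extract,
    subset_blocks,
)
from .preprocess import Normalizer

__all__ = [
    "CLASSES",
    "SVMConfig",
    "TrainedClassifier",
    "CVResult",
    "GridSearchResult",
    "SubsetScore",
    "COARSE_C_EXPONENTS",
    "COARSE_GAMMA_EXPONENTS",
    "train_svm",
    "train_knn",
    "predict",
    "cross_validate",
    "cross_validate_knn",
    "coarse_grid_search",
    "refine_grid_search",
    "wrapper_select",
    "knn_classify",
]

#: Canonical phenotype order used throughout.
CLASSES: tuple[str, ...] = ("hatched", "unhatched", "dead")

#: Coarse grid exponents: C in {2^-5, 2^-3, ..., 2^15}, gamma in
#: {2^-15, 2^-13, ..., 2^3} — 11 x 10 = 110 points.
COARSE_C_EXPONENTS: tuple[int, ...] = tuple(range(-5, 16, 2))
COARSE_GAMMA_EXPONENTS: tuple[int, ...] = tuple(range(-15, 4, 2))


@dataclass(frozen=True)
class SVMConfig:
    """Gaussian-kernel SVM hyperparameters."""

    C: float = 1.0
    gamma: float = 0.1
    tol: float = 1e-3
    shrinking: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.C) and self.C > 0):
            raise ValueError(f"C must be finite and positive, got {self.C}")
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError(f"gamma must be finite and positive, got {self.gamma}")


@dataclass
class TrainedClassifier:
    """A fitted phenotype classifier plus everything prediction needs.

    For ``kind="svm_ovo"`` the model holds one binary SVC per unordered
    class pair; for ``kind="knn"`` it stores the training vectors.  The
    normalizer and subset code travel with the model so new raw images are
    descriptor-extracted and standardized with training-set statistics.
    """

    kind: str
    classes: tuple[str, ...]
    machines: dict[tuple[str, str], SVC] | None = None
    train_X: np.ndarray | None = None
    train_y: np.ndarray | None = None
    k: int | None = None
    subset_code: str | None = None
    normalizer: Normalizer | None = None
    train_ids: tuple[str, ...] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_machines(self) -> int:
        return len(self.machines) if self.machines else 0


@dataclass(frozen=True)
class CVResult:
    """Per-fold cross-validation accuracies (percent)."""

    fold_accuracies: np.ndarray
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


@dataclass(frozen=True)
class GridSearchResult:
    """Accuracy surface of a (C, gamma) grid search."""

    c_values: np.ndarray
    gamma_values: np.ndarray
    accuracy: np.ndarray       # (n_C, n_gamma) mean CV accuracy, percent
    accuracy_sd: np.ndarray    # matching fold-accuracy SDs
    best_c: float
    best_gamma: float
    seed: int
    tie_break: str = "smallest C, then smallest gamma"

    @property
    def best_accuracy(self) -> float:
        i = int(np.argwhere(self.c_values == self.best_c)[0, 0])
        j = int(np.argwhere(self.gamma_values == self.best_gamma)[0, 0])
        return float(self.accuracy[i, j])

    @property
    def best_sd(self) -> float:
        i = int(np.argwhere(self.c_values == self.best_c)[0, 0])
        j = int(np.argwhere(self.gamma_values == self.best_gamma)[0, 0])
        return float(self.accuracy_sd[i, j])


@dataclass(frozen=True)
class SubsetScore:
    """Wrapper-selection record for one descriptor subset."""

    code: str
    mean_accuracy: float
    sd: float
    best_c: float
    best_gamma: float


# ---------------------------------------------------------------------------
# label / matrix plumbing
# ---------------------------------------------------------------------------


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _class_order(y: np.ndarray, classes: Sequence[str] | None) -> tuple[str, ...]:
    present = set(y.tolist())
    if classes is not None:
        missing = [c for c in classes if c not in present]
        if missing:
            raise ValueError(f"class {missing[0]!r} absent from the labels")
        return tuple(classes)
    if present <= set(CLASSES):
        return tuple(c for c in CLASSES if c in present)
    return tuple(sorted(present, key=str))


# ---------------------------------------------------------------------------
# SVM training and prediction
# ---------------------------------------------------------------------------


def _fit_pairwise(
    X: np.ndarray, y: np.ndarray, order: tuple[str, ...], cfg: SVMConfig
) -> dict[tuple[str, str], SVC]:
    machines: dict[tuple[str, str], SVC] = {}
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            mask = (y == a) | (y == b)
            svc = SVC(
                kernel="rbf",
                C=cfg.C,
                gamma=cfg.gamma,
                tol=cfg.tol,
                shrinking=cfg.shrinking,
            )
            # binary target: 1 for class b, 0 for class a, so a positive
            # decision value points at b
            svc.fit(X[mask], (y[mask] == b).astype(int))
            machines[(a, b)] = svc
    return machines


def train_svm(
    X,
    y,
    cfg: SVMConfig,
    classes: Sequence[str] | None = None,
    subset_code: str | None = None,
    normalizer: Normalizer | None = None,
    train_ids: Sequence[str] | None = None,
) -> TrainedClassifier:
    """Fit the one-vs-one Gaussian-kernel SVM on a normalized matrix.

    ``X`` must already be standardized (training convention); pass the
    fitted :class:`~zfpheno.preprocess.Normalizer` so the model can
    standardize raw inputs at prediction time.
    """
    Xm = _as_matrix(X)
    ya = np.asarray(y)
    order = _class_order(ya, classes)
    if len(order) < 2:
        raise ValueError("need at least two classes to train a classifier")
    machines = _fit_pairwise(Xm, ya, order, cfg)
    return TrainedClassifier(
        kind="svm_ovo",
        classes=order,
        machines=machines,
        subset_code=subset_code,
        normalizer=normalizer,
        train_ids=tuple(train_ids) if train_ids is not None else None,
        metadata={"config": cfg},
    )


def _predict_svm_matrix(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    order = model.classes
    idx = {c: i for i, c in enumerate(order)}
    n = X.shape[0]
    votes = np.zeros((n, len(order)), dtype=int)
    margins = np.zeros((n, len(order)))
    for (a, b), svc in model.machines.items():
        d = svc.decision_function(X)  # > 0 favors b
        win_b = d > 0
        votes[win_b, idx[b]] += 1
        votes[~win_b, idx[a]] += 1
        margins[:, idx[b]] += d
        margins[:, idx[a]] -= d
    out = np.empty(n, dtype=object)
    for i in range(n):
        v = votes[i]
        best = np.flatnonzero(v == v.max())
        if len(best) == 1:
            out[i] = order[best[0]]
        else:
            # vote tie: largest summed signed decision value wins
            out[i] = order[best[int(np.argmax(margins[i, best]))]]
    return out.astype(str)


def _predict_knn_matrix(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    return knn_classify(model.train_X, model.train_y, X, k=model.k)


def predict(model: TrainedClassifier, x, cfg: EdgeConfig | None = None):
    """Predict the phenotype of an image, a feature vector, or a batch.

    A :class:`GrayImage` is descriptor-extracted with the model's subset
    code and standardized with the stored normalizer.  A raw (un-scaled)
    feature vector or matrix is standardized if the model carries a
    normalizer; otherwise it is used as-is.
    """
    if isinstance(x, GrayImage):
        if model.subset_code is None:
            raise ValueError("model has no subset code; cannot extract descriptors")
        vec = extract(x, model.subset_code, cfg).values
        return predict(model, vec)
    if isinstance(x, (pd.DataFrame, pd.Series)):
        x = x.to_numpy(dtype=float)
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if model.normalizer is not None:
        if arr.shape[1] != len(model.normalizer.names):
            raise ValueError(
                f"feature dimension {arr.shape[1]} does not match the model's "
                f"{len(model.normalizer.names)} components"
            )
        arr = np.atleast_2d(model.normalizer.transform(arr))
    if model.kind == "svm_ovo":
        ref = next(iter(model.machines.values()))
        if arr.shape[1] != ref.n_features_in_:
            raise ValueError(
                f"feature dimension {arr.shape[1]} does not match the trained "
                f"dimension {ref.n_features_in_}"
            )
        labels = _predict_svm_matrix(model, arr)
    elif model.kind == "knn":
        labels = _predict_knn_matrix(model, arr)
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    return labels[0] if single else labels


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _fold_indices(y: np.ndarray, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    _, counts = np.unique(y, return_counts=True)
    n_min = int(counts.min())
    if n_min < folds:
        warnings.warn(
            f"smallest class has {n_min} members < {folds} folds; "
            f"using {max(2, n_min)} folds (best-effort stratification)",
            stacklevel=3,
        )
        folds = max(2, n_min)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _prepared_folds(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Standardized train/test matrices per fold.

    The normalizer is fit on each training split only — held-out rows
    never contribute to the statistics that scale them.
    """
    out = []
    for tr, te in _fold_indices(y, folds, seed):
        norm = Normalizer.fit(X[tr])
        out.append((np.atleast_2d(norm.transform(X[tr])), y[tr],
                    np.atleast_2d(norm.transform(X[te])), y[te]))
    return out


def cross_validate(X, y, cfg: SVMConfig, folds: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold CV accuracy of the one-vs-one SVM.

    ``X`` holds raw (un-normalized) features; standardization is re-fit
    inside each training split.
    """
    Xm, ya = _as_matrix(X), np.asarray(y)
    if len(ya) < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    order = _class_order(ya, None)
    accs = []
    for Xtr, ytr, Xte, yte in _prepared_folds(Xm, ya, folds, seed):
        machines = _fit_pairwise(Xtr, ytr, order, cfg)
        model = TrainedClassifier(kind="svm_ovo", classes=order, machines=machines)
        pred = _predict_svm_matrix(model, Xte)
        accs.append(100.0 * float(np.mean(pred == yte)))
    return CVResult(fold_accuracies=np.asarray(accs), seed=seed)


def cross_validate_knn(X, y, k: int = 10, folds: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold CV accuracy of the k-NN baseline (same folds)."""
    Xm, ya = _as_matrix(X), np.asarray(y)
    accs = []
    for Xtr, ytr, Xte, yte in _prepared_folds(Xm, ya, folds, seed):
        pred = knn_classify(Xtr, ytr, Xte, k=min(k, len(ytr)))
        accs.append(100.0 * float(np.mean(pred == yte)))
    return CVResult(fold_accuracies=np.asarray(accs), seed=seed)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    d = (A**2).sum(1)[:, None] - 2.0 * A @ B.T + (B**2).sum(1)[None, :]
    return np.maximum(d, 0.0)


def _grid_search(
    X: np.ndarray,
    y: np.ndarray,
    c_values: np.ndarray,
    gamma_values: np.ndarray,
    folds: int,
    seed: int,
    tol: float = 1e-3,
) -> GridSearchResult:
    """Shared (C, gamma) grid scorer.

    The pairwise squared-distance matrices are computed once per fold and
    class pair; the Gaussian kernel is then exponentiated once per gamma
    and shared across every C value (libsvm runs on the precomputed
    kernel), which is algebraically identical to fitting each (C, gamma)
    from scratch.
    """
    order = _class_order(y, None)
    idx = {c: i for i, c in enumerate(order)}
    prepared = _prepared_folds(X, y, folds, seed)
    acc = np.zeros((len(c_values), len(gamma_values), len(prepared)))
    pairs = [(a, b) for i, a in enumerate(order) for b in order[i + 1 :]]
    for f, (Xtr, ytr, Xte, yte) in enumerate(prepared):
        n_te = len(yte)
        votes = np.zeros((len(c_values), len(gamma_values), n_te, len(order)), dtype=int)
        margins = np.zeros((len(c_values), len(gamma_values), n_te, len(order)))
        for a, b in pairs:
            mask = (ytr == a) | (ytr == b)
            ybin = (ytr[mask] == b).astype(int)
            d_tr = _sq_dists(Xtr[mask], Xtr[mask])
            d_te = _sq_dists(Xte, Xtr[mask])
            for j, gamma in enumerate(gamma_values):
                K_tr = np.exp(-gamma * d_tr)
                K_te = np.exp(-gamma * d_te)
                for i, C in enumerate(c_values):
                    svc = SVC(kernel="precomputed", C=float(C), tol=tol)
                    svc.fit(K_tr, ybin)
                    dec = svc.decision_function(K_te)  # > 0 favors b
                    win_b = dec > 0
                    votes[i, j, win_b, idx[b]] += 1
                    votes[i, j, ~win_b, idx[a]] += 1
                    margins[i, j, :, idx[b]] += dec
                    margins[i, j, :, idx[a]] -= dec
        classes_arr = np.asarray(order)
        for i in range(len(c_values)):
            for j in range(len(gamma_values)):
                v = votes[i, j]
                top = v == v.max(axis=1, keepdims=True)
                masked = np.where(top, margins[i, j], -np.inf)
                pred = classes_arr[np.argmax(masked, axis=1)]
                acc[i, j, f] = 100.0 * float(np.mean(pred == yte))
    mean = acc.mean(axis=2)
    sd = acc.std(axis=2, ddof=1)
    # argmax with ties broken toward smallest C, then smallest gamma;
    # iteration order (C asc, gamma asc) makes the first strict max win
    best_i, best_j = 0, 0
    best = -np.inf
    for i in range(len(c_values)):
        for j in range(len(gamma_values)):
            if mean[i, j] > best:
                best = mean[i, j]
                best_i, best_j = i, j
    return GridSearchResult(
        c_values=np.asarray(c_values, dtype=float),
        gamma_values=np.asarray(gamma_values, dtype=float),
        accuracy=mean,
        accuracy_sd=sd,
        best_c=float(c_values[best_i]),
        best_gamma=float(gamma_values[best_j]),
        seed=seed,
    )


def coarse_grid_search(
    X,
    y,
    folds: int = 10,
    seed: int = 0,
    c_exponents: Sequence[int] = COARSE_C_EXPONENTS,
    gamma_exponents: Sequence[int] = COARSE_GAMMA_EXPONENTS,
) -> GridSearchResult:
    """Log2 grid search over (C, gamma) scored by stratified k-fold CV."""
    return _grid_search(
        _as_matrix(X),
        np.asarray(y),
        np.power(2.0, np.asarray(list(c_exponents), dtype=float)),
        np.power(2.0, np.asarray(list(gamma_exponents), dtype=float)),
        folds,
        seed,
    )


def refine_grid_search(
    X,
    y,
    coarse_best: tuple[float, float],
    folds: int = 10,
    seed: int = 0,
    units: int = 30,
) -> GridSearchResult:
    """Linear 31x31 grid over +-2 exponents around the coarse optimum.

    The region [C/4, 4C] x [gamma/4, 4*gamma] — the smallest coarse-grid
    cell neighbourhood covering the optimum — is divided into ``units``
    equal linear steps per axis (endpoints included).
    """
    C0, g0 = coarse_best
    c_values = np.linspace(C0 / 4.0, C0 * 4.0, units + 1)
    gamma_values = np.linspace(g0 / 4.0, g0 * 4.0, units + 1)
    return _grid_search(_as_matrix(X), np.asarray(y), c_values, gamma_values, folds, seed)


# ---------------------------------------------------------------------------
# wrapper descriptor selection
# ---------------------------------------------------------------------------


def wrapper_select(
    X,
    y,
    folds: int = 10,
    seed: int = 0,
    c_exponents: Sequence[int] = COARSE_C_EXPONENTS,
    gamma_exponents: Sequence[int] = COARSE_GAMMA_EXPONENTS,
) -> tuple[list[SubsetScore], str]:
    """Score all 63 non-empty descriptor subsets by coarse-grid CV accuracy.

    ``X`` must be a DataFrame holding the full 263-component extraction
    with block-prefixed column names (``LEHD_0`` ... ``CLD_14``).  The
    same seeded fold split is reused for every subset so accuracies are
    comparable.  Returns the per-subset report (in subset-code order) and
    the best code (ties go to the smaller subset, then the lexicographically
    smaller code).
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError("wrapper_select needs a DataFrame with block-prefixed columns")
    X = X.rename(columns=str)
    ya = np.asarray(y)
    block_cols = {
        name: [c for c in X.columns if c.startswith(f"{name}_")] for name in BLOCK_ORDER
    }
    empty = [name for name, cols in block_cols.items() if not cols]
    if empty:
        raise ValueError(f"feature table is missing descriptor blocks: {empty}")
    scores: list[SubsetScore] = []
    for code_int in range(1, 64):
        code = format(code_int, "06b")
        cols = [c for name in subset_blocks(code) for c in block_cols[name]]
        res = coarse_grid_search(
            X[cols], ya, folds=folds, seed=seed,
            c_exponents=c_exponents, gamma_exponents=gamma_exponents,
        )
        scores.append(
            SubsetScore(code, res.best_accuracy, res.best_sd, res.best_c, res.best_gamma)
        )
    best = max(
        scores,
        key=lambda s: (s.mean_accuracy, -s.code.count("1"), [-ord(c) for c in s.code]),
    )
    return scores, best.code


def subset_report(scores: Sequence[SubsetScore]) -> pd.DataFrame:
    """Wrapper-selection report as a table (subset, mean, sd, best C, gamma)."""
    return pd.DataFrame(
        {
            "subset": [s.code for s in scores],
            "mean_accuracy": [s.mean_accuracy for s in scores],
            "sd": [s.sd for s in scores],
            "best_C": [s.best_c for s in scores],
            "best_gamma": [s.best_gamma for s in scores],
        }
    )


# ---------------------------------------------------------------------------
# k-NN baseline
# ---------------------------------------------------------------------------


def knn_classify(X_train, y_train, X_test, k: int = 10) -> np.ndarray:
    """k-nearest-neighbour labels by Euclidean distance and majority vote.

    A vote tie is resolved by the nearest neighbour whose class is among
    the tied classes.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    Xtr = _as_matrix(X_train)
    Xte = np.atleast_2d(_as_matrix(X_test))
    ytr = np.asarray(y_train)
    if k > len(ytr):
        raise ValueError(f"k={k} exceeds the {len(ytr)} training samples")
    nn = NearestNeighbors(n_neighbors=k).fit(Xtr)
    _, idx = nn.kneighbors(Xte)
    out = np.empty(len(Xte), dtype=object)
    for i, row in enumerate(idx):
        labels = ytr[row]  # ordered by increasing distance
        uniq, counts = np.unique(labels, return_counts=True)
        tied = set(uniq[counts == counts.max()].tolist())
        if len(tied) == 1:
            out[i] = tied.pop()
        else:
            out[i] = next(lab for lab in labels if lab in tied)
    return out.astype(str)


def train_knn(
    X,
    y,
    k: int = 10,
    normalizer: Normalizer | None = None,
    subset_code: str | None = None,
    train_ids: Sequence[str] | None = None,
) -> TrainedClassifier:
    """Package normalized training data as a k-NN classifier."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    Xm, ya = _as_matrix(X), np.asarray(y)
    return TrainedClassifier(
        kind="knn",
        classes=_class_order(ya, None),
        train_X=Xm,
        train_y=ya,
        k=min(k, len(ya)),
        subset_code=subset_code,
        normalizer=normalizer,
        train_ids=tuple(train_ids) if train_ids is not None else None,
    )
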