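"""Single-subject connectome classification of baseline progression rate.

The progression rate is (48 - ALSFRS-R) / months since symptom onset,
binarized at 0.68/month into fast vs. slow progressors.  Each patient's
unthresholded connectivity matrix is vectorized (upper triangle, row-major),
reduced by PCA to the components explaining 80% of the training variance,
and classified with a linear-kernel SVM.  Accuracy is estimated by nested
stratified cross-validation (outer folds estimate generalization, inner
folds tune C); significance comes from re-running the whole pipeline on
label-shuffled data; and edge importance is back-mapped as the sum over the
top SVM-weighted components of |w_pc| * |loading_pc,edge|.

PCA and the SVM are always fitted on the training portion of a fold only,
so no information leaks from test subjects into the transform or the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataio import Cohort, ConnectivityMatrix, NodeAtlas, SubjectRecord
from .exceptions import ConfigError

DEFAULT_C_GRID = tuple(10.0**k for k in range(-3, 4))
RATE_CUTOFF = 0.68


def progression_rate(alsfrs_r: int, duration_months: float) -> float:
    """(48 - ALSFRS-R) / months since disease onset, in points per month."""
    if not 0 <= alsfrs_r <= 48:
        raise ConfigError(f"alsfrs_r={alsfrs_r} outside [0, 48]")
    if duration_months <= 0:
        raise ConfigError(f"duration_months={duration_months} must be > 0")
    return (48 - alsfrs_r) / duration_months


def progression_class(rate: float, cutoff: float = RATE_CUTOFF) -> str:
    """'fast' iff the rate exceeds the cut-off, else 'slow'."""
    return "fast" if rate > cutoff else "slow"


@dataclass(frozen=True)
class ProgressionLabel:
    rate: float
    cls: str
    cutoff: float = RATE_CUTOFF

    @classmethod
    def from_record(cls, record: SubjectRecord, cutoff: float = RATE_CUTOFF):
        rate = progression_rate(record.alsfrs_r, record.duration_months)
        return cls(rate=rate, cls=progression_class(rate, cutoff), cutoff=cutoff)


@dataclass
class PredictionResult:
    fold_accuracies: list[float]
    mean_balanced_accuracy: float
    chosen_C_per_fold: list[float]
    n_components_per_fold: list[int]
    p_perm: float | None = None
    importance: np.ndarray | None = None
    top_connections: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "fold_accuracies": list(map(float, self.fold_accuracies)),
            "mean_balanced_accuracy": float(self.mean_balanced_accuracy),
            "chosen_C_per_fold": list(map(float, self.chosen_C_per_fold)),
            "n_components_per_fold": list(map(int, self.n_components_per_fold)),
            "p_perm": None if self.p_perm is None else float(self.p_perm),
        }
        if self.top_connections is not None:
            out["top_connections"] = self.top_connections.to_dict(orient="records")
        return out


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def vectorize_edges(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Upper-triangle edge vector in row-major (i < j) order; edge (0, 1) is
    index 0, length N(N-1)/2."""
    w = matrix.weights if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    iu, ju = np.triu_indices(w.shape[0], 1)
    return w[iu, ju]


def devectorize_edges(vec: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`vectorize_edges` (symmetric, zero diagonal)."""
    iu, ju = np.triu_indices(n_nodes, 1)
    if len(vec) != len(iu):
        raise ConfigError(f"vector length {len(vec)} != {len(iu)} for N={n_nodes}")
    out = np.zeros((n_nodes, n_nodes))
    out[iu, ju] = vec
    out[ju, iu] = vec
    return out


def edge_index_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_nodes, 1)


def patient_feature_matrix(cohort: Cohort, cutoff: float = RATE_CUTOFF):
    """Edge vectors and fast/slow labels for the patient subset.

    Returns ``(X, y, subject_ids)`` with y = 1 for fast progressors.
    """
    pats = cohort.patients()
    x = np.stack([vectorize_edges(m) for m in pats.matrices])
    y = np.array(
        [ProgressionLabel.from_record(r, cutoff).cls == "fast" for r in pats.records],
        dtype=int,
    )
    return x, y, pats.subject_ids


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAReduction:
    mean: np.ndarray
    loadings: np.ndarray           # (k, n_edges), orthonormal rows
    explained_variance_ratio: np.ndarray
    k: int

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.mean) @ self.loadings.T


def pca_reduce(train_vectors: np.ndarray, variance_target: float = 0.8) -> PCAReduction:
    """Centered PCA keeping the smallest k with cumulative explained
    variance >= the target.

    New subjects must be transformed with the training mean and loadings
    only (see :meth:`PCAReduction.transform`).
    """
    if not 0 < variance_target <= 1:
        raise ConfigError(f"variance_target={variance_target} outside (0, 1]")
    x = np.asarray(train_vectors, dtype=float)
    if x.shape[0] < 2:
        raise ConfigError("pca_reduce needs >= 2 training subjects")
    mean = x.mean(axis=0)
    xc = x - mean
    # economy SVD: at most n_samples - 1 informative components
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    nonzero = var > var[0] * 1e-12 if var[0] > 0 else np.zeros_like(var, dtype=bool)
    var = var[nonzero]
    vt = vt[nonzero]
    ratio = var / var.sum()
    k = int(np.searchsorted(np.cumsum(ratio), variance_target - 1e-12) + 1)
    k = min(k, len(ratio))
    return PCAReduction(mean=mean, loadings=vt[:k], explained_variance_ratio=ratio, k=k)


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """(sensitivity + specificity) / 2 for binary 0/1 labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    recalls = [
        np.mean(y_pred[y_true == c] == c) for c in (0, 1) if np.any(y_true == c)
    ]
    return float(np.mean(recalls))


def _tune_C(
    scores: np.ndarray, y: np.ndarray, inner_k: int, c_grid, seed: int
) -> float:
    """Inner-CV balanced accuracy over the C grid; smallest C wins ties.

    ``scores`` are PCA-transformed training features (the transform is
    refitted inside each inner fold on that fold's training part).
    """
    inner_k = min(inner_k, int(np.bincount(y).min()))
    if inner_k < 2:
        raise ConfigError("training fold too small to tune C")
    inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    accs = np.zeros(len(c_grid))
    for tr, te in inner.split(scores, y):
        for ci, c in enumerate(c_grid):
            clf = SVC(kernel="linear", C=c)
            clf.fit(scores[tr], y[tr])
            accs[ci] += balanced_accuracy(y[te], clf.predict(scores[te]))
    best = int(np.argmax(np.round(accs, 12)))  # argmax takes the first (smallest C) tie
    return float(c_grid[best])


def nested_cv_svm(
    vectors: np.ndarray,
    labels: np.ndarray,
    outer_k: int = 10,
    inner_k: int = 5,
    c_grid=DEFAULT_C_GRID,
    variance_target: float = 0.8,
    seed: int = 0,
    pca_global: bool = False,
    standardize: bool = False,
) -> PredictionResult:
    """Nested stratified CV of the PCA + linear-SVM classifier.

    Per outer fold the PCA and SVM see the training portion only; C is
    chosen by inner-CV balanced accuracy; the outer-fold score is the
    balanced accuracy (mean of sensitivity and specificity) on the held-out
    subjects.  Deterministic for a fixed seed.

    ``pca_global=True`` fits one PCA on the whole sample before the CV (a
    laxer variant some studies use; it leaks test-subject variance into the
    transform and is off by default).  ``standardize=True`` z-scores each
    edge with training-fold statistics before the PCA.
    """
    x = np.asarray(vectors, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ConfigError("both classes must be present")
    minority = int(np.bincount(y).min())
    if minority < 2:
        raise ConfigError("need >= 2 subjects in each class")
    if outer_k > minority:
        warnings.warn(
            f"outer_k={outer_k} exceeds minority class size {minority}; clamping",
            stacklevel=2,
        )
        outer_k = minority
    if pca_global and standardize:
        raise ConfigError("pca_global and standardize cannot be combined")
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    shared_pca = pca_reduce(x, variance_target) if pca_global else None
    fold_acc, fold_c, fold_k = [], [], []
    for f, (tr, te) in enumerate(outer.split(x, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ConfigError(f"outer fold {f} lost a class; reduce outer_k")
        x_tr, x_te = x[tr], x[te]
        if standardize:
            mu = x_tr.mean(axis=0)
            sd = x_tr.std(axis=0)
            sd[sd == 0] = 1.0
            x_tr = (x_tr - mu) / sd
            x_te = (x_te - mu) / sd
        pca = shared_pca if pca_global else pca_reduce(x_tr, variance_target)
        s_tr = pca.transform(x_tr)
        best_c = _tune_C(s_tr, y[tr], inner_k, c_grid,
                         seed=(seed * 1009 + f) % (2**31 - 1))
        clf = SVC(kernel="linear", C=best_c)
        clf.fit(s_tr, y[tr])
        acc = balanced_accuracy(y[te], clf.predict(pca.transform(x_te)))
        fold_acc.append(float(acc))
        fold_c.append(best_c)
        fold_k.append(pca.k)
    return PredictionResult(
        fold_accuracies=fold_acc,
        mean_balanced_accuracy=float(np.mean(fold_acc)),
        chosen_C_per_fold=fold_c,
        n_components_per_fold=fold_k,
    )


def permutation_significance(
    vectors: np.ndarray,
    labels: np.ndarray,
    acc_obs: float | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    **cv_kwargs,
) -> tuple[float, np.ndarray]:
    """Label-shuffle null for the nested-CV accuracy.

    The full pipeline (PCA, C tuning, outer evaluation) is re-run per
    shuffled labeling; p = (1 + #{acc_perm >= acc_obs}) / (n_perm + 1).
    Returns ``(p, null_accuracies)``.
    """
    y = np.asarray(labels, dtype=int)
    if acc_obs is None:
        acc_obs = nested_cv_svm(vectors, y, seed=seed, **cv_kwargs).mean_balanced_accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        y_perm = rng.permutation(y)
        res = nested_cv_svm(
            vectors, y_perm, seed=int(rng.integers(0, 2**31 - 1)), **cv_kwargs
        )
        null[p] = res.mean_balanced_accuracy
    p_val = (1 + int(np.count_nonzero(null >= acc_obs - 1e-12))) / (n_perm + 1)
    return float(p_val), null


# ---------------------------------------------------------------------------
# importance back-mapping
# ---------------------------------------------------------------------------

def connection_importance(
    svm_weights: np.ndarray,
    loadings: np.ndarray,
    atlas: NodeAtlas,
    top_n_pcs: int = 10,
    top_n_edges: int = 50,
    signed: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Back-map SVM weights from component space to connection space.

    The ``top_n_pcs`` components with the largest |SVM weight| are selected;
    importance(edge) = sum over selected components of |w_pc| *
    |loading_pc,edge|.  Returns the full importance vector and a ranked
    table of the ``top_n_edges`` connections with region names.

    ``signed=True`` sums w_pc * loading without absolute values and ranks by
    magnitude; the sign of a principal axis is arbitrary, so this variant is
    seed-dependent and off by default.
    """
    w = np.asarray(svm_weights, dtype=float).ravel()
    if top_n_pcs > len(w):
        warnings.warn(
            f"top_n_pcs={top_n_pcs} > {len(w)} available components; clamping",
            stacklevel=2,
        )
        top_n_pcs = len(w)
    sel = np.argsort(-np.abs(w), kind="stable")[:top_n_pcs]
    if signed:
        importance = np.abs(w[sel] @ loadings[sel])
    else:
        importance = np.abs(w[sel]) @ np.abs(loadings[sel])
    order = np.argsort(-importance, kind="stable")[:top_n_edges]
    iu, ju = np.triu_indices(atlas.n, 1)
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "region_a": [atlas.names[iu[e]] for e in order],
            "region_b": [atlas.names[ju[e]] for e in order],
            "edge_i": iu[order],
            "edge_j": ju[order],
            "importance": importance[order],
        }
    )
    return importance, table


def predict_progression(
    cohort: Cohort,
    cutoff: float = RATE_CUTOFF,
    outer_k: int = 10,
    inner_k: int = 5,
    c_grid=DEFAULT_C_GRID,
    variance_target: float = 0.8,
    n_perm: int | None = None,
    top_n_pcs: int = 10,
    top_n_edges: int = 50,
    seed: int = 0,
) -> PredictionResult:
    """End-to-end progression-rate classification for a cohort's patients.

    Runs nested CV, optionally the label-shuffle significance test
    (``n_perm``), then refits PCA + SVM on all patients with the modal best
    C across outer folds and back-maps importance to connections.
    """
    x, y, _ = patient_feature_matrix(cohort, cutoff)
    result = nested_cv_svm(x, y, outer_k, inner_k, c_grid, variance_target, seed)
    if n_perm:
        p_val, _ = permutation_significance(
            x, y, acc_obs=result.mean_balanced_accuracy, n_perm=n_perm, seed=seed,
            outer_k=outer_k, inner_k=inner_k, c_grid=c_grid,
            variance_target=variance_target,
        )
        result.p_perm = p_val
    cs, counts = np.unique(result.chosen_C_per_fold, return_counts=True)
    modal_c = float(cs[np.argmax(counts)])
    pca = pca_reduce(x, variance_target)
    clf = SVC(kernel="linear", C=modal_c)
    clf.fit(pca.transform(x), y)
    importance, table = connection_importance(
        clf.coef_, pca.loadings, cohort.atlas, top_n_pcs, top_n_edges
    )
    result.importance = importance
    result.top_connections = table
    return result
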