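"""Fisher LDA on a PCA subspace, with leave-one-out evaluation.

Feature vectors (concatenated per-voxel network features) live in a space
whose dimension is the number of selected voxels — typically thousands —
while cohorts have tens to hundreds of subjects.  Training therefore first
projects onto the leading k principal components of the training set
(k = 40 for small cohorts, 100 for large ones, which covers the bulk of the
data variance), then finds the Fisher direction w maximizing the Rayleigh
quotient

    J(w) = (w' S_B w) / (w' S_W w)

with S_W the pooled within-class scatter and S_B the rank-one between-class
scatter of the two class means.  The closed form is w ∝ S_W^{-1}(mu_A - mu_C),
with a small ridge on S_W when it is singular.  A test subject is projected,
dotted with w and compared against the midpoint of the projected class means;
the ADHD class sits above the midpoint by construction, and exact ties go to
control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ADHD",
    "CONTROL",
    "FeatureVector",
    "PcaLdaModel",
    "LdaScatter",
    "ClassificationMetrics",
    "fit_pca",
    "fit_lda",
    "train_classifier",
    "predict_label",
    "loocv_predictions",
    "loocv_detection_rate",
    "compute_metrics",
]

logger = logging.getLogger(__name__)

ADHD = "ADHD"
CONTROL = "control"

#: default PCA dimensions: small single-site cohorts vs the full multi-site set
DEFAULT_K_SMALL = 40
DEFAULT_K_LARGE = 100


@dataclass
class FeatureVector:
    """One subject's concatenated per-voxel features, with a fixed layout.

    ``layout`` identifies the voxel ordering (and per-voxel component count)
    so vectors from different subjects are only ever combined when they are
    aligned; any hashable token works (the pipeline uses a digest of the
    mask's voxel indices and the feature kind).
    """

    values: np.ndarray
    subject_id: str = ""
    label: str = "unknown"
    layout: object = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


@dataclass
class LdaScatter:
    S_W: np.ndarray  # pooled within-class scatter, symmetric PSD
    S_B: np.ndarray  # between-class scatter, rank <= 1


@dataclass
class PcaLdaModel:
    training_mean: np.ndarray
    components: np.ndarray  # (k, d), rows orthonormal
    explained_variance_fractions: np.ndarray
    k: int
    w: np.ndarray  # Fisher direction in the k-space
    class_means_projected: tuple[float, float]  # (ADHD, control) along w
    class_counts: tuple[int, int]  # (n_ADHD, n_control)
    class_mean_vectors: np.ndarray  # (2, k): projected class means (ADHD, control)
    decision_midpoint: float
    label_order: tuple[str, str] = (ADHD, CONTROL)
    layout: object = None
    scatter: LdaScatter | None = None


def _as_matrix(features, check_layout: bool = True):
    """Stack FeatureVectors (or accept a plain matrix + labels tuple)."""
    layouts = {fv.layout for fv in features}
    if check_layout and len(layouts) > 1:
        raise ValueError(f"feature vectors have mismatched layouts: {layouts}")
    lengths = {fv.values.size for fv in features}
    if len(lengths) > 1:
        raise ValueError(f"feature vectors have mismatched lengths: {sorted(lengths)}")
    X = np.stack([fv.values for fv in features])
    labels = np.array([fv.label for fv in features])
    layout = next(iter(layouts)) if layouts else None
    return X, labels, layout


def fit_pca(X_train: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal basis of the training matrix (rows = subjects).

    Returns ``(mean, components, explained_variance_fractions)`` where
    ``components`` has k orthonormal rows sorted by decreasing variance and
    the fractions are each component's share of the *total* training
    variance.  k is capped at min(n - 1, d) with a logged warning.
    """
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 training vectors")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n, d = X.shape
    k_max = min(n - 1, d)
    if k > k_max:
        logger.warning("PCA k=%d exceeds min(n-1, d)=%d; capping", k, k_max)
        k = k_max
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD: n is small, d may be thousands
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    if total <= 0:
        raise ValueError("training data has zero variance; PCA undefined")
    fractions = (s[:k] ** 2) / total
    return mean, Vt[:k], fractions


def fit_lda(
    Z: np.ndarray,
    labels: np.ndarray,
    ridge_scale: float = 1e-6,
) -> tuple[np.ndarray, float, LdaScatter]:
    """Fisher discriminant direction for two classes in the projected space.

    ``w`` solves S_W w ∝ (mu_A - mu_C); when S_W is singular (k near n - 1,
    or duplicated features) a ridge of ``ridge_scale * trace(S_W)/k`` is
    added to the diagonal.  ``w`` is oriented so the ADHD class mean projects
    above the midpoint of the two projected class means.
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    present = set(labels.tolist())
    if not {ADHD, CONTROL} <= present:
        raise ValueError(f"both classes required for LDA, got labels {sorted(present)}")
    is_a = labels == ADHD
    Za, Zc = Z[is_a], Z[labels == CONTROL]
    mu_a = Za.mean(axis=0)
    mu_c = Zc.mean(axis=0)
    Da, Dc = Za - mu_a, Zc - mu_c
    S_W = Da.T @ Da + Dc.T @ Dc
    diff = mu_a - mu_c
    S_B = np.outer(diff, diff)
    k = Z.shape[1]

    try:
        w = np.linalg.solve(S_W, diff)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        eps = ridge_scale * (np.trace(S_W) / max(k, 1) or 1.0)
        logger.warning("singular within-class scatter; adding ridge %.3g", eps)
        w = np.linalg.solve(S_W + eps * np.eye(k), diff)
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
    if w @ diff < 0:  # orient: ADHD above midpoint
        w = -w
    midpoint = float(0.5 * (w @ mu_a + w @ mu_c))
    return w, midpoint, LdaScatter(S_W=S_W, S_B=S_B)


def train_classifier(features, k: int) -> PcaLdaModel:
    """Fit PCA then Fisher LDA on a cohort of FeatureVectors."""
    X, labels, layout = _as_matrix(features)
    mean, components, fractions = fit_pca(X, k)
    Z = (X - mean) @ components.T
    w, midpoint, scatter = fit_lda(Z, labels)
    is_a = labels == ADHD
    mu_a = Z[is_a].mean(axis=0)
    mu_c = Z[~is_a].mean(axis=0)
    return PcaLdaModel(
        training_mean=mean,
        components=components,
        explained_variance_fractions=fractions,
        k=components.shape[0],
        w=w,
        class_means_projected=(float(w @ mu_a), float(w @ mu_c)),
        class_counts=(int(is_a.sum()), int((~is_a).sum())),
        class_mean_vectors=np.stack([mu_a, mu_c]),
        decision_midpoint=midpoint,
        layout=layout,
        scatter=scatter,
    )


def predict_label(model: PcaLdaModel, x) -> str:
    """Project a feature vector, dot with w, compare to the midpoint.

    Above the midpoint -> ADHD; at or below -> control (ties are resolved
    to control).
    """
    if isinstance(x, FeatureVector):
        if model.layout is not None and x.layout is not None and x.layout != model.layout:
            raise ValueError("feature-vector layout does not match the model layout")
        vals = x.values
    else:
        vals = np.asarray(x, dtype=float).ravel()
    if vals.size != model.training_mean.size:
        raise ValueError(
            f"feature length {vals.size} != model dimension {model.training_mean.size}"
        )
    score = model.w @ (model.components @ (vals - model.training_mean))
    return ADHD if score > model.decision_midpoint else CONTROL


def loocv_predictions(features, k: int) -> list[str]:
    """Leave-one-out predicted label for every subject.

    For each subject the classifier (PCA *and* LDA) is refit on the n - 1
    others — the held-out vector never enters the mean, the basis, or the
    scatter — and the held-out subject is predicted.
    """
    X, labels, _ = _as_matrix(features)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"LOOCV needs at least 3 subjects, got {n}")
    if not {ADHD, CONTROL} <= set(labels.tolist()):
        raise ValueError("both classes required")
    preds: list[str] = []
    idx = np.arange(n)
    for i in range(n):
        rest = idx != i
        mean, components, _ = fit_pca(X[rest], k)
        Z = (X[rest] - mean) @ components.T
        w, midpoint, _ = fit_lda(Z, labels[rest])
        score = w @ (components @ (X[i] - mean))
        preds.append(ADHD if score > midpoint else CONTROL)
    return preds


def loocv_detection_rate(features, k: int) -> float:
    """Leave-one-out detection rate in percent (n folds, no leakage)."""
    preds = loocv_predictions(features, k)
    truths = [fv.label for fv in features]
    return 100.0 * sum(p == t for p, t in zip(preds, truths)) / len(preds)


def loocv_predictions_gram(X: np.ndarray, labels: np.ndarray, k: int) -> list[str]:
    """Fast leave-one-out predictions via the n x n Gram matrix.

    Mathematically equivalent to :func:`loocv_predictions` (Fisher LDA
    predictions are invariant to the choice of orthonormal basis of the PCA
    subspace, so computing the subspace from the Gram matrix instead of the
    data SVD changes nothing but runtime), and much faster when the feature
    dimension is far larger than the cohort: every fold costs O(n^2) plus an
    n x n eigendecomposition instead of an SVD of the full data block.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"LOOCV needs at least 3 subjects, got {n}")
    G0 = X @ X.T
    preds: list[str] = []
    idx = np.arange(n)
    for i in range(n):
        r = idx[idx != i]
        m = r.size
        J = G0[np.ix_(r, r)]
        rm = J.mean(axis=1)
        gm = rm.mean()
        Jc = J - rm[:, None] - rm[None, :] + gm
        evals, U = np.linalg.eigh(Jc)
        order = np.argsort(evals)[::-1]
        kk = min(k, m - 1)
        keep = order[:kk]
        s2 = np.clip(evals[keep], 0.0, None)
        pos = s2 > s2[0] * 1e-12 if s2.size and s2[0] > 0 else np.zeros(kk, bool)
        keep = keep[pos]
        s = np.sqrt(s2[pos])
        Uk = U[:, keep]
        Z = Uk * s  # projected training data in the PCA basis
        w, midpoint, _ = fit_lda(Z, labels[r])
        # held-out projection from Gram entries only:
        # (x_j - mu)(x_i - mu)^T = G0[j,i] - mean_l G0[l,i] - mean_l G0[j,l] + mean G0
        c_i = G0[r, i].mean()
        vec = G0[r, i] - c_i - rm + gm
        z_i = (Uk / s).T @ vec
        preds.append(ADHD if float(w @ z_i) > midpoint else CONTROL)
    return preds


@dataclass
class ClassificationMetrics:
    """Confusion counts and derived rates; ADHD is the positive class.

    ``detection_rate`` is the percent of correct predictions (both classes);
    ``sensitivity`` = TP/(TP+FN) and ``specificity`` = TN/(TN+FP) are in
    [0, 1].  A ratio with a zero denominator is NaN, never silently 0.
    """

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def detection_rate(self) -> float:
        return 100.0 * (self.TP + self.TN) / self.n

    @property
    def sensitivity(self) -> float:
        denom = self.TP + self.FN
        return self.TP / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.TN + self.FP
        return self.TN / denom if denom else float("nan")


def compute_metrics(predicted, truth) -> ClassificationMetrics:
    """Confusion counts of predicted vs true labels (ADHD positive)."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths")
    if not predicted:
        raise ValueError("empty input")
    TP = sum(p == ADHD and t == ADHD for p, t in zip(predicted, truth))
    TN = sum(p == CONTROL and t == CONTROL for p, t in zip(predicted, truth))
    FP = sum(p == ADHD and t == CONTROL for p, t in zip(predicted, truth))
    FN = sum(p == CONTROL and t == ADHD for p, t in zip(predicted, truth))
    return ClassificationMetrics(TP=TP, TN=TN, FP=FP, FN=FN)
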