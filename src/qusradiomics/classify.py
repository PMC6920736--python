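"""Subject-level LOOCV with wrapper sequential forward selection.

The response-prediction protocol: for every left-out subject, feature
standardization, sequential forward selection (SFS, capped at three features
by the one-in-ten rule) and classifier training are all performed on the
remaining n-1 subjects only; the held-out subject is then scored.  The
per-fold scores are pooled over the whole cohort and summarized as
sensitivity, specificity, accuracy (threshold 0.5, complete response = the
positive class) and the ROC AUC with a DeLong 95% confidence interval.

Classifiers (all return a posterior-like score in [0, 1] for the positive
class, on features z-scored with training-fold statistics):

* ``logistic`` — maximum-likelihood linear logit with a tiny L2 ridge
  (lambda = 1e-6) so separable folds still converge;
* ``naive_bayes`` — per-class independent Gaussians with a pooled-variance
  floor, empirical priors;
* ``knn`` — one nearest neighbor, Euclidean; the score blends the inverse
  distances to the nearest neighbor of each class so pooled ROC curves are
  not degenerate: s = (1/(1+d+)) / (1/(1+d+) + 1/(1+d-)).

SFS utility is the inner leave-one-out accuracy on the training subjects
with the wrapped classifier; ties break toward the lower feature index and
selection stops when no candidate improves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SubjectRecord",
    "FoldResult",
    "ClassifierResult",
    "train_classifier",
    "sfs_select",
    "loocv_evaluate",
    "pooled_metrics",
    "delong_ci",
]

POSITIVE_LABEL = "CR"
LOGISTIC_RIDGE = 1e-6
CLASSIFIER_KINDS = ("logistic", "naive_bayes", "knn")


@dataclass
class SubjectRecord:
    """One subject: id, 40 named radiomic features, binary response label."""

    subject_id: str
    features: dict[str, float]
    label: str  # "CR" | "PR"

    def __post_init__(self) -> None:
        if self.label not in ("CR", "PR"):
            raise ValueError(f"label must be CR or PR, got {self.label!r}")


def records_to_matrix(
    records: list[SubjectRecord], feature_names: list[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix, 0/1 labels (1 = positive class) and subject ids."""
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique")
    X = np.array([[r.features[f] for f in feature_names] for r in records], dtype=float)
    y = np.array([1 if r.label == POSITIVE_LABEL else 0 for r in records])
    return X, y, ids


# ---------------------------------------------------------------------------
# Classifiers


class _Scorer:
    """Trained model: maps raw feature rows to positive-class scores."""

    def __init__(self, kind, mean, scale, params):
        self.kind = kind
        self._mean = mean
        self._scale = scale
        self._params = params

    def score(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(np.asarray(X, dtype=float)) - self._mean) / self._scale
        p = self._params
        if self.kind == "logistic":
            eta = Z @ p["w"] + p["b"]
            return 1.0 / (1.0 + np.exp(-eta))
        if self.kind == "naive_bayes":
            ll = []
            for cls in (0, 1):
                m, v = p["mean"][cls], p["var"][cls]
                ll.append(
                    np.log(p["prior"][cls])
                    - 0.5 * np.sum(np.log(2 * np.pi * v) + (Z - m) ** 2 / v, axis=1)
                )
            d = ll[1] - ll[0]
            return 1.0 / (1.0 + np.exp(-np.clip(d, -500, 500)))
        # knn, k = 1
        out = np.empty(Z.shape[0])
        for i, z in enumerate(Z):
            d_pos = np.sqrt(((p["X1"] - z) ** 2).sum(axis=1)).min()
            d_neg = np.sqrt(((p["X0"] - z) ** 2).sum(axis=1)).min()
            s_pos = 1.0 / (1.0 + d_pos)
            s_neg = 1.0 / (1.0 + d_neg)
            out[i] = s_pos / (s_pos + s_neg)
        return out


def _fit_logistic(Z: np.ndarray, y: np.ndarray, ridge: float = LOGISTIC_RIDGE):
    """Newton/IRLS for the ridge-stabilized logit (intercept unpenalized)."""
    n, d = Z.shape
    A = np.column_stack([Z, np.ones(n)])
    beta = np.zeros(d + 1)
    penalty = np.full(d + 1, ridge)
    penalty[-1] = 0.0
    for _ in range(100):
        eta = A @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = np.maximum(mu * (1 - mu), 1e-12)
        grad = A.T @ (y - mu) - penalty * beta
        H = (A * W[:, None]).T @ A + np.diag(penalty + 1e-12)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta[:d], beta[d]


def train_classifier(kind: str, X: np.ndarray, y: np.ndarray) -> _Scorer:
    """Fit one classifier on (features, 0/1 labels); returns a scorer.

    Standardization statistics are fitted here, on the training rows only;
    constant features are neutralized (unit scale, centered) with a warning.
    """
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if np.isnan(X).any():
        raise ValueError("training features contain missing values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need >= 2 subjects per class")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    if np.any(scale == 0):
        warnings.warn("constant feature(s) in training data; neutralized")
        scale = np.where(scale == 0, 1.0, scale)
    Z = (X - mean) / scale
    if kind == "logistic":
        w, b = _fit_logistic(Z, y)
        params = {"w": w, "b": b}
    elif kind == "naive_bayes":
        var_floor = 1e-6 * float(Z.var(axis=0).mean() or 1.0)
        params = {"mean": {}, "var": {}, "prior": {}}
        for cls in (0, 1):
            Zc = Z[y == cls]
            params["mean"][cls] = Zc.mean(axis=0)
            params["var"][cls] = np.maximum(Zc.var(axis=0), var_floor)
            params["prior"][cls] = len(Zc) / len(Z)
    else:
        params = {"X0": Z[y == 0], "X1": Z[y == 1]}
    return _Scorer(kind, mean, scale, params)


# ---------------------------------------------------------------------------
# Sequential forward selection


def _loo_accuracy_nb(X: np.ndarray, y: np.ndarray) -> float:
    """Closed-form leave-one-out Gaussian-NB accuracy, vectorized over folds.

    Identical to fitting :func:`train_classifier` per fold: NB posteriors are
    invariant to the per-fold affine standardization, and the z-space
    variance floor of 1e-6 corresponds to 1e-6 times the per-feature
    training variance in raw units.
    """
    n, d = X.shape
    counts = np.bincount(y, minlength=2)
    sums = np.stack([X[y == c].sum(axis=0) for c in (0, 1)])
    sumsqs = np.stack([(X[y == c] ** 2).sum(axis=0) for c in (0, 1)])
    tot_sum = X.sum(axis=0)
    tot_sumsq = (X**2).sum(axis=0)
    mu_tot = (tot_sum - X) / (n - 1)
    var_tot = np.maximum((tot_sumsq - X**2) / (n - 1) - mu_tot**2, 0.0)
    floor = 1e-6 * var_tot

    M = np.empty((2, n, d))
    V = np.empty((2, n, d))
    prior = np.empty((2, n))
    for c in (0, 1):
        own = y == c
        nc = np.maximum(counts[c] - own.astype(int), 1)  # class size per fold
        M[c] = (sums[c] - np.where(own[:, None], X, 0.0)) / nc[:, None]
        V[c] = (sumsqs[c] - np.where(own[:, None], X**2, 0.0)) / nc[:, None] - M[c] ** 2
        prior[c] = nc / (n - 1)
    V = np.maximum(V, np.maximum(floor[None], 1e-300))
    ll = (
        np.log(prior)[:, :, None] / d  # spread prior across the feature sum
        - 0.5 * (np.log(2 * np.pi * V) + (X[None] - M) ** 2 / V)
    ).sum(axis=2)
    pred = ll[1] >= ll[0]
    valid = np.minimum(counts[0] - (y == 0), counts[1] - (y == 1)) >= 2
    correct = (pred == (y == 1)) & valid
    return correct.sum() / n


def _loo_accuracy_knn(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out 1-NN accuracy with per-fold standardization."""
    n, d = X.shape
    counts = np.bincount(y, minlength=2)
    idx = np.arange(n)
    correct = 0
    for i in range(n):
        if min(counts[0] - (y[i] == 0), counts[1] - (y[i] == 1)) < 2:
            continue
        tr = idx != i
        Xtr = X[tr]
        mean = Xtr.mean(axis=0)
        scale = Xtr.std(axis=0)
        scale[scale == 0] = 1.0
        Z = (Xtr - mean) / scale
        zi = (X[i] - mean) / scale
        d2 = ((Z - zi) ** 2).sum(axis=1)
        ytr = y[tr]
        d_pos = d2[ytr == 1].min()
        d_neg = d2[ytr == 0].min()
        pred = d_pos <= d_neg
        correct += int(pred == bool(y[i]))
    return correct / n


def _inner_loo_accuracy(X: np.ndarray, y: np.ndarray, kind: str) -> float:
    """Leave-one-out accuracy on the training subjects (SFS utility).

    naive_bayes and knn use closed-form fast paths equivalent to refitting
    per fold; logistic refits the IRLS model per fold.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if kind == "naive_bayes":
        return _loo_accuracy_nb(X, y)
    if kind == "knn":
        return _loo_accuracy_knn(X, y)
    n = len(y)
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        ytr = y[tr]
        if len(np.unique(ytr)) < 2 or np.bincount(ytr, minlength=2).min() < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_classifier(kind, X[tr], ytr)
        pred = model.score(X[i : i + 1])[0] >= 0.5
        correct += int(pred == bool(y[i]))
    return correct / n


def sfs_select(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    max_features: int = 3,
    candidates: list[int] | None = None,
) -> list[int]:
    """Greedy wrapper SFS on the training set; returns ordered column indices.

    The feature budget is the smaller of ``max_features`` and the
    one-in-ten-rule cap floor(n_train / 10); a cap below one is an error.
    Candidate columns containing missing values are excluded up front.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("SFS requires both classes in the training set")
    cap = min(max_features, len(y) // 10)
    if cap < 1:
        raise ValueError(
            f"one-in-ten rule cap is {len(y) // 10} for n={len(y)}; too few subjects"
        )
    pool = candidates if candidates is not None else list(range(X.shape[1]))
    pool = [j for j in pool if np.isfinite(X[:, j]).all()]
    selected: list[int] = []
    best_util = -np.inf
    while len(selected) < cap and pool:
        utils = np.array(
            [_inner_loo_accuracy(X[:, selected + [j]], y, kind) for j in pool]
        )
        j_best = int(np.argmax(utils))  # argmax takes the first = lowest index on ties
        if utils[j_best] <= best_util:
            break
        best_util = float(utils[j_best])
        selected.append(pool.pop(j_best))
    return selected


# ---------------------------------------------------------------------------
# Pooled metrics and LOOCV


def _auc_concordance(scores: np.ndarray, y: np.ndarray) -> float:
    """Pairwise concordance probability, ties counted one half."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (len(pos) * len(neg)))


def delong_ci(scores: np.ndarray, y: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """DeLong asymptotic confidence interval for the pooled AUC."""
    from scipy.stats import norm

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    auc = psi.mean()
    v10 = psi.mean(axis=1)  # structural components over positives
    v01 = psi.mean(axis=0)
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))


@dataclass(frozen=True)
class PooledMetrics:
    sensitivity: float  # %
    specificity: float  # %
    accuracy: float  # %
    auc: float
    auc_ci: tuple[float, float]


def pooled_metrics(
    scores: np.ndarray, y: np.ndarray, threshold: float = 0.5
) -> PooledMetrics:
    """Sn/Sp/Acc (percent, threshold on the score) and AUC with DeLong CI.

    The positive class (label 1) is complete response; sensitivity is the
    detection rate of complete responders.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("pooled metrics need both classes")
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    auc = _auc_concordance(scores, y)
    return PooledMetrics(
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        accuracy=100.0 * (tp + tn) / len(y),
        auc=auc,
        auc_ci=delong_ci(scores, y),
    )


@dataclass
class FoldResult:
    held_out_id: str
    score: float
    predicted: str
    true_label: str
    selected_features: list[str]


@dataclass
class ClassifierResult:
    kind: str
    max_features: int
    folds: list[FoldResult]
    metrics: PooledMetrics

    def selected_feature_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for fold in self.folds:
            for f in fold.selected_features:
                counts[f] = counts.get(f, 0) + 1
        return dict(sorted(counts.items(), key=lambda kv: -kv[1]))


def loocv_evaluate(
    records: list[SubjectRecord],
    kind: str,
    max_features: int = 3,
    feature_names: list[str] | None = None,
    fixed_features: list[str] | None = None,
) -> ClassifierResult:
    """Subject-level leave-one-out evaluation with per-fold selection.

    For each subject, standardization, SFS and training use only the other
    n-1 subjects; the held-out subject is never touched until scoring.  Pass
    ``fixed_features`` to evaluate a predetermined feature set (no SFS), as
    for the published univariate/multivariate models.
    """
    if feature_names is None:
        feature_names = sorted(records[0].features.keys()) if fixed_features is None else None
    if fixed_features is not None:
        feature_names = fixed_features
    X, y, ids = records_to_matrix(records, feature_names)
    n = len(records)
    if n < 10:
        raise ValueError("LOOCV protocol requires n >= 10 subjects")
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both classes")
    folds = []
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        if fixed_features is not None:
            cols = list(range(len(feature_names)))
        else:
            cols = sfs_select(X[tr], y[tr], kind, max_features)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_classifier(kind, X[np.ix_(tr, cols)], y[tr])
        s = float(model.score(X[i : i + 1, cols])[0])
        scores[i] = s
        folds.append(
            FoldResult(
                held_out_id=ids[i],
                score=s,
                predicted=POSITIVE_LABEL if s >= 0.5 else "PR",
                true_label=POSITIVE_LABEL if y[i] == 1 else "PR",
                selected_features=[feature_names[c] for c in cols],
            )
        )
    return ClassifierResult(
        kind=kind,
        max_features=len(feature_names) if fixed_features is not None else max_features,
        folds=folds,
        metrics=pooled_metrics(scores, y),
    )
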