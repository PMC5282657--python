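"""Three-way leaf-shape classification (mosaic / semi-mosaic / round).

Three classifiers operate on the 19-trait feature table:

* stepwise discriminant analysis (SDA), written from scratch: traits enter
  one at a time by the largest drop in Wilks' Lambda (the ratio of
  within-class to total scatter determinants), gated by an F-to-enter test;
  after every entry, already-included traits whose partial F falls below the
  F-to-remove threshold are dropped.  Two canonical linear discriminant
  functions are then fitted on the selected traits and samples are assigned
  to the nearest class centroid in that 2-D canonical space;
* a polynomial-kernel support vector machine with features min-max scaled to
  [0, 1] on training statistics only (kernel parameter gamma = 1.5, penalty
  C = 2, one-vs-one multiclass);
* a random forest (default 1000 trees, majority vote).

Evaluation supports a fixed train/test split and leave-one-out
cross-validation; in LOO every per-fold step (scaling, stepwise selection)
is refitted inside the fold, so no information leaks from the held-out
sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

CLASS_ORDER = ("mosaic", "semi-mosaic", "round")
DEFAULT_SEED = 20170131


@dataclass
class FeatureTable:
    """Samples x traits with optional 3-class labels."""

    features: pd.DataFrame            # numeric, one row per sample
    labels: np.ndarray | None = None  # str per sample, or None
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = pd.DataFrame(self.features).astype(float)
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.features):
                raise ValueError("labels length mismatch")
            if len(np.unique(self.labels)) > 3:
                raise ValueError("at most 3 classes supported")
        if self.ids is None:
            self.ids = np.arange(len(self.features))

    def subset(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            self.features.iloc[idx].reset_index(drop=True),
            None if self.labels is None else self.labels[idx],
            np.asarray(self.ids)[idx],
        )

    @classmethod
    def from_csv(cls, path, label_column: str = "label",
                 id_column: str = "id") -> "FeatureTable":
        df = pd.read_csv(path, comment="#")
        labels = df.pop(label_column).to_numpy() if label_column in df else None
        ids = df.pop(id_column).to_numpy() if id_column in df else None
        return cls(df, labels, ids)


@dataclass
class StepwiseModel:
    selected_traits: list
    wilks_path: list
    lda_functions: tuple        # (coef (p, 2), intercept (2,))
    class_centroids: np.ndarray  # (n_classes, 2)
    classes: np.ndarray
    history: list = field(default_factory=list)


@dataclass
class ClassificationReport:
    confusion: pd.DataFrame      # rows = true class, percent
    accuracy: float              # percent
    loo_cv_accuracy: float | None = None


# --------------------------------------------------------------------------
# Wilks' Lambda machinery

def _scatter_matrices(X: np.ndarray, y: np.ndarray):
    """Within-class (W) and total (T) scatter matrices."""
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for cls in np.unique(y):
        Xc = X[y == cls]
        mc = Xc.mean(axis=0)
        W += (Xc - mc).T @ (Xc - mc)
    return W, T


def wilks_lambda(X: np.ndarray, y: np.ndarray, cols) -> float:
    """Lambda = det(W) / det(T) on the selected columns; 1.0 for no columns."""
    cols = list(cols)
    if not cols:
        return 1.0
    W, T = _scatter_matrices(X[:, cols], y)
    det_t = linalg.det(T)
    if det_t <= 0:
        return np.inf
    det_w = linalg.det(W)
    if det_w < 0:
        return np.inf
    return float(det_w / det_t)


def _partial_f(lam_small: float, lam_big: float, n: int, g: int, p: int) -> float:
    """F statistic for adding the (p+1)-th variable: lam_big has p+1 vars.

    F = ((n - g - p) / (g - 1)) * (lam_small / lam_big - 1)
    """
    if lam_big <= 0 or not np.isfinite(lam_big):
        return 0.0
    dof = n - g - p
    if dof <= 0:
        return 0.0
    return (dof / (g - 1)) * (lam_small / lam_big - 1.0)


def stepwise_select(train: FeatureTable, f_enter: float = 3.84,
                    f_remove: float = 2.71) -> StepwiseModel:
    """Stepwise trait selection by Wilks' Lambda with F entry/removal gates.

    At each step the candidate minimizing the partial Lambda enters if its
    F-to-enter exceeds ``f_enter``; afterwards any included trait whose
    F-to-remove falls below ``f_remove`` leaves again.  Terminates when no
    move qualifies, then fits the canonical discriminant functions.
    """
    if train.labels is None:
        raise ValueError("training table needs labels")
    X = train.features.to_numpy()
    y = train.labels
    names = list(train.features.columns)
    classes = np.unique(y)
    g = len(classes)
    if g < 2 or min((y == c).sum() for c in classes) < 2:
        raise ValueError("need >= 2 classes with >= 2 samples each")
    n = len(X)

    selected: list[int] = []
    wilks_path: list[float] = []
    history: list[tuple] = []
    current_lam = 1.0
    while True:
        moved = False
        # entry step
        best = None
        for j in range(X.shape[1]):
            if j in selected:
                continue
            lam = wilks_lambda(X, y, selected + [j])
            if not np.isfinite(lam):
                warnings.warn(f"trait {names[j]} gives singular scatter; skipped")
                continue
            if best is None or lam < best[1]:
                best = (j, lam)
        if best is not None:
            j, lam = best
            f = _partial_f(current_lam, lam, n, g, len(selected))
            if f > f_enter:
                selected.append(j)
                current_lam = lam
                wilks_path.append(lam)
                history.append(("enter", names[j], lam, f))
                moved = True
        # removal step
        if len(selected) > 1:
            while True:
                worst = None
                for j in selected:
                    rest = [s for s in selected if s != j]
                    lam_rest = wilks_lambda(X, y, rest)
                    f = _partial_f(lam_rest, current_lam, n, g, len(rest))
                    if worst is None or f < worst[1]:
                        worst = (j, f, lam_rest)
                if worst is not None and worst[1] < f_remove:
                    j, f, lam_rest = worst
                    selected.remove(j)
                    current_lam = lam_rest
                    history.append(("remove", names[j], lam_rest, f))
                    moved = True
                    if len(selected) <= 1:
                        break
                else:
                    break
        if not moved:
            break

    if not selected:
        raise ValueError("no variable qualifies for entry")

    coef, intercept, centroids = _canonical_lda(X[:, selected], y, classes)
    return StepwiseModel(
        selected_traits=[names[j] for j in selected],
        wilks_path=wilks_path,
        lda_functions=(coef, intercept),
        class_centroids=centroids,
        classes=classes,
        history=history,
    )


def _canonical_lda(X: np.ndarray, y: np.ndarray, classes: np.ndarray):
    """Two canonical discriminant functions from the W^-1 B eigenproblem."""
    W, T = _scatter_matrices(X, y)
    B = T - W
    n, p = X.shape
    Sw = W / max(n - len(classes), 1)
    # ridge for numerically singular within-class scatter
    Sw = Sw + 1e-10 * np.trace(Sw) / max(p, 1) * np.eye(p)
    evals, evecs = linalg.eigh(B, Sw * max(n - len(classes), 1))
    order = np.argsort(evals)[::-1]
    n_func = min(len(classes) - 1, p)
    coef = evecs[:, order[:n_func]]
    if coef.shape[1] < 2:  # pad a zero second function for 2-D plotting space
        coef = np.hstack([coef, np.zeros((p, 1))])
    grand = X.mean(axis=0)
    intercept = -grand @ coef
    centroids = np.vstack([(X[y == c].mean(axis=0)) @ coef + intercept
                           for c in classes])
    return coef, intercept, centroids


def classify_lda(model: StepwiseModel, table: FeatureTable) -> np.ndarray:
    """Nearest-centroid assignment in the 2-D canonical function space."""
    missing = [t for t in model.selected_traits if t not in table.features]
    if missing:
        raise ValueError(f"table lacks selected traits: {missing}")
    X = table.features[model.selected_traits].to_numpy()
    coef, intercept = model.lda_functions
    scores = X @ coef + intercept
    d = np.linalg.norm(scores[:, None, :] - model.class_centroids[None], axis=2)
    # ties resolve to the lowest class index (argmin is first minimum)
    return model.classes[np.argmin(d, axis=1)]


# --------------------------------------------------------------------------
# SVM and random forest

def _minmax_fit(X: np.ndarray):
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        warnings.warn("constant feature(s) scaled to 0")
    span = np.where(constant, 1.0, span)
    return lo, span, constant


def _minmax_apply(X, lo, span, constant):
    Xs = (X - lo) / span
    Xs[:, constant] = 0.0
    return Xs


def svm_classify(train: FeatureTable, test: FeatureTable,
                 kernel_param: float = 1.5, penalty: float = 2.0,
                 degree: int = 3) -> np.ndarray:
    """Polynomial-kernel SVM, (gamma <x,y>)^degree with gamma = kernel_param.

    Features are min-max scaled to [0, 1] using training statistics only
    (test values outside the training range map outside [0, 1], no
    clipping).  Multiclass is one-vs-one.
    """
    if train.labels is None:
        raise ValueError("training table needs labels")
    Xtr = train.features.to_numpy()
    Xte = test.features[train.features.columns].to_numpy()
    lo, span, constant = _minmax_fit(Xtr)
    clf = SVC(kernel="poly", degree=degree, gamma=kernel_param, coef0=0.0,
              C=penalty)
    clf.fit(_minmax_apply(Xtr, lo, span, constant), train.labels)
    return clf.predict(_minmax_apply(Xte, lo, span, constant))


def rf_classify(train: FeatureTable, test: FeatureTable,
                n_trees: int = 1000, seed: int = DEFAULT_SEED) -> np.ndarray:
    """Random forest majority vote with a fixed seed for reproducibility."""
    if train.labels is None:
        raise ValueError("training table needs labels")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(train.features.to_numpy(), train.labels)
    return clf.predict(test.features[train.features.columns].to_numpy())


# --------------------------------------------------------------------------
# Evaluation

def _predict(method: str, train: FeatureTable, test: FeatureTable,
             **params) -> np.ndarray:
    if method == "sda":
        try:
            model = stepwise_select(train,
                                    f_enter=params.get("f_enter", 3.84),
                                    f_remove=params.get("f_remove", 2.71))
        except ValueError as exc:
            if "no variable qualifies" not in str(exc):
                raise
            # Nothing discriminates: emit a fixed, prior-free class (the
            # first in sort order).  Using the modal class instead would be
            # anti-correlated under LOO, where the held-out sample's class
            # is always one short in the training fold.
            classes = np.unique(train.labels)
            return np.full(len(test.features), classes[0])
        return classify_lda(model, test)
    if method == "svm":
        return svm_classify(train, test,
                            kernel_param=params.get("kernel_param", 1.5),
                            penalty=params.get("penalty", 2.0),
                            degree=params.get("degree", 3))
    if method == "rf":
        return rf_classify(train, test,
                           n_trees=params.get("n_trees", 1000),
                           seed=params.get("seed", DEFAULT_SEED))
    raise ValueError(f"unknown method: {method!r}")


def _confusion_percent(y_true: np.ndarray, y_pred: np.ndarray,
                       classes: np.ndarray) -> pd.DataFrame:
    mat = np.zeros((len(classes), len(classes)))
    for i, c in enumerate(classes):
        sel = y_true == c
        total = sel.sum()
        for j, p in enumerate(classes):
            mat[i, j] = 100.0 * np.sum(y_pred[sel] == p) / total if total else 0.0
    return pd.DataFrame(mat, index=classes, columns=classes)


def loo_predict(method: str, table: FeatureTable, **params) -> np.ndarray:
    """Leave-one-out predictions; every fold refits the full pipeline."""
    if table.labels is None:
        raise ValueError("labeled table required")
    n = len(table.features)
    preds = np.empty(n, dtype=object)
    all_idx = np.arange(n)
    for i in range(n):
        train = table.subset(all_idx[all_idx != i])
        if len(np.unique(train.labels)) < len(np.unique(table.labels)):
            raise ValueError(f"class absent from training fold {i}")
        preds[i] = _predict(method, train, table.subset([i]), **params)[0]
    return preds.astype(str)


def evaluate(method: str, table: FeatureTable, mode: str = "loo",
             test: FeatureTable | None = None,
             with_loo: bool = False, **params) -> ClassificationReport:
    """Evaluate one classifier by split or leave-one-out cross-validation.

    ``mode='split'`` fits on ``table`` and reports on ``test`` (which must
    carry labels); ``mode='loo'`` aggregates leave-one-out predictions over
    ``table``.  ``with_loo`` additionally attaches the LOO accuracy to a
    split report.
    """
    if table.labels is None:
        raise ValueError("labeled table required")
    classes = np.unique(table.labels)
    if mode == "split":
        if test is None or test.labels is None:
            raise ValueError("split mode needs a labeled test table")
        y_pred = _predict(method, table, test, **params)
        y_true = test.labels
    elif mode == "loo":
        y_pred = loo_predict(method, table, **params)
        y_true = table.labels
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    conf = _confusion_percent(y_true, y_pred, classes)
    acc = 100.0 * float(np.mean(y_pred == y_true))
    loo_acc = None
    if with_loo:
        loo_pred = loo_predict(method, table, **params)
        loo_acc = 100.0 * float(np.mean(loo_pred == table.labels))
    if mode == "loo":
        loo_acc = acc
    return ClassificationReport(conf, acc, loo_acc)
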