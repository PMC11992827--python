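"""AdaBoost compound-target interaction classifier and its evaluation.

The classifier is a boosted ensemble of depth-limited decision trees,
f(x) = sign(sum_k alpha_k G_k(x)), with the weak-learner capacity expressed
as a maximum number of splits.  Weak learners are fitted with scikit-learn
(SAMME boosting); the ensemble decision rule, the evaluation metrics
(precision, recall, F1, rank-statistic AUC, MCC) and the cross-validation
harness are implemented here.  A tie at the decision threshold (score exactly
0) predicts negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier


# ---------------------------------------------------------------------------
# feature normalization (parameters saved for reuse at predict time)


@dataclass
class Normalizer:
    """Per-column rescaling fitted on training data.

    ``minmax`` maps each column to [0, 1] by its training min/max (constant
    columns map to 0); ``zscore`` centers and scales by the training std.
    Test values outside the training range may leave [0, 1]; that is allowed.
    """

    method: str = "minmax"
    offset: np.ndarray | None = None
    scale: np.ndarray | None = None
    columns: list[str] | None = None

    def fit(self, X: pd.DataFrame) -> "Normalizer":
        values = X.to_numpy(dtype=float)
        if self.method == "minmax":
            lo, hi = values.min(axis=0), values.max(axis=0)
            self.offset, self.scale = lo, hi - lo
        elif self.method == "zscore":
            self.offset, self.scale = values.mean(axis=0), values.std(axis=0)
        else:
            raise ValueError(f"unknown normalization method {self.method!r}")
        self.scale = np.where(self.scale == 0, 1.0, self.scale)  # constants -> 0
        self.columns = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.offset is None:
            raise RuntimeError("Normalizer not fitted")
        values = (X[self.columns].to_numpy(dtype=float) - self.offset) / self.scale
        return pd.DataFrame(values, columns=self.columns, index=X.index)

    def to_jsonable(self) -> dict:
        return {
            "method": self.method,
            "offset": self.offset.tolist(),
            "scale": self.scale.tolist(),
            "columns": self.columns,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "Normalizer":
        return cls(
            method=d["method"],
            offset=np.asarray(d["offset"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            columns=list(d["columns"]),
        )


def normalize_features(table: pd.DataFrame, method: str = "minmax"):
    """Fit a :class:`Normalizer` on a feature table and return
    ``(normalized table, normalizer)``; the label column passes through."""
    features = table.drop(columns=["label"], errors="ignore")
    norm = Normalizer(method=method).fit(features)
    out = norm.transform(features)
    if "label" in table.columns:
        out["label"] = table["label"].to_numpy()
    return out, norm


# ---------------------------------------------------------------------------
# the boosted ensemble


@dataclass
class _TreeArrays:
    """A fitted decision tree flattened to arrays for traversal/serialization."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_class: np.ndarray  # predicted class (0/1) at each node

    @classmethod
    def from_sklearn(cls, tree: DecisionTreeClassifier, classes: np.ndarray) -> "_TreeArrays":
        t = tree.tree_
        leaf_class = classes[np.argmax(t.value.reshape(t.node_count, -1), axis=1)]
        return cls(
            t.children_left.copy(), t.children_right.copy(),
            t.feature.copy(), t.threshold.copy(), leaf_class.astype(int),
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=int)
        while True:
            internal = self.children_left[node] >= 0
            if not internal.any():
                break
            idx = np.where(internal)[0]
            go_left = X[idx, self.feature[node[idx]]] <= self.threshold[node[idx]]
            node[idx] = np.where(
                go_left, self.children_left[node[idx]], self.children_right[node[idx]]
            )
        return self.leaf_class[node]

    def to_jsonable(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "leaf_class": self.leaf_class.tolist(),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "_TreeArrays":
        return cls(
            np.asarray(d["children_left"]), np.asarray(d["children_right"]),
            np.asarray(d["feature"]), np.asarray(d["threshold"], dtype=float),
            np.asarray(d["leaf_class"]),
        )


@dataclass
class AdaboostModel:
    """The trained ensemble: weak learners, their weights and the fitted
    normalizer, with the descriptor roster it expects."""

    trees: list[_TreeArrays]
    alphas: np.ndarray
    normalizer: Normalizer
    columns: list[str]
    kind: str = ""

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Weighted vote sum_k alpha_k (2 G_k(x) - 1); positive means class 1."""
        Xn = self.normalizer.transform(X[self.columns]).to_numpy(dtype=float)
        score = np.zeros(len(Xn))
        for alpha, tree in zip(self.alphas, self.trees):
            score += alpha * (2.0 * tree.predict(Xn) - 1.0)
        return score

    def save(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "alphas": self.alphas.tolist(),
            "trees": [t.to_jsonable() for t in self.trees],
            "normalizer": self.normalizer.to_jsonable(),
            "columns": self.columns,
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "AdaboostModel":
        d = json.loads(Path(path).read_text())
        return cls(
            trees=[_TreeArrays.from_jsonable(t) for t in d["trees"]],
            alphas=np.asarray(d["alphas"], dtype=float),
            normalizer=Normalizer.from_jsonable(d["normalizer"]),
            columns=list(d["columns"]),
            kind=d["kind"],
        )


def _check_training_inputs(X: np.ndarray, y: np.ndarray) -> None:
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")


def fit_adaboost(
    table: pd.DataFrame,
    labels=None,
    max_splits: int = 20,
    n_learners: int = 30,
    learning_rate: float = 0.1,
    seed: int = 0,
    normalization: str = "minmax",
) -> AdaboostModel:
    """Train the boosted CTI classifier.

    ``max_splits`` limits each weak tree to at most that many internal splits
    (max_leaf_nodes = max_splits + 1).  Normalization is fitted on the
    training features and stored with the model.  Deterministic given seed.
    """
    if labels is None:
        labels = table["label"]
    features = table.drop(columns=["label"], errors="ignore")
    y = np.asarray(labels, dtype=int)
    norm = Normalizer(method=normalization).fit(features)
    Xn = norm.transform(features).to_numpy(dtype=float)
    _check_training_inputs(Xn, y)

    clf = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_leaf_nodes=max_splits + 1, random_state=seed),
        n_estimators=n_learners,
        learning_rate=learning_rate,
        random_state=seed,
    )
    clf.fit(Xn, y)
    trees = [_TreeArrays.from_sklearn(est, clf.classes_) for est in clf.estimators_]
    alphas = np.asarray(clf.estimator_weights_[: len(trees)], dtype=float)
    return AdaboostModel(
        trees=trees, alphas=alphas, normalizer=norm,
        columns=list(features.columns), kind=table.attrs.get("kind", ""),
    )


def fit_stump_baseline(table: pd.DataFrame, labels=None, seed: int = 0) -> AdaboostModel:
    """Single decision-stump baseline behind the same model interface, for
    comparison against the boosted ensemble."""
    return fit_adaboost(table, labels, max_splits=1, n_learners=1, learning_rate=1.0, seed=seed)


def predict(model: AdaboostModel, rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Scores (the weighted vote sum) and hard labels; a score of exactly 0
    predicts negative."""
    if len(rows) == 0:
        return np.array([]), np.array([], dtype=int)
    scores = model.decision_scores(rows)
    return scores, (scores > 0).astype(int)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    auc: float
    mcc: float
    counts: ConfusionCounts
    m_positives: int = 0
    n_negatives: int = 0
    folds: list[dict] = field(default_factory=list)
    notes: str = ""

    def to_jsonable(self) -> dict:
        d = {
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "auc": self.auc, "mcc": self.mcc,
            "counts": vars(self.counts),
            "M": self.m_positives, "N": self.n_negatives,
        }
        if self.folds:
            d["folds"] = self.folds
        if self.notes:
            d["notes"] = self.notes
        return d


def rank_auc(scores, labels) -> float:
    """AUC via the rank statistic: (sum of positive ranks - M(M+1)/2)/(M N),
    with average ranks on ties.  Equals the fraction of positive-negative
    pairs ordered correctly, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    m = int(np.sum(labels == 1))
    n = int(np.sum(labels == 0))
    if m == 0 or n == 0:
        raise ValueError("rank AUC needs at least one positive and one negative")
    ranks = rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def metrics(counts: ConfusionCounts, scores=None, labels=None) -> MetricsReport:
    """Precision, recall, F1 and MCC from confusion counts; rank AUC from the
    continuous scores when given (0-denominator metrics report 0)."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    auc = rank_auc(scores, labels) if scores is not None else float("nan")
    labels_arr = np.asarray(labels, dtype=int) if labels is not None else None
    return MetricsReport(
        precision=float(precision), recall=float(recall), f1=float(f1),
        auc=auc, mcc=mcc(counts), counts=counts,
        m_positives=int((labels_arr == 1).sum()) if labels_arr is not None else tp + fn,
        n_negatives=int((labels_arr == 0).sum()) if labels_arr is not None else counts.tn + fp,
    )


# ---------------------------------------------------------------------------
# cross validation


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row order independent of input permutation (content-lexicographic)."""
    keys = [X[:, j] for j in range(X.shape[1] - 1, -1, -1)] + [y]
    return np.lexsort(keys)


def kfold_cv(
    table: pd.DataFrame,
    labels=None,
    k: int = 10,
    seed: int = 0,
    max_splits: int = 20,
    n_learners: int = 30,
    learning_rate: float = 0.1,
    normalization: str = "minmax",
) -> MetricsReport:
    """Stratified k-fold cross validation of the boosted classifier.

    Rows are first put in a content-canonical order, then permuted by the
    seeded RNG, so fold membership (and hence every metric) is invariant to
    the order rows arrive in.  Normalization is fitted inside each training
    fold only.  Returns the pooled report with a per-fold breakdown.
    """
    if labels is None:
        labels = table["label"]
    features = table.drop(columns=["label"], errors="ignore")
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")

    rng = np.random.default_rng(seed)
    order = _canonical_order(X, y)[rng.permutation(n)]

    # stratified round-robin assignment over the shuffled canonical order
    fold_of = np.empty(n, dtype=int)
    for cls in np.unique(y):
        members = order[y[order] == cls]
        fold_of[members] = np.arange(len(members)) % k

    pooled_scores = np.empty(n)
    pooled_pred = np.empty(n, dtype=int)
    folds = []
    for fold in range(k):
        test = fold_of == fold
        train_tbl = features[~test]
        model = fit_adaboost(
            train_tbl.assign(label=y[~test]), max_splits=max_splits,
            n_learners=n_learners, learning_rate=learning_rate,
            seed=seed, normalization=normalization,
        )
        scores, pred = predict(model, features[test])
        pooled_scores[test], pooled_pred[test] = scores, pred
        fold_counts = ConfusionCounts.from_labels(y[test], pred)
        fold_report = metrics(fold_counts, scores if len(np.unique(y[test])) > 1 else None,
                              y[test] if len(np.unique(y[test])) > 1 else None)
        folds.append({"fold": fold, **fold_report.to_jsonable()})

    report = metrics(ConfusionCounts.from_labels(y, pooled_pred), pooled_scores, y)
    report.folds = folds
    report.notes = f"stratified {k}-fold CV, seed={seed}"
    return report


# ---------------------------------------------------------------------------
# per-target screening


def screen_targets(
    model: AdaboostModel,
    compounds: pd.DataFrame,
    sequences: dict[str, str],
    targets: list[str] | None = None,
    uniprot_ids: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Predict every compound against every target and report, per target,
    the percentage of compounds predicted to interact (CTI success rate)."""
    from .features import assemble_feature_table

    if not model.kind:
        raise ValueError("model does not record its dataset kind")
    variant = "full" if model.kind.endswith("F") else "motif"
    if targets is None:
        suffix = f"|{variant}"
        targets = sorted(k[: -len(suffix)] for k in sequences if k.endswith(suffix))
    rows = []
    for tid in targets:
        pairs = pd.DataFrame({
            "compound_id": compounds["compound_id"],
            "target_id": tid,
            "label": 0,  # placeholder; predictions ignore it
        })
        feats = assemble_feature_table(pairs, compounds, sequences, model.kind)
        _, pred = predict(model, feats)
        rows.append({
            "target_id": tid,
            "uniprot_id": (uniprot_ids or {}).get(tid, ""),
            "success_rate": 100.0 * float(np.mean(pred)),
        })
    return pd.DataFrame(rows, columns=["target_id", "uniprot_id", "success_rate"])
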