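"""Binary classification with cross-validated ROC/AUC.

Method 1 is a random forest (500 trees, sqrt(p) features per split,
unlimited depth).  Method 2 is a pluggable automated model-selection
backend behind a score-producing interface; the package ships a simple
built-in logistic-regression backend, and external frameworks can be
registered at run time.  If a configured backend is unavailable the
pipeline records the skip and continues with method 1 only.

Evaluation: five-fold cross-validation, AUC per fold by the rank
(Mann-Whitney) statistic with ties counted 1/2, mean and variance across
folds, and a 95% CI from the t distribution with n_folds - 1 degrees of
freedom.  Folds are stratified by class and can group by patient so all
cells of one patient share a fold (recommended: cells within a patient are
correlated; cell-level folding is the default to mirror common practice
but is optimistic under patient effects).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ValidationError
from .model import FeatureTable
from .selection import SelectionResult, rank_and_select

RF_DEFAULTS = {"n_estimators": 500, "max_features": "sqrt", "max_depth": None}


# -- fold planning -----------------------------------------------------------

@dataclass
class FoldPlan:
    n_folds: int
    assignment: Dict[str, int]        # cell_id -> fold index
    stratified: bool
    grouping: str                     # "cell" | "patient"
    seed: int

    def test_ids(self, fold: int) -> List[str]:
        return [cid for cid, f in self.assignment.items() if f == fold]

    def train_ids(self, fold: int) -> List[str]:
        return [cid for cid, f in self.assignment.items() if f != fold]


def make_folds(table: FeatureTable, n_folds: int = 5, grouping: str = "cell",
               seed: int = 0, stratified: bool = True) -> FoldPlan:
    """Deterministic stratified fold assignment at cell or patient level."""
    cell_ids = list(table.cell_ids)
    labels = np.asarray(table.labels)
    classes = sorted(set(labels))
    y = np.array([classes.index(v) for v in labels])
    rng = np.random.default_rng(seed)

    if grouping == "cell":
        if len(cell_ids) < n_folds:
            raise ValidationError("fewer cells than folds")
        folds = np.empty(len(cell_ids), dtype=int)
        if stratified:
            # deal shuffled cells of each class round-robin over folds,
            # rotating the starting fold per class to balance fold sizes
            start = 0
            for ci in range(len(classes)):
                idx = np.nonzero(y == ci)[0]
                rng.shuffle(idx)
                folds[idx] = (start + np.arange(idx.size)) % n_folds
                start += idx.size
        else:
            idx = rng.permutation(len(cell_ids))
            folds[idx] = np.arange(len(cell_ids)) % n_folds
        assignment = {cid: int(f) for cid, f in zip(cell_ids, folds)}
    elif grouping == "patient":
        patients = np.asarray(table.patient_ids)
        uniq = sorted(set(patients))
        if len(uniq) < n_folds:
            raise ValidationError("fewer patients than folds under patient grouping")
        # assign patients round-robin within their majority class, shuffled
        pat_class = {}
        for p in uniq:
            labs = labels[patients == p]
            vals, counts = np.unique(labs, return_counts=True)
            pat_class[p] = vals[np.argmax(counts)]
        # each class dealt round-robin from fold 0 so test folds stay
        # class-balanced; infeasible fold counts surface as empty folds
        pat_fold = {}
        for cls in classes:
            order = np.array([p for p in uniq if pat_class[p] == cls], dtype=object)
            rng.shuffle(order)
            for i, p in enumerate(order):
                pat_fold[p] = i % n_folds
        assignment = {cid: int(pat_fold[p]) for cid, p in zip(cell_ids, patients)}
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")

    plan = FoldPlan(n_folds=n_folds, assignment=assignment,
                    stratified=stratified, grouping=grouping, seed=seed)
    # every training split must contain both classes
    for f in range(n_folds):
        train = set(plan.train_ids(f))
        train_labels = {lab for cid, lab in zip(cell_ids, labels) if cid in train}
        if len(train_labels) < len(classes):
            raise ValidationError(
                f"fold {f}: a class is absent from the training split; use fewer folds"
            )
        if not plan.test_ids(f):
            raise ValidationError(f"fold {f} is empty; use fewer folds")
    return plan


# -- ROC / AUC ---------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence,
            positive_label=None) -> Tuple[np.ndarray, float]:
    """Step ROC curve and AUC by the rank/Mann-Whitney statistic (ties = 1/2).

    Returns ``(points, auc)`` where points is an (m, 2) array of (FPR, TPR)
    from (0, 0) to (1, 1), monotone nondecreasing in both coordinates.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValidationError("ROC/AUC requires exactly two classes in the labels")
    pos = positive_label if positive_label is not None else classes[1]
    y = labels == pos
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC/AUC requires both classes present")

    ranks = stats.rankdata(scores)            # midranks handle ties as 1/2
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # step curve: sweep thresholds from high to low, grouping tied scores
    order = np.argsort(-scores, kind="mergesort")
    y_sorted = y[order]
    s_sorted = scores[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    last_of_tie = np.nonzero(np.diff(s_sorted) != 0)[0]
    keep = np.append(last_of_tie, y.size - 1)
    points = np.column_stack([fp[keep] / n_neg, tp[keep] / n_pos])
    points = np.vstack([[0.0, 0.0], points])
    return points, float(auc)


# -- classifiers -------------------------------------------------------------

def train_rf_and_score(train: FeatureTable, test: FeatureTable,
                       features: Sequence[str], class_b: str,
                       seed: int = 0,
                       rf_config: Optional[dict] = None) -> np.ndarray:
    """Fit the random forest on the training cells and return probability
    scores for ``class_b`` on the test cells."""
    cfg = dict(RF_DEFAULTS)
    cfg.update(rf_config or {})
    y_train = train.labels
    if len(set(y_train)) < 2:
        raise ValidationError("degenerate training set: only one class present")
    clf = RandomForestClassifier(random_state=seed, n_jobs=1, **cfg)
    clf.fit(train.matrix(features), y_train)
    proba = clf.predict_proba(test.matrix(features))
    col = list(clf.classes_).index(class_b)
    return proba[:, col]


BackendFn = Callable[[np.ndarray, np.ndarray, np.ndarray, dict, int], np.ndarray]
_BACKENDS: Dict[str, BackendFn] = {}


def register_backend(name: str, fn: BackendFn) -> None:
    """Register an automated model-selection backend.

    ``fn(X_train, y_train, X_test, config, seed)`` must return scores in
    [0, 1] for the positive class (y == 1)."""
    _BACKENDS[name] = fn


def _logistic_backend(X_train, y_train, X_test, config, seed):
    model = make_pipeline(StandardScaler(),
                          LogisticRegression(max_iter=1000, random_state=seed,
                                             **(config.get("logistic_kwargs") or {})))
    model.fit(X_train, y_train)
    return model.predict_proba(X_test)[:, 1]


register_backend("logistic", _logistic_backend)


def run_automl_backend(train: FeatureTable, test: FeatureTable,
                       features: Sequence[str], class_b: str,
                       backend_config: Optional[dict] = None,
                       seed: int = 0) -> Tuple[Optional[np.ndarray], str]:
    """Score the test cells with a registered backend.

    Returns ``(scores, status)``; scores is None when the backend is absent
    or fails, and the status string records why so the pipeline can continue
    with method 1 only."""
    backend_config = backend_config or {}
    name = backend_config.get("name", "logistic")
    fn = _BACKENDS.get(name)
    if fn is None:
        return None, f"backend unavailable: {name!r} not registered"
    y_train = (train.labels == class_b).astype(int)
    if y_train.min() == y_train.max():
        raise ValidationError("degenerate training set: only one class present")
    try:
        scores = fn(train.matrix(features), y_train, test.matrix(features),
                    backend_config, seed)
    except Exception as exc:  # backend failure must not abort the pipeline
        return None, f"backend {name!r} failed: {exc}"
    return np.asarray(scores, dtype=float), f"ok:{name}"


# -- cross-validated comparison ----------------------------------------------

@dataclass
class CVResult:
    """Five-fold ROC/AUC summary for one binary comparison and classifier."""

    comparison: Tuple[str, str]
    classifier_id: str
    per_fold_auc: List[float]
    mean_auc: float
    fold_variance: float
    ci95: Tuple[float, float]
    roc_points: np.ndarray                      # pooled step curve
    per_fold_roc: List[np.ndarray] = field(default_factory=list)
    feature_set: Optional[List[str]] = None     # global-mode selection
    fold_features: List[List[str]] = field(default_factory=list)
    fold_train_cells: List[List[str]] = field(default_factory=list)
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "comparison": list(self.comparison),
            "classifier_id": self.classifier_id,
            "per_fold_auc": [float(a) for a in self.per_fold_auc],
            "mean_auc": float(self.mean_auc),
            "fold_variance": float(self.fold_variance),
            "fold_sd": float(np.sqrt(self.fold_variance)),
            "ci95": [float(self.ci95[0]), float(self.ci95[1])],
            "feature_set": self.feature_set,
            "fold_features": self.fold_features,
            "roc_points": [[float(x), float(y)] for x, y in self.roc_points],
            "status": self.status,
        }


def summarize_fold_aucs(fold_aucs: Sequence[float]) -> Tuple[float, float, Tuple[float, float]]:
    """Mean, sample variance, and t-based 95% CI of per-fold AUCs."""
    a = np.asarray(fold_aucs, dtype=float)
    mean = float(a.mean())
    var = float(a.var(ddof=1)) if a.size > 1 else 0.0
    if a.size > 1 and var > 0:
        hw = float(stats.t.ppf(0.975, a.size - 1) * np.sqrt(var / a.size))
    else:
        hw = 0.0
    return mean, var, (mean - hw, mean + hw)


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 100003 + 7919 * (fold + 1)) % (2 ** 31)


def run_comparison(table: FeatureTable, class_a: str, class_b: str,
                   k: int = 8, selection_mode: str = "fold",
                   redundancy_rho: float = 0.95,
                   discretization: str = "threshold",
                   classifiers: Sequence[str] = ("random_forest",),
                   backend_config: Optional[dict] = None,
                   n_folds: int = 5, grouping: str = "cell",
                   seed: int = 0,
                   rf_config: Optional[dict] = None,
                   selection: Optional[SelectionResult] = None
                   ) -> Dict[str, CVResult]:
    """Cross-validated binary comparison of two groups.

    ``selection_mode`` is ``"fold"`` (leakage-safe: features re-selected on
    each training fold) or ``"global"`` (one selection on all cells before
    CV; optimistically biased and labelled as such in the result status).
    A precomputed ``selection`` forces its feature set in every fold.
    """
    if selection_mode not in ("fold", "global"):
        raise ValidationError(f"unknown selection_mode {selection_mode!r}")
    sub = table.subset([class_a, class_b])
    if set(sub.data["group_label"]) != {class_a, class_b}:
        raise ValidationError("both classes must be present in the table")
    plan = make_folds(sub, n_folds=n_folds, grouping=grouping, seed=seed)

    global_features: Optional[List[str]] = None
    if selection is not None:
        global_features = list(selection.selected)
    elif selection_mode == "global":
        global_features = rank_and_select(
            sub, class_a, class_b, k=k, redundancy_rho=redundancy_rho,
            discretization=discretization).selected

    id_index = {cid: i for i, cid in enumerate(sub.cell_ids)}
    results: Dict[str, CVResult] = {}
    per_clf_scores: Dict[str, List[np.ndarray]] = {c: [] for c in classifiers}
    per_clf_aucs: Dict[str, List[float]] = {c: [] for c in classifiers}
    per_clf_roc: Dict[str, List[np.ndarray]] = {c: [] for c in classifiers}
    pooled_labels: List[np.ndarray] = []
    fold_features: List[List[str]] = []
    fold_train_cells: List[List[str]] = []
    backend_status = ""

    for f in range(n_folds):
        train_ids = plan.train_ids(f)
        test_ids = plan.test_ids(f)
        tr = FeatureTable(sub.data.iloc[[id_index[c] for c in train_ids]],
                          feature_names=sub.feature_names)
        te = FeatureTable(sub.data.iloc[[id_index[c] for c in test_ids]],
                          feature_names=sub.feature_names)
        if global_features is not None:
            feats = global_features
        else:
            feats = rank_and_select(tr, class_a, class_b, k=k,
                                    redundancy_rho=redundancy_rho,
                                    discretization=discretization).selected
        fold_features.append(list(feats))
        fold_train_cells.append(list(train_ids))
        pooled_labels.append(te.labels)
        fseed = _fold_seed(seed, f)
        for clf in classifiers:
            if clf == "random_forest":
                scores = train_rf_and_score(tr, te, feats, class_b,
                                            seed=fseed, rf_config=rf_config)
            elif clf == "automl":
                scores, backend_status = run_automl_backend(
                    tr, te, feats, class_b, backend_config, seed=fseed)
                if scores is None:
                    continue
            else:
                raise ValidationError(f"unknown classifier {clf!r}")
            pts, auc = roc_auc(scores, te.labels, positive_label=class_b)
            per_clf_scores[clf].append(scores)
            per_clf_aucs[clf].append(auc)
            per_clf_roc[clf].append(pts)

    all_labels = np.concatenate(pooled_labels)
    for clf in classifiers:
        aucs = per_clf_aucs[clf]
        if not aucs:
            # backend never produced scores; record the skip
            results[clf] = CVResult(
                comparison=(class_a, class_b), classifier_id=clf,
                per_fold_auc=[], mean_auc=float("nan"), fold_variance=float("nan"),
                ci95=(float("nan"), float("nan")),
                roc_points=np.array([[0.0, 0.0], [1.0, 1.0]]),
                status=backend_status or "no scores produced")
            continue
        mean, var, ci = summarize_fold_aucs(aucs)
        pooled_scores = np.concatenate(per_clf_scores[clf])
        pooled_pts, _ = roc_auc(pooled_scores, all_labels, positive_label=class_b)
        clf_id = clf
        if clf == "automl":
            clf_id = f"automl[{(backend_config or {}).get('name', 'logistic')}]"
        status = "ok"
        if selection_mode == "global" and selection is None:
            status = "ok (global selection: AUC optimistically biased)"
        elif clf == "automl":
            status = backend_status
        results[clf] = CVResult(
            comparison=(class_a, class_b), classifier_id=clf_id,
            per_fold_auc=[float(a) for a in aucs], mean_auc=mean,
            fold_variance=var, ci95=ci, roc_points=pooled_pts,
            per_fold_roc=per_clf_roc[clf],
            feature_set=global_features,
            fold_features=fold_features,
            fold_train_cells=fold_train_cells,
            status=status)
    return results


def group_pairs(groups: Sequence[str]) -> List[Tuple[str, str]]:
    return list(itertools.combinations(sorted(set(groups)), 2))
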