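"""Nested feature selection and group classification.

Implements the two-arm model comparison between regional band power
(90 features) and connectome edges (4005 features): a nested 10-fold
feature-selection loop (optional univariate rank-sum pre-filter, gated
by whether PCA separates the groups; recursive random-forest feature
elimination stabilised over repeated runs), consensus feature lists
(features selected in at least 4 of 10 folds for connectivity, 2 of 10
for power), a final RBF-SVM evaluated with stratified 10-fold
cross-validation, label-permutation significance tests (add-one
convention), a PLS-DA generalisability check and training-set ROC-AUC
as a comparative-only metric.

Held-out subjects never touch filtering, selection, scaling or fitting:
every data-dependent step happens inside the training folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, silhouette_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

CONSENSUS_THRESHOLDS = {"connectivity": 4, "power": 2}


@dataclass
class FeatureMatrix:
    """Subjects x features with per-feature annotations."""

    X: np.ndarray
    names: list[str]
    kind: str  # 'power' | 'connectivity'
    band: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if len(self.names) != self.X.shape[1]:
            raise ValueError("annotation count must equal feature count")


@dataclass
class SelectionResult:
    fold_features: list[list[int]]  # selected feature indices per outer fold
    fold_accuracy: list[float]  # held-out accuracy per outer fold
    consensus_counts: np.ndarray  # per feature, folds selecting it (0..k)
    consensus_list: list[int]  # features with count >= threshold
    threshold: int
    used_univariate_filter: bool


@dataclass
class ClassifierReport:
    cv_accuracy_mean: float  # %
    cv_accuracy_sd: float  # %
    training_accuracy: float  # %
    svm_permutation_p: float | None = None
    plsda_permutation_p: float | None = None
    training_roc_auc: float | None = None
    n_features: int = 0


def edge_to_index(i: int, j: int, n_seeds: int) -> int:
    """Position of upper-triangle edge (i < j) in the vectorised connectome."""
    if not 0 <= i < j < n_seeds:
        raise ValueError("edge must satisfy 0 <= i < j < n_seeds")
    return i * n_seeds - i * (i + 1) // 2 + (j - i - 1)


def index_to_edge(k: int, n_seeds: int) -> tuple[int, int]:
    """Inverse of :func:`edge_to_index`."""
    if not 0 <= k < n_seeds * (n_seeds - 1) // 2:
        raise ValueError("edge index out of range")
    i = 0
    while k >= n_seeds - i - 1:
        k -= n_seeds - i - 1
        i += 1
    return i, i + 1 + k


def build_features(
    source: pd.DataFrame | np.ndarray,
    band: str,
    subject_order: list[str] | None = None,
    seed_labels: list[str] | None = None,
) -> FeatureMatrix:
    """Vectorise one band into a feature matrix.

    Power: a long-format subject x seed x band table -> 90 features.
    Connectivity: a (subjects, seeds, seeds) stack -> n(n-1)/2 edge
    features in deterministic i < j order (round-trippable via
    :func:`edge_to_index` / :func:`index_to_edge`).
    """
    if isinstance(source, pd.DataFrame):
        sub = source[source["band"] == band]
        wide = sub.pivot(index="subject_id", columns="seed", values="power")
        if subject_order is not None:
            wide = wide.loc[subject_order]
        names = [
            seed_labels[s] if seed_labels else f"seed_{s}" for s in wide.columns
        ]
        return FeatureMatrix(wide.to_numpy(), names, "power", band)
    conn = np.asarray(source, dtype=float)
    n_seeds = conn.shape[-1]
    iu = np.triu_indices(n_seeds, k=1)
    X = conn[:, iu[0], iu[1]]
    if seed_labels:
        names = [f"{seed_labels[i]}:{seed_labels[j]}" for i, j in zip(*iu)]
    else:
        names = [f"edge_{i}_{j}" for i, j in zip(*iu)]
    return FeatureMatrix(X, names, "connectivity", band)


def _svm_pipeline() -> Pipeline:
    # features are z-scored with training-fold statistics only
    return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale"))


def pca_separation_check(X: np.ndarray, y: np.ndarray, threshold: float = 0.2) -> bool:
    """Do the group labels cluster in the first two principal components?

    Quantifies "visual PCA separation" as a silhouette score of the
    labels in PC1/PC2 exceeding ``threshold``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(X, axis=0).shape[0] < 3:
        raise ValueError("degenerate input: fewer than 3 distinct subjects")
    k = min(2, X.shape[1], X.shape[0] - 1)
    scores = PCA(n_components=k).fit_transform(StandardScaler().fit_transform(X))
    return bool(silhouette_score(scores, y) > threshold)


def univariate_filter(
    X_train: np.ndarray, y_train: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Indices of features with rank-sum p < alpha on the training subjects.

    Uncorrected by design — this is a permissive pre-filter, applied
    inside outer folds only.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    a, b = X_train[y_train == 1], X_train[y_train != 1]
    keep = []
    for f in range(X_train.shape[1]):
        if np.ptp(X_train[:, f]) == 0:
            continue
        p = sps.mannwhitneyu(a[:, f], b[:, f], alternative="two-sided").pvalue
        if p < alpha:
            keep.append(f)
    return np.asarray(keep, dtype=int)


def rrf_fs(
    X: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 10,
    drop_fraction: float = 0.2,
    oob_tolerance: float = 0.02,
    n_trees: int = 500,
    rng: np.random.Generator | int | None = None,
) -> list[int]:
    """Recursive random-forest feature selection, stabilised by repetition.

    Each iteration (fresh forest seed) runs a full recursive
    elimination path: fit a random forest with out-of-bag scoring, drop
    the bottom ``drop_fraction`` of features by impurity importance,
    and repeat down to two features; the iteration then keeps the
    *smallest* feature set along the path whose OOB accuracy stays
    within ``oob_tolerance`` of the path's best.  A feature is returned
    when it survives in at least half of the iterations — the
    repetition damps the run-to-run instability of forest importances.

    On informative data the path's accuracy collapses once relevant
    features are dropped, so the kept set is the informative core; on
    pure noise the OOB fluctuates around chance everywhere and the rule
    collapses to a small arbitrary set that rarely repeats across
    iterations, so the consensus stays near-empty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_features = X.shape[1]
    if n_features < 2:
        return list(range(n_features))
    rng = np.random.default_rng(rng)

    survival = np.zeros(n_features)
    for _ in range(n_iterations):
        seed = int(rng.integers(2**31))

        def fit(cols):
            return RandomForestClassifier(
                n_estimators=n_trees, max_features="sqrt", oob_score=True,
                random_state=seed, n_jobs=1,
            ).fit(X[:, cols], y)

        current = np.arange(n_features)
        rf = fit(current)
        path = [(current, rf.oob_score_)]
        while current.size > 2:
            n_drop = max(1, int(np.floor(drop_fraction * current.size)))
            current = np.sort(current[np.argsort(rf.feature_importances_)[n_drop:]])
            rf = fit(current)
            path.append((current, rf.oob_score_))
        best = max(oob for _, oob in path)
        kept = min(
            (cols for cols, oob in path if oob >= best - oob_tolerance),
            key=len,
        )
        survival[kept] += 1
    return list(np.flatnonzero(survival >= n_iterations / 2))


def nested_fs(
    features: FeatureMatrix,
    labels: np.ndarray,
    k: int = 10,
    consensus_threshold: int | None = None,
    use_univariate: bool | None = None,
    n_trees: int = 500,
    n_iterations: int = 10,
    rng: np.random.Generator | int | None = None,
) -> SelectionResult:
    """Nested k-fold feature selection with consensus aggregation.

    For each outer fold: (optionally) the univariate rank-sum filter,
    then recursive RF selection, both computed on the k-1 training
    folds only; an SVM trained on the selected features is scored on
    the held-out fold.  The consensus list keeps features selected in
    at least ``consensus_threshold`` folds (defaults: 4 for
    connectivity, 2 for power — power skips the univariate pre-filter,
    so its per-fold lists are already conservative).

    ``use_univariate=None`` applies the filter automatically when the
    univariate reduction of the complete data separates groups under
    PCA, and only for connectivity features.
    """
    X, y = features.X, np.asarray(labels)
    rng = np.random.default_rng(rng)
    if consensus_threshold is None:
        consensus_threshold = CONSENSUS_THRESHOLDS[features.kind]
    if use_univariate is None:
        if features.kind == "connectivity":
            idx = univariate_filter(X, y)
            use_univariate = idx.size >= 2 and pca_separation_check(X[:, idx], y)
        else:
            use_univariate = False

    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    counts = np.zeros(X.shape[1])
    fold_features: list[list[int]] = []
    fold_accuracy: list[float] = []
    for train, test in skf.split(X, y):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            raise ValueError("stratification failed: a fold is missing a class")
        pool = np.arange(X.shape[1])
        if use_univariate:
            pool = univariate_filter(X[train], y[train])
            if pool.size == 0:
                pool = np.arange(X.shape[1])
        local = rrf_fs(X[np.ix_(train, pool)], y[train], n_iterations=n_iterations,
                       n_trees=n_trees, rng=rng)
        selected = sorted(int(pool[i]) for i in local)
        counts[selected] += 1
        fold_features.append(selected)
        model = _svm_pipeline().fit(X[np.ix_(train, selected)], y[train])
        fold_accuracy.append(float(model.score(X[np.ix_(test, selected)], y[test])))
    consensus = list(np.flatnonzero(counts >= consensus_threshold))
    return SelectionResult(
        fold_features, fold_accuracy, counts, consensus,
        consensus_threshold, bool(use_univariate),
    )


def _cv_accuracy(model, X, y, k, random_state) -> np.ndarray:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=random_state)
    accs = []
    for train, test in skf.split(X, y):
        m = clone(model).fit(X[train], y[train])
        accs.append(m.score(X[test], y[test]))
    return np.asarray(accs)


def final_svm(
    X: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    rng: np.random.Generator | int | None = None,
) -> ClassifierReport:
    """Stratified k-fold CV of the consensus-feature SVM (accuracy in %)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(rng)
    accs = _cv_accuracy(_svm_pipeline(), X, y, k, int(rng.integers(2**31)))
    full = _svm_pipeline().fit(X, y)
    return ClassifierReport(
        cv_accuracy_mean=float(100 * accs.mean()),
        cv_accuracy_sd=float(100 * accs.std(ddof=1)),
        training_accuracy=float(100 * full.score(X, y)),
        n_features=X.shape[1],
    )


def label_permutation_test(
    X: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    k: int = 10,
    rng: np.random.Generator | int | None = None,
    model=None,
) -> tuple[float, float]:
    """Classifier label-permutation test: (observed CV accuracy, p).

    p = (1 + #{permuted accuracy >= observed}) / (1 + n_perm), the
    standard permutation convention for classifier significance.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(rng)
    model = model if model is not None else _svm_pipeline()
    cv_seed = int(rng.integers(2**31))
    obs = _cv_accuracy(model, X, y, k, cv_seed).mean()
    exceed = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        if len(np.unique(y_perm)) < 2:
            continue
        if _cv_accuracy(model, X, y_perm, k, cv_seed).mean() >= obs:
            exceed += 1
    return float(obs), float((1 + exceed) / (1 + n_perm))


class _PLSDA:
    """PLS regression on one-hot labels; class = argmax of the prediction."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def get_params(self, deep=True):
        return {"n_components": self.n_components}

    def set_params(self, **params):
        self.__dict__.update(params)
        return self

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        Y = np.column_stack([(y == c).astype(float) for c in self.classes_])
        k = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self.pls_ = PLSRegression(n_components=max(k, 1), scale=True).fit(X, Y)
        return self

    def predict(self, X):
        return self.classes_[np.argmax(self.pls_.predict(X), axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == y))


def plsda_validate(
    X: np.ndarray,
    labels: np.ndarray,
    n_components: int = 2,
    n_perm: int = 1000,
    k: int = 10,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """PLS-DA generalisability check: (observed CV accuracy, permutation p)."""
    return label_permutation_test(
        X, labels, n_perm=n_perm, k=k, rng=rng, model=_PLSDA(n_components)
    )


def training_roc_auc(X: np.ndarray, labels: np.ndarray) -> float:
    """ROC-AUC of the SVM's decision scores on its own training set.

    An optimistic, comparative-only metric: with no held-out cohort it
    answers "does the model at least rank its training subjects
    correctly", not "does it generalise".  Tied scores contribute 1/2,
    so an uninformative model scores 0.5.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    model = _svm_pipeline().fit(X, y)
    scores = model.decision_function(X)
    if np.ptp(scores) == 0:
        return 0.5
    return float(roc_auc_score(y, scores))


def compare_models(reports: dict[str, ClassifierReport]) -> pd.DataFrame:
    """Model comparison table ranked by CV accuracy (ties broken by name)."""
    rows = []
    for name, r in reports.items():
        rows.append(
            {
                "model": name,
                "cv_accuracy_mean": r.cv_accuracy_mean,
                "cv_accuracy_sd": r.cv_accuracy_sd,
                "training_accuracy": r.training_accuracy,
                "training_roc_auc": r.training_roc_auc,
                "svm_permutation_p": r.svm_permutation_p,
                "plsda_permutation_p": r.plsda_permutation_p,
                "n_features": r.n_features,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["cv_accuracy_mean", "model"], ascending=[False, True], kind="mergesort"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def run_ml_arm(
    features: FeatureMatrix,
    labels: np.ndarray,
    n_perm: int = 1000,
    n_trees: int = 500,
    n_iterations: int = 10,
    k: int = 10,
    rng: np.random.Generator | int | None = None,
) -> tuple[SelectionResult, ClassifierReport]:
    """Full arm: nested FS -> consensus -> final SVM -> permutation tests."""
    rng = np.random.default_rng(rng)
    selection = nested_fs(features, labels, k=k, n_trees=n_trees,
                          n_iterations=n_iterations, rng=rng)
    idx = selection.consensus_list or list(range(features.X.shape[1]))
    Xc = features.X[:, idx]
    report = final_svm(Xc, labels, k=k, rng=rng)
    _, report.svm_permutation_p = label_permutation_test(Xc, labels, n_perm=n_perm,
                                                         k=k, rng=rng)
    _, report.plsda_permutation_p = plsda_validate(Xc, labels, n_perm=n_perm,
                                                   k=k, rng=rng)
    report.training_roc_auc = training_roc_auc(Xc, labels)
    return selection, report
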