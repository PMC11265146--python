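"""Nested cross-validation harness, feature selection, and metrics.

The harness reproduces a bidirectional platform-transfer benchmark: a
classifier is trained on one platform's data (the *training distribution*)
and evaluated, in every outer fold, on four test sets built from the same
held-out samples:

1. ``reference`` — same-platform data (positive control);
2. ``log2``      — other-platform data, untransformed (negative control);
3. ``fsqn``      — other-platform data quantile-normalized per gene to the
   training distribution;
4. ``fsmvn``     — other-platform data mean/SD-matched per gene to the
   training distribution.

Fold assignments are shared across conditions, models and feature-selection
methods, so comparisons are paired.  Everything that could leak — the
normalization target, feature selection, hyperparameter tuning — sees only
the outer-training samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.metrics import make_scorer
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import ExpressionMatrix, LabelVector
from .normalize import fsqn, fsmvn
from .synthetic import PairedCohort

__all__ = [
    "CVConfig",
    "FoldAssignment",
    "FeatureSelectionResult",
    "EvaluationRecord",
    "Classifier",
    "stratified_folds",
    "select_features_lasso",
    "select_features_svm",
    "train_classifier",
    "balanced_accuracy",
    "cohen_kappa",
    "mase",
    "MaseResult",
    "fit_fold",
    "nested_cv_experiment",
    "feature_sweep_experiment",
    "records_to_frame",
    "mean_lasso_feature_count",
]

CONDITIONS = ("reference", "log2", "fsqn", "fsmvn")
DIRECTIONS = ("A_trains", "B_trains")
MODELS = ("svm_linear", "glmnet")
FS_METHODS = ("full", "lasso", "svm_importance")


@dataclass(frozen=True)
class CVConfig:
    """Layer sizes and seed for the nested cross-validation.

    The outer layer (default tenfold) drives all reported metrics; the
    inner layer (default fivefold) tunes hyperparameters and, for LASSO
    selection, the penalty.
    """

    outer_k: int = 10
    inner_k: int = 5
    seed: int = 0


def _fold_seed(seed: int, fold: int) -> int:
    return (seed + 7919 * fold) % (2**31 - 1)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    fold: np.ndarray  # fold index per sample, 1..k
    k: int
    seed: int

    def test_indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold == f)

    def train_indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold != f)


def stratified_folds(labels: LabelVector, k: int, seed: int = 0) -> FoldAssignment:
    """Assign samples to k stratified folds; class counts differ by ≤1 across folds."""
    y = labels.to_array()
    counts = pd.Series(y).value_counts()
    too_small = counts[counts < k]
    if len(too_small):
        raise ValueError(
            f"classes smaller than k={k}: {dict(too_small)}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.zeros(len(labels), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), y), start=1):
        fold[test_idx] = f
    return FoldAssignment(fold, k, seed)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

@dataclass
class FeatureSelectionResult:
    method: str
    selected_gene_ids: list[str]
    requested_count: int | None = None
    per_class_importance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(set(self.selected_gene_ids)) != len(self.selected_gene_ids):
            raise ValueError("selected gene ids contain duplicates")


def select_features_lasso(
    X: ExpressionMatrix,
    y: LabelVector,
    cv_folds: int = 5,
    seed: int = 0,
) -> FeatureSelectionResult:
    """Genes with nonzero coefficients in an L1 multinomial logistic fit.

    The penalty is chosen to minimize mean cross-validated multinomial
    deviance over a descending grid; features are standardized before the
    fit (as glmnet does by default).
    """
    X.require_complete("select_features_lasso")
    labels = y.align_to(X)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        penalty="l1",
        solver="saga",
        Cs=np.logspace(-3, 1, 10),
        cv=cv,
        scoring="neg_log_loss",  # deviance / (2n), same argmin
        max_iter=5000,
        tol=1e-3,
        random_state=seed,
        n_jobs=1,
    )
    scaler = StandardScaler()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(scaler.fit_transform(X.values), labels.to_array())
    nonzero = np.any(model.coef_ != 0.0, axis=0)
    selected = [g for g, nz in zip(X.gene_ids, nonzero) if nz]
    if not selected:
        warnings.warn("LASSO selected no features at the optimal penalty")
    return FeatureSelectionResult("lasso", selected, requested_count=None)


def select_features_svm(
    X: ExpressionMatrix,
    y: LabelVector,
    total_count: int,
) -> FeatureSelectionResult:
    """Top genes per class by one-vs-rest ROC variable importance.

    Per-gene, per-class importance is the AUC of the gene used alone as a
    score for that class, folded as ``max(AUC, 1 - AUC)``.  The top
    ``ceil(total_count / K)`` genes of each class are unioned and
    deduplicated, so the achieved count is only approximately the request.
    """
    X.require_complete("select_features_svm")
    labels = y.align_to(X)
    classes = labels.classes
    K = len(classes)
    if total_count < K:
        raise ValueError(f"total_count must be ≥ the number of classes ({K})")
    p = X.n_genes
    if total_count > p:
        warnings.warn(f"requested {total_count} features but only {p} genes exist; returning all")
        imp = pd.DataFrame(1.0, index=X.gene_ids, columns=classes)
        return FeatureSelectionResult("svm_importance", list(X.gene_ids), total_count, imp)

    yarr = labels.to_array()
    ranks = np.apply_along_axis(rankdata, 0, X.values)  # midranks per gene
    n = X.n_samples
    importance = np.empty((p, K))
    for c, cls in enumerate(classes):
        mask = yarr == cls
        n1 = int(mask.sum())
        n0 = n - n1
        rank_sum = ranks[mask].sum(axis=0)
        auc = (rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)
        importance[:, c] = np.maximum(auc, 1.0 - auc)

    per_class = math.ceil(total_count / K)
    selected: list[str] = []
    seen: set[str] = set()
    order = np.arange(p)
    for c in range(K):
        # stable sort: descending importance, gene order breaks ties
        top = order[np.argsort(-importance[:, c], kind="stable")][:per_class]
        for g in top:
            gid = X.gene_ids[g]
            if gid not in seen:
                seen.add(gid)
                selected.append(gid)
    imp_frame = pd.DataFrame(importance, index=X.gene_ids, columns=classes)
    return FeatureSelectionResult("svm_importance", selected, total_count, imp_frame)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

@dataclass
class Classifier:
    """A fitted predictor tied to the gene set it was trained on."""

    model: str
    estimator: object
    gene_ids: list[str]
    best_params: dict = field(default_factory=dict)

    def predict(self, X: ExpressionMatrix) -> np.ndarray:
        if X.gene_ids != self.gene_ids:
            raise ValueError("matrix genes do not match the classifier's training genes")
        X.require_complete("predict")
        return np.asarray(self.estimator.predict(X.values), dtype=object)

    @property
    def coefficients(self) -> np.ndarray:
        est = self.estimator
        final = est.best_estimator_ if hasattr(est, "best_estimator_") else est
        if isinstance(final, Pipeline):
            final = final[-1]
        return np.asarray(final.coef_)


def _ba_scorer():
    def score(y_true, y_pred):
        cm = _sk_confusion(y_true, y_pred, labels=sorted(set(y_true) | set(y_pred)))
        return balanced_accuracy(cm)

    return make_scorer(score)


def train_classifier(
    X: ExpressionMatrix,
    y: LabelVector,
    model: str = "svm_linear",
    tuning_folds: int = 5,
    seed: int = 0,
) -> Classifier:
    """Fit a classifier with inner stratified-CV hyperparameter tuning.

    ``svm_linear`` tunes the cost of a linear-kernel SVM; ``glmnet`` tunes
    the elastic-net mixing and penalty strength of a multinomial logistic
    model (features standardized inside the pipeline).  Tuning maximizes
    balanced accuracy.  Deterministic for a given seed.
    """
    X.require_complete("train_classifier")
    labels = y.align_to(X)
    yarr = labels.to_array()
    if len(set(yarr)) < 2:
        raise ValueError("training fold contains a single class")
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")

    counts = pd.Series(yarr).value_counts()
    folds = int(min(tuning_folds, counts.min()))
    if folds < 2:
        raise ValueError("every class needs ≥2 members for inner-CV tuning")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    if model == "svm_linear":
        base = SVC(kernel="linear", random_state=seed)
        grid = {"C": [0.01, 0.1, 1.0, 10.0]}
    else:
        base = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    LogisticRegression(
                        penalty="elasticnet",
                        solver="saga",
                        max_iter=5000,
                        tol=1e-3,
                        random_state=seed,
                    ),
                ),
            ]
        )
        grid = {
            "clf__l1_ratio": [0.1, 0.55, 1.0],
            "clf__C": np.logspace(-3, 1, 10).tolist(),
        }

    search = GridSearchCV(base, grid, scoring=_ba_scorer(), cv=cv, n_jobs=1, refit=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X.values, yarr)
    return Classifier(model, search, list(X.gene_ids), dict(search.best_params_))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def balanced_accuracy(confusion: np.ndarray) -> float:
    """Mean over classes of (sensitivity + specificity) / 2.

    One-vs-rest sensitivity and specificity are computed per class from the
    K x K count matrix (rows = truth, columns = prediction); classes with
    zero true members are excluded with a warning.
    """
    cm = np.asarray(confusion, dtype=float)
    _validate_confusion(cm)
    total = cm.sum()
    per_class = []
    excluded = 0
    for c in range(cm.shape[0]):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            excluded += 1
            continue
        sens = tp / (tp + fn)
        spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        per_class.append(np.nanmean([sens, spec]))
    if excluded:
        warnings.warn(f"{excluded} class(es) with zero true members excluded from balanced accuracy")
    if not per_class:
        raise ValueError("no class has any true member")
    return float(np.mean(per_class))


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) from a confusion matrix."""
    cm = np.asarray(confusion, dtype=float)
    _validate_confusion(cm)
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / n**2
    if p_e >= 1.0:
        warnings.warn("degenerate confusion matrix (expected agreement 1); kappa set to 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _validate_confusion(cm: np.ndarray) -> None:
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any() or not np.allclose(cm, np.round(cm)):
        raise ValueError("confusion matrix must hold non-negative integer counts")
    if cm.sum() < 1:
        raise ValueError("confusion matrix must contain at least one observation")


@dataclass
class MaseResult:
    """Per-gene mean absolute scaled error plus its summary over genes."""

    per_gene: pd.Series
    mean: float
    sd: float
    excluded_genes: list[str] = field(default_factory=list)


def mase(normalized: ExpressionMatrix, reference: ExpressionMatrix) -> MaseResult:
    """Mean absolute scaled error of ``normalized`` against ``reference``.

    For gene j: ``mean_i |x_ij - y_ij| / mean_i |y_ij - ybar_j|``.  Genes
    whose reference column is constant (zero denominator) are excluded with
    a warning.
    """
    if normalized.sample_ids != reference.sample_ids or normalized.gene_ids != reference.gene_ids:
        raise ValueError("mase requires identical samples and genes in identical order")
    normalized.require_complete("mase")
    reference.require_complete("mase")
    X = normalized.values
    Y = reference.values
    num = np.abs(X - Y).mean(axis=0)
    den = np.abs(Y - Y.mean(axis=0)).mean(axis=0)
    ok = den > 0
    excluded = [g for g, k in zip(reference.gene_ids, ok) if not k]
    if excluded:
        warnings.warn(f"{len(excluded)} constant reference gene(s) excluded from MASE")
    vals = num[ok] / den[ok]
    genes = [g for g, k in zip(reference.gene_ids, ok) if k]
    per_gene = pd.Series(vals, index=genes, name="mase")
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    return MaseResult(per_gene, float(np.mean(vals)), sd, excluded)


# ---------------------------------------------------------------------------
# the experiment
# ---------------------------------------------------------------------------

@dataclass
class EvaluationRecord:
    """One outer-fold result for one test condition."""

    direction: str
    condition: str
    model: str
    fs_method: str
    n_features: int
    outer_fold: int
    balanced_accuracy: float
    kappa: float
    mase: float | None


def records_to_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def _training_platform(cohort: PairedCohort, direction: str) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    if direction == "A_trains":
        return cohort.platform_a, cohort.platform_b
    if direction == "B_trains":
        return cohort.platform_b, cohort.platform_a
    raise ValueError(f"direction must be one of {DIRECTIONS}")


def fit_fold(
    cohort: PairedCohort,
    direction: str,
    folds: FoldAssignment,
    fold: int,
    model: str = "svm_linear",
    fs_method: str = "full",
    config: CVConfig = CVConfig(),
    n_features: int | None = None,
) -> tuple[Classifier, list[str]]:
    """Train the fold's classifier; returns (classifier, selected genes).

    Only outer-training samples of the training platform are touched, so
    the result is by construction independent of the held-out fold's data.
    """
    if fs_method not in FS_METHODS:
        raise ValueError(f"fs_method must be one of {FS_METHODS}")
    train_mat, _ = _training_platform(cohort, direction)
    train_idx = folds.train_indices(fold)
    X_train = train_mat.subset_samples(train_idx)
    y_train = cohort.labels.subset(train_idx)
    seed = _fold_seed(config.seed, fold)

    if fs_method == "full":
        selected = list(X_train.gene_ids)
    elif fs_method == "lasso":
        selected = select_features_lasso(X_train, y_train, config.inner_k, seed).selected_gene_ids
        if not selected:
            warnings.warn(f"fold {fold}: empty LASSO selection; falling back to all genes")
            selected = list(X_train.gene_ids)
    else:
        if n_features is None:
            raise ValueError("fs_method='svm_importance' requires n_features")
        selected = select_features_svm(X_train, y_train, n_features).selected_gene_ids

    X_sel = X_train.subset_genes(selected)
    clf = train_classifier(X_sel, y_train, model, config.inner_k, seed)
    return clf, selected


def nested_cv_experiment(
    cohort: PairedCohort,
    direction: str = "A_trains",
    model: str = "svm_linear",
    fs_method: str = "full",
    config: CVConfig = CVConfig(),
    n_features: int | None = None,
    folds: FoldAssignment | None = None,
) -> list[EvaluationRecord]:
    """Run the four-condition outer loop; returns one record per fold x condition.

    Per outer fold the training distribution is the training platform minus
    the held-out fold; feature selection and tuning see only that data; the
    four test sets are built from the held-out samples, with FSQN/FSMVN
    applied *after* restriction to the selected genes, using the training
    distribution as target.  MASE is recorded for cross-platform conditions
    only (the reference has no paired counterpart to normalize).
    """
    if folds is None:
        folds = stratified_folds(cohort.labels, config.outer_k, config.seed)
    train_mat, other_mat = _training_platform(cohort, direction)
    classes = cohort.labels.classes

    records: list[EvaluationRecord] = []
    for fold in range(1, folds.k + 1):
        try:
            clf, selected = fit_fold(cohort, direction, folds, fold, model, fs_method, config, n_features)
            test_idx = folds.test_indices(fold)
            y_test = cohort.labels.subset(test_idx).to_array()

            ref = train_mat.subset_samples(test_idx).subset_genes(selected)
            raw = other_mat.subset_samples(test_idx).subset_genes(selected)
            target = train_mat.subset_samples(folds.train_indices(fold)).subset_genes(selected)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                test_sets = {
                    "reference": ref,
                    "log2": raw,
                    "fsqn": fsqn(raw, target).normalized,
                    "fsmvn": fsmvn(raw, target).normalized,
                }

            for condition, X_test in test_sets.items():
                pred = clf.predict(X_test)
                cm = _sk_confusion(y_test, pred, labels=classes)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ba = balanced_accuracy(cm)
                    kap = cohen_kappa(cm)
                    err = None if condition == "reference" else mase(X_test, ref).mean
                records.append(
                    EvaluationRecord(
                        direction, condition, model, fs_method, len(selected), fold, ba, kap, err
                    )
                )
        except Exception as exc:  # annotate failures with their position in the design
            raise RuntimeError(f"fold {fold}, direction {direction}, model {model}: {exc}") from exc
    return records


def mean_lasso_feature_count(
    cohort: PairedCohort,
    direction: str = "A_trains",
    config: CVConfig = CVConfig(),
    folds: FoldAssignment | None = None,
) -> int:
    """Mean (rounded) LASSO-selected feature count across outer folds.

    Used to size the SVM-importance selection so both selection methods
    work at a comparable feature budget.
    """
    if folds is None:
        folds = stratified_folds(cohort.labels, config.outer_k, config.seed)
    train_mat, _ = _training_platform(cohort, direction)
    counts = []
    for fold in range(1, folds.k + 1):
        idx = folds.train_indices(fold)
        res = select_features_lasso(
            train_mat.subset_samples(idx), cohort.labels.subset(idx), config.inner_k, _fold_seed(config.seed, fold)
        )
        counts.append(len(res.selected_gene_ids))
    return int(round(float(np.mean(counts))))


def feature_sweep_experiment(
    cohort: PairedCohort,
    counts: list[int],
    model: str = "svm_linear",
    config: CVConfig = CVConfig(),
    direction: str = "A_trains",
    folds: FoldAssignment | None = None,
) -> pd.DataFrame:
    """Repeat the nested-CV experiment at several SVM-importance budgets.

    ``counts`` must be sorted descending and bounded by the gene count.
    The returned frame adds a ``requested_count`` column; achieved counts
    are the records' ``n_features``.
    """
    if sorted(counts, reverse=True) != list(counts):
        raise ValueError("counts must be sorted descending")
    if max(counts) > cohort.n_genes:
        raise ValueError("largest requested count exceeds the number of genes")
    if folds is None:
        folds = stratified_folds(cohort.labels, config.outer_k, config.seed)
    frames = []
    for count in counts:
        recs = nested_cv_experiment(
            cohort, direction, model, "svm_importance", config, n_features=count, folds=folds
        )
        frame = records_to_frame(recs)
        frame["requested_count"] = count
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
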