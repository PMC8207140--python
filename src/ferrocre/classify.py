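"""Shadow-feature all-relevant selection and expression-type classification.

Selection follows the shadow-feature (Boruta-style) scheme: at each
iteration every feature is duplicated as a permuted "shadow", a tree
ensemble is fitted, and a feature scores a hit when its importance
strictly exceeds the best shadow importance.  Accumulated hits are
compared against a Binomial(iterations, 0.5) null with a two-sided test:
significantly many hits confirms a feature, significantly few rejects
it, the rest stay tentative.

Classification uses gradient-boosted trees on binary motif presence
features, with class undersampling to the minority size and stratified
cross-validation; reported metrics are the pooled confusion matrix, the
per-cell "enrichment %" (cell as a share of its predicted-class total;
20% is chance for five balanced classes), balanced accuracy defined as
the macro mean over classes of (sensitivity + specificity) / 2, and
one-vs-rest macro AUC-ROC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

__all__ = [
    "FeatureSelectionResult",
    "ClassifierReport",
    "shadow_select",
    "fit_and_evaluate",
    "binary_tissue_model",
    "enrichment_matrix",
    "balanced_accuracy",
]


def _default_model(seed: int, n_classes: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=60,
        max_depth=3,
        learning_rate=0.3,
        objective="multi:softprob" if n_classes > 2 else "binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=seed % (2**31 - 1),
        verbosity=0,
    )


@dataclass
class FeatureSelectionResult:
    """Confirmed / tentative / rejected partition plus importance trace."""

    confirmed: list[str]
    tentative: list[str]
    rejected: list[str]
    trace: pd.DataFrame
    importance_scaled: pd.Series
    n_iterations: int


@dataclass
class ClassifierReport:
    """Pooled cross-validated confusion counts and summary metrics."""

    classes: list[str]
    confusion_counts: pd.DataFrame  # rows: predicted, columns: true
    enrichment_pct: pd.DataFrame
    balanced_accuracy: float
    auc_roc: float
    folds: int
    seed: int
    features_used: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion_counts": self.confusion_counts.to_dict(),
            "enrichment_pct": self.enrichment_pct.round(4).to_dict(),
            "balanced_accuracy": self.balanced_accuracy,
            "auc_roc": self.auc_roc,
            "folds": self.folds,
            "seed": self.seed,
            "features_used": self.features_used,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def shadow_select(
    features: pd.DataFrame,
    labels,
    max_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    model=None,
) -> FeatureSelectionResult:
    """All-relevant feature selection against permuted shadow features.

    Runs up to ``max_iter`` iterations, stopping early once every
    feature is confirmed or rejected.  Deterministic for a fixed seed.
    ``importance_scaled`` is the mean real-feature importance over
    iterations rescaled so the maximum is 100.
    """
    labels = pd.Series(np.asarray(labels), index=features.index)
    if labels.nunique() < 2:
        raise ValueError("labels must contain at least 2 classes")
    if features.shape[1] < 1:
        raise ValueError("at least one feature is required")
    rng = np.random.default_rng(seed)
    codes = pd.factorize(labels, sort=True)[0]
    n_classes = len(np.unique(codes))
    names = list(features.columns)
    X = features.to_numpy(float)
    hits = pd.Series(0, index=names)
    decided: dict[str, str] = {}
    trace_rows = []
    importance_sum = pd.Series(0.0, index=names)

    t = 0
    for t in range(1, max_iter + 1):
        shadow = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
        Xt = np.hstack([X, shadow])
        mdl = model() if model is not None else _default_model(
            int(rng.integers(2**31 - 1)), n_classes
        )
        mdl.fit(Xt, codes)
        imp = np.asarray(mdl.feature_importances_, float)
        real, sh = imp[: X.shape[1]], imp[X.shape[1] :]
        best_shadow = sh.max() if sh.size else 0.0
        hit_now = real > best_shadow
        hits += hit_now
        importance_sum += real
        trace_rows.append(real)
        for j, name in enumerate(names):
            if name in decided:
                continue
            p = binomtest(int(hits[name]), t, 0.5).pvalue
            if p <= alpha:
                decided[name] = "confirmed" if hits[name] > t / 2 else "rejected"
        if len(decided) == len(names):
            break

    confirmed = [n for n in names if decided.get(n) == "confirmed"]
    rejected = [n for n in names if decided.get(n) == "rejected"]
    tentative = [n for n in names if n not in decided]
    mean_imp = importance_sum / t
    top = mean_imp.max()
    scaled = mean_imp * (100.0 / top) if top > 0 else mean_imp
    trace = pd.DataFrame(trace_rows, columns=names)
    trace.index.name = "iteration"
    return FeatureSelectionResult(confirmed, tentative, rejected, trace, scaled, t)


def enrichment_matrix(confusion_counts: pd.DataFrame) -> pd.DataFrame:
    """Each cell as a percentage of its predicted-class (row) total.

    An empty predicted class yields a row of zeros rather than NaNs.
    """
    counts = confusion_counts.to_numpy(float)
    if (counts < 0).any():
        raise ValueError("confusion counts must be nonnegative")
    row_totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_totals > 0, counts / row_totals * 100.0, 0.0)
    return pd.DataFrame(
        pct, index=confusion_counts.index, columns=confusion_counts.columns
    )


def balanced_accuracy(confusion_counts: pd.DataFrame) -> float:
    """Macro mean over classes of (sensitivity + specificity) / 2.

    The confusion matrix is read with predictions on rows and truth on
    columns; sensitivity and specificity are one-vs-rest per class.
    """
    counts = confusion_counts.to_numpy(float)
    total = counts.sum()
    per_class = []
    for i in range(counts.shape[0]):
        tp = counts[i, i]
        fn = counts[:, i].sum() - tp
        fp = counts[i, :].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn > 0 else 0.0
        spec = tn / (tn + fp) if tn + fp > 0 else 0.0
        per_class.append((sens + spec) / 2.0)
    return float(np.mean(per_class))


def _undersample(labels: pd.Series, rng: np.random.Generator) -> pd.Index:
    counts = labels.value_counts()
    size = int(counts.min())
    keep = []
    for cls in sorted(counts.index):
        members = labels.index[labels == cls].to_numpy()
        keep.extend(rng.choice(members, size=size, replace=False))
    return pd.Index(keep)


def fit_and_evaluate(
    features: pd.DataFrame,
    labels,
    folds: int = 5,
    undersample: bool = True,
    seed: int = 0,
    feature_subset: list[str] | None = None,
    model=None,
) -> ClassifierReport:
    """Stratified cross-validated boosted-tree classification report.

    Classes are optionally undersampled to the minority size before
    splitting.  The pooled out-of-fold predictions build the confusion
    matrix (rows: predicted, columns: true), the per-cell enrichment
    percentages, balanced accuracy, and macro one-vs-rest AUC-ROC
    (plain binary AUC for two classes).
    """
    labels = pd.Series(np.asarray(labels), index=features.index)
    if feature_subset is not None:
        features = features[list(feature_subset)]
    rng = np.random.default_rng(seed)
    class_names = sorted(labels.unique())
    too_small = [c for c in class_names if (labels == c).sum() < folds]
    if too_small:
        raise ValueError(f"classes smaller than {folds} members: {too_small}")
    if undersample:
        idx = _undersample(labels, rng)
        features, labels = features.loc[idx], labels.loc[idx]

    X = features.to_numpy(float)
    y = np.asarray([class_names.index(c) for c in labels])
    n_classes = len(class_names)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31 - 1))
    pred = np.empty(len(y), int)
    proba = np.zeros((len(y), n_classes))
    for train, test in skf.split(X, y):
        mdl = model() if model is not None else _default_model(seed, n_classes)
        mdl.fit(X[train], y[train])
        proba[test] = mdl.predict_proba(X[test])
        pred[test] = proba[test].argmax(axis=1)

    counts = np.zeros((n_classes, n_classes), float)
    for p, t in zip(pred, y):
        counts[p, t] += 1
    confusion = pd.DataFrame(counts, index=class_names, columns=class_names)
    confusion.index.name = "predicted"
    confusion.columns.name = "true"

    if n_classes == 2:
        from sklearn.metrics import roc_auc_score

        auc = float(roc_auc_score(y, proba[:, 1]))
    else:
        from sklearn.metrics import roc_auc_score

        auc = float(
            roc_auc_score(y, proba, multi_class="ovr", average="macro")
        )
    return ClassifierReport(
        classes=list(class_names),
        confusion_counts=confusion,
        enrichment_pct=enrichment_matrix(confusion),
        balanced_accuracy=balanced_accuracy(confusion),
        auc_roc=auc,
        folds=folds,
        seed=seed,
        features_used=list(features.columns),
    )


def binary_tissue_model(
    features: pd.DataFrame,
    labels,
    folds: int = 5,
    undersample: bool = True,
    seed: int = 0,
    model=None,
) -> ClassifierReport:
    """Responsive-vs-none model for a single tissue (binary AUC)."""
    labels = pd.Series(np.asarray(labels), index=features.index)
    if labels.nunique() != 2:
        raise ValueError("binary_tissue_model requires exactly two classes")
    return fit_and_evaluate(
        features, labels, folds=folds, undersample=undersample, seed=seed, model=model
    )
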