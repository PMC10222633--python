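"""Weight-grid optimization and validation.

The category weights (c++, c+, c-, c--) are enumerated on a Cartesian
grid (step 0.1 by default: 20 x 20 x 30 x 30 = 360,000 combinations).
For each combination the aural labels are scored and binned into the
three quality classes, which become the target a classifier (DT, RF,
SVM or AdaBoost) must predict from the acoustic features; the weights
attaining the highest macro F1 on a fixed stratified 80/20 split are
reported, Table-style, as per-coefficient ranges.

Combinations whose induced quality labels are identical necessarily
produce identical splits and metrics (the features and the split seed
are fixed), so evaluations are memoized on the induced label vector;
results are bit-identical to naive per-combination evaluation.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from sri.core import QUALITY_CLASSES, AuralLabel, WeightSet, quality_bin, sri_score
from sri.errors import ConfigurationError, DegenerateInputError, ValidationError
from sri.features import FeatureTable

__all__ = [
    "WeightGrid",
    "ClassifierSpec",
    "EvalMetrics",
    "GridResult",
    "weight_grid",
    "class_weights",
    "stratified_split",
    "build_classifier",
    "train_eval",
    "precision_recall_f1",
    "grid_search",
    "kfold_cv",
]

logger = logging.getLogger(__name__)

CLASSIFIER_FAMILIES = ("DT", "RF", "SVM", "AdaBoost")


@dataclass(frozen=True)
class WeightGrid:
    """Finite value sets for the four coefficients; the search space is
    their Cartesian product."""

    c_plusplus: tuple[float, ...]
    c_plus: tuple[float, ...]
    c_minus: tuple[float, ...]
    c_minusminus: tuple[float, ...]
    step: float = 0.1

    def __post_init__(self) -> None:
        for name in ("c_plusplus", "c_plus", "c_minus", "c_minusminus"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ConfigurationError(f"{name} grid is empty")
        # every grid point must be a valid WeightSet
        WeightSet(self.c_plusplus[0], self.c_plus[0],
                  self.c_minus[0], self.c_minusminus[0])
        WeightSet(self.c_plusplus[-1], self.c_plus[-1],
                  self.c_minus[-1], self.c_minusminus[-1])

    @property
    def n_combinations(self) -> int:
        return (len(self.c_plusplus) * len(self.c_plus)
                * len(self.c_minus) * len(self.c_minusminus))

    def combinations(self):
        """Lazily enumerate all weight combinations."""
        for pp, p, m, mm in itertools.product(
                self.c_plusplus, self.c_plus, self.c_minus, self.c_minusminus):
            yield WeightSet(pp, p, m, mm)


def _arange(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step)) + 1
    return tuple(round(lo + i * step, 10) for i in range(n))


def weight_grid(step: float = 0.1,
                c_plusplus: tuple[float, float] = (2.0, 4.9),
                c_plus: tuple[float, float] = (0.1, 2.0),
                c_minus: tuple[float, float] = (-2.0, -0.1),
                c_minusminus: tuple[float, float] = (-4.9, -2.0)) -> WeightGrid:
    """Default grid: 30 values for c++ and c-- each, 20 for c+ and c-
    each, at step 0.1 — 360,000 combinations. Ranges are inclusive on
    both given endpoints and fully overridable.
    """
    if step <= 0:
        raise ConfigurationError("step must be positive")
    for lo, hi in (c_plusplus, c_plus, c_minus, c_minusminus):
        if lo > hi:
            raise ConfigurationError(f"range ({lo}, {hi}) is inverted")
        n_steps = (hi - lo) / step
        if abs(round(n_steps) - n_steps) > 1e-9:
            raise ConfigurationError(
                f"range ({lo}, {hi}) is not a multiple of step {step}"
            )
    return WeightGrid(
        c_plusplus=_arange(*c_plusplus, step),
        c_plus=_arange(*c_plus, step),
        c_minus=_arange(*c_minus, step),
        c_minusminus=_arange(*c_minusminus, step),
        step=step,
    )


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of one classifier family.

    ``max_depth`` applies to DT/RF, ``rbf_gamma`` to SVM (None means the
    inverse feature-count-and-variance scaling), ``n_estimators`` to
    RF/AdaBoost. Library defaults are kept elsewhere.
    """

    family: str
    max_depth: int | None = 5
    rbf_gamma: float | None = None
    n_estimators: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValidationError(
                f"family must be one of {CLASSIFIER_FAMILIES}, got {self.family!r}"
            )


@dataclass
class EvalMetrics:
    """Per-class and macro precision/recall/F1 from a confusion matrix."""

    confusion: np.ndarray
    classes: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    undefined_flags: list[str] = field(default_factory=list)

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    @property
    def precision_sd(self) -> float:
        return float(self.precision.std(ddof=1)) if self.precision.size > 1 else 0.0

    @property
    def recall_sd(self) -> float:
        return float(self.recall.std(ddof=1)) if self.recall.size > 1 else 0.0

    @property
    def f1_sd(self) -> float:
        return float(self.f1.std(ddof=1)) if self.f1.size > 1 else 0.0


def class_weights(labels) -> dict[str, float]:
    """Inverse-frequency class weights W_j = (1/|j|) * (T/N).

    T is the total item count and N the number of represented classes;
    the weighted supports sum back to T.
    """
    y = pd.Series(list(labels))
    if y.empty:
        raise DegenerateInputError("no labels")
    counts = y.value_counts()
    total = len(y)
    n_classes = len(counts)
    if (counts == 0).any():
        raise ValidationError("class with zero members")
    return {cls: total / (cnt * n_classes) for cls, cnt in counts.items()}


def stratified_split(X: np.ndarray, y: np.ndarray, train_fraction: float = 0.8,
                     seed: int = 0):
    """Deterministic stratified train/test split.

    Classes with a single member cannot be stratified; they are placed
    in the training set with a warning.
    """
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must lie in (0, 1)")
    y = np.asarray(y)
    idx = np.arange(y.size)
    counts = pd.Series(y).value_counts()
    singletons = counts[counts < 2].index
    if len(singletons) > 0:
        logger.warning(
            "classes %s have a single member; assigned to train",
            list(singletons),
        )
        single_mask = np.isin(y, list(singletons))
        rest = idx[~single_mask]
        tr, te = train_test_split(
            rest, train_size=train_fraction, stratify=y[rest], random_state=seed
        )
        tr = np.concatenate([tr, idx[single_mask]])
    else:
        tr, te = train_test_split(
            idx, train_size=train_fraction, stratify=y, random_state=seed
        )
    tr = np.sort(tr)
    te = np.sort(te)
    return (X[tr], y[tr]), (X[te], y[te])


def build_classifier(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator for a classifier spec."""
    if spec.family == "DT":
        return DecisionTreeClassifier(max_depth=spec.max_depth,
                                      random_state=spec.seed)
    if spec.family == "RF":
        return RandomForestClassifier(n_estimators=spec.n_estimators,
                                      max_depth=spec.max_depth,
                                      random_state=spec.seed)
    if spec.family == "SVM":
        gamma = spec.rbf_gamma if spec.rbf_gamma is not None else "scale"
        return OneVsRestClassifier(
            SVC(kernel="rbf", gamma=gamma, random_state=spec.seed)
        )
    if spec.family == "AdaBoost":
        return AdaBoostClassifier(n_estimators=spec.n_estimators,
                                  random_state=spec.seed)
    raise ValidationError(f"unknown family {spec.family!r}")


def train_eval(spec: ClassifierSpec, train, test,
               class_weight_map: dict[str, float] | None = None) -> EvalMetrics:
    """Fit on the training split with per-class sample weights and
    evaluate on the test split."""
    X_tr, y_tr = train
    X_te, y_te = test
    if len(np.unique(y_tr)) < 2:
        raise DegenerateInputError("training target has a single class")
    clf = build_classifier(spec)
    if class_weight_map is not None:
        sample_weight = np.array([class_weight_map[c] for c in y_tr])
        if isinstance(clf, OneVsRestClassifier):
            # route per-sample weights through to each one-vs-all binary SVM
            from sklearn import config_context

            with config_context(enable_metadata_routing=True):
                clf.estimator.set_fit_request(sample_weight=True)
                clf.fit(X_tr, y_tr, sample_weight=sample_weight)
        else:
            clf.fit(X_tr, y_tr, sample_weight=sample_weight)
    else:
        clf.fit(X_tr, y_tr)
    y_pred = clf.predict(X_te)
    present = [c for c in QUALITY_CLASSES if c in set(y_te) | set(y_pred)]
    cm = _sk_confusion_matrix(y_te, y_pred, labels=present)
    return precision_recall_f1(cm, classes=tuple(present))


def precision_recall_f1(cm, classes: tuple[str, ...] | None = None) -> EvalMetrics:
    """Metrics from a confusion matrix (rows = truth, columns = predicted).

    Per class, one-vs-rest TP/FP/FN give precision, recall and F1; a
    zero denominator yields 0 with the class recorded in
    ``undefined_flags``.
    """
    cm = np.asarray(cm, dtype=np.int64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValidationError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValidationError("confusion matrix counts must be non-negative")
    k = cm.shape[0]
    if classes is None:
        classes = tuple(str(i) for i in range(k))
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    flags = []
    precision = np.zeros(k)
    recall = np.zeros(k)
    f1 = np.zeros(k)
    for i in range(k):
        if tp[i] + fp[i] > 0:
            precision[i] = tp[i] / (tp[i] + fp[i])
        else:
            flags.append(f"precision[{classes[i]}]")
        if tp[i] + fn[i] > 0:
            recall[i] = tp[i] / (tp[i] + fn[i])
        else:
            flags.append(f"recall[{classes[i]}]")
        if precision[i] + recall[i] > 0:
            f1[i] = 2 * precision[i] * recall[i] / (precision[i] + recall[i])
    return EvalMetrics(confusion=cm, classes=classes, precision=precision,
                       recall=recall, f1=f1, undefined_flags=flags)


@dataclass
class GridResult:
    """All per-combination records plus the arg-max set."""

    records: pd.DataFrame
    best_weights: list[WeightSet]
    best_f1: float

    def best_ranges(self) -> dict[str, tuple[float, float]]:
        """Per-coefficient [min, max] over the best set (interval-style
        reporting)."""
        out = {}
        for name in ("c_plusplus", "c_plus", "c_minus", "c_minusminus"):
            vals = [getattr(w, name) for w in self.best_weights]
            out[name] = (min(vals), max(vals))
        return out


def _align(features: FeatureTable, aural: list[AuralLabel]):
    by_id = {lab.recording_id: lab for lab in aural}
    ids = list(features.data.index)
    missing = [r for r in ids if r not in by_id]
    if missing:
        raise ValidationError(
            f"{len(missing)} feature rows have no aural label, e.g. {missing[:3]}"
        )
    return features.matrix(), [by_id[r] for r in ids]


def grid_search(features: FeatureTable, aural: list[AuralLabel],
                spec: ClassifierSpec, grid: WeightGrid, seed: int = 0,
                train_fraction: float = 0.8,
                log_every: float = 30.0) -> GridResult:
    """Exhaustive weight-grid search with classifier macro F1 objective.

    For every weight combination: score each recording, bin into
    quality classes, stratified-split (fixed seed across combinations),
    fit the classifier with inverse-frequency class weights and record
    macro precision/recall/F1. Combinations where all recordings fall
    in one class are recorded with NaN metrics. All combinations within
    1e-12 of the maximal F1 form the best set.
    """
    X, labels = _align(features, aural)
    cache: dict[bytes, tuple] = {}
    records = []
    best_f1 = -np.inf
    t0 = time.monotonic()
    last_log = t0
    n_total = grid.n_combinations
    for i, w in enumerate(grid.combinations()):
        y = np.array([quality_bin(sri_score(lab, w)) for lab in labels])
        key = y.tobytes()
        if key not in cache:
            if len(np.unique(y)) < 2:
                cache[key] = (np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)
            else:
                train, test = stratified_split(X, y, train_fraction, seed)
                cw = class_weights(train[1])
                metrics = train_eval(spec, train, test, cw)
                cache[key] = (
                    metrics.macro_precision, metrics.precision_sd,
                    metrics.macro_recall, metrics.recall_sd,
                    metrics.macro_f1, metrics.f1_sd,
                )
        rec = cache[key]
        records.append((w.c_plusplus, w.c_plus, w.c_minus, w.c_minusminus) + rec)
        if np.isfinite(rec[4]) and rec[4] > best_f1:
            best_f1 = rec[4]
        now = time.monotonic()
        if now - last_log >= log_every:
            logger.info(
                "grid search: %d/%d combinations (%.1f/s), best F1 %.4f",
                i + 1, n_total, (i + 1) / (now - t0), best_f1,
            )
            last_log = now
    df = pd.DataFrame(records, columns=[
        "c_plusplus", "c_plus", "c_minus", "c_minusminus",
        "precision", "precision_sd", "recall", "recall_sd", "f1", "f1_sd",
    ])
    if not np.isfinite(best_f1):
        raise DegenerateInputError(
            "no weight combination produced more than one quality class"
        )
    best_mask = np.isfinite(df["f1"]) & (df["f1"] >= best_f1 - 1e-12)
    best = [
        WeightSet(r.c_plusplus, r.c_plus, r.c_minus, r.c_minusminus)
        for r in df[best_mask].itertuples()
    ]
    return GridResult(records=df, best_weights=best, best_f1=float(best_f1))


def kfold_cv(features: FeatureTable, aural: list[AuralLabel], w: WeightSet,
             spec: ClassifierSpec, k: int, repeats: int,
             seed: int = 0) -> pd.DataFrame:
    """Repeated stratified k-fold validation at fixed weights.

    Returns one row per (repeat, fold) with macro precision/recall/F1;
    summarize with ``df["f1"].mean()`` +/- ``df["f1"].std()``.
    """
    X, labels = _align(features, aural)
    y = np.array([quality_bin(sri_score(lab, w)) for lab in labels])
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        raise ConfigurationError(
            f"every class needs >= k={k} members, got {counts.to_dict()}"
        )
    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats,
                                       random_state=seed)
    rows = []
    for fold_idx, (tr, te) in enumerate(splitter.split(X, y)):
        cw = class_weights(y[tr])
        metrics = train_eval(spec, (X[tr], y[tr]), (X[te], y[te]), cw)
        rows.append({
            "repeat": fold_idx // k,
            "fold": fold_idx % k,
            "precision": metrics.macro_precision,
            "recall": metrics.macro_recall,
            "f1": metrics.macro_f1,
        })
    return pd.DataFrame(rows)
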