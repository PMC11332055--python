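"""Cross-validated categorization of responses.

The protocol: 10-fold cross-validation with folds grouped by narrative (all
evaluations of one narrative share a fold, so no narrative ever spans a
train/test split), per-fold SVD compression of the feature matrix, an inner
5-fold selection of how many leading SVD dimensions to keep (over a fixed
ladder of candidate counts, choosing the count with the fewest inner-fold
miscategorizations, ties toward the smallest), and a multinomial logistic
regression fitted on the compressed training features.  Every record
receives exactly one out-of-fold prediction.

A parallel routine predicts the four continuous rating-scale totals with
multiple linear regression under the identical protocol, using squared
error as the inner selection criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression, LogisticRegression

from .records import EMOTIONS, SCALE_NAMES, ValidationError

#: Candidate numbers of leading SVD dimensions tried during inner selection.
DIMENSION_LADDER: tuple[int, ...] = (
    1, 2, 3, 5, 7, 10, 14, 19, 26, 35, 46, 61, 80, 105,
    137, 179, 234, 305, 397, 517, 768,
)


def ladder_for(d: int) -> tuple[int, ...]:
    """The ladder truncated at feature dimensionality ``d`` (``d`` itself is
    always a candidate, so low-dimensional feature sets can use all columns)."""
    if d < 1:
        raise ValidationError("feature dimensionality must be positive")
    return tuple(v for v in DIMENSION_LADDER if v < d) + (d,)


@dataclass
class FeatureMatrix:
    """A design matrix with narrative grouping metadata.

    Row ``i`` always corresponds to input record ``i``; ``narrative_ids``
    drive grouped fold assignment.
    """

    X: np.ndarray
    narrative_ids: np.ndarray
    labels: np.ndarray
    feature_set: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.narrative_ids = np.asarray(self.narrative_ids)
        self.labels = np.asarray(self.labels)
        n = self.X.shape[0]
        if len(self.narrative_ids) != n or len(self.labels) != n:
            raise ValidationError("metadata length must match the matrix rows")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("feature matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass
class FoldPlan:
    """Narrative-disjoint assignment of records to folds."""

    fold_of_record: np.ndarray  # int fold index per record, 0..k-1
    k: int
    narrative_fold: dict = field(default_factory=dict)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_record == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_record != fold)


@dataclass
class ClassificationResult:
    predicted: np.ndarray
    true_labels: np.ndarray
    percent_correct: float
    fold_plan: FoldPlan
    selected_dims: list[int]
    coefficients: list[np.ndarray]  # per fold, classes x dims
    feature_set: str

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "percent_correct": self.percent_correct,
            "selected_dims": [int(m) for m in self.selected_dims],
            "fold_of_record": self.fold_plan.fold_of_record.tolist(),
            "predicted": self.predicted.tolist(),
            "true": self.true_labels.tolist(),
            "coefficients": [c.tolist() for c in self.coefficients],
        }


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def make_group_folds(
    narrative_ids: Sequence, k: int = 10, rng=None
) -> FoldPlan:
    """Randomly assign narratives (not records) to ``k`` folds.

    Narratives are shuffled, then greedily placed — most-read narratives
    first — into the currently smallest fold, keeping fold sizes as even as
    the narrative multiplicities allow.
    """
    rng = _as_rng(rng)
    ids = np.asarray(narrative_ids)
    unique, counts = np.unique(ids, return_counts=True)
    if len(unique) < k:
        raise ValidationError(
            f"need at least k={k} distinct narratives, got {len(unique)}"
        )
    order = rng.permutation(len(unique))
    # stable sort keeps the shuffled order within equal multiplicities
    order = order[np.argsort(-counts[order], kind="stable")]
    fold_sizes = np.zeros(k, dtype=int)
    narrative_fold: dict = {}
    for idx in order:
        f = int(np.argmin(fold_sizes))
        narrative_fold[unique[idx]] = f
        fold_sizes[f] += counts[idx]
    fold_of_record = np.array([narrative_fold[i] for i in ids], dtype=int)
    return FoldPlan(fold_of_record=fold_of_record, k=k, narrative_fold=narrative_fold)


def assert_no_leakage(plan: FoldPlan, narrative_ids: Sequence) -> None:
    """Raise if any narrative appears in two folds."""
    ids = np.asarray(narrative_ids)
    for f in range(plan.k):
        test_set = set(ids[plan.test_indices(f)])
        train_set = set(ids[plan.train_indices(f)])
        if test_set & train_set:
            raise AssertionError(
                f"narrative leakage in fold {f}: {sorted(test_set & train_set)[:5]}"
            )


class SVDCompressor:
    """Project features onto leading right-singular vectors of the training
    matrix (no column centering by default; a switch is provided)."""

    def __init__(self, center: bool = False):
        self.center = center
        self.mean_: Optional[np.ndarray] = None
        self.components_: Optional[np.ndarray] = None
        self.singular_values_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "SVDCompressor":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValidationError("SVD needs a 2-D matrix with at least two rows")
        if not np.any(X):
            raise ValidationError("cannot compress an all-zero matrix")
        self.mean_ = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
        _, s, vt = np.linalg.svd(X - self.mean_, full_matrices=False)
        self.singular_values_ = s
        self.components_ = vt
        return self

    @property
    def n_components_(self) -> int:
        assert self.components_ is not None, "fit first"
        return self.components_.shape[0]

    def transform(self, X: np.ndarray, m: Optional[int] = None) -> np.ndarray:
        assert self.components_ is not None, "fit first"
        m = self.n_components_ if m is None else m
        if not 1 <= m <= self.n_components_:
            raise ValidationError(f"m={m} outside [1, {self.n_components_}]")
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_[:m].T


def _fit_multinomial(Z: np.ndarray, y: np.ndarray, ridge: float) -> LogisticRegression:
    model = LogisticRegression(
        C=1.0 / ridge, solver="lbfgs", max_iter=1000, tol=1e-4
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Z, y)
    return model


def _predict_codes(model: LogisticRegression, Z: np.ndarray) -> np.ndarray:
    # argmax over probabilities; ties resolve to the lowest class code,
    # i.e. the fixed EMOTIONS order
    proba = model.predict_proba(Z)
    return np.asarray(model.classes_)[np.argmax(proba, axis=1)]


def select_dimensions(
    X_train: np.ndarray,
    y_train: np.ndarray,
    groups_train: Sequence,
    ladder: Sequence[int],
    inner_k: int = 5,
    rng=None,
    task: str = "classify",
    ridge: float = 1e-6,
    center: bool = False,
) -> int:
    """Pick the ladder entry with the fewest inner-validation errors.

    Inner folds are grouped by narrative like the outer ones.  For
    classification the criterion is the miscategorization count; for
    regression (``task="regress"``, 1-D continuous ``y_train``) it is the
    summed squared error.  Ties break toward the smallest dimensionality.
    """
    rng = _as_rng(rng)
    X_train = np.asarray(X_train, dtype=float)
    inner_k = min(inner_k, len(np.unique(np.asarray(groups_train))))
    plan = make_group_folds(groups_train, k=inner_k, rng=rng)

    splits = []
    for f in range(inner_k):
        tr, va = plan.train_indices(f), plan.test_indices(f)
        svd = SVDCompressor(center=center).fit(X_train[tr])
        splits.append((tr, va, svd, svd.transform(X_train)))
    m_cap = min(s[2].n_components_ for s in splits)
    candidates = [m for m in ladder if m <= m_cap]
    if not candidates:
        raise ValidationError("dimension ladder is empty after truncation")

    scores = np.zeros(len(candidates))
    for tr, va, _, Z in splits:
        for j, m in enumerate(candidates):
            if task == "classify":
                model = _fit_multinomial(Z[tr, :m], y_train[tr], ridge)
                scores[j] += np.sum(_predict_codes(model, Z[va, :m]) != y_train[va])
            else:
                reg = LinearRegression().fit(Z[tr, :m], y_train[tr])
                resid = reg.predict(Z[va, :m]) - y_train[va]
                scores[j] += float(resid @ resid)
    return int(candidates[int(np.argmin(scores))])  # argmin: first = smallest m


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    try:
        return np.array([EMOTIONS.index(l) for l in labels], dtype=int)
    except ValueError as e:
        raise ValidationError(f"unknown emotion label: {e}") from e


def cross_validated_categorize(
    features: FeatureMatrix,
    k: int = 10,
    rng=None,
    inner_k: int = 5,
    ridge: float = 1e-6,
    center: bool = False,
    ladder: Optional[Sequence[int]] = None,
) -> ClassificationResult:
    """Out-of-fold multinomial categorization of every record.

    Per fold: fit the SVD and select the dimensionality on the 90% training
    split only, fit the multinomial model on the compressed training
    features, and predict the held-out 10%.
    """
    rng = _as_rng(rng)
    y = _encode_labels(features.labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("need at least two classes to categorize")
    ladder = tuple(ladder) if ladder is not None else ladder_for(features.d)
    plan = make_group_folds(features.narrative_ids, k=k, rng=rng)
    assert_no_leakage(plan, features.narrative_ids)

    predicted = np.full(features.n, -1, dtype=int)
    selected_dims: list[int] = []
    coefficients: list[np.ndarray] = []
    classes_present = set(np.unique(y).tolist())
    for f in range(k):
        tr, te = plan.train_indices(f), plan.test_indices(f)
        if set(np.unique(y[tr]).tolist()) != classes_present:
            missing = classes_present - set(np.unique(y[tr]).tolist())
            raise ValidationError(
                f"fold {f}: training split lacks class(es) "
                f"{[EMOTIONS[c] for c in sorted(missing)]}"
            )
        m = select_dimensions(
            features.X[tr], y[tr], features.narrative_ids[tr], ladder,
            inner_k=inner_k, rng=rng, task="classify", ridge=ridge, center=center,
        )
        svd = SVDCompressor(center=center).fit(features.X[tr])
        m = min(m, svd.n_components_)
        model = _fit_multinomial(svd.transform(features.X[tr], m), y[tr], ridge)
        predicted[te] = _predict_codes(model, svd.transform(features.X[te], m))
        selected_dims.append(m)
        coefficients.append(np.asarray(model.coef_))

    assert np.all(predicted >= 0), "every record must receive a prediction"
    pct = float(np.mean(predicted == y) * 100.0)
    return ClassificationResult(
        predicted=np.array([EMOTIONS[c] for c in predicted]),
        true_labels=np.asarray(features.labels),
        percent_correct=pct,
        fold_plan=plan,
        selected_dims=selected_dims,
        coefficients=coefficients,
        feature_set=features.feature_set,
    )


def regress_scale_scores(
    features: FeatureMatrix,
    targets: np.ndarray,
    k: int = 10,
    rng=None,
    inner_k: int = 5,
    center: bool = False,
    ladder: Optional[Sequence[int]] = None,
) -> dict:
    """Out-of-fold linear-regression predictions of the four scale totals.

    Same grouped-fold + SVD + ladder protocol as the categorization, with
    squared error as the inner selection criterion; one prediction per
    record per scale.
    """
    rng = _as_rng(rng)
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 1:
        targets = targets[:, None]
    if targets.shape[0] != features.n:
        raise ValidationError("targets must align with feature rows")
    for j in range(targets.shape[1]):
        if np.ptp(targets[:, j]) == 0:
            warnings.warn(
                f"target column {j} is constant; downstream correlations undefined",
                stacklevel=2,
            )
    ladder = tuple(ladder) if ladder is not None else ladder_for(features.d)
    plan = make_group_folds(features.narrative_ids, k=k, rng=rng)
    assert_no_leakage(plan, features.narrative_ids)

    preds = np.full(targets.shape, np.nan)
    dims: list[list[int]] = []
    for f in range(k):
        tr, te = plan.train_indices(f), plan.test_indices(f)
        svd = SVDCompressor(center=center).fit(features.X[tr])
        fold_dims = []
        for j in range(targets.shape[1]):
            m = select_dimensions(
                features.X[tr], targets[tr, j], features.narrative_ids[tr], ladder,
                inner_k=inner_k, rng=rng, task="regress", center=center,
            )
            m = min(m, svd.n_components_)
            reg = LinearRegression().fit(svd.transform(features.X[tr], m), targets[tr, j])
            preds[te, j] = reg.predict(svd.transform(features.X[te], m))
            fold_dims.append(m)
        dims.append(fold_dims)

    assert np.all(np.isfinite(preds))
    return {
        "predictions": preds,
        "selected_dims": dims,
        "fold_plan": plan,
        "scales": list(SCALE_NAMES)[: targets.shape[1]],
    }
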