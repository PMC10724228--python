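"""Pairwise learning-to-rank core: preference pairs, RankSVM, CV, ranking.

Each degradability dataset is converted to within-dataset preference pairs
``((x1, x2), t)`` with ``t = +1`` when polymer 1 is the more degradable of
the two (pairs are never formed across datasets — the raw values are not
comparable).  A linear ranking SVM with weight vector ``w`` and no intercept
is trained on the difference vectors ``z = x1 - x2`` by minimizing

    0.5 * ||w||^2 + C * sum_i max(0, 1 - t_i * w.z_i)

The degradability score of any polymer is then ``d = w.x``, and sorting all
polymers by ``d`` yields a single unified ranking across datasets.

The QP is solved in the dual (a box-constrained quadratic program over the
pair multipliers), which is exact, deterministic, and fast at the problem
sizes that arise here (tens to hundreds of pairs).
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import GroupKFold, KFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .data import DegradationDataset, Polymer
from .errors import (
    ConfigurationError,
    ConvergenceError,
    SchemeMismatchError,
    ValidationError,
)
from .featurize import FingerprintSet

#: Default hyperparameter grid: log-spaced over 1e-4 .. 10 plus C = 0.007,
#: the optimum reported for the study datasets.
DEFAULT_C_GRID: tuple[float, ...] = tuple(
    sorted(set(np.logspace(-4, 1, 12)) | {0.007})
)


class RankSVM(BaseEstimator):
    """Linear ranking SVM without intercept, in scikit-learn estimator form.

    ``fit`` consumes difference vectors ``X[i] = x1_i - x2_i`` and labels
    ``y[i] = t_i`` in {-1, +1}.  The fitted weight vector is ``coef_``;
    ``decision_function`` returns ``w.z`` for pair difference vectors (and
    equally ``w.x`` for single-item fingerprints, since the model is linear
    with no intercept).

    The dual is solved by cyclic coordinate descent with exact per-coordinate
    minimization (the standard dual solver for linear SVMs); the run is
    deterministic and convergence is certified by the duality gap.

    Parameters
    ----------
    C : float
        Trade-off between the margin and the hinge slack, > 0.
    tol : float
        Relative duality-gap tolerance used to declare convergence.
    max_iter : int
        Cap on coordinate-descent passes over the pairs.
    warm_start : bool
        Reuse the previous fit's dual coefficients as the starting point
        (useful when refitting the same pairs along a C path).
    """

    def __init__(
        self,
        C: float = 1.0,
        tol: float = 1e-6,
        max_iter: int = 20000,
        warm_start: bool = False,
    ):
        self.C = C
        self.tol = tol
        self.max_iter = max_iter
        self.warm_start = warm_start

    def fit(self, X, y):
        if not self.C > 0:
            raise ConfigurationError(f"C must be > 0, got {self.C}")
        X, y = check_X_y(X, y, ensure_min_samples=1)
        labels = np.unique(y)
        if not np.all(np.isin(labels, (-1, 1))):
            raise ValidationError(f"labels must be in {{-1, +1}}, got {labels}")
        if not np.all(np.isfinite(X)):
            raise ValidationError("non-finite fingerprint components")
        Z = X * y[:, None]
        M = Z.shape[0]
        Q = Z @ Z.T
        diag = np.diag(Q).copy()
        if (
            self.warm_start
            and getattr(self, "dual_coef_", None) is not None
            and self.dual_coef_.shape == (M,)
        ):
            alpha = np.clip(self.dual_coef_, 0.0, self.C)
            grad = Q @ alpha - 1.0
        else:
            alpha = np.zeros(M)
            grad = -np.ones(M)  # grad of the dual objective: Q.alpha - 1
        gap = np.inf
        primal = dual_obj = np.nan
        n_pass = 0
        for n_pass in range(1, self.max_iter + 1):
            max_delta = 0.0
            for i in range(M):
                g = grad[i]
                if diag[i] > 0:
                    new = min(max(alpha[i] - g / diag[i], 0.0), self.C)
                else:
                    # zero difference vector: dual is linear in alpha_i
                    new = self.C if g < 0 else 0.0
                step = new - alpha[i]
                if step != 0.0:
                    alpha[i] = new
                    grad += step * Q[i]
                    max_delta = max(max_delta, abs(step))
            if n_pass % 5 == 0 or max_delta == 0.0:
                w = Z.T @ alpha
                primal = 0.5 * w @ w + self.C * np.maximum(0.0, 1.0 - Z @ w).sum()
                dual_obj = alpha.sum() - 0.5 * alpha @ (grad + 1.0)
                gap = primal - dual_obj
                if gap <= self.tol * max(1.0, abs(primal)):
                    break
        w = Z.T @ alpha
        primal = 0.5 * w @ w + self.C * np.maximum(0.0, 1.0 - Z @ w).sum()
        dual_obj = alpha.sum() - 0.5 * alpha @ (grad + 1.0)
        gap = primal - dual_obj
        if gap > self.tol * max(1.0, abs(primal)):
            raise ConvergenceError(
                f"dual solver did not converge in {n_pass} passes: duality gap "
                f"{gap:.3e} (primal {primal:.6e}, dual {dual_obj:.6e})"
            )
        self.coef_ = w
        self.dual_coef_ = alpha
        self.n_features_in_ = X.shape[1]
        self.n_iter_ = n_pass
        self.duality_gap_ = float(gap)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)

    def score(self, X, y) -> float:
        """Preference accuracy: fraction of pairs with sign(w.z) == t."""
        return float(np.mean(self.predict(X) == np.asarray(y)))


# ---------------------------------------------------------------------------
# Preference pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreferencePair:
    """One within-dataset comparison: t = +1 iff polymer 1 is more degradable."""

    x1: np.ndarray
    x2: np.ndarray
    t: int
    dataset_id: str
    id1: str = ""
    id2: str = ""

    @property
    def diff(self) -> np.ndarray:
        return self.x1 - self.x2


@dataclass
class PreferenceSet:
    """Pairs plus the tie report (tied values are excluded, not dropped silently)."""

    pairs: list[PreferencePair]
    n_tied: int = 0
    dataset_ids: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __add__(self, other: "PreferenceSet") -> "PreferenceSet":
        return PreferenceSet(
            pairs=self.pairs + other.pairs,
            n_tied=self.n_tied + other.n_tied,
            dataset_ids=self.dataset_ids + other.dataset_ids,
        )

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(M, dim) difference-vector matrix and (M,) label vector."""
        if not self.pairs:
            raise ValidationError("no preference pairs")
        X = np.stack([p.diff for p in self.pairs])
        y = np.array([p.t for p in self.pairs])
        return X, y

    @property
    def groups(self) -> np.ndarray:
        """Polymer-pair group keys (both member ids), for grouped CV."""
        return np.array([f"{p.id1}|{p.id2}" for p in self.pairs])


def build_preferences(
    dataset: DegradationDataset, fingerprints: FingerprintSet
) -> PreferenceSet:
    """Convert one dataset into preference pairs over its fingerprints.

    One pair per unordered polymer pair with distinct values, oriented as
    (row-earlier, row-later); tied values are excluded and counted in
    ``n_tied``.  A dataset of fewer than two records yields an empty set.
    """
    pairs: list[PreferencePair] = []
    n_tied = 0
    records = dataset.records
    for (p1, v1), (p2, v2) in itertools.combinations(records, 2):
        if v1 == v2:
            n_tied += 1
            continue
        pairs.append(
            PreferencePair(
                x1=fingerprints[p1.id],
                x2=fingerprints[p2.id],
                t=1 if v1 > v2 else -1,
                dataset_id=dataset.id,
                id1=p1.id,
                id2=p2.id,
            )
        )
    return PreferenceSet(pairs=pairs, n_tied=n_tied, dataset_ids=(dataset.id,))


def build_all_preferences(
    datasets: Sequence[DegradationDataset], fingerprints: FingerprintSet
) -> PreferenceSet:
    """Pairs from every dataset, never across datasets."""
    combined = PreferenceSet(pairs=[], n_tied=0, dataset_ids=())
    for ds in datasets:
        combined = combined + build_preferences(ds, fingerprints)
    return combined


# ---------------------------------------------------------------------------
# Model container, training, scoring
# ---------------------------------------------------------------------------

MODEL_FORMAT_VERSION = 1


@dataclass
class RankModel:
    """A trained ranking model: weights, trade-off C, featurization scheme."""

    w: np.ndarray
    C: float
    scheme_id: str
    training_meta: dict = field(default_factory=dict)
    norm_min: float | None = None
    norm_max: float | None = None

    def _check_scheme(self, scheme_id: str) -> None:
        if scheme_id != self.scheme_id:
            raise SchemeMismatchError(self.scheme_id, scheme_id)

    def score(self, x: np.ndarray) -> float:
        """Degradability score d = w.x of one fingerprint."""
        return float(np.dot(self.w, np.asarray(x)))

    def scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.w

    def predict_preference(self, x1: np.ndarray, x2: np.ndarray) -> float:
        """Signed preference y = w.(x1 - x2); sign(y) is the prediction."""
        return float(np.dot(self.w, np.asarray(x1) - np.asarray(x2)))

    def set_normalization(self, training_scores: Sequence[float]) -> None:
        """Record the training-score min/max used by min-max normalization."""
        scores = np.asarray(training_scores, dtype=float)
        self.norm_min = float(scores.min())
        self.norm_max = float(scores.max())

    def normalize(self, d: np.ndarray | float):
        """Affine map sending training-score min/max to [0, 1] (queries may exceed it)."""
        if self.norm_min is None or self.norm_max is None:
            raise ValidationError("normalization range not set; call set_normalization")
        span = self.norm_max - self.norm_min
        if span == 0:
            span = 1.0
        return (d - self.norm_min) / span

    # -- persistence ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "scheme_id": self.scheme_id,
            "w": [float(v) for v in self.w],
            "C": self.C,
            "norm_min": self.norm_min,
            "norm_max": self.norm_max,
            "training_meta": self.training_meta,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RankModel":
        return cls(
            w=np.array(doc["w"], dtype=float),
            C=float(doc["C"]),
            scheme_id=str(doc["scheme_id"]),
            training_meta=dict(doc.get("training_meta", {})),
            norm_min=doc.get("norm_min"),
            norm_max=doc.get("norm_max"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RankModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train(
    preferences: PreferenceSet,
    C: float,
    scheme_id: str = "",
    seed: int | None = None,
) -> RankModel:
    """Fit the ranking SVM on all pairs at trade-off ``C``."""
    X, y = preferences.to_arrays()
    svm = RankSVM(C=C).fit(X, y)
    meta = {
        "M": len(preferences),
        "n_tied_excluded": preferences.n_tied,
        "dataset_ids": list(preferences.dataset_ids),
        "training_accuracy": svm.score(X, y),
        "duality_gap": svm.duality_gap_,
    }
    if seed is not None:
        meta["seed"] = seed
    return RankModel(w=svm.coef_, C=C, scheme_id=scheme_id, training_meta=meta)


@dataclass
class CVResult:
    best_C: float
    accuracy_by_C: dict[float, float]
    fold_accuracies: dict[float, list[float]]
    n_folds: int
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "C": list(self.accuracy_by_C),
                "mean_accuracy": list(self.accuracy_by_C.values()),
            }
        )


def select_C(
    preferences: PreferenceSet,
    grid: Sequence[float] = DEFAULT_C_GRID,
    n_folds: int = 5,
    seed: int = 0,
    group_by_polymer_pair: bool = False,
) -> CVResult:
    """Choose C by k-fold cross-validated preference accuracy.

    Pairs are shuffled with ``seed`` and split into ``n_folds``; accuracy is
    the held-out fraction of pairs with sign(w.z) = t.  The best C maximizes
    mean accuracy, ties resolved toward the smaller C.  By default folds
    partition *pairs*; ``group_by_polymer_pair`` keeps duplicated polymer
    pairs (shared across datasets) in one fold, a stricter splitter that
    avoids cross-fold leakage of identical comparisons.
    """
    grid = sorted(float(c) for c in grid)
    if not grid:
        raise ConfigurationError("empty C grid")
    if any(c <= 0 for c in grid):
        raise ConfigurationError("C grid values must be > 0")
    X, y = preferences.to_arrays()
    M = len(y)
    if M < n_folds:
        raise ConfigurationError(f"need at least n_folds={n_folds} pairs, have {M}")
    if group_by_polymer_pair:
        rng = np.random.default_rng(seed)
        order = rng.permutation(M)
        splitter = GroupKFold(n_splits=n_folds)
        splits = [
            (order[tr], order[te])
            for tr, te in splitter.split(X[order], y[order], preferences.groups[order])
        ]
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(X))
    fold_acc: dict[float, list[float]] = {c: [] for c in grid}
    for train_idx, test_idx in splits:
        svm = RankSVM(warm_start=True)  # continuation along the C path
        for c in grid:
            svm.set_params(C=c).fit(X[train_idx], y[train_idx])
            fold_acc[c].append(svm.score(X[test_idx], y[test_idx]))
    mean_acc = {c: float(np.mean(accs)) for c, accs in fold_acc.items()}
    best_C = grid[0]
    for c in grid[1:]:
        if mean_acc[c] > mean_acc[best_C]:
            best_C = c
    return CVResult(
        best_C=best_C,
        accuracy_by_C=mean_acc,
        fold_accuracies=fold_acc,
        n_folds=n_folds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Unified ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankEntry:
    rank: int
    polymer: Polymer
    d: float
    d_norm: float | None
    dataset_id: str


@dataclass
class UnifiedRanking:
    """Polymers from all sources ordered by degradability score d (descending)."""

    entries: list[RankEntry]
    normalization: str = "raw"

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def position(self, abbreviation: str, dataset_id: str | None = None) -> int:
        """1-based rank of a polymer (optionally disambiguated by source)."""
        for e in self.entries:
            if e.polymer.abbreviation == abbreviation and (
                dataset_id is None or e.dataset_id == dataset_id
            ):
                return e.rank
        raise KeyError(abbreviation)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rank": [e.rank for e in self.entries],
                "abbreviation": [e.polymer.abbreviation for e in self.entries],
                "d_raw": [e.d for e in self.entries],
                "d_norm": [e.d_norm for e in self.entries],
                "dataset_id": [e.dataset_id for e in self.entries],
            }
        )


def unified_ranking(
    model: RankModel,
    polymers: Sequence[Polymer],
    fingerprints: FingerprintSet,
    normalization: str = "raw",
) -> UnifiedRanking:
    """Rank ``polymers`` by d = w.x, descending; ties break on abbreviation.

    ``normalization="minmax"`` additionally reports scores under the affine
    map taking the model's recorded training-score range to [0, 1]; when the
    model carries no recorded range, the range of the scored set is used and
    recorded.
    """
    model._check_scheme(fingerprints.scheme_id)
    if normalization not in ("raw", "minmax"):
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    scored = [(model.score(fingerprints[p.id]), p) for p in polymers]
    if normalization == "minmax" and model.norm_min is None:
        model.set_normalization([s for s, _ in scored])
    scored.sort(key=lambda sp: (-sp[0], sp[1].abbreviation))
    entries = [
        RankEntry(
            rank=i + 1,
            polymer=p,
            d=s,
            d_norm=float(model.normalize(s)) if normalization == "minmax" else None,
            dataset_id=p.dataset_id,
        )
        for i, (s, p) in enumerate(scored)
    ]
    return UnifiedRanking(entries=entries, normalization=normalization)
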