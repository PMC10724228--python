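"""k-nearest-neighbor applicability domain for the ranking model.

A query polymer is scored only if it lies inside the fingerprint-space
region populated by the training set.  In-domain is defined by the mean
Euclidean distance to the k nearest reference fingerprints; the cutoff is a
percentile (default 95) of the leave-self-out mean-kNN distances of the
reference points themselves, so roughly (100 - percentile)% of the training
set sits outside its own domain by construction.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import ConfigurationError, SchemeMismatchError


class KNNApplicabilityDomain(BaseEstimator):
    """kNN applicability-domain filter in scikit-learn estimator form.

    Parameters
    ----------
    k : int
        Number of nearest reference neighbors averaged over (>= 1, < n_ref).
    percentile : float
        Percentile of the reference leave-self-out distances used as the
        in-domain threshold.
    metric : str
        Distance metric label, passed to the neighbor search.
    scheme_id : str, optional
        Featurization scheme of the reference fingerprints; queries under a
        different scheme are rejected when both sides declare one.
    """

    def __init__(
        self,
        k: int = 5,
        percentile: float = 95.0,
        metric: str = "euclidean",
        scheme_id: str | None = None,
    ):
        self.k = k
        self.percentile = percentile
        self.metric = metric
        self.scheme_id = scheme_id

    def fit(self, X, y=None):
        X = check_array(X)
        if not 1 <= self.k < X.shape[0]:
            raise ConfigurationError(
                f"k must satisfy 1 <= k < n_reference ({X.shape[0]}), got {self.k}"
            )
        if not 0 < self.percentile <= 100:
            raise ConfigurationError("percentile must be in (0, 100]")
        self.reference_ = X
        self._nn = NearestNeighbors(n_neighbors=self.k, metric=self.metric).fit(X)
        # leave-self-out: query with k+1 and drop the self column
        dist, _ = NearestNeighbors(n_neighbors=self.k + 1, metric=self.metric).fit(
            X
        ).kneighbors(X)
        self.reference_distances_ = dist[:, 1:].mean(axis=1)
        self.threshold_ = float(
            np.percentile(self.reference_distances_, self.percentile)
        )
        return self

    def decision_function(self, X) -> np.ndarray:
        """Mean distance of each query to its k nearest reference points."""
        check_is_fitted(self, "threshold_")
        X = check_array(X)
        dist, _ = self._nn.kneighbors(X)
        return dist.mean(axis=1)

    def predict(self, X) -> np.ndarray:
        """Boolean in-domain flag per query."""
        return self.decision_function(X) <= self.threshold_

    def check_scheme(self, scheme_id: str) -> None:
        if self.scheme_id is not None and scheme_id != self.scheme_id:
            raise SchemeMismatchError(self.scheme_id, scheme_id)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "threshold_")
        doc = {
            "k": self.k,
            "percentile": self.percentile,
            "metric": self.metric,
            "scheme_id": self.scheme_id,
            "threshold": self.threshold_,
            "reference": [[float(v) for v in row] for row in self.reference_],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "KNNApplicabilityDomain":
        doc = json.loads(Path(path).read_text())
        model = cls(
            k=int(doc["k"]),
            percentile=float(doc["percentile"]),
            metric=str(doc["metric"]),
            scheme_id=doc.get("scheme_id"),
        ).fit(np.array(doc["reference"], dtype=float))
        model.threshold_ = float(doc["threshold"])
        return model


def fit_ad(
    reference_fingerprints: np.ndarray,
    k: int = 5,
    percentile: float = 95.0,
    scheme_id: str | None = None,
) -> KNNApplicabilityDomain:
    """Fit the applicability-domain filter on training fingerprints."""
    return KNNApplicabilityDomain(k=k, percentile=percentile, scheme_id=scheme_id).fit(
        np.asarray(reference_fingerprints)
    )


def in_domain(ad: KNNApplicabilityDomain, x: np.ndarray) -> tuple[bool, float]:
    """(flag, mean kNN distance) for a single query fingerprint."""
    x = np.asarray(x).reshape(1, -1)
    dist = float(ad.decision_function(x)[0])
    return bool(dist <= ad.threshold_), dist
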