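"""End-to-end orchestration: datasets -> preferences -> CV -> model -> outputs.

``run_unified_ranking`` wires the whole training path together: fingerprint
every polymer, build within-dataset preference pairs, pick the trade-off C
by cross-validated preference accuracy, refit on *all* pairs at the chosen
C, and emit the unified ranking.  ``run_factor_analysis`` then fits the
descriptor regression tree on the model's (min-max normalized) scores and
categorizes its leaves.

Every run is controlled by a :class:`RunConfig`; outputs carry the config
hash in a comment header so a ranking file can always be traced to the
exact configuration and seed that produced it.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .data import DegradationDataset, read_dataset
from .errors import ConfigurationError
from .featurize import (
    DEFAULT_SCHEME,
    FingerprintSet,
    FunctionalGroupCounter,
    fingerprint_polymers,
    make_fingerprinter,
)
from .ranksvm import (
    DEFAULT_C_GRID,
    CVResult,
    RankModel,
    UnifiedRanking,
    build_all_preferences,
    select_C,
    train,
    unified_ranking,
)
from .tree import CategoryRule, DegradabilityTree, categorize_leaves


@dataclass
class DatasetSpec:
    path: str
    dataset_id: str
    smiles_col: str = "smiles"
    value_col: str = "value"
    name_col: str | None = "name"
    abbreviation_col: str | None = "abbreviation"


@dataclass
class RunConfig:
    """Full provenance-bearing configuration of a pipeline run."""

    datasets: list[DatasetSpec] = field(default_factory=list)
    scheme: str = DEFAULT_SCHEME
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_folds: int = 5
    seed: int = 0
    normalization: str = "minmax"
    group_cv_by_polymer_pair: bool = False
    max_leaves: int = 10
    min_leaf_size: int = 1
    ad_k: int = 5
    ad_percentile: float = 95.0

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["c_grid"] = [float(c) for c in self.c_grid]
        return doc

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclass_fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        doc = dict(doc)
        if "datasets" in doc:
            doc["datasets"] = [
                DatasetSpec(**d) if isinstance(d, dict) else d for d in doc["datasets"]
            ]
        if "c_grid" in doc:
            doc["c_grid"] = tuple(float(c) for c in doc["c_grid"])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(doc)

    def provenance_header(self) -> str:
        return f"polyrank {__version__} | config {self.hash()} | seed {self.seed}"


def load_datasets(config: RunConfig) -> list[DegradationDataset]:
    if not config.datasets:
        raise ConfigurationError("no datasets configured")
    out = []
    for spec in config.datasets:
        cmap = {"smiles": spec.smiles_col, "value": spec.value_col}
        if spec.name_col:
            cmap["name"] = spec.name_col
        if spec.abbreviation_col:
            cmap["abbreviation"] = spec.abbreviation_col
        out.append(read_dataset(spec.path, cmap, dataset_id=spec.dataset_id))
    return out


@dataclass
class RankingRun:
    """Everything produced by one unified-ranking run."""

    model: RankModel
    ranking: UnifiedRanking
    cv: CVResult
    fingerprints: FingerprintSet
    datasets: list[DegradationDataset]
    config: RunConfig

    @property
    def report(self) -> dict:
        return {
            "config_hash": self.config.hash(),
            "n_datasets": len(self.datasets),
            "n_polymers": sum(len(d) for d in self.datasets),
            "n_pairs": self.model.training_meta["M"],
            "n_tied_excluded": self.model.training_meta["n_tied_excluded"],
            "best_C": self.cv.best_C,
            "cv_accuracy_at_best_C": self.cv.accuracy_by_C[self.cv.best_C],
            "training_accuracy": self.model.training_meta["training_accuracy"],
        }


def run_unified_ranking(
    config: RunConfig, datasets: Sequence[DegradationDataset] | None = None
) -> RankingRun:
    """Train on all configured datasets and build the unified ranking.

    ``datasets`` may be passed directly (e.g. the packaged fixtures or a
    synthetic instance); otherwise they are read from the configured paths.
    """
    if datasets is None:
        datasets = load_datasets(config)
    datasets = list(datasets)
    if not datasets:
        raise ConfigurationError("empty dataset list")
    fingerprinter = make_fingerprinter(config.scheme)
    all_polymers = [p for ds in datasets for p in ds.polymers]
    fps = fingerprint_polymers(all_polymers, fingerprinter)
    prefs = build_all_preferences(datasets, fps)
    cv = select_C(
        prefs,
        grid=config.c_grid,
        n_folds=config.n_folds,
        seed=config.seed,
        group_by_polymer_pair=config.group_cv_by_polymer_pair,
    )
    model = train(prefs, C=cv.best_C, scheme_id=fps.scheme_id, seed=config.seed)
    model.training_meta["cv_accuracy_by_C"] = {
        f"{c:g}": acc for c, acc in cv.accuracy_by_C.items()
    }
    model.set_normalization([model.score(fps[p.id]) for p in all_polymers])
    ranking = unified_ranking(model, all_polymers, fps, normalization=config.normalization)
    return RankingRun(
        model=model,
        ranking=ranking,
        cv=cv,
        fingerprints=fps,
        datasets=datasets,
        config=config,
    )


@dataclass
class FactorAnalysis:
    tree: DegradabilityTree
    categories: CategoryRule
    descriptor_table: "np.ndarray"
    scores: np.ndarray
    labels: list[str]
    rendered: str

    @property
    def report(self) -> dict:
        return {
            "n_leaves": self.tree.n_leaves_,
            "split_features": self.tree.split_features_,
            "leaf_means": [float(m) for m in self.tree.leaf_means_],
            "boundaries": list(self.categories.boundaries),
            "leaf_categories": self.categories.leaf_categories,
        }


def run_factor_analysis(run: RankingRun, use_normalized_scores: bool = True) -> FactorAnalysis:
    """Fit the descriptor tree on the trained model's scores.

    Scores are min-max normalized by default so leaf means live on the
    [0, 1] scale on which the three-category bands are defined; raw scores
    are available via ``use_normalized_scores=False``.
    """
    polymers = [p for ds in run.datasets for p in ds.polymers]
    descriptors = FunctionalGroupCounter().transform(polymers)
    scores = np.array([run.model.score(run.fingerprints[p.id]) for p in polymers])
    if use_normalized_scores:
        if run.model.norm_min is None:
            run.model.set_normalization(scores)
        scores = np.asarray(run.model.normalize(scores))
    tree = DegradabilityTree(
        max_leaves=run.config.max_leaves, min_leaf_size=run.config.min_leaf_size
    ).fit(descriptors, scores)
    labels = [p.abbreviation for p in polymers]
    if tree.n_leaves_ >= 3:
        categories = categorize_leaves(tree)
    else:
        categories = CategoryRule(
            boundaries=(float("nan"), float("nan")),
            leaf_categories={leaf.leaf_id: "middle" for leaf in tree.leaves_},
            provenance="fallback-single-category",
        )
    return FactorAnalysis(
        tree=tree,
        categories=categories,
        descriptor_table=descriptors,
        scores=scores,
        labels=labels,
        rendered=tree.render_text(labels),
    )


def write_ranking(run: RankingRun, path: str | Path) -> None:
    frame = run.ranking.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# {run.config.provenance_header()}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_cv_curve(run: RankingRun, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {run.config.provenance_header()}\n")
        run.cv.to_frame().to_csv(fh, sep="\t", index=False)
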