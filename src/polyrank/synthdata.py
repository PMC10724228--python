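"""Synthetic multi-dataset generator and packaged study fixtures.

The generator emulates the premise of the integration problem: several
laboratories observe the *same* latent degradability through different,
incompatible measurement conditions.  Surrogate "polymers" carry synthetic
300-component fingerprints x drawn from a standard normal; the latent score
is s = w_true.x; dataset j reports g_j(s) + eps with g_j a strictly
increasing condition distortion (identity, softplus-style "log1p-scale",
signed power, or positive affine) and eps Gaussian observation noise.
Because each g_j is monotone, within-dataset preference pairs are noiselessly
consistent with the latent order when noise_sd = 0, which is what makes the
ground truth recoverable by the ranking model and usable in recovery tests.

``study_datasets`` returns the three packaged study datasets (24 literature
polymers ranked by weight loss per day, and two 7- and 8-polymer exposure
datasets measured by the δ index).
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import DegradationDataset, Polymer, dataset_from_frame
from .errors import ConfigurationError
from .featurize import FingerprintSet


def _make_transform(label: str) -> Callable[[np.ndarray], np.ndarray]:
    if label == "identity":
        return lambda s: s
    if label == "log1p-scale":
        return lambda s: np.log1p(np.exp(np.clip(s, -500, 500)))  # softplus
    if label.startswith("power:"):
        gamma = float(label.split(":", 1)[1])
        if gamma <= 0:
            raise ConfigurationError(f"power exponent must be > 0: {label!r}")
        return lambda s: np.sign(s) * np.abs(s) ** gamma
    if label.startswith("affine:"):
        a, b = (float(v) for v in label.split(":", 1)[1].split(","))
        if a <= 0:
            raise ConfigurationError(f"affine slope must be > 0: {label!r}")
        return lambda s: a * s + b
    raise ConfigurationError(f"unknown transform label {label!r}")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the recovery setting used throughout the test suite:
    three datasets of 20 polymers, one monotone distortion per dataset, and
    observation noise of 0.05 standard deviations of the latent score.
    """

    n_polymers: tuple[int, ...] = (20, 20, 20)
    dim: int = 300
    transforms: tuple[str, ...] = ("identity", "power:2", "log1p-scale")
    noise_sd: float | tuple[float, ...] = 0.05
    noise_relative: bool = True  # noise_sd in units of sd(latent score)
    overlap: int = 0  # polymers shared between consecutive dataset pairs
    w_true: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.transforms) != len(self.n_polymers):
            raise ConfigurationError(
                "need one transform per dataset "
                f"({len(self.n_polymers)} datasets, {len(self.transforms)} transforms)"
            )
        for label in self.transforms:
            _make_transform(label)  # validate eagerly
        sds = self.noise_sds
        if any(sd < 0 for sd in sds):
            raise ConfigurationError("noise_sd must be >= 0")
        if self.overlap < 0 or any(self.overlap > n for n in self.n_polymers):
            raise ConfigurationError("overlap must be >= 0 and <= each dataset size")

    @property
    def noise_sds(self) -> tuple[float, ...]:
        if isinstance(self.noise_sd, (int, float)):
            return tuple(float(self.noise_sd) for _ in self.n_polymers)
        if len(self.noise_sd) != len(self.n_polymers):
            raise ConfigurationError("need one noise_sd per dataset")
        return tuple(float(v) for v in self.noise_sd)


@dataclass
class GroundTruth:
    """Latent structure behind a generated instance."""

    w_true: np.ndarray
    latent: dict[str, float]  # polymer id -> latent score s
    fingerprints: FingerprintSet

    def latent_of(self, polymers: Sequence[Polymer]) -> np.ndarray:
        return np.array([self.latent[p.id] for p in polymers])


SYNTH_SCHEME = "synthetic"


def generate(config: SynthConfig) -> tuple[list[DegradationDataset], GroundTruth]:
    """Draw one synthetic multi-dataset instance; bit-reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    n_unique = sum(config.n_polymers) - config.overlap * (len(config.n_polymers) - 1)
    if config.w_true is not None:
        w_true = np.asarray(config.w_true, dtype=float)
        if w_true.shape != (config.dim,):
            raise ConfigurationError(
                f"w_true must have shape ({config.dim},), got {w_true.shape}"
            )
    else:
        w_true = rng.normal(size=config.dim) / np.sqrt(config.dim)
    X = rng.normal(size=(n_unique, config.dim))
    s_all = X @ w_true
    polymers = [
        Polymer(
            id=f"syn:{i:04d}",
            name=f"synthetic polymer {i}",
            abbreviation=f"SYN{i:04d}",
            smiles="*" + "C" * (i + 1) + "*",  # placeholder repeat unit
        )
        for i in range(n_unique)
    ]
    vectors = {p.id: X[i] for i, p in enumerate(polymers)}
    latent = {p.id: float(s_all[i]) for i, p in enumerate(polymers)}

    datasets: list[DegradationDataset] = []
    cursor = 0
    prev_members: list[int] = []
    for j, (n_j, label) in enumerate(zip(config.n_polymers, config.transforms)):
        shared = prev_members[: config.overlap] if j > 0 else []
        n_new = n_j - len(shared)
        members = shared + list(range(cursor, cursor + n_new))
        cursor += n_new
        g = _make_transform(label)
        s_j = s_all[members]
        sd = config.noise_sds[j]
        if config.noise_relative:
            sd = sd * (float(np.std(s_j)) or 1.0)
        values = g(s_j) + rng.normal(scale=sd, size=n_j) if sd > 0 else g(s_j)
        values = values - values.min()  # shift to >= 0; monotone, order-preserving
        dataset_id = f"synth{j}"
        records = [
            (
                Polymer(
                    id=polymers[m].id,
                    name=polymers[m].name,
                    abbreviation=polymers[m].abbreviation,
                    smiles=polymers[m].smiles,
                    dataset_id=dataset_id,
                ),
                float(v),
            )
            for m, v in zip(members, values)
        ]
        datasets.append(
            DegradationDataset(id=dataset_id, records=records, units="synthetic")
        )
        prev_members = members
    truth = GroundTruth(
        w_true=w_true,
        latent=latent,
        fingerprints=FingerprintSet(scheme_id=SYNTH_SCHEME, vectors=vectors),
    )
    return datasets, truth


def write_instance(
    datasets: Sequence[DegradationDataset],
    truth: GroundTruth,
    out_dir: str | Path,
) -> None:
    """Write one TSV per dataset plus ground_truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .data import write_dataset

    for ds in datasets:
        write_dataset(ds, out / f"{ds.id}.tsv")
    rows = [
        {"polymer_id": pid, "latent_score": s} for pid, s in sorted(truth.latent.items())
    ]
    pd.DataFrame(rows).to_csv(out / "ground_truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged study fixtures
# ---------------------------------------------------------------------------

_FIXTURE_UNITS = {"literature": "%/day", "exp1": "delta", "exp2": "delta"}


def _fixture_frame(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("polyrank.datasets") / f"{name}.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def study_datasets() -> dict[str, DegradationDataset]:
    """The three packaged study datasets keyed 'literature', 'exp1', 'exp2'.

    The literature dataset (24 polymers) is ranked by weight loss per day;
    the two exposure datasets (7 and 8 polymers) by the δ index.  SMILES are
    canonicalized on load.
    """
    out = {}
    for name in ("literature", "exp1", "exp2"):
        frame = _fixture_frame(name)
        out[name] = dataset_from_frame(
            frame,
            {"smiles": "smiles", "value": "value", "name": "name", "abbreviation": "abbreviation"},
            dataset_id=name,
            units=_FIXTURE_UNITS[name],
        )
    return out


def exposure_measurements() -> pd.DataFrame:
    """Raw exposure measurements of the first experimental dataset.

    Columns: name, abbreviation, smiles, W_film [mg], TOC [mg/L],
    V_water [mL], M_c [%], S_film [cm²], value (the published δ).
    """
    return _fixture_frame("exp1")
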