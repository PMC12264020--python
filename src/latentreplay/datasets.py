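"""Synthetic domain-incremental latent benchmarks.

Domain-incremental continual learning assumes a fixed label set whose input
distribution shifts from task to task (new acquisition site, staining
protocol, tissue type, ...).  This module emulates that setting directly in
latent space: each domain draws class-conditional isotropic Gaussian latent
vectors, and between-domain shift is controlled by three knobs — a mean
translation applied to every class, a per-class scale, and a rotation in the
first two latent coordinates.  The resulting sequence of labelled
train/test splits is the unit every other module consumes, so the whole
method is testable without images or pretrained backbones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml


class ValidationError(ValueError):
    """Raised when a spec or dataset violates its contract."""


class ParseError(ValueError):
    """Raised when an on-disk dataset file is malformed."""


@dataclass(frozen=True)
class DomainSpec:
    """Recipe for one domain's class-conditional latent distribution.

    Parameters
    ----------
    domain_id : str
        Short identifier, used as directory name on disk.
    n_train_per_class, n_test_per_class : int
        Exact per-class sample counts for each split.
    class_means : (C, d) array
        Base class centroids before domain shift.
    class_scales : (C,) array
        Isotropic standard deviation per class; strictly positive.
    shift_vector : (d,) array
        Translation added to every class mean (the domain shift).
    rotation_angle : float
        Rotation in radians applied in latent coordinates (0, 1) after
        translation and scaling.
    seed : int
        Non-negative seed; train and test draws use independent spawned
        streams so changing one count never perturbs the other split.
    """

    domain_id: str
    n_train_per_class: int
    n_test_per_class: int
    class_means: np.ndarray
    class_scales: np.ndarray
    shift_vector: np.ndarray
    rotation_angle: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.asarray(self.class_means, dtype=float)
        scales = np.asarray(self.class_scales, dtype=float)
        shift = np.asarray(self.shift_vector, dtype=float)
        if means.ndim != 2:
            raise ValidationError("class_means must be a (C, d) matrix")
        c, d = means.shape
        if c < 2 or d < 2:
            raise ValidationError(f"need C >= 2 and d >= 2, got C={c}, d={d}")
        if scales.shape != (c,):
            raise ValidationError("class_scales must have one entry per class")
        if np.any(scales <= 0):
            raise ValidationError("all class scales must be strictly positive")
        if shift.shape != (d,):
            raise ValidationError(
                f"shift_vector dimension {shift.shape} mismatches d={d}"
            )
        if self.n_train_per_class <= 0 or self.n_test_per_class <= 0:
            raise ValidationError("per-class counts must be positive")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")
        object.__setattr__(self, "class_means", means)
        object.__setattr__(self, "class_scales", scales)
        object.__setattr__(self, "shift_vector", shift)

    @property
    def n_classes(self) -> int:
        return self.class_means.shape[0]

    @property
    def dim(self) -> int:
        return self.class_means.shape[1]


@dataclass
class LatentDataset:
    """Labelled latent vectors for one domain and split."""

    domain_id: str
    split: str
    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValidationError("features must be a 2-d matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValidationError(
                f"{self.features.shape[0]} feature rows vs "
                f"{self.labels.shape[0]} labels"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("features contain non-finite values")
        if self.labels.size and self.labels.min() < 0:
            raise ValidationError("negative class index")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def _rotate01(x: np.ndarray, angle: float) -> np.ndarray:
    """Rotate rows of x by `angle` in the plane of coordinates (0, 1)."""
    if angle == 0.0:
        return x
    out = x.copy()
    c, s = math.cos(angle), math.sin(angle)
    out[:, 0] = c * x[:, 0] - s * x[:, 1]
    out[:, 1] = s * x[:, 0] + c * x[:, 1]
    return out


def _draw_split(spec: DomainSpec, n_per_class: int, stream_key: int) -> LatentDataset:
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(stream_key,))
    )
    c, d = spec.class_means.shape
    blocks, labels = [], []
    for cls in range(c):
        center = spec.class_means[cls] + spec.shift_vector
        z = rng.standard_normal((n_per_class, d))
        blocks.append(center + spec.class_scales[cls] * z)
        labels.append(np.full(n_per_class, cls, dtype=int))
    features = _rotate01(np.vstack(blocks), spec.rotation_angle)
    split = "train" if stream_key == 0 else "test"
    return LatentDataset(spec.domain_id, split, features, np.concatenate(labels))


def make_domain(spec: DomainSpec) -> tuple[LatentDataset, LatentDataset]:
    """Generate the (train, test) pair for one domain.

    Class ``c`` is drawn from an isotropic Gaussian at
    ``class_means[c] + shift_vector`` with standard deviation
    ``class_scales[c]``, then rotated by ``rotation_angle`` in coordinates
    (0, 1).  Fully reproducible from ``spec.seed``; train and test use
    independent streams.
    """
    return _draw_split(spec, spec.n_train_per_class, 0), _draw_split(
        spec, spec.n_test_per_class, 1
    )


def make_sequence(
    specs: Sequence[DomainSpec],
) -> list[tuple[LatentDataset, LatentDataset]]:
    """Generate an ordered task sequence; element t is task t (1-based in reports)."""
    if not specs:
        raise ValidationError("sequence needs at least one domain spec")
    c0, d0 = specs[0].n_classes, specs[0].dim
    for s in specs[1:]:
        if s.n_classes != c0 or s.dim != d0:
            raise ValidationError(
                "domain-incremental contract violated: all domains must share "
                f"the label set and latent dimension (expected C={c0}, d={d0}, "
                f"got C={s.n_classes}, d={s.dim} for {s.domain_id!r})"
            )
    return [make_domain(s) for s in specs]


# ---------------------------------------------------------------------------
# On-disk format: delimited text, columns f0..f{d-1} + label, one row per
# latent vector.  A sequence is <domain>/{train,test}.tsv + sequence.yaml.
# ---------------------------------------------------------------------------

def write_dataset(ds: LatentDataset, path: str | Path, sep: str = "\t") -> None:
    path = Path(path)
    df = pd.DataFrame(ds.features, columns=[f"f{j}" for j in range(ds.dim)])
    df["label"] = ds.labels
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_dataset(
    path: str | Path, domain_id: str | None = None, split: str | None = None
) -> LatentDataset:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    header = path.open().readline().rstrip("\n").split(sep)
    feature_cols = [h for h in header if h.startswith("f")]
    if "label" not in header:
        raise ParseError(f"{path}: header {header!r} lacks a 'label' column")
    expected = [f"f{j}" for j in range(len(feature_cols))]
    if feature_cols != expected:
        raise ParseError(
            f"{path}: feature columns {feature_cols!r} are not f0..f{len(feature_cols)-1}"
        )
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in feature_cols:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric feature cell at data row {row}, column {col!r}"
            )
    labels = pd.to_numeric(df["label"], errors="coerce")
    if labels.isna().any():
        row = int(np.flatnonzero(labels.isna().to_numpy())[0])
        raise ParseError(f"{path}: unknown label at data row {row}")
    if domain_id is None:
        domain_id = path.parent.name or path.stem
    if split is None:
        split = path.stem
    return LatentDataset(
        domain_id, split, df[feature_cols].to_numpy(float), labels.to_numpy(int)
    )


def write_sequence(
    specs: Sequence[DomainSpec], out_dir: str | Path
) -> list[tuple[LatentDataset, LatentDataset]]:
    """Materialise a sequence as <domain>/{train,test}.tsv + sequence.yaml."""
    out_dir = Path(out_dir)
    pairs = make_sequence(specs)
    for spec, (train, test) in zip(specs, pairs):
        write_dataset(train, out_dir / spec.domain_id / "train.tsv")
        write_dataset(test, out_dir / spec.domain_id / "test.tsv")
    manifest = {"domains": [s.domain_id for s in specs]}
    (out_dir / "sequence.yaml").write_text(yaml.safe_dump(manifest))
    return pairs


def read_sequence(seq_dir: str | Path) -> list[tuple[LatentDataset, LatentDataset]]:
    seq_dir = Path(seq_dir)
    manifest_path = seq_dir / "sequence.yaml"
    if not manifest_path.exists():
        raise ParseError(f"{seq_dir}: missing sequence.yaml manifest")
    manifest = yaml.safe_load(manifest_path.read_text())
    if not isinstance(manifest, dict) or "domains" not in manifest:
        raise ParseError(f"{manifest_path}: manifest must map 'domains' to a list")
    pairs = []
    for dom in manifest["domains"]:
        train = read_dataset(seq_dir / dom / "train.tsv", dom, "train")
        test = read_dataset(seq_dir / dom / "test.tsv", dom, "test")
        if train.dim != test.dim:
            raise ParseError(f"{dom}: train/test dimension mismatch")
        pairs.append((train, test))
    if not pairs:
        raise ParseError(f"{seq_dir}: empty sequence")
    dims = {p[0].dim for p in pairs}
    if len(dims) > 1:
        raise ParseError(f"{seq_dir}: heterogeneous latent dimensions {sorted(dims)}")
    return pairs


# ---------------------------------------------------------------------------
# Default benchmark: four domains, three classes (monocyte / eosinophil /
# lymphocyte analogue), d=16, with strong heterogeneous shifts so that naive
# sequential fine-tuning visibly forgets early domains.
# ---------------------------------------------------------------------------

DEFAULT_DIM = 16
DEFAULT_N_CLASSES = 3
DEFAULT_CLASS_SEP = 4.0
DEFAULT_SHIFT_NORM = 8.0
DEFAULT_N_TRAIN_PER_CLASS = 100
DEFAULT_N_TEST_PER_CLASS = 50


def default_benchmark_specs(
    base_seed: int = 0,
    n_domains: int = 4,
    dim: int = DEFAULT_DIM,
    n_classes: int = DEFAULT_N_CLASSES,
    n_train_per_class: int = DEFAULT_N_TRAIN_PER_CLASS,
    n_test_per_class: int = DEFAULT_N_TEST_PER_CLASS,
    class_sep: float = DEFAULT_CLASS_SEP,
    shift_norm: float = DEFAULT_SHIFT_NORM,
) -> list[DomainSpec]:
    """Specs for the default synthetic 4-domain benchmark.

    Class centroids sit ``class_sep`` apart along the first axes; domain t
    is translated by a ``shift_norm``-long vector in a domain-specific
    direction, rotated by t*pi/8 in coordinates (0, 1), and mildly
    rescaled — mimicking heterogeneous between-site shifts while keeping
    classes separable within every domain.
    """
    means = np.zeros((n_classes, dim))
    for c in range(n_classes):
        means[c, c % dim] = class_sep
    rng = np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(99,)))
    specs = []
    for t in range(n_domains):
        if t == 0:
            shift = np.zeros(dim)
        else:
            direction = rng.standard_normal(dim)
            shift = shift_norm * direction / np.linalg.norm(direction)
        specs.append(
            DomainSpec(
                domain_id=f"domain{t + 1}",
                n_train_per_class=n_train_per_class,
                n_test_per_class=n_test_per_class,
                class_means=means,
                class_scales=np.full(n_classes, 1.5 + 0.15 * t),
                shift_vector=shift,
                rotation_angle=t * math.pi / 8,
                seed=base_seed * 1000 + t,
            )
        )
    return specs
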