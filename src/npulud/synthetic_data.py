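"""Seeded synthetic PU datasets with known ground truth.

Two generators stand in for downloadable benchmarks so every stage of the
pipeline is testable offline:

* :func:`generate_gaussian_pu` draws two class-conditional Gaussian
  clusters (isotropic unit within-class standard deviation, centroids a
  configurable number of standard deviations apart) plus optional
  class-conditional categorical features, then hides labels at the
  configured masking ratio.
* :func:`generate_grid_toy` lays the two classes out on separated
  axis-aligned columns of a grid — the same low-weight-positive /
  high-weight-negative structure as the built-in 20-instance example — with
  a deterministic spaced-out masked subset, so unanimous-vote relabeling
  recovers every hidden label and a depth-1 threshold tree separates the
  classes.

One pseudo-random stream per dataset is split deterministically between
feature sampling and masking, so the same config and seed always reproduce
the same dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_core import (
    NEGATIVE,
    POSITIVE,
    UNLABELED,
    FeatureSpec,
    Instance,
    MaskingConfig,
    ParameterError,
    PUDataset,
    mask_labels,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the Gaussian PU generator.

    ``separation`` is the Euclidean distance between class centroids in
    units of the (unit) within-class standard deviation; 6 gives nearly
    disjoint clusters, 1 heavy overlap.
    """

    n: int = 200
    d_numeric: int = 2
    d_categorical: int = 0
    separation: float = 6.0
    positive_fraction: float = 0.5
    mask_ratio: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ParameterError("need n >= 10")
        if not (0.0 < self.positive_fraction < 1.0):
            raise ParameterError("positive_fraction must be in (0, 1)")
        if self.positive_fraction * self.n < 1:
            raise ParameterError("need at least one positive instance")
        if not (0.0 <= self.mask_ratio <= 1.0):
            raise ParameterError("mask_ratio outside [0, 1]")
        if self.d_numeric < 0 or self.d_categorical < 0:
            raise ParameterError("feature counts must be non-negative")
        if self.d_numeric + self.d_categorical == 0:
            raise ParameterError("need at least one feature")
        if self.separation < 0:
            raise ParameterError("separation must be non-negative")


#: category preference of each class for categorical features: the positive
#: class favors the first category, the negative class the last.
_CAT_LEVELS = ("a", "b", "c")
_CAT_P_POS = (0.7, 0.2, 0.1)
_CAT_P_NEG = (0.1, 0.2, 0.7)


def generate_gaussian_pu(config: SyntheticConfig) -> PUDataset:
    """Draw a seeded Gaussian-cluster PU dataset per the configuration."""
    rng = np.random.default_rng(config.seed)
    feature_rng, mask_seed = rng.spawn(1)[0], int(rng.integers(0, 2**31 - 1))

    n_pos = int(round(config.positive_fraction * config.n))
    n_pos = min(max(n_pos, 1), config.n - 1)
    labels = [POSITIVE] * n_pos + [NEGATIVE] * (config.n - n_pos)

    # centroids `separation` apart along the all-ones diagonal
    offset = (
        config.separation / np.sqrt(config.d_numeric) if config.d_numeric else 0.0
    )
    num = np.empty((config.n, config.d_numeric))
    for i, lab in enumerate(labels):
        mean = 0.0 if lab == POSITIVE else offset
        num[i] = feature_rng.normal(mean, 1.0, size=config.d_numeric)

    cat = np.empty((config.n, config.d_categorical), dtype=object)
    for j in range(config.d_categorical):
        for i, lab in enumerate(labels):
            p = _CAT_P_POS if lab == POSITIVE else _CAT_P_NEG
            cat[i, j] = feature_rng.choice(_CAT_LEVELS, p=p)

    specs = [
        FeatureSpec(
            f"x{j}", "numeric",
            observed_range=(float(num[:, j].min()), float(num[:, j].max())),
        )
        for j in range(config.d_numeric)
    ] + [
        FeatureSpec(f"c{j}", "categorical", categories=_CAT_LEVELS)
        for j in range(config.d_categorical)
    ]
    instances = []
    for i, lab in enumerate(labels):
        values = tuple(float(v) for v in num[i]) + tuple(cat[i])
        instances.append(
            Instance(id=i + 1, values=values, observed_label=lab, true_label=lab)
        )
    dataset = PUDataset(specs=specs, instances=instances)
    if config.mask_ratio > 0:
        dataset = mask_labels(dataset, MaskingConfig(ratio=config.mask_ratio, seed=mask_seed))
    return dataset


def generate_grid_toy(scale: int = 1) -> PUDataset:
    """Deterministic separable grid dataset of size 20*scale.

    Positives sit in a low-weight column (weight 1), negatives in a
    high-weight column (weight 8), both spread along the count axis.  One
    instance per column block of ten is masked, spaced so that its three
    nearest neighbors are labeled members of its own class — unanimous-vote
    relabeling therefore recovers every masked label exactly.
    """
    if scale < 1:
        raise ParameterError("scale must be >= 1")
    n_per_class = 10 * scale
    rows = []  # (weight, count, true_label, masked?)
    for i in range(n_per_class):
        rows.append((1.0, float(i), POSITIVE, i % 10 == 4))
    for i in range(n_per_class):
        rows.append((8.0, float(i), NEGATIVE, i % 10 == 4))
    weights = [r[0] for r in rows]
    counts = [r[1] for r in rows]
    specs = [
        FeatureSpec("weight", "numeric", observed_range=(min(weights), max(weights))),
        FeatureSpec("count", "numeric", observed_range=(min(counts), max(counts))),
    ]
    instances = [
        Instance(
            id=i + 1,
            values=(w, c),
            observed_label=UNLABELED if masked else lab,
            true_label=lab,
        )
        for i, (w, c, lab, masked) in enumerate(rows)
    ]
    return PUDataset(specs=specs, instances=instances)
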