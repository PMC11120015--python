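"""Stage 1: unanimous-vote k-nearest-neighbor relabeling of unlabeled data.

An unlabeled instance x is a *strong positive instance* when every one of
its k nearest neighbors N_k(x) in the dataset D carries the positive label
— unanimity, not majority.  Strong positives form P_UL and are relabeled
positive; everything else in U is relabeled negative (N_UL), so that
U = P_UL + N_UL and the output dataset is fully labeled.

Distances are Euclidean over mixed features: numeric differences are
min-max scaled by default, categorical features contribute 0/1 overlap, and
any comparison involving a missing value contributes 1.  The search is
exhaustive (the datasets this method targets are small); ties are broken by
ascending instance id so results are reproducible.  Relabeling is a single
pass over U using only the original labels of D — assignments never cascade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset_core import (
    MISSING,
    NEGATIVE,
    POSITIVE,
    UNLABELED,
    FeatureSpec,
    Instance,
    ParameterError,
    PUDataset,
    SchemaError,
)


@dataclass(frozen=True)
class NeighborConfig:
    """Neighborhood search parameters.

    k defaults to 3, the setting used throughout the method's evaluation.
    ``neighbor_pool`` selects whether neighbors are drawn from all of D or
    only from the labeled positives; ``distance_normalization`` toggles
    min-max scaling of numeric differences.
    """

    k: int = 3
    neighbor_pool: str = "all_of_D"  # or "labeled_positives_only"
    distance_normalization: str = "minmax"  # or "none"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")
        if self.neighbor_pool not in ("all_of_D", "labeled_positives_only"):
            raise ParameterError(f"unknown neighbor pool {self.neighbor_pool!r}")
        if self.distance_normalization not in ("minmax", "none"):
            raise ParameterError(f"unknown normalization {self.distance_normalization!r}")


@dataclass(frozen=True)
class NeighborQueryResult:
    """The k nearest neighbors of one query, ascending by (distance, id)."""

    query_id: int
    neighbors: tuple[tuple[int, float], ...]

    @property
    def neighbor_ids(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.neighbors)


@dataclass
class RelabelingReport:
    """Audit trail of one relabeling pass: U = P_UL + N_UL."""

    pul_ids: set[int] = field(default_factory=set)
    nul_ids: set[int] = field(default_factory=set)
    queries: dict[int, NeighborQueryResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pul_ids": sorted(self.pul_ids),
            "nul_ids": sorted(self.nul_ids),
            "queries": {
                str(qid): [[i, d] for i, d in q.neighbors] for qid, q in self.queries.items()
            },
        }


def pairwise_distance(
    a: Instance,
    b: Instance,
    specs: list[FeatureSpec],
    normalization: str = "minmax",
) -> float:
    """Euclidean distance between two instances over mixed feature types.

    Numeric features contribute ``((a-b)/range)**2`` under min-max scaling
    (raw squared difference under ``normalization="none"``; zero when the
    observed range is zero).  Categorical features contribute 0 if equal,
    else 1.  Any comparison involving a missing value contributes 1.
    """
    if len(a.values) != len(specs) or len(b.values) != len(specs):
        raise SchemaError("instance does not conform to the feature specs")
    total = 0.0
    for spec, va, vb in zip(specs, a.values, b.values):
        if va is MISSING or vb is MISSING:
            total += 1.0
        elif spec.kind == "numeric":
            diff = float(va) - float(vb)
            if normalization == "minmax":
                lo, hi = spec.observed_range if spec.observed_range else (0.0, 0.0)
                rng = hi - lo
                diff = diff / rng if rng > 0 else 0.0
            total += diff * diff
        else:
            total += 0.0 if va == vb else 1.0
    return math.sqrt(total)


def _encode(dataset: PUDataset, normalization: str):
    """Column-encode the dataset for vectorized distance computation."""
    n = len(dataset)
    num_idx = [j for j, s in enumerate(dataset.specs) if s.kind == "numeric"]
    cat_idx = [j for j, s in enumerate(dataset.specs) if s.kind == "categorical"]
    num = np.full((n, len(num_idx)), np.nan)
    cat = np.full((n, len(cat_idx)), -1, dtype=int)
    cat_codes = [
        {c: i for i, c in enumerate(dataset.specs[j].categories)} for j in cat_idx
    ]
    for i, inst in enumerate(dataset.instances):
        for jj, j in enumerate(num_idx):
            v = inst.values[j]
            if v is not MISSING:
                num[i, jj] = float(v)
        for jj, j in enumerate(cat_idx):
            v = inst.values[j]
            if v is not MISSING:
                cat[i, jj] = cat_codes[jj].get(v, len(cat_codes[jj]))
    scale = np.ones(len(num_idx))
    if normalization == "minmax" and num_idx:
        for jj, j in enumerate(num_idx):
            r = dataset.specs[j].observed_range
            if r is not None and r[1] > r[0]:
                scale[jj] = r[1] - r[0]
            else:
                col = num[:, jj]
                fin = col[~np.isnan(col)]
                span = fin.max() - fin.min() if fin.size else 0.0
                scale[jj] = span if span > 0 else 1.0
    return num, cat, scale


def _sq_dist_to_all(num, cat, scale, qi: int) -> np.ndarray:
    """Squared distances from row qi to every row (missing comparisons -> 1).

    Differences are divided by the scale AFTER subtraction, exactly as in
    :func:`pairwise_distance`, so equal raw differences stay exactly tied
    under min-max normalization.
    """
    n = num.shape[0]
    total = np.zeros(n)
    if num.shape[1]:
        diff = (num - num[qi]) / scale
        sq = diff * diff
        miss = np.isnan(sq)
        sq[miss] = 1.0
        total += sq.sum(axis=1)
    if cat.shape[1]:
        q = cat[qi]
        neq = (cat != q).astype(float)
        miss = (cat < 0) | (q < 0)
        neq[miss] = 1.0
        total += neq.sum(axis=1)
    return total


def k_nearest(
    dataset: PUDataset,
    query: Instance,
    config: NeighborConfig = NeighborConfig(),
) -> NeighborQueryResult:
    """Exhaustive k-nearest-neighbor search, excluding the query itself.

    Returns the k pool members with smallest distance; ties are broken by
    ascending instance id.  The pool is all of D or only labeled positives,
    per the configuration.
    """
    ids = dataset.ids()
    pos_in_pool = {i: idx for idx, i in enumerate(ids)}
    if query.id in pos_in_pool:
        qi = pos_in_pool[query.id]
        work = dataset
    else:
        work = replace(dataset, instances=dataset.instances + [query])
        ids = work.ids()
        qi = len(ids) - 1
    num, cat, scale = _encode(work, config.distance_normalization)
    sq = _sq_dist_to_all(num, cat, scale, qi)

    candidates = []
    for idx, inst in enumerate(work.instances):
        if inst.id == query.id:
            continue
        if config.neighbor_pool == "labeled_positives_only" and inst.observed_label != POSITIVE:
            continue
        candidates.append((math.sqrt(sq[idx]), inst.id))
    if len(candidates) < config.k:
        raise ParameterError(
            f"neighbor pool has {len(candidates)} members, fewer than k={config.k}"
        )
    candidates.sort()
    return NeighborQueryResult(
        query_id=query.id,
        neighbors=tuple((i, d) for d, i in candidates[: config.k]),
    )


def is_strong_positive(result: NeighborQueryResult, dataset: PUDataset) -> bool:
    """True iff every neighbor's observed label is positive (unanimity).

    Unlabeled and negative neighbors both break unanimity.
    """
    return all(dataset.by_id(i).observed_label == POSITIVE for i in result.neighbor_ids)


def relabel_unlabeled(
    dataset: PUDataset,
    config: NeighborConfig = NeighborConfig(),
) -> tuple[PUDataset, RelabelingReport]:
    """Assign a label to every unlabeled instance of D in a single pass.

    Strong positives join P_UL (relabeled positive); all other unlabeled
    instances join N_UL (relabeled negative).  Decisions use only the
    ORIGINAL observed labels of D — new assignments never feed back into
    the neighbor search.  Labeled instances are returned unchanged; true
    labels are preserved everywhere.
    """
    report = RelabelingReport()
    unlabeled = [i for i in dataset.instances if i.observed_label == UNLABELED]
    if not unlabeled:
        return dataset.copy(), report
    if dataset.n_p < 1:
        raise ParameterError("relabeling requires at least one labeled positive")
    if config.neighbor_pool == "labeled_positives_only":
        if dataset.n_p < config.k:
            raise ParameterError(
                f"positive pool has {dataset.n_p} members, fewer than k={config.k}"
            )
    elif len(dataset) < config.k + 1:
        raise ParameterError(f"dataset has {len(dataset)} instances, need >= k+1")

    num, cat, scale = _encode(dataset, config.distance_normalization)
    ids = dataset.ids()
    labels = [i.observed_label for i in dataset.instances]
    pool_mask = np.ones(len(dataset), dtype=bool)
    if config.neighbor_pool == "labeled_positives_only":
        pool_mask = np.array([lab == POSITIVE for lab in labels])

    id_pos = {i: idx for idx, i in enumerate(ids)}
    decided: dict[int, str] = {}
    for inst in sorted(unlabeled, key=lambda i: i.id):
        qi = id_pos[inst.id]
        sq = _sq_dist_to_all(num, cat, scale, qi)
        cands = sorted(
            (math.sqrt(sq[idx]), ids[idx])
            for idx in range(len(ids))
            if ids[idx] != inst.id and pool_mask[idx]
        )
        result = NeighborQueryResult(
            query_id=inst.id, neighbors=tuple((i, d) for d, i in cands[: config.k])
        )
        report.queries[inst.id] = result
        if all(labels[id_pos[i]] == POSITIVE for i in result.neighbor_ids):
            decided[inst.id] = POSITIVE
            report.pul_ids.add(inst.id)
        else:
            decided[inst.id] = NEGATIVE
            report.nul_ids.add(inst.id)

    out = [
        replace(i, observed_label=decided[i.id]) if i.id in decided else i
        for i in dataset.instances
    ]
    return replace(dataset, instances=out), report
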