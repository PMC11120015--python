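"""Stage 2: entropy-based decision tree (C4.5 lineage).

The tree is built on the fully labeled output of the relabeling stage,
P_L + P_UL + N_UL.  Node splits are chosen by information gain or by the
normalized gain ratio (the default, consistent with C4.5): numeric features
propose binary thresholds at midpoints between consecutive distinct sorted
values, categorical features propose one multiway split over their observed
categories (at most once per path).  Entropy is Shannon entropy in bits,
-sum R_i log2 R_i; information gain is the drop from the parent's entropy
to the size-weighted mean entropy of the children and is always
non-negative on empirical counts.

There is no pruning; ``min_leaf`` (default 2) guards degenerate splits.
Leaves predict their majority class, with ties resolved toward the parent's
majority and finally toward the positive class, so tree construction is
deterministic and independent of instance storage order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .dataset_core import (
    MISSING,
    NEGATIVE,
    POSITIVE,
    UNLABELED,
    FeatureSpec,
    FormatError,
    Instance,
    ParameterError,
    PUDataset,
)

GAIN_TOL = 1e-12


@dataclass(frozen=True)
class ClassCounts:
    """Per-class instance counts at a node, with proportions R_i."""

    counts: tuple[tuple[str, int], ...]  # ordered (class, count) pairs

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "ClassCounts":
        tally: dict[str, int] = {}
        for lab in labels:
            tally[lab] = tally.get(lab, 0) + 1
        return cls(counts=tuple(sorted(tally.items())))

    @property
    def total(self) -> int:
        return sum(c for _, c in self.counts)

    @property
    def proportions(self) -> dict[str, float]:
        t = self.total
        return {k: c / t for k, c in self.counts if t > 0}

    def count(self, label: str) -> int:
        return dict(self.counts).get(label, 0)

    def majority(self, prefer: Sequence[str] = (POSITIVE,)) -> str:
        """Class with the largest count; ties resolved by ``prefer`` order,
        then lexicographically."""
        best = max(c for _, c in self.counts)
        tied = sorted(k for k, c in self.counts if c == best)
        for p in prefer:
            if p in tied:
                return p
        return tied[0]


def entropy(counts: ClassCounts) -> float:
    """Shannon entropy in bits: -sum R_i log2 R_i, with 0 log 0 = 0."""
    t = counts.total
    if t == 0:
        raise ParameterError("entropy of an empty node is undefined")
    h = 0.0
    for _, c in counts.counts:
        if c > 0:
            r = c / t
            h -= r * math.log2(r)
    return h


def expected_entropy(parent: ClassCounts, partition: Sequence[ClassCounts]) -> float:
    """Size-weighted mean entropy of the children D_1..D_v."""
    t = parent.total
    if t == 0:
        raise ParameterError("cannot split an empty node")
    if sum(p.total for p in partition) != t:
        raise ParameterError("partition does not cover the parent exactly")
    return sum((p.total / t) * entropy(p) for p in partition if p.total > 0)


def information_gain(parent: ClassCounts, partition: Sequence[ClassCounts]) -> float:
    """Entropy drop from parent to partition; non-negative."""
    return entropy(parent) - expected_entropy(parent, partition)


def split_information(parent: ClassCounts, partition: Sequence[ClassCounts]) -> float:
    """Entropy of the partition sizes themselves (the gain-ratio denominator)."""
    t = parent.total
    si = 0.0
    for p in partition:
        if p.total > 0:
            w = p.total / t
            si -= w * math.log2(w)
    return si


def gain_ratio(parent: ClassCounts, partition: Sequence[ClassCounts]) -> float | None:
    """Information gain normalized by split information (C4.5).

    Returns None (a skip signal, not an error) when the split information is
    zero, i.e. for single-branch partitions.
    """
    si = split_information(parent, partition)
    if si <= 0.0:
        return None
    return information_gain(parent, partition) / si


@dataclass(frozen=True)
class SplitCandidate:
    """One evaluated split: feature F_i, its branches, and its scores."""

    feature_index: int
    kind: str  # "numeric_threshold" | "categorical_multiway"
    threshold: float | None
    branch_values: tuple | None  # category per branch (categorical only)
    child_counts: tuple[ClassCounts, ...]
    child_ids: tuple[tuple[int, ...], ...]
    gain: float
    gain_ratio: float | None


def _route_numeric(instances, j, threshold):
    """<=threshold / >threshold branches; missing goes to the larger child."""
    left, right, miss = [], [], []
    for inst in instances:
        v = inst.values[j]
        if v is MISSING:
            miss.append(inst)
        elif float(v) <= threshold:
            left.append(inst)
        else:
            right.append(inst)
    target = left if len(left) >= len(right) else right
    target.extend(miss)
    return [left, right]


def _route_categorical(instances, j, categories):
    branches = {c: [] for c in categories}
    miss = []
    for inst in instances:
        v = inst.values[j]
        if v is MISSING or v not in branches:
            miss.append(inst)
        else:
            branches[v].append(inst)
    if miss:
        largest = max(categories, key=lambda c: (len(branches[c]), c))
        branches[largest].extend(miss)
    return [branches[c] for c in categories]


def _candidate(instances, j, kind, threshold, branch_values, children) -> SplitCandidate | None:
    nonempty = [c for c in children if c]
    if len(nonempty) < 2:
        return None
    parent = ClassCounts.from_labels(i.observed_label for i in instances)
    counts = tuple(ClassCounts.from_labels(i.observed_label for i in c) for c in children)
    g = information_gain(parent, counts)
    return SplitCandidate(
        feature_index=j,
        kind=kind,
        threshold=threshold,
        branch_values=branch_values,
        child_counts=counts,
        child_ids=tuple(tuple(i.id for i in c) for c in children),
        gain=g,
        gain_ratio=gain_ratio(parent, counts),
    )


def best_split(
    instances: Sequence[Instance],
    specs: Sequence[FeatureSpec],
    criterion: str = "gain_ratio",
    used_categorical: frozenset[int] = frozenset(),
) -> SplitCandidate | None:
    """Evaluate every candidate split and return the best, or None.

    Numeric features propose thresholds at midpoints between consecutive
    distinct sorted values; categorical features (not yet used on this path)
    propose one multiway split.  Candidates with gain <= 0 are discarded;
    under the gain-ratio criterion, candidates with zero split information
    are skipped.  Ties break toward the smaller feature index, then the
    smaller threshold.
    """
    if criterion not in ("gain", "gain_ratio"):
        raise ParameterError(f"unknown criterion {criterion!r}")
    if len(instances) < 2:
        return None
    best: SplitCandidate | None = None
    best_key: tuple | None = None
    for j, spec in enumerate(specs):
        candidates: list[SplitCandidate] = []
        if spec.kind == "numeric":
            vals = sorted({float(i.values[j]) for i in instances if i.values[j] is not MISSING})
            for lo, hi in zip(vals, vals[1:]):
                t = (lo + hi) / 2.0
                cand = _candidate(
                    instances, j, "numeric_threshold", t, None,
                    _route_numeric(instances, j, t),
                )
                if cand:
                    candidates.append(cand)
        else:
            if j in used_categorical:
                continue
            cats = tuple(
                sorted({i.values[j] for i in instances if i.values[j] is not MISSING})
            )
            if len(cats) >= 2:
                cand = _candidate(
                    instances, j, "categorical_multiway", None, cats,
                    _route_categorical(instances, j, cats),
                )
                if cand:
                    candidates.append(cand)
        for cand in candidates:
            if cand.gain <= GAIN_TOL:
                continue
            if criterion == "gain_ratio":
                if cand.gain_ratio is None:
                    continue
                score = cand.gain_ratio
            else:
                score = cand.gain
            thr = cand.threshold if cand.threshold is not None else 0.0
            # maximize score; ties -> smaller feature index, smaller threshold
            key = (-score, cand.feature_index, thr)
            if best_key is None or key < best_key:
                best, best_key = cand, key
    return best


# ---------------------------------------------------------------------------
# Tree model


@dataclass
class TreeNode:
    counts: ClassCounts
    prediction: str
    # internal nodes only:
    feature_index: int | None = None
    kind: str | None = None
    threshold: float | None = None
    branch_values: tuple | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def node_count(self) -> int:
        return 1 + sum(c.node_count() for c in self.children)

    def depth(self) -> int:
        return 0 if self.is_leaf else 1 + max(c.depth() for c in self.children)


@dataclass
class DecisionTreeModel:
    """A trained tree: root node, feature schema and training metadata."""

    root: TreeNode
    specs: list[FeatureSpec]
    criterion: str
    min_leaf: int
    max_depth: int | None
    n_training: int

    def node_count(self) -> int:
        return self.root.node_count()

    def depth(self) -> int:
        return self.root.depth()


def _grow(instances, specs, criterion, min_leaf, max_depth, depth, parent_majority, used_cat):
    counts = ClassCounts.from_labels(i.observed_label for i in instances)
    prediction = counts.majority(prefer=(parent_majority, POSITIVE))
    node = TreeNode(counts=counts, prediction=prediction)
    pure = len(counts.counts) == 1
    if pure or counts.total < 2 * min_leaf or (max_depth is not None and depth >= max_depth):
        return node
    cand = best_split(instances, specs, criterion=criterion, used_categorical=used_cat)
    if cand is None:
        return node
    groups = [
        [i for i in instances if i.id in set(ids)] for ids in cand.child_ids
    ]
    node.feature_index = cand.feature_index
    node.kind = cand.kind
    node.threshold = cand.threshold
    node.branch_values = cand.branch_values
    next_used = used_cat | {cand.feature_index} if cand.kind == "categorical_multiway" else used_cat
    node.children = [
        _grow(g, specs, criterion, min_leaf, max_depth, depth + 1, prediction, next_used)
        for g in groups
    ]
    return node


def build_tree(
    train: PUDataset,
    criterion: str = "gain_ratio",
    min_leaf: int = 2,
    max_depth: int | None = None,
) -> DecisionTreeModel:
    """Build the classifier M on a fully labeled dataset.

    Recursion stops when a node is pure, smaller than ``2*min_leaf``, hits
    ``max_depth``, or no candidate split has positive gain.
    """
    if not train.instances:
        raise ParameterError("cannot build a tree on an empty dataset")
    if train.n_u > 0:
        raise ParameterError("training set still contains unlabeled instances")
    root = _grow(
        train.instances, train.specs, criterion, min_leaf, max_depth,
        depth=0, parent_majority=POSITIVE, used_cat=frozenset(),
    )
    return DecisionTreeModel(
        root=root,
        specs=list(train.specs),
        criterion=criterion,
        min_leaf=min_leaf,
        max_depth=max_depth,
        n_training=len(train),
    )


def predict(model: DecisionTreeModel, instance: Instance) -> str:
    """Route an instance to a leaf and return the leaf's class.

    A missing value at a split — or an unseen category — follows the child
    with the largest training count.  Total and deterministic.
    """
    node = model.root
    while not node.is_leaf:
        j = node.feature_index
        v = instance.values[j]
        child = None
        if node.kind == "numeric_threshold":
            if v is not MISSING:
                child = node.children[0] if float(v) <= node.threshold else node.children[1]
        else:
            if v is not MISSING and v in node.branch_values:
                child = node.children[node.branch_values.index(v)]
        if child is None:
            child = max(node.children, key=lambda c: c.counts.total)
        node = child
    return node.prediction


def predict_dataset(model: DecisionTreeModel, dataset: PUDataset) -> dict[int, str]:
    """Predicted class for every instance, keyed by id (output C)."""
    return {inst.id: predict(model, inst) for inst in dataset.instances}


# ---------------------------------------------------------------------------
# Serialization


def _node_to_dict(node: TreeNode) -> dict:
    d: dict = {
        "counts": list(node.counts.counts),
        "prediction": node.prediction,
    }
    if not node.is_leaf:
        d.update(
            feature_index=node.feature_index,
            kind=node.kind,
            threshold=node.threshold,
            branch_values=list(node.branch_values) if node.branch_values else None,
            children=[_node_to_dict(c) for c in node.children],
        )
    return d


def _node_from_dict(d: dict) -> TreeNode:
    try:
        node = TreeNode(
            counts=ClassCounts(counts=tuple((k, int(c)) for k, c in d["counts"])),
            prediction=d["prediction"],
        )
        if "children" in d:
            node.feature_index = int(d["feature_index"])
            node.kind = d["kind"]
            node.threshold = None if d["threshold"] is None else float(d["threshold"])
            node.branch_values = tuple(d["branch_values"]) if d["branch_values"] else None
            node.children = [_node_from_dict(c) for c in d["children"]]
        return node
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed tree node: {exc}") from exc


def serialize(model: DecisionTreeModel) -> str:
    """JSON document for a trained model (round-trips exactly)."""
    doc = {
        "format": "npulud-tree",
        "version": 1,
        "criterion": model.criterion,
        "min_leaf": model.min_leaf,
        "max_depth": model.max_depth,
        "n_training": model.n_training,
        "specs": [
            {
                "name": s.name,
                "kind": s.kind,
                "categories": list(s.categories),
                "observed_range": list(s.observed_range) if s.observed_range else None,
            }
            for s in model.specs
        ],
        "root": _node_to_dict(model.root),
    }
    return json.dumps(doc, indent=1)


def deserialize(document: str) -> DecisionTreeModel:
    """Parse a model written by :func:`serialize`."""
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "npulud-tree":
        raise FormatError("not an npulud tree document")
    try:
        specs = [
            FeatureSpec(
                name=s["name"],
                kind=s["kind"],
                categories=tuple(s["categories"]),
                observed_range=tuple(s["observed_range"]) if s["observed_range"] else None,
            )
            for s in doc["specs"]
        ]
        return DecisionTreeModel(
            root=_node_from_dict(doc["root"]),
            specs=specs,
            criterion=doc["criterion"],
            min_leaf=int(doc["min_leaf"]),
            max_depth=doc["max_depth"],
            n_training=int(doc["n_training"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed tree document: {exc}") from exc


def save_model(model: DecisionTreeModel, path: str | Path) -> None:
    Path(path).write_text(serialize(model))


def load_model(path: str | Path) -> DecisionTreeModel:
    return deserialize(Path(path).read_text())
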