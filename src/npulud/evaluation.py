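"""Evaluation harness: masking + stratified 10-fold CV, metrics, sweeps,
and the paired Wilcoxon signed-rank comparison.

The protocol mirrors how PU methods are benchmarked on fully labeled data:
a fraction of the labels is hidden once over the whole dataset (the masking
ratio, e.g. 5%), the dataset is split into ten stratified folds, and for
each fold the pipeline — unanimous-vote kNN relabeling on the training
portion, then an entropy decision tree — is trained and scored on the held
out fold against the retained TRUE labels.  Accuracy, precision, recall and
F-measure are the usual confusion-matrix ratios:

    ACC = (TP+TN)/(TP+TN+FP+FN)    PR = TP/(TP+FP)
    R   = TP/(TP+FN)               FM = 2TP/(2TP+FN+FP)

Two methods are compared across datasets with the two-sided Wilcoxon
signed-rank test: zero differences are discarded, tied absolute differences
take midranks, and the null distribution is exact (computed by dynamic
programming over the signed ranks) up to 25 effective pairs, with a
tie-corrected normal approximation above.

Published per-dataset benchmark results (24 public tabular datasets; a
five-dataset F-measure comparison against Ada* PU learners) ship as
packaged TSVs so the aggregate numbers can be recomputed without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .dataset_core import (
    NEGATIVE,
    POSITIVE,
    UNKNOWN,
    InputError,
    MaskingConfig,
    ParameterError,
    PUDataset,
    mask_labels,
)
from .decision_tree import build_tree, predict
from .pu_relabeling import NeighborConfig, relabel_unlabeled

DEFAULT_RATIOS = (0.05, 0.10, 0.15, 0.20)


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """ACC/PR/R/FM with degenerate-denominator flags."""

    ACC: float
    PR: float
    R: float
    FM: float
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.ACC, "PR": self.PR, "R": self.R, "FM": self.FM}


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with 'positive' as the positive class."""
    if len(true_labels) != len(predicted_labels):
        raise InputError("label sequences differ in length")
    tp = tn = fp = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == POSITIVE and p == POSITIVE:
            tp += 1
        elif t == NEGATIVE and p == NEGATIVE:
            tn += 1
        elif t == NEGATIVE and p == POSITIVE:
            fp += 1
        elif t == POSITIVE and p == NEGATIVE:
            fn += 1
        else:
            raise InputError(f"non-binary label pair ({t!r}, {p!r})")
    return ConfusionMatrix(TP=tp, TN=tn, FP=fp, FN=fn)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The four ratio metrics; empty denominators yield 0 and are flagged."""
    if cm.total == 0:
        raise ParameterError("empty confusion matrix")
    degenerate = []
    acc = (cm.TP + cm.TN) / cm.total
    pr = r = fm = 0.0
    if cm.TP + cm.FP > 0:
        pr = cm.TP / (cm.TP + cm.FP)
    else:
        degenerate.append("PR")
    if cm.TP + cm.FN > 0:
        r = cm.TP / (cm.TP + cm.FN)
    else:
        degenerate.append("R")
    if 2 * cm.TP + cm.FN + cm.FP > 0:
        fm = 2 * cm.TP / (2 * cm.TP + cm.FN + cm.FP)
    else:
        degenerate.append("FM")
    return MetricsReport(ACC=acc, PR=pr, R=r, FM=fm, degenerate=tuple(degenerate))


# ---------------------------------------------------------------------------
# Cross-validation


def stratified_kfold(
    dataset: PUDataset,
    folds: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> list[tuple[list[int], list[int]]]:
    """Seeded k-fold split on true labels; returns (train_ids, test_ids) pairs.

    Stratification deals each class's shuffled members across folds in a
    continuing cyclic order, so fold sizes differ by at most one and
    per-fold class proportions are within one instance of the global ones
    (best-effort when a class has fewer members than folds).
    """
    n = len(dataset)
    if folds < 2:
        raise ParameterError("need at least 2 folds")
    if folds > n:
        raise ParameterError(f"{folds} folds but only {n} instances")
    rng = np.random.default_rng(seed)
    assignment: dict[int, int] = {}
    if stratified:
        groups: dict[str, list[int]] = {}
        for inst in dataset.instances:
            groups.setdefault(inst.true_label, []).append(inst.id)
        cursor = 0
        for label in sorted(groups):
            ids = np.array(sorted(groups[label]))
            rng.shuffle(ids)
            for id_ in ids:
                assignment[int(id_)] = cursor % folds
                cursor += 1
    else:
        ids = np.array(sorted(dataset.ids()))
        rng.shuffle(ids)
        for pos, id_ in enumerate(ids):
            assignment[int(id_)] = pos % folds
    out = []
    all_ids = dataset.ids()
    for f in range(folds):
        test = [i for i in all_ids if assignment[i] == f]
        train = [i for i in all_ids if assignment[i] != f]
        out.append((train, test))
    return out


@dataclass
class CVResult:
    """Per-fold metrics of one cross-validated run plus their means."""

    fold_metrics: list[MetricsReport]
    mask_ratio: float
    k: int
    folds: int
    seed: int

    @property
    def mean(self) -> MetricsReport:
        return MetricsReport(
            ACC=float(np.mean([m.ACC for m in self.fold_metrics])),
            PR=float(np.mean([m.PR for m in self.fold_metrics])),
            R=float(np.mean([m.R for m in self.fold_metrics])),
            FM=float(np.mean([m.FM for m in self.fold_metrics])),
        )


def run_npulud_cv(
    dataset: PUDataset,
    mask_ratio: float = 0.05,
    k: int = 3,
    tree_params: dict | None = None,
    folds: int = 10,
    seed: int = 0,
    neighbor_pool: str = "all_of_D",
    normalization: str = "minmax",
    stratified: bool = True,
) -> CVResult:
    """Cross-validate the full pipeline on a fully labeled dataset.

    Labels are masked once over the whole dataset (seeded).  Per fold, the
    training portion is relabeled from its observed labels, a tree is built
    on the result, and the held-out fold is scored against TRUE labels.
    """
    if any(i.true_label == UNKNOWN for i in dataset.instances):
        raise ParameterError("cross-validation needs true labels on every instance")
    masked = mask_labels(dataset.unmask(), MaskingConfig(ratio=mask_ratio, seed=seed))
    tree_params = dict(tree_params or {})
    ncfg = NeighborConfig(k=k, neighbor_pool=neighbor_pool, distance_normalization=normalization)
    splits = stratified_kfold(dataset, folds=folds, seed=seed, stratified=stratified)
    fold_metrics = []
    for train_ids, test_ids in splits:
        train = masked.subset(train_ids)
        if train.n_u > 0:
            train, _ = relabel_unlabeled(train, ncfg)
        model = build_tree(train, **tree_params)
        test = dataset.subset(test_ids)
        truth = [i.true_label for i in test.instances]
        preds = [predict(model, i) for i in test.instances]
        fold_metrics.append(metrics(confusion(truth, preds)))
    return CVResult(fold_metrics=fold_metrics, mask_ratio=mask_ratio, k=k, folds=folds, seed=seed)


def ratio_sweep(
    dataset: PUDataset,
    ratios=DEFAULT_RATIOS,
    k: int = 3,
    seed: int = 0,
    folds: int = 10,
    tree_params: dict | None = None,
) -> dict[float, float]:
    """Mean CV accuracy per masking ratio (shared fold seed across ratios)."""
    return {
        float(r): run_npulud_cv(
            dataset, mask_ratio=r, k=k, folds=folds, seed=seed, tree_params=tree_params
        ).mean.ACC
        for r in ratios
    }


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank test


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    w_minus: float
    statistic: float  # min(W+, W-)
    p_value: float | None
    n_effective: int
    method: str  # "exact" | "normal" | "degenerate"


def _exact_sf_le(doubled_ranks: list[int], w2: int) -> float:
    """P(W+ <= w2/2) under the exact signed-rank null, via DP on 2*ranks."""
    total = sum(doubled_ranks)
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    return float(dist[: w2 + 1].sum())


def wilcoxon_signed_rank(a, b, exact_limit: int = 25) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test of b against a.

    Differences b-a; zeros discarded; midranks for tied magnitudes; exact
    two-sided p (DP over the observed ranks) for n_effective <= exact_limit,
    tie-corrected normal approximation above.  All-zero differences give a
    degenerate result with no p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired samples must be 1-d and equal length")
    if len(a) < 6:
        raise ParameterError("need at least 6 pairs")
    d = b - a
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 0.0, 0.0, None, 0, "degenerate")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_limit:
        doubled = [int(round(2 * r)) for r in ranks]
        p = min(1.0, 2.0 * _exact_sf_le(doubled, int(round(2 * w))))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float((tie_counts**3 - tie_counts).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.cdf(z)))
        method = "normal"
    return WilcoxonResult(w_plus, w_minus, w, p, n, method)


# ---------------------------------------------------------------------------
# Packaged benchmark tables and aggregation


def _load_tsv(name: str) -> pd.DataFrame:
    with resources.files("npulud.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_benchmark_accuracies() -> pd.DataFrame:
    """Published 10-fold CV accuracies (%) of the supervised tree (DT) and
    the PU pipeline on 24 public tabular datasets, at 5% masking."""
    return _load_tsv("benchmark_accuracy.tsv")


def load_ratio_benchmark() -> pd.DataFrame:
    """Published PU-pipeline accuracies (%) per masking ratio (5-20%)."""
    return _load_tsv("ratio_sweep_accuracy.tsv")


def load_fmeasure_benchmark() -> pd.DataFrame:
    """Published F-measure (%) comparison against four Ada* PU learners on
    five shared datasets."""
    return _load_tsv("fmeasure_comparison.tsv")


def round_half_up(x: float, decimals: int = 2) -> float:
    factor = 10**decimals
    return np.floor(x * factor + 0.5) / factor


def column_means(df: pd.DataFrame, decimals: int = 2) -> dict[str, float]:
    """Arithmetic column means of the numeric columns, rounded half-up to
    the stated precision only at presentation."""
    out = {}
    for col in df.columns:
        if pd.api.types.is_numeric_dtype(df[col]):
            out[col] = float(round_half_up(float(df[col].mean()), decimals))
    return out


@dataclass
class BenchmarkResult:
    """Aggregate view of a multi-dataset comparison."""

    per_dataset: pd.DataFrame
    column_means: dict[str, float]
    wilcoxon: WilcoxonResult | None = None


def summarize_benchmark() -> BenchmarkResult:
    """Column means of the packaged accuracy table plus the paired Wilcoxon
    comparison of the two methods across the 24 datasets."""
    df = load_benchmark_accuracies()
    wil = wilcoxon_signed_rank(df["dt_accuracy"].values, df["npulud_accuracy"].values)
    return BenchmarkResult(per_dataset=df, column_means=column_means(df), wilcoxon=wil)


def fmeasure_improvement() -> float:
    """Mean F-measure advantage (percentage points) of the PU pipeline over
    the average of the four competitor column means."""
    df = load_fmeasure_benchmark()
    means = column_means(df)
    competitors = [v for k, v in means.items() if k != "npulud"]
    return float(round_half_up(means["npulud"] - float(np.mean(competitors)), 2))
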