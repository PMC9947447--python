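"""Outer Monte Carlo cross-validation, metrics and cross-fold aggregation.

The outer protocol is tenfold Monte Carlo cross-validation (MCCV): in each
iteration the majority class is randomly under-sampled to the minority-class
size, the balanced dataset is split 80/20 (stratified), the grouping and
scoring stages run on the training 80% only, and for each ``j`` in
``1..j_max`` a final model on the top-``j`` gene union is evaluated on the
held-out 20%. Per-``j`` metrics and gene counts are averaged over folds, and
group scores are aggregated into a single ranked pathway list.

Sensitivity, specificity and AUC are undefined when a test split lacks one
class; such folds contribute ``None`` and are excluded from the means (their
count is logged). Stratified splitting makes this rare.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .io import ExpressionDataset, GeneSetCollection

logger = logging.getLogger("gsmpath")


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def confusion_metrics(
    counts: ConfusionCounts,
) -> tuple[float | None, float | None, float | None]:
    """(sensitivity, specificity, accuracy) from confusion counts.

    SE = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total. A ratio with a
    zero denominator is undefined and returned as ``None`` (callers exclude
    such folds from averages rather than propagating NaN).
    """
    se = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    sp = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    acc = (counts.tp + counts.tn) / counts.total if counts.total else None
    return se, sp, acc


def auc(scores: Sequence[float], labels: Sequence[int]) -> float | None:
    """Area under the ROC curve via the Mann–Whitney U statistic.

    The probability that a randomly chosen positive sample scores higher
    than a randomly chosen negative one, with ties counting one half.
    Computed from midranks: ``U = R_pos - n_pos(n_pos+1)/2`` and
    ``AUC = U / (n_pos * n_neg)``. Returns ``None`` when only one class is
    present.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # midranks for ties
    u = float(ranks[y == 1].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


@dataclass(frozen=True)
class FoldMetrics:
    """One evaluation's metrics; ``None`` marks an undefined ratio."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    auc: float | None
    counts: ConfusionCounts


# ---------------------------------------------------------------------------
# sampling protocol
# ---------------------------------------------------------------------------

def undersample_majority(data: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Random under-sampling of the majority class to the minority size.

    Every minority-class sample is kept; a uniform random subset of the
    majority class of equal size is kept. The returned dataset preserves the
    input sample order.
    """
    y = data.y
    n_pos, n_neg = data.class_counts()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("undersample_majority needs both classes present")
    if n_pos == n_neg:
        return data
    rng = np.random.default_rng(seed)
    maj = 1 if n_pos > n_neg else 0
    maj_idx = np.flatnonzero(y == maj)
    keep_maj = set(rng.choice(maj_idx, size=min(n_pos, n_neg), replace=False).tolist())
    keep = [i for i in range(data.n_samples) if y[i] != maj or i in keep_maj]
    return data.subset_samples(keep)


def mc_split(
    data: ExpressionDataset, train_frac: float, seed: int
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """One stratified Monte Carlo train/test split.

    Per class, ``round(train_frac * n_class)`` samples go to training
    (clamped so both parts retain at least one sample of each class). Train
    and test partition the input; sample order is preserved in both parts.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    y = data.y
    n_pos, n_neg = data.class_counts()
    if min(n_pos, n_neg) < 2:
        raise ValueError("mc_split needs >= 2 samples per class")
    rng = np.random.default_rng(seed)
    train_idx: set[int] = set()
    for cls in (1, 0):
        idx = np.flatnonzero(y == cls)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.update(rng.choice(idx, size=n_train, replace=False).tolist())
    train = data.subset_samples([i for i in range(data.n_samples) if i in train_idx])
    test = data.subset_samples([i for i in range(data.n_samples) if i not in train_idx])
    return train, test


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of one run, echoed into the report."""

    k_folds: int = 10
    train_frac: float = 0.8
    inner_r: int = 5
    inner_train_frac: float = 0.8
    j_max: int = 10
    min_group_size: int = 3
    top_genes: int | None = None  # optional t-test pre-filter of the gene universe
    undersample: str = "each_fold"  # "each_fold" (balanced test) or "train_only"
    equal_var_ttest: bool = False
    seed: int = 0
    dataset_name: str = "dataset"

    def __post_init__(self) -> None:
        if self.k_folds < 1 or self.j_max < 1 or self.inner_r < 1:
            raise ValueError("k_folds, j_max and inner_r must all be >= 1")
        if self.undersample not in ("each_fold", "train_only"):
            raise ValueError(f"unknown undersample mode {self.undersample!r}")

    def as_dict(self) -> dict:
        return {
            "k_folds": self.k_folds, "train_frac": self.train_frac,
            "inner_r": self.inner_r, "inner_train_frac": self.inner_train_frac,
            "j_max": self.j_max, "min_group_size": self.min_group_size,
            "top_genes": self.top_genes, "undersample": self.undersample,
            "equal_var_ttest": self.equal_var_ttest, "seed": self.seed,
            "dataset_name": self.dataset_name,
        }


@dataclass(frozen=True)
class FoldResult:
    """Everything one MCCV iteration produced."""

    fold_index: int
    per_j: Mapping[int, tuple[FoldMetrics, list[str]]]  # j -> (metrics, gene union)
    ranked: list  # ranked GroupScore list of this fold
    train_counts: tuple[int, int]  # (positive, negative) in the training split
    test_counts: tuple[int, int]


@dataclass(frozen=True)
class RunReport:
    """Cross-fold averages plus the aggregated ranked pathway list."""

    dataset_name: str
    per_j_mean: Mapping[int, Mapping[str, float | None]]
    aggregated_ranking: list[dict]
    fold_results: tuple[FoldResult, ...]
    config: Mapping
    version: str = ""


def _mean_defined(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def run_gsm(
    data: ExpressionDataset,
    sets: GeneSetCollection,
    config: RunConfig,
    classifier=None,
) -> RunReport:
    """The full grouping–scoring–modeling pipeline under outer MCCV.

    For each of ``k_folds`` iterations: under-sample the majority class
    (fresh draw per fold), split 80/20 stratified, compute per-gene t
    statistics on the training part, restrict the gene sets to the (possibly
    t-test-filtered) training gene universe, score every set by inner CV on
    the training part, rank them, and for each ``j`` evaluate the top-``j``
    model on the held-out test part. The held-out samples take no part in
    grouping or scoring.
    """
    from . import gsm as _gsm  # deferred: gsm imports this module's metrics
    from . import preprocess as _pp

    clf = classifier if classifier is not None else _gsm.ClassifierSpec()
    master = config.seed
    folds: list[FoldResult] = []

    for fold in range(1, config.k_folds + 1):
        if config.undersample == "each_fold":
            balanced = undersample_majority(data, _gsm.derive_seed(master, fold, 1))
            train, test = mc_split(balanced, config.train_frac,
                                   _gsm.derive_seed(master, fold, 2))
        else:
            train, test = mc_split(data, config.train_frac,
                                   _gsm.derive_seed(master, fold, 2))
            train = undersample_majority(train, _gsm.derive_seed(master, fold, 1))

        stats = _pp.compute_t_statistics(train, equal_var=config.equal_var_ttest)
        if config.top_genes is not None:
            universe = _pp.select_top_genes(stats, config.top_genes)
            # keep dataset column order for deterministic unions
            keep = set(universe)
            universe = [g for g in train.gene_ids if g in keep]
        else:
            universe = list(train.gene_ids)

        restricted = _gsm.restrict_groups(sets, universe, config.min_group_size)
        scores = []
        for gi, grp in enumerate(restricted):
            sub = _gsm.build_subdataset(train, grp)
            scores.append(_gsm.score_group(
                sub, clf, r=config.inner_r,
                inner_train_frac=config.inner_train_frac,
                seed=_gsm.derive_seed(master, fold, 3, gi),
                set_id=grp.set_id, name=grp.name,
            ))
        ranked = _gsm.rank_groups(scores)

        per_j: dict[int, tuple[FoldMetrics, list[str]]] = {}
        for j in range(1, min(config.j_max, len(ranked)) + 1):
            genes = _gsm.combine_top_groups(ranked, restricted, j)
            metrics, _ = _gsm.train_and_evaluate(
                train, test, genes, clf, seed=_gsm.derive_seed(master, fold, 4, j)
            )
            per_j[j] = (metrics, genes)
        folds.append(FoldResult(fold_index=fold, per_j=per_j, ranked=ranked,
                                train_counts=train.class_counts(),
                                test_counts=test.class_counts()))
        logger.info("fold %d/%d: %d groups scored, best=%s (%.3f)",
                    fold, config.k_folds, len(ranked),
                    ranked[0].set_id, ranked[0].score)

    return _aggregate(data, sets, config, folds)


def _aggregate(
    data: ExpressionDataset,
    sets: GeneSetCollection,
    config: RunConfig,
    folds: list[FoldResult],
) -> RunReport:
    try:
        from importlib.metadata import version as _v
        pkg_version = _v("gsmpath")
    except Exception:  # not installed (e.g. run from a source tree)
        pkg_version = "unknown"

    j_levels = sorted({j for f in folds for j in f.per_j})
    per_j_mean: dict[int, dict[str, float | None]] = {}
    for j in j_levels:
        ms = [f.per_j[j][0] for f in folds if j in f.per_j]
        gs = [len(f.per_j[j][1]) for f in folds if j in f.per_j]
        undefined = sum(1 for m in ms if m.auc is None)
        if undefined:
            logger.info("j=%d: %d fold(s) with undefined AUC excluded from the mean",
                        j, undefined)
        per_j_mean[j] = {
            "accuracy": _mean_defined([m.accuracy for m in ms]),
            "sensitivity": _mean_defined([m.sensitivity for m in ms]),
            "specificity": _mean_defined([m.specificity for m in ms]),
            "auc": _mean_defined([m.auc for m in ms]),
            "n_genes": float(np.mean(gs)),
        }

    # aggregated ranking: mean score per set across folds; a set missing from
    # a fold (dropped by restriction) takes that fold's minimum score and
    # worst rank so absence is penalised, not ignored
    ever_ranked = {s.set_id for f in folds for s in f.ranked}
    names = {s.set_id: s.name for f in folds for s in f.ranked}
    rows = []
    for set_id in (s.set_id for s in sets if s.set_id in ever_ranked):
        scores_across: list[float] = []
        ranks_across: list[float] = []
        for f in folds:
            by_id = {s.set_id: s for s in f.ranked}
            if set_id in by_id:
                scores_across.append(by_id[set_id].score)
                ranks_across.append(by_id[set_id].rank)
            else:
                scores_across.append(min(s.score for s in f.ranked))
                ranks_across.append(len(f.ranked))
        rows.append({
            "set_id": set_id,
            "name": names[set_id],
            "mean_score": float(np.mean(scores_across)),
            "mean_rank": float(np.mean(ranks_across)),
        })
    rows.sort(key=lambda r: (-r["mean_score"], r["mean_rank"], r["set_id"]))

    return RunReport(
        dataset_name=config.dataset_name,
        per_j_mean=per_j_mean,
        aggregated_ranking=rows,
        fold_results=tuple(folds),
        config=config.as_dict(),
        version=pkg_version,
    )
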