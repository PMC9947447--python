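"""Grouping, scoring and modeling of pathway gene sets.

The three stages of the wrapper feature-selection architecture:

* **Grouping** — restrict each gene set to the genes actually measured and
  carve one sub-dataset per set out of the training matrix
  (:func:`restrict_groups`, :func:`build_subdataset`);
* **Scoring** — rate each sub-dataset by the mean accuracy of a classifier
  over ``r`` repeated stratified inner train/test splits
  (:func:`score_group`), then order the sets (:func:`rank_groups`);
* **Modeling** — pool the genes of the ``j`` best sets and fit/evaluate a
  final classifier on the outer split (:func:`combine_top_groups`,
  :func:`train_and_evaluate`).

The default classifier is a 100-tree random forest with unlimited depth,
but any scikit-learn style estimator can be plugged in through
:class:`ClassifierSpec`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .io import ExpressionDataset, GeneSet, GeneSetCollection
from . import evaluation as _ev

logger = logging.getLogger("gsmpath")


def derive_seed(*parts: int) -> int:
    """Deterministic child seed from a tuple of integers (< 2**31).

    Every stochastic step (fold split, under-sampling draw, inner repeat,
    classifier initialisation) derives its seed from
    ``(master seed, fold index, group index, repeat index, ...)`` so any
    single quantity in a run can be reproduced in isolation.
    """
    ss = np.random.SeedSequence(list(parts))
    return int(ss.generate_state(1)[0] % (2**31))


class ThresholdStump:
    """Deterministic depth-1 classifier: one feature, one threshold.

    Fits by exhaustively scanning candidate thresholds (midpoints between
    consecutive distinct values) on every feature and both polarities,
    maximising training accuracy. Ties are broken toward the lowest feature
    index, the ``>=`` polarity, then the smallest threshold, so the fit is
    fully deterministic. Useful as a transparent stand-in for the random
    forest in exactness tests.
    """

    def __init__(self) -> None:
        self.feature_: int | None = None
        self.threshold_: float = 0.0
        self.polarity_: int = 1  # 1: predict positive when x >= threshold

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ThresholdStump":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = len(y)
        best_acc = -1.0
        # scan in canonical order (feature asc, >= before <, threshold asc);
        # strict improvement means the first optimum seen wins ties
        for f in range(X.shape[1]):
            col = X[:, f]
            uniq = np.unique(col)
            cands = [uniq[0] - 1.0, *((uniq[:-1] + uniq[1:]) / 2.0), uniq[-1] + 1.0]
            for polarity in (1, -1):
                for t in cands:
                    pred = (col >= t) if polarity == 1 else (col < t)
                    acc = float((pred.astype(int) == y).sum()) / n
                    if acc > best_acc:
                        best_acc = acc
                        self.feature_, self.threshold_, self.polarity_ = f, float(t), polarity
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        col = np.asarray(X, dtype=float)[:, self.feature_]
        if self.polarity_ == 1:
            return (col >= self.threshold_).astype(int)
        return (col < self.threshold_).astype(int)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = self.predict(X).astype(float)
        return np.column_stack([1.0 - p, p])

    @property
    def classes_(self) -> np.ndarray:
        return np.array([0, 1])


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier scores groups and fits the final models.

    ``algorithm="random_forest"`` (the default: 100 trees, unlimited depth)
    or ``"decision_stump"``; alternatively supply ``factory``, a callable
    ``seed -> estimator`` returning any object with ``fit`` / ``predict`` /
    ``predict_proba``.
    """

    algorithm: str = "random_forest"
    n_trees: int = 100
    max_depth: int | None = None
    factory: Callable[[int], object] | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.factory is None and self.algorithm not in (
            "random_forest", "decision_stump",
        ):
            raise ValueError(f"unknown classifier algorithm {self.algorithm!r}")

    def build(self, seed: int):
        if self.factory is not None:
            return self.factory(seed)
        if self.algorithm == "decision_stump":
            return ThresholdStump()
        return RandomForestClassifier(
            n_estimators=self.n_trees, max_depth=self.max_depth,
            random_state=seed,
        )


@dataclass(frozen=True)
class GroupScore:
    """Inner-CV performance of one gene set (the S-stage output)."""

    set_id: str
    name: str
    score: float
    mean_sensitivity: float
    mean_specificity: float
    n_genes_used: int
    rank: int = 0


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def restrict_groups(
    sets: GeneSetCollection, universe: Sequence[str], min_group_size: int = 3
) -> GeneSetCollection:
    """Intersect every set with the measured gene universe.

    Surviving genes are reordered to the universe (dataset) order, so that
    downstream gene unions are in dataset order. Sets retaining fewer than
    ``min_group_size`` genes are dropped; dropping everything is a
    configuration error (no gene set overlaps the expression data).
    """
    if min_group_size < 1:
        raise ValueError("min_group_size must be >= 1")
    order = {g: i for i, g in enumerate(universe)}
    kept: list[GeneSet] = []
    dropped = 0
    for s in sets:
        genes = sorted((g for g in s.genes if g in order), key=order.__getitem__)
        if len(genes) >= min_group_size:
            kept.append(GeneSet(set_id=s.set_id, name=s.name, genes=tuple(genes)))
        else:
            dropped += 1
    if dropped:
        logger.info("restrict_groups: dropped %d/%d sets below %d genes",
                    dropped, sets.k, min_group_size)
    if not kept:
        raise ValueError("no gene set overlaps the expression data")
    return GeneSetCollection(sets=tuple(kept))


def build_subdataset(data: ExpressionDataset, group: GeneSet) -> ExpressionDataset:
    """The expression matrix restricted to one group's genes.

    Columns are exactly the group's genes in dataset order; all samples and
    labels are retained; ``data`` is not modified.
    """
    order = {g: i for i, g in enumerate(data.gene_ids)}
    missing = [g for g in group.genes if g not in order]
    if missing:
        raise KeyError(
            f"group {group.set_id!r} references genes absent from the dataset: "
            f"{', '.join(missing)} (restrict_groups should have removed them)"
        )
    genes = sorted(group.genes, key=order.__getitem__)
    return data.subset_genes(genes)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_group(
    sub: ExpressionDataset,
    clf: ClassifierSpec,
    r: int = 5,
    inner_train_frac: float = 0.8,
    seed: int = 0,
    set_id: str = "",
    name: str = "",
) -> GroupScore:
    """Score one sub-dataset by ``r`` repeated inner train/test splits.

    Each repeat draws a stratified Monte Carlo split of ``sub`` (fraction
    ``inner_train_frac`` for training), fits the classifier on the inner
    training part and evaluates on the inner test part. The group's score is
    the mean accuracy over repeats; mean sensitivity and specificity are
    collected alongside. Only the samples inside ``sub`` are ever touched.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    n_pos, n_neg = sub.class_counts()
    if min(n_pos, n_neg) < 2:
        raise ValueError("score_group needs both classes with >= 2 samples")

    accs: list[float] = []
    sens: list[float] = []
    specs: list[float] = []
    for rep in range(r):
        tr, te = _ev.mc_split(sub, inner_train_frac, derive_seed(seed, rep, 0))
        model = clf.build(derive_seed(seed, rep, 1))
        model.fit(tr.values, tr.y)
        pred = np.asarray(model.predict(te.values), dtype=int)
        counts = _ev.ConfusionCounts.from_predictions(te.y, pred)
        se, sp, acc = _ev.confusion_metrics(counts)
        accs.append(acc)
        if se is not None:
            sens.append(se)
        if sp is not None:
            specs.append(sp)
    return GroupScore(
        set_id=set_id or "group",
        name=name or set_id or "group",
        score=float(np.mean(accs)),
        mean_sensitivity=float(np.mean(sens)) if sens else float("nan"),
        mean_specificity=float(np.mean(specs)) if specs else float("nan"),
        n_genes_used=sub.n_genes,
    )


def rank_groups(scores: Sequence[GroupScore]) -> list[GroupScore]:
    """Order groups for selection and assign 1-based ranks.

    Descending score; ties broken by descending mean sensitivity, then by
    fewer genes (parsimony), then by set id — a total, deterministic order.
    """
    if not scores:
        raise ValueError("rank_groups requires at least one score")

    def key(s: GroupScore):
        sens = s.mean_sensitivity
        if sens != sens:  # NaN sensitivity sorts last among ties
            sens = -1.0
        return (-s.score, -sens, s.n_genes_used, s.set_id)

    ordered = sorted(scores, key=key)
    return [dataclasses.replace(s, rank=i + 1) for i, s in enumerate(ordered)]


# ---------------------------------------------------------------------------
# Modeling
# ---------------------------------------------------------------------------

def combine_top_groups(
    ranked: Sequence[GroupScore], sets: GeneSetCollection, j: int
) -> list[str]:
    """Union of the genes of the ``j`` best-ranked groups.

    De-duplicated, ordered by group rank then by each group's stored
    (dataset) gene order; the union for ``j`` is always a prefix-superset of
    the union for ``j-1``.
    """
    if not 1 <= j <= len(ranked):
        raise ValueError(f"j={j} out of range 1..{len(ranked)}")
    by_rank = sorted(ranked, key=lambda s: s.rank)
    genes: dict[str, None] = {}
    for s in by_rank[:j]:
        for g in sets.get(s.set_id).genes:
            genes.setdefault(g)
    return list(genes)


def train_and_evaluate(
    train: ExpressionDataset,
    test: ExpressionDataset,
    genes: Sequence[str],
    clf: ClassifierSpec,
    seed: int = 0,
):
    """Fit the final model on ``train`` restricted to ``genes``; score ``test``.

    Returns ``(FoldMetrics, scores)`` where ``scores`` are the classifier's
    positive-class probabilities for the test samples (the AUC input).
    """
    n_pos, n_neg = train.class_counts()
    if min(n_pos, n_neg) < 1:
        raise ValueError("train_and_evaluate needs both classes in the training data")
    tr = train.subset_genes(genes)
    te = test.subset_genes(genes)
    model = clf.build(seed)
    model.fit(tr.values, tr.y)
    pred = np.asarray(model.predict(te.values), dtype=int)
    classes = list(np.asarray(model.classes_))
    proba = np.asarray(model.predict_proba(te.values), dtype=float)
    scores = proba[:, classes.index(1)]
    counts = _ev.ConfusionCounts.from_predictions(te.y, pred)
    se, sp, acc = _ev.confusion_metrics(counts)
    auc_value = _ev.auc(scores, te.y)
    metrics = _ev.FoldMetrics(
        accuracy=acc, sensitivity=se, specificity=sp, auc=auc_value, counts=counts
    )
    return metrics, scores
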