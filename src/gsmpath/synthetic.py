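"""Synthetic two-class expression data with planted pathway signal.

The generator emulates the study design the pipeline targets: a two-class
(disease vs control) expression matrix and a collection of gene sets, a few
of which are "informative" — a fraction of their genes is mean-shifted in
the positive class by ``effect_size`` within-class standard deviations.
Baseline expression is standard normal per gene per sample, so the per-gene
t-test assumptions hold exactly; adjacent sets share a controlled fraction
of genes, mimicking genes that act in multiple pathways.

The returned :class:`SyntheticTruth` records exactly which sets and genes
carry signal, which is what makes recovery and calibration experiments
possible without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import (
    NEGATIVE,
    POSITIVE,
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    informative_set_ids: tuple[str, ...]
    shifted_genes: tuple[str, ...]
    effect_size: float
    informative_fraction: float
    seed: int


def generate(
    n_pos: int = 40,
    n_neg: int = 40,
    n_genes: int = 1000,
    n_sets: int = 50,
    genes_per_set: int = 20,
    n_informative_sets: int = 3,
    effect_size: float = 2.0,
    informative_fraction: float = 0.5,
    overlap_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[ExpressionDataset, GeneSetCollection, SyntheticTruth]:
    """Generate a labeled expression matrix, gene sets and their ground truth.

    Gene sets are laid out consecutively over the gene universe with
    ``overlap_fraction`` of each set shared with its predecessor. Informative
    sets are drawn at random among non-adjacent positions (so no two
    informative sets share genes and the planted genes are distinct); within
    each, ``ceil(informative_fraction * genes_per_set)`` genes chosen at
    random get mean ``+effect_size`` in positive-class samples.

    Raises ``ValueError`` when the geometry is infeasible (too few genes for
    the requested sets under the overlap model, or more informative sets
    than non-adjacent slots).
    """
    if min(n_pos, n_neg) < 2:
        raise ValueError("need at least 2 samples per class")
    if not 0 <= n_informative_sets <= n_sets:
        raise ValueError("n_informative_sets must be in [0, n_sets]")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if not 0.0 <= informative_fraction <= 1.0 or not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("fractions must lie in [0, 1]")

    n_shared = int(round(overlap_fraction * genes_per_set))
    n_fresh = genes_per_set - n_shared
    if n_fresh < 1:
        raise ValueError("overlap_fraction leaves no fresh genes per set")
    needed = genes_per_set + (n_sets - 1) * n_fresh
    if needed > n_genes:
        raise ValueError(
            f"{n_sets} sets of {genes_per_set} genes with overlap "
            f"{overlap_fraction} need {needed} genes, only {n_genes} available"
        )
    if n_informative_sets > math.ceil(n_sets / 2):
        raise ValueError("too many informative sets to keep them non-adjacent")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    gene_ids = tuple(f"G{i + 1:0{width}d}" for i in range(n_genes))

    # consecutive layout: set i starts where set i-1's fresh genes ended,
    # reusing the last n_shared genes of set i-1
    sets = []
    start = 0
    for i in range(n_sets):
        idx = range(start, start + genes_per_set)
        sets.append(GeneSet(
            set_id=f"SET{i + 1:03d}",
            name=f"synthetic pathway {i + 1}",
            genes=tuple(gene_ids[j] for j in idx),
        ))
        start += n_fresh
    collection = GeneSetCollection(sets=tuple(sets))

    # choose non-adjacent informative sets
    informative: list[int] = []
    candidates = list(range(n_sets))
    while len(informative) < n_informative_sets:
        if not candidates:
            raise ValueError("could not place informative sets non-adjacently")
        pick = int(rng.choice(candidates))
        informative.append(pick)
        candidates = [c for c in candidates if abs(c - pick) > 1]
    informative.sort()

    n_shift = math.ceil(informative_fraction * genes_per_set)
    shifted: list[str] = []
    gene_col = {g: j for j, g in enumerate(gene_ids)}
    n = n_pos + n_neg
    X = rng.standard_normal((n, n_genes))
    labels = (POSITIVE,) * n_pos + (NEGATIVE,) * n_neg
    for i in informative:
        chosen = rng.choice(len(sets[i].genes), size=n_shift, replace=False)
        for c in sorted(chosen):
            g = sets[i].genes[c]
            X[:n_pos, gene_col[g]] += effect_size
            shifted.append(g)

    data = ExpressionDataset(
        sample_ids=tuple(f"S{i + 1:04d}" for i in range(n)),
        gene_ids=gene_ids,
        values=X,
        labels=labels,
    )
    truth = SyntheticTruth(
        informative_set_ids=tuple(sets[i].set_id for i in informative),
        shifted_genes=tuple(shifted),
        effect_size=effect_size,
        informative_fraction=informative_fraction,
        seed=seed,
    )
    return data, collection, truth
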