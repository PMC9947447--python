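"""Per-gene differential-expression statistics on training data.

The scoring stage is preceded by a per-gene two-sample t-test comparing the
positive (disease) and negative (control) samples of the *training* split.
The statistics serve two purposes: they are attached to the ranked-group
output as supporting evidence, and they can optionally restrict the gene
universe to the ``n`` most differential genes before grouping.

Statistics are always recomputed per cross-validation fold from that fold's
training samples only, so the held-out test split never influences them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import ExpressionDataset


@dataclass(frozen=True)
class GeneStats:
    """t-test summary for one gene: positive vs negative class."""

    gene: str
    t_statistic: float
    p_value: float


def compute_t_statistics(
    train: ExpressionDataset, equal_var: bool = False
) -> list[GeneStats]:
    """Two-sample t-test per gene between the two classes of ``train``.

    Welch's unequal-variance test by default (``equal_var=False``); pass
    ``equal_var=True`` for the pooled-variance Student's t.

    Genes with zero variance in both classes are assigned ``t=0, p=1``
    rather than NaN so that downstream rankings are total orders; this is a
    totality rule applied even in the degenerate case where the two classes
    sit at different constants.
    """
    y = train.y
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < 2:
        raise ValueError(
            f"t-test needs >= 2 samples per class (positive={n_pos}, negative={n_neg})"
        )
    pos = train.values[y == 1, :]
    neg = train.values[y == 0, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(pos, neg, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = (pos.var(axis=0) == 0) & (neg.var(axis=0) == 0)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    # any residual non-finite result (numerical underflow) is treated the same
    bad = ~(np.isfinite(t) & np.isfinite(p))
    t[bad] = 0.0
    p[bad] = 1.0
    return [
        GeneStats(gene=g, t_statistic=float(t[j]), p_value=float(p[j]))
        for j, g in enumerate(train.gene_ids)
    ]


def select_top_genes(stats: list[GeneStats], n: int) -> list[str]:
    """The ``min(n, len(stats))`` most differential genes.

    Sorted by ascending p-value; ties broken by descending ``|t|``, then by
    gene symbol so the ranking is deterministic. The ordering is prefix
    stable: the top-``n`` list is a prefix of the top-``(n+1)`` list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(stats, key=lambda s: (s.p_value, -abs(s.t_statistic), s.gene))
    return [s.gene for s in ordered[:n]]
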