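"""Shared fixtures: tiny hand-built datasets and file writers."""

import numpy as np
import pytest

from gsmpath import ExpressionDataset, GeneSet, GeneSetCollection, NEGATIVE, POSITIVE


def make_dataset(values, labels, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionDataset(
        sample_ids=tuple(sample_ids or (f"s{i}" for i in range(n))),
        gene_ids=tuple(gene_ids or (f"g{j}" for j in range(m))),
        values=values,
        labels=tuple(POSITIVE if l else NEGATIVE for l in labels),
    )


def random_dataset(n_pos, n_neg, n_genes, seed=0):
    rng = np.random.default_rng(seed)
    return make_dataset(
        rng.standard_normal((n_pos + n_neg, n_genes)),
        [1] * n_pos + [0] * n_neg,
    )


@pytest.fixture
def four_sample_tsv(tmp_path):
    """4 samples x 3 genes with case/ctrl labels."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "sample\tgA\tgB\tgC\tlabel\n"
        "s1\t1.0\t2.0\t3.0\tcase\n"
        "s2\t1.5\t2.5\t3.5\tcase\n"
        "s3\t0.5\t1.0\t1.5\tctrl\n"
        "s4\t0.7\t1.2\t1.7\tctrl\n"
    )
    return path


@pytest.fixture
def small_collection():
    return GeneSetCollection(sets=(
        GeneSet("S1", "first", ("gA", "gB", "gC")),
        GeneSet("S2", "second", ("gB", "gC", "gD")),
        GeneSet("S3", "third", ("gX", "gY", "gZ")),
    ))
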