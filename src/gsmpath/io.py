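"""Reading and writing the tool's external representations.

Three kinds of files cross the package boundary:

* labeled expression tables (TSV/CSV; one row per sample, one column per
  gene, plus a label column),
* gene-set collections (standard GMT or a two-column ``set_id<TAB>gene``
  listing),
* run reports (XLSX workbook with ``performance`` and ``ranked_groups``
  sheets, or a pair of CSV files).

Everything downstream works on the validated in-memory containers defined
here: :class:`ExpressionDataset`, :class:`GeneSet`, :class:`GeneSetCollection`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gsmpath")

#: canonical class tokens used throughout the package
POSITIVE = "positive"
NEGATIVE = "negative"


class FormatError(ValueError):
    """A file does not conform to the expected dialect or is inconsistent."""


@dataclass(frozen=True)
class ExpressionDataset:
    """A two-class labeled expression matrix, samples x genes.

    ``values[i, j]`` is the expression of gene ``gene_ids[j]`` in sample
    ``sample_ids[i]``; units are arbitrary (intensities or counts, treated
    as continuous). ``labels`` holds the canonical tokens ``"positive"`` /
    ``"negative"``.
    """

    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n, m = values.shape if values.ndim == 2 else (-1, -1)
        if (n, m) != (len(self.sample_ids), len(self.gene_ids)):
            raise FormatError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise FormatError(f"duplicate gene identifiers: {', '.join(dupes)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise FormatError(f"duplicate sample identifiers: {', '.join(dupes)}")
        if len(self.labels) != n:
            raise FormatError("every sample must carry exactly one label")
        bad = set(self.labels) - {POSITIVE, NEGATIVE}
        if bad:
            raise FormatError(f"unknown label tokens: {sorted(bad)}")
        if not np.isfinite(values).all():
            raise FormatError("expression matrix contains non-finite values")

    # -- convenience accessors -------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def y(self) -> np.ndarray:
        """Binary label vector, 1 = positive class."""
        return np.fromiter(
            (1 if lb == POSITIVE else 0 for lb in self.labels), dtype=np.int64,
            count=self.n_samples,
        )

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative)."""
        y = self.y
        return int(y.sum()), int((1 - y).sum())

    def subset_samples(self, index: Sequence[int]) -> "ExpressionDataset":
        index = list(index)
        return ExpressionDataset(
            sample_ids=tuple(self.sample_ids[i] for i in index),
            gene_ids=self.gene_ids,
            values=self.values[index, :],
            labels=tuple(self.labels[i] for i in index),
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        pos = {g: j for j, g in enumerate(self.gene_ids)}
        try:
            cols = [pos[g] for g in genes]
        except KeyError as exc:  # contract violation, not a user error
            raise KeyError(f"gene {exc.args[0]!r} absent from dataset") from None
        return ExpressionDataset(
            sample_ids=self.sample_ids,
            gene_ids=tuple(genes),
            values=self.values[:, cols],
            labels=self.labels,
        )


@dataclass(frozen=True)
class GeneSet:
    """One named group of gene symbols (a pathway treated as a plain set).

    ``genes`` preserves first-appearance order but contains no duplicates;
    repeated symbols in the source file are collapsed.
    """

    set_id: str
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.set_id!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            # normalise instead of erroring: duplicates are "ignored"
            object.__setattr__(self, "genes", _unique_ordered(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of :class:`GeneSet` with unique identifiers."""

    sets: tuple[GeneSet, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate set identifiers: {', '.join(_duplicates(ids))}")

    @property
    def k(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def get(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


def _unique_ordered(items: Sequence[str]) -> tuple[str, ...]:
    return tuple(dict.fromkeys(items))


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for it in items:
        if it in seen and it not in out:
            out.append(it)
        seen.add(it)
    return out


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path,
    label_column: str = "label",
    positive_label: str | None = None,
    delimiter: str | None = None,
    transpose: bool = False,
    impute_missing: bool = False,
) -> ExpressionDataset:
    """Read a labeled expression table into an :class:`ExpressionDataset`.

    The expected layout is one row per sample: the first column holds the
    sample identifier, the remaining columns are gene symbols plus one label
    column. Rows are never silently transposed; pass ``transpose=True`` for
    genes-in-rows files (the label column is then a label *row*).

    Parameters
    ----------
    label_column:
        Header of the column holding the class token.
    positive_label:
        Which of the two label tokens maps to the positive (disease) class.
        Defaults to the lexicographically smaller token, with a warning.
    delimiter:
        Field separator; inferred from the file extension when ``None``
        (``.csv`` -> comma, otherwise tab).
    impute_missing:
        When ``True``, missing expression cells are filled with the per-gene
        mean; the default is to reject files with missing values.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"

    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=delimiter), None)
    if not header:
        raise FormatError(f"{path}: empty file")

    df = pd.read_csv(path, sep=delimiter, index_col=0, header=0)
    if transpose:
        df = df.T
        header = [str(c) for c in df.columns]
        columns = header
    else:
        columns = header[1:]  # drop the sample-id column header

    dupes = _duplicates(columns)
    if dupes:
        raise FormatError(f"{path}: duplicate gene columns: {', '.join(dupes)}")
    if label_column not in columns:
        raise FormatError(f"{path}: label column {label_column!r} not found")

    labels_raw = df[label_column]
    if labels_raw.isna().any():
        missing = [str(s) for s in df.index[labels_raw.isna()]]
        raise FormatError(f"{path}: samples without a label: {', '.join(missing)}")
    labels_raw = labels_raw.astype(str)
    tokens = sorted(labels_raw.unique())
    if len(tokens) != 2:
        raise FormatError(
            f"{path}: expected exactly 2 label values, found {len(tokens)}: {tokens}"
        )
    if positive_label is None:
        positive_label = tokens[0]
        logger.warning("positive_label not given; using %r as the positive class",
                       positive_label)
    if positive_label not in tokens:
        raise FormatError(
            f"{path}: positive label {positive_label!r} not among label values {tokens}"
        )

    expr = df.drop(columns=[label_column])
    numeric = expr.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & expr.notna()
    if bad.any().any():
        i, j = np.argwhere(bad.values)[0]
        raise FormatError(
            f"{path}: non-numeric expression value {expr.iat[i, j]!r} at "
            f"sample {expr.index[i]!r}, gene {expr.columns[j]!r}"
        )
    if numeric.isna().any().any():
        if not impute_missing:
            n_missing = int(numeric.isna().values.sum())
            raise FormatError(
                f"{path}: {n_missing} missing expression values "
                f"(pass impute_missing=True to fill with per-gene means)"
            )
        numeric = numeric.fillna(numeric.mean(axis=0))

    labels = tuple(POSITIVE if t == positive_label else NEGATIVE for t in labels_raw)
    ds = ExpressionDataset(
        sample_ids=tuple(str(s) for s in df.index),
        gene_ids=tuple(str(c) for c in numeric.columns),
        values=numeric.to_numpy(dtype=float),
        labels=labels,
    )
    n_pos, n_neg = ds.class_counts()
    if min(n_pos, n_neg) < 2:
        raise FormatError(
            f"{path}: each class needs >= 2 samples (positive={n_pos}, negative={n_neg})"
        )
    return ds


def write_expression_table(
    data: ExpressionDataset, path: str | Path, label_column: str = "label",
    positive_token: str = POSITIVE, negative_token: str = NEGATIVE,
    delimiter: str | None = None,
) -> None:
    """Serialize a dataset back to a delimited table (inverse of the reader)."""
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(data.values, index=list(data.sample_ids),
                      columns=list(data.gene_ids))
    df.insert(0, label_column,
              [positive_token if lb == POSITIVE else negative_token
               for lb in data.labels])
    df.index.name = "sample"
    df.to_csv(path, sep=delimiter, float_format="%.6g")


# ---------------------------------------------------------------------------
# gene-set collections
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path, format: str = "gmt") -> GeneSetCollection:
    """Read a gene-set collection from a GMT or two-column file.

    GMT dialect: tab-separated ``set_id<TAB>description<TAB>gene1<TAB>...``
    (at least three fields per line). Two-column dialect: ``set_id<TAB>gene``
    with one membership per line; the set id doubles as its name.

    Duplicate genes within a set are collapsed, and sets left empty are
    dropped with a logged warning.
    """
    path = Path(path)
    if format not in ("gmt", "two_column"):
        raise ValueError(f"unknown gene-set format {format!r}")

    sets: list[GeneSet] = []
    if format == "gmt":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                    )
                set_id, name = fields[0], fields[1]
                genes = _unique_ordered([g for g in fields[2:] if g])
                if not genes:
                    logger.warning("dropping empty gene set %r (%s:%d)", set_id, path, lineno)
                    continue
                sets.append(GeneSet(set_id=set_id, name=name, genes=genes))
    else:
        membership: dict[str, list[str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                    )
                membership.setdefault(fields[0], []).append(fields[1])
        for set_id, genes in membership.items():
            uniq = _unique_ordered([g for g in genes if g])
            if not uniq:
                logger.warning("dropping empty gene set %r (%s)", set_id, path)
                continue
            sets.append(GeneSet(set_id=set_id, name=set_id, genes=uniq))

    return GeneSetCollection(sets=tuple(sets))


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as standard GMT (inverse of ``read_gene_sets``)."""
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.name, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# run reports
# ---------------------------------------------------------------------------

PERFORMANCE_COLUMNS = [
    "dataset", "j", "mean_accuracy", "mean_sensitivity", "mean_specificity",
    "mean_auc", "mean_n_genes",
]
RANKING_COLUMNS = ["set_id", "name", "mean_score", "mean_rank"]


def report_frames(report) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the two report tables (performance per j, aggregated ranking)."""
    perf_rows = []
    for j in sorted(report.per_j_mean):
        m = report.per_j_mean[j]
        perf_rows.append({
            "dataset": report.dataset_name,
            "j": j,
            "mean_accuracy": m["accuracy"],
            "mean_sensitivity": m["sensitivity"],
            "mean_specificity": m["specificity"],
            "mean_auc": m["auc"],
            "mean_n_genes": m["n_genes"],
        })
    perf = pd.DataFrame(perf_rows, columns=PERFORMANCE_COLUMNS)
    ranking = pd.DataFrame(
        [{"set_id": r["set_id"], "name": r["name"],
          "mean_score": r["mean_score"], "mean_rank": r["mean_rank"]}
         for r in report.aggregated_ranking],
        columns=RANKING_COLUMNS,
    )
    return perf, ranking


def write_report(report, path: str | Path, format: str = "csv") -> None:
    """Write a run report as XLSX (two sheets) or two CSV files.

    For ``format="csv"`` the tables land in ``<stem>_performance.csv`` and
    ``<stem>_ranked_groups.csv`` next to ``path``. Numbers are written with
    six decimals so repeated runs with the same seed produce byte-identical
    files.
    """
    path = Path(path)
    perf, ranking = report_frames(report)
    if format == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as xw:
            perf.to_excel(xw, sheet_name="performance", index=False)
            ranking.to_excel(xw, sheet_name="ranked_groups", index=False)
            pd.DataFrame(sorted(report.config.items()),
                         columns=["parameter", "value"]).to_excel(
                xw, sheet_name="config", index=False)
    elif format == "csv":
        stem = path.parent / (path.stem.removesuffix("_performance"))
        perf.to_csv(f"{stem}_performance.csv", index=False, float_format="%.6f")
        ranking.to_csv(f"{stem}_ranked_groups.csv", index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown report format {format!r}")
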