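"""Readers and writers for feature tables, taxonomy assignments and labels.

Accepted dialects
-----------------
* Feature table: TSV or CSV (delimiter sniffed from the extension and the
  header line), QIIME-classic layout: feature rows, sample columns, first
  column holds feature IDs (the ``#OTU ID`` header cell is tolerated), an
  optional leading ``# Constructed from biom file`` comment line is
  skipped, and an optional trailing column literally named ``taxonomy``
  (case-insensitive) holds Greengenes-style strings.
* Taxonomy: two-column TSV/CSV (feature ID, taxonomy string).
* Labels: two-column CSV/TSV with a header (sample ID, label).

BIOM (HDF5/JSON) is deliberately not read here; convert upstream.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._table import FeatureTable, LabelVector

logger = logging.getLogger(__name__)

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy_file",
    "read_labels",
    "write_labels",
    "align",
]


def _sniff_sep(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".txt"):
        return "\t"
    # fall back to inspecting the first non-comment line
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                continue
            return "," if line.count(",") > line.count("\t") else "\t"
    return "\t"


def _check_duplicates(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} IDs: {dups}")


def read_feature_table(
    path: str | Path,
    orientation: str = "features_as_rows",
) -> tuple[FeatureTable, dict[str, str] | None]:
    """Read a count table, returning it in samples x features orientation.

    Parameters
    ----------
    path
        TSV/CSV file. The first column holds row IDs.
    orientation
        ``"features_as_rows"`` (QIIME-classic, the default) or
        ``"samples_as_rows"``. Orientation is an explicit flag, never
        auto-detected: silent transposition is the classic pipeline bug.

    Returns
    -------
    table, taxonomy
        The table, and a ``feature_id -> taxonomy string`` dict if a
        ``taxonomy`` column was embedded (only meaningful for
        ``features_as_rows``), else ``None``.
    """
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0, comment=None, skiprows=_comment_rows(path)
    )
    df.index = df.index.astype(str)
    df.index.name = None
    if df.size == 0:
        raise ValueError(f"empty table: {path}")

    taxonomy: dict[str, str] | None = None
    tax_cols = [c for c in df.columns if str(c).strip().lower() == "taxonomy"]
    if tax_cols:
        if orientation != "features_as_rows":
            raise ValueError("a taxonomy column requires features_as_rows orientation")
        taxonomy = df[tax_cols[0]].astype(str).to_dict()
        df = df.drop(columns=tax_cols)

    _check_duplicates(df.index, "row")
    _check_duplicates(df.columns, "column")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at row {df.index[r]!r}, column {df.columns[c]!r}; "
            "counts must be complete"
        )

    if orientation == "features_as_rows":
        numeric = numeric.T
    numeric.columns = pd.Index([str(c) for c in numeric.columns])
    numeric.index = pd.Index([str(i) for i in numeric.index])
    return FeatureTable(numeric, stage="raw"), taxonomy


def _comment_rows(path: Path):
    """Row indices of leading '# ' comment lines (biom export banner)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.startswith("# "):
                rows.append(i)
            else:
                break
    return rows or None


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    orientation: str = "features_as_rows",
    taxonomy: dict[str, str] | None = None,
) -> None:
    """Write a table; inverse of :func:`read_feature_table`."""
    path = Path(path)
    sep = _sniff_sep(path) if path.exists() else ("," if path.suffix == ".csv" else "\t")
    df = table.data
    if orientation == "features_as_rows":
        df = df.T.copy()
        df.index.name = "#OTU ID"
        if taxonomy is not None:
            df = df.assign(taxonomy=[taxonomy.get(f, "") for f in df.index])
    else:
        df = df.copy()
        df.index.name = "sample"
    df.to_csv(path, sep=sep)


def read_taxonomy_file(path: str | Path) -> dict[str, str]:
    """Read a two-column (feature ID, taxonomy string) TSV/CSV."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"taxonomy file {path} needs two columns, got {df.shape[1]}")
    ids = df.iloc[:, 0].astype(str)
    _check_duplicates(pd.Index(ids), "feature")
    return dict(zip(ids, df.iloc[:, 1].astype(str)))


def read_labels(path: str | Path) -> LabelVector:
    """Read a two-column (sample ID, label) file and coerce labels to {0,1}.

    The lexicographically smaller raw label value maps to 0; the mapping is
    stored on the result and logged.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns, got {df.shape[1]}")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    raw = df.iloc[:, 1].astype(str).str.strip()
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample IDs in labels: {dups}")
    classes = sorted(raw.unique())
    if len(classes) == 1:
        raise ValueError(f"single class {classes[0]!r}: need two classes")
    if len(classes) > 2:
        raise ValueError(f"more than two classes: {classes}")
    mapping = {classes[0]: 0, classes[1]: 1}
    logger.info("label mapping: %s", mapping)
    labels = raw.map(mapping).to_numpy()
    return LabelVector(sample_ids=sample_ids, labels=labels, mapping=mapping)


def write_labels(labels: LabelVector, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    pd.DataFrame({"sample": labels.sample_ids, "label": labels.labels}).to_csv(
        path, sep=sep, index=False
    )


def align(table: FeatureTable, labels: LabelVector) -> tuple[FeatureTable, LabelVector]:
    """Restrict table and labels to their shared samples, in table order.

    Idempotent; raises on an empty intersection. Dropped counts are logged.
    """
    shared = [s for s in table.sample_ids if s in set(labels.sample_ids)]
    if not shared:
        raise ValueError("no shared sample IDs between table and labels")
    dropped_t = table.n_samples - len(shared)
    dropped_l = len(labels) - len(shared)
    if dropped_t or dropped_l:
        logger.info(
            "align: dropped %d table samples and %d label samples", dropped_t, dropped_l
        )
    if dropped_t == 0 and dropped_l == 0 and shared == labels.sample_ids:
        return table, labels
    y = labels.to_series().loc[shared]
    return (
        FeatureTable(table.data.loc[shared], stage=table.stage),
        LabelVector(sample_ids=shared, labels=y.to_numpy(), mapping=labels.mapping),
    )
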