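"""Ingest AIRR-style rearrangement tables and tabulate gene-segment usage.

A rearrangement table has one row per sequence (or per clone, if the caller
collapsed clones upstream) with a sample/repertoire identifier column and one
or more gene-call columns holding IMGT-style identifiers such as
``IGHV1-2*02``.  This module parses those tables, collapses allele-level calls
to the gene or family level, and counts how often each feature occurs in each
repertoire.  The resulting counts matrix is the universal input to the
dissimilarity computation in :mod:`rdikit.rdi`.

No sequence alignment or gene assignment happens here: gene calls are taken
verbatim from the annotation tool that produced the table.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ParseError

CollapseLevel = Literal["allele", "gene", "family"]
_LEVELS = ("allele", "gene", "family")

__all__ = [
    "RepertoireAnnotationTable",
    "FeatureCountTable",
    "read_airr",
    "collapse_gene_call",
    "tabulate_features",
]


@dataclass
class RepertoireAnnotationTable:
    """Per-sequence records: (repertoire id, {column -> raw gene call})."""

    records: list[tuple[str, dict[str, str]]]
    column_names: list[str]

    def __post_init__(self) -> None:
        for rid, calls in self.records:
            if not rid:
                raise DataError("record with empty repertoire id")
            missing = set(self.column_names) - set(calls)
            if missing:
                raise DataError(f"record missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FeatureCountTable:
    """Repertoires x features matrix of non-negative integer counts."""

    repertoire_ids: list[str]
    feature_labels: list[str]
    counts: np.ndarray
    feature_name: str = "feature"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.repertoire_ids),
            len(self.feature_labels),
        ):
            raise DataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.repertoire_ids)} repertoires x "
                f"{len(self.feature_labels)} features"
            )
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise DataError("counts must be non-negative integers")
            if np.any(self.counts < 0):
                raise DataError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        if len(set(self.repertoire_ids)) != len(self.repertoire_ids):
            raise DataError("repertoire ids must be unique")
        if len(set(self.feature_labels)) != len(self.feature_labels):
            raise DataError("feature labels must be unique")

    @property
    def n_repertoires(self) -> int:
        return len(self.repertoire_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_labels)

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.repertoire_ids, columns=self.feature_labels
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "repertoire_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, feature_name: str = "feature") -> "FeatureCountTable":
        df = pd.read_csv(path, index_col=0)
        return cls(
            repertoire_ids=[str(i) for i in df.index],
            feature_labels=[str(c) for c in df.columns],
            counts=df.to_numpy(dtype=np.int64),
            feature_name=feature_name,
        )


def read_airr(
    path: str | Path,
    id_column: str = "repertoire_id",
    feature_columns: Sequence[str] = ("v_call",),
    delimiter: str = "\t",
) -> RepertoireAnnotationTable:
    """Read a rearrangement TSV into a :class:`RepertoireAnnotationTable`.

    Only ``id_column`` and ``feature_columns`` are kept; other columns are
    ignored.  Rows with empty feature values are retained (they are filtered
    later, during tabulation).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ConfigurationError
        If the header lacks ``id_column`` or any of ``feature_columns``.
    ParseError
        On a ragged row, with its 1-based line number.
    """
    path = Path(path)
    feature_columns = list(feature_columns)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file", line=1) from None
        for col in [id_column, *feature_columns]:
            if col not in header:
                raise ConfigurationError(
                    f"column {col!r} not found in header of {path} "
                    f"(available: {header})"
                )
        idx = {col: header.index(col) for col in [id_column, *feature_columns]}
        records: list[tuple[str, dict[str, str]]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, got {len(row)}", line=lineno
                )
            rid = row[idx[id_column]]
            if not rid:
                raise ParseError(f"empty {id_column!r} value", line=lineno)
            records.append((rid, {c: row[idx[c]] for c in feature_columns}))
    return RepertoireAnnotationTable(records=records, column_names=feature_columns)


def collapse_gene_call(raw_call: str, level: CollapseLevel) -> str | None:
    """Collapse an IMGT-style gene call to allele, gene, or family level.

    ``"IGHV1-2*02"`` becomes ``"IGHV1-2"`` at gene level and ``"IGHV1"`` at
    family level.  Multi-assignment strings (comma-separated candidates) are
    resolved to the first candidate provided all candidates agree once
    collapsed to the requested level; disagreement, like an empty input,
    yields ``None``.  Total function: never raises on data.
    """
    if level not in _LEVELS:
        raise ConfigurationError(f"unknown collapse level {level!r}; use one of {_LEVELS}")
    if raw_call is None:
        return None
    candidates = [c.strip() for c in raw_call.split(",") if c.strip()]
    if not candidates:
        return None
    collapsed = [_collapse_one(c, level) for c in candidates]
    if len(set(collapsed)) != 1:
        return None
    return collapsed[0]


def _collapse_one(call: str, level: CollapseLevel) -> str:
    if level == "allele":
        return call
    gene = call.split("*", 1)[0]
    if level == "gene":
        return gene
    return gene.split("-", 1)[0]


def tabulate_features(
    table: RepertoireAnnotationTable,
    feature_column: str,
    level: CollapseLevel = "gene",
) -> FeatureCountTable:
    """Count collapsed feature calls per repertoire.

    Records whose call is ambiguous or empty (``collapse_gene_call`` returns
    ``None``) are dropped.  The feature universe is the union of observed
    collapsed calls across all repertoires, sorted lexicographically; a
    feature absent from a repertoire gets an explicit zero.  A repertoire left
    with no usable records triggers a warning and is kept as an all-zero row
    (it will be rejected downstream by ``calc_rdi``).
    """
    if feature_column not in table.column_names:
        raise ConfigurationError(
            f"feature column {feature_column!r} not in table columns "
            f"{table.column_names}"
        )
    # preserve first-seen repertoire order
    rep_ids: list[str] = []
    rep_index: dict[str, int] = {}
    tallies: dict[str, dict[str, int]] = {}
    for rid, calls in table.records:
        if rid not in rep_index:
            rep_index[rid] = len(rep_ids)
            rep_ids.append(rid)
            tallies[rid] = {}
        feat = collapse_gene_call(calls[feature_column], level)
        if feat is None:
            continue
        tallies[rid][feat] = tallies[rid].get(feat, 0) + 1

    labels = sorted({f for t in tallies.values() for f in t})
    counts = np.zeros((len(rep_ids), len(labels)), dtype=np.int64)
    col = {f: j for j, f in enumerate(labels)}
    for rid, tally in tallies.items():
        i = rep_index[rid]
        for f, c in tally.items():
            counts[i, col[f]] = c
    for rid in rep_ids:
        if not tallies[rid]:
            warnings.warn(
                f"repertoire {rid!r} has no usable {feature_column} calls; "
                "retained as an all-zero row",
                stacklevel=2,
            )
    return FeatureCountTable(
        repertoire_ids=rep_ids,
        feature_labels=labels,
        counts=counts,
        feature_name=f"{feature_column}:{level}",
    )
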