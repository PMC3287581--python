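"""Label tables and dataset filters for hierarchical classification targets.

Structures are labelled either by four-level Enzyme Commission (EC) numbers,
by SCOP hierarchy levels (class → fold → superfamily → family), or by
free-text superfamily/family names (as in curated enzyme benchmarks).  Label
tables are plain TSV with canonical column names; a convenience reader for
ASTRAL/SCOP ``dir.cla`` files is provided for real SCOP data.

Filters mirror common benchmark hygiene: classes below a minimum number of
representatives are removed entirely so that every class can support
stratified cross-validation.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Mapping, TextIO, Union

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError, IdentifierCollisionError, SchemaError

logger = logging.getLogger(__name__)

LABEL_COLUMNS = (
    "ec",
    "scop_class",
    "scop_fold",
    "scop_superfamily",
    "scop_family",
    "superfamily",
    "family",
)

#: Hierarchy levels selectable for classification.
LEVELS = ("EC4",) + LABEL_COLUMNS[1:]

_EC_RE = re.compile(r"^[0-9]+(\.[0-9n\-]+){3}$")


@dataclass
class LabelTable:
    """Structure-id → label records, one row per structure (or SCOP domain)."""

    data: pd.DataFrame  # index: structure_id; columns ⊆ LABEL_COLUMNS

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise IdentifierCollisionError(f"duplicate structure ids: {dupes}")

    def __len__(self) -> int:
        return len(self.data)

    def __contains__(self, structure_id: str) -> bool:
        return structure_id in self.data.index


@dataclass
class LabeledDataset:
    """Aligned features + one class label per feature row."""

    features: object  # CSMatrix or ReducedMatrix (anything with row_ids/values/take)
    labels: np.ndarray
    level: str
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if not self.ids:
            self.ids = list(self.features.row_ids)
        if len(self.labels) != len(self.ids):
            raise ValueError("one label per feature row required")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.features.values, dtype=float)

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def with_features(self, features) -> "LabeledDataset":
        """Same rows and labels over a different feature representation."""
        if list(features.row_ids) != self.ids:
            raise ValueError("row ids of the new features do not match")
        return LabeledDataset(features, self.labels.copy(), self.level, list(self.ids))


def _validate_ec(series: pd.Series) -> None:
    bad = [
        (i + 1, v)
        for i, v in enumerate(series.tolist())
        if pd.notna(v) and not _EC_RE.match(str(v))
    ]
    if bad:
        detail = "; ".join(f"row {r}: {v!r}" for r, v in bad[:5])
        raise SchemaError(f"malformed EC numbers ({len(bad)} rows): {detail}")


def _validate_scop_hierarchy(df: pd.DataFrame) -> None:
    """Same fold ⇒ same class, same superfamily ⇒ same fold, etc."""
    chain = ["scop_class", "scop_fold", "scop_superfamily", "scop_family"]
    present = [c for c in chain if c in df.columns]
    for parent, child in zip(present, present[1:]):
        sub = df[[parent, child]].dropna()
        nparents = sub.groupby(child)[parent].nunique()
        conflicts = nparents[nparents > 1]
        if len(conflicts):
            raise SchemaError(
                f"SCOP hierarchy violation: {child} value(s) "
                f"{list(conflicts.index[:3])} map to multiple {parent} values"
            )


def read_label_table(
    source: Union[str, os.PathLike, TextIO],
    schema: Mapping[str, str] | None = None,
) -> LabelTable:
    """Read a TSV label table.

    ``schema`` maps file column names to canonical ones ("id", "ec",
    "scop_class", ..., "superfamily", "family"); by default canonical names
    are expected in the header, with "structure_id" or "id" as the id column.
    EC strings are validated (four dot-separated fields) with offending row
    numbers reported; SCOP hierarchy consistency is checked when several
    levels are present.
    """
    try:
        df = pd.read_csv(source, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyDatasetError("label table is empty") from exc
    if df.empty:
        raise EmptyDatasetError("label table has no rows")
    if schema:
        df = df.rename(columns=dict(schema))
        if "id" in df.columns:
            df = df.rename(columns={"id": "structure_id"})
    elif "id" in df.columns and "structure_id" not in df.columns:
        df = df.rename(columns={"id": "structure_id"})
    if "structure_id" not in df.columns:
        raise SchemaError(
            f"no id column found (have {list(df.columns)}); "
            "expected 'structure_id'/'id' or a schema mapping"
        )
    label_cols = [c for c in df.columns if c in LABEL_COLUMNS]
    if not label_cols:
        raise SchemaError("label table needs at least one label column")
    if "ec" in df.columns:
        _validate_ec(df["ec"])
    df = df.set_index("structure_id")[label_cols]
    _validate_scop_hierarchy(df)
    return LabelTable(df)


def read_scop_cla(source: Union[str, os.PathLike, TextIO]) -> LabelTable:
    """Read an ASTRAL/SCOP ``dir.cla``-style file into a LabelTable.

    Each non-comment line holds: sid, PDB id, description, sccs, sunid,
    hierarchy.  The sccs string (e.g. ``a.1.1.1``) supplies the four SCOP
    levels: class ``a``, fold ``a.1``, superfamily ``a.1.1``, family
    ``a.1.1.1``.  Domain sids become the structure ids.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = open(source).read().splitlines()
    rows = []
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise SchemaError(f"unparseable cla line: {line!r}")
        sid, sccs = parts[0], parts[3]
        fields = sccs.split(".")
        if len(fields) != 4:
            raise SchemaError(f"bad sccs string {sccs!r} for domain {sid}")
        rows.append(
            {
                "structure_id": sid,
                "scop_class": fields[0],
                "scop_fold": ".".join(fields[:2]),
                "scop_superfamily": ".".join(fields[:3]),
                "scop_family": sccs,
            }
        )
    if not rows:
        raise EmptyDatasetError("cla file has no domain lines")
    df = pd.DataFrame(rows).set_index("structure_id")
    return LabelTable(df)


def _level_column(level: str) -> str:
    if level == "EC4":
        return "ec"
    if level in LABEL_COLUMNS:
        return level
    raise ValueError(f"unknown level {level!r}; choose from {('EC4',) + LABEL_COLUMNS[1:]}")


def select_level(table: LabelTable, features, level: str) -> LabeledDataset:
    """Attach class labels at a hierarchy level to feature rows.

    EC4 uses all four EC fields jointly as the class label.  Feature rows
    absent from the table, or lacking the requested level, are dropped with
    a logged count.
    """
    col = _level_column(level)
    if col not in table.data.columns:
        raise SchemaError(f"label table has no {col!r} column")
    keep_idx, labels = [], []
    for i, rid in enumerate(features.row_ids):
        if rid in table.data.index:
            value = table.data.at[rid, col]
            if pd.notna(value):
                keep_idx.append(i)
                labels.append(str(value))
                continue
        logger.debug("row %s dropped: no %s label", rid, level)
    dropped = len(features.row_ids) - len(keep_idx)
    if dropped:
        logger.info("select_level(%s): dropped %d unlabeled rows", level, dropped)
    if not keep_idx:
        raise EmptyDatasetError(f"no rows carry a {level} label")
    return LabeledDataset(features.take(keep_idx), np.array(labels, dtype=object), level)


def filter_min_representatives(dataset: LabeledDataset, min_count: int) -> LabeledDataset:
    """Drop every class with fewer than ``min_count`` members; keep row order."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = dataset.class_counts()
    keep_classes = {c for c, n in counts.items() if n >= min_count}
    if not keep_classes:
        raise EmptyDatasetError(
            f"no class has {min_count} representatives (max is {max(counts.values())})"
        )
    keep_idx = [i for i, lab in enumerate(dataset.labels) if lab in keep_classes]
    return LabeledDataset(
        dataset.features.take(keep_idx),
        dataset.labels[keep_idx],
        dataset.level,
        [dataset.ids[i] for i in keep_idx],
    )
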