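"""Input/output and the core data containers.

Expression matrices are plain delimited text: a header row of sample IDs and
a first column of gene (or probe) IDs, values already log2-transformed and
normalised upstream.  Sample classes come from a two-column table, gene sets
from standard GMT.  An optional Illumina-style detection-score matrix can be
used to drop probes that are not reliably detected in any class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("attract")

__all__ = [
    "ExpressionDataset",
    "PathwayCollection",
    "read_expression",
    "write_expression",
    "read_classes",
    "read_gmt",
    "write_gmt",
    "filter_detection",
]


@dataclass
class ExpressionDataset:
    """A log2 expression matrix (genes x samples) plus a class label per sample.

    Parameters
    ----------
    values:
        DataFrame with unique gene IDs as index and unique sample IDs as
        columns; all entries finite.
    classes:
        Series mapping sample ID -> class label.  Must cover every column of
        ``values``; entries for unknown samples are dropped with a warning.
    """

    values: pd.DataFrame
    classes: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        arr = np.asarray(self.values, dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        self.values = pd.DataFrame(arr, index=self.values.index.astype(str),
                                   columns=self.values.columns.astype(str))

        cls = pd.Series(self.classes)
        cls.index = cls.index.astype(str)
        missing = [s for s in self.values.columns if s not in cls.index]
        if missing:
            raise ValueError(f"samples missing a class label: {missing}")
        extra = [s for s in cls.index if s not in self.values.columns]
        if extra:
            warnings.warn(f"class table has {len(extra)} sample(s) not in the "
                          f"expression matrix; ignored: {extra}")
            cls = cls.drop(index=extra)
        # align to column order
        self.classes = cls.reindex(self.values.columns).astype(str)

        counts = self.replicate_counts
        if len(counts) < 2:
            raise ValueError(f"need >= 2 classes, got {len(counts)}")
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"classes with fewer than 2 replicates: {small}")
        if (counts < 3).any():
            small = counts[counts < 3].index.tolist()
            warnings.warn(
                f"classes with fewer than 3 replicates: {small}; "
                "at least three replicates per class are recommended"
            )

    # -- derived quantities ------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        """N, the total sample count."""
        return self.values.shape[1]

    @property
    def class_labels(self) -> list[str]:
        """Distinct class labels, in first-appearance order."""
        return list(dict.fromkeys(self.classes))

    @property
    def n_classes(self) -> int:
        """K, the number of distinct classes."""
        return len(self.class_labels)

    @property
    def replicate_counts(self) -> pd.Series:
        """r_k: replicate count per class, in first-appearance order."""
        return self.classes.value_counts().reindex(self.class_labels)

    def samples_of(self, label: str) -> pd.Index:
        return self.values.columns[(self.classes == label).to_numpy()]

    def subset_genes(self, genes) -> "ExpressionDataset":
        """Row subset preserving the given order; unknown genes are an error."""
        genes = list(genes)
        unknown = [g for g in genes if g not in self.values.index]
        if unknown:
            raise KeyError(f"genes not in dataset: {unknown}")
        return ExpressionDataset(self.values.loc[genes], self.classes.copy())


@dataclass
class PathwayCollection:
    """Gene-set definitions: pathway ID -> set of gene IDs, plus display names.

    A gene may belong to many pathways; empty sets are invalid.
    """

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for pid, members in self.sets.items():
            members = frozenset(str(g) for g in members)
            if not members:
                raise ValueError(f"pathway {pid!r} has an empty gene set")
            clean[str(pid)] = members
        self.sets = clean
        self.names = {str(k): str(v) for k, v in self.names.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, pid: str) -> bool:
        return pid in self.sets

    def __getitem__(self, pid: str) -> frozenset[str]:
        return self.sets[pid]

    def ids(self) -> list[str]:
        return list(self.sets)

    def name_of(self, pid: str) -> str:
        return self.names.get(pid, pid)

    def annotated_genes(self) -> frozenset[str]:
        """Union of all member genes (genes carrying any annotation)."""
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


# -- readers / writers -----------------------------------------------------

def _sniff_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited expression (or detection-score) matrix.

    First column gene IDs, header row sample IDs, numeric body.  Row and
    column order are preserved.  Raises on duplicate gene/sample IDs and on
    malformed or non-finite cells, naming the offending row and column.
    """
    delimiter = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene IDs: {dups}")
    if any(str(c).startswith("Unnamed:") or str(c).endswith((".1", ".2"))
           for c in df.columns):
        # pandas mangles duplicate header fields; re-check the raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(delimiter)[1:]
        seen = set()
        for h in header:
            if h in seen:
                raise ValueError(f"{path}: duplicate sample ID {h!r}")
            seen.add(h)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ValueError(
                f"{path}: malformed numeric cell at gene {gene!r}, sample {col!r}: "
                f"{df.loc[gene, col]!r}"
            )
        if converted.isna().any() or not np.isfinite(converted.to_numpy()).all():
            gene = df.index[~np.isfinite(converted.to_numpy(dtype=float))][0]
            raise ValueError(f"{path}: non-finite value at gene {gene!r}, sample {col!r}")
        out[col] = converted.astype(float)
    return out


def write_expression(values: pd.DataFrame, path: str | Path,
                     delimiter: str | None = None) -> None:
    """Write a matrix in the same layout `read_expression` accepts."""
    delimiter = _sniff_delimiter(path, delimiter)
    values.to_csv(path, sep=delimiter, index_label="gene_id")


def read_classes(path: str | Path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column sample->class table (no header required).

    Lines starting with '#' and a header line named 'sample...' are skipped.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            rows.append((parts[0], parts[1]))
    if rows and rows[0][0].lower() in {"sample", "sample_id", "id"}:
        rows = rows[1:]
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate sample IDs in class table: {dups}")
    return pd.Series({i: c for i, c in rows}, name="class")


def write_classes(classes: pd.Series, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\n")
        for sample, label in classes.items():
            fh.write(f"{sample}\t{label}\n")


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read gene sets in GMT format (tab-delimited: ID, description, genes...).

    Genes are deduplicated within each set; a set left empty is rejected, as
    is a line with fewer than three fields.
    """
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pid, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {pid!r} has no genes")
            if pid in sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway ID {pid!r}")
            sets[pid] = frozenset(genes)
            names[pid] = desc
    return PathwayCollection(sets=sets, names=names)


def write_gmt(pathways: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in pathways.ids():
            genes = sorted(pathways[pid])
            fh.write("\t".join([pid, pathways.name_of(pid), *genes]) + "\n")


# -- detection filter ------------------------------------------------------

def filter_detection(expr: ExpressionDataset, detection: pd.DataFrame,
                     score_min: float = 0.99,
                     sample_frac: float = 0.75) -> ExpressionDataset:
    """Drop genes not reliably detected in any class.

    A gene is retained iff there exists a class k in which the fraction of
    samples with detection score >= ``score_min`` is >= ``sample_frac``
    (both comparisons inclusive; the fraction is evaluated exactly, without
    rounding the replicate count).  Gene order is preserved, so the filter is
    idempotent.
    """
    if list(detection.index) != list(expr.values.index) or \
       list(detection.columns) != list(expr.values.columns):
        raise ValueError("detection matrix is not aligned to the expression matrix "
                         f"(expr {expr.values.shape}, detection {detection.shape})")
    scores = np.asarray(detection, dtype=float)
    keep = np.zeros(scores.shape[0], dtype=bool)
    for label in expr.class_labels:
        mask = (expr.classes == label).to_numpy()
        frac = (scores[:, mask] >= score_min).mean(axis=1)
        keep |= frac >= sample_frac
    kept = expr.values.index[keep]
    logger.info("detection filter: retained %d/%d genes", keep.sum(), len(keep))
    return ExpressionDataset(expr.values.loc[kept], expr.classes.copy())
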