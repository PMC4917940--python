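"""Count-matrix container, delimited-text I/O and the expression filter.

The central object is :class:`CountMatrix`: a genes x samples matrix of raw
read counts with per-sample condition (and, for matched designs, subject)
annotations.  Condition and subject labels in metadata may be arbitrary
strings; they are mapped to integer indices ``1..D`` (``1..n``) in order of
first appearance in the metadata, which keeps the mapping deterministic.

In a *matched* design every subject contributes exactly one sample to every
condition, so all conditions share the same sample size ``n`` and
between-condition correlation of expression within a subject is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DesignError,
    EmptyResultError,
    FormatError,
    MetadataError,
)

__all__ = [
    "CountMatrix",
    "NormalizedCounts",
    "read_counts",
    "write_counts",
    "filter_genes",
]


@dataclass
class CountMatrix:
    """Gene x sample read counts with condition/subject annotations.

    Parameters
    ----------
    counts
        ``(G, N)`` array of non-negative integers.
    gene_ids
        ``G`` unique gene labels.
    sample_ids
        ``N`` unique sample labels, in file/column order.
    conditions
        ``(N,)`` condition index per sample, values in ``1..D``.
    subjects
        Optional ``(N,)`` subject index per sample, values in ``1..n``;
        present iff the design is matched.
    condition_labels
        Original condition labels, position ``d - 1`` holds the label mapped
        to condition ``d``.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    conditions: np.ndarray
    subjects: Optional[np.ndarray] = None
    condition_labels: tuple = ()
    subject_labels: tuple = ()

    def __post_init__(self) -> None:
        self.counts = _as_count_array(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.conditions = np.asarray(self.conditions, dtype=np.int64)
        if self.subjects is not None:
            self.subjects = np.asarray(self.subjects, dtype=np.int64)
        if not self.condition_labels:
            self.condition_labels = tuple(
                str(d) for d in range(1, self.conditions.max(initial=0) + 1)
            )
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        G, N = self.counts.shape
        if len(self.gene_ids) != G:
            raise FormatError(f"{len(self.gene_ids)} gene ids for {G} rows")
        if len(self.sample_ids) != N:
            raise FormatError(f"{len(self.sample_ids)} sample ids for {N} columns")
        if len(set(map(str, self.gene_ids))) != G:
            raise FormatError("gene ids are not unique")
        if len(set(map(str, self.sample_ids))) != N:
            raise FormatError("sample ids are not unique")
        if self.conditions.shape != (N,):
            raise MetadataError("conditions must annotate every sample")
        d_values = np.unique(self.conditions)
        D = d_values.max()
        if not np.array_equal(d_values, np.arange(1, D + 1)):
            raise MetadataError("condition indices must cover 1..D")
        if (self.n_d < 2).any():
            bad = [d + 1 for d in np.flatnonzero(self.n_d < 2)]
            raise DesignError(
                f"every condition needs at least two replicates; "
                f"condition(s) {bad} have fewer"
            )
        if self.subjects is not None:
            self._validate_matched()

    def _validate_matched(self) -> None:
        assert self.subjects is not None
        subj = np.unique(self.subjects)
        for d in range(1, self.D + 1):
            in_d = self.subjects[self.conditions == d]
            if len(in_d) != len(subj) or len(np.unique(in_d)) != len(in_d) or not np.array_equal(
                np.sort(in_d), subj
            ):
                raise DesignError(
                    f"matched design requires every subject exactly once per "
                    f"condition; condition {d} violates this"
                )

    # -- shape / design properties ------------------------------------------

    @property
    def G(self) -> int:
        return self.counts.shape[0]

    @property
    def N(self) -> int:
        return self.counts.shape[1]

    @property
    def D(self) -> int:
        return int(self.conditions.max())

    @property
    def n_d(self) -> np.ndarray:
        """Samples per condition, ``(D,)``."""
        return np.bincount(self.conditions, minlength=self.D + 1)[1:]

    @property
    def is_matched(self) -> bool:
        return self.subjects is not None

    @property
    def n_subjects(self) -> int:
        if self.subjects is None:
            raise DesignError("unmatched design has no subjects")
        return int(self.subjects.max())

    # -- views ---------------------------------------------------------------

    def condition_columns(self, d: int) -> np.ndarray:
        """Column indices of condition ``d`` (matched: ordered by subject)."""
        idx = np.flatnonzero(self.conditions == d)
        if self.subjects is not None:
            idx = idx[np.argsort(self.subjects[idx], kind="stable")]
        return idx

    def split_by_condition(self, values: Optional[np.ndarray] = None) -> list:
        """Per-condition ``(G, n_d)`` blocks of ``values`` (default: counts)."""
        values = self.counts if values is None else values
        return [values[:, self.condition_columns(d)] for d in range(1, self.D + 1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def metadata_frame(self) -> pd.DataFrame:
        cond = [self.condition_labels[d - 1] for d in self.conditions]
        meta = pd.DataFrame({"sample_id": self.sample_ids, "condition": cond})
        if self.subjects is not None:
            labels = self.subject_labels or tuple(
                str(i) for i in range(1, self.n_subjects + 1)
            )
            meta["subject"] = [labels[i - 1] for i in self.subjects]
        return meta

    def select_genes(self, keep: np.ndarray) -> "CountMatrix":
        """New CountMatrix restricted to genes selected by ``keep``."""
        return CountMatrix(
            counts=self.counts[keep],
            gene_ids=self.gene_ids[keep],
            sample_ids=self.sample_ids,
            conditions=self.conditions,
            subjects=self.subjects,
            condition_labels=self.condition_labels,
            subject_labels=self.subject_labels,
        )


@dataclass
class NormalizedCounts:
    """Normalized counts ``Y = [X / delta]`` with the size factors used.

    ``matrix`` holds the rounded Y values with the same annotations as the
    source counts; ``size_factors`` records the per-sample delta.
    """

    matrix: CountMatrix
    size_factors: "object"  # multide.normalize.SizeFactors

    @property
    def values(self) -> np.ndarray:
        return self.matrix.counts

    def __getattr__(self, name):
        # delegate shape/design properties to the underlying CountMatrix
        if name.startswith("_") or name == "matrix":
            raise AttributeError(name)
        return getattr(self.matrix, name)


def _as_count_array(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise FormatError("counts must be a 2-D genes x samples matrix")
    if arr.dtype.kind == "f":
        if not np.isfinite(arr).all():
            raise FormatError("counts contain non-finite values")
        if not np.equal(np.mod(arr, 1), 0).all():
            raise FormatError("counts contain non-integer values")
        arr = arr.astype(np.int64)
    elif arr.dtype.kind not in "iu":
        raise FormatError(f"counts have non-numeric dtype {arr.dtype}")
    else:
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise FormatError("counts contain negative values")
    return arr


# ---------------------------------------------------------------------------
# I/O


def _read_table(path) -> pd.DataFrame:
    """Read a TSV (default) or CSV table; the delimiter is sniffed."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def read_counts(counts_path, metadata_path) -> CountMatrix:
    """Load a delimited counts file plus sample metadata into a CountMatrix.

    The counts file has a header row of sample ids and a leading gene-id
    column.  Metadata must contain columns ``sample_id`` and ``condition``
    and may contain ``subject`` for matched designs.  Sample order follows
    the counts file.
    """
    raw = _read_table(counts_path)
    raw = raw.set_index(raw.columns[0])
    meta = _read_table(metadata_path)
    return from_frames(raw, meta)


def from_frames(counts: pd.DataFrame, meta: pd.DataFrame) -> CountMatrix:
    """Build a CountMatrix from in-memory counts and metadata frames."""
    for col in ("sample_id", "condition"):
        if col not in meta.columns:
            raise MetadataError(f"metadata is missing required column '{col}'")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    by_sample = meta.set_index("sample_id")
    if by_sample.index.has_duplicates:
        raise MetadataError("metadata contains duplicate sample ids")
    sample_ids = [str(s) for s in counts.columns]
    missing = [s for s in sample_ids if s not in by_sample.index]
    if missing:
        raise MetadataError(f"samples missing from metadata: {missing}")

    # labels -> indices 1..D in order of first appearance in the metadata
    cond_labels = list(dict.fromkeys(meta["condition"].tolist()))
    cond_of = {lab: i + 1 for i, lab in enumerate(cond_labels)}
    conditions = np.array(
        [cond_of[by_sample.loc[s, "condition"]] for s in sample_ids], dtype=np.int64
    )

    subjects = None
    subj_labels: tuple = ()
    if "subject" in meta.columns and meta["subject"].notna().all():
        labels = list(dict.fromkeys(meta["subject"].tolist()))
        subj_of = {lab: i + 1 for i, lab in enumerate(labels)}
        subjects = np.array(
            [subj_of[by_sample.loc[s, "subject"]] for s in sample_ids], dtype=np.int64
        )
        subj_labels = tuple(str(x) for x in labels)

    return CountMatrix(
        counts=counts.to_numpy(),
        gene_ids=counts.index.to_numpy(dtype=object),
        sample_ids=np.array(sample_ids, dtype=object),
        conditions=conditions,
        subjects=subjects,
        condition_labels=tuple(str(x) for x in cond_labels),
        subject_labels=subj_labels,
    )


def write_counts(cm: CountMatrix, counts_path, metadata_path=None, sep="\t") -> None:
    """Write counts (and optionally metadata) as delimited text."""
    frame = cm.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(counts_path, sep=sep)
    if metadata_path is not None:
        cm.metadata_frame().to_csv(metadata_path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Filtering


def filter_genes(cm: CountMatrix, min_max_count: int = 50) -> CountMatrix:
    """Keep genes whose maximum count exceeds ``min_max_count`` in *every* condition.

    The comparison is strict (``> min_max_count``), so a gene whose largest
    count in some condition equals the threshold is removed.  Raises
    :class:`EmptyResultError` if no gene survives.
    """
    if min_max_count < 0:
        raise ValueError("min_max_count must be >= 0")
    maxima = np.stack([blk.max(axis=1) for blk in cm.split_by_condition()])
    keep = (maxima > min_max_count).all(axis=0)
    if not keep.any():
        raise EmptyResultError(
            f"no gene has max count > {min_max_count} in every condition"
        )
    return cm.select_genes(keep)
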