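"""Between-lane size factors and count normalization.

Four size-factor methods are provided, all operating on raw counts:

``MEDIAN``
    per-sample median divided by the geometric mean of all medians;
``TOTAL``
    per-sample total divided by the arithmetic mean of all totals;
``QUANTILE``
    per-sample 75th percentile divided by the arithmetic mean of all
    75th percentiles (linear-interpolation quantile convention);
``TMM``
    precision-weighted trimmed mean of gene-wise log2 relative expression
    (M-values) against a reference sample, exponentiated back from the
    log2 scale and rescaled to geometric mean 1.

Normalized counts are ``Y = [X / delta]`` with ``[.]`` the nearest integer
under round-half-to-even (numpy's rounding), fixed so half-way ties are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import gmean

from .data import CountMatrix, NormalizedCounts
from .errors import DegenerateSampleError, InsufficientGenesError

__all__ = [
    "SizeFactors",
    "median_size_factors",
    "total_size_factors",
    "quantile_size_factors",
    "tmm_size_factors",
    "size_factors",
    "normalize_counts",
    "METHODS",
]

METHODS = ("median", "total", "quantile", "tmm")


@dataclass
class SizeFactors:
    """Per-sample scaling factors ``delta`` (all positive)."""

    delta: np.ndarray
    method: str
    sample_ids: np.ndarray
    reference_sample: Optional[str] = None

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if (self.delta <= 0).any() or not np.isfinite(self.delta).all():
            raise DegenerateSampleError("size factors must be finite and positive")


def median_size_factors(cm: CountMatrix) -> SizeFactors:
    """MEDIAN: sample median over the geometric mean of all sample medians."""
    m = np.median(cm.counts, axis=0)
    if (m <= 0).any():
        bad = list(cm.sample_ids[m <= 0])
        raise DegenerateSampleError(
            f"zero median count in sample(s) {bad}; filter low-count genes first"
        )
    return SizeFactors(m / gmean(m), "median", cm.sample_ids)


def total_size_factors(cm: CountMatrix) -> SizeFactors:
    """TOTAL: sample total over the arithmetic mean of all sample totals."""
    s = cm.counts.sum(axis=0).astype(float)
    if (s <= 0).any():
        bad = list(cm.sample_ids[s <= 0])
        raise DegenerateSampleError(f"zero total count in sample(s) {bad}")
    return SizeFactors(s / s.mean(), "total", cm.sample_ids)


def quantile_size_factors(cm: CountMatrix) -> SizeFactors:
    """QUANTILE: sample 75th percentile over the mean of all 75th percentiles."""
    q = np.percentile(cm.counts, 75, axis=0)
    if (q <= 0).any():
        bad = list(cm.sample_ids[q <= 0])
        raise DegenerateSampleError(f"zero 75th percentile in sample(s) {bad}")
    return SizeFactors(q / q.mean(), "quantile", cm.sample_ids)


def _auto_reference(counts: np.ndarray) -> int:
    """Sample whose upper quartile is closest to the mean upper quartile."""
    uq = np.percentile(counts, 75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_size_factors(
    cm: CountMatrix,
    trim_fraction: float = 0.30,
    reference: Optional[str] = None,
    min_genes: int = 10,
) -> SizeFactors:
    """Weighted trimmed mean of M-values against a reference sample.

    For each sample, gene-wise M-values ``log2((X/N) / (X_ref/N_ref))`` are
    computed over genes with positive counts in both the sample and the
    reference; the upper and lower ``trim_fraction`` of the M-values are
    removed, and the rest are averaged with inverse-variance weights
    ``1 / ((N-X)/(N X) + (N_ref-X_ref)/(N_ref X_ref))``.  The factor is
    ``2**mean``; all factors are rescaled to geometric mean 1.

    No trimming by absolute expression is applied beyond the implicit
    exclusion of zero-count genes: only the M-values themselves are trimmed.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    X = cm.counts.astype(float)
    lib = X.sum(axis=0)
    if reference is None:
        ref = _auto_reference(X)
    else:
        where = np.flatnonzero(cm.sample_ids == reference)
        if len(where) == 0:
            raise DegenerateSampleError(f"reference sample {reference!r} not found")
        ref = int(where[0])

    with np.errstate(divide="ignore"):
        log_ref = np.log2(X[:, ref] / lib[ref])  # -inf rows are masked below
    factors = np.empty(cm.N)
    for j in range(cm.N):
        if j == ref:
            factors[j] = 1.0
            continue
        usable = (X[:, j] > 0) & (X[:, ref] > 0)
        M = np.log2(X[usable, j] / lib[j]) - log_ref[usable]
        var = (lib[j] - X[usable, j]) / (lib[j] * X[usable, j]) + (
            lib[ref] - X[usable, ref]
        ) / (lib[ref] * X[usable, ref])
        order = np.argsort(M, kind="stable")
        k = len(M)
        lo = int(np.floor(k * trim_fraction))
        keep = order[lo : k - lo]
        if len(keep) < min_genes:
            raise InsufficientGenesError(
                f"only {len(keep)} usable genes after trimming for sample "
                f"{cm.sample_ids[j]!r} (need >= {min_genes})"
            )
        w = 1.0 / var[keep]
        factors[j] = 2.0 ** (np.sum(w * M[keep]) / np.sum(w))

    factors /= gmean(factors)
    return SizeFactors(
        factors, "tmm", cm.sample_ids, reference_sample=str(cm.sample_ids[ref])
    )


_DISPATCH = {
    "median": median_size_factors,
    "total": total_size_factors,
    "quantile": quantile_size_factors,
    "tmm": tmm_size_factors,
}


def size_factors(cm: CountMatrix, method: str = "median", **kwargs) -> SizeFactors:
    """Dispatch to one of the four size-factor methods by name."""
    try:
        fn = _DISPATCH[method.lower()]
    except KeyError:
        raise ValueError(f"unknown normalization method {method!r}") from None
    return fn(cm, **kwargs)


def normalize_counts(cm: CountMatrix, sf: SizeFactors) -> NormalizedCounts:
    """Normalized counts ``Y = [X / delta]``, round-half-to-even."""
    Y = np.rint(cm.counts / sf.delta[None, :]).astype(np.int64)
    matrix = CountMatrix(
        counts=Y,
        gene_ids=cm.gene_ids,
        sample_ids=cm.sample_ids,
        conditions=cm.conditions,
        subjects=cm.subjects,
        condition_labels=cm.condition_labels,
        subject_labels=cm.subject_labels,
    )
    return NormalizedCounts(matrix=matrix, size_factors=sf)


def normalize(cm: CountMatrix, method: str = "median", **kwargs) -> NormalizedCounts:
    """Convenience: compute size factors and normalize in one call."""
    return normalize_counts(cm, size_factors(cm, method, **kwargs))
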