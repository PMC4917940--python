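"""Between-condition correlation of latent expression in matched designs.

In a matched design the same subject is measured in every condition, which
correlates the latent (gamma-distributed) expressions Z across conditions.
The correlation rho_{d1 d2} is assumed common to all genes, and for each
gene the observable count correlation satisfies

    corr(Y_d1, Y_d2) = rho * mu1 * mu2 * phi
                       / sqrt((mu1 + mu1^2 phi)(mu2 + mu2^2 phi)),

so inverting the relation gene by gene and averaging over genes yields an
estimator of rho.  The per-gene sample correlation is computed over the n
subject pairs and passed through a small-sample bias correction before
rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Tuple

import numpy as np

from .data import NormalizedCounts
from .dispersion import DispersionSet
from .errors import DesignError
from .fit import ModelFit

__all__ = ["CorrelationEstimate", "estimate_rho"]

log = logging.getLogger(__name__)


@dataclass
class CorrelationEstimate:
    """Pairwise condition correlations ``rho`` (symmetric, unit diagonal)."""

    rho: np.ndarray  # (D, D)
    per_gene_r: Dict[Tuple[int, int], np.ndarray]  # corrected r per pair, NaN = skipped
    n_used: Dict[Tuple[int, int], int]
    correction: str = "olkin-pratt"

    def pair(self, d1: int, d2: int) -> float:
        """rho for conditions ``d1``, ``d2`` (1-based, order-free)."""
        return float(self.rho[d1 - 1, d2 - 1])


def _corrected_r(r: np.ndarray, n: int, correction: str) -> np.ndarray:
    """Small-sample bias correction of per-gene sample correlations.

    The Olkin–Pratt-type correction ``r (1 + (1 - r^2) / (2 (n - 3)))`` is
    applied for n >= 4; at n = 3 it is undefined and r is returned as-is.
    ``correction='none'`` disables it.
    """
    if correction == "none" or n < 4:
        return r
    if correction == "olkin-pratt":
        return r * (1.0 + (1.0 - r**2) / (2.0 * (n - 3)))
    raise ValueError(f"unknown correction {correction!r}")


def estimate_rho(
    nc: NormalizedCounts,
    fit: ModelFit,
    phi: DispersionSet,
    correction: str = "olkin-pratt",
) -> CorrelationEstimate:
    """Estimate rho_{d1 d2} for every condition pair of a matched design.

    Per pair and gene: the subject-paired sample correlation of
    ``(Y_{i d1 g}, Y_{i d2 g})``, bias-corrected, is rescaled by

        sqrt((mu1 + mu1^2 phi)(mu2 + mu2^2 phi)) / (mu1 mu2 phi)

    and averaged over genes; the average is clamped to [-1, 1].  Genes with
    zero within-pair variance, or with phi at the numerical floor (the
    rescaling divides by phi), are excluded from the average; exclusion
    counts are logged.
    """
    cm = nc.matrix
    if not cm.is_matched:
        raise DesignError("correlation estimation requires a matched design")
    n = cm.n_subjects
    if n < 3:
        raise DesignError("need at least 3 matched subjects to estimate rho")

    # (D, n, G) normalized counts aligned by subject within condition
    blocks = np.stack([b.T for b in cm.split_by_condition(nc.values)])
    D = cm.D
    usable_phi = phi.phi > phi.floor

    rho = np.eye(D)
    per_gene_r: Dict[Tuple[int, int], np.ndarray] = {}
    n_used: Dict[Tuple[int, int], int] = {}
    for d1, d2 in combinations(range(D), 2):
        Y1, Y2 = blocks[d1].astype(float), blocks[d2].astype(float)
        x = Y1 - Y1.mean(axis=0)
        y = Y2 - Y2.mean(axis=0)
        sx = np.sqrt((x**2).sum(axis=0))
        sy = np.sqrt((y**2).sum(axis=0))
        nonzero = (sx > 0) & (sy > 0)
        r = np.full(cm.G, np.nan)
        r[nonzero] = (x * y).sum(axis=0)[nonzero] / (sx[nonzero] * sy[nonzero])
        r = _corrected_r(r, n, correction)

        use = nonzero & usable_phi
        skipped = int(cm.G - use.sum())
        if skipped:
            log.info(
                "rho(%d,%d): skipped %d gene(s) with zero paired variance or "
                "floored dispersion", d1 + 1, d2 + 1, skipped,
            )
        mu1, mu2 = fit.mu_dg[d1], fit.mu_dg[d2]
        scale = np.sqrt(
            (mu1 + mu1**2 * phi.phi) * (mu2 + mu2**2 * phi.phi)
        ) / (mu1 * mu2 * phi.phi)
        value = float(np.mean(r[use] * scale[use]))
        value = float(np.clip(value, -1.0, 1.0))
        rho[d1, d2] = rho[d2, d1] = value
        per_gene_r[(d1 + 1, d2 + 1)] = r
        n_used[(d1 + 1, d2 + 1)] = int(use.sum())

    return CorrelationEstimate(rho, per_gene_r, n_used, correction)
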