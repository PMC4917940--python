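"""Variance of the per-gene score, 1-df Wald test and multiplicity adjustment.

The DE hypothesis for gene g is H_g: v_g = 0, a single degree of freedom
regardless of the number of conditions D.  Treating the grand mean, the
condition effects and u as known (they pool information across all genes,
so their variances are negligible relative to the per-gene quantities), the
delta method gives

unmatched:  var(v_g) = sum_d n_d u_d^2 (1/mu_dg + phi_g) / (sum_d n_d u_d^2)^2

matched (n_d = n): the same numerator evaluated with weights u_d^2 plus the
cross term 2 sum_{d1<d2} u_d1 u_d2 phi_g rho_{d1 d2}, all divided by
n (sum_d u_d^2)^2.  At rho = 0 the matched form reduces exactly to the
unmatched one.

The Wald statistic T_g = v_g^2 / var(v_g) is chi-squared with 1 df under
the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .correlation import CorrelationEstimate
from .dispersion import DispersionSet
from .errors import MultiDEError
from .fit import ModelFit

__all__ = [
    "TestResult",
    "var_v_unmatched",
    "var_v_matched",
    "wald_test",
    "adjust_pvalues",
    "VAR_FLOOR",
]

log = logging.getLogger(__name__)

#: lower clamp for the matched variance when a strongly negative cross term
#: (estimation noise in rho) would drive it non-positive
VAR_FLOOR = 1e-12


@dataclass
class TestResult:
    """Per-gene Wald test of H_g: v_g = 0."""

    v: np.ndarray
    var_v: np.ndarray
    T: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    adjust_method: str
    gene_ids: Optional[np.ndarray] = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.var_v)

    def n_significant(self, alpha: float = 0.05, adjusted: bool = True) -> int:
        p = self.p_adj if adjusted else self.p
        return int((p < alpha).sum())


def var_v_unmatched(fit: ModelFit, phi: DispersionSet) -> np.ndarray:
    """Plug-in variance of v_g for independent (unmatched) samples."""
    w = fit.n_d * fit.u**2
    total = w.sum()
    if total <= 0:
        raise MultiDEError("u is identically zero; variance undefined")
    return (w @ (1.0 / fit.mu_dg + phi.phi[None, :])) / total**2


def var_v_matched(
    fit: ModelFit,
    phi: DispersionSet,
    rho: CorrelationEstimate,
    floor: float = VAR_FLOOR,
) -> np.ndarray:
    """Plug-in variance of v_g for matched samples (n per condition).

    Includes the between-condition covariance through the cross term
    ``2 sum_{d1<d2} u_d1 u_d2 phi_g rho_{d1 d2}``; with u of mixed signs and
    positive rho this is negative, reflecting the efficiency gain of the
    matched design.  A non-positive result (possible under extreme rho
    estimates) is clamped at a small positive floor with a logged warning.
    """
    n_d = fit.n_d
    n = int(n_d[0])
    if not np.all(n_d == n):
        raise MultiDEError("matched variance requires equal n per condition")
    u2 = fit.u**2
    total = u2.sum()
    if total <= 0:
        raise MultiDEError("u is identically zero; variance undefined")
    main = u2 @ (1.0 / fit.mu_dg + phi.phi[None, :])
    cross_coef = 2.0 * sum(
        fit.u[d1] * fit.u[d2] * rho.rho[d1, d2]
        for d1, d2 in combinations(range(len(fit.u)), 2)
    )
    var = (main + cross_coef * phi.phi) / (n * total**2)
    bad = var <= 0
    if bad.any():
        log.warning(
            "matched variance non-positive for %d gene(s); clamped at %g",
            int(bad.sum()), floor,
        )
        var = np.maximum(var, floor)
    return var


def wald_test(
    fit: ModelFit,
    var_v: np.ndarray,
    adjust_method: str = "bh",
) -> TestResult:
    """1-df Wald test per gene with the chosen multiplicity adjustment."""
    var_v = np.asarray(var_v, dtype=float)
    if (var_v <= 0).any():
        raise MultiDEError("var_v must be positive")
    T = fit.v**2 / var_v
    p = chi2.sf(T, df=1)
    p_adj = adjust_pvalues(p, adjust_method)
    return TestResult(
        v=fit.v, var_v=var_v, T=T, p=p, p_adj=p_adj,
        adjust_method=adjust_method, gene_ids=fit.gene_ids,
    )


def adjust_pvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini–Hochberg step-up, Bonferroni, or no adjustment."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise MultiDEError("p-values must lie in [0, 1]")
    method = method.lower()
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method in ("bh", "fdr_bh"):
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")
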