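"""Scoring DE calls against simulation truth: ROC/AUC and top-N empirical FDR.

Genes are ranked by ascending p-value with ties broken by gene index
(stable), which makes every curve deterministic.  The internal multi-df
comparator is a minimal per-gene Wald-type chi-square test on the full
interaction row — the classical (D-1)-df alternative the 1-df test is
designed to beat — used only as a benchmarking baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .dispersion import DispersionSet
from .errors import MultiDEError
from .fit import ModelFit

__all__ = ["EvalReport", "roc", "empirical_fdr", "evaluate", "anova_comparator"]


@dataclass
class EvalReport:
    """ROC points, AUC and the empirical FDR of the top-N calls."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    fdr_at_topN: np.ndarray  # index N-1 = FDR among the N smallest p


def _ranking(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.lexsort((np.arange(len(p)), p))  # stable: (p, gene index)


def _de_mask(truth) -> np.ndarray:
    if hasattr(truth, "is_de"):
        return np.asarray(truth.is_de, dtype=bool)
    return np.asarray(truth, dtype=bool)


def roc(p: np.ndarray, truth) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve over the p-value ranking and its trapezoidal AUC.

    ``truth`` is a SimTruth or boolean DE mask; needs at least one DE and
    one EE gene.  Returns ``(fpr, tpr, auc)`` with the (0, 0) origin
    prepended.
    """
    is_de = _de_mask(truth)
    if is_de.all() or not is_de.any():
        raise MultiDEError("ROC needs at least one DE and one EE gene")
    order = _ranking(p)
    hits = is_de[order]
    tpr = np.concatenate([[0.0], np.cumsum(hits) / is_de.sum()])
    fpr = np.concatenate([[0.0], np.cumsum(~hits) / (~is_de).sum()])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def empirical_fdr(p: np.ndarray, truth, N_max: int | None = None) -> np.ndarray:
    """Fraction of truly EE genes among the N most significant, N = 1..N_max."""
    is_de = _de_mask(truth)
    G = len(is_de)
    N_max = G if N_max is None else N_max
    if N_max > G:
        raise MultiDEError(f"N_max {N_max} exceeds the number of genes {G}")
    order = _ranking(p)
    false = ~is_de[order][:N_max]
    return np.cumsum(false) / np.arange(1, N_max + 1)


def evaluate(p: np.ndarray, truth, N_max: int | None = None) -> EvalReport:
    fpr, tpr, auc = roc(p, truth)
    return EvalReport(fpr, tpr, auc, empirical_fdr(p, truth, N_max))


def anova_comparator(fit: ModelFit, phi: DispersionSet) -> np.ndarray:
    """(D-1)-df chi-square p-values from the unreduced interaction rows.

    The statistic sums the squared fitted interactions over conditions,
    standardized by the delta-method variance n_d^{-1}(1/mu_dg + phi_g) of
    each cell's log mean.  This is the no-dimension-reduction baseline; its
    p-values are only used to benchmark the 1-df test's ranking.
    """
    var_gamma = (1.0 / fit.mu_dg + phi.phi[None, :]) / fit.n_d[:, None]
    T = (fit.gamma**2 / var_gamma).sum(axis=0)
    return chi2.sf(T, df=len(fit.n_d) - 1)
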