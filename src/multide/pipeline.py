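"""End-to-end DE analysis: normalize -> dispersion -> fit (-> rho) -> test.

This is the composition the CLI `test` subcommand and most library users
run.  The matched branch is taken automatically when the metadata carries
subjects (and can be forced off); it adds the between-condition correlation
estimate and the matched variance formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .correlation import CorrelationEstimate, estimate_rho
from .data import CountMatrix, NormalizedCounts
from .dispersion import DispersionSet, estimate_dispersion
from .fit import ModelFit, fit as fit_model
from .inference import TestResult, var_v_matched, var_v_unmatched, wald_test
from .normalize import normalize

__all__ = ["DEResult", "run_de"]

log = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Bundle of every intermediate product of a DE run."""

    normalized: NormalizedCounts
    dispersion: DispersionSet
    fit: ModelFit
    test: TestResult
    rho: Optional[CorrelationEstimate] = None

    def table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-gene result table (v, se, T, p, p_adj, DE flag).

        ``log2fc_unit`` converts the natural-log score v to the log2 scale:
        the fitted log2 fold change between conditions d1 and d2 for gene g
        is ``(u_d1 - u_d2) * v_g / log(2)``.
        """
        t = self.test
        return pd.DataFrame(
            {
                "gene_id": t.gene_ids,
                "v": t.v,
                "log2_v": t.v / np.log(2.0),
                "se": t.se,
                "T": t.T,
                "p": t.p,
                "p_adj": t.p_adj,
                "significant": t.p_adj < alpha,
            }
        )


def run_de(
    cm: CountMatrix,
    method: str = "tmm",
    matched: Optional[bool] = None,
    prior_df: float = 100.0,
    dispersion: Optional[DispersionSet] = None,
    adjust: str = "bh",
    two_pass: bool = False,
    alpha: float = 0.05,
    reference: int = 0,
    correction: str = "olkin-pratt",
) -> DEResult:
    """Run the full DE pipeline on a count matrix.

    Parameters
    ----------
    method
        Size-factor method (median, total, quantile, tmm).
    matched
        Force matched/unmatched handling; default: matched iff the metadata
        has subjects.  Asking for matched without subjects is an error;
        subjects with ``matched=False`` are ignored with a warning.
    prior_df
        Shrinkage strength for the dispersion estimator (0 disables).
    dispersion
        Pre-computed per-gene dispersions (bypasses estimation).
    two_pass
        Refit u restricted to the first pass's BH-significant genes
        (``p_adj < alpha``), sharpening u when most genes are EE.
    """
    if matched is None:
        matched = cm.is_matched
    if matched and not cm.is_matched:
        from .errors import DesignError

        raise DesignError("matched analysis requested but metadata has no subjects")
    if not matched and cm.is_matched:
        log.warning("metadata has subjects but unmatched analysis was requested; "
                    "between-condition correlation will be ignored")

    nc = normalize(cm, method)
    phi = dispersion if dispersion is not None else estimate_dispersion(nc, prior_df)
    mf = fit_model(nc, reference=reference)

    rho = estimate_rho(nc, mf, phi, correction=correction) if matched else None

    def _test(model_fit: ModelFit) -> TestResult:
        if matched:
            var = var_v_matched(model_fit, phi, rho)
        else:
            var = var_v_unmatched(model_fit, phi)
        return wald_test(model_fit, var, adjust_method=adjust)

    result = _test(mf)
    if two_pass:
        de_set = result.p_adj < alpha
        if de_set.any():
            mf = fit_model(nc, de_set=de_set, reference=reference)
            result = _test(mf)
        else:
            log.warning("two-pass refit skipped: no significant genes in pass 1")

    return DEResult(normalized=nc, dispersion=phi, fit=mf, test=result, rho=rho)
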