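"""Two-factor log-linear model with a rank-1 interaction.

The log expected normalized count is modeled as

    log mu_dg = mu + alpha_d + beta_g + gamma_dg,   gamma_dg = u_d * v_g,

with identifiability constraints

    sum_d n_d alpha_d = 0,   sum_g beta_g = 0,
    sum_d n_d u_d = 0 and u_1 = 1,   sum_g v_g = 0.

Main effects and the full interaction gamma_dg have closed-form moment
estimators from the per-cell log means eta_dg = log(mean Y).  The rank-1
factors (u, v) minimize the weighted least squares objective

    l(u, v) = sum_dg n_d (gamma_dg - u_d v_g)^2

via alternating closed-form updates; the weights n_d reflect the asymptotic
variance of gamma_dg being proportional to 1/n_d.  Because gamma satisfies
the two centering constraints, the constraints on u and v hold automatically
at every iterate and are asserted, not imposed.

The per-gene score v_g is the quantity tested downstream: v_g = 0 means the
gene is equally expressed across all conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data import NormalizedCounts
from .errors import (
    DegenerateInteractionError,
    UnstableReferenceError,
    ZeroMeanError,
)

__all__ = [
    "ModelFit",
    "estimate_eta",
    "moment_effects",
    "wls_rank1",
    "refine_u",
    "fit",
    "rank1_svd_oracle",
]

log = logging.getLogger(__name__)


@dataclass
class ModelFit:
    """All fitted parameters of the rank-1 interaction model."""

    mu: float
    alpha: np.ndarray  # (D,)
    beta: np.ndarray  # (G,)
    gamma: np.ndarray  # (D, G)
    u: np.ndarray  # (D,), u[reference] = 1
    v: np.ndarray  # (G,)
    eta: np.ndarray  # (D, G) log cell means
    mu_dg: np.ndarray  # (D, G) cell means of Y
    n_d: np.ndarray  # (D,)
    iterations: int
    converged: bool
    objective_trace: np.ndarray
    reference: int = 0
    gene_ids: Optional[np.ndarray] = None


def estimate_eta(nc: NormalizedCounts) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell means ``mu_dg`` of normalized counts and ``eta = log mu_dg``.

    Natural logarithms are used throughout the model; any fold changes shown
    to users are converted to log2 at the interface only.
    """
    mu_dg = np.stack(
        [blk.mean(axis=1) for blk in nc.matrix.split_by_condition(nc.values)]
    )
    if (mu_dg <= 0).any():
        d, g = np.argwhere(mu_dg <= 0)[0]
        raise ZeroMeanError(
            f"zero sample mean for gene {nc.matrix.gene_ids[g]!r} in condition "
            f"{d + 1}; apply filter_genes before fitting"
        )
    return np.log(mu_dg), mu_dg


def moment_effects(
    eta: np.ndarray, n_d: Sequence[int]
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Moment estimators of the grand mean, main effects and interaction.

    mu    = sum_dg n_d eta_dg / (G sum_d n_d)
    alpha = gene-average of eta_dg minus mu
    beta  = n_d-weighted condition average of eta_dg minus mu
    gamma = eta - mu - alpha - beta

    The four centering identities hold exactly up to rounding.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("eta must be finite")
    n_d = np.asarray(n_d, dtype=float)
    D, G = eta.shape
    total = n_d.sum()
    mu = float((n_d @ eta).sum() / (G * total))
    alpha = eta.mean(axis=1) - mu
    beta = (n_d @ eta) / total - mu
    gamma = eta - mu - alpha[:, None] - beta[None, :]
    return mu, alpha, beta, gamma


def wls_rank1(
    gamma: np.ndarray,
    n_d: Sequence[int],
    max_iter: int = 500,
    tol: float = 1e-10,
    reference: int = 0,
    init: str = "svd",
    de_set: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Alternating weighted least squares for the rank-1 factors (u, v).

    Starting from v (leading right singular vector of the sqrt(n_d)-row-scaled
    gamma, or column means with ``init='means'``), iterate the closed-form
    u-update (rescaled so ``u[reference] = 1``) and v-update until the
    relative change of the objective falls below ``tol``.  The objective is
    recorded after each full cycle; it is non-increasing.

    Returns ``(u, v, objective_trace, converged)``.
    """
    gamma = np.asarray(gamma, dtype=float)
    n_d = np.asarray(n_d, dtype=float)
    D, G = gamma.shape
    if np.allclose(gamma, 0.0):
        raise DegenerateInteractionError(
            "interaction matrix is identically zero; no rank-1 factors exist"
        )
    if init == "svd":
        A = np.sqrt(n_d)[:, None] * gamma
        _, s, vt = np.linalg.svd(A, full_matrices=False)
        v = s[0] * vt[0]
    elif init == "means":
        v = gamma.mean(axis=0)
        if np.allclose(v, 0.0):  # centered columns: fall back to first row
            v = gamma[0].copy()
    else:
        raise ValueError(f"unknown init {init!r}")

    trace = []
    prev = np.inf
    converged = False
    u = np.zeros(D)
    for it in range(1, max_iter + 1):
        u = _update_u(gamma, v, reference, de_set)
        w = n_d * u**2
        v = (gamma.T @ (n_d * u)) / w.sum()
        obj = float(np.sum(n_d[:, None] * (gamma - np.outer(u, v)) ** 2))
        trace.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(1.0, prev):
            converged = True
            break
        prev = obj
    return u, v, np.asarray(trace), converged


def _update_u(
    gamma: np.ndarray,
    v: np.ndarray,
    reference: int,
    de_set: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Closed-form u-update, optionally restricted to a DE gene set S."""
    if de_set is not None:
        sel = np.asarray(de_set)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        if len(sel) == 0:
            log.warning("empty DE gene set; falling back to all genes")
            sel = None
    else:
        sel = None
    g_use = gamma if sel is None else gamma[:, sel]
    v_use = v if sel is None else v[sel]
    denom = np.sum(v_use**2)
    if denom == 0:
        raise DegenerateInteractionError("v restricted to the DE set is zero")
    u_tilde = (g_use @ v_use) / denom
    anchor = u_tilde[reference]
    if abs(anchor) < 1e-12 * max(1.0, np.abs(u_tilde).max()):
        raise UnstableReferenceError(
            f"interaction factor for reference condition {reference + 1} is "
            "numerically zero; choose another reference condition"
        )
    return u_tilde / anchor


def refine_u(
    gamma: np.ndarray,
    n_d: Sequence[int],
    v: np.ndarray,
    de_set: np.ndarray,
    reference: int = 0,
) -> np.ndarray:
    """One u-update summing only over a DE gene set S (rescaled to u_ref = 1).

    Restricting the sums to genes believed to be differentially expressed
    removes the pure-noise contribution of the (typically many) genes with
    v_g = 0.  With S = all genes this reduces to the unrestricted update.
    """
    return _update_u(np.asarray(gamma, dtype=float), np.asarray(v, float),
                     reference, de_set)


def fit(
    nc: NormalizedCounts,
    de_set: Optional[np.ndarray] = None,
    max_iter: int = 500,
    tol: float = 1e-10,
    reference: int = 0,
    init: str = "svd",
) -> ModelFit:
    """Full model fit: cell means -> moment effects -> rank-1 WLS.

    ``de_set`` (boolean mask or index array over genes) restricts the
    u-updates to a previously identified DE gene set; v is always fitted for
    every gene.
    """
    eta, mu_dg = estimate_eta(nc)
    n_d = nc.matrix.n_d
    mu, alpha, beta, gamma = moment_effects(eta, n_d)
    u, v, trace, converged = wls_rank1(
        gamma, n_d, max_iter=max_iter, tol=tol, reference=reference,
        init=init, de_set=de_set,
    )
    return ModelFit(
        mu=mu,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        u=u,
        v=v,
        eta=eta,
        mu_dg=mu_dg,
        n_d=np.asarray(n_d),
        iterations=len(trace),
        converged=converged,
        objective_trace=trace,
        reference=reference,
        gene_ids=nc.matrix.gene_ids,
    )


def rank1_svd_oracle(
    gamma: np.ndarray, n_d: Sequence[int], reference: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted best rank-1 approximation via SVD (independent of the WLS path).

    Minimizing sum_dg n_d (gamma - u_d v_g)^2 is an unweighted rank-1
    approximation of ``A = diag(sqrt(n_d)) gamma``; the solution is the
    leading singular triple, back-transformed and rescaled to u_ref = 1.
    Returns ``(u, v, objective)``.
    """
    gamma = np.asarray(gamma, dtype=float)
    n_d = np.asarray(n_d, dtype=float)
    root = np.sqrt(n_d)
    A = root[:, None] * gamma
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    u_raw = U[:, 0] / root
    v_raw = s[0] * Vt[0]
    anchor = u_raw[reference]
    if abs(anchor) < 1e-15:
        raise UnstableReferenceError("oracle reference factor is zero")
    u = u_raw / anchor
    v = v_raw * anchor
    obj = float(np.sum(n_d[:, None] * (gamma - np.outer(u, v)) ** 2))
    return u, v, obj
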