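"""Synthetic multi-condition RNA-seq counts with full ground truth.

Three generators are provided:

``simulate_rank1``
    counts from the rank-1 interaction model itself: latent expressions Z
    are gamma with mean mu_dg = exp(mu + alpha_d + beta_g + u_d v_g) and
    variance phi_g mu_dg^2, coupled across conditions (matched designs) by
    a Gaussian copula with pairwise correlations rho_{d1 d2}; observed
    counts are Poisson with mean Z * delta, so Y = [X / delta] is marginally
    negative binomial with the modeled mean and dispersion.
``simulate_saturated``
    a misspecification stress design: DE genes get a free interaction row
    gamma_dg drawn uniformly (re-centered so sum_d n_d gamma_dg = 0) that is
    not rank-1 across genes.
``spike_in_perturbation``
    a semi-synthetic design built from any real count matrix: samples are
    randomly re-assigned to conditions and a random gene subset has its
    counts multiplied by per-condition factors.

Default parameter values are the generative settings of the study the model
targets: G = 10^4 genes of which 90 % are equally expressed, grand mean
mu = 4 (natural-log scale, mean count ~55), beta_g ~ N(0, 0.25^2),
phi_g ~ Gamma(shape 5, rate 20), delta ~ LogNormal(0, 0.25^2),
rho ~ U(0.2, 0.4) for matched designs, and the fixed u_d vectors below with
n = 4 matched subjects or n_d = D + d - 1 unmatched samples.

Determinism: all draws come from one ``numpy.random.default_rng(seed)``
stream in a fixed order (beta, phi, v magnitudes, rho, delta, copula
normals, Poisson), so equal seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaincinv, ndtr

from .data import CountMatrix
from .errors import ConfigError

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_rank1",
    "simulate_saturated",
    "spike_in_perturbation",
    "MATCHED_U",
    "UNMATCHED_U",
]

#: default interaction factors u_d per number of conditions, matched designs
MATCHED_U = {
    2: (1.0, -1.0),
    3: (1.0, 0.2, -1.2),
    4: (1.0, 0.4, -0.6, -0.8),
    5: (1.0, 0.5, 0.0, -0.5, -1.0),
}

#: default u_d for unmatched designs (n_d = D + d - 1)
UNMATCHED_U = {
    2: (1.0, -2.0 / 3.0),
    3: (1.0, 3.0 / 4.0, -6.0 / 5.0),
    4: (1.0, 4.0 / 5.0, -3.0 / 6.0, -5.0 / 7.0),
    5: (1.0, 5.0 / 6.0, 3.0 / 7.0, -5.0 / 8.0, -8.0 / 9.0),
}


@dataclass
class SimConfig:
    """Generative settings; defaults are the reference study conditions."""

    D: int = 3
    design: str = "matched"
    G: int = 10_000
    n: Optional[int] = None  # matched: subjects per condition (default 4)
    n_d: Optional[Sequence[int]] = None  # unmatched: per-condition sizes
    mu: float = 4.0
    u: Optional[Sequence[float]] = None
    n_ee: Optional[int] = None  # default: 90 % of G
    n_up: Optional[int] = None  # default: 5 % of G
    n_down: Optional[int] = None
    v_scale: float = 0.32
    v_scale_is_sd: bool = False  # False: 0.32 is a variance (sd ~0.566)
    beta_sd: float = 0.25
    sizefactor_log_sd: float = 0.25
    phi_shape: float = 5.0
    phi_rate: float = 20.0
    rho_range: Tuple[float, float] = (0.2, 0.4)
    seed: int = 0
    keep_latent: bool = False

    def __post_init__(self) -> None:
        if self.D < 2:
            raise ConfigError("need at least two conditions")
        if self.design not in ("matched", "unmatched"):
            raise ConfigError(f"unknown design {self.design!r}")
        if self.n_ee is None:
            self.n_ee = int(round(0.9 * self.G))
        if self.n_up is None:
            self.n_up = (self.G - self.n_ee) // 2
        if self.n_down is None:
            self.n_down = self.G - self.n_ee - self.n_up
        if self.n_ee + self.n_up + self.n_down != self.G:
            raise ConfigError("EE + up + down gene counts must equal G")

    @property
    def sizes(self) -> np.ndarray:
        """Per-condition sample sizes n_d."""
        if self.design == "matched":
            n = 4 if self.n is None else self.n
            return np.full(self.D, n, dtype=int)
        if self.n_d is not None:
            sizes = np.asarray(self.n_d, dtype=int)
            if len(sizes) != self.D:
                raise ConfigError("n_d must have one entry per condition")
            return sizes
        return np.arange(self.D, 2 * self.D)  # n_d = D + d - 1

    def resolved_u(self) -> np.ndarray:
        table = MATCHED_U if self.design == "matched" else UNMATCHED_U
        u = self.u if self.u is not None else table.get(self.D)
        if u is None:
            raise ConfigError(f"no default u for D={self.D}; supply one")
        u = np.asarray(u, dtype=float)
        if len(u) != self.D:
            raise ConfigError("u must have one entry per condition")
        if u[0] != 1.0:
            raise ConfigError("u_1 must equal 1")
        if abs(float(self.sizes @ u)) > 1e-8 * max(1.0, np.abs(u).max()):
            raise ConfigError("u must satisfy sum_d n_d u_d = 0")
        return u

    @property
    def v_sd(self) -> float:
        return self.v_scale if self.v_scale_is_sd else float(np.sqrt(self.v_scale))


@dataclass
class SimTruth:
    """Generative parameters and DE labels accompanying simulated counts."""

    mu: float
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray  # (D, G)
    phi: np.ndarray
    delta: np.ndarray  # (N,) in sample order
    de_label: np.ndarray  # per gene: "EE", "up", "down" or "DE"
    u: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None
    rho: Optional[np.ndarray] = None  # (D, D), matched designs only
    latent: Optional[np.ndarray] = None  # (G, N) latent Z, if kept

    @property
    def mu_dg(self) -> np.ndarray:
        return np.exp(self.mu + self.alpha[:, None] + self.beta[None, :] + self.gamma)

    @property
    def is_de(self) -> np.ndarray:
        return self.de_label != "EE"

    def frame(self, gene_ids) -> pd.DataFrame:
        out = pd.DataFrame({"gene_id": gene_ids, "de_label": self.de_label,
                            "beta": self.beta, "phi": self.phi})
        if self.v is not None:
            out["v"] = self.v
        return out


def _gene_ids(G: int) -> np.ndarray:
    width = len(str(G))
    return np.array([f"g{i + 1:0{width}d}" for i in range(G)], dtype=object)


def _draw_shared(cfg: SimConfig, rng: np.random.Generator):
    """Draws common to both model-based generators, in documented order."""
    beta = rng.normal(0.0, cfg.beta_sd, cfg.G)
    phi = rng.gamma(cfg.phi_shape, 1.0 / cfg.phi_rate, cfg.G)
    mags = np.abs(rng.normal(0.0, cfg.v_sd, cfg.n_up + cfg.n_down))
    v = np.zeros(cfg.G)
    v[cfg.n_ee : cfg.n_ee + cfg.n_up] = -mags[: cfg.n_up]  # up-regulated
    v[cfg.n_ee + cfg.n_up :] = mags[cfg.n_up :]  # down-regulated
    label = np.array(
        ["EE"] * cfg.n_ee + ["up"] * cfg.n_up + ["down"] * cfg.n_down, dtype=object
    )
    rho = None
    if cfg.design == "matched":
        rho = np.eye(cfg.D)
        for d1 in range(cfg.D):
            for d2 in range(d1 + 1, cfg.D):
                rho[d1, d2] = rho[d2, d1] = rng.uniform(*cfg.rho_range)
    return beta, phi, v, label, rho


def _draw_counts(
    cfg: SimConfig,
    rng: np.random.Generator,
    mu_dg: np.ndarray,
    phi: np.ndarray,
    rho: Optional[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Latent gamma draws (copula-coupled if matched) and Poisson counts.

    Returns ``(X, delta, Z)`` with X and Z of shape (G, N), samples ordered
    condition-major (all of condition 1, then condition 2, ...; matched
    designs order subjects identically within every condition).
    """
    sizes = cfg.sizes
    N = int(sizes.sum())
    delta = rng.lognormal(0.0, cfg.sizefactor_log_sd, N)
    shape = 1.0 / phi  # gamma shape a: mean a*s = mu, var a*s^2 = phi*mu^2
    X = np.empty((cfg.G, N), dtype=np.int64)
    Z_out = np.empty((cfg.G, N)) if cfg.keep_latent else None

    if cfg.design == "matched":
        n = int(sizes[0])
        try:
            L = np.linalg.cholesky(rho)
        except np.linalg.LinAlgError:
            raise ConfigError("rho matrix is not positive definite") from None
        W = rng.standard_normal((n, cfg.G, cfg.D)) @ L.T
        U = ndtr(W)  # (n, G, D) uniform copula coordinates
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        for d in range(cfg.D):
            Z = gammaincinv(shape[None, :], U[:, :, d]) * (phi * mu_dg[d])[None, :]
            cols = slice(offsets[d], offsets[d + 1])
            X[:, cols] = rng.poisson(Z * delta[cols][:, None]).T
            if Z_out is not None:
                Z_out[:, cols] = Z.T
    else:
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        for d in range(cfg.D):
            n_d = int(sizes[d])
            Z = rng.gamma(shape[None, :], (phi * mu_dg[d])[None, :], (n_d, cfg.G))
            cols = slice(offsets[d], offsets[d + 1])
            X[:, cols] = rng.poisson(Z * delta[cols][:, None]).T
            if Z_out is not None:
                Z_out[:, cols] = Z.T
    return X, delta, Z_out


def _assemble(cfg: SimConfig, X: np.ndarray) -> CountMatrix:
    sizes = cfg.sizes
    conditions = np.repeat(np.arange(1, cfg.D + 1), sizes)
    if cfg.design == "matched":
        n = int(sizes[0])
        subjects = np.tile(np.arange(1, n + 1), cfg.D)
        sample_ids = np.array(
            [f"c{d}_s{i}" for d, i in zip(conditions, subjects)], dtype=object
        )
        subject_labels = tuple(f"s{i}" for i in range(1, n + 1))
    else:
        subjects = None
        sample_ids = np.array(
            [f"c{d}_r{i + 1}" for d in range(1, cfg.D + 1) for i in range(sizes[d - 1])],
            dtype=object,
        )
        subject_labels = ()
    return CountMatrix(
        counts=X,
        gene_ids=_gene_ids(cfg.G),
        sample_ids=sample_ids,
        conditions=conditions,
        subjects=subjects,
        condition_labels=tuple(f"c{d}" for d in range(1, cfg.D + 1)),
        subject_labels=subject_labels,
    )


def simulate_rank1(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Counts from the rank-1 interaction model (gamma_dg = u_d v_g)."""
    rng = np.random.default_rng(cfg.seed)
    u = cfg.resolved_u()
    beta, phi, v, label, rho = _draw_shared(cfg, rng)
    alpha = np.zeros(cfg.D)
    gamma = np.outer(u, v)
    mu_dg = np.exp(cfg.mu + alpha[:, None] + beta[None, :] + gamma)
    X, delta, Z = _draw_counts(cfg, rng, mu_dg, phi, rho)
    truth = SimTruth(
        mu=cfg.mu, alpha=alpha, beta=beta, gamma=gamma, phi=phi, delta=delta,
        de_label=label, u=u, v=v, rho=rho, latent=Z,
    )
    return _assemble(cfg, X), truth


def simulate_saturated(
    cfg: SimConfig, gamma_range: Tuple[float, float] = (-0.75, 0.75)
) -> tuple[CountMatrix, SimTruth]:
    """Counts from a saturated interaction model (no rank-1 structure).

    DE genes receive an interaction row drawn i.i.d. uniform on
    ``gamma_range`` and re-centered (n_d-weighted) so the identifiability
    constraint sum_d n_d gamma_dg = 0 holds and the fitted interaction
    targets a well-defined quantity.  EE genes keep gamma = 0.  The v draws
    of the shared stream are consumed (keeping draw order aligned with
    ``simulate_rank1``) but unused; DE labels come from the same gene slots.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.sizes
    beta, phi, _, label, rho = _draw_shared(cfg, rng)
    label = np.where(label == "EE", "EE", "DE")
    alpha = np.zeros(cfg.D)
    gamma = np.zeros((cfg.D, cfg.G))
    n_de = cfg.n_up + cfg.n_down
    if n_de and gamma_range[1] > gamma_range[0]:
        raw = rng.uniform(gamma_range[0], gamma_range[1], (cfg.D, n_de))
        raw -= (sizes @ raw) / sizes.sum()  # re-center per gene
        gamma[:, cfg.n_ee :] = raw
    mu_dg = np.exp(cfg.mu + alpha[:, None] + beta[None, :] + gamma)
    X, delta, Z = _draw_counts(cfg, rng, mu_dg, phi, rho)
    truth = SimTruth(
        mu=cfg.mu, alpha=alpha, beta=beta, gamma=gamma, phi=phi, delta=delta,
        de_label=label, u=None, v=None, rho=rho, latent=Z,
    )
    return _assemble(cfg, X), truth


def spike_in_perturbation(
    cm: CountMatrix,
    D: int,
    de_count: Optional[int] = None,
    de_fraction: Optional[float] = None,
    factors: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> tuple[CountMatrix, SimTruth]:
    """Semi-synthetic DE data from a real count matrix.

    Samples are randomly re-assigned to ``D`` equally sized conditions; a
    random subset of genes is declared DE and its counts in condition k are
    multiplied by ``factors[k-1]`` and rounded to the nearest integer.  The
    default factors (1.0, 1.1, 0.9) perturb the second condition up by 10 %
    and the third down by 10 %.
    """
    if cm.N % D != 0:
        raise ConfigError(f"{cm.N} samples cannot be split into {D} equal groups")
    if factors is None:
        if D != 3:
            raise ConfigError("default factors are defined for D=3 only")
        factors = (1.0, 1.1, 0.9)
    factors = np.asarray(factors, dtype=float)
    if len(factors) != D:
        raise ConfigError("need one factor per condition")
    if de_count is None:
        if de_fraction is None:
            raise ConfigError("give de_count or de_fraction")
        de_count = int(round(de_fraction * cm.G))
    if not 0 <= de_count <= cm.G:
        raise ConfigError(f"de_count {de_count} outside 0..{cm.G}")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(cm.N)
    conditions = np.empty(cm.N, dtype=np.int64)
    per = cm.N // D
    for d in range(D):
        conditions[perm[d * per : (d + 1) * per]] = d + 1
    de_genes = rng.choice(cm.G, size=de_count, replace=False)

    counts = cm.counts.astype(float)
    scale = factors[conditions - 1]  # per-sample factor
    counts[de_genes] = np.rint(counts[de_genes] * scale[None, :])
    label = np.array(["EE"] * cm.G, dtype=object)
    label[de_genes] = "DE"

    out = CountMatrix(
        counts=counts.astype(np.int64),
        gene_ids=cm.gene_ids,
        sample_ids=cm.sample_ids,
        conditions=conditions,
        subjects=None,
        condition_labels=tuple(f"c{d}" for d in range(1, D + 1)),
    )
    truth = SimTruth(
        mu=np.nan, alpha=np.zeros(D), beta=np.zeros(cm.G),
        gamma=np.log(factors)[:, None] * (label == "DE")[None, :],
        phi=np.full(cm.G, np.nan), delta=np.ones(cm.N), de_label=label,
    )
    return out, truth
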