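"""Marker-based kinship and heritability estimation.

The kinship matrix K is the covariance of the polygenic random effect in
the mixed model y = mu + g + e with g ~ N(0, sigma_g^2 K).  Two
heritability estimators are provided:

* broad-sense H^2 from a one-way random-effects ANOVA over replicated
  plants of each accession, and
* marker-based narrow-sense h^2 from REML variance components of the
  kinship model fitted to accession means.

The REML fit uses the standard spectral trick: K is eigendecomposed once
and the restricted likelihood becomes a one-dimensional function of the
variance ratio delta = sigma_e^2 / sigma_g^2, optimized on a log grid
followed by Brent refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .genotypes import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "compute_kinship",
    "broad_sense_H2",
    "narrow_sense_h2",
    "spectral_reml",
]


@dataclass
class KinshipMatrix:
    """Symmetric PSD relatedness matrix with mean(diag) = 1 scaling."""

    values: np.ndarray
    accession_ids: list[str]
    scaling: str = "standardized-meandiag1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match accession ids")

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.accession_ids, columns=self.accession_ids
        )


@dataclass
class VarianceComponents:
    """REML variance components of the single-kernel kinship model."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    h2: float
    reml_loglik: float
    at_boundary: bool = False


def compute_kinship(G: GenotypeMatrix, ridge: float = 1e-6) -> KinshipMatrix:
    """Standardized (VanRaden-type) kinship K = Z Z' / m.

    Each SNP column is centred and scaled to unit variance (missing calls
    mean-imputed); K is rescaled so that mean(diag) = 1 and a small ridge
    is added to guarantee positive definiteness.
    """
    if G.n_accessions < 2 or G.n_snps < 1:
        raise ValueError("need at least 2 accessions and 1 SNP")
    Z = G.imputed()
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    poly = sd > 0
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; kinship undefined")
    Z = (Z[:, poly] - mu[poly]) / sd[poly]
    K = Z @ Z.T / Z.shape[1]
    K *= 1.0 / np.mean(np.diag(K))
    K += ridge * np.eye(K.shape[0])
    return KinshipMatrix(values=K, accession_ids=list(G.accession_ids))


def broad_sense_H2(pheno: pd.DataFrame, value_col: str = "phi_psii") -> float:
    """Broad-sense heritability at one time point from replicate plants.

    ``pheno`` holds one row per plant with columns ``accession`` and
    ``value_col`` (already restricted to a single time point).  One-way
    random-effects ANOVA among accessions gives

        H^2 = (MS_among - MS_within) / (MS_among + (r - 1) MS_within)

    with r the harmonic-mean replicate count (robust to mild unbalance);
    the estimate is truncated to [0, 1].
    """
    groups = pheno.groupby("accession")[value_col]
    sizes = groups.size()
    if (sizes < 2).all():
        raise ValueError("broad-sense H2 needs replicated accessions")
    sizes = sizes[sizes >= 1]
    a = len(sizes)
    n_tot = int(sizes.sum())
    grand = pheno[value_col].mean()
    means = groups.mean()
    ss_among = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(
        ((pheno[value_col] - pheno["accession"].map(means)) ** 2).sum()
    )
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (n_tot - a)
    r_bar = len(sizes) / float((1.0 / sizes).sum())
    h2 = (ms_among - ms_within) / (ms_among + (r_bar - 1.0) * ms_within)
    return float(np.clip(h2, 0.0, 1.0))


def _reml_pieces(delta, lam, yt, Xt):
    w = 1.0 / (lam + delta)
    XtW = Xt * w[:, None]
    A = XtW.T @ Xt
    beta = np.linalg.solve(A, XtW.T @ yt)
    r = yt - Xt @ beta
    quad = float(r @ (w * r))
    return w, A, beta, quad


def reml_loglik(delta, lam, yt, Xt):
    """Restricted log-likelihood at variance ratio ``delta``, profiled over
    sigma_g^2 and the fixed effects (rotated data)."""
    n, p = Xt.shape
    w, A, _, quad = _reml_pieces(delta, lam, yt, Xt)
    df = n - p
    sign, logdet_A = np.linalg.slogdet(A)
    sign0, logdet_XX = np.linalg.slogdet(Xt.T @ Xt)
    return 0.5 * (
        df * np.log(df / (2.0 * np.pi))
        - df
        - df * np.log(quad)
        + np.sum(np.log(w))
        - logdet_A
        + logdet_XX
    )


def spectral_reml(
    y: np.ndarray,
    K_eig: tuple[np.ndarray, np.ndarray],
    X: np.ndarray | None = None,
    grid: tuple[float, float, int] = (-5.0, 5.0, 100),
) -> VarianceComponents:
    """REML for y = X b + g + e with g ~ N(0, sigma_g^2 K).

    ``K_eig`` is the (eigenvalues, eigenvectors) pair of K.  delta is
    located on a log-spaced grid then refined with Brent; the profile
    gives sigma_g^2 = quad / (n - p) and h^2 = 1 / (1 + delta).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    lam, U = K_eig
    n = y.shape[0]
    if X is None:
        X = np.ones((n, 1))
    yt = U.T @ y
    Xt = U.T @ X

    log_deltas = np.linspace(grid[0], grid[1], grid[2])
    lls = np.array(
        [reml_loglik(10.0**ld, lam, yt, Xt) for ld in log_deltas]
    )
    i = int(np.argmax(lls))
    at_boundary = i in (0, len(log_deltas) - 1)
    lo = log_deltas[max(i - 1, 0)]
    hi = log_deltas[min(i + 1, len(log_deltas) - 1)]
    if lo < hi:
        res = optimize.minimize_scalar(
            lambda ld: -reml_loglik(10.0**ld, lam, yt, Xt),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        log_delta = float(res.x)
        ll = -float(res.fun)
        if ll < lls[i]:
            log_delta, ll = float(log_deltas[i]), float(lls[i])
    else:
        log_delta, ll = float(log_deltas[i]), float(lls[i])
    delta = 10.0**log_delta
    _, _, _, quad = _reml_pieces(delta, lam, yt, Xt)
    sigma_g2 = quad / (n - X.shape[1])
    sigma_e2 = delta * sigma_g2
    return VarianceComponents(
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        delta=float(delta),
        h2=float(1.0 / (1.0 + delta)),
        reml_loglik=float(ll),
        at_boundary=at_boundary,
    )


def narrow_sense_h2(
    y: np.ndarray | pd.Series, K: KinshipMatrix
) -> VarianceComponents:
    """Marker-based narrow-sense heritability of accession means.

    Fits y = mu + g + e, g ~ N(0, sigma_g^2 K), by spectral REML and
    returns the variance components with h^2 = sigma_g^2 /
    (sigma_g^2 + sigma_e^2).
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != K.n:
        raise ValueError("phenotype length does not match kinship")
    lam, U = np.linalg.eigh(K.values)
    return spectral_reml(y, (lam, U))
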