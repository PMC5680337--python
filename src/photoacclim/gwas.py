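"""Per-time-point single-trait mixed-model association scan.

The scan fits the kinship mixed model y = mu + s b + g + e to accession
means.  In the default ``approx`` mode the variance ratio delta is
estimated once under the null (no SNP) and held fixed for every SNP:
phenotype, intercept and SNP are rotated to the kinship eigenbasis,
weighted by (lambda_i + delta)^(-1/2), and each SNP is tested by weighted
least squares — the classic EMMAX approximation.  ``exact`` mode
re-estimates delta per SNP by REML.

Two test statistics are offered: an F test with (1, n-2) degrees of
freedom using the per-SNP residual variance (default; better calibrated
at moderate n) and a Wald chi-square using the null-model variance
(the statistic to which the multi-trait scan reduces for one trait).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .kinship import KinshipMatrix, VarianceComponents, narrow_sense_h2, spectral_reml

__all__ = [
    "ScanResult",
    "maf_filter",
    "fit_null",
    "gwas_scan",
    "genomic_inflation",
]

P_FLOOR = 1e-300


@dataclass
class ScanResult:
    """Per-SNP association results for one trait / time point."""

    table: pd.DataFrame
    trait: str
    n: int
    delta: float
    mode: str

    @property
    def neglog10p(self) -> np.ndarray:
        return self.table["neglog10p"].to_numpy()


def maf_filter(G: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Retain SNPs with minor-allele frequency >= ``maf_min`` on
    non-missing calls, preserving order."""
    if not 0.0 < maf_min <= 0.5:
        raise ValueError("maf_min must be in (0, 0.5]")
    keep = np.where(G.maf() >= maf_min)[0]
    return G.take_snps(keep)


def fit_null(y: np.ndarray, K: KinshipMatrix) -> VarianceComponents:
    """Null-model variance components (no SNP effect); alias of the
    narrow-sense heritability REML fit."""
    return narrow_sense_h2(y, K)


def gwas_scan(
    y: np.ndarray | pd.Series,
    G: GenotypeMatrix,
    K: KinshipMatrix,
    mode: str = "approx",
    stat: str = "f",
    trait: str = "phi_psii",
    K_eig: tuple[np.ndarray, np.ndarray] | None = None,
    null: VarianceComponents | None = None,
) -> ScanResult:
    """Mixed-model association scan of one trait against all SNPs.

    ``G`` should already be MAF-filtered; missing dosages are
    mean-imputed per SNP so n is constant across SNPs.  A precomputed
    eigendecomposition of K and/or null fit can be passed to amortize
    repeated scans on the same panel.
    """
    if mode not in ("approx", "exact"):
        raise ValueError("mode must be 'approx' or 'exact'")
    if stat not in ("f", "chi2"):
        raise ValueError("stat must be 'f' or 'chi2'")
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n != K.n or n != G.n_accessions:
        raise ValueError("y, G and K are not conformable")
    if K_eig is None:
        lam, U = np.linalg.eigh(K.values)
    else:
        lam, U = K_eig
    if null is None:
        null = spectral_reml(y, (lam, U))
    delta = null.delta

    X = G.imputed()
    yt = U.T @ y
    ones_t = U.T @ np.ones(n)
    St = U.T @ X

    if mode == "approx":
        w = 1.0 / (lam + delta)
        sw = np.sqrt(w)
        ys = sw * yt
        x0 = sw * ones_t
        S = sw[:, None] * St
        # residualize on the (transformed) intercept
        x0x0 = x0 @ x0
        yr = ys - x0 * (x0 @ ys) / x0x0
        Sr = S - np.outer(x0, (x0 @ S) / x0x0)
        sxx = np.einsum("ij,ij->j", Sr, Sr)
        sxy = Sr.T @ yr
        syy = yr @ yr
        ok = sxx > 1e-12 * max(x0x0, 1.0)
        beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
        if stat == "f":
            rss = np.maximum(syy - beta * sxy, 0.0)
            dof = n - 2
            sigma2 = rss / dof
            fstat = np.where(ok & (sigma2 > 0), beta * sxy / np.where(sigma2 > 0, sigma2, 1.0), 0.0)
            p = stats.f.sf(fstat, 1, dof)
            se = np.sqrt(np.where(ok, sigma2 / np.where(ok, sxx, 1.0), np.nan))
            statistic = fstat
        else:
            sigma_g2 = null.sigma_g2
            wald = np.where(ok, beta**2 * sxx / sigma_g2, 0.0)
            p = stats.chi2.sf(wald, 1)
            se = np.sqrt(np.where(ok, sigma_g2 / np.where(ok, sxx, 1.0), np.nan))
            statistic = wald
        p = np.where(ok, p, 1.0)
        deltas = np.full(G.n_snps, delta)
    else:
        beta = np.empty(G.n_snps)
        se = np.empty(G.n_snps)
        statistic = np.empty(G.n_snps)
        p = np.empty(G.n_snps)
        deltas = np.empty(G.n_snps)
        ok = np.ones(G.n_snps, dtype=bool)
        for j in range(G.n_snps):
            Xj = np.column_stack([np.ones(n), X[:, j]])
            if np.std(X[:, j]) == 0:
                ok[j] = False
                beta[j], se[j], statistic[j], p[j], deltas[j] = 0, np.nan, 0, 1, delta
                continue
            vc = spectral_reml(y, (lam, U), X=Xj)
            deltas[j] = vc.delta
            w = 1.0 / (lam + vc.delta)
            Xt = np.column_stack([ones_t, St[:, j]])
            A = (Xt * w[:, None]).T @ Xt
            b = np.linalg.solve(A, (Xt * w[:, None]).T @ yt)
            r = yt - Xt @ b
            sigma2 = float(r @ (w * r)) / (n - 2)
            cov = sigma2 * np.linalg.inv(A)
            beta[j] = b[1]
            se[j] = np.sqrt(cov[1, 1])
            statistic[j] = (b[1] / se[j]) ** 2
            p[j] = stats.f.sf(statistic[j], 1, n - 2)

    p = np.clip(p, P_FLOOR, 1.0)
    table = pd.DataFrame(
        {
            "chrom": G.chrom,
            "pos": G.pos,
            "snp_id": G.snp_ids,
            "beta": beta,
            "se": se,
            "statistic": statistic,
            "p": p,
            "neglog10p": -np.log10(p),
            "tested": ok,
        }
    )
    return ScanResult(table=table, trait=trait, n=n, delta=delta, mode=mode)


def genomic_inflation(pvals: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Genomic inflation factor and QQ-plot coordinates.

    lambda_GC is the median association chi-square over the theoretical
    null median (chi2_1 at 0.5 ~ 0.4549).  QQ coordinates pair sorted
    observed -log10 p with uniform quantiles i/(n+1).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 p-values")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
    ps = np.sort(p)
    n = ps.size
    expected = np.arange(1, n + 1) / (n + 1.0)
    qq = pd.DataFrame(
        {
            "expected_neglog10p": -np.log10(expected),
            "observed_neglog10p": -np.log10(ps),
        }
    )
    return lam, qq
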