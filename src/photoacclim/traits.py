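"""Derived traits and the multi-trait mixed-model (MTMM) scan.

Three routes condense the Phi_PSII time series into GWAS traits:

* standardized genotypic means of the HL time points,
* their leading principal components, and
* acclimation-curve parameters (maximum cross-day slope, early recovery,
  late recovery) computed per plant and averaged per accession.

The MTMM jointly tests a SNP against several correlated traits under
vec(Y) ~ N(mu, Vg (x) K + Ve (x) I): the trait covariance splits into a
genetic part proportional to kinship and an environmental part.  The two
covariances are estimated once under the null by REML on the kinship
eigenbasis; each SNP then gets a generalized-least-squares effect vector
and a Wald chi-square with one degree of freedom per trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix
from .kinship import KinshipMatrix, spectral_reml
from .schedule import MeasurementSchedule, default_schedule

__all__ = [
    "genotypic_means",
    "PCATraits",
    "pc_traits",
    "curve_parameters",
    "MtmmFit",
    "mtmm_scan",
]


def genotypic_means(
    pheno: pd.DataFrame,
    phase: str = "HL",
    standardize: bool = True,
) -> pd.DataFrame:
    """Accession x time-point matrix of mean Phi_PSII for one phase.

    Columns are labelled ``d<day>s<slot>`` in schedule order.  With
    ``standardize`` each column is z-scored (mean 0, variance 1), the
    form used as input for principal-component traits.
    """
    sub = pheno[pheno["phase"] == phase] if phase != "all" else pheno
    if sub.empty:
        raise ValueError(f"no records in phase {phase!r}")
    sub = sub.assign(tp=("d" + sub["day"].astype(str) + "s" + sub["slot"].astype(str)))
    order = sub.drop_duplicates(["day", "slot"]).sort_values(["day", "slot"])["tp"]
    wide = sub.pivot_table(
        index="accession", columns="tp", values="phi_psii", aggfunc="mean"
    )[list(order)]
    if wide.isna().any().any():
        missing = [
            f"{acc}:{tp}"
            for acc, row in wide.iterrows()
            for tp, v in row.items()
            if pd.isna(v)
        ]
        raise ValueError(f"accessions missing time points: {missing[:10]}")
    if standardize:
        wide = (wide - wide.mean()) / wide.std(ddof=1)
    wide.columns.name = None
    return wide


@dataclass
class PCATraits:
    """Principal-component scores of a trait matrix, with loadings."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pc_traits(T: pd.DataFrame, k: int = 4) -> PCATraits:
    """First ``k`` principal-component traits of a standardized matrix.

    Scores come from the SVD of the column-centred matrix; each
    component's sign is fixed so the largest-magnitude loading is
    positive, making results reproducible across SVD implementations.
    """
    if k > min(T.shape[0] - 1, T.shape[1]):
        raise ValueError("k exceeds the possible number of components")
    Xc = T.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if rank < k:
        raise ValueError(f"matrix rank {rank} < requested k={k}")
    flip = np.sign(Vt[np.arange(len(s)), np.argmax(np.abs(Vt), axis=1)])
    U, Vt = U * flip, Vt * flip[:, None]
    scores = pd.DataFrame(
        (U * s)[:, :k], index=T.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    loadings = pd.DataFrame(
        Vt[:k].T, index=T.columns, columns=scores.columns
    )
    evr = (s**2) / np.sum(s**2)
    return PCATraits(scores=scores, loadings=loadings, explained_variance_ratio=evr[:k])


def curve_parameters(
    pheno: pd.DataFrame,
    schedule: MeasurementSchedule | None = None,
    per_accession: bool = True,
) -> pd.DataFrame:
    """Acclimation-curve parameters per plant, then accession means.

    From the HL time points of each plant:

    * ``max_slope`` — the largest (Phi(t2) - Phi(t1)) / (t2 - t1) over
      all HL pairs t1 < t2 lying on *different* days, time in hours
      since the HL onset;
    * ``early_recovery`` — the largest Phi on HL day 2 minus the lowest
      Phi on HL day 1;
    * ``late_recovery`` — the largest Phi on HL days 3-4 minus the
      largest Phi on HL day 2.
    """
    if schedule is None:
        schedule = default_schedule()
    hl_tps = [tp for tp in schedule if tp.phase == "HL"]
    hl_days = sorted({schedule.hl_day_index(tp) for tp in hl_tps})
    if len(hl_days) < 2:
        raise ValueError("need at least two HL days for curve parameters")
    hours = {
        (tp.day, tp.slot): schedule.hours_since_hl_onset(tp) for tp in hl_tps
    }
    hl_day = {(tp.day, tp.slot): schedule.hl_day_index(tp) for tp in hl_tps}

    sub = pheno[pheno["phase"] == "HL"]
    rows = []
    for (acc, rep), grp in sub.groupby(["accession", "replicate"], sort=True):
        key = list(zip(grp["day"], grp["slot"]))
        t = np.array([hours[k] for k in key])
        d = np.array([hl_day[k] for k in key])
        v = grp["phi_psii"].to_numpy(dtype=float)
        present = set(d)
        needed = set(hl_days)
        if not needed <= present:
            raise ValueError(
                f"plant {acc}/{rep} missing HL day(s) {sorted(needed - present)}"
            )
        # max cross-day slope
        dt = t[None, :] - t[:, None]
        dv = v[None, :] - v[:, None]
        cross = (d[None, :] != d[:, None]) & (dt > 0)
        max_slope = float(np.max(dv[cross] / dt[cross]))
        early = float(v[d == 2].max() - v[d == 1].min())
        late_days = (d >= 3) & (d <= hl_days[-1])
        late = float(v[late_days].max() - v[d == 2].max()) if late_days.any() else np.nan
        rows.append((acc, rep, max_slope, early, late))
    per_plant = pd.DataFrame(
        rows,
        columns=["accession", "replicate", "max_slope", "early_recovery", "late_recovery"],
    )
    if not per_accession:
        return per_plant
    return (
        per_plant.groupby("accession")[["max_slope", "early_recovery", "late_recovery"]]
        .mean()
        .sort_index()
    )


# ---------------------------------------------------------------------------
# multi-trait mixed model


@dataclass
class MtmmFit:
    """Null covariances and per-SNP joint tests of the MTMM."""

    table: pd.DataFrame
    Vg: np.ndarray
    Ve: np.ndarray
    traits: list[str]
    reml_loglik: float
    n_iter: int


def _pack(L: np.ndarray) -> np.ndarray:
    p = L.shape[0]
    idx = np.tril_indices(p)
    v = L[idx].copy()
    diag = np.arange(p)
    dpos = np.searchsorted(np.ravel_multi_index(idx, (p, p)), diag * p + diag)
    v[dpos] = np.log(np.maximum(L[diag, diag], 1e-12))
    return v


def _unpack(v: np.ndarray, p: int) -> np.ndarray:
    L = np.zeros((p, p))
    idx = np.tril_indices(p)
    L[idx] = v
    d = np.arange(p)
    L[d, d] = np.exp(np.clip(np.diag(L), -30, 30))
    return L


def _mtmm_negloglik(params, lam, Yt, x0, p):
    m = p * (p + 1) // 2
    Lg = _unpack(params[:m], p)
    Le = _unpack(params[m:], p)
    Vg = Lg @ Lg.T
    Ve = Le @ Le.T
    Sig = lam[:, None, None] * Vg[None] + Ve[None]  # (n, p, p)
    try:
        C = np.linalg.cholesky(Sig)
    except np.linalg.LinAlgError:
        return 1e30
    logdet = 2.0 * np.sum(np.log(np.einsum("ijj->ij", C)))
    Sinv = np.linalg.inv(Sig)
    A = np.einsum("i,ijk->jk", x0**2, Sinv)
    b = np.einsum("i,ijk,ik->j", x0, Sinv, Yt)
    mu = np.linalg.solve(A, b)
    R = Yt - np.outer(x0, mu)
    quad = np.einsum("ij,ijk,ik->", R, Sinv, R)
    sgnA, logdetA = np.linalg.slogdet(A)
    if sgnA <= 0:
        return 1e30
    return 0.5 * (logdet + logdetA + quad)


def fit_mtmm_null(
    Y: np.ndarray,
    lam: np.ndarray,
    U: np.ndarray,
    max_iter: int = 2000,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """REML fit of vec(Y) ~ N(1 mu', Vg (x) K + Ve (x) I) on the
    eigenbasis of K, by quasi-Newton over Cholesky factors."""
    n, p = Y.shape
    Yt = U.T @ Y
    x0 = U.T @ np.ones(n)
    S = np.cov(Y.T, ddof=1).reshape(p, p)
    L0 = np.linalg.cholesky(S / 2.0 + 1e-8 * np.eye(p))
    start = np.concatenate([_pack(L0), _pack(L0)])
    res = optimize.minimize(
        _mtmm_negloglik,
        start,
        args=(lam, Yt, x0, p),
        method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-10, "fatol": 1e-12},
    )
    res2 = optimize.minimize(
        _mtmm_negloglik,
        res.x,
        args=(lam, Yt, x0, p),
        method="Powell",
        options={"maxiter": max_iter},
    )
    best = res2 if res2.fun <= res.fun else res
    if not (res.success or res2.success):
        raise RuntimeError(
            f"MTMM covariance estimation did not converge "
            f"({res.nit}+{res2.nit} iterations, f={best.fun:.6g})"
        )
    m = p * (p + 1) // 2
    Lg = _unpack(best.x[:m], p)
    Le = _unpack(best.x[m:], p)
    return Lg @ Lg.T, Le @ Le.T, -float(best.fun), int(res.nit + res2.nit)


def mtmm_scan(
    T: pd.DataFrame,
    G: GenotypeMatrix,
    K: KinshipMatrix,
    K_eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> MtmmFit:
    """Multi-trait mixed-model scan: joint Wald test of a SNP on all traits.

    The null covariances (Vg, Ve) are fitted once; each SNP's p-vector of
    effects is then estimated by GLS with those covariances fixed and
    tested against chi-square with one degree of freedom per trait.  For
    a single trait this reduces exactly to the single-trait scan's Wald
    statistic.
    """
    Y = T.to_numpy(dtype=float)
    n, p = Y.shape
    if p > 6:
        raise ValueError("MTMM is limited to at most 6 traits")
    if n != K.n or n != G.n_accessions:
        raise ValueError("traits, G and K are not conformable")
    if K_eig is None:
        lam, U = np.linalg.eigh(K.values)
    else:
        lam, U = K_eig

    if p == 1:
        vc = spectral_reml(Y[:, 0], (lam, U))
        Vg = np.array([[vc.sigma_g2]])
        Ve = np.array([[vc.sigma_e2]])
        ll, n_iter = vc.reml_loglik, 0
    else:
        Vg, Ve, ll, n_iter = fit_mtmm_null(Y, lam, U)

    Yt = U.T @ Y
    x0 = U.T @ np.ones(n)
    St = U.T @ G.imputed()  # (n, m)
    Sig = lam[:, None, None] * Vg[None] + Ve[None]
    Sinv = np.linalg.inv(Sig)  # (n, p, p)

    A00 = np.einsum("i,ijk->jk", x0**2, Sinv)
    Sy = np.einsum("ijk,ik->ij", Sinv, Yt)  # (n, p)
    v0 = x0 @ Sy  # (p,)

    m = St.shape[1]
    A01 = np.einsum("i,im,ijk->mjk", x0, St, Sinv)  # (m, p, p)
    A11 = np.einsum("im,ijk->mjk", St**2, Sinv)
    v1 = St.T @ Sy  # (m, p)

    M = np.empty((m, 2 * p, 2 * p))
    M[:, :p, :p] = A00[None]
    M[:, :p, p:] = A01
    M[:, p:, :p] = A01
    M[:, p:, p:] = A11
    rhs = np.concatenate([np.broadcast_to(v0, (m, p)), v1], axis=1)

    wald = np.empty(m)
    betas = np.empty((m, p))
    ok = np.ones(m, dtype=bool)
    for j in range(m):
        try:
            Minv = np.linalg.inv(M[j])
            theta = Minv @ rhs[j]
            b = theta[p:]
            cov_bb = Minv[p:, p:]
            wald[j] = float(b @ np.linalg.solve(cov_bb, b))
            betas[j] = b
        except np.linalg.LinAlgError:
            ok[j] = False
            wald[j] = 0.0
            betas[j] = 0.0
    pvals = np.where(ok, stats.chi2.sf(wald, df=p), 1.0)
    pvals = np.clip(pvals, 1e-300, 1.0)
    table = pd.DataFrame(
        {
            "chrom": G.chrom,
            "pos": G.pos,
            "snp_id": G.snp_ids,
            "wald": wald,
            "df": p,
            "p": pvals,
            "neglog10p": -np.log10(pvals),
            "tested": ok,
        }
    )
    for i, name in enumerate(T.columns):
        table[f"beta_{name}"] = betas[:, i]
    return MtmmFit(
        table=table, Vg=Vg, Ve=Ve, traits=list(T.columns), reml_loglik=ll, n_iter=n_iter
    )
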