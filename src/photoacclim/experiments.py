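"""Desk-scale validation experiments for the whole pipeline.

Each function runs a seeded Monte-Carlo experiment that probes one
statistical property of the method on synthetic data: type-I error
calibration of the mixed-model scan, heritability recovery across the
LL/HL phases, power and temporal classification of planted QTLs, and
power of the quantitative-complementation ANOVA.  They return plain
dicts of summary numbers and are used by the acceptance machinery and
the test suite.
"""

from __future__ import annotations

import numpy as np

from .followup import quantitative_complementation_anova, qpcr_fold_change
from .genotypes import GenotypeMatrix, simulate_genotypes
from .gwas import genomic_inflation, gwas_scan
from .kinship import compute_kinship, spectral_reml
from .qtl import SignificanceGrid, call_and_classify
from .schedule import default_schedule
from .simulate import (
    QtlSpec,
    qtl_effect_for_pve,
    simulate_f1_complementation,
    simulate_phenotypes,
    simulate_qpcr,
)
from .traits import genotypic_means

__all__ = [
    "null_calibration",
    "heritability_recovery",
    "planted_qtl_recovery",
    "complementation_power",
    "qpcr_recovery",
]

# accession-mean phenotypic variances of the default generator
BG_VAR = {"LL": 4e-4, "HL": 2.5e-3}


def _panel(seed: int, n_accessions: int = 300, n_snps: int = 1000):
    G = simulate_genotypes(
        n_accessions, n_snps, n_subpops=3, fst=0.1, seed=seed
    )
    K = compute_kinship(G)
    lam, U = np.linalg.eigh(K.values)
    return G, K, (lam, U)


def null_calibration(
    seed: int,
    n_accessions: int = 300,
    n_snps: int = 1000,
    n_permutations: int = 20,
    alpha: float = 0.05,
) -> dict:
    """Type-I error and genomic inflation under permuted phenotypes.

    The phenotype (one HL accession-mean trait) is permuted across
    accessions, destroying both SNP and kinship association; the scan's
    p-values should then be uniform.
    """
    G, K, eig = _panel(seed, n_accessions, n_snps)
    pheno = simulate_phenotypes(G, K, h2_ll=0.05, h2_hl=0.4, seed=seed + 1)
    y = (
        genotypic_means(pheno, phase="all", standardize=False)
        .loc[G.accession_ids]["d4s2"]
        .to_numpy()
    )
    rng = np.random.default_rng(seed + 2)
    pvals = []
    for _ in range(n_permutations):
        yp = rng.permutation(y)
        res = gwas_scan(yp, G, K, K_eig=eig)
        pvals.append(res.table["p"].to_numpy())
    p = np.concatenate(pvals)
    lam_gc, _ = genomic_inflation(p)
    return {
        "type1_error": float((p < alpha).mean()),
        "lambda_gc": lam_gc,
        "n_tests": int(p.size),
    }


def heritability_recovery(
    seed: int,
    n_sims: int = 100,
    n_accessions: int = 300,
    n_snps: int = 2000,
    h2_hl: float = 0.4,
) -> dict:
    """Recover phase-specific narrow-sense heritability from the generator.

    LL is simulated with zero heritability and HL with ``h2_hl``; the
    REML estimate is taken on accession means of one representative time
    point per phase, mirroring the near-zero-before-stress /
    substantial-after-stress pattern.
    """
    G, K, eig = _panel(seed, n_accessions, n_snps)
    h2_hl_hat, h2_ll_hat = [], []
    for s in range(n_sims):
        pheno = simulate_phenotypes(
            G, K, h2_ll=0.0, h2_hl=h2_hl, seed=seed + 1000 + s
        )
        means = (
            genotypic_means(pheno, phase="all", standardize=False)
            .loc[G.accession_ids]
        )
        h2_hl_hat.append(spectral_reml(means["d4s2"].to_numpy(), eig).h2)
        h2_ll_hat.append(spectral_reml(means["d1s2"].to_numpy(), eig).h2)
    return {
        "true_h2_hl": h2_hl,
        "mean_h2_hl": float(np.mean(h2_hl_hat)),
        "median_h2_ll": float(np.median(h2_ll_hat)),
        "n_sims": n_sims,
    }


PLANTED_CLASSES = ("LL-only", "early-HL", "late-HL", "constitutive")
EXPECTED_INTERVAL_CLASS = {
    "LL-only": "LL",
    "early-HL": "earlyHL",
    "late-HL": "lateHL",
    "constitutive": "LL+HL",
}


def planted_qtl_recovery(
    seed: int,
    n_sims: int = 50,
    n_accessions: int = 300,
    n_snps: int = 2000,
    pve: float = 0.15,
    threshold: float = 4.0,
    min_recurrence: int = 3,
) -> dict:
    """Power and temporal classification of one planted QTL per class.

    Four QTLs (one per temporal class, on different chromosomes) each
    explain ``pve`` of the accession-mean variance of their active
    phase.  Power counts runs where the planted SNP reaches the
    -log10 p threshold at >= ``min_recurrence`` active-phase time
    points; classification accuracy is scored on the merged interval
    containing the planted SNP.
    """
    sched = default_schedule()
    G, K, eig = _panel(seed, n_accessions, n_snps)
    per_chrom = n_snps // 5
    power = dict.fromkeys(PLANTED_CLASSES, 0)
    detected = dict.fromkeys(PLANTED_CLASSES, 0)
    correct = dict.fromkeys(PLANTED_CLASSES, 0)
    snp_rng = np.random.default_rng(seed + 77)
    for s in range(n_sims):
        # draw the causal SNP per class anew each replicate (one per
        # chromosome so the 100-kb windows cannot merge): power is then
        # an average over loci, not a property of one arbitrary SNP
        snp_idx = [
            int(snp_rng.integers(c * per_chrom, (c + 1) * per_chrom))
            for c in range(4)
        ]
        qtls = [
            QtlSpec(
                snp_index=i,
                temporal_class=c,
                effect=qtl_effect_for_pve(
                    G, i, pve, BG_VAR["LL" if c == "LL-only" else "HL"]
                ),
            )
            for i, c in zip(snp_idx, PLANTED_CLASSES)
        ]
        pheno = simulate_phenotypes(
            G, K, sched, qtls=qtls, h2_ll=0.05, h2_hl=0.4,
            seed=seed + 5000 + s,
        )
        means = (
            genotypic_means(pheno, phase="all", standardize=False)
            .loc[G.accession_ids]
        )
        mats = [
            gwas_scan(means[lab].to_numpy(), G, K, K_eig=eig)
            .table["neglog10p"].to_numpy()
            for lab in sched.labels()
        ]
        grid = SignificanceGrid(np.column_stack(mats), G.chrom, G.pos, sched)
        for q, c in zip(qtls, PLANTED_CLASSES):
            row = grid.neglog10p[q.snp_index]
            idx = sched.ll_indices if c == "LL-only" else sched.hl_indices
            if (row[idx] >= threshold).sum() >= min_recurrence:
                power[c] += 1
        intervals = call_and_classify(
            grid, threshold=threshold, min_recurrence=min_recurrence
        )
        for q, c in zip(qtls, PLANTED_CLASSES):
            pos, ch = G.pos[q.snp_index], G.chrom[q.snp_index]
            for iv in intervals:
                if iv.chrom == ch and iv.start <= pos <= iv.end:
                    detected[c] += 1
                    if iv.temporal_class == EXPECTED_INTERVAL_CLASS[c]:
                        correct[c] += 1
                    break
    min_power = min(power[c] / n_sims for c in PLANTED_CLASSES)
    total_detected = sum(detected.values())
    class_accuracy = (
        sum(correct.values()) / total_detected if total_detected else 0.0
    )
    return {
        "n_sims": n_sims,
        "power_per_class": {c: power[c] / n_sims for c in PLANTED_CLASSES},
        "min_power": float(min_power),
        "class_accuracy": float(class_accuracy),
    }


def complementation_power(
    seed: int,
    n_runs: int = 200,
    interaction: float = 0.05,
    noise_sd: float = 0.01,
    n_per_cross: int = 16,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the maternal x allele interaction test."""
    rejections = 0
    for s in range(n_runs):
        f1 = simulate_f1_complementation(
            allele_effects={"A": 0.0, "B": 0.02},
            interaction=interaction,
            noise_sd=noise_sd,
            n_per_cross=n_per_cross,
            seed=seed + s,
        )
        res = quantitative_complementation_anova(f1, alpha=alpha)
        rejections += int(res.significant)
    return {"power": rejections / n_runs, "n_runs": n_runs}


def qpcr_recovery(
    seed: int,
    n_runs: int = 100,
    true_fold: float = 2.0,
    ct_noise_sd: float = 0.1,
) -> dict:
    """Mean recovered HL/LL fold change across noisy qPCR simulations."""
    folds = []
    for s in range(n_runs):
        q = simulate_qpcr(
            {"gt1": {"YS1": true_fold}}, ct_noise_sd=ct_noise_sd,
            seed=seed + s,
        )
        f, _ = qpcr_fold_change(q)
        folds.append(f["fold_change"].mean())
    return {
        "true_fold": true_fold,
        "mean_recovered_fold": float(np.mean(folds)),
        "n_runs": n_runs,
    }
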