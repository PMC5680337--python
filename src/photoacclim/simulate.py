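"""Synthetic phenotype, annotation, cross and qPCR data generators.

These generators emulate the statistical structure of a diversity-panel
acclimation experiment: a kinship-structured polygenic background whose
heritability differs between the LL and HL phases, planted QTLs with
distinct temporal effect profiles, a piecewise baseline acclimation curve,
non-overlapping gene annotations with evidence attributes, a 2x2
quantitative-complementation F1 design, and qPCR Ct tables normalized to
two reference genes.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .kinship import KinshipMatrix
from .schedule import MeasurementSchedule, TimePoint, default_schedule

__all__ = [
    "QtlSpec",
    "baseline_curve",
    "qtl_effect_for_pve",
    "simulate_phenotypes",
    "simulate_gene_table",
    "simulate_f1_complementation",
    "simulate_qpcr",
    "PhenotypeStats",
]

TEMPORAL_CLASSES = ("LL-only", "early-HL", "late-HL", "constitutive")


@dataclass(frozen=True)
class QtlSpec:
    """A planted QTL: which SNP, when it acts, and how strongly.

    ``temporal_class`` selects the active time points: ``LL-only`` (the LL
    phase), ``early-HL`` (HL days 1..split), ``late-HL`` (HL days
    split+1..end), ``constitutive`` (all points).  ``effect`` is the
    additive effect in Phi_PSII units per alternate-allele copy, applied
    at active time points and exactly zero elsewhere.
    """

    snp_index: int
    temporal_class: str
    effect: float
    hl_day_split: int = 2

    def active_mask(self, schedule: MeasurementSchedule) -> np.ndarray:
        if self.temporal_class not in TEMPORAL_CLASSES:
            raise ValueError(f"unknown temporal class {self.temporal_class!r}")
        mask = np.zeros(len(schedule), dtype=bool)
        for i, tp in enumerate(schedule):
            if self.temporal_class == "constitutive":
                mask[i] = True
            elif self.temporal_class == "LL-only":
                mask[i] = tp.phase == "LL"
            elif tp.phase == "HL":
                d = schedule.hl_day_index(tp)
                if self.temporal_class == "early-HL":
                    mask[i] = d <= self.hl_day_split
                else:
                    mask[i] = d > self.hl_day_split
        return mask


def baseline_curve(
    schedule: MeasurementSchedule,
    ll_level: float = 0.78,
    hl_drop: float = 0.22,
    recovery_fraction: float = 0.6,
    recovery_halflife_h: float = 30.0,
    within_day_dip: float = 0.01,
) -> np.ndarray:
    """Piecewise population-mean acclimation curve mu(t).

    Constant at ``ll_level`` in LL; at HL onset Phi_PSII drops by
    ``hl_drop`` and then recovers a fraction ``recovery_fraction`` of the
    drop with exponential saturation (half-life in hours since onset).
    A small dip after the first slot of each day mimics the within-day
    depression at higher midday irradiance.
    """
    mu = np.empty(len(schedule))
    for i, tp in enumerate(schedule):
        if tp.phase == "LL":
            mu[i] = ll_level
        else:
            t = schedule.hours_since_hl_onset(tp)
            rec = recovery_fraction * (1.0 - 0.5 ** (t / recovery_halflife_h))
            mu[i] = ll_level - hl_drop * (1.0 - rec)
        if tp.slot > 1:
            mu[i] -= within_day_dip
    return mu


def qtl_effect_for_pve(
    G: GenotypeMatrix,
    snp_index: int,
    pve: float,
    background_var: float,
) -> float:
    """Per-allele effect so a QTL explains ``pve`` of accession-mean variance.

    ``background_var`` is the accession-mean phenotypic variance without
    the QTL (polygenic plus residual); the QTL variance a^2 Var(x) is set
    to pve/(1-pve) times it, so it accounts for ``pve`` of the total.
    """
    if not 0.0 < pve < 1.0:
        raise ValueError("pve must be in (0, 1)")
    x = G.imputed()[:, snp_index]
    vx = x.var()
    if vx == 0:
        raise ValueError("QTL SNP is monomorphic")
    return float(np.sqrt(pve / (1.0 - pve) * background_var / vx))


@dataclass
class PhenotypeStats:
    """Generator bookkeeping returned alongside the phenotype table."""

    clipped_fraction: float
    sigma_g2: dict = field(default_factory=dict)
    sigma_e2: dict = field(default_factory=dict)
    h2_unreachable: bool = False


def simulate_phenotypes(
    G: GenotypeMatrix,
    K: KinshipMatrix,
    schedule: MeasurementSchedule | None = None,
    qtls: list[QtlSpec] | None = None,
    baseline: np.ndarray | None = None,
    h2_ll: float = 0.05,
    h2_hl: float = 0.4,
    n_replicates: int = 3,
    accession_mean_var_ll: float = 4e-4,
    accession_mean_var_hl: float = 2.5e-3,
    seed: int | None = None,
    return_stats: bool = False,
):
    """Simulate per-plant Phi_PSII series over the measurement schedule.

    The model for plant r of accession i at time point t is

        Phi_irt = mu(t) + sum_q a_q(t) x_iq + g_i(phase(t)) + e_irt

    with one polygenic draw g ~ N(0, sigma_g^2 K) per phase and i.i.d.
    residuals.  sigma_g^2 and sigma_e^2 are solved per phase so that the
    narrow-sense heritability of accession means (variance
    sigma_g^2 + sigma_e^2 / n_replicates) equals ``h2_ll`` / ``h2_hl`` at
    the configured accession-mean phenotypic variance.  Values are
    clipped to [0, 1]; the clipped fraction is reported in the stats.
    """
    if schedule is None:
        schedule = default_schedule()
    qtls = qtls or []
    if not (0.0 <= h2_ll < 1.0 and 0.0 <= h2_hl < 1.0):
        raise ValueError("heritabilities must be in [0, 1)")
    for q in qtls:
        if not 0 <= q.snp_index < G.n_snps:
            raise ValueError(f"QTL snp_index {q.snp_index} out of range")
    if baseline is None:
        baseline = baseline_curve(schedule)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape[0] != len(schedule):
        raise ValueError("baseline curve length does not match schedule")

    rng = np.random.default_rng(seed)
    n = G.n_accessions
    T = len(schedule)
    phases = np.array([tp.phase for tp in schedule])

    var_target = {"LL": accession_mean_var_ll, "HL": accession_mean_var_hl}
    h2 = {"LL": h2_ll, "HL": h2_hl}
    sigma_g2 = {ph: h2[ph] * var_target[ph] for ph in ("LL", "HL")}
    sigma_e2 = {
        ph: n_replicates * (1.0 - h2[ph]) * var_target[ph] for ph in ("LL", "HL")
    }

    L = np.linalg.cholesky(K.values)
    g = {ph: np.sqrt(sigma_g2[ph]) * (L @ rng.standard_normal(n))
         for ph in ("LL", "HL")}

    X = G.imputed()
    qtl_term = np.zeros((n, T))
    for q in qtls:
        mask = q.active_mask(schedule)
        qtl_term[:, mask] += q.effect * X[:, [q.snp_index]]

    # (accession, replicate, time) noise
    sd_t = np.array([np.sqrt(sigma_e2[ph]) for ph in phases])
    e = rng.standard_normal((n, n_replicates, T)) * sd_t[None, None, :]
    g_t = np.stack([g[ph] for ph in phases], axis=1)  # (n, T)
    values = baseline[None, None, :] + (qtl_term + g_t)[:, None, :] + e

    clipped = float(((values < 0) | (values > 1)).mean())
    values = np.clip(values, 0.0, 1.0)

    acc = np.repeat(G.accession_ids, n_replicates * T)
    rep = np.tile(np.repeat(np.arange(1, n_replicates + 1), T), n)
    day = np.tile([tp.day for tp in schedule], n * n_replicates)
    slot = np.tile([tp.slot for tp in schedule], n * n_replicates)
    phase = np.tile(phases, n * n_replicates)
    pheno = pd.DataFrame(
        {
            "accession": acc,
            "replicate": rep,
            "day": day,
            "slot": slot,
            "phase": phase,
            "phi_psii": values.reshape(-1),
        }
    )
    if return_stats:
        stats = PhenotypeStats(
            clipped_fraction=clipped, sigma_g2=sigma_g2, sigma_e2=sigma_e2
        )
        return pheno, stats
    return pheno


EVIDENCE_COLS = (
    "ontology_match",
    "coexpression_r2",
    "rosette_expressed",
    "literature_function",
    "segregating_polymorphism",
)


def simulate_gene_table(
    G: GenotypeMatrix,
    gene_density: float = 1 / 5000.0,
    evidence_rates: tuple[float, float, float, float, float] = (
        0.2,
        0.1,
        0.8,
        0.05,
        0.1,
    ),
    mean_gene_length: int = 2500,
    causal_gene: str | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tile non-overlapping genes along each chromosome with evidence.

    ``gene_density`` is genes per bp; evidence attributes (ontology match,
    co-expression with light-response genes, rosette expression,
    literature function, segregating polymorphism) are independent
    Bernoulli draws at ``evidence_rates``.  Co-expression is stored as a
    max r^2: above 0.8 when the criterion fires, below otherwise.  If
    ``causal_gene`` names a gene id, its first three criteria are forced
    true so it always reaches the 3-of-5 priority rule.
    """
    if gene_density <= 0:
        raise ValueError("gene_density must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for c in G.chromosomes:
        chrom_len = int(G.pos[G.chrom == c].max()) + mean_gene_length * 2
        n_genes = max(int(round(chrom_len * gene_density)), 1)
        spacing = chrom_len / n_genes
        for j in range(n_genes):
            length = int(rng.integers(mean_gene_length // 2, mean_gene_length * 2))
            start = int(j * spacing) + 1 + int(rng.integers(0, max(int(spacing) - length, 1)))
            end = min(start + length, chrom_len)
            rows.append((f"{c}g{j + 1:05d}", c, start, end,
                         "+" if rng.random() < 0.5 else "-"))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    m = len(genes)
    r = evidence_rates
    genes["ontology_match"] = rng.random(m) < r[0]
    coex = rng.random(m) < r[1]
    genes["coexpression_r2"] = np.where(
        coex, rng.uniform(0.801, 1.0, m), rng.uniform(0.0, 0.8, m)
    )
    genes["rosette_expressed"] = rng.random(m) < r[2]
    genes["literature_function"] = rng.random(m) < r[3]
    genes["segregating_polymorphism"] = rng.random(m) < r[4]
    if causal_gene is not None:
        if causal_gene not in set(genes["gene_id"]):
            raise ValueError(f"no such gene {causal_gene!r}")
        i = genes.index[genes["gene_id"] == causal_gene][0]
        genes.loc[i, "ontology_match"] = True
        genes.loc[i, "coexpression_r2"] = 0.95
        genes.loc[i, "rosette_expressed"] = True
    return genes


def simulate_f1_complementation(
    allele_effects: dict[str, float],
    maternal_effects: dict[str, float] | None = None,
    interaction: float = 0.0,
    noise_sd: float = 0.01,
    schedule: MeasurementSchedule | None = None,
    n_per_cross: int = 16,
    grand_mean_response: float = -0.15,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a quantitative-complementation F1 experiment.

    A wild-type and a knock-out mutant maternal line are each crossed to
    tester accessions carrying different natural alleles; the F1
    phenotype is the per-plant Phi_PSII series.  The acclimation response
    (HL mean minus LL mean) of each F1 follows a two-way fixed-effects
    model; a nonzero ``interaction`` (added in the mutant x second-allele
    cell) is the signature of a causal gene.  Returns a tidy per-plant,
    per-time-point table.
    """
    if maternal_effects is None:
        maternal_effects = {"WT": 0.0, "mutant": -0.02}
    if len(maternal_effects) != 2:
        raise ValueError("exactly two maternal levels required")
    if len(allele_effects) < 2:
        raise ValueError("need at least two tester alleles")
    if n_per_cross < 2:
        raise ValueError("n_per_cross < 2: interaction ANOVA not estimable")
    if schedule is None:
        schedule = default_schedule()
    rng = np.random.default_rng(seed)
    mu = baseline_curve(schedule)
    phases = np.array([tp.phase for tp in schedule])
    hl = phases == "HL"
    baseline_response = mu[hl].mean() - mu[~hl].mean()
    alleles = list(allele_effects)
    rows = []
    for maternal, m_eff in maternal_effects.items():
        for ai, (allele, a_eff) in enumerate(allele_effects.items()):
            inter = (
                interaction
                if (maternal != "WT" and ai == len(alleles) - 1)
                else 0.0
            )
            for plant in range(1, n_per_cross + 1):
                resp = grand_mean_response + m_eff + a_eff + inter
                # shift the HL plateau so this plant's expected
                # (HL mean - LL mean) equals its model response
                series = mu + np.where(hl, resp - baseline_response, 0.0)
                series = series + rng.normal(0.0, noise_sd, len(schedule))
                for tp, v in zip(schedule, series):
                    rows.append(
                        (maternal, allele, plant, tp.day, tp.slot, tp.phase, v)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "maternal",
            "tester_allele",
            "plant",
            "day",
            "slot",
            "phase",
            "phi_psii",
        ],
    )


def simulate_qpcr(
    genotype_fold_changes: dict[str, dict[str, float]],
    ct_noise_sd: float = 0.1,
    n_biological: int = 3,
    n_technical: int = 3,
    reference_genes: tuple[str, str] = ("UBQ7", "CB5E"),
    reference_ct: float = 20.0,
    target_ct_ll: float = 24.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table for LL and HL conditions.

    ``genotype_fold_changes`` maps genotype -> gene -> true HL/LL
    expression fold.  Ct = baseline - log2(relative expression) + noise;
    reference-gene expression is condition-independent.  Each biological
    replicate carries ``n_technical`` technical replicates.
    """
    for gmap in genotype_fold_changes.values():
        if any(f <= 0 for f in gmap.values()):
            raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, gmap in genotype_fold_changes.items():
        for cond in ("LL", "HL"):
            for bio in range(1, n_biological + 1):
                # sample-level offset common to all genes (input amount)
                sample_shift = rng.normal(0.0, ct_noise_sd)
                for gene in (*reference_genes, *gmap):
                    if gene in reference_genes:
                        base = reference_ct
                    else:
                        base = target_ct_ll
                        if cond == "HL":
                            base -= np.log2(gmap[gene])
                    for tech in range(1, n_technical + 1):
                        ct = base + sample_shift + rng.normal(0.0, ct_noise_sd)
                        rows.append((genotype, bio, tech, cond, gene, ct))
    return pd.DataFrame(
        rows,
        columns=["genotype", "bio_rep", "tech_rep", "condition", "gene", "ct"],
    )
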