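import numpy as np
import pytest
from scipy import stats

from photoacclim import (
    QtlSpec,
    baseline_curve,
    compute_kinship,
    default_schedule,
    qtl_effect_for_pve,
    simulate_f1_complementation,
    simulate_gene_table,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_qpcr,
)
from photoacclim.followup import f1_response_summary, qpcr_fold_change


def group_mean_diff(pheno, G, snp_index, day, slot):
    """Oracle: mean Phi of dosage-2 minus dosage-0 accessions at a point."""
    sub = pheno[(pheno["day"] == day) & (pheno["slot"] == slot)]
    means = sub.groupby("accession")["phi_psii"].mean()
    acc = np.array(G.accession_ids)
    d = G.dosages[:, snp_index]
    return means[acc[d == 2]].mean() - means[acc[d == 0]].mean()


def test_no_signal_variance_is_residual_over_replicates(small_panel, schedule):
    G, K, _ = small_panel
    reps = 3
    pheno, st = simulate_phenotypes(
        G, K, schedule, h2_ll=0.0, h2_hl=0.0, n_replicates=reps,
        seed=1, return_stats=True,
    )
    sub = pheno[(pheno["day"] == 4) & (pheno["slot"] == 2)]
    v = sub.groupby("accession")["phi_psii"].mean().var()
    expected = st.sigma_e2["HL"] / reps
    assert v == pytest.approx(expected, rel=0.5)


def test_constitutive_qtl_shifts_group_means_everywhere(schedule):
    G = simulate_genotypes(150, 200, seed=41)
    K = compute_kinship(G)
    a = 0.02
    q = QtlSpec(snp_index=10, temporal_class="constitutive", effect=a)
    diffs = {tp: [] for tp in [(1, 1), (2, 3), (4, 2), (6, 3)]}
    for s in range(50):
        pheno = simulate_phenotypes(
            G, K, schedule, qtls=[q], h2_ll=0.05, h2_hl=0.3, seed=100 + s
        )
        for day, slot in diffs:
            diffs[(day, slot)].append(group_mean_diff(pheno, G, 10, day, slot))
    for tp, vals in diffs.items():
        assert np.mean(vals) == pytest.approx(2 * a, abs=0.006), tp


def test_early_hl_qtl_acts_only_on_first_hl_days(schedule):
    G = simulate_genotypes(150, 200, seed=43)
    K = compute_kinship(G)
    a = 0.03
    q = QtlSpec(snp_index=5, temporal_class="early-HL", effect=a)
    active, inactive = [], []
    for s in range(50):
        pheno = simulate_phenotypes(
            G, K, schedule, qtls=[q], h2_ll=0.05, h2_hl=0.3, seed=200 + s
        )
        active.append(group_mean_diff(pheno, G, 5, 3, 2))  # HL day 1
        inactive.append(group_mean_diff(pheno, G, 5, 1, 2))  # LL day
        inactive.append(group_mean_diff(pheno, G, 5, 6, 2))  # HL day 4
    assert np.mean(active) == pytest.approx(2 * a, abs=0.008)
    assert np.mean(inactive) == pytest.approx(0.0, abs=0.008)


def test_phenotypes_deterministic_and_bounded(small_panel, schedule):
    G, K, _ = small_panel
    a = simulate_phenotypes(G, K, schedule, seed=9)
    b = simulate_phenotypes(G, K, schedule, seed=9)
    assert a.equals(b)
    assert a["phi_psii"].between(0, 1).all()


def test_clipping_is_rare_under_defaults(small_panel, schedule):
    G, K, _ = small_panel
    _, st = simulate_phenotypes(G, K, schedule, seed=10, return_stats=True)
    assert st.clipped_fraction < 0.01


def test_qtl_index_out_of_range(small_panel, schedule):
    G, K, _ = small_panel
    q = QtlSpec(snp_index=G.n_snps, temporal_class="constitutive", effect=0.01)
    with pytest.raises(ValueError, match="out of range"):
        simulate_phenotypes(G, K, schedule, qtls=[q], seed=0)


def test_qtl_effect_for_pve_yields_requested_variance_share():
    G = simulate_genotypes(300, 100, seed=45)
    bg = 2.5e-3
    a = qtl_effect_for_pve(G, 0, 0.15, bg)
    vq = a**2 * G.imputed()[:, 0].var()
    assert vq / (vq + bg) == pytest.approx(0.15, rel=1e-10)


def test_baseline_curve_shape(schedule):
    mu = baseline_curve(schedule)
    ll = [mu[i] for i in schedule.ll_indices]
    hl = [mu[i] for i in schedule.hl_indices]
    assert max(ll) > max(hl)  # HL drop
    assert hl[-1] > hl[0]  # saturating recovery


# ---------------------------------------------------------------------------
# gene table


def test_gene_table_rate_extremes(small_panel):
    G, _, _ = small_panel
    none = simulate_gene_table(G, evidence_rates=(0, 0, 0, 0, 0), seed=1)
    assert not none["ontology_match"].any()
    assert (none["coexpression_r2"] <= 0.8).all()
    allg = simulate_gene_table(G, evidence_rates=(1, 1, 1, 1, 1), seed=1)
    assert allg["ontology_match"].all()
    assert (allg["coexpression_r2"] > 0.8).all()


def test_gene_table_rates_within_binomial_bounds():
    G = simulate_genotypes(20, 100, n_chromosomes=1,
                           chromosome_length=10_000_000, seed=47)
    rates = (0.2, 0.2, 0.8, 0.1, 0.3)
    genes = simulate_gene_table(
        G, gene_density=2000 / 10_000_000, evidence_rates=rates, seed=48
    )
    n = len(genes)
    assert n >= 1500
    observed = [
        genes["ontology_match"].mean(),
        (genes["coexpression_r2"] > 0.8).mean(),
        genes["rosette_expressed"].mean(),
        genes["literature_function"].mean(),
        genes["segregating_polymorphism"].mean(),
    ]
    for rate, obs in zip(rates, observed):
        lo = stats.binom.ppf(0.005, n, rate) / n
        hi = stats.binom.ppf(0.995, n, rate) / n
        assert lo <= obs <= hi


def test_genes_are_non_overlapping_and_within_bounds(small_panel):
    G, _, _ = small_panel
    genes = simulate_gene_table(G, seed=3)
    assert (genes["start"] < genes["end"]).all()
    for _, grp in genes.groupby("chrom"):
        g = grp.sort_values("start")
        assert (g["start"].values[1:] > g["end"].values[:-1]).all()


# ---------------------------------------------------------------------------
# F1 complementation and qPCR generators


def test_f1_additive_means_give_zero_interaction():
    f1 = simulate_f1_complementation(
        allele_effects={"A": 0.0, "B": 0.03},
        interaction=0.0,
        noise_sd=1e-9,
        n_per_cross=4,
        seed=5,
    )
    resp = f1_response_summary(f1)
    cells = resp.groupby(["maternal", "tester_allele"])["response"].mean()
    # additivity: difference between alleles identical across maternal lines
    dwt = cells["WT"]["B"] - cells["WT"]["A"]
    dmu = cells["mutant"]["B"] - cells["mutant"]["A"]
    assert dwt == pytest.approx(dmu, abs=1e-6)


def test_f1_design_is_balanced_with_default_n16():
    f1 = simulate_f1_complementation(
        allele_effects={"A": 0.0, "B": 0.02}, seed=6
    )
    counts = f1.groupby(["maternal", "tester_allele"])["plant"].nunique()
    assert (counts == 16).all() and len(counts) == 4


def test_f1_rejects_underpowered_design():
    with pytest.raises(ValueError, match="n_per_cross"):
        simulate_f1_complementation(
            allele_effects={"A": 0.0, "B": 0.02}, n_per_cross=1, seed=0
        )


@pytest.mark.parametrize("fold", [1.0, 4.0])
def test_qpcr_noiseless_fold_recovery(fold):
    q = simulate_qpcr({"gt": {"YS1": fold}}, ct_noise_sd=0.0, seed=1)
    folds, _ = qpcr_fold_change(q)
    assert folds["fold_change"].to_numpy() == pytest.approx(fold)


def test_qpcr_noisy_fold_recovery_monte_carlo():
    from photoacclim.experiments import qpcr_recovery

    out = qpcr_recovery(seed=60, n_runs=100, true_fold=2.0, ct_noise_sd=0.1)
    assert 1.7 < out["mean_recovered_fold"] < 2.3


def test_qpcr_rejects_nonpositive_fold():
    with pytest.raises(ValueError, match="positive"):
        simulate_qpcr({"gt": {"YS1": 0.0}}, seed=0)
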