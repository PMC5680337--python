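import numpy as np
import pandas as pd
import pytest
from scipy import stats

from photoacclim import (
    assign_haplotypes,
    haplotype_phenotype_tests,
    qpcr_fold_change,
    quantitative_complementation_anova,
    simulate_f1_complementation,
    simulate_genotypes,
    simulate_qpcr,
)


# ---------------------------------------------------------------------------
# haplotypes


def test_identical_region_gives_one_haplotype():
    G = simulate_genotypes(25, 50, seed=121)
    G.dosages[:, 5:8] = 2
    lo, hi = int(G.pos[5]), int(G.pos[7])
    groups = assign_haplotypes(G, "Chr1", lo, hi)
    assert len(groups) == 1 and groups[0].frequency == 1.0


def test_haplotype_partition_matches_string_hashing_oracle():
    G = simulate_genotypes(60, 200, seed=123)
    snps = G.snps_in_region("Chr2", 1, 30_000_000)
    lo, hi = int(G.pos[snps[0]]), int(G.pos[snps[-1]])
    groups = assign_haplotypes(G, "Chr2", lo, hi, min_freq=0.0)
    oracle = {}
    for i, acc in enumerate(G.accession_ids):
        key = tuple(G.dosages[i, snps])
        oracle.setdefault(key, []).append(acc)
    assert {frozenset(g.members) for g in groups} == {
        frozenset(m) for m in oracle.values()
    }
    assert sum(g.frequency for g in groups) == pytest.approx(1.0)


def test_missing_calls_excluded_and_min_freq_applied():
    G = simulate_genotypes(50, 100, missing_rate=0.1, seed=125)
    snps = G.snps_in_region("Chr1", 1, 30_000_000)[:4]
    lo, hi = int(G.pos[snps[0]]), int(G.pos[snps[-1]])
    groups = assign_haplotypes(G, "Chr1", lo, hi, min_freq=0.04)
    complete = ~(G.dosages[:, snps] == -1).any(axis=1)
    for g in groups:
        assert g.frequency > 0.04
        for m in g.members:
            assert complete[G.accession_ids.index(m)]


def test_empty_region_raises():
    G = simulate_genotypes(10, 20, seed=127)
    with pytest.raises(ValueError, match="no SNPs"):
        assign_haplotypes(G, "Chr1", 1, 2)


def test_identical_groups_give_t_zero_p_one():
    from photoacclim.followup import HaplotypeGroup

    groups = [
        HaplotypeGroup("H1", "000", ["a1", "a2", "a3"], 0.5),
        HaplotypeGroup("H2", "222", ["b1", "b2", "b3"], 0.5),
    ]
    pheno = pd.Series(
        [0.5, 0.6, 0.7, 0.5, 0.6, 0.7],
        index=["a1", "a2", "a3", "b1", "b2", "b3"],
    )
    out = haplotype_phenotype_tests(groups, pheno)
    assert out["t"][0] == pytest.approx(0.0, abs=1e-12)
    assert out["p"][0] == pytest.approx(1.0)


def test_welch_t_matches_hand_formula():
    from photoacclim.followup import HaplotypeGroup

    a = np.array([0.50, 0.55, 0.60, 0.52])
    b = np.array([0.70, 0.68, 0.75])
    groups = [
        HaplotypeGroup("H1", "0", [f"a{i}" for i in range(4)], 0.6),
        HaplotypeGroup("H2", "2", [f"b{i}" for i in range(3)], 0.4),
    ]
    pheno = pd.Series(
        np.concatenate([a, b]),
        index=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(3)],
    )
    out = haplotype_phenotype_tests(groups, pheno, welch=True)
    # hand-computed Welch statistic
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df_hand = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
    assert out["t"][0] == pytest.approx(t_hand, abs=1e-10)
    assert out["p"][0] == pytest.approx(p_hand, abs=1e-10)


def test_null_haplotype_pvalues_are_uniform():
    from photoacclim.followup import HaplotypeGroup

    rng = np.random.default_rng(129)
    pvals = []
    for _ in range(200):
        vals = rng.normal(0.6, 0.05, 60)
        pheno = pd.Series(vals, index=[f"x{i}" for i in range(60)])
        groups = [
            HaplotypeGroup("H1", "0", [f"x{i}" for i in range(30)], 0.5),
            HaplotypeGroup("H2", "2", [f"x{i}" for i in range(30, 60)], 0.5),
        ]
        pvals.append(haplotype_phenotype_tests(groups, pheno)["p"][0])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_separated_groups_always_detected():
    from photoacclim.followup import HaplotypeGroup

    rng = np.random.default_rng(131)
    hits = 0
    for _ in range(100):
        a = rng.normal(0.60, 0.01, 20)
        b = rng.normal(0.66, 0.01, 20)  # 2a = 0.06 >> noise
        pheno = pd.Series(
            np.concatenate([a, b]), index=[f"x{i}" for i in range(40)]
        )
        groups = [
            HaplotypeGroup("H1", "0", [f"x{i}" for i in range(20)], 0.5),
            HaplotypeGroup("H2", "2", [f"x{i}" for i in range(20, 40)], 0.5),
        ]
        hits += haplotype_phenotype_tests(groups, pheno)["p"][0] < 0.05
    assert hits >= 95


# ---------------------------------------------------------------------------
# quantitative complementation


def balanced_f1(cell_means, n=3, jitter=None):
    rows = []
    for (m, a), mu in cell_means.items():
        for plant in range(n):
            v = mu if jitter is None else mu + jitter[(m, a, plant)]
            rows.append({"maternal": m, "tester_allele": a, "plant": plant,
                         "response": v})
    return pd.DataFrame(rows)


def test_additive_cell_means_give_zero_interaction_F():
    means = {("WT", "A"): 10, ("WT", "B"): 12, ("mut", "A"): 11, ("mut", "B"): 13}
    # identical symmetric spread in every cell keeps cell means exact
    jitter = {(m, a, p): eps for (m, a) in means
              for p, eps in enumerate((-0.1, 0.0, 0.1))}
    f1 = balanced_f1(means, n=3, jitter=jitter)
    res = quantitative_complementation_anova(f1)
    assert res.interaction_F == pytest.approx(0.0, abs=1e-10)


def hand_two_way_anova(df):
    """Textbook sums-of-squares partition for a balanced 2x2xn design."""
    grand = df["response"].mean()
    n = len(df) // 4
    ss_a = sum(
        2 * n * (df[df["maternal"] == m]["response"].mean() - grand) ** 2
        for m in df["maternal"].unique()
    )
    ss_b = sum(
        2 * n * (df[df["tester_allele"] == a]["response"].mean() - grand) ** 2
        for a in df["tester_allele"].unique()
    )
    cell = df.groupby(["maternal", "tester_allele"])["response"].mean()
    ss_cells = sum(
        n * (cell[m, a] - grand) ** 2
        for m in df["maternal"].unique()
        for a in df["tester_allele"].unique()
    )
    ss_int = ss_cells - ss_a - ss_b
    resid = df["response"] - df.apply(
        lambda r: cell[r["maternal"], r["tester_allele"]], axis=1
    )
    ss_err = (resid**2).sum()
    df_err = len(df) - 4
    F = (ss_int / 1) / (ss_err / df_err)
    p = stats.f.sf(F, 1, df_err)
    return F, p


def test_interaction_F_matches_hand_partition():
    rng = np.random.default_rng(135)
    means = {("WT", "A"): 10.0, ("WT", "B"): 12.0,
             ("mut", "A"): 11.0, ("mut", "B"): 13.7}
    jitter = {
        (m, a, p): rng.normal(0, 0.5)
        for m, a in means
        for p in range(3)
    }
    f1 = balanced_f1(means, n=3, jitter=jitter)
    res = quantitative_complementation_anova(f1)
    F_hand, p_hand = hand_two_way_anova(f1)
    assert res.interaction_F == pytest.approx(F_hand, abs=1e-10)
    assert res.interaction_p == pytest.approx(p_hand, abs=1e-10)


def test_interaction_invariant_to_allele_relabeling():
    f1 = simulate_f1_complementation(
        allele_effects={"A": 0.0, "B": 0.02},
        interaction=0.05, noise_sd=0.01, seed=137,
    )
    res1 = quantitative_complementation_anova(f1)
    swapped = f1.assign(
        tester_allele=f1["tester_allele"].map({"A": "B", "B": "A"})
    )
    res2 = quantitative_complementation_anova(swapped)
    assert res1.interaction_p == pytest.approx(res2.interaction_p, rel=1e-9)


def test_empty_cell_rejected():
    f1 = balanced_f1(
        {("WT", "A"): 10, ("WT", "B"): 12, ("mut", "A"): 11, ("mut", "B"): 13}
    )
    broken = f1[~((f1["maternal"] == "mut") & (f1["tester_allele"] == "B"))]
    with pytest.raises(ValueError):
        quantitative_complementation_anova(broken)


# ---------------------------------------------------------------------------
# qPCR


def test_one_cycle_shift_is_twofold_change():
    q = simulate_qpcr({"gt": {"YS1": 2.0}}, ct_noise_sd=0.0, seed=1)
    folds, _ = qpcr_fold_change(q)
    assert folds["fold_change"].to_numpy() == pytest.approx(2.0)


def test_identical_ct_gives_fold_one():
    q = simulate_qpcr({"gt": {"YS1": 1.0}}, ct_noise_sd=0.0, seed=1)
    folds, _ = qpcr_fold_change(q)
    assert folds["fold_change"].to_numpy() == pytest.approx(1.0)


def test_fold_change_invariant_to_global_ct_shift():
    q = simulate_qpcr({"gt": {"YS1": 3.0}}, ct_noise_sd=0.05, seed=139)
    f1, _ = qpcr_fold_change(q)
    f2, _ = qpcr_fold_change(q.assign(ct=q["ct"] + 5.0))
    assert np.allclose(f1["fold_change"], f2["fold_change"], rtol=1e-9)


def test_missing_reference_gene_is_named():
    q = simulate_qpcr({"gt": {"YS1": 2.0}}, seed=1)
    broken = q[q["gene"] != "UBQ7"]
    with pytest.raises(ValueError, match="UBQ7"):
        qpcr_fold_change(broken)


def test_genotype_differences_detected_by_anova():
    q = simulate_qpcr(
        {"gt1": {"YS1": 4.0}, "gt2": {"YS1": 1.0}}, ct_noise_sd=0.05, seed=141
    )
    _, anova = qpcr_fold_change(q)
    assert anova.loc[anova["gene"] == "YS1", "p"].iloc[0] < 0.01
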