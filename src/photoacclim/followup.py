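"""Allele-level follow-up statistics.

Three analyses confirm a candidate gene's contribution:

* haplotype analysis — accessions are grouped by their SNP string over
  the gene's promoter + coding region; haplotype groups above a minimum
  frequency are compared phenotypically by pairwise t-tests;
* quantitative complementation — F1s of a wild-type and a knock-out
  maternal line crossed to accessions carrying different natural
  alleles; a significant maternal x tester-allele interaction in a
  two-way ANOVA on the acclimation response shows the gene is causal;
* qPCR fold-change analysis — expression normalized to two reference
  genes, HL expression expressed as fold change over the LL average,
  compared across genotypes by one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .genotypes import GenotypeMatrix

__all__ = [
    "HaplotypeGroup",
    "AnovaResult",
    "assign_haplotypes",
    "haplotype_phenotype_tests",
    "f1_response_summary",
    "quantitative_complementation_anova",
    "qpcr_fold_change",
]


@dataclass
class HaplotypeGroup:
    label: str
    snp_string: str
    members: list[str]
    frequency: float


@dataclass
class AnovaResult:
    """Interaction-focused summary of a fixed-effects ANOVA."""

    table: pd.DataFrame
    interaction_F: float
    interaction_df: tuple[int, int]
    interaction_p: float
    significant: bool


def assign_haplotypes(
    G: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    min_freq: float = 0.04,
) -> list[HaplotypeGroup]:
    """Group accessions by identical dosage strings over a gene region.

    Accessions with any missing call in the region are excluded; groups
    with frequency (among complete accessions) at or below ``min_freq``
    are dropped.  Groups are labelled H1, H2, ... by decreasing
    frequency (ties by SNP string).
    """
    snps = G.snps_in_region(chrom, start, end)
    if snps.size == 0:
        raise ValueError(f"no SNPs in {chrom}:{start}-{end}")
    D = G.dosages[:, snps]
    complete = ~(D == -1).any(axis=1)
    strings: dict[str, list[str]] = {}
    for i in np.where(complete)[0]:
        s = "".join(str(int(d)) for d in D[i])
        strings.setdefault(s, []).append(G.accession_ids[i])
    n_typed = int(complete.sum())
    groups = [
        (s, members, len(members) / n_typed) for s, members in strings.items()
    ]
    groups = [g for g in groups if g[2] > min_freq]
    groups.sort(key=lambda g: (-g[2], g[0]))
    return [
        HaplotypeGroup(
            label=f"H{i + 1}", snp_string=s, members=members, frequency=f
        )
        for i, (s, members, f) in enumerate(groups)
    ]


def haplotype_phenotype_tests(
    groups: list[HaplotypeGroup],
    pheno_summary: pd.Series,
    welch: bool = True,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """All pairwise two-sided t-tests between haplotype groups.

    ``pheno_summary`` maps accession to a scalar phenotype (e.g. mean
    HL-phase Phi_PSII).  Welch's unequal-variance test is the default;
    groups reduced to fewer than two phenotyped members are excluded.
    """
    usable = []
    for g in groups:
        vals = pheno_summary.reindex(g.members).dropna().to_numpy()
        if len(vals) >= 2:
            usable.append((g.label, vals))
    if len(usable) < 2:
        raise ValueError("need at least two haplotype groups with >= 2 members")
    rows = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            la, a = usable[i]
            lb, b = usable[j]
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
            rows.append(
                {
                    "group_a": la,
                    "group_b": lb,
                    "n_a": len(a),
                    "n_b": len(b),
                    "mean_a": a.mean(),
                    "mean_b": b.mean(),
                    "t": float(t),
                    "p": float(p),
                }
            )
    out = pd.DataFrame(rows)
    if bonferroni:
        out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def f1_response_summary(f1: pd.DataFrame) -> pd.DataFrame:
    """Per-plant acclimation response: mean HL minus mean LL Phi_PSII."""
    def resp(grp: pd.DataFrame) -> float:
        hl = grp.loc[grp["phase"] == "HL", "phi_psii"].mean()
        ll = grp.loc[grp["phase"] == "LL", "phi_psii"].mean()
        return hl - ll

    out = (
        f1.groupby(["maternal", "tester_allele", "plant"])
        .apply(resp, include_groups=False)
        .rename("response")
        .reset_index()
    )
    return out


def quantitative_complementation_anova(
    f1: pd.DataFrame,
    alpha: float = 0.05,
) -> AnovaResult:
    """Two-way fixed-effects ANOVA of the F1 acclimation response.

    ``f1`` is either a per-time-point table (with ``phase``/``phi_psii``
    columns, condensed per plant first) or a per-plant table with a
    ``response`` column.  The maternal x tester-allele interaction is
    the quantitative-complementation test: it asks whether the allelic
    difference depends on whether the maternal line carries a working
    copy of the gene.  Type-II sums of squares are used (robust to mild
    imbalance from plant loss).
    """
    if "response" not in f1.columns:
        f1 = f1_response_summary(f1)
    cells = f1.groupby(["maternal", "tester_allele"]).size()
    if (cells < 2).any() or len(cells) < 4:
        raise ValueError("each maternal x allele cell needs >= 2 plants")
    model = smf.ols(
        "response ~ C(maternal) * C(tester_allele)", data=f1
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    inter = table.loc["C(maternal):C(tester_allele)"]
    df1 = int(inter["df"])
    df2 = int(table.loc["Residual", "df"])
    F = float(inter["F"])
    p = float(inter["PR(>F)"])
    return AnovaResult(
        table=table,
        interaction_F=F,
        interaction_df=(df1, df2),
        interaction_p=p,
        significant=p < alpha,
    )


def qpcr_fold_change(
    q: pd.DataFrame,
    reference_genes: tuple[str, str] = ("UBQ7", "CB5E"),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """HL/LL expression fold changes per genotype x gene, with ANOVA.

    Technical replicates are averaged per biological sample; relative
    expression is 2^-(Ct_target - mean(Ct_ref1, Ct_ref2)) (the delta-Ct
    model with geometric-mean reference normalization); the fold change
    of an HL biological replicate is its expression over the mean LL
    expression of the same genotype.  A one-way ANOVA across genotypes
    on the per-replicate fold changes is reported per gene.
    """
    tech = (
        q.groupby(["genotype", "bio_rep", "condition", "gene"])["ct"]
        .mean()
        .reset_index()
    )
    samples = tech.pivot_table(
        index=["genotype", "bio_rep", "condition"], columns="gene", values="ct"
    )
    for ref in reference_genes:
        if ref not in samples.columns or samples[ref].isna().any():
            bad = (
                samples.index[samples[ref].isna()].tolist()
                if ref in samples.columns
                else samples.index.tolist()
            )
            raise ValueError(f"reference gene {ref} missing for samples {bad[:5]}")
    ref_ct = samples[list(reference_genes)].mean(axis=1)
    targets = [g for g in samples.columns if g not in reference_genes]
    expr = 2.0 ** -(samples[targets].sub(ref_ct, axis=0))
    expr = expr.reset_index()

    rows = []
    for gene in targets:
        for genotype, grp in expr.groupby("genotype"):
            ll_mean = grp.loc[grp["condition"] == "LL", gene].mean()
            hl = grp.loc[grp["condition"] == "HL", [gene, "bio_rep"]]
            for _, r in hl.iterrows():
                rows.append(
                    {
                        "genotype": genotype,
                        "gene": gene,
                        "bio_rep": int(r["bio_rep"]),
                        "fold_change": float(r[gene] / ll_mean),
                    }
                )
    folds = pd.DataFrame(rows)

    anova_rows = []
    for gene, grp in folds.groupby("gene"):
        by_gt = [g["fold_change"].to_numpy() for _, g in grp.groupby("genotype")]
        if len(by_gt) >= 2 and all(len(v) >= 2 for v in by_gt):
            F, p = stats.f_oneway(*by_gt)
        else:
            F, p = np.nan, np.nan
        anova_rows.append(
            {"gene": gene, "F": float(F), "p": float(p),
             "significant": bool(p < alpha) if np.isfinite(p) else False}
        )
    return folds, pd.DataFrame(anova_rows)
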