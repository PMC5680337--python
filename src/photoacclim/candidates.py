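"""Candidate-gene extraction and the 5-criteria, 3-of-5 prioritization.

Genes intersecting a QTL window are candidates.  Five evidence criteria
drive prioritization: (1) a gene-ontology match to chloroplast /
photosynthesis / light-stress terms, (2) co-expression with
light-response genes at r^2 > 0.8 (strict), (3) any expression in the
vegetative rosette, (4) a literature-annotated photosynthetic function,
and (5) a polymorphism segregating between the two groups of accessions
with the most extreme phenotypes.  A gene scoring three or more enters
the priority list.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .qtl import QtlInterval

__all__ = [
    "genes_in_windows",
    "score_criteria",
    "extreme_group_segregation",
]

CRITERIA = (
    "ontology",
    "coexpression",
    "rosette",
    "literature",
    "segregation",
)


def genes_in_windows(
    qtls: list[QtlInterval], genes: pd.DataFrame
) -> pd.DataFrame:
    """Genes whose body intersects any QTL interval (1-based inclusive).

    A gene spanning several QTLs is listed once, with every QTL id it
    touches in ``qtl_ids``.
    """
    hits: dict[str, list[int]] = {}
    for q in qtls:
        sel = genes[
            (genes["chrom"] == q.chrom)
            & (genes["start"] <= q.end)
            & (genes["end"] >= q.start)
        ]
        for gid in sel["gene_id"]:
            hits.setdefault(gid, []).append(q.qtl_id)
    out = genes[genes["gene_id"].isin(hits)].copy()
    out["qtl_ids"] = out["gene_id"].map(
        lambda g: ",".join(str(i) for i in sorted(hits[g]))
    )
    return out.reset_index(drop=True)


def score_criteria(
    candidates: pd.DataFrame,
    extreme_flags: pd.Series | dict | None = None,
    min_score: int = 3,
    r2_threshold: float = 0.8,
) -> pd.DataFrame:
    """Score the five prioritization criteria and flag priority genes.

    ``candidates`` carries the evidence attributes (``ontology_match``,
    ``coexpression_r2``, ``rosette_expressed``, ``literature_function``,
    ``segregating_polymorphism``).  ``extreme_flags``, if given, maps
    gene id to the extreme-group segregation result and overrides the
    table's own column.  Co-expression fires only at r^2 strictly above
    ``r2_threshold``.
    """
    out = candidates.copy()
    out["crit_ontology"] = out["ontology_match"].astype(bool)
    out["crit_coexpression"] = out["coexpression_r2"].astype(float) > r2_threshold
    out["crit_rosette"] = out["rosette_expressed"].astype(bool)
    out["crit_literature"] = out["literature_function"].astype(bool)
    if extreme_flags is not None:
        flags = pd.Series(extreme_flags)
        out["crit_segregation"] = (
            out["gene_id"].map(flags).fillna(False).astype(bool)
        )
    else:
        out["crit_segregation"] = out["segregating_polymorphism"].astype(bool)
    crit_cols = [f"crit_{c}" for c in CRITERIA]
    out["score"] = out[crit_cols].sum(axis=1).astype(int)
    out["priority"] = out["score"] >= min_score
    return out


def extreme_group_segregation(
    pheno_summary: pd.Series,
    G: GenotypeMatrix,
    genes: pd.DataFrame,
    group_size: int = 15,
    freq_gap: float = 0.6,
) -> pd.Series:
    """Does any polymorphism in a gene segregate between extreme groups?

    Accessions are ranked by ``pheno_summary`` (default usage: mean
    HL-phase Phi_PSII); the top and bottom ``group_size`` accessions form
    the extreme groups (boundary ties broken by accession id).  A SNP
    segregates when its allele-frequency difference between the groups
    is at least ``freq_gap`` in absolute value; a gene is flagged when
    any SNP within its body segregates.  Returns a boolean Series
    indexed by gene id.
    """
    if len(pheno_summary) < 2 * group_size:
        raise ValueError("need at least 2 * group_size accessions")
    ranked = (
        pheno_summary.rename("value")
        .rename_axis("accession")
        .reset_index()
        .sort_values(["value", "accession"], kind="stable")
    )
    low = ranked["accession"].head(group_size).tolist()
    high = ranked["accession"].tail(group_size).tolist()
    acc_index = {a: i for i, a in enumerate(G.accession_ids)}
    low_i = [acc_index[a] for a in low]
    high_i = [acc_index[a] for a in high]

    D = G.imputed()

    def freq(rows: list[int], snps: np.ndarray) -> np.ndarray:
        return D[np.ix_(rows, snps)].mean(axis=0) / 2.0

    flags = {}
    for _, g in genes.iterrows():
        snps = G.snps_in_region(g["chrom"], int(g["start"]), int(g["end"]))
        if snps.size == 0:
            flags[g["gene_id"]] = False
            continue
        gap = np.abs(freq(high_i, snps) - freq(low_i, snps))
        flags[g["gene_id"]] = bool((gap >= freq_gap).any())
    return pd.Series(flags, name="segregating")
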