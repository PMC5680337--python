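"""Reading and writing the standard interchange formats.

Genotypes travel as VCF 4.2 (1-based, GT fields, ``./.`` for missing),
gene tables as GFF3 (1-based inclusive) or BED (0-based half-open),
phenotype series / evidence / qPCR tables as headed CSV, and kinship
matrices as TSV with an accession header row and column.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .kinship import KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_phenotypes",
    "read_phenotypes",
    "write_genes_gff3",
    "read_genes_gff3",
    "write_genes_bed",
    "read_genes_bed",
    "write_kinship",
    "read_kinship",
]

PHENO_COLUMNS = ["accession", "replicate", "day", "slot", "phase", "phi_psii"]


class ParseError(ValueError):
    """Malformed record in an input file; the message names the line."""


# ---------------------------------------------------------------------------
# VCF


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write homozygous-coded dosages as a plain-text VCF 4.2 file."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=photoacclim\n")
        for c in G.chromosomes:
            length = int(G.pos[G.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.accession_ids)
            + "\n"
        )
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        ids = G.snp_ids
        for j in range(G.n_snps):
            calls = "\t".join(gt_code[int(d)] for d in G.dosages[:, j])
            fh.write(
                f"{G.chrom[j]}\t{G.pos[j]}\t{ids[j]}\t{G.ref[j]}\t{G.alt[j]}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic VCF into a GenotypeMatrix.

    Multi-allelic sites are skipped (a count is logged); malformed
    records raise :class:`ParseError` naming the offending line.
    """
    from cyvcf2 import VCF

    path = Path(path)
    # locate the header line to convert record index -> file line number
    header_lines = 0
    with path.open() as fh:
        for line in fh:
            header_lines += 1
            if line.startswith("#CHROM"):
                break
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt, cols = [], [], [], [], []
    skipped = 0
    for i, var in enumerate(vcf):
        lineno = header_lines + 1 + i
        if len(var.ALT) != 1:
            skipped += 1
            continue
        try:
            dos = np.empty(len(samples), dtype=np.int8)
            for s, gt in enumerate(var.genotypes):
                a, b = int(gt[0]), int(gt[1])
                dos[s] = -1 if (a < 0 or b < 0) else a + b
        except Exception as exc:  # pragma: no cover - defensive
            raise ParseError(f"{path}:{lineno}: malformed genotype record") from exc
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        cols.append(dos)
    if skipped:
        logger.info("skipped %d non-biallelic site(s) in %s", skipped, path)
    if not cols:
        raise ParseError(f"{path}: no biallelic records found")
    return GenotypeMatrix(
        accession_ids=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosages=np.column_stack(cols),
    )


# ---------------------------------------------------------------------------
# phenotype / generic CSV tables


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno[PHENO_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing phenotype column(s) {sorted(missing)}")
    bad = df.index[(df["phi_psii"] < 0) | (df["phi_psii"] > 1)]
    if len(bad):
        raise ParseError(
            f"{path}: phi_psii outside [0,1] at data line {int(bad[0]) + 2}"
        )
    return df


# ---------------------------------------------------------------------------
# gene annotations

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
EVIDENCE_COLUMNS = [
    "ontology_match",
    "coexpression_r2",
    "rosette_expressed",
    "literature_function",
    "segregating_polymorphism",
]


def write_genes_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write a gene table as GFF3 (1-based inclusive coordinates);
    evidence attributes ride along in column 9."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = [f"ID={g['gene_id']}"]
            for col in EVIDENCE_COLUMNS:
                if col in genes.columns:
                    attrs.append(f"{col}={g[col]}")
            fh.write(
                f"{g['chrom']}\tphotoacclim\tgene\t{int(g['start'])}\t"
                f"{int(g['end'])}\t.\t{g['strand']}\t.\t{';'.join(attrs)}\n"
            )


def read_genes_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i >= end_i:
                raise ParseError(f"{path}:{lineno}: start >= end")
            amap = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "ID" not in amap:
                raise ParseError(f"{path}:{lineno}: gene record without ID")
            row = {
                "gene_id": amap["ID"],
                "chrom": chrom,
                "start": start_i,
                "end": end_i,
                "strand": strand,
            }
            for col in EVIDENCE_COLUMNS:
                if col in amap:
                    v = amap[col]
                    row[col] = (
                        float(v) if col == "coexpression_r2" else v == "True"
                    )
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no gene records found")
    return pd.DataFrame(rows)


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """BED is 0-based half-open: start becomes start - 1, end stays."""
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"].astype(int) - 1,
            "end": genes["end"].astype(int),
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int) + 1,
            "end": bed["end"].astype(int),
            "strand": bed["strand"],
        }
    )


# ---------------------------------------------------------------------------
# kinship


def write_kinship(K: KinshipMatrix, path: str | Path) -> None:
    K.to_frame().to_csv(path, sep="\t")


def read_kinship(path: str | Path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: kinship row/column accessions differ")
    return KinshipMatrix(values=df.to_numpy(dtype=float), accession_ids=list(df.index))
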