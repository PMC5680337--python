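"""Genotype container and Balding-Nichols style panel simulation.

Genotypes are biallelic dosages (0/1/2 copies of the alternate allele,
-1 for missing) for a diversity panel of accessions.  The simulator
emulates an inbred (selfing) species panel: accessions are homozygous by
default, population structure follows the Balding-Nichols model in which
subpopulation allele frequencies are Beta-distributed around an ancestral
frequency with dispersion set by Fst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix", "simulate_genotypes"]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix (accessions x SNPs) with a genomic map.

    ``dosages`` holds integers in {0, 1, 2} with -1 for missing calls.
    Positions are 1-based and strictly increasing within a chromosome.
    """

    accession_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    subpop: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.dosages.shape != (len(self.accession_ids), len(self.pos)):
            raise ValueError("dosage matrix shape does not match ids/map")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def snp_ids(self) -> list[str]:
        return [f"{c}_{p}" for c, p in zip(self.chrom, self.pos)]

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP over non-missing calls."""
        d = self.dosages
        obs = d != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        return np.minimum(f, 1.0 - f)

    def imputed(self) -> np.ndarray:
        """Float dosages with missing calls mean-imputed per SNP."""
        d = self.dosages.astype(float)
        miss = self.dosages == MISSING
        if miss.any():
            obs = ~miss
            col_mean = np.where(
                obs.sum(axis=0) > 0,
                np.where(obs, d, 0.0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1),
                0.0,
            )
            d = np.where(miss, col_mean[None, :], d)
        return d

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosages=self.dosages[:, index],
            subpop=self.subpop,
        )

    def snps_in_region(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of SNPs with start <= pos <= end on ``chrom``."""
        return np.where(
            (self.chrom == chrom) & (self.pos >= start) & (self.pos <= end)
        )[0]


def _chromosome_positions(rng, n: int, length: int) -> np.ndarray:
    pos = np.sort(rng.integers(1, length + 1, size=n))
    # resolve collisions deterministically; panels are far from saturated
    for i in range(1, n):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def simulate_genotypes(
    n_accessions: int,
    n_snps: int,
    n_chromosomes: int = 5,
    n_subpops: int = 1,
    fst: float = 0.0,
    maf_min: float = 0.05,
    missing_rate: float = 0.0,
    inbred: bool = True,
    chromosome_length: int = 30_000_000,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Simulate a structured diversity panel of biallelic SNPs.

    Ancestral allele frequencies are uniform on (0.1, 0.9); with
    ``fst > 0`` each of ``n_subpops`` subpopulations draws its own
    frequency from Beta(p(1-F)/F, (1-p)(1-F)/F).  Inbred accessions carry
    dosage 0 or 2 (a single Bernoulli draw per accession/SNP); outbred
    accessions draw two alleles.  SNPs whose realized minor-allele
    frequency falls below ``maf_min`` are redrawn, so the returned panel
    is already MAF-filtered.
    """
    if n_subpops < 1:
        raise ValueError("n_subpops must be >= 1")
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0, 1)")
    if not 0.0 < maf_min < 0.5:
        raise ValueError("maf_min must be in (0, 0.5)")
    if n_snps < n_chromosomes:
        raise ValueError(
            f"cannot place {n_snps} SNPs on {n_chromosomes} chromosomes"
        )
    rng = np.random.default_rng(seed)

    subpop = rng.integers(0, n_subpops, size=n_accessions)

    def draw(m: int) -> np.ndarray:
        p_anc = rng.uniform(0.1, 0.9, size=m)
        if fst > 0.0 and n_subpops > 1:
            a = p_anc * (1.0 - fst) / fst
            b = (1.0 - p_anc) * (1.0 - fst) / fst
            p_sub = rng.beta(a[None, :], b[None, :], size=(n_subpops, m))
        else:
            p_sub = np.tile(p_anc, (n_subpops, 1))
        p_acc = p_sub[subpop, :]  # (n_accessions, m)
        if inbred:
            d = 2 * (rng.random((n_accessions, m)) < p_acc).astype(np.int8)
        else:
            d = (
                (rng.random((n_accessions, m)) < p_acc).astype(np.int8)
                + (rng.random((n_accessions, m)) < p_acc).astype(np.int8)
            )
        return d

    dosages = draw(n_snps)
    for _ in range(200):
        f = dosages.mean(axis=0) / 2.0
        low = np.minimum(f, 1 - f) < maf_min
        if not low.any():
            break
        dosages[:, low] = draw(int(low.sum()))
    else:
        raise RuntimeError("could not reach requested MAF after 200 redraws")

    if missing_rate > 0.0:
        miss = rng.random(dosages.shape) < missing_rate
        dosages = np.where(miss, np.int8(MISSING), dosages)

    per_chrom = np.full(n_chromosomes, n_snps // n_chromosomes)
    per_chrom[: n_snps % n_chromosomes] += 1
    chrom = np.concatenate(
        [np.repeat(f"Chr{i + 1}", c) for i, c in enumerate(per_chrom)]
    ).astype(object)
    pos = np.concatenate(
        [_chromosome_positions(rng, int(c), chromosome_length) for c in per_chrom]
    )

    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4

    return GenotypeMatrix(
        accession_ids=[f"acc{i:04d}" for i in range(n_accessions)],
        chrom=chrom,
        pos=pos,
        ref=bases[ref_idx],
        alt=bases[alt_idx],
        dosages=dosages,
        subpop=subpop,
    )
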