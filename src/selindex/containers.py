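"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive dosage matrix with a missingness mask.

    Dosages count copies of the A1 allele (0, 1 or 2); missing entries are
    ``np.nan``.  Variant metadata (chromosome, position, alleles) is carried
    so the matrix round-trips through PLINK text and binary dialects.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray = field(default=None)  # type: ignore[assignment]
    pos: np.ndarray = field(default=None)  # type: ignore[assignment]
    a1: np.ndarray = field(default=None)  # type: ignore[assignment]
    a2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x SNPs array")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.snp_ids) != m:
            raise ValueError(f"{len(self.snp_ids)} snp ids for {m} columns")
        if self.chrom is None:
            self.chrom = np.ones(m, dtype=int)
        if self.pos is None:
            self.pos = np.arange(1, m + 1, dtype=int)
        if self.a1 is None:
            self.a1 = np.full(m, "A", dtype=object)
        if self.a2 is None:
            self.a2 = np.full(m, "B", dtype=object)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def variant_call_rates(self) -> np.ndarray:
        """Fraction of non-missing genotypes per variant."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_call_rates(self) -> np.ndarray:
        """Fraction of non-missing genotypes per sample."""
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def allele_freqs(self) -> np.ndarray:
        """A1 allele frequency per SNP from non-missing dosages (nan if all missing)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self) -> np.ndarray:
        """Per-SNP counts of hom-A1, het, hom-A2 among non-missing genotypes."""
        d = self.dosages
        counts = np.empty((self.n_snps, 3), dtype=int)
        counts[:, 0] = np.nansum(d == 2, axis=0)
        counts[:, 1] = np.nansum(d == 1, axis=0)
        counts[:, 2] = np.nansum(d == 0, axis=0)
        return counts

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        """Return a copy restricted to boolean masks / index arrays along each axis."""
        si = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        vi = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if vi.dtype == bool:
            vi = np.flatnonzero(vi)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(si, vi)].copy(),
            sample_ids=[self.sample_ids[i] for i in si],
            snp_ids=[self.snp_ids[j] for j in vi],
            chrom=self.chrom[vi].copy(),
            pos=self.pos[vi].copy(),
            a1=self.a1[vi].copy(),
            a2=self.a2[vi].copy(),
        )
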