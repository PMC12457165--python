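"""Additive genomic relationship matrix (GRM) and principal-component covariates.

The default construction is the single-ratio form: missing dosages are
mean-imputed per SNP, columns are centered by twice the sample allele
frequency, and G = M M' / sum_j 2 p_j (1 - p_j) over the polymorphic SNPs.
A per-SNP-standardized variant (each column scaled to unit variance before
averaging) is available as a method switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import GenotypeMatrix


@dataclass
class Grm:
    """Symmetric individuals x individuals relationship matrix with an
    eigendecomposition cache (eigenvalues descending)."""

    matrix: np.ndarray
    ids: list[str]
    n_snps_used: int
    eigen: tuple | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} does not match {n} ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8 * max(1.0, np.abs(self.matrix).max())):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def eigendecomposition(self) -> tuple:
        """Cached ``(eigenvalues, eigenvectors)`` with eigenvalues descending."""
        if self.eigen is None:
            vals, vecs = np.linalg.eigh(self.matrix)
            order = np.argsort(vals)[::-1]
            self.eigen = (vals[order], vecs[:, order])
        return self.eigen

    def subset(self, ids: list[str]) -> "Grm":
        pos = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"ids not in GRM: {missing[:5]}")
        idx = np.array([pos[s] for s in ids])
        return Grm(self.matrix[np.ix_(idx, idx)].copy(), list(ids), self.n_snps_used)

    def block(self, row_ids: list[str], col_ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.ids)}
        ri = np.array([pos[s] for s in row_ids])
        ci = np.array([pos[s] for s in col_ids])
        return self.matrix[np.ix_(ri, ci)]


def compute_grm(gm: GenotypeMatrix, method: str = "vanraden1") -> Grm:
    """Build the additive GRM from post-QC genotypes.

    Monomorphic SNPs are excluded from numerator and denominator.  Raises if
    fewer than 2 individuals or no polymorphic SNP remains.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 individuals for a GRM")
    d = gm.dosages.copy()
    p = gm.allele_freqs()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not np.any(poly):
        raise ValueError("no polymorphic SNPs")
    d = d[:, poly]
    p = p[poly]
    # mean imputation, then centering by 2p
    col_mean = 2.0 * p
    nan_mask = np.isnan(d)
    if nan_mask.any():
        d[nan_mask] = np.broadcast_to(col_mean, d.shape)[nan_mask]
    M = d - col_mean
    het = 2.0 * p * (1.0 - p)
    if method == "vanraden1":
        G = (M @ M.T) / het.sum()
    elif method == "standardized":
        Ms = M / np.sqrt(het)
        G = (Ms @ Ms.T) / len(p)
    else:
        raise ValueError(f"unknown GRM method {method!r}")
    G = (G + G.T) / 2.0
    return Grm(G, list(gm.sample_ids), int(poly.sum()))


def compute_pcs(grm: Grm, k: int) -> np.ndarray:
    """Top-k principal-component coordinates: eigenvectors scaled by the
    square root of their (non-negative-clipped) eigenvalues.

    Sign convention: within each component, the coordinate of largest
    magnitude is made positive, so repeated runs are bit-identical.
    """
    if k >= grm.n:
        raise ValueError(f"k = {k} must be smaller than n = {grm.n}")
    vals, vecs = grm.eigendecomposition()
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0.0, None))
    for j in range(k):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def write_grm_csv(grm: Grm, path: str | Path) -> None:
    import pandas as pd
    pd.DataFrame(grm.matrix, index=grm.ids, columns=grm.ids).to_csv(path)


def read_grm_csv(path: str | Path) -> Grm:
    import pandas as pd
    df = pd.read_csv(path, index_col=0)
    return Grm(df.to_numpy(), [str(c) for c in df.columns], n_snps_used=0)


def write_grm_bin(grm: Grm, prefix: str | Path) -> None:
    """Write the GCTA triplet: <prefix>.grm.bin (float32 lower triangle,
    row-major), <prefix>.grm.N.bin, <prefix>.grm.id."""
    prefix = Path(prefix)
    n = grm.n
    tri = grm.matrix[np.tril_indices(n)]
    tri.astype(np.float32).tofile(str(prefix) + ".grm.bin")
    np.full(tri.shape, grm.n_snps_used, dtype=np.float32).tofile(str(prefix) + ".grm.N.bin")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for s in grm.ids:
            fh.write(f"FAM\t{s}\n")


def read_grm_bin(prefix: str | Path) -> Grm:
    prefix = Path(prefix)
    ids = []
    with open(str(prefix) + ".grm.id") as fh:
        for line in fh:
            ids.append(line.split()[1])
    n = len(ids)
    tri = np.fromfile(str(prefix) + ".grm.bin", dtype=np.float32).astype(float)
    if len(tri) != n * (n + 1) // 2:
        raise ValueError("GRM binary length inconsistent with id file")
    G = np.zeros((n, n))
    G[np.tril_indices(n)] = tri
    G = G + np.tril(G, -1).T
    counts = np.fromfile(str(prefix) + ".grm.N.bin", dtype=np.float32)
    n_used = int(counts[0]) if len(counts) else 0
    return Grm(G, ids, n_used)
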