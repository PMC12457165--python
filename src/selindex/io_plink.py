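"""Readers and writers for the PLINK text (.ped/.map) and binary (.bed/.bim/.fam) dialects.

Dosages count A1 alleles.  The binary codec follows the SNP-major .bed layout:
per SNP, samples are packed four to a byte, two bits each, least-significant
pair first, with 00 = hom A1, 01 = missing, 10 = het, 11 = hom A2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .containers import GenotypeMatrix

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> dosage of A1
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _pedigree_cols(gm: GenotypeMatrix, pedigree: dict | None):
    rows = []
    for sid in gm.sample_ids:
        sire, dam = (None, None)
        if pedigree is not None and sid in pedigree:
            sire, dam = pedigree[sid]
        rows.append((sire or "0", dam or "0"))
    return rows


def write_map(gm: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        for j in range(gm.n_snps):
            fh.write(f"{gm.chrom[j]}\t{gm.snp_ids[j]}\t0\t{gm.pos[j]}\n")


def write_ped_map(gm: GenotypeMatrix, prefix: str | Path, pedigree: dict | None = None) -> None:
    prefix = Path(prefix)
    write_map(gm, prefix.with_suffix(".map"))
    parents = _pedigree_cols(gm, pedigree)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            sire, dam = parents[i]
            fields = ["FAM", sid, sire, dam, "0", "-9"]
            row = gm.dosages[i]
            for j in range(gm.n_snps):
                d = row[j]
                a1, a2 = gm.a1[j], gm.a2[j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [str(a1), str(a1)]
                elif d == 1:
                    fields += [str(a1), str(a2)]
                else:
                    fields += [str(a2), str(a2)]
            fh.write(" ".join(fields) + "\n")


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    chrom, snp_ids, pos = [], [], []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            c, sid, _cm, bp = line.split()
            chrom.append(int(c))
            snp_ids.append(sid)
            pos.append(int(bp))
    m = len(snp_ids)
    sample_ids, rows = [], []
    alleles: list[set] = [set() for _ in range(m)]
    raw = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            fields = line.split()
            sample_ids.append(fields[1])
            geno = fields[6:]
            if len(geno) != 2 * m:
                raise ValueError(f"ped row for {fields[1]} has {len(geno)//2} genotypes, expected {m}")
            pairs = [(geno[2 * j], geno[2 * j + 1]) for j in range(m)]
            raw.append(pairs)
            for j, (x, y) in enumerate(pairs):
                for a in (x, y):
                    if a != "0":
                        alleles[j].add(a)
    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    for j in range(m):
        obs = sorted(alleles[j])
        if not obs:
            obs = ["A", "B"]
        a1[j] = obs[0]
        a2[j] = obs[-1] if len(obs) > 1 else obs[0]
    dosages = np.full((len(sample_ids), m), np.nan)
    for i, pairs in enumerate(raw):
        for j, (x, y) in enumerate(pairs):
            if x == "0" or y == "0":
                continue
            dosages[i, j] = (x == a1[j]) + (y == a1[j])
    return GenotypeMatrix(dosages, sample_ids, snp_ids,
                          chrom=np.array(chrom), pos=np.array(pos), a1=a1, a2=a2)


def write_bed(gm: GenotypeMatrix, prefix: str | Path, pedigree: dict | None = None) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(gm.n_snps):
            fh.write(f"{gm.chrom[j]}\t{gm.snp_ids[j]}\t0\t{gm.pos[j]}\t{gm.a1[j]}\t{gm.a2[j]}\n")
    parents = _pedigree_cols(gm, pedigree)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            sire, dam = parents[i]
            fh.write(f"FAM {sid} {sire} {dam} 0 -9\n")
    n = gm.n_samples
    # dosage -> 2-bit code
    codes = np.full(gm.dosages.shape, 1, dtype=np.uint8)  # missing
    codes[gm.dosages == 2] = 0
    codes[gm.dosages == 1] = 2
    codes[gm.dosages == 0] = 3
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        padded = np.zeros((gm.n_snps, n_bytes * 4), dtype=np.uint8)
        padded[:, :n] = codes.T
        packed = (
            padded[:, 0::4]
            | (padded[:, 1::4] << 2)
            | (padded[:, 2::4] << 4)
            | (padded[:, 3::4] << 6)
        ).astype(np.uint8)
        fh.write(packed.tobytes())


def read_bed(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    chrom, snp_ids, pos, a1, a2 = [], [], [], [], []
    with open(prefix.with_suffix(".bim")) as fh:
        for line in fh:
            c, sid, _cm, bp, x, y = line.split()
            chrom.append(int(c)); snp_ids.append(sid); pos.append(int(bp))
            a1.append(x); a2.append(y)
    sample_ids = []
    with open(prefix.with_suffix(".fam")) as fh:
        for line in fh:
            sample_ids.append(line.split()[1])
    n, m = len(sample_ids), len(snp_ids)
    n_bytes = (n + 3) // 4
    data = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(data[:3]) != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    body = data[3:].reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0x03
    codes[:, 1::4] = (body >> 2) & 0x03
    codes[:, 2::4] = (body >> 4) & 0x03
    codes[:, 3::4] = (body >> 6) & 0x03
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    return GenotypeMatrix(dosages, sample_ids, snp_ids,
                          chrom=np.array(chrom), pos=np.array(pos),
                          a1=np.array(a1, dtype=object), a2=np.array(a2, dtype=object))


def read_genotypes(prefix: str | Path) -> GenotypeMatrix:
    """Auto-detect dialect: binary if <prefix>.bed exists, else text."""
    prefix = Path(prefix)
    if prefix.with_suffix(".bed").exists():
        return read_bed(prefix)
    if prefix.with_suffix(".ped").exists():
        return read_ped_map(prefix)
    raise FileNotFoundError(f"no .bed or .ped found for prefix {prefix}")
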