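"""Synthetic breeding-population generator.

Emulates the statistical structure of a closed guide-dog breeding colony:
unlinked biallelic SNPs, a founder pool plus gene-dropped offspring (a subset
of which form parent-offspring trios with fully recorded parents), and
liability-threshold phenotypes (binary health diagnoses, ordinal behavior
scores, continuous scores) with per-trait heritabilities.  A binary "success"
outcome is built as a noisy weighted combination of trait liabilities so that
its point-biserial correlations with the traits approach configured targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .containers import GenotypeMatrix
from . import io_plink


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class SimTraitSpec:
    """One simulated trait: name, type, heritability and marginal distribution.

    For binary traits ``prevalence_or_thresholds`` is the case fraction; for
    ordinal traits it is the per-category frequency vector (summing to 1,
    category 0 first); continuous traits ignore it.
    """

    name: str
    kind: str  # binary | ordinal | continuous
    heritability: float
    prevalence_or_thresholds: float | tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "ordinal", "continuous"):
            raise ConfigurationError(f"unknown trait kind {self.kind!r}")
        if not 0.0 <= self.heritability <= 1.0:
            raise ConfigurationError(
                f"heritability for {self.name!r} must be in [0, 1], got {self.heritability}")
        if self.kind == "binary":
            p = float(self.prevalence_or_thresholds)
            if not 0.0 < p < 1.0:
                raise ConfigurationError(f"prevalence for {self.name!r} must be in (0, 1)")
        elif self.kind == "ordinal":
            freqs = np.asarray(self.prevalence_or_thresholds, dtype=float)
            if freqs.ndim != 1 or len(freqs) < 2:
                raise ConfigurationError(f"ordinal trait {self.name!r} needs >= 2 category frequencies")
            if np.any(freqs <= 0) or not np.isclose(freqs.sum(), 1.0):
                raise ConfigurationError(
                    f"category frequencies for {self.name!r} must be positive and sum to 1")
            cum = np.cumsum(freqs)
            if np.any(np.diff(cum) <= 0):
                raise ConfigurationError(f"cumulative frequencies for {self.name!r} must strictly increase")


@dataclass
class SimConfig:
    """Full simulation configuration; ``seed`` determines every output bit."""

    n_founders: int = 500
    n_offspring: int = 344
    n_trio_offspring: int = 172
    n_snps: int = 20_000
    n_causal_per_trait: int = 200
    maf_range: tuple = (0.05, 0.5)
    trait_specs: list = field(default_factory=list)
    success_weights: dict = field(default_factory=dict)
    success_rate: float = 0.5
    birth_year_range: tuple = (1998, 2023)
    year_effect: float = 0.0
    residual_corr: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ConfigurationError("need at least 2 founders")
        if self.n_trio_offspring > self.n_offspring:
            raise ConfigurationError(
                f"n_trio_offspring ({self.n_trio_offspring}) exceeds n_offspring ({self.n_offspring})")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.residual_corr < 1.0:
            raise ConfigurationError("residual_corr must be in [0, 1)")
        names = {s.name for s in self.trait_specs}
        unknown = set(self.success_weights) - names
        if unknown:
            raise ConfigurationError(f"success_weights name undefined traits: {sorted(unknown)}")

    @property
    def n_individuals(self) -> int:
        return self.n_founders + self.n_offspring


@dataclass
class TruePopulation:
    """A simulated population with its generating truths attached."""

    genotypes: GenotypeMatrix            # masked (observed) dosages
    pedigree: dict                       # id -> (sire or None, dam or None)
    phenotypes: "pd.DataFrame"           # id-indexed trait/covariate table
    liabilities: "pd.DataFrame"          # id x trait latent liabilities
    true_bv: "pd.DataFrame"              # id x trait true breeding values
    realized_success_corr: dict = field(default_factory=dict)
    config: SimConfig = None             # type: ignore[assignment]


def _mate_pairs(rng: np.random.Generator, n_founders: int, n_pairs: int) -> np.ndarray:
    """Draw (sire, dam) founder index pairs, distinct within each pair."""
    sires = rng.integers(0, n_founders, size=n_pairs)
    dams = rng.integers(0, n_founders, size=n_pairs)
    clash = sires == dams
    while np.any(clash):
        dams[clash] = rng.integers(0, n_founders, size=clash.sum())
        clash = sires == dams
    return np.column_stack([sires, dams])


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None):
    """Simulate founder and gene-dropped offspring dosages.

    Founders draw two Bernoulli(p) alleles per SNP with p ~ Uniform(maf_range).
    Each offspring receives, independently per SNP, one uniformly chosen allele
    from each parent (unlinked loci).  Only the first ``n_trio_offspring``
    offspring have their parents recorded in the pedigree (and present in the
    sample); the rest descend from unrecorded "ghost" parents drawn from the
    founder distribution, emulating incomplete parental records.

    Returns ``(complete, observed, pedigree)`` where *complete* has no missing
    entries and *observed* applies the completely-at-random missingness mask.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    nf, no, nt = config.n_founders, config.n_offspring, config.n_trio_offspring
    m = config.n_snps
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    founders = (rng.random((nf, m)) < p).astype(float) + (rng.random((nf, m)) < p)

    def drop(parents_a: np.ndarray, parents_b: np.ndarray) -> np.ndarray:
        # transmitted allele ~ Bernoulli(dosage / 2), independently per locus
        u1 = rng.random(parents_a.shape) < parents_a / 2.0
        u2 = rng.random(parents_b.shape) < parents_b / 2.0
        return u1.astype(float) + u2.astype(float)

    trio_pairs = _mate_pairs(rng, nf, nt)
    trio_off = drop(founders[trio_pairs[:, 0]], founders[trio_pairs[:, 1]])

    n_ghost_off = no - nt
    ghost_a = (rng.random((n_ghost_off, m)) < p).astype(float) + (rng.random((n_ghost_off, m)) < p)
    ghost_b = (rng.random((n_ghost_off, m)) < p).astype(float) + (rng.random((n_ghost_off, m)) < p)
    ghost_off = drop(ghost_a, ghost_b)

    dosages = np.vstack([founders, trio_off, ghost_off])
    founder_ids = [f"F{i:04d}" for i in range(nf)]
    offspring_ids = [f"O{i:04d}" for i in range(no)]
    sample_ids = founder_ids + offspring_ids
    snp_ids = [f"snp{j}" for j in range(m)]

    pedigree: dict = {sid: (None, None) for sid in sample_ids}
    for k in range(nt):
        pedigree[offspring_ids[k]] = (founder_ids[trio_pairs[k, 0]], founder_ids[trio_pairs[k, 1]])

    complete = GenotypeMatrix(dosages, sample_ids, snp_ids)
    observed = GenotypeMatrix(dosages.copy(), list(sample_ids), list(snp_ids),
                              chrom=complete.chrom.copy(), pos=complete.pos.copy(),
                              a1=complete.a1.copy(), a2=complete.a2.copy())
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        observed.dosages[mask] = np.nan
    return complete, observed, pedigree


def simulate_trait(complete: GenotypeMatrix, spec: SimTraitSpec, config: SimConfig,
                   rng: np.random.Generator, env: np.ndarray | None = None):
    """Simulate one trait under the liability-threshold model.

    Causal effects for ``n_causal_per_trait`` SNPs are drawn Normal and the
    resulting genetic values are standardized to variance exactly h2; an
    independent Normal(0, 1 - h2) environmental deviate completes a unit
    variance liability.  Binary/ordinal phenotypes are the liability cut at
    standard-normal quantiles of the configured prevalence / category
    frequencies; continuous phenotypes are the liability itself.

    Returns ``(liability, phenotype, true_bv)`` arrays.
    """
    h2 = spec.heritability
    n = complete.n_samples
    if env is None:
        env = rng.standard_normal(n)
    if h2 > 0:
        n_causal = min(config.n_causal_per_trait, complete.n_snps)
        causal = rng.choice(complete.n_snps, size=n_causal, replace=False)
        p = complete.allele_freqs()[causal]
        scale = np.sqrt(h2 / max(n_causal * np.mean(2 * p * (1 - p)), 1e-12))
        beta = rng.normal(0.0, scale, size=n_causal)
        g = complete.dosages[:, causal] @ beta
        sd = g.std()
        if sd < 1e-12:
            g = np.zeros(n)
        else:
            g = (g - g.mean()) / sd * np.sqrt(h2)
    else:
        g = np.zeros(n)
    liability = g + np.sqrt(1.0 - h2) * env

    if spec.kind == "binary":
        thr = norm.ppf(1.0 - float(spec.prevalence_or_thresholds))
        phenotype = (liability > thr).astype(int)
    elif spec.kind == "ordinal":
        freqs = np.asarray(spec.prevalence_or_thresholds, dtype=float)
        cuts = norm.ppf(np.cumsum(freqs)[:-1])
        phenotype = np.searchsorted(cuts, liability, side="left")
    else:
        phenotype = liability.copy()
    return liability, phenotype, g


def simulate_success(liabilities: dict, success_weights: dict, success_rate: float,
                     rng: np.random.Generator, n: int | None = None):
    """Build the binary success outcome from trait liabilities.

    The latent success liability is a weighted sum of trait liabilities plus
    independent noise, with latent weights deflated by the dichotomization
    attenuation factor phi(z) / sqrt(q(1-q)) so the realized point-biserial
    correlation between the binary outcome and each trait liability
    approaches the configured target.  Returns ``(success, realized_corr)``.
    """
    unknown = set(success_weights) - set(liabilities)
    if unknown:
        raise ConfigurationError(f"success weights name unsimulated traits: {sorted(unknown)}")
    names = list(success_weights)
    if liabilities:
        n = len(next(iter(liabilities.values())))
    elif n is None:
        raise ConfigurationError("n must be given when no trait liabilities exist")
    z = norm.ppf(1.0 - success_rate)
    atten = norm.pdf(z) / np.sqrt(success_rate * (1.0 - success_rate))
    c = np.array([success_weights[t] / atten for t in names])
    ss = float(np.sum(c**2))
    if ss >= 1.0:
        c = c / np.sqrt(ss / 0.99)  # rescale so latent variance stays 1
        ss = 0.99
    L = np.column_stack([liabilities[t] for t in names]) if names else np.zeros((n, 0))
    s = L @ c + np.sqrt(1.0 - ss) * rng.standard_normal(n)
    success = (s > z).astype(int)
    realized = {}
    for t in names:
        x = liabilities[t]
        if success.std() == 0 or np.std(x) == 0:
            realized[t] = 0.0
        else:
            realized[t] = float(np.corrcoef(success, x)[0, 1])
    return success, realized


def simulate_population(config: SimConfig) -> TruePopulation:
    """Run the full generator: genotypes, pedigree, traits, success, covariates."""
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    complete, observed, pedigree = simulate_genotypes(config, rng)
    n = complete.n_samples
    ids = complete.sample_ids

    years = rng.integers(config.birth_year_range[0], config.birth_year_range[1] + 1, size=n)
    year_dev = (years - np.mean(config.birth_year_range)) / max(
        (config.birth_year_range[1] - config.birth_year_range[0]) / 2.0, 1.0)

    # optional equicorrelated environmental residuals across traits
    shared_env = rng.standard_normal(n)
    liab, phen, bvs = {}, {}, {}
    for spec in config.trait_specs:
        if config.residual_corr > 0:
            env = (np.sqrt(config.residual_corr) * shared_env
                   + np.sqrt(1 - config.residual_corr) * rng.standard_normal(n))
        else:
            env = rng.standard_normal(n)
        env = env + config.year_effect * year_dev
        L, P, g = simulate_trait(complete, spec, config, rng, env=env)
        liab[spec.name], phen[spec.name], bvs[spec.name] = L, P, g

    success, realized = simulate_success(liab, config.success_weights, config.success_rate,
                                         rng, n=n)

    pheno = pd.DataFrame({"id": ids})
    pheno["sire"] = [pedigree[i][0] for i in ids]
    pheno["dam"] = [pedigree[i][1] for i in ids]
    pheno["birth_year"] = years
    pheno["success"] = success
    for spec in config.trait_specs:
        pheno[spec.name] = phen[spec.name]
    pheno = pheno.set_index("id", drop=False)

    liabilities = pd.DataFrame(liab, index=pd.Index(ids, name="id"))
    true_bv = pd.DataFrame(bvs, index=pd.Index(ids, name="id"))
    return TruePopulation(observed, pedigree, pheno, liabilities, true_bv,
                          realized_success_corr=realized, config=config)


def write_population(pop: TruePopulation, prefix: str | Path, fmt: str = "bed") -> None:
    """Write PLINK genotypes, the phenotype CSV and a JSON truth sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "bed":
        io_plink.write_bed(pop.genotypes, prefix, pop.pedigree)
    elif fmt == "ped":
        io_plink.write_ped_map(pop.genotypes, prefix, pop.pedigree)
    else:
        raise ConfigurationError(f"unknown genotype format {fmt!r}")
    pop.phenotypes.to_csv(prefix.parent / (prefix.name + ".pheno.csv"), index=False)
    truth = {
        "seed": pop.config.seed if pop.config else None,
        "realized_success_corr": pop.realized_success_corr,
        "true_bv": {c: pop.true_bv[c].tolist() for c in pop.true_bv.columns},
        "ids": list(pop.true_bv.index),
    }
    with open(prefix.parent / (prefix.name + ".truth.json"), "w") as fh:
        json.dump(truth, fh)
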