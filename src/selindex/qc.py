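"""SNP and sample quality control.

Filters applied in the conventional PLINK order: variant call rate, sample
call rate, Hardy-Weinberg equilibrium (exact test), minor allele frequency.
All thresholds are strict inequalities on the failing side: a variant is
removed when its call rate is *less than* the threshold, when its HWE exact
p-value is *below* alpha, or when its MAF is *less than* the minimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import gammaln

from .containers import GenotypeMatrix


@dataclass
class QcThresholds:
    """Default thresholds reproduce the standard pipeline: call rates 0.90,
    HWE exact p < 1e-5, MAF < 0.01."""

    min_variant_call_rate: float = 0.90
    min_sample_call_rate: float = 0.90
    hwe_alpha: float = 1e-5
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_variant_call_rate", "min_sample_call_rate", "hwe_alpha", "min_maf"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class QcReport:
    n_variants_in: int = 0
    n_variants_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    removed_variants: list = field(default_factory=list)  # (id, reason, statistic)
    removed_samples: list = field(default_factory=list)   # (id, call_rate)

    def validate(self) -> None:
        if self.n_variants_in - len(self.removed_variants) != self.n_variants_out:
            raise AssertionError("variant accounting broken: in - removed != out")
        if self.n_samples_in - len(self.removed_samples) != self.n_samples_out:
            raise AssertionError("sample accounting broken: in - removed != out")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def summary(self) -> str:
        lines = [
            f"variants: {self.n_variants_in} in, {len(self.removed_variants)} removed, "
            f"{self.n_variants_out} out",
            f"samples:  {self.n_samples_in} in, {len(self.removed_samples)} removed, "
            f"{self.n_samples_out} out",
        ]
        by_reason: dict[str, int] = {}
        for _, reason, _stat in self.removed_variants:
            by_reason[reason] = by_reason.get(reason, 0) + 1
        for reason, k in sorted(by_reason.items()):
            lines.append(f"  {reason}: {k}")
        return "\n".join(lines)


def _check_nonempty(gm: GenotypeMatrix) -> None:
    if gm.n_samples == 0 or gm.n_snps == 0:
        raise ValueError("empty genotype matrix")


def variant_call_rate_filter(gm: GenotypeMatrix, threshold: float):
    """Drop variants with call rate strictly below ``threshold``."""
    _check_nonempty(gm)
    rates = gm.variant_call_rates()
    keep = rates >= threshold
    removed = [(gm.snp_ids[j], "variant_call_rate", float(rates[j]))
               for j in np.flatnonzero(~keep)]
    return gm.subset(snps=keep), removed


def sample_call_rate_filter(gm: GenotypeMatrix, threshold: float):
    """Drop samples with call rate strictly below ``threshold``."""
    _check_nonempty(gm)
    rates = gm.sample_call_rates()
    keep = rates >= threshold
    removed = [(gm.sample_ids[i], float(rates[i])) for i in np.flatnonzero(~keep)]
    return gm.subset(samples=keep), removed


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the conditional probabilities of every configuration no
    more probable than the observed one.  Monomorphic input returns 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped samples")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0
    rare = min(n_A, n_a)
    # possible heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = (max(n_A, n_a) - hets) // 2
    # log P(het = h | n, n_A) up to a shared constant
    logp = (hets * np.log(2.0)
            - gammaln(hets + 1) - gammaln(hom_rare + 1) - gammaln(hom_common + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_Aa)[0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_filter(gm: GenotypeMatrix, alpha: float):
    """Drop variants whose HWE exact p-value is strictly below ``alpha``."""
    _check_nonempty(gm)
    counts = gm.genotype_counts()
    pvals = np.array([hwe_exact_test(int(c[0]), int(c[1]), int(c[2])) if c.sum() > 0 else 1.0
                      for c in counts])
    keep = pvals >= alpha
    removed = [(gm.snp_ids[j], "hwe", float(pvals[j])) for j in np.flatnonzero(~keep)]
    return gm.subset(snps=keep), removed


def maf_filter(gm: GenotypeMatrix, min_maf: float):
    """Drop variants with minor allele frequency strictly below ``min_maf``."""
    _check_nonempty(gm)
    maf = gm.maf()
    keep = np.nan_to_num(maf, nan=0.0) >= min_maf
    removed = [(gm.snp_ids[j], "maf", float(maf[j])) for j in np.flatnonzero(~keep)]
    return gm.subset(snps=keep), removed


def run_qc(gm: GenotypeMatrix, thresholds: QcThresholds | None = None,
           keep_snps: list[str] | None = None):
    """Apply the full QC cascade; returns ``(filtered, QcReport)``.

    ``keep_snps`` optionally restricts the matrix to a variant-ID keep-list
    before filtering (e.g. an array-subset list).
    """
    thresholds = QcThresholds() if thresholds is None else thresholds
    _check_nonempty(gm)
    if keep_snps is not None:
        wanted = set(keep_snps)
        gm = gm.subset(snps=[j for j, s in enumerate(gm.snp_ids) if s in wanted])
        _check_nonempty(gm)
    report = QcReport(n_variants_in=gm.n_snps, n_samples_in=gm.n_samples)

    gm, removed = variant_call_rate_filter(gm, thresholds.min_variant_call_rate)
    report.removed_variants.extend(removed)
    gm2, removed_s = sample_call_rate_filter(gm, thresholds.min_sample_call_rate)
    report.removed_samples.extend(removed_s)
    gm = gm2
    gm, removed = hwe_filter(gm, thresholds.hwe_alpha)
    report.removed_variants.extend(removed)
    gm, removed = maf_filter(gm, thresholds.min_maf)
    report.removed_variants.extend(removed)

    report.n_variants_out = gm.n_snps
    report.n_samples_out = gm.n_samples
    report.validate()
    return gm, report
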