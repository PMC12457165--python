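"""Default study-scale simulation configuration.

Encodes the breeding-colony conditions the analysis was designed around:
844 Labrador Retrievers (a founder pool plus offspring, 172 of which form
complete parent trios), tens of thousands of biallelic SNPs at 91.4% overall
genotyping rate, 20 low-prevalence binary health diagnoses and 7 ordinal
behavior traits with their observed marker heritabilities and category
frequencies, and a binary training-success outcome whose correlations with
the traits follow the observed correlation table (trainability ~0.53 the
strongest).
"""

from __future__ import annotations

from .index import SUCCESS_CORRELATIONS
from .simulate import SimConfig, SimTraitSpec

# Marker (pseudo-)heritability per trait, as estimated on the real colony.
TRAIT_HERITABILITIES: dict[str, float] = {
    "base_narrow_mandibular_canines": 0.146,
    "malocclusion_class_i": 0.148,
    "distichiasis": 0.092,
    "ppm": 0.142,
    "loose_interphalangeal_collateral_ligaments": 0.109,
    "umbilical_hernia": 0.037,
    "histiocytoma": 0.039,
    "atopic_dermatitis": 0.044,
    "allergic_dermatitis": 0.019,
    "alopecia_bridge_of_nose": 0.022,
    "acral_lick_dermatitis": 0.046,
    "muzzle_folliculitis": 0.023,
    "panosteitis": 0.163,
    "oral_papillomatosis": 0.089,
    "supernumerary_teeth": 0.0,
    "retained_deciduous_teeth": 0.131,
    "anodontia": 0.247,
    "mandibular_distocclusion": 0.269,
    "mandibular_prognathism": 0.080,
    "mandibular_mesiocclusion": 0.139,
    "distraction": 0.177,
    "neck": 0.209,
    "soundness": 0.0,
    "rating": 0.179,
    "pace": 0.153,
    "pull": 0.066,
    "trainability": 0.147,
}

# Observed category frequencies on the condensed scales (n = 844),
# category 0 first.
ORDINAL_FREQUENCIES: dict[str, tuple] = {
    "pace": (44 / 844, 551 / 844, 249 / 844),
    "pull": (51 / 844, 744 / 844, 49 / 844),
    "neck": (75 / 844, 496 / 844, 273 / 844),
    "rating": (22 / 844, 32 / 844, 282 / 844, 305 / 844, 11 / 844,
               174 / 844, 10 / 844, 8 / 844),
    "soundness": (98 / 844, 484 / 844, 262 / 844),
    # trainability's raw scale is unpublished; a plausible 5-level spread
    "trainability": (0.05, 0.20, 0.40, 0.25, 0.10),
}

# distraction condenses to a 0/1 scale; simulated as binary, prevalence of 1s
DISTRACTION_PREVALENCE = 384 / 844

DEFAULT_HEALTH_PREVALENCE = 0.05


def study_trait_specs(health_prevalence: float = DEFAULT_HEALTH_PREVALENCE) -> list[SimTraitSpec]:
    specs: list[SimTraitSpec] = []
    for name, h2 in TRAIT_HERITABILITIES.items():
        if name in ORDINAL_FREQUENCIES:
            specs.append(SimTraitSpec(name, "ordinal", h2, ORDINAL_FREQUENCIES[name]))
        elif name == "distraction":
            specs.append(SimTraitSpec(name, "binary", h2, DISTRACTION_PREVALENCE))
        else:
            specs.append(SimTraitSpec(name, "binary", h2, health_prevalence))
    return specs


def default_study_config(seed: int = 0, n_snps: int = 20_000) -> SimConfig:
    """The generator defaults: the full 844-dog, 27-trait study configuration."""
    weights = {name: SUCCESS_CORRELATIONS[name] for name in TRAIT_HERITABILITIES}
    return SimConfig(
        n_founders=500,
        n_offspring=344,
        n_trio_offspring=172,
        n_snps=n_snps,
        n_causal_per_trait=200,
        maf_range=(0.05, 0.5),
        trait_specs=study_trait_specs(),
        success_weights=weights,
        success_rate=0.5,
        birth_year_range=(1998, 2023),
        missing_rate=0.086,
        seed=seed,
    )
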