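"""Multi-trait selection indices for guide-dog breeding candidates.

Behavior traits arrive as ordinal scores on condensed scales (raw trainer
category labels are first mapped to integers); each is normalized to [0, 1]
by its direction of association with training success:

* negative direction (neck, distraction, rating):  |x_max - x| / x_max
* positive direction (soundness, trainability):     x / x_max
* neutral optimum-at-1 (pace, pull):                1 - |x - 1|

Normalized values are weighted by each trait's correlation with success and
summed into the Behavior Score.  Binary health diagnoses contribute their
(negative) correlation with success directly, summing to the Health Score,
and grouped diagnosis tallies give the Dental/Ocular/Dermal/Health Counts.
The Total Score is a weighted combination of Health and Behavior Scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

BEHAVIOR_TRAITS = ("neck", "distraction", "rating", "soundness", "trainability", "pace", "pull")


class UnknownLabelError(KeyError):
    """Raised when a raw category label has no entry in the standardization map."""


@dataclass
class TraitSpec:
    """Scoring metadata for one trait."""

    name: str
    kind: str            # binary_health | ordinal_behavior | continuous
    direction: str       # negative | positive | neutral
    x_max: float
    weight_r: float      # Pearson correlation of the trait with success
    category_group: str  # dental | ocular | dermal | neuro_musculoskeletal | other | behavior
    optimum: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("negative", "positive", "neutral"):
            raise ValueError(f"bad direction {self.direction!r} for {self.name!r}")
        if self.x_max <= 0:
            raise ValueError(f"x_max must be positive for {self.name!r}")
        if not -1.0 <= self.weight_r <= 1.0:
            raise ValueError(f"weight_r out of [-1, 1] for {self.name!r}")


@dataclass
class IndexWeights:
    """Weights combining Health and Behavior Scores into the Total Score."""

    w_health: float = 0.02
    w_behavior: float = 0.324

    def __post_init__(self) -> None:
        if self.w_health == 0 and self.w_behavior == 0:
            raise ValueError("index weights must not both be zero")


# Raw trainer-category label -> condensed integer score, per behavior trait.
# Adjacent raw categories with thin occupancy are pooled so every retained
# score level covers at least ~5% of the population.
STANDARDIZATION_MAP: dict[str, dict[str, int]] = {
    "pace": {
        "Fast": 2, "Above average": 2, "High average": 2,
        "Average": 1,
        "Less than average": 0,
    },
    "distraction": {
        "High": 1, "Above average": 1,
        "Average": 0, "Less than average": 0,
    },
    "pull": {
        "Hard": 2, "Above average": 2,
        "Average": 1, "Defined average": 1,
        "Less than average": 0,
    },
    "neck": {
        "Hard": 2, "Above average": 2,
        "Average": 1,
        "Less than average": 0, "Easy": 0,
    },
    "rating": {
        "5": 7, "4+": 6, "4": 5, "4-": 4, "3+": 3, "3": 2, "3-": 1, "2+": 0,
    },
    "soundness": {
        "Sound": 2, "Above average": 1, "Average": 0, "Less than average": 0,
    },
}

# Per-trait correlation with training success (health rows all negative).
SUCCESS_CORRELATIONS: dict[str, float] = {
    # dental
    "base_narrow_mandibular_canines": -0.026,
    "malocclusion_class_i": -0.035,
    "supernumerary_teeth": -0.024,
    "retained_deciduous_teeth": -0.013,
    "anodontia": -0.014,
    "mandibular_distocclusion": -0.105,
    "mandibular_prognathism": -0.031,
    "mandibular_mesiocclusion": -0.047,
    # ocular
    "distichiasis": -0.032,
    "ppm": -0.025,
    # dermal
    "histiocytoma": -0.036,
    "atopic_dermatitis": -0.1,
    "allergic_dermatitis": -0.009,
    "alopecia_bridge_of_nose": -0.027,
    "acral_lick_dermatitis": -0.029,
    "muzzle_folliculitis": -0.009,
    # neuro / musculoskeletal
    "loose_interphalangeal_collateral_ligaments": -0.003,
    "panosteitis": -0.02,
    # other
    "umbilical_hernia": -0.009,
    "oral_papillomatosis": -0.02,
    # behavior
    "distraction": -0.107,
    "neck": -0.108,
    "soundness": 0.127,
    "rating": -0.144,
    "pace": 0.02,
    "pull": 0.017,
    "trainability": 0.531,
}

_HEALTH_GROUPS: dict[str, str] = {
    "base_narrow_mandibular_canines": "dental",
    "malocclusion_class_i": "dental",
    "supernumerary_teeth": "dental",
    "retained_deciduous_teeth": "dental",
    "anodontia": "dental",
    "mandibular_distocclusion": "dental",
    "mandibular_prognathism": "dental",
    "mandibular_mesiocclusion": "dental",
    "distichiasis": "ocular",
    "ppm": "ocular",
    "histiocytoma": "dermal",
    "atopic_dermatitis": "dermal",
    "allergic_dermatitis": "dermal",
    "alopecia_bridge_of_nose": "dermal",
    "acral_lick_dermatitis": "dermal",
    "muzzle_folliculitis": "dermal",
    "loose_interphalangeal_collateral_ligaments": "neuro_musculoskeletal",
    "panosteitis": "neuro_musculoskeletal",
    "umbilical_hernia": "other",
    "oral_papillomatosis": "other",
}

_BEHAVIOR_DIRECTION = {
    "neck": ("negative", 2), "distraction": ("negative", 1), "rating": ("negative", 7),
    "soundness": ("positive", 2), "trainability": ("positive", 4),
    "pace": ("neutral", 2), "pull": ("neutral", 2),
}

HEALTH_TRAITS = tuple(_HEALTH_GROUPS)


def default_trait_specs() -> dict[str, TraitSpec]:
    """The shipped trait catalogue: 20 binary health traits + 7 behavior traits."""
    specs: dict[str, TraitSpec] = {}
    for name, group in _HEALTH_GROUPS.items():
        specs[name] = TraitSpec(name=name, kind="binary_health", direction="negative",
                                x_max=1, weight_r=SUCCESS_CORRELATIONS[name],
                                category_group=group)
    for name, (direction, x_max) in _BEHAVIOR_DIRECTION.items():
        specs[name] = TraitSpec(name=name, kind="ordinal_behavior", direction=direction,
                                x_max=x_max, weight_r=SUCCESS_CORRELATIONS[name],
                                category_group="behavior")
    return specs


def load_trait_config(path: str | Path | None = None):
    """Load trait specs, standardization map and index weights from YAML.

    With no path, loads the versioned config bundled with the package.
    Returns ``(specs, standardization_map, IndexWeights)``.
    """
    if path is None:
        text = resources.files("selindex").joinpath("traits.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    specs = {}
    for name, d in cfg["traits"].items():
        specs[name] = TraitSpec(name=name, kind=d["kind"], direction=d["direction"],
                                x_max=d["x_max"], weight_r=d["weight_r"],
                                category_group=d["category_group"],
                                optimum=d.get("optimum", 1.0))
    smap = {t: {str(k): int(v) for k, v in m.items()}
            for t, m in cfg["standardization"].items()}
    w = cfg.get("index_weights", {})
    weights = IndexWeights(w_health=w.get("w_health", 0.02),
                           w_behavior=w.get("w_behavior", 0.324))
    return specs, smap, weights


def standardize_trait(raw_label, smap: dict[str, dict[str, int]] | None, trait: str) -> int:
    """Map a raw trainer category label to its condensed integer score."""
    smap = STANDARDIZATION_MAP if smap is None else smap
    if trait not in smap:
        raise UnknownLabelError(f"no standardization map for trait {trait!r}")
    table = smap[trait]
    key = str(raw_label).strip()
    if key in table:
        return table[key]
    # case-insensitive fallback
    lowered = {k.lower(): v for k, v in table.items()}
    if key.lower() in lowered:
        return lowered[key.lower()]
    raise UnknownLabelError(
        f"unknown {trait!r} label {raw_label!r}; valid labels: {sorted(table)}")


def normalize_negative(x: float, x_max: float) -> float:
    """Higher raw score is worse: |x_max - x| / x_max, 1 at x=0 and 0 at x=x_max."""
    if x_max == 0:
        raise ValueError("x_max must be nonzero")
    return abs(x_max - x) / x_max


def normalize_positive(x: float, x_max: float) -> float:
    """Higher raw score is better: x / x_max."""
    if x_max == 0:
        raise ValueError("x_max must be nonzero")
    return x / x_max


def normalize_neutral(x: float) -> float:
    """Optimum at the middle score (1 on a 0/1/2 scale): 1 - |x - 1|."""
    return 1.0 - abs(x - 1.0)


def normalize_by_direction(x: float, spec: TraitSpec) -> float:
    if spec.direction == "negative":
        return normalize_negative(x, spec.x_max)
    if spec.direction == "positive":
        return normalize_positive(x, spec.x_max)
    return normalize_neutral(x)


def behavior_score(standardized: dict[str, float], specs: dict[str, TraitSpec],
                   raw_sign_weights: bool = False) -> float:
    """Weighted sum of direction-normalized behavior trait scores.

    Each normalized value (1 = optimal) is multiplied by the magnitude of the
    trait's correlation with success.  With ``raw_sign_weights`` the signed
    correlation is used instead (the literal reading, which re-penalizes
    already-inverted traits).
    """
    missing = [t for t in BEHAVIOR_TRAITS if t not in standardized
               or standardized[t] is None or (isinstance(standardized[t], float) and np.isnan(standardized[t]))]
    if missing:
        raise ValueError(f"missing behavior traits: {missing}")
    total = 0.0
    for t in BEHAVIOR_TRAITS:
        spec = specs[t]
        w = spec.weight_r if raw_sign_weights else abs(spec.weight_r)
        total += normalize_by_direction(standardized[t], spec) * w
    return total


def health_score(diagnoses: dict[str, int], specs: dict[str, TraitSpec]) -> float:
    """Sum of binary diagnosis status times the trait's (negative) correlation."""
    total = 0.0
    for name, spec in specs.items():
        if spec.kind != "binary_health":
            continue
        status = diagnoses.get(name, 0)
        if status is None or (isinstance(status, float) and np.isnan(status)):
            status = 0
        total += int(status) * spec.weight_r
    return total


def total_score(health: float, behavior: float, weights: IndexWeights) -> float:
    return weights.w_health * health + weights.w_behavior * behavior


def category_counts(diagnoses: dict[str, int], specs: dict[str, TraitSpec] | None = None):
    """Tally diagnosed conditions per category.

    Returns ``(dental, ocular, dermal, health)`` where *health* counts every
    diagnosed condition across all groups (each diagnosis adds one point).
    """
    specs = default_trait_specs() if specs is None else specs
    dental = ocular = dermal = health = 0
    for name, spec in specs.items():
        if spec.kind != "binary_health":
            continue
        status = diagnoses.get(name, 0)
        if status is None or (isinstance(status, float) and np.isnan(status)):
            status = 0
        status = int(status)
        if not status:
            continue
        health += 1
        if spec.category_group == "dental":
            dental += 1
        elif spec.category_group == "ocular":
            ocular += 1
        elif spec.category_group == "dermal":
            dermal += 1
    return dental, ocular, dermal, health


def score_table(pheno: pd.DataFrame, specs: dict[str, TraitSpec] | None = None,
                weights: IndexWeights | None = None,
                smap: dict[str, dict[str, int]] | None = None,
                raw_sign_weights: bool = False) -> pd.DataFrame:
    """Append index columns to a phenotype table.

    Behavior columns holding string labels are standardized through the
    condensation map first; numeric columns are taken as already-condensed
    scores.  Adds behavior_score, health_score, total_score and the
    dental/ocular/dermal/health counts.  Parental scores (parent_total_score,
    parent_health_score, parent_behavior_score) are joined for rows whose
    sire and dam both appear in the table.
    """
    specs = default_trait_specs() if specs is None else specs
    weights = IndexWeights() if weights is None else weights
    out = pheno.copy()

    for t in BEHAVIOR_TRAITS:
        if t in out.columns and out[t].dtype == object:
            out[t] = [standardize_trait(v, smap, t) for v in out[t]]

    bscores, hscores, counts = [], [], []
    health_names = [n for n, s in specs.items() if s.kind == "binary_health"]
    for _, row in out.iterrows():
        std = {t: row[t] for t in BEHAVIOR_TRAITS if t in out.columns}
        bscores.append(behavior_score(std, specs, raw_sign_weights=raw_sign_weights))
        diag = {n: row[n] for n in health_names if n in out.columns}
        hscores.append(health_score(diag, specs))
        counts.append(category_counts(diag, specs))
    out["behavior_score"] = bscores
    out["health_score"] = hscores
    out["total_score"] = [total_score(h, b, weights) for h, b in zip(hscores, bscores)]
    cc = np.array(counts, dtype=int)
    out["dental_count"], out["ocular_count"], out["dermal_count"], out["health_count"] = cc.T

    if "sire" in out.columns and "dam" in out.columns:
        by_id = out.set_index("id") if "id" in out.columns else out
        for col in ("total_score", "health_score", "behavior_score"):
            parent_col = f"parent_{col}"
            vals = []
            for _, row in out.iterrows():
                sire, dam = row.get("sire"), row.get("dam")
                if (isinstance(sire, str) and sire in by_id.index
                        and isinstance(dam, str) and dam in by_id.index):
                    vals.append((by_id.at[sire, col] + by_id.at[dam, col]) / 2.0)
                else:
                    vals.append(np.nan)
            out[parent_col] = vals
    return out
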