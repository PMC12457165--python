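"""Behavior, Health and Total selection indices for individual dogs.

Shows the raw-label condensation, the direction-aware normalizations, and
the correlation-weighted index arithmetic for two contrasting dogs.
"""

from selindex import (IndexWeights, behavior_score, category_counts,
                      default_trait_specs, health_score, standardize_trait,
                      total_score)

specs = default_trait_specs()

# Raw trainer categories condense to integer scores
print("Pace 'High average'  ->", standardize_trait("High average", None, "pace"))
print("Rating '3+'          ->", standardize_trait("3+", None, "rating"))
print("Soundness 'Sound'    ->", standardize_trait("Sound", None, "soundness"))

# A strong candidate: calm, sound, highly trainable, average pace/pull
strong = {"neck": 0, "distraction": 0, "rating": 0, "soundness": 2,
          "trainability": 4, "pace": 1, "pull": 1}
# A weak candidate: hard to control, distractible, unsound
weak = {"neck": 2, "distraction": 1, "rating": 7, "soundness": 0,
        "trainability": 1, "pace": 0, "pull": 2}

b_strong = behavior_score(strong, specs)
b_weak = behavior_score(weak, specs)
print(f"\nBehavior Score: strong {b_strong:.3f}, weak {b_weak:.3f} "
      "(each normalized trait x |correlation with success|, summed)")

# Health Score: each diagnosis contributes its (negative) correlation
diagnoses = {"atopic_dermatitis": 1, "mandibular_distocclusion": 1}
h = health_score(diagnoses, specs)
print(f"Health Score with atopic dermatitis + mandibular distocclusion: {h:.3f}")
print("category counts (dental, ocular, dermal, total):",
      category_counts(diagnoses, specs))

weights = IndexWeights()  # w_health=0.02, w_behavior=0.324
print(f"Total Score (strong dog, those diagnoses): "
      f"{total_score(h, b_strong, weights):.3f}")
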