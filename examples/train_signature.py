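"""Train intensity-predictive signatures and test separate modifiability.

Trains a LASSO-PCR pattern per modality with leave-one-subject-out
cross-validation, then builds the 2×2 forced-choice matrix: each
pattern discriminating high vs low intensity of its own modality
(diagonal) and of the other modality (off-diagonal). With orthogonal
latent patterns the diagonal should be near 100% and the off-diagonal
near chance — the signature of dissociable representations.
"""

import numpy as np

import painsig as ps

sim = ps.simulate_dataset(seed=1)
cfg = ps.TrainerConfig(seed=0)

cv = {m: ps.loso_crossval(sim.dataset, m, cfg)
      for m in ("somatic", "vicarious")}

print("forced-choice accuracy (high vs low, averaged over sites):")
for trained in ("somatic", "vicarious"):
    for tested in ("somatic", "vicarious"):
        if tested == trained:
            scores = cv[trained].table
        else:
            scores = cv[trained].crossval_scores(
                sim.dataset.select(modality=tested))
        fc = ps.forced_choice_from_scores(scores)
        print(f"  {trained}-trained pattern on {tested} images: "
              f"{fc.accuracy:6.1%}  (p = {fc.p_value:.2e})")

r = ps.pattern_similarity(cv["somatic"].full_pattern,
                          cv["vicarious"].full_pattern)
print(f"spatial correlation of the two trained patterns: r = {r:+.3f}")
w = cv["somatic"].full_pattern.weights
cos = sim.truth.W_som.weights @ w / np.linalg.norm(w)
print(f"cosine of somatic pattern with the generating truth: {cos:.3f}")
print("Diagonal ≈ 100% with off-diagonal ≈ 50% and near-zero pattern "
      "correlation demonstrates separate modifiability.")
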