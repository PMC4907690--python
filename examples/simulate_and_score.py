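"""Generate a synthetic pain study and score it with a known signature.

Builds a small 3 (stimulation level) × 2 (body site) × 2 (modality)
study, scores every somatic image with the somatic ground-truth pattern
(dot product of weights and image), and prints the mean signature
response per level with within-participant SEM — the response should
rise monotonically with level, because that is how the data were built.
"""

import numpy as np

import painsig as ps
from painsig.inference import within_subject_sem

sim = ps.simulate_dataset(grid_shape=(12, 14, 12), n_subjects=12, seed=3)
somatic = sim.dataset.select(modality="somatic")

table = ps.score_dataset(sim.truth.W_som, somatic)
per = table.groupby(["subject", "level"])["response"].mean().unstack("level")
sems = within_subject_sem(per)

print("somatic-signature response by stimulation level:")
for level in per.columns:
    print(f"  level {level}: {per[level].mean():8.3f} "
          f"± {sems[level]:.3f} (within-participant SEM)")

fc = ps.forced_choice_from_scores(table)
print(f"high-vs-low forced-choice accuracy: {fc.accuracy:.0%} "
      f"(exact binomial p = {fc.p_value:.2e}, AUC = {fc.auc:.2f})")
print("A monotone response with ~100% forced-choice accuracy means the "
      "signature tracks the manipulated intensity.")
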