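"""Body-site decoding: upper vs lower limb linear SVM.

Trains a leave-one-subject-out linear SVM to separate upper-limb from
lower-limb images within each modality and reports the forced-choice
accuracy on per-subject mean decision values. The synthetic site
patterns are strong and orthogonal to the modality patterns, so
accuracy should be near 100% — the somatotopy check.
"""

import painsig as ps
from painsig.pipeline import _site_forced_choice

sim = ps.simulate_dataset(grid_shape=(14, 16, 14), n_subjects=16, seed=2)
cfg = ps.TrainerConfig(seed=0)

for modality in ("somatic", "vicarious"):
    table = ps.svm_loso(sim.dataset, modality, cfg)
    fc = _site_forced_choice(table)
    print(f"{modality}: UL-vs-LL forced-choice accuracy "
          f"{fc.accuracy:.0%} (p = {fc.p_value:.2e}, AUC = {fc.auc:.2f})")

print("Accuracy near 100% in both modalities shows the images carry "
      "decodable body-site information (somatotopy).")
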