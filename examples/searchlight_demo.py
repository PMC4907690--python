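"""Searchlight decoding: find where local patterns predict ratings.

Plants rating-predictive signal inside a small sphere of an otherwise
empty volume, runs an 4 mm searchlight over a grid of centers, and
reports where within-modality decoding peaks and how cross-modality
prediction behaves (it should be centered on zero — no shared local
code between the two modalities here).
"""

import numpy as np

import painsig as ps
from painsig.imgio import BrainMask, isotropic_geometry
from painsig.searchlight import (TrialSet, run_searchlight, sphere_indices,
                                 summarize_searchlight)

rng = np.random.default_rng(5)
shape = (12, 12, 12)
mask = BrainMask(isotropic_geometry(shape, 2.0), np.ones(shape, bool))
true_center = (6, 6, 6)
blob = sphere_indices(mask, true_center, 4.0).member_voxels
w = np.zeros(mask.V)
w[blob] = 1.0
w /= np.linalg.norm(w)

n_trials, runs = 40, np.repeat(np.arange(4), 10)
amp_a, amp_b = rng.uniform(1, 3, n_trials), rng.uniform(1, 3, n_trials)
somatic = TrialSet(mask, np.outer(amp_a, w)
                   + rng.normal(0, 0.005, (n_trials, mask.V)),
                   20 * amp_a, runs, "somatic")
vicarious = TrialSet(mask, rng.normal(0, 0.005, (n_trials, mask.V)),
                     20 * amp_b, runs, "vicarious")

centers = [tuple(v) for v in mask.voxel_coords()[::5]]
result = run_searchlight(somatic, vicarious, radius_mm=4.0,
                         centers=centers,
                         config=ps.TrainerConfig(lasso_lambda=0.01, seed=0))

best = result.table.loc[result.table["r_within_a"].idxmax()]
print(f"searched {len(result.table)} spheres of radius 4 mm")
print(f"best within-modality sphere: center "
      f"({best['i']:.0f}, {best['j']:.0f}, {best['k']:.0f}), "
      f"r = {best['r_within_a']:.3f}  [signal planted at {true_center}]")
print(f"cross-modality r across spheres: mean "
      f"{np.nanmean(result.table['r_cross_ab']):+.3f}")

summary = summarize_searchlight(result, top_fraction=0.05)
print(f"top-5% within-modality spheres: {summary['r_within_a']['n_top']} "
      f"(cutoff r = {summary['r_within_a']['cutoff']:.3f})")
print("The top spheres cluster on the planted blob; cross-modality "
      "prediction hovers around zero, i.e. no shared local code.")
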