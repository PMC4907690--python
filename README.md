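# painsig

Multivariate brain-signature analysis of somatic and vicarious pain.

`painsig` re-implements, as a tested and reusable Python library, the
analysis framework used to ask whether feeling pain and perceiving
others' pain share a neural code: train voxel-wise *signatures* that
predict reported pain intensity from fMRI activation maps, score new
images by dot-product signature response, and run the validation
battery that establishes sensitivity, specificity, and *separate
modifiability* of the somatic and vicarious patterns. Because the
original subject-level images are not public, the package ships a
first-class synthetic-data generator that emulates the study's
3 (stimulation level) × 2 (body site) × 2 (modality) within-subject
design, so every stage is exercisable end to end.

It is written for neuroimaging methodologists and for anyone who wants
a transparent, scriptable reference implementation of this analysis
family (signature scoring, LASSO-PCR training, forced-choice
validation, bootstrap thresholding, searchlight decoding).

## The model

A **signature** is a weight map w over in-mask voxels; its response to
an activation image x (a subject-condition beta/contrast map) is

    s = w · x = Σ_v w_v x_v .

Signatures are trained by **LASSO-PCR**: center the training images,
rotate into principal components, fit an L1-penalized regression of
intensity ratings on component scores, and back-project the
coefficients to voxel space (prediction for a new image is
`w·x + intercept`). Training uses **leave-one-subject-out
cross-validation** (LOSO), so every subject is scored by a pattern
that never saw their data.

Validation asks, per subject, whether the signature response is higher
for the truly more intense condition (**two-alternative forced
choice**, exact binomial inference, ROC/AUC), whether each pattern
responds *only* to its own modality (the separate-modifiability
matrix), which voxels contribute reliably (subject-level **bootstrap**
of the weight map with BH-FDR control), whether body-site information
is decodable (**linear SVM**, upper vs lower limb), where local
information lives (**searchlight** sphere decoding of trial-level
data), and how responses unfold in time (**smoothed-FIR** time
courses, beta-series trial amplitudes).

## Worked example

```python
import painsig as ps

sim = ps.simulate_dataset(seed=1)          # 28 subjects × 3×2×2 design
cv = ps.loso_crossval(sim.dataset, "somatic", ps.TrainerConfig(seed=0))

fc = ps.forced_choice_from_scores(cv.table)
print(f"high-vs-low accuracy: {fc.accuracy:.0%}  (p = {fc.p_value:.1e})")

cross = cv.crossval_scores(sim.dataset.select(modality="vicarious"))
print(f"cross-modality accuracy: "
      f"{ps.forced_choice_from_scores(cross).accuracy:.0%}")
```

prints

```
high-vs-low accuracy: 100%  (p = 7.5e-09)
cross-modality accuracy: 61%
```

The somatic-trained signature orders every held-out subject's high
above their low somatic condition (100%, exact binomial p < 1e-4) but
is near chance on the vicarious images — the two intensities are
carried by different patterns. `examples/` contains one short script
per capability (scoring, training, somatotopy SVM, FIR time courses,
searchlight), each printing its numbers with a line on what they mean.

A thin CLI mirrors the pipeline: `painsig simulate | validate | train |
score | searchlight | report` (see `painsig --help`).

## Layout

```
src/painsig/     imgio, synth, datasets, signature, firstlevel,
                 train, inference, searchlight, pipeline, cli
examples/        narrative scripts, one per capability
tests/           pytest suite (unit, property, acceptance)
docs/methods.md  models, assumptions, numerical choices, limitations
```
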