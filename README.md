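# ptosiskit

Morphometry and machine-learning decision support for blepharoptosis
(drooping upper eyelid) surgery planning.

Choosing between the two standard ptosis operations — levator muscle
resection and frontalis suspension — conventionally hinges on a single
hand-measured quantity, the levator muscle function, compared against a
3–4 mm threshold. This package implements a richer, reproducible
pipeline for that decision: seven key periocular distances are measured
both on 2D photographs (pixel distances converted to millimetres with a
10 mm fiducial disc, scale S = D̄ᵢ/10 px·mm⁻¹) and on 3D face meshes
(as *surface* distances over an interpolated height field), and a
two-stage cascade of gradient-boosted decision trees first diagnoses
ptosis, then selects the operation.

The seven distances (each measured in 2D and 3D, giving 14 features per
eye plus the surgery label — 15 items per eye):

| symbol | distance |
|---|---|
| MRD1 | corneal light reflex → upper lid margin (signed) |
| MRD2 | corneal light reflex → lower lid margin |
| c | inner canthus → eye center |
| d | epicanthus → eye center |
| e | inner canthus → outer canthus |
| f | palpebral fissure length (horizontal canthal span) |
| g | palpebral fissure width (maximal vertical aperture) |

The classifier is written from first principles: the additive model
F(x) = f₀ + Σₘ η·hₘ(x), where each CART tree hₘ is grown greedily on the
first/second derivatives (g, h) of the logistic loss, with the
regularized second-order split gain
½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G_L+G_R)²/(H_L+H_R+λ)],
Newton leaf weights −G/(H+λ), constant per-round shrinkage η, and
exhaustive grid search over hyperparameters on a validation carve-out.

Because real patient photographs and scans cannot be shared, the
package ships a synthetic cohort generator with known ground-truth
anatomy (44/61/47 class structure over 152 eyes by default) so every
stage is testable end to end; `ptosiskit.reference` records the
published operating points of the original clinical evaluation for
comparison and consistency checks.

## Worked example

```bash
python examples/04_full_experiment.py
```

generates a 152-eye synthetic cohort with 0.3 mm annotation noise,
measures all 14 distances, splits 7:3 stratified, trains the cascade
under each feature scheme and prints:

```
Metric    Diagnostic discrimination     Surgical procedure classification
          3D        2D        BOTH      3D        2D        BOTH
ACC       0.9783    0.9783    0.9783    1.0000    0.9091    0.9394
AUC       0.9848    1.0000    0.9848    1.0000    0.9586    0.9774
F1-score  0.9846    0.9851    0.9846    1.0000    0.8889    0.9286
Precision 1.0000    0.9706    1.0000    1.0000    0.9231    0.9286
Recall    0.9697    1.0000    0.9697    1.0000    0.8571    0.9286
```

Each cell is one of the five binary-classification indicators on the 46
held-out test eyes: the diagnostic columns score "ptosis vs healthy" on
all test eyes, the surgical columns score "resection vs suspension" on
the truly surgical test eyes only. Synthetic cohorts are deliberately
cleaner than clinical data, so these values sit above the published
clinical operating points — see `docs/methods.md` for what they do and
do not demonstrate.

The other examples are smaller: `01_generate_cohort.py` (anatomy and
labelling rule), `02_measure_eye.py` (calibration plus both measurement
paths on one eye), `03_boosted_trees.py` (the boosted-tree core and
grid search).

A thin CLI drives the same pipeline stage by stage through an artifact
directory:

```bash
ptosiskit all --seed 0 --out runs/demo          # or: simulate, measure,
ptosiskit report --out runs/demo                # dataset, train, evaluate, report
```

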