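# Methods

This note documents the models, numerical choices and limitations
behind ptosiskit, in the order data flows through the pipeline.

## Clinical decision rule and synthetic anatomy

The package models the standard two-step surgical logic for
blepharoptosis. An eye is ptotic when its margin reflex distance 1
(MRD1, corneal light reflex to upper lid margin) falls below a
diagnosis threshold; among ptotic eyes, adequate levator muscle
function selects levator resection and poor function selects frontalis
suspension. Clinical practice quotes the function threshold as 3 or
4 mm; the generator defaults to 4 mm (`plan_threshold_mm`),
configurable. No standard MRD1 cutoff for "needs no surgery" exists in
the same crisp form, so the generator's `dx_threshold_mm = 2.5 mm` is
an explicit modelling stand-in, not a clinical claim.

Class-conditional anatomy (all mm, truncated normals):

| parameter | no surgery | resection | suspension |
|---|---|---|---|
| levator function | 13 ± 2 (10–17) | 6.5 ± 1.5 (> plan+0.5) | 2.0 ± 1.0 (< plan−0.5) |
| MRD1 | 4.0 ± 0.5 (≥ dx+0.3) | −1.4 + 0.34·lev ± 0.1 | −1.4 + 0.34·lev ± 0.1 |
| MRD2 | 5.0 ± 0.5 | same | same |
| fissure width | MRD1 + MRD2 ± 0.15 | same | same |
| canthal span | 29 ± 1.5 | same | same |
| eyeball radius | 12 ± 0.5 | same | same |

Two deliberate choices need justification. First, levator function is
*not* among the 14 measurable features, yet the plan stage must learn
from distances alone; the generator therefore ties MRD1 monotonically
to levator function for surgical eyes (severe ptosis goes with poor
function, as clinically observed), with a 1 mm guard band around the
plan threshold so that noise-free cohorts are linearly separable in lid
geometry. Passing tests on such cohorts demonstrates that the pipeline
*can recover a recoverable rule*; it says nothing about how well real
ptosis aetiology is predictable from photographs. Second, `noise_sd_mm`
is annotation noise, applied to landmark coordinates and disc readings
only — never to the anatomy — so labels always remain consistent with
the generating phenotype.

Cohort class counts use largest-remainder rounding of
`n_eyes × class_proportions` (defaults reproduce 44/61/47 at n = 152);
eyes alternate sides at random and left eyes are generated mirrored
about x = 0. All seven distances are reflection-invariant, so a single
right-eye measurement convention serves both sides.

## Synthetic periocular geometry

Each eye is a height field z(x, y) over the frontal plane: a spherical
cap of the eyeball radius over a 3 mm-radius central corneal zone,
joined by a value- and slope-matched cubic (Hermite) blend that decays
to the flat surround at 7 mm, dipping slightly below it like the soft
tissue around the globe. The mesh is this field sampled on a regular
grid (default spacing 0.5 mm) over the landmark bounding box plus a
3.5 mm margin.

Landmark placement resolves a genuine tension: the 2D path measures
frontal projections while the 3D path measures surface arcs, and both
are required to reproduce the same generating parameter. A landmark at
target distance d from the eye center is therefore placed at the
in-plane offset t solving (t + s(t))/2 = d (Brent's method, 1e-6 mm
tolerance), where s(t) is the analytic surface path length. The
curvature stretch is thus split evenly: the projected distance reads
d·(1 − ε/2) and the surface distance d·(1 + ε/2), with ε the local
stretch, ≤ ~1.5% on this geometry. Measured round-trip errors on
noise-free eyes are below 0.7% on both paths (the acceptance script
recomputes this bound). The canthal pair and the fissure aperture pair
are solved jointly by the same rule, scaling their separation about a
fixed midpoint.

## Morphometry

**2D.** Pixel coordinates (image y down) are converted to mm with the
fiducial scale S = mean(disc diameters px)/10 mm. MRD1 is signed by
the vertical order of upper lid margin vs eye center — negative when a
severely ptotic lid has crossed the reflex. Fissure length is the
horizontal canthal separation; all other measures are Euclidean.
The "eye center" landmark is the annotated corneal light reflex.

**3D.** The mesh is interpolated as a C1 Clough–Tocher height field
(depth as a function of the two frontal coordinates) which reproduces
every vertex exactly. A distance is the length of the in-plane segment
between two landmarks lifted onto that field: the segment is sampled at
≥ 128 points, the 3D polyline summed, and the step count doubled until
the length changes by < 1e-4 relative (verified against analytic sphere
geodesics to < 1% for separations up to 90°). This lifted-polyline
path is an upper bound near the true geodesic for the gentle, convex
patches measured here; exact polyhedral geodesics are out of scope. All
seven 3D measures are surface paths; a `mode="chord"` switch exposes
straight 3D chords for sensitivity analysis. 3D fissure length — the
*horizontal* fissure extent — uses the surface path between the canthi's
x-positions at their mean height, so canthal tilt lengthens the canthal
distance but not the fissure length, mirroring the 2D definition. The
OBJ reader accepts the v/f subset (1-based indices, polygon fan
triangulation) and model units are declared per mesh
(`model_units_per_mm`, 1 for generated cohorts).

Distances are reported to 4 decimals in CSV output; in-memory values
keep full precision.

## Records, splitting, balancing

A record is eye_id + 14 features + label; eyes missing any distance are
screened out at assembly (count logged). Normalization is per-feature
z-scoring with statistics frozen on the training rows (zero-variance
features map to 0 with a warning); the stored transform is reused on
test rows, so nothing leaks. The split is 7:3 by `round((1−f)·n)`,
stratified by label through largest-remainder class quotas, seeded.
Each cascade stage balances its binary training rows by oversampling
the minority class with replacement to parity; held-out rows are never
balanced. Eyes are split independently — two eyes of one synthetic
"patient" do not exist here, but the API documents that eye-level
splitting of real paired data risks leakage.

## Boosted trees

The classifier is a from-scratch second-order gradient-boosted CART
ensemble with logistic loss: per round, g = p − y and h = p(1 − p) at
the current margins (clamped to ±30), a tree grown greedily by the
regularized gain ½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G)²/(H+λ)] over all
features and observed midpoints, Newton leaf weights −G/(H+λ), and a
constant shrinkage η multiplying every leaf (no line search — the
per-round coefficient is the learning rate). Ties in gain break to the
lowest feature index, then lowest threshold; there is no subsampling
and no early stopping. Defaults: η = 0.1, 100 rounds, depth 3, λ = 1.
Grid search (default grid η ∈ {0.05, 0.1, 0.3} × depth {2, 3, 4} ×
rounds {50, 100, 200} × λ {0, 1}) minimizes log-loss on a stratified
25% validation carve-out of the training rows, ties keeping enumeration
order. The greedy splitter is property-tested against an exhaustive
enumeration oracle, and whole-model probabilities against xgboost at
matched settings.

## Cascade and evaluation

Stage 1 (positive = ptosis) trains on all rows; stage 2 (positive =
frontalis suspension, the costlier operation, so its precision tracks
avoidable cost) trains on surgical rows only. Decision thresholds are
0.5, configurable. Evaluation reports ACC, precision, recall, F1 and
AUC per task × scheme; AUC is the tie-corrected pairwise-ranking
statistic (= trapezoidal ROC area). Plan metrics are computed only
over *truly* surgical test eyes — the alternative (scoring stage 2 on
everything stage 1 waves through) mixes diagnostic errors into plan
quality; the package picks the conditioning that isolates each stage.
Degenerate denominators yield 0 with a warning.

## Problem sizes and limitations

The test suite and acceptance script use cohorts of 9–152 eyes for
schema/round-trip checks and five seeded 500-eye cohorts at 0.3 mm
annotation noise for parameter recovery; these sizes give stable
metrics while keeping a full run in minutes on one CPU. Known
limitations: the generator's class-conditional distributions are
plausible but invented, its geometry has no texture, no eyelashes, no
head pose or camera distortion, and its separability guard band makes
classification easier than clinical reality — so the near-perfect
synthetic metrics are an upper bound, not a forecast. The published
clinical operating points stored in `ptosiskit.reference` are used only
for display and internal-consistency checks (e.g. F1 = 2PR/(P+R)),
never as training targets.
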