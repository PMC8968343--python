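# Methods

## The grading problem

Standard automated perimetry measures differential light sensitivity at a
fixed grid of locations; the clinically meaningful object is the per-point
deviation from an age-matched normal (total deviation on Humphrey
instruments, the negatives of the comparison graph on Octopus instruments).
All deviations in this package use the Humphrey sign convention (negative =
loss) and right-eye spatial convention (x > 0 temporal, y > 0 superior, so
the physiologic blind spot sits near (+15°, ±3°)). Summary indices such as
mean deviation (MD) compress the field into one number and miss the *shape*
of the loss; the five-category morphological scale graded here keys on shape:
whether absolute defects exist, whether they connect to the blind spot,
whether both hemifields carry arcs around a spared central island, and
whether the central island has collapsed.

## Test-pattern geometry

Grid fixtures (`src/vfgrade/data/grid_*.csv`) carry point coordinates in
degrees plus blind-spot flags.

* **HFA 24-2** (54 points) and **HFA 30-2** (76 points) are the standard
  6°-spaced lattices offset 3° from the meridians; the 24-2 grid extends one
  extra point nasally (x = −27° at y = ±3°), making it the only shipped grid
  without mirror symmetry. The 24-2 point set is an exact subset of the
  30-2 set, which is what makes the 30-2 → 24-2 "conversion" a pure
  coordinate restriction with no interpolation.
* **Octopus G1** (59 points): the exact G1 coordinates are instrument
  constants that are not reproduced here; the shipped fixture is a
  *synthetic reconstruction* matching the pattern's qualitative geometry —
  59 irregularly spaced points including a foveal point, denser centrally,
  mirror-symmetric in both axes, at most five points temporal of 20°. Any
  analysis tied to the true G1 layout should replace this fixture (the file
  format is one line per point).

Adjacency, which drives defect connectivity, is the 8-neighbourhood
(distance ≤ 9°) on the rectangular Humphrey lattices and the Delaunay
triangulation with edges > 10° pruned on the irregular G1 grid. Delaunay
edges are the natural dual of the Voronoi parcellation used for rendering.

Left-eye exams are brought to right-eye orientation by reassigning the value
at (x, y) to (−x, y). On the asymmetric 24-2 grid the two nasal extension
points have no mirror image, so a raw left-eye 24-2 record cannot be
mirrored and the conversion raises an error listing the unmatched points;
30-2 and G1 exams mirror exactly, and the practical route for left 24-2 data
is to ingest the 30-2 exam, mirror, then restrict.

## Voronoi rendering

A field is rendered on a size-S square (default 224): pixel (i, j) has its
centre at degree coordinates ((j + 0.5 − S/2)/s, (S/2 − i − 0.5)/s) with
s = (S/2)/30 px per degree. Every pixel inside the inscribed circle (30°
eccentricity) takes the 8-bit grayscale of its Euclidean-nearest test point;
outside pixels are zero. Grayscale uses the *fixed* window [−35, +5] dB
mapped affinely onto [0, 255] with half-up rounding — a global window rather
than per-image normalisation, so absolute severity maps to absolute
darkness and images are comparable across patients and instruments.
Equidistant pixels go to the lowest point index (a pure determinism device;
it affects a measure-zero set of pixel/grid configurations). Test points
beyond 30° would fall outside the circle and are clamped radially onto its
boundary before rendering. Blind-spot points are rendered as ordinary
Voronoi cells.

## Rule cascade (the label oracle)

"Absolute defect" is operationalised as deviation ≤ −20 dB — a declared
constant (`RuleConfig.threshold`), chosen far below both the simulated
baseline (relative dips in [−5, +3] dB) and realistic test-retest noise, so
that the mask predicate is crisp. Blind-spot points are excluded from the
mask but their neighbours count as blind-spot-connected (the anchor must
exist geometrically for "connection to the blind spot" to be decidable).
The cascade is evaluated worst-first:

* **5** if all non-temporal points are masked and ≥ 90 % of points are
  masked (central collapse, possibly sparing the temporal crescent
  x > 20°), or the median deviation is ≤ −20 dB with no spared central
  island; subtype: diffuse if any temporal-crescent point survives, else
  total loss.
* **4** if only the central island (eccentricity ≤ 8°) is spared (tubular),
  or the island is spared while *both* hemifields contain a masked chain
  linking a blind-spot neighbour to the nasal field at x ≤ −10° (double
  arcuate).
* **3** if any masked component touches a blind-spot neighbour; subtype
  altitudinal if ≥ 90 % of one hemifield is masked, arcuate if the
  component reaches x ≤ −10°, else partial arcuate.
* **2** if a qualifying component exists with no blind-spot connection — a
  component of ≥ 2 points, or a singleton at least 8 dB below threshold
  (lone threshold-grazing points are treated as noise); subtype paracentral
  if the component lies wholly within 12°, else nasal step (centroid x < 0)
  or temporal wedge.
* **1** otherwise.

Every constant above lives in `RuleConfig` and is configurable. Mixed
presentations resolve to the first matching branch (worst first, then the
largest/deepest component for the subtype); alternates are not enumerated.
Deepening already-masked points cannot lower the category: the mask is
unchanged and only the category-5 median criterion can newly fire.

## Synthetic fields

The generator emulates the study conditions of a graded glaucoma corpus:
a truncated-normal baseline (sd 1 dB, window [−5, +3] dB) plus one defect
archetype at a −32 dB floor, per-point Gaussian noise (default 2 dB in the
training corpus), clamping to the device window [−40, +10] dB and rounding
to 0.1 dB. One-sided defects pick superior/inferior by a seeded fair coin.
Arcs are shortest adjacency paths through the 9–24° Bjerrum band from a
blind-spot neighbour to the most nasal band point (the partial form keeps
the blind-spot half), so connectivity holds by construction on any grid.
Labels are **generative** — they come from the requested subtype, never from
re-classification — so noise can degrade a CNN's input but cannot change
ground truth. Noiseless archetypes are recovered by the rule cascade with
100 % category and subtype agreement on both shipped grids (the
generator/oracle closure property that the acceptance checks assert).

What the generator does *not* emulate: test-retest variability structure,
fatigue and learning effects, cataract-induced diffuse depression as a
confounder, media opacities, or the empirical frequency mix of subtypes.
Passing tests therefore demonstrate internal consistency of the pipeline and
learnability of the archetype geometry, not clinical performance on patient
data.

## The residual grader

The network is implemented directly in numpy (im2col convolutions via BLAS,
batch normalisation, ReLU, residual blocks with identity or 1×1-projection
shortcuts, global average pooling, a fully connected softmax head), with
hand-derived backward passes verified against central finite differences.
Two presets:

* `resnet34` — the classical layout: 7×7 stride-2 stem, 3×3 stride-2 max
  pool, 16 residual blocks growing channels 64 → 512 (the feature map is
  7×7 at input 224), softmax over 5 classes.
* `small` — 3×3 stride-1 stem at input 64×64, four residual blocks with
  channels 16 → 64. This is the preset used in tests and the acceptance
  runs; full 224×224 ResNet-34 training is out of desk scale on one CPU,
  but the architecture is constructed and shape-verified.

Loss: cross-entropy plus L2, `−(1/N) ΣΣ y_ic log p_ic + (λ/2) Σ ω²`
(natural log, ε-clamp 1e−12 inside the log). The regularised weights are
convolution and linear kernels only — biases and normalisation parameters
are excluded, standard weight-decay practice. Optimiser: Adam; learning
rate `lr0 · 0.1^⌊epoch/step⌋`. Two named schedules mirror the two-corpus
transfer design: `hfa` (150 epochs, batch 8, lr0 1e−3, step 40, λ 1e−6) and
`octopus` (500 epochs, batch 8, lr0 1e−6, step 50, λ 1e−4); the Octopus
model is initialised from the final Humphrey parameters (`transfer_init`
copies every tensor and errors on any shape mismatch). Training keeps the
final-epoch weights; the best-validation epoch's weights are additionally
recorded in the history. Minority classes in a training split are upsampled
by vertical flip and uniform ±15° rotation (zero-filled and re-masked, so
the out-of-circle-zero invariant survives). Images enter the network as
grayscale/255 in [0, 1]. Saliency is the absolute input gradient of the
predicted-class logit, max-normalised to [0, 1].

Desk-scale training conditions used by the acceptance runs (sizes chosen so
the whole pipeline runs on one CPU in minutes): `small` preset at 64×64,
100 fields per class at 2 dB noise, 30 epochs, batch 32, lr 1e−3, 20 %
stratified holdout; the transfer comparison fine-tunes on 20 G1 fields per
class for 10 epochs (batch 8, lr 1e−4, λ 1e−4) against a from-scratch
counterpart under the identical schedule, evaluated on an independent G1
set, across five seeds.

## Metrics

Precision/recall use the standard orientation (precision = TP/(TP+FP),
recall = TP/(TP+FN)); F1 = 2TP/(2TP+FP+FN) is invariant under exchanging
the two error counts. One-vs-rest AUC is computed by the rank statistic
(Mann–Whitney; average ranks give ties half weight), which is what makes an
all-pairs counting oracle an exact cross-check; the "total" AUC is the
unweighted (macro) mean over classes present — the conservative choice
under class imbalance. The paired comparison of two graders is a two-tailed
paired t-test on per-case correctness indicators (the only pairing unit that
yields a within-dataset paired test); degenerate cases are fixed by
convention: identical vectors → (t = 0, p = 1), constant non-zero
difference → (±∞, 0) as the zero-variance limit.

## Structure–function sectors

Field points are grouped into 10 clusters, each linked to an angular sector
of the optic-nerve-head circle. The shipped tables are synthetic stand-ins:
36° angular wedges of the field, with cluster k mapped to the ONH arc
[36(10−k), 36(11−k))° — a disjoint cover of 360° encoding the inverted
field-to-disc correspondence. A cluster is damaged when its mean deviation
is ≤ −5 dB (declared constant, configurable). On the noiseless synthetic
corpus the mean damaged-cluster count increases strictly across categories
1→4, mirroring the expectation that structural damage grows with the
functional grade; the tables are data, not code, and can be replaced by a
published cluster scheme without touching the logic.

## Clinic logic

Timelines are keyed by (patient id, eye); progression is a category increase
relative to the immediately preceding exam (an MD-slope criterion is out of
scope — the grading scale is the unit of change). Category decreases are
retained in the timeline but not flagged. Follow-up advice is a table in
`data/followup.yaml` (12 / 6 / 3–6 / 1–3 / 1 months for categories 1–5);
progression overrides to 1–2 months and the override never lengthens the
interval. The store is a single versioned JSON file, diffable and
hand-editable.

## Numerical choices and degenerate inputs

* Deviations outside [−40, +10] dB are clamped on load with a warning.
* Grayscale rounding is half-up; Voronoi ties go to the lowest point index.
* Per-record seeds in `generate_dataset` follow
  `(master + 1_000_003·i) mod 2³¹`.
* Empty reliability-filter input returns two empty lists; an empty defect
  mask yields zero components; a class missing from a training split is an
  error naming the class.
* H-P-A boundaries are assigned to the worse stage (MD = −12 dB is severe,
  MD = −6 dB is moderate).

## Known limitations

* The CNN is CPU-bound numpy; the `resnet34` preset is faithful in
  structure but not practical to train here, and no attempt is made to
  reproduce clinical accuracies reported for models trained on patient
  corpora.
* The G1 grid and the 10-cluster tables are synthetic reconstructions (see
  above); replace the fixtures for instrument-exact work.
* The rule cascade is an oracle for the synthetic archetypes and a
  transparent baseline; it is not a model of specialist inter-rater
  behaviour on real fields, where mixed and shallow presentations dominate.
* Only the VF side of damaged-sector counting is implemented; fundus
  photographs are out of scope.
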