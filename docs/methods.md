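# Methods

## The problem and the pipeline

The package targets the setting where per-exam expert labels are scarce
but every CT exam has a free-text report. Training labels are extracted
from reports ("weak" or "auto" labels); a per-organ multiple-instance
classifier is trained on them; evaluation is against expert/ground-truth
labels. The pipeline stages and their contracts:

report text → organ-label vectors → (volume, mask) → organ crop →
slice bags → MIL classifier → per-category probabilities → organ
anomaly score → ensemble + threshold → decision.

## Report information extraction

Entity tagging is longest-match, left-to-right, case-insensitive over a
versioned YAML lexicon (`src/ctanomaly/data/lexicon.yaml`); regex
entries (prefix `re:`) cover size expressions. Relation extraction links
each modifier to the nearest non-modifier entity within the same
sentence by character gap, ties broken leftward; no cross-sentence
relations.

Certainty is an ordinal 0–4 grade from a cue table
("no evidence of" → 0, "cannot be excluded" → 1, "possible" → 2,
"suspicious for" → 3, assertive phrasing → 4). Decisions that the
grading source did not dictate, chosen here once and documented:

- A finding with no certainty modifier is graded 4 (an unhedged
  assertion is definite presence).
- If several certainty cues link to one finding, the minimum grade wins
  (explicit negation dominates).
- Kidney findings route left/right via the location modifier; without
  laterality both sides are flagged (conservative recall).
- A finding word missing from an organ's category table falls into an
  implicit `other` category, so the organ is still flagged abnormal and
  the invariant `abnormal == any(category)` holds for every vector.
- Findings with no linked location modifier are not attributed to any
  organ. Indirect peri-organ signs are intentionally not mapped to the
  organ.
- An organ's binary label is "any finding with grade ≥ 1", not the
  maximum grade over findings.

The engine is deterministic; a learned tagger can be substituted behind
the same `Entity`/`Relation`/`FindingRecord` contract.

## Preprocessing

Fixed composition order: **crop → window → resize → bag**. The organ is
bounding-box cropped with a 4-voxel margin and non-organ voxels set to
−1000 HU; windowing (level 100, width 300 HU) clips and scales to
[−1, 1]; trilinear resize to the target grid (256×256×64 by default)
then cannot introduce values outside [−1, 1]. Windowing before resize
keeps the background fill from bleeding mid-range values into the organ.
Slice bags stack `window = 5` adjacent axial slices as channels at
`step = 2`, giving `floor((D − 5)/2) + 1` bags; with D = 64 the last
slice (index 63) is never covered — accepted, no padding. Exams with
fewer than 40 or more than 300 axial slices are excluded.

## The MIL classifier

Architecture: a 2D conv encoder embeds each five-channel bag; a
single-layer unidirectional LSTM (hidden 128 by default) runs along the
bag sequence; a shared fully connected layer maps each step's hidden
state to per-category logits, which are averaged over the bag axis
(global average pooling along slices, the default of the two supported
pooling readings); independent sigmoids with mean binary cross-entropy
implement multi-label learning. The organ anomaly score is the maximum
category probability; an optional "any-abnormal" extra head exists
behind a config flag. The encoder is pluggable; the default is a small
trainable CNN (stride-2 3×3 conv blocks) so the package trains on one
CPU — large pretrained encoders are a drop-in via the same
forward/backward contract, not bundled.

Two implementation choices matter for trainability at this scale and are
deliberate:

- **Per-exam channel normalisation** in the encoder (statistics over the
  bag batch and spatial axes of the current forward pass, identical in
  training and inference). Phantom — and organ-masked clinical — crops
  are nearly constant across exams, so unnormalised features vary only
  microscopically and gradient descent stalls at the base-rate solution;
  normalising each exam against its own anatomy makes focal deviations
  dominate the feature scale. No running averages: outputs stay
  deterministic and independent of batch composition.
- **Spatial max pooling** at the encoder output: a focal lesion occupies
  a few percent of a slice, which average pooling dilutes below the
  noise floor; max pooling keeps the blob-detector activations.

The network, LSTM backprop-through-time, AdamW (decoupled weight decay
0.01) and cosine annealing are implemented in NumPy (float32; tests
switch to float64 for numerical gradient checks, which pass to ~1e-7).

## Training protocol

Patient-grouped k-fold cross-validation (k = 5): patients are shuffled
under a seed and split into folds differing by at most one patient; all
exams of a patient share a fold, so no identity leaks. Each fold trains
12 epochs and keeps the epoch with the highest validation AUC of the
organ-abnormal score (earliest epoch on ties). Validation AUC uses the
binary organ-abnormal score, not mean per-category AUC. Inference
averages the five models' category probabilities, then takes the max.
The decision threshold is the median of per-fold thresholds maximising
validation F1; the candidate grid is midpoints of sorted unique scores
plus {0, 1}, ties to the smallest threshold; `score ≥ t` is positive.

Package defaults are 12 epochs, AdamW, lr 2.3e-4 and cosine annealing —
a rate sized for large pretrained encoders. For the small CPU encoder
used in the tests and the acceptance script the training configuration
is lr 3e-3, batch size 8 — a standard Adam-scale rate for nets of this
size, fixed once before the evaluation runs.

## Evaluation statistics

- ROC AUC (Mann–Whitney), PR AUC (average precision), accuracy /
  sensitivity / specificity / F1 (F1 = 0 when its denominator is 0),
  Cohen's κ (marginal-product chance agreement; 1.0 in the degenerate
  all-agree single-class case).
- Percentile bootstrap CIs: 1000 resamples at exam level, 2.5th/97.5th
  percentiles; resamples with undefined statistics are redrawn so the
  count stays 1000, and the redraw count is tracked.
- DeLong's paired AUC test via structural components (placement values),
  two-sided normal approximation, no continuity correction; degenerate
  zero-variance ties give p = 1.
- Dice, with the both-empty convention 1.0; normalised surface Dice with
  boundaries from face-connected erosion difference (array borders count
  as boundary) and exact Euclidean distance transforms under anisotropic
  spacing; default tolerance 1 mm, per-organ configurable. Empty-mask
  conventions: both empty → 1.0, exactly one empty → 0.0.

All are cross-checked in the test suite against independent brute-force
oracles (exhaustive pair counting, hand-summed average precision,
explicit surface-distance search, label-preserving score-swap
permutation for DeLong).

## The phantom generator

Each exam is a fixed body ellipse (20 HU) on air (−1000 HU) holding six
disjoint ellipsoidal organs with tissue-like mean attenuations (liver
60, spleen 50, kidneys 30, pancreas 40, gallbladder 10 HU) plus
voxel-wise Gaussian noise (σ = 10 HU). Per (organ, category), a
spherical lesion is inserted with the configured prevalence (default
0.15 per category); hypodense categories (cyst, fatty change,
hydronephrosis) subtract the lesion contrast (default 40 HU), the rest
add it. Lesion centres are rejection-sampled so every lesion voxel lies
inside the organ; when the sampled radius cannot fit, smaller radii are
tried down to one voxel. Reports state each finding with the grade-4
template sentence and each normal organ with the grade-0 sentence.
Label noise corrupts organ statements independently at the configured
rate: abnormal organs lose their findings, normal organs gain one
spurious category — a corrupted statement always differs from the
truth, so the empirical corruption rate estimates the nominal rate
directly. Exams are assigned to patients at 1.7 exams/patient to
exercise patient-grouped folds. Everything is byte-reproducible under a
seed (NIfTI written through gzip with a fixed mtime).

What the phantom does **not** emulate: realistic anatomy and texture,
contrast phases, scanner artefacts, inter-patient anatomical variation,
lesion shape diversity, report language variety beyond the template
lexicon. Passing tests therefore demonstrate that the pipeline's
machinery — label extraction, preprocessing geometry, optimisation,
protocol, statistics — is correct and that contrast anomalies of the
configured size are learnable from noisy weak labels; they do not
certify clinical performance.

## Problem sizes

Default phantom grid 96×96×64 (2×2×3 mm); tests and the acceptance
script use a desk-scale configuration — 32×32×24 grid (4×4×6 mm), organ
crops resized to 24×24×16 (6 bags), encoder widths (8, 16, 32), feature
dim 32, LSTM hidden 64 — chosen once as the package's CPU-scale study
conditions. The end-to-end learnability run trains a single model on
2000 exams with 10% label noise and evaluates 200 held-out phantoms
(held-out liver AUC ≈ 0.97–0.98 across seeds). The dataset-size /
label-source experiment trains the full ensemble protocol at sizes
(30, 200, 600) with report-derived labels and size 30 with clean labels,
k = 5 folds, three seeds: larger noisy-label cohorts beat the small
clean-label cohort, and AUC increases with n (≈ 0.69 → 0.74 → 0.97
mean across seeds).

## Known limitations

- The lexicon covers the phantom's template language plus common
  English radiology phrasings; it is not a general clinical NER system
  (no Japanese processing, no negation scope beyond the cue table).
- Multi-organ segmentation itself is out of scope: masks are consumed
  as inputs, and only their Dice/NSD evaluation is implemented.
- The NumPy network is single-threaded and CPU-bound; it is a correct,
  small-scale realisation of the architecture, not a performance
  implementation.
- The anomaly score's max-over-categories rule assumes comparably
  calibrated category heads; the optional any-abnormal head is the
  alternative when that assumption is doubtful.
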