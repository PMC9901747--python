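# Methods

`calscreen` implements an automated screening pipeline for calcium-imaging
recordings of cultured astrocytes: each 16-bit time-lapse stack is collapsed
to a single projection image, cell somas are segmented by a descending
multi-level threshold sweep, per-ROI fluorescence traces are assembled into a
"feature image", and a panel of classical classifiers labels each recording
as control or disease.  A synthetic-recording generator provides ground-truth
data with the same statistical structure, so every stage can be validated
end to end.

## Projection

Three per-pixel temporal statistics summarise a T×H×W stack as one H×W
image:

* `maxint` — max over t of I(t, y, x);
* `std` — population standard deviation over t (divide-by-T; the common
  image-stack convention), rounded to an integer;
* `stdscale` — the std image stretched linearly so its min maps to 0 and its
  max to 65535 before quantisation.

All three end as 8-bit images via `round(v * 255 / 65535)`.  Only the std
image receives the contrast stretch — its raw dynamic range is a small
fraction of 16 bits, so quantising it directly (the `std` variant) crushes
most of its contrast; the stretch is what distinguishes `stdscale`.  The
max-intensity image is quantised directly.  Rounding is half-up everywhere,
applied once after a floating-point intermediate, so projections are
bit-reproducible across platforms.

## Segmentation (multi-level thresholding)

The 8-bit projection is first smoothed with a 5×5 box mean (reflected
borders; the window sum is computed in exact integer arithmetic and rounded
half-up, so the filter is also bit-stable).  A threshold then descends from
255 to 0; at each level the binary image `pixel >= t` is decomposed into
connected components (8-connectivity by default).  Candidate cell regions
evolve under three area criteria, in pixels:

* **junction** (default 500): when two or more growing regions meet inside
  one component they merge only if their current areas sum to at most this
  value; otherwise all of them freeze at their current pixels.  "Current"
  areas are the regions' sizes before absorbing the new component.
* **stopping** (default 3000): a growth step that would push a region past
  this area instead freezes it at its last conforming mask.  A merge is
  subject to the same rule: if the merged candidate component is too large,
  the merged region freezes at the union of its members' pixels, so no
  growth step ever exceeds the cap.
* **elimination** (default 500): after the sweep, surviving regions smaller
  than this are discarded as noise.

Components that touch only frozen regions spawn nothing — they are the halo
of a finished cell.  At threshold 0 the whole image is one component and the
ordinary rules apply: with several growing regions present the junction rule
mass-freezes them; a lone region either absorbs the image (if small enough)
or freezes at its last mask.  Binarisation uses `>=`, so saturated pixels
can seed regions at level 255.  The output is a dense integer label image
with ids 1..K and is a pure function of (image, parameters).

The defaults 500/3000/500 are the operating point used throughout; they are
sized for somas imaged at 25× on a 512×512 EMCCD (a soma of half-peak radius
8–14 px has a detected footprint of roughly 700–2300 px once its halo is
included).

## Evaluation

A segmentation is scored against ground truth with Intersection over
Minimum, IoM(S, GT) = |S∩GT| / min(|S|, |GT|), which saturates at 1 under
containment and therefore tolerates halo over-growth around a correctly
found soma.  Segments and ground truths are matched one-to-one, greedily by
descending IoM (ties broken by ascending ids for determinism); a pair counts
as a true positive only when its IoM is strictly greater than the threshold.
Precision, recall and F-score follow the usual definitions with 0/0 ratios
defined as 0.  A sweep over thresholds (default 0.1, 0.2, 0.3, 0.4, 0.5,
0.7) yields one report per level; because lowering the threshold can only
add acceptable pairs ahead of the greedy frontier, the F-score is
non-increasing in the threshold.  Study-level summaries average per-video
F-scores.  An exhaustive optimal-assignment oracle is kept in the test suite
and agrees with the greedy protocol on all tested instances.

## Features and augmentation

Traces are means of the **raw 16-bit** frames inside each ROI — the
projection image only locates the cells.  The K×T trace matrix of one
recording is its feature image.  Because all ROIs of a recording share one
treatment, any row permutation is a valid sample of the same class: each
recording is shuffled 200 times.  Every shuffled matrix is min-max
normalised to [0, 1], resampled to 32×128 with a separable cubic-convolution
kernel (Catmull-Rom, a = −0.5, pixel-centre alignment, edge-clamped taps, no
antialias prefilter — the kernel is pinned so resampled values are stable),
clipped back to [0, 1] (bicubic interpolation overshoots), and flattened
row-major to a length-4096 vector.  The per-image normalisation treats the
matrix as an image with a bounded intensity scale; a raw-scale mode is kept
behind a flag.  The height 32 reflects the typical ROI count per recording;
128 columns preserve the width:height ratio for 5-minute 1-Hz recordings.

The train/test split is at the **video** level (default 15 of 21 disease and
7 of 12 control videos in training, i.e. 66.7% of samples): shuffled copies
of one recording are near-duplicates, and letting them straddle the split
would leak the answer into the test set.  A sample-level split is possible
but deliberately discouraged.

## Classifier panel

Twenty presets spanning SVMs, k-NN, tree ensembles and single decision
trees (see `classification.CLASSIFIER_NAMES`).  The fine/medium/coarse
granularity naming maps to: Gaussian-kernel scales sqrt(P)/4, sqrt(P),
4·sqrt(P) (P = number of features; gamma = 1/scale²); neighbour counts 1,
10, 100 (capped at the fitting-fold size); at most 100/20/4 tree splits;
ensembles use 30 learners.  "RUSBoosted Trees" is realised as AdaBoost over
class-weight-balanced trees — the imbalance-aware boosting preset.
Distance-based models are standardised with training-split statistics;
trees consume raw features.  Training accuracy is reported as stratified
5-fold cross-validation on the training split (resubstitution accuracy is
also recorded); the held-out test set is never touched during model
selection.  The best classifier is the argmax of test accuracy with ties
broken by panel order.  Numeric parity with any other toolbox's presets is
a non-goal; the preset map is frozen so results are reproducible.

## Synthetic recordings

One simulated recording is a field of radially decaying somas over a dark
background.  Cell k has the time course

    F_k(t) = F0 + Σ_e A_e · exp(−(t − t_e)/τ),  t ≥ t_e,

with event times drawn frame-wise from a Poisson process (rate λ per frame)
and instant rise / exponential decay.  Disease recordings (label 1) model
the acute patient-IgG response: after a treatment-onset frame the event rate
and amplitude are multiplied by configurable factors (defaults ×2 and ×1.5).
A pixel is the sum over cells of profile × F_k(t), plus Poisson shot noise
and Gaussian read noise, rounded half-up and clipped to 16 bits.

The photometric profile is a Gaussian with half-peak exactly at the nominal
radius r, truncated at 1.9 r (a hard-disc profile is available for
closed-form oracle tests, since on a disc every ground-truth pixel carries
the analytic trace).  Ground truth is the half-peak disc, area ≈ πr².

Default scene: 512×512 frames (full EMCCD sensor), 300 frames at 1 Hz, 30
somas of radius 8–14 px with centres at least 46 px apart (≈1.6 soma
diameters — a healthy sparse culture), baseline 6000 counts, transient
amplitude 4000 counts, λ = 0.03 events/frame, τ = 8 frames, onset at frame
100, read noise σ = 50 counts, shot noise on.  The spacing matters for
parameter recovery: two growing regions freeze when their halos meet, at an
area of roughly π(d·r₁/(r₁+r₂))² for the smaller soma at centre distance d,
so recovering every planted soma against the 500-px elimination criterion
requires d ≳ 44 for the worst small-next-to-large pairing; random sequential
placement cannot reach that spacing for 30 such cells in a field much
smaller than the full sensor.

What the generator does **not** emulate: astrocyte processes/filopodia and
microdomain events, intercellular calcium waves, photobleaching, motion,
the ATP viability pulse at the end of the real protocol, and cell-shape
irregularity.  Passing tests therefore demonstrate correct mechanics and
recoverability under idealised soma-level signals, not performance on real
cultures.

## Numerical choices and degenerate inputs

* Rounding: half-up everywhere (`floor(x + 0.5)`), once per quantisation.
* Linear scaling of a constant image is undefined; it warns and returns the
  input unchanged.  IoM of an empty mask raises.
* Trace extraction requires at least one ROI; an all-background label image
  is an error, while a recording whose segmentation survives with zero ROIs
  is skipped by the pipeline with a per-video note.
* All randomness flows through named integer seeds (shuffle, split,
  simulator); two runs with identical configuration and seeds produce
  byte-identical reports.
* Greedy matching ties (equal IoM) are broken by ascending segment then
  ground-truth id.

## Problem sizes in the checks

The packaged acceptance checks run on scaled studies chosen as sensible
desk-scale experiments: segmentation recovery on 10 default-scene videos;
classification on a 12 disease + 8 control study with 50 shuffles per
recording (30 for the null-effect control study, where every classifier
must sit at chance).  For chance-level bounds the binomial unit is the
*video*, not the sample: shuffled copies of one recording are statistically
dependent, so n is the number of test videos.

## Known limitations

* The refused-merge rule freezes every region involved in a contact; a
  variant that lets regions keep growing separately would need a rule for
  partitioning the shared component and is not implemented.
* Greedy IoM matching is not guaranteed optimal for adversarial overlap
  patterns (the test oracle checks it on random geometric instances).
* The classifier presets are reasonable realisations of their names, not
  re-implementations of any specific toolbox's defaults.
* Segmentation assumes bright somas on a dark background; dense confluent
  cultures violate the spacing assumptions and will under-segment.
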