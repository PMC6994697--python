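# Methods

This note records the models implemented in `qpi-deathwatch`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic benchmarks do and do not demonstrate.

## Phase-to-mass model

Dry mass density per pixel follows m = φλ/(2πα) with φ the measured
phase (radians), λ the illumination wavelength (default 0.65 μm) and α
the specific refraction increment (default 0.18 μm³/pg, the standard
value for cellular dry matter). Cell dry mass is the sum of m over the
cell mask times the pixel area (μm²), so it is exactly linear in φ and
additive over disjoint masks. Phase is stored as float32 TIFF —
quantizing to integers would bias mass sums. The per-cell *density*
feature is reported in pg/pixel (mass / pixel count), matching the scale
used for classification; a pg/μm² value is recoverable through
`DryMassParams.pixel_size`.

## Tracking

**Assumptions.** One nucleus per cell, visible in a Hoechst-like channel
in every frame; nuclei move less than their spacing per frame; no
divisions (dividing or appearing cells are deliberately not modelled —
tracks can only be lost, never born; cells that are lost, merge, or drop
out of the foreground are excluded from analysis as incomplete
tracklets).

**Nuclei foreground (MSER).** The nuclei frame is min-max scaled to
8 bit and bright components are enumerated on the max-tree; a component
is kept when its relative area growth over `mser_delta` grey levels is
at most `mser_max_variation` and its area is within
[`mser_min_area`, `mser_max_area`]. Defaults: delta 5 (on the 8-bit
scale), area ∈ [30, 5000] px, max variation 0.5 — loose enough that a
nucleus yields at least one stable region, tight enough to drop noise
specks. The binary union of all stable regions is used, since the EM
stage only needs background suppression, not instance separation.

**Weighted EM.** Per frame, the 2-D Gaussian mixture is warm-started
from the previous frame and updated with `em_steps` = 5 iterations of EM
(a few steps suffice because the warm start is near the optimum, and
more steps would let components drift during transient morphology
changes). The EM runs separately inside each 4-connected foreground
cluster, on the components whose previous means fall inside it; a
component outside every cluster is assigned to the nearest cluster
within 2·√(largest covariance eigenvalue) and is otherwise flagged lost.
Pixel intensities weight the likelihood (brighter nuclei pixels count
more); the weighted log-likelihood is asserted non-decreasing across the
iterations. Covariance matrices are symmetrized and eigenvalue-floored
at 0.25 px² — the floor only engages for degenerate single-pixel
clusters, so the monotonicity guarantee is not disturbed in practice.
Frame-0 components start at the seed points with identity covariance and
equal weights.

**Movement-Regularized Watershed.** Foreground comes from a single
phase threshold frozen for the whole sequence (default: Otsu on frame 0;
configurable — synthetic benchmarks pass an explicit threshold because
post-death corpses are much dimmer than Otsu's frame-0 split), followed
by hole filling and removal of objects under `min_area` = 30 px. The
watershed floods the negated phase image from the tracked-nuclei seeds,
with two inter-frame constraints: the elevation inside the per-label
erosion (disk radius `r_e` = 5 px) of the previous masks is forced far
below every real elevation, and the admissible foreground is clipped to
the dilation (disk radius `r_d` = 5 px) of the previous foreground. After
flooding, prior ownership is enforced exactly: a pixel inside cell j's
eroded previous mask either belongs to j or leaves the foreground. The
radii bound the contour speed: r_e limits how fast a cell boundary can
retreat into a neighbour, r_d how fast the outline can advance into
background. 5 px/frame is generous for adherent cells at 3 min/frame.
The −∞ of the forced-catchment construction is realized as
(−|phase|max − 10⁶) so any standard watershed implementation applies.
Watershed and connected components use 4-connectivity; plateau ties
resolve by scan order, making the whole stage deterministic.

## Feature extraction

Eleven per-frame features per cell: mass (pg), area (px and μm²),
density (pg/px), centroid speed (px/frame), circularity (4πA/P² with the
Crofton perimeter, clipped to [0, 1]), moment-ellipse eccentricity,
histogram maximum (normalized frequency), histogram-maximum position and
histogram entropy (base 2, bits), and CDS. Histogram bins: 32 bins over
the global in-mask phase range of the sequence, frozen so the position
feature is comparable across frames. CDS uses the current frame's mask
on both frames, making it robust to segmentation jitter; the implemented
form divides the root-sum-of-squares by |Mₙ| (an `rms` variant dividing
inside the root is provided for sensitivity checks, but all defaults use
the standard form). CDS is undefined at frame 0 and forward-filled
before model input.

## Death detection

Targets are peak-normalized Gaussians, exp(−(t−t_death)²/(2σ²)) with
σ = 50 frames (2.5 h of timing uncertainty at 3 min/frame), identically
zero for survivors; peak normalization is what makes a fixed absolute
response threshold meaningful. The regressor is a 2-layer bidirectional
LSTM (100 units per direction) followed by fully connected layers
(100, 50, 100, ReLU, dropout 0.5) and a linear per-frame output, trained
with masked MSE, Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999), global gradient-norm
clipping at 1, decoupled weight decay 10⁻³, batch 256, 40 epochs, and
random-clipping augmentation (each signal shortened by up to 1/3 from a
random end; a death clipped away turns the sample into "alive-so-far").
Those are the reference defaults. The network is implemented directly in
NumPy (forward + backpropagation-through-time); sequences are
left-aligned and the backward direction flips each sequence within its
valid length, so hidden states never cross padding.

Inference: per-feature z-scoring with training-set statistics, then the
earliest maximum of the response; a maximum strictly above 0.4 is the
death frame, otherwise alive. Raising the threshold can only remove
detections (monotonicity). Evaluation follows the ±100-frame rule; with
annotated field-of-view ids, `leave_one_fov_out_splits` provides the
cross-validation protocol. Survival curves accumulate detected deaths
over the population (everyone alive at frame 0) and IT₅₀ is the first
frame at which the dead fraction reaches 0.5, in hours.

**Scaled-down training configuration.** The test-suite and acceptance
recovery runs use 200 synthetic cells (100 planted deaths) over 300
frames, 10 epochs, hidden width 32, batch 4, lr 10⁻², and augmentation
factor 3 (three independently clipped variants of each signal per
epoch). At this population size the reference batch of 256 would yield
almost no gradient steps, so the batch/lr/width are scaled with the
problem; the detection threshold (0.4), the ±100-frame rule, the target
σ and the epoch count are not scaled. This configuration recovers all
planted deaths with margin across seeds.

## Death-type classification

Each dying cell is summarized by its feature means over the
`window` = 200 frames (10 h) before death, never including the death
frame; shorter histories use what exists. A linear SVM (hinge loss,
C = 1.0, balanced class weights — C unset by any reference, so the
standard default) on z-scored density and CDS separates apoptotic from
lytic deaths; one model per cell line, since lines differ
morphologically, which is also why normalization is per line. The
decision margin (signed distance to the boundary, positive = apoptotic)
quantifies the "near the dividing line" ambiguity of intermediate
deaths. `feature_subset_sweep` reports cross-validated accuracy for all
feature subsets; it is a reporting tool and asserts nothing about which
subset wins. Two fluorescence statistics verify labels where reporter
channels exist: the caspase-3/7 onset (earliest frame reaching 1/3 of
the mean post-death caspase level over 200 frames) minus the death frame
— positive for apoptosis, ~0 for lytic death — and mean pre-death
in-nucleus Hoechst brightness (condensation proxy, higher for
apoptosis). The apoptotic-class proportion helper supports
caspase-inhibitor (z-VAD-FMK-style) population comparisons.

## Synthetic scenes

The generator emulates what the analysis depends on, not microscope
optics. Cells are anisotropic cosine-tapered phase blobs whose discrete
integrated mass is normalized to a scripted trajectory each frame
(exact at zero noise), moving as bounded random walks around
non-overlapping base positions (placement fails loudly after 100
attempts). Apoptotic deaths script area shrinkage at constant mass
(density up), frame-decorrelated boundary lobes and intensity flicker
(CDS up), a brightening/shrinking nucleus, then a mass collapse over ≤5
frames to a 5 % corpse; lytic deaths script swelling at constant mass
(density down) and an abrupt 1-frame collapse. Reporter channels are
mask-filling logistic onsets: caspase leads the PI step by
`caspase_delay_apoptotic` = 40 frames (2 h) for apoptotic cells and by 0
for lytic ones. The pre-death effect sizes are package choices made to
be qualitatively consistent with published death-aligned average curves
(roughly +80 % density for apoptosis, −50 % for lysis over the pre-death
window in the direct signal generator); they are configuration, not
measured values. Everything derives from one seeded generator, so equal
seeds give bitwise-equal scenes.

Not emulated: holographic reconstruction and optical point-spread,
halo/shade-off artifacts, cell division and collision, touching-cell
clusters, background drift, photobleaching. Consequently, passing
benchmarks show the algorithms are implemented correctly and recover
planted structure under realistic noise — not that real-data accuracy
matches any published figure; real validation requires annotated
microscope data.

**Benchmark sizes.** Tracking fidelity: 10 cells, 200 frames, 448×448 px,
zero noise, ~25 px cell spacing per 1 px/frame motion. MRW guarantees:
5 moving cells, 12 noisy frames, plus a 3-cell static sequence. Detector
and classifier recovery: the 200-cell signal population above. These
sizes were chosen so the full suite runs on a laptop-class single CPU in
minutes.

## Known limitations

- No track births or divisions: a cell entering the field, or a
  division, is ignored or discarded rather than modelled.
- The frozen global foreground threshold assumes stable illumination;
  drifting backgrounds would need per-frame thresholding, which the
  MRW's growth bound would then regularize.
- MSER stability is computed on the union of stable regions; two nuclei
  merging into one bright blob are separated only by the EM posterior,
  not by the region detector.
- The detector's absolute 0.4 threshold presumes peak-normalized
  targets; recalibration is needed if σ or the target normalization
  changes.
- The classifier is strictly binary; intermediate morphotypes
  (pyroptosis-like, ambiguous) land near the margin rather than in a
  class of their own.
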