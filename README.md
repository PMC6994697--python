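# qpi-deathwatch

Label-free detection and classification of single-cell death in
quantitative phase imaging (QPI) time-lapses.

QPI measures the optical phase shift φ (radians) per pixel, which is
proportional to the local dry mass of the cell. That makes it possible to
watch — without any stain — the events that define cell death: the steep
loss of dry mass when the plasma membrane ruptures, the condensation and
membrane blebbing of apoptosis ("dance of death"), and the swelling that
precedes lytic death (the necrosis-like morphotype shared by necroptosis,
pyroptosis, ferroptosis and accidental death). This package is aimed at
people running drug-response or cytotoxicity time-lapses on a QPI
microscope who want per-cell death timepoints, survival curves and a
morphotype call (apoptotic vs lytic) for each death.

## Method

The pipeline has three stages:

1. **Tracking.** Nuclei (Hoechst channel) are tracked by fitting a 2-D
   Gaussian mixture with a few steps of weighted EM per frame, warm-started
   from the previous frame; an MSER detector removes background before EM,
   and the EM runs separately inside each connected nuclei cluster. Whole
   cells are then segmented with a *Movement-Regularized Watershed* (MRW):
   a seeded watershed of the negated phase image in which pixels inside a
   per-label erosion Ŝₜ₋₁ of the previous masks cannot change owner, and no
   foreground pixel may appear outside a dilation F̂ₜ₋₁ of the previous
   foreground — so inter-frame contour movement is bounded by the
   erosion/dilation radii. Only cells tracked through every frame without
   loss or merging are analysed.

2. **Death detection.** Eleven per-frame features are extracted per cell —
   dry mass m = φλ/(2πα) integrated over the mask (λ = 0.65 μm,
   α ≈ 0.18 μm³/pg), area (px and μm²), density (pg/pixel), centroid speed,
   circularity, eccentricity, three phase-histogram features, and the
   *Cell Dynamic Score*

       CDS = (1/|Mₙ|) · sqrt( Σ_{x∈Mₙ} (Iₙ₋₁(x) − Iₙ(x))² ),

   the frame-to-frame intra-mask intensity change (high during apoptotic
   blebbing). A bidirectional LSTM regresses, per frame, a Gaussian target
   curve (peak 1 at the annotated death frame, σ = 50 frames; all-zero for
   survivors). At inference the death frame is the earliest maximum of the
   response when it exceeds 0.4, otherwise the cell is called alive.
   Detections within ±100 frames (±5 h at 3 min/frame) of the annotation
   count as correct. Cumulative death counts give the survival curve and
   IT₅₀ (time at which half the population has died).

3. **Death-type classification.** Each death is summarized by the mean of
   its features over the 200 frames (10 h) before death, and a linear SVM —
   one per cell line — separates apoptotic (high density, high CDS) from
   lytic (low density, low CDS) deaths using just those two features. Where
   caspase-3/7 and propidium iodide (PI) reporters exist, the caspase→PI
   onset delay and pre-death Hoechst brightness verify the labels.

A fully seeded synthetic-scene generator renders phase/nuclei/reporter
channels with ground-truth masks and planted deaths of both morphotypes, so
the whole pipeline is testable without any microscope data.

## Worked example

Run the full pipeline on a synthetic scene with six planted deaths
(three apoptotic, three lytic) among eight cells:

```python
from qpi_deathwatch.pipeline import run_pipeline

config = {
    "seed": 1,
    "scene": {
        "n_cells": 8, "T": 100, "H": 360, "W": 360, "noise_sd": 0.02,
        "death_plan": {"1": [40, "apoptotic"], "2": [48, "lytic"],
                        "3": [55, "apoptotic"], "4": [60, "lytic"],
                        "5": [35, "lytic"], "6": [70, "apoptotic"]},
        "predeath_window": 30,
    },
    "tracking": {"foreground_threshold": 0.1},
    "detector": {"hidden_units": 16, "batch_size": 4, "epochs": 8,
                  "learning_rate": 1e-2, "augment_factor": 3},
    "classifier": {"death_frame_source": "predicted", "window": 30},
}
outputs = run_pipeline(config, "example_out")
print(outputs["summary"])
print(outputs["predictions"].to_string(index=False))
print(outputs["types"].to_string(index=False))
```

prints

```
{'it50_hours': 2.9, 'n_tracked': 8, 'n_dead': 6, 'n_apoptotic': 3, 'n_lytic': 3}
 cell_id  death_frame  confidence
       1         43.0    0.521682
       2         53.0    0.482592
       3         58.0    0.514712
       4         66.0    0.509664
       5         42.0    0.467125
       6         77.0    0.516033
       7          NaN    0.232666
       8          NaN    0.228539
 cell_id      type    margin
       1 apoptotic  1.081154
       2     lytic -1.571327
       3 apoptotic  2.095299
       4     lytic -1.381345
       5     lytic -1.787213
       6 apoptotic  1.496393
```

All eight cells are tracked through the whole sequence; the six planted
deaths are detected within a few frames of their scripted timepoints
(confidence is the response maximum, thresholded at 0.4; cells 7–8 stay
below it and are called alive); the half-population death time IT₅₀ is
2.9 h (frame 58 at 3 min/frame); and every death is assigned the planted
morphotype, with the signed margin giving distance from the SVM boundary
(positive = apoptotic side). The same stages are exposed on the command
line as `qpi-deathwatch scene|track|features|detect|classify|run|report`.

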