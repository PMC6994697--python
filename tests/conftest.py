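"""Shared fixtures: synthetic datasets and the scaled-down trained detector.

The expensive fixtures are session-scoped so the benchmark-style checks
(tracking fidelity, detector recovery, classifier recovery) reuse one
computation each.
"""

from __future__ import annotations

import numpy as np
import pytest

from qpi_deathwatch.death_detection import DeathDetector, series_from_table
from qpi_deathwatch.synthetic_scenes import (
    SceneConfig,
    generate_feature_signals,
    generate_scene,
)
from qpi_deathwatch.tracking import (
    TrackingParams,
    filter_complete_tracklets,
    track_sequence,
)

# study conditions of the scaled-down detector recovery run: 200 cells
# (100 dying, 100 alive), 300 frames, 10 epochs, fixed seed
SIGNAL_SEED = 123
SIGNAL_T = 300
DETECTOR_PARAMS = dict(
    hidden_units=32,
    batch_size=4,
    learning_rate=1e-2,
    epochs=10,
    augment_factor=3,
    random_state=SIGNAL_SEED,
)


@pytest.fixture(scope="session")
def signal_dataset():
    """200 synthetic feature-signal cells: 50 apoptotic + 50 lytic deaths
    planted at frames 60..260, 100 survivors."""
    rng = np.random.default_rng(SIGNAL_SEED)
    plan = {
        cid: (int(rng.integers(60, 260)), "apoptotic" if cid <= 50 else "lytic")
        for cid in range(1, 101)
    }
    table, annotations = generate_feature_signals(
        200, SIGNAL_T, plan, noise_sd=0.05, seed=SIGNAL_SEED
    )
    ids, X = series_from_table(table)
    ann_map = {a.cell_id: a.death_frame for a in annotations}
    y = [ann_map.get(cid) for cid in ids]
    return {
        "table": table,
        "annotations": annotations,
        "plan": plan,
        "ids": ids,
        "X": X,
        "y": y,
    }


@pytest.fixture(scope="session")
def trained_detector(signal_dataset):
    det = DeathDetector(**DETECTOR_PARAMS)
    det.fit(signal_dataset["X"], signal_dataset["y"])
    return det


@pytest.fixture(scope="session")
def tracking_benchmark():
    """10 well-separated cells tracked over 200 noise-free frames."""
    cfg = SceneConfig(
        n_cells=10,
        T=200,
        H=448,
        W=448,
        noise_sd=0.0,
        motion_speed=1.0,
        seed=42,
    )
    seq, gt_masks, gt_centers, annotations = generate_scene(cfg)
    params = TrackingParams(foreground_threshold=0.1)
    trackset, masks, info = track_sequence(
        seq, [tuple(c) for c in gt_centers[0]], params
    )
    kept = filter_complete_tracklets(masks, trackset, info)
    return {
        "config": cfg,
        "sequence": seq,
        "gt_masks": gt_masks,
        "gt_centers": gt_centers,
        "trackset": trackset,
        "masks": masks,
        "info": info,
        "kept": kept,
        "params": params,
    }


@pytest.fixture()
def small_scene():
    """A quick 4-cell scene with one lytic and one apoptotic death."""
    cfg = SceneConfig(
        n_cells=4,
        T=30,
        H=220,
        W=220,
        noise_sd=0.01,
        seed=7,
        death_plan={2: (15, "lytic"), 3: (18, "apoptotic")},
        predeath_window=10,
    )
    return cfg, *generate_scene(cfg)
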