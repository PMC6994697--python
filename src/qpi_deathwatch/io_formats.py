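"""Readers and writers for the pipeline's on-disk artifacts.

Images and label masks travel as multi-page TIFF (one file per channel,
one page per frame); feature/tracklet/annotation tables as plain CSV;
configuration and acquisition metadata as JSON.  Phase is stored as
real-valued (float32) TIFF pages — dry mass is linear in phase, so
integer quantization would bias mass sums.

Frame indices are 0-based throughout; time in hours = frame *
frame_interval / 60.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageSequence",
    "CellMaskSequence",
    "AnnotationRecord",
    "FEATURE_COLUMNS",
    "TABLE_COLUMNS",
    "read_image_sequence",
    "write_image_sequence",
    "read_label_masks",
    "write_label_masks",
    "read_feature_table",
    "write_feature_table",
    "read_annotations",
    "write_annotations",
]

#: The 11 per-frame quantitative-phase features fed to the detector, in the
#: fixed documented column order of the feature table.
FEATURE_COLUMNS = [
    "mass",                # total dry mass (pg)
    "area_px",             # mask area (pixels)
    "area_um2",            # mask area (um^2)
    "density",             # mean per-pixel dry mass (pg/pixel)
    "speed",               # centroid displacement (px/frame)
    "circularity",         # 4*pi*A/P^2, clipped to [0, 1]
    "eccentricity",        # moment-ellipse eccentricity, [0, 1)
    "hist_max",            # max normalized histogram frequency
    "hist_max_position",   # phase value at the argmax bin center
    "hist_entropy",        # Shannon entropy of the histogram (bits)
    "cds",                 # Cell Dynamic Score
]

#: Full schema of the feature table: identifiers, features, centroid.
TABLE_COLUMNS = ["cell_id", "frame"] + FEATURE_COLUMNS + [
    "centroid_row",
    "centroid_col",
]


@dataclass
class ImageSequence:
    """Time-ordered multi-channel frame stack with acquisition metadata.

    Parameters
    ----------
    channels : mapping of channel name -> float array, shape (T, H, W)
        At least a ``"phase"`` channel (radians); optional ``"nuclei"``
        (Hoechst), ``"caspase"`` (Casp-3/7 reporter) and ``"pi"``
        (propidium iodide) channels.
    frame_interval : float
        Minutes per frame (> 0).
    pixel_size : float
        Micrometres per pixel (> 0).
    fov_id : str
        Opaque field-of-view identifier.
    """

    channels: dict[str, np.ndarray]
    frame_interval: float
    pixel_size: float
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        if "phase" not in self.channels:
            raise ValueError("ImageSequence requires a 'phase' channel")
        shapes = {name: np.asarray(a).shape for name, a in self.channels.items()}
        ref = shapes["phase"]
        if len(ref) != 3:
            raise ValueError(f"channel arrays must be (T, H, W); got {ref}")
        for name, shp in shapes.items():
            if shp != ref:
                raise ValueError(
                    f"channel {name!r} shape {shp} != phase shape {ref}"
                )
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")
        if not np.all(np.isfinite(self.channels["phase"])):
            raise ValueError("phase values must be finite")

    @property
    def phase(self) -> np.ndarray:
        return self.channels["phase"]

    @property
    def n_frames(self) -> int:
        return self.channels["phase"].shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels["phase"].shape

    def hours(self, frame: int | np.ndarray) -> np.ndarray:
        """Convert a 0-based frame index to hours since acquisition start."""
        return np.asarray(frame) * self.frame_interval / 60.0


@dataclass
class CellMaskSequence:
    """Per-frame labeled single-cell masks (0 = background).

    ``labels[t]`` is an integer (T-consistent) label image; a nonzero value
    is a persistent track id, identical across frames for the same cell.
    ``foreground[t]`` is the thresholded foreground mask the labels were
    carved from (optional).
    """

    labels: np.ndarray  # (T, H, W) non-negative int
    foreground: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be (T, H, W)")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def cell_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-cell death annotation: timepoint (or alive) and morphotype."""

    cell_id: int
    death_frame: int | None = None
    death_type: str = "none"  # {"apoptotic", "lytic", "none"}

    def __post_init__(self) -> None:
        if self.death_type not in ("apoptotic", "lytic", "none"):
            raise ValueError(f"unknown death_type {self.death_type!r}")
        if self.death_type != "none" and self.death_frame is None:
            raise ValueError("death_type set but death_frame missing")


# ---------------------------------------------------------------------------
# image stacks


def write_image_sequence(seq: ImageSequence, path: str | Path) -> None:
    """Write each channel as ``<path>/<channel>.tif`` plus metadata.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, arr in seq.channels.items():
        tifffile.imwrite(
            path / f"{name}.tif",
            np.asarray(arr, dtype=np.float32),
            photometric="minisblack",
        )
    meta = {
        "frame_interval": seq.frame_interval,
        "pixel_size": seq.pixel_size,
        "fov_id": seq.fov_id,
        "channels": sorted(seq.channels),
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))


def read_image_sequence(
    path: str | Path,
    channel_map: Mapping[str, str] | None = None,
    metadata: Mapping[str, float] | None = None,
) -> ImageSequence:
    """Read a multi-channel TIFF stack directory into an :class:`ImageSequence`.

    Parameters
    ----------
    path : directory containing one multi-page TIFF per channel.
    channel_map : optional mapping of channel name -> file name; defaults to
        the channel list recorded in ``metadata.json``.
    metadata : optional override for ``frame_interval`` / ``pixel_size`` /
        ``fov_id`` (required if no ``metadata.json`` is present).
    """
    path = Path(path)
    meta: dict = {}
    meta_file = path / "metadata.json"
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
    if metadata:
        meta.update(metadata)
    if channel_map is None:
        names = meta.get("channels")
        if names is None:
            names = sorted(p.stem for p in path.glob("*.tif"))
        channel_map = {name: f"{name}.tif" for name in names}
    channels = {}
    for name, fname in channel_map.items():
        arr = tifffile.imread(path / fname)
        if arr.ndim == 2:
            arr = arr[None]
        channels[name] = np.asarray(arr)
    shapes = {n: a.shape for n, a in channels.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"channel shapes differ: {shapes}")
    try:
        return ImageSequence(
            channels=channels,
            frame_interval=float(meta["frame_interval"]),
            pixel_size=float(meta["pixel_size"]),
            fov_id=str(meta.get("fov_id", "fov0")),
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"missing acquisition metadata: {exc}") from exc


# ---------------------------------------------------------------------------
# label masks


def write_label_masks(masks: CellMaskSequence, path: str | Path) -> None:
    """Write label masks as a multi-page int32 TIFF (lossless)."""
    labels = np.asarray(masks.labels)
    if labels.min() < 0:
        raise ValueError("labels must be non-negative")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.astype(np.int32), photometric="minisblack")
    if masks.foreground is not None:
        fg_path = path.with_name(path.stem + "_foreground" + path.suffix)
        tifffile.imwrite(fg_path, masks.foreground.astype(np.uint8), photometric="minisblack")


def read_label_masks(path: str | Path) -> CellMaskSequence:
    path = Path(path)
    labels = tifffile.imread(path)
    if labels.ndim == 2:
        labels = labels[None]
    fg_path = path.with_name(path.stem + "_foreground" + path.suffix)
    foreground = None
    if fg_path.exists():
        foreground = tifffile.imread(fg_path).astype(bool)
        if foreground.ndim == 2:
            foreground = foreground[None]
    return CellMaskSequence(labels=labels.astype(np.int64), foreground=foreground)


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    """Write a long-form feature table (one row per cell per frame) as CSV.

    Column order is fixed (:data:`TABLE_COLUMNS`); values are written with
    shortest-round-trip repr precision, so they parse back exactly.
    """
    unknown = set(features.columns) - set(TABLE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown feature column(s): {sorted(unknown)}")
    missing = set(TABLE_COLUMNS) - set(features.columns)
    if missing:
        raise ValueError(f"missing feature column(s): {sorted(missing)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features[TABLE_COLUMNS].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(TABLE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown feature column(s): {sorted(unknown)}")
    return df


# ---------------------------------------------------------------------------
# annotations


def write_annotations(records: list[AnnotationRecord], path: str | Path) -> None:
    rows = [
        {
            "cell_id": r.cell_id,
            "death_frame": "" if r.death_frame is None else int(r.death_frame),
            "death_type": r.death_type,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["cell_id", "death_frame", "death_type"]).to_csv(
        Path(path), index=False
    )


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        dframe = row["death_frame"]
        dframe = None if pd.isna(dframe) else int(dframe)
        records.append(
            AnnotationRecord(
                cell_id=int(row["cell_id"]),
                death_frame=dframe,
                death_type=str(row["death_type"]),
            )
        )
    return records
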