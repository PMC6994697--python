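"""Seeded synthetic QPI time-lapse scenes with ground-truthed death events.

The generator emulates the phenomenology of treated adherent-cell
time-lapses: smooth phase blobs whose integrated dry mass follows a
scripted trajectory, a Hoechst-like nuclei channel, and two planted
death morphotypes —

* **apoptotic**: the cell shrinks and condenses (density rises) while the
  membrane blebs (frame-decorrelated boundary/intensity fluctuation that
  drives the Cell Dynamic Score up), then the mass collapses over a few
  frames (secondary necrosis of the post-apoptotic corpse);
* **lytic**: the cell swells (area up, density down), then the mass
  collapses abruptly on membrane rupture.

Optional caspase-3/7 and propidium-iodide reporter channels follow
logistic onsets: for apoptotic cells the caspase onset precedes the PI
step by a configurable delay (default 40 frames = 2 h at 3 min/frame);
for lytic cells both rise together.

Everything is driven by one :class:`numpy.random.Generator`; identical
seeds give bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import AnnotationRecord, CellMaskSequence, ImageSequence

__all__ = [
    "SceneConfig",
    "PlacementError",
    "generate_scene",
    "generate_feature_signals",
    "generate_reporter_signals",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping initial nuclei cannot be placed."""


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene; defaults are the package's study
    conditions (a downsampled 10x field of view at 3 min/frame)."""

    n_cells: int = 15
    T: int = 200
    H: int = 512
    W: int = 512
    frame_interval: float = 3.0       # min/frame
    pixel_size: float = 0.5           # um/px
    #: cell_id (1-based) -> (death_frame, "apoptotic"|"lytic"); absent = survivor
    death_plan: dict[int, tuple[int, str]] = field(default_factory=dict)
    motion_speed: float = 1.0         # random-walk step sd, px/frame
    max_drift: float = 6.0            # reflecting bound on drift from base, px
    base_mass: float = 250.0          # pg
    base_radius: float = 14.0         # px
    noise_sd: float = 0.02            # phase noise, radians
    wavelength: float = 0.65          # um
    alpha: float = 0.18               # specific refraction increment, um^3/pg
    nucleus_sigma: float = 3.5        # px
    with_reporters: bool = False
    caspase_delay_apoptotic: int = 40  # frames caspase precedes PI/death
    caspase_delay_lytic: int = 0
    predeath_window: int = 100        # frames over which morphotype develops
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for cid, (dframe, kind) in self.death_plan.items():
            if not (0 <= dframe < self.T):
                raise ValueError(f"death_frame {dframe} outside [0, T) for cell {cid}")
            if kind not in ("apoptotic", "lytic"):
                raise ValueError(f"unknown death type {kind!r}")
            if not (1 <= cid <= self.n_cells):
                raise ValueError(f"death_plan cell id {cid} out of range")


# ---------------------------------------------------------------------------
# scripted trajectories

def _scripted_trajectory(cfg: SceneConfig, cid: int, rng: np.random.Generator):
    """Per-frame (mass, area_factor, bleb_amp, flicker) for one cell."""
    T = cfg.T
    mass = np.full(T, cfg.base_mass * (1.0 + 0.1 * rng.standard_normal()))
    area = np.ones(T)
    bleb = np.zeros(T)
    flicker = np.zeros(T)
    plan = cfg.death_plan.get(cid)
    if plan is None:
        return mass, area, bleb, flicker
    d, kind = plan
    w0 = max(0, d - cfg.predeath_window)
    ramp = np.zeros(T)
    if d > w0:
        ramp[w0:d] = np.linspace(0.0, 1.0, d - w0, endpoint=False) + 1.0 / (d - w0)
    ramp[d:] = 1.0
    if kind == "apoptotic":
        # shrinkage + condensation: area down at constant mass => density up
        area = 1.0 - 0.35 * ramp
        bleb = 0.10 * ramp
        flicker = 0.06 * ramp
        collapse_len = 4
    else:  # lytic: swelling at constant mass => density down
        area = 1.0 + 0.60 * ramp
        collapse_len = 1
    # mass collapse at death, small residual corpse
    residual = 0.05
    for k in range(collapse_len):
        t = d + k
        if t < T:
            frac = 1.0 - (k + 1) / collapse_len * (1.0 - residual)
            mass[t] = mass[w0] * frac
    if d + collapse_len < T:
        mass[d + collapse_len:] = mass[w0] * residual
    # the corpse is compact and quiet
    area[min(d + collapse_len, T - 1):] = 0.45 if kind == "apoptotic" else 0.7
    bleb[d:] = 0.0
    flicker[d:] = 0.0
    return mass, area, bleb, flicker


def _place_cells(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping base positions; raises PlacementError after 100 tries."""
    # worst-case support radius: swelling * blebbing, plus drift bound
    r_max = cfg.base_radius * math.sqrt(1.6) * 1.12 + cfg.max_drift
    min_sep = 2.0 * r_max + 2.0
    margin = r_max + 1.0
    if cfg.H - 2 * margin <= 0 or cfg.W - 2 * margin <= 0:
        raise PlacementError("scene too small for cell radius")
    centers: list[np.ndarray] = []
    for _ in range(cfg.n_cells):
        for attempt in range(100):
            c = np.array(
                [
                    rng.uniform(margin, cfg.H - margin),
                    rng.uniform(margin, cfg.W - margin),
                ]
            )
            if all(np.linalg.norm(c - p) >= min_sep for p in centers):
                centers.append(c)
                break
        else:
            raise PlacementError(
                f"could not place {cfg.n_cells} non-overlapping nuclei "
                f"in {cfg.H}x{cfg.W} after 100 attempts"
            )
    return np.array(centers)


def _random_walk(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """(T, n_cells, 2) drift offsets, reflected inside [-max_drift, max_drift]."""
    steps = rng.normal(0.0, cfg.motion_speed, size=(cfg.T, cfg.n_cells, 2))
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)
    # reflect into the bounded box (triangle-wave folding)
    D = cfg.max_drift
    if D > 0:
        walk = np.abs((walk + D) % (4 * D) - 2 * D) - D
    else:
        walk = np.zeros_like(walk)
    return walk


def generate_scene(cfg: SceneConfig):
    """Render a synthetic scene.

    Returns
    -------
    seq : ImageSequence
        Channels: phase (+ nuclei; + caspase/pi when ``with_reporters``).
    gt_masks : CellMaskSequence
        Ground-truth per-frame single-cell label masks (exact render support).
    gt_centers : ndarray, shape (T, n_cells, 2)
        Ground-truth nuclei centers (row, col) per frame.
    annotations : list of AnnotationRecord
        The planted death plan.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    bases = _place_cells(cfg, rng)
    walk = _random_walk(cfg, rng)

    # per-cell shape and scripted trajectories
    aspect = rng.uniform(0.7, 1.0, size=cfg.n_cells)
    theta = rng.uniform(0, np.pi, size=cfg.n_cells)
    traj = [_scripted_trajectory(cfg, cid, rng) for cid in range(1, cfg.n_cells + 1)]
    bleb_phase = rng.uniform(0, 2 * np.pi, size=(cfg.T, cfg.n_cells))
    bleb_lobes = rng.integers(6, 10, size=cfg.n_cells)
    flick = rng.standard_normal(size=(cfg.T, cfg.n_cells))

    mass_to_phase = 2 * np.pi * cfg.alpha / cfg.wavelength  # rad per (pg/um^2)
    T, H, W = cfg.T, cfg.H, cfg.W
    phase = np.zeros((T, H, W), dtype=np.float64)
    nuclei = np.zeros((T, H, W), dtype=np.float64)
    labels = np.zeros((T, H, W), dtype=np.int64)
    casp = np.zeros((T, H, W), dtype=np.float64) if cfg.with_reporters else None
    pi = np.zeros((T, H, W), dtype=np.float64) if cfg.with_reporters else None

    rr_full, cc_full = np.mgrid[0:H, 0:W]
    for t in range(T):
        for i in range(cfg.n_cells):
            cid = i + 1
            mass_t, area_t, bleb_t, flick_t = (a[t] for a in traj[i])
            mass_t = mass_t * (1.0 + flick_t * flick[t, i])
            r_eff = cfg.base_radius * math.sqrt(max(area_t, 1e-6))
            center = bases[i] + walk[t, i]
            pad = int(math.ceil(r_eff * (1 + bleb_t) / min(aspect[i], 1.0))) + 2
            r0 = max(0, int(center[0]) - pad)
            r1 = min(H, int(center[0]) + pad + 1)
            c0 = max(0, int(center[1]) - pad)
            c1 = min(W, int(center[1]) + pad + 1)
            rr = rr_full[r0:r1, c0:c1] - center[0]
            cc = cc_full[r0:r1, c0:c1] - center[1]
            ct, st = math.cos(theta[i]), math.sin(theta[i])
            u = (ct * rr + st * cc) / r_eff
            v = (-st * rr + ct * cc) / (r_eff * aspect[i])
            rad = np.sqrt(u * u + v * v)
            if bleb_t > 0:
                ang = np.arctan2(v, u)
                rad = rad / (1.0 + bleb_t * np.sin(bleb_lobes[i] * ang + bleb_phase[t, i]))
            w = np.where(rad < 1.0, np.cos(np.pi * rad / 2.0) ** 2, 0.0)
            support = w > 0
            total_w = w.sum()
            if total_w > 0:
                # amplitude chosen so the discrete Eq.-1 mass equals the script
                phi_amp = mass_t * mass_to_phase / (total_w * cfg.pixel_size**2)
                phase[t, r0:r1, c0:c1] += phi_amp * w
                labels[t, r0:r1, c0:c1][support] = cid

            # nuclei: Gaussian spot; apoptotic condensation brightens/shrinks it
            plan = cfg.death_plan.get(cid)
            condense = 0.0
            if plan is not None and plan[1] == "apoptotic":
                ramp = traj[i][2][t] / 0.10 if traj[i][2][t] > 0 else (1.0 if t >= plan[0] else 0.0)
                condense = ramp
            sig = cfg.nucleus_sigma * (1.0 - 0.3 * condense)
            amp = 1.0 + 0.8 * condense
            d2 = rr * rr + cc * cc
            nuclei[t, r0:r1, c0:c1] += amp * np.exp(-d2 / (2 * sig * sig))

            if cfg.with_reporters and plan is not None:
                d, kind = plan
                delay = (
                    cfg.caspase_delay_apoptotic
                    if kind == "apoptotic"
                    else cfg.caspase_delay_lytic
                )
                casp_level = float(expit((t - (d - delay)) / 2.0))
                pi_level = float(expit((t - d) / 0.5))
                casp[t, r0:r1, c0:c1][support] = casp_level
                pi[t, r0:r1, c0:c1][support] = pi_level

    if cfg.noise_sd > 0:
        phase = phase + rng.normal(0.0, cfg.noise_sd, size=phase.shape)
        nuclei = nuclei + rng.normal(0.0, cfg.noise_sd / 2, size=nuclei.shape)

    channels = {"phase": phase, "nuclei": nuclei}
    if cfg.with_reporters:
        channels["caspase"] = casp
        channels["pi"] = pi
    seq = ImageSequence(
        channels=channels,
        frame_interval=cfg.frame_interval,
        pixel_size=cfg.pixel_size,
        fov_id=f"synthetic-seed{cfg.seed}",
    )
    gt_masks = CellMaskSequence(labels=labels)
    gt_centers = bases[None, :, :] + walk
    annotations = [
        AnnotationRecord(
            cell_id=cid,
            death_frame=cfg.death_plan[cid][0] if cid in cfg.death_plan else None,
            death_type=cfg.death_plan[cid][1] if cid in cfg.death_plan else "none",
        )
        for cid in range(1, cfg.n_cells + 1)
    ]
    return seq, gt_masks, gt_centers, annotations


# ---------------------------------------------------------------------------
# direct feature-signal synthesis (no rendering)

def generate_feature_signals(
    n_cells: int,
    T: int,
    death_plan: dict[int, tuple[int, str]] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    predeath_window: int = 200,
    fov_ids: int = 1,
) -> tuple[pd.DataFrame, list[AnnotationRecord]]:
    """Emit 11-feature time series directly, with class-conditional signatures.

    Apoptotic cells show rising density and CDS in the ``predeath_window``
    frames before death; lytic cells show rising area and falling density;
    both show a sustained mass drop at death; survivors are stationary.
    ``noise_sd`` is a relative (multiplicative) noise level; 0 gives
    constant survivor signals.

    Returns a long-form feature table (``TABLE_COLUMNS`` plus ``fov``) and
    the matching annotations.
    """
    death_plan = death_plan or {}
    rng = np.random.default_rng(seed)
    frames = np.arange(T)
    rows = []
    annotations = []
    for cid in range(1, n_cells + 1):
        base = {
            "mass": 250.0 * (1 + 0.1 * rng.standard_normal()),
            "density": 2.0 + 0.15 * rng.standard_normal(),
            "speed": abs(1.0 + 0.2 * rng.standard_normal()),
            "circularity": min(0.98, 0.85 + 0.05 * rng.standard_normal()),
            "eccentricity": min(0.95, abs(0.4 + 0.1 * rng.standard_normal())),
            "hist_max": min(0.9, 0.30 + 0.05 * rng.standard_normal()),
            "hist_entropy": 3.0 + 0.2 * rng.standard_normal(),
            "cds": abs(0.05 + 0.01 * rng.standard_normal()),
        }
        mass = np.full(T, base["mass"])
        density = np.full(T, base["density"])
        cds = np.full(T, base["cds"])
        speed = np.full(T, base["speed"])
        circ = np.full(T, base["circularity"])
        ecc = np.full(T, base["eccentricity"])
        hist_max = np.full(T, base["hist_max"])
        hist_entropy = np.full(T, base["hist_entropy"])
        area = mass / density

        plan = death_plan.get(cid)
        if plan is not None:
            d, kind = plan
            w0 = max(0, d - predeath_window)
            ramp = np.zeros(T)
            if d > w0:
                ramp[w0:d] = np.linspace(0, 1, d - w0, endpoint=False)
            ramp[d:] = 1.0
            if kind == "apoptotic":
                density = density * (1 + 0.8 * ramp)
                cds = cds * (1 + 6.0 * ramp)
                circ = np.minimum(0.99, circ + 0.08 * ramp)
            else:
                density = density * (1 - 0.5 * ramp)
                speed = speed * (1 - 0.3 * ramp)
            area = mass / density
            if kind == "lytic":
                area = area.copy()  # swelling already implied by density drop
            # sustained mass collapse at death
            collapse_len = 4 if kind == "apoptotic" else 1
            residual = 0.08
            for k in range(collapse_len):
                if d + k < T:
                    mass[d + k] = base["mass"] * (
                        1 - (k + 1) / collapse_len * (1 - residual)
                    )
            if d + collapse_len < T:
                mass[d + collapse_len:] = base["mass"] * residual
            post = slice(min(d + collapse_len, T), T)
            density[post] = density[min(d + collapse_len, T - 1)] * 0.5
            cds[post] = 0.01
            speed[post] = 0.05
            area = np.where(frames >= d, mass / np.maximum(density, 1e-6), area)
            annotations.append(AnnotationRecord(cid, d, kind))
        else:
            annotations.append(AnnotationRecord(cid, None, "none"))

        if noise_sd > 0:
            def jitter(x):
                return x * (1 + rng.normal(0, noise_sd, size=T))
            mass, density, cds, speed, area = map(
                jitter, (mass, density, cds, speed, area)
            )
            hist_max = jitter(hist_max)
            hist_entropy = jitter(hist_entropy)
            circ = np.clip(jitter(circ), 0, 1)
            ecc = np.clip(jitter(ecc), 0, 0.999)

        df = pd.DataFrame(
            {
                "cell_id": cid,
                "frame": frames,
                "mass": mass,
                "area_px": area,
                "area_um2": area * 0.25,
                "density": density,
                "speed": speed,
                "circularity": circ,
                "eccentricity": ecc,
                "hist_max": hist_max,
                "hist_max_position": density,  # histogram mode tracks density
                "hist_entropy": hist_entropy,
                "cds": cds,
                "centroid_row": 0.0,
                "centroid_col": 0.0,
            }
        )
        df.loc[0, "cds"] = np.nan  # CDS undefined at frame 0
        df["fov"] = (cid - 1) % fov_ids
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    return table, annotations


def generate_reporter_signals(
    T: int,
    death_frame: int,
    kind: str,
    caspase_delay: int | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell caspase-3/7 and PI reporter time series with logistic onsets.

    The caspase onset precedes the PI step (= death) by ``caspase_delay``
    frames for apoptotic cells (default 40 = 2 h at 3 min/frame) and rises
    simultaneously for lytic cells (default 0).
    """
    if kind not in ("apoptotic", "lytic"):
        raise ValueError(f"unknown death type {kind!r}")
    if caspase_delay is None:
        caspase_delay = 40 if kind == "apoptotic" else 0
    t = np.arange(T, dtype=float)
    casp = expit((t - (death_frame - caspase_delay)) / 2.0)
    pi = expit((t - death_frame) / 0.5)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        casp = casp + rng.normal(0, noise_sd, T)
        pi = pi + rng.normal(0, noise_sd, T)
    return casp, pi
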