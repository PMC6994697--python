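"""Nuclei tracking and single-cell segmentation across a time-lapse.

The tracker has two stages:

1. **Nuclei tracking** — a 2-D Gaussian mixture is fitted to the nuclei
   channel with a few steps of weighted EM per frame, warm-started from
   the previous frame so component identities persist.  Background pixels
   are excluded beforehand with an MSER (maximally stable extremal
   regions) detector, and the EM runs separately inside each connected
   foreground cluster.  No births or divisions are modelled; appearing
   cells are ignored and stranded components are flagged lost.

2. **Cell segmentation** — the tracked nuclei seed a watershed of the
   (negated) phase image, constrained by the previous frame's masks: the
   *Movement-Regularized Watershed* (MRW).  Pixels inside a per-label
   erosion of the previous single-cell masks cannot change owner, and no
   foreground pixel may appear farther than the dilation radius outside
   the previous foreground — bounding the inter-frame contour motion by
   the erosion/dilation radii.

Only cells tracked through the whole sequence without loss or merging
("complete tracklets") are passed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk, max_tree
from skimage.segmentation import watershed

from .io_formats import CellMaskSequence, ImageSequence

__all__ = [
    "GaussianComponent",
    "NucleiTrackSet",
    "TrackingParams",
    "CellTracker",
    "segment_foreground",
    "mser_nuclei_foreground",
    "initialize_tracks",
    "em_update",
    "split_nuclei_masks",
    "movement_regularized_watershed",
    "track_sequence",
    "filter_complete_tracklets",
]

_STRUCT4 = ndi.generate_binary_structure(2, 1)  # 4-connectivity throughout


@dataclass
class GaussianComponent:
    """One tracked nucleus: a 2-D Gaussian with a persistent identity."""

    id: int
    mean: np.ndarray          # (row, col), px
    covariance: np.ndarray    # 2x2 SPD, px^2
    weight: float = 1.0       # mixing proportion within its cluster

    def copy(self) -> "GaussianComponent":
        return GaussianComponent(
            self.id, self.mean.copy(), self.covariance.copy(), self.weight
        )


@dataclass
class NucleiTrackSet:
    """Per-frame Gaussian components and nuclei label images."""

    components: list[list[GaussianComponent]]
    nuclei_labels: np.ndarray                    # (T, H, W) int
    lost_ids: set[int] = field(default_factory=set)
    loglik_history: list[dict[int, list[float]]] = field(default_factory=list)
    # loglik_history[t][cluster_label] = weighted log-likelihood per EM step


@dataclass
class TrackingParams:
    """Tunable tracking constants (all config-exposed)."""

    foreground_threshold: float | None = None  # radians; None = Otsu on frame 0
    min_area: int = 30                         # px, small-object removal
    mser_delta: int = 5                        # grey levels on 8-bit scale
    mser_min_area: int = 30
    mser_max_area: int = 5000
    mser_max_variation: float = 0.5
    em_steps: int = 5                          # "several steps" per frame
    r_e: int = 5                               # erosion radius (MRW), px
    r_d: int = 5                               # dilation radius (MRW), px
    cov_floor: float = 0.25                    # eigenvalue floor, px^2
    lost_radius_factor: float = 2.0            # x sqrt(max cov eigenvalue)


# ---------------------------------------------------------------------------
# foreground segmentation


def segment_foreground(phase_frame, threshold: float, min_area: int = 30):
    """Threshold the phase image, fill holes, drop small specks."""
    mask = np.asarray(phase_frame) >= threshold
    mask = ndi.binary_fill_holes(mask, structure=_STRUCT4)
    if min_area > 1:
        labels, n = ndi.label(mask, structure=_STRUCT4)
        if n:
            sizes = np.bincount(labels.ravel())
            mask = sizes[labels] >= min_area
            mask &= labels > 0
    return mask


def mser_nuclei_foreground(
    nuclei_frame,
    delta: int = 5,
    min_area: int = 30,
    max_area: int = 5000,
    max_variation: float = 0.5,
):
    """Binary union of maximally stable extremal regions of the nuclei image.

    The frame is min-max scaled to 8 bit; bright components are enumerated
    on the max-tree and a component is kept when its relative area growth
    over ``delta`` grey levels, (|Q_{v-delta}| - |Q_v|)/|Q_v|, is at most
    ``max_variation`` and its area lies in [min_area, max_area].  The
    returned mask is the union of all such regions.
    """
    img = np.asarray(nuclei_frame, dtype=float)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros(img.shape, dtype=bool)
    img8 = np.round((img - lo) / (hi - lo) * 255.0).astype(np.uint8)

    parent, order = max_tree(img8, connectivity=1)
    parent = parent.ravel()
    flat = img8.ravel().astype(np.int32)
    n = flat.size

    area = np.ones(n, dtype=np.int64)
    for p in order[::-1]:
        q = parent[p]
        if q != p:
            area[q] += area[p]

    root = order[0]
    # canonical nodes: one representative pixel per component
    canonical = (flat != flat[parent]) | (np.arange(n) == root)

    selected = np.zeros(n, dtype=bool)
    for p in np.flatnonzero(canonical):
        a = area[p]
        if a < min_area or a > max_area:
            continue
        v = flat[p]
        # ancestor component at level <= v - delta
        q = p
        while flat[parent[q]] > v - delta and parent[q] != q:
            q = parent[q]
        anc = parent[q]
        if flat[anc] > v - delta:  # ran into the root before dropping delta
            anc = q if flat[q] <= v - delta else anc
        variation = (area[anc] - a) / a
        if variation <= max_variation:
            selected[p] = True

    # a pixel is in the union if any component on its root path is selected
    flag = selected.copy()
    for p in order:
        q = parent[p]
        if q != p and flag[q]:
            flag[p] = True
    return flag.reshape(img.shape)


# ---------------------------------------------------------------------------
# Gaussian mixture nuclei tracking


def initialize_tracks(seed_points) -> list[GaussianComponent]:
    """One identity-covariance component per frame-0 seed point."""
    seeds = [np.asarray(s, dtype=float) for s in seed_points]
    if len({tuple(np.round(s, 6)) for s in seeds}) != len(seeds):
        raise ValueError("duplicate seed points")
    n = len(seeds)
    return [
        GaussianComponent(
            id=i + 1, mean=s, covariance=np.eye(2), weight=1.0 / max(n, 1)
        )
        for i, s in enumerate(seeds)
    ]


def _log_gauss2(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log pdf of a 2-D Gaussian at rows of X (analytic 2x2 inverse)."""
    a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
    det = a * c - b * b
    det = max(det, 1e-300)
    d = X - mean
    quad = (c * d[:, 0] ** 2 - 2 * b * d[:, 0] * d[:, 1] + a * d[:, 1] ** 2) / det
    return -0.5 * (quad + np.log(det)) - np.log(2 * np.pi)


def _cluster_loglik(
    X: np.ndarray, w: np.ndarray, comps: list[GaussianComponent]
) -> tuple[float, np.ndarray]:
    """Weighted log-likelihood and responsibilities for one cluster."""
    logp = np.column_stack(
        [np.log(max(c.weight, 1e-300)) + _log_gauss2(X, c.mean, c.covariance) for c in comps]
    )
    m = logp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
    resp = np.exp(logp - lse[:, None])
    return float((w * lse).sum()), resp


def _floor_cov(cov: np.ndarray, floor: float) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() < floor:
        vals = np.maximum(vals, floor)
        cov = (vecs * vals) @ vecs.T
    return cov


def em_update(
    components: list[GaussianComponent],
    nuclei_frame,
    nuclei_foreground,
    n_steps: int = 5,
    cov_floor: float = 0.25,
    lost_radius_factor: float = 2.0,
):
    """Update the mixture with ``n_steps`` of weighted EM, per cluster.

    Clusters are the 4-connected components of the nuclei foreground; each
    cluster's EM runs only on the components whose previous means fall
    inside it (or within a covariance-scaled radius of it).  Pixel
    intensities weight the likelihood.

    Returns (updated components, lost ids this frame, per-cluster
    log-likelihood histories).  The weighted log-likelihood is
    non-decreasing over the EM iterations within each cluster.
    """
    img = np.asarray(nuclei_frame, dtype=float)
    fg = np.asarray(nuclei_foreground, dtype=bool)
    labels, n_clusters = ndi.label(fg, structure=_STRUCT4)

    # component -> cluster assignment
    assignment: dict[int, list[GaussianComponent]] = {}
    lost: set[int] = set()
    cluster_coords: dict[int, np.ndarray] = {}
    for lab in range(1, n_clusters + 1):
        cluster_coords[lab] = np.argwhere(labels == lab)
    for comp in components:
        r, c = np.round(comp.mean).astype(int)
        lab = 0
        if 0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]:
            lab = int(labels[r, c])
        if lab == 0:
            # nearest cluster within the allowed radius, else lost
            max_eig = float(np.linalg.eigvalsh(comp.covariance).max())
            radius = lost_radius_factor * np.sqrt(max(max_eig, 1e-12))
            best, best_d = 0, np.inf
            for cl, coords in cluster_coords.items():
                d = np.sqrt(((coords - comp.mean) ** 2).sum(axis=1)).min() if len(coords) else np.inf
                if d < best_d:
                    best, best_d = cl, d
            if best and best_d <= radius:
                lab = best
            else:
                lost.add(comp.id)
                continue
        assignment.setdefault(lab, []).append(comp)

    updated: list[GaussianComponent] = []
    histories: dict[int, list[float]] = {}
    for lab, comps in assignment.items():
        X = cluster_coords[lab].astype(float)
        w = np.clip(img[tuple(cluster_coords[lab].T)], 0.0, None)
        if w.sum() <= 0:
            w = np.ones(len(X))
        comps = [c.copy() for c in comps]
        # renormalize mixing weights within the cluster
        wsum = sum(c.weight for c in comps)
        for c in comps:
            c.weight = c.weight / wsum if wsum > 0 else 1.0 / len(comps)

        ll, resp = _cluster_loglik(X, w, comps)
        hist = [ll]
        for _ in range(n_steps):
            wr = w[:, None] * resp
            Nk = wr.sum(axis=0)
            for k, comp in enumerate(comps):
                if Nk[k] <= 1e-12:
                    continue  # starved component keeps previous parameters
                mu = (wr[:, k] @ X) / Nk[k]
                d = X - mu
                cov = (wr[:, k] * d.T) @ d / Nk[k]
                comp.mean = mu
                comp.covariance = _floor_cov(cov, cov_floor)
                comp.weight = Nk[k] / Nk.sum()
            ll, resp = _cluster_loglik(X, w, comps)
            hist.append(ll)
        histories[lab] = hist
        updated.extend(comps)

    # keep the original order; carry lost components unchanged (frozen)
    by_id = {c.id: c for c in updated}
    out = []
    for comp in components:
        if comp.id in by_id:
            out.append(by_id[comp.id])
        else:
            out.append(comp.copy())
    return out, lost, histories


def split_nuclei_masks(
    components: list[GaussianComponent], nuclei_foreground, exclude: set[int] | None = None
) -> np.ndarray:
    """Label each foreground pixel by the maximal-responsibility component."""
    fg = np.asarray(nuclei_foreground, dtype=bool)
    out = np.zeros(fg.shape, dtype=np.int64)
    comps = [c for c in components if not (exclude and c.id in exclude)]
    if not comps or not fg.any():
        return out
    coords = np.argwhere(fg).astype(float)
    logp = np.column_stack(
        [np.log(max(c.weight, 1e-300)) + _log_gauss2(coords, c.mean, c.covariance) for c in comps]
    )
    winners = np.argmax(logp, axis=1)
    ids = np.array([c.id for c in comps])
    out[fg] = ids[winners]
    return out


# ---------------------------------------------------------------------------
# Movement-Regularized Watershed


def _per_label_erosion(label_img: np.ndarray, radius: int) -> np.ndarray:
    """Erode each nonzero label independently with a disk structuring element."""
    if radius <= 0:
        return label_img.copy()
    selem = disk(radius)
    out = np.zeros_like(label_img)
    for lab in np.unique(label_img):
        if lab == 0:
            continue
        er = ndi.binary_erosion(label_img == lab, structure=selem)
        out[er] = lab
    return out


def movement_regularized_watershed(
    phase_frame,
    foreground,
    seeds,
    prev_labels=None,
    prev_foreground=None,
    r_e: int = 5,
    r_d: int = 5,
):
    """Seeded watershed of the phase image with inter-frame regularization.

    With a previous frame available, the elevation inside the per-label
    erosion of the previous masks is forced far below everything else so
    those pixels stay with their prior owner, and the admissible
    foreground is clipped to the dilation of the previous foreground so
    no pixel appears farther than ``r_d`` outside it.  Frame 0 (no
    previous masks) runs a plain seeded watershed.

    Returns (label image S_t, effective foreground F*_t).
    """
    phase = np.asarray(phase_frame, dtype=float)
    fg = np.asarray(foreground, dtype=bool)
    seeds = np.asarray(seeds)

    if prev_labels is None:
        f_star = fg
        s_hat = None
    else:
        s_hat = _per_label_erosion(np.asarray(prev_labels), r_e)
        f_hat = ndi.binary_dilation(
            np.asarray(prev_foreground, dtype=bool), structure=disk(r_d)
        )
        f_star = fg & f_hat

    elevation = -phase
    if s_hat is not None and (s_hat > 0).any():
        # forced catchment of the prior owner: far below any real elevation
        big = np.abs(phase).max() + 1e6
        elevation = elevation.copy()
        elevation[s_hat > 0] = -big

    markers = np.where(f_star, seeds, 0)
    labels = watershed(elevation, markers=markers, mask=f_star, connectivity=1)

    if s_hat is not None:
        # exact ownership guarantee: a pixel inside another cell's eroded
        # previous mask cannot change owner (it may only leave the foreground)
        keep = (s_hat > 0) & f_star
        labels[keep] = s_hat[keep]
    return labels, f_star


# ---------------------------------------------------------------------------
# sequence-level driver


@dataclass
class TrackletInfo:
    """Per-cell bookkeeping produced by :func:`track_sequence`."""

    empty_frames: dict[int, list[int]]
    merged_ids: set[int]
    lost_ids: set[int]

    def complete_ids(self, all_ids: list[int]) -> list[int]:
        return [
            i
            for i in all_ids
            if i not in self.lost_ids
            and i not in self.merged_ids
            and not self.empty_frames.get(i)
        ]


def track_sequence(
    seq: ImageSequence,
    seeds,
    params: TrackingParams | None = None,
):
    """Run MSER -> EM -> nuclei split -> MRW over all frames.

    Parameters
    ----------
    seq : ImageSequence with ``phase`` and ``nuclei`` channels.
    seeds : frame-0 nucleus seed points, list of (row, col).
    params : tracking constants; foreground threshold defaults to Otsu on
        frame 0, frozen for the sequence.

    Returns (NucleiTrackSet, CellMaskSequence, TrackletInfo).
    """
    params = params or TrackingParams()
    if "nuclei" not in seq.channels:
        raise ValueError("tracking requires a 'nuclei' channel")
    phase = seq.phase
    nuclei = seq.channels["nuclei"]
    T, H, W = phase.shape

    threshold = params.foreground_threshold
    if threshold is None:
        threshold = float(threshold_otsu(phase[0]))

    components = initialize_tracks(seeds)
    all_ids = [c.id for c in components]
    nuclei_labels = np.zeros((T, H, W), dtype=np.int64)
    cell_labels = np.zeros((T, H, W), dtype=np.int64)
    fg_seq = np.zeros((T, H, W), dtype=bool)
    per_frame_components: list[list[GaussianComponent]] = []
    loglik_history: list[dict[int, list[float]]] = []
    lost_ids: set[int] = set()
    merged_ids: set[int] = set()
    empty_frames: dict[int, list[int]] = {i: [] for i in all_ids}

    prev_labels = None
    prev_fg = None
    for t in range(T):
        nuc_fg = mser_nuclei_foreground(
            nuclei[t],
            delta=params.mser_delta,
            min_area=params.mser_min_area,
            max_area=params.mser_max_area,
            max_variation=params.mser_max_variation,
        )
        components, lost_t, hist = em_update(
            components,
            nuclei[t],
            nuc_fg,
            n_steps=params.em_steps,
            cov_floor=params.cov_floor,
            lost_radius_factor=params.lost_radius_factor,
        )
        lost_ids |= lost_t
        loglik_history.append(hist)
        nuclei_labels[t] = split_nuclei_masks(components, nuc_fg, exclude=lost_ids)
        per_frame_components.append([c.copy() for c in components])

        fg = segment_foreground(phase[t], threshold, params.min_area)
        labels, f_star = movement_regularized_watershed(
            phase[t],
            fg,
            nuclei_labels[t],
            prev_labels=prev_labels,
            prev_foreground=prev_fg,
            r_e=params.r_e,
            r_d=params.r_d,
        )
        cell_labels[t] = labels
        fg_seq[t] = f_star

        present = set(np.unique(labels)) - {0}
        for cid in all_ids:
            if cid not in present and cid not in lost_ids:
                empty_frames[cid].append(t)
        # merge check: a live cell whose nucleus sits in another cell's region
        for comp in components:
            if comp.id in lost_ids:
                continue
            r, c = np.round(comp.mean).astype(int)
            if 0 <= r < H and 0 <= c < W:
                owner = int(labels[r, c])
                if owner not in (0, comp.id):
                    merged_ids |= {comp.id, owner}
        prev_labels = labels
        prev_fg = f_star

    trackset = NucleiTrackSet(
        components=per_frame_components,
        nuclei_labels=nuclei_labels,
        lost_ids=lost_ids,
        loglik_history=loglik_history,
    )
    masks = CellMaskSequence(labels=cell_labels, foreground=fg_seq)
    info = TrackletInfo(
        empty_frames=empty_frames, merged_ids=merged_ids, lost_ids=lost_ids
    )
    return trackset, masks, info


def filter_complete_tracklets(
    masks: CellMaskSequence, trackset: NucleiTrackSet, info: TrackletInfo | None = None
) -> list[int]:
    """Ids of cells present in every frame, never lost and never merged."""
    ids = sorted({c.id for frame in trackset.components for c in frame})
    if info is not None:
        return info.complete_ids(ids)
    kept = []
    for cid in ids:
        if cid in trackset.lost_ids:
            continue
        if all((masks.labels[t] == cid).any() for t in range(masks.n_frames)):
            kept.append(cid)
    return kept


class CellTracker:
    """Convenience wrapper bundling :class:`TrackingParams` with the driver."""

    def __init__(self, params: TrackingParams | None = None, **overrides):
        params = params or TrackingParams()
        if overrides:
            params = replace(params, **overrides)
        self.params = params

    def track(self, seq: ImageSequence, seeds):
        return track_sequence(seq, seeds, self.params)
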