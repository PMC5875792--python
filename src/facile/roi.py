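"""ROI masks, automated segmentation, time-course extraction, cell tracking.

Manual label masks are the primary input: segmentation of somata in this
kind of data is ordinarily drawn by hand over the SUM image and the activity
maps. :func:`auto_segment` automates the same cues — fluorescence intensity
(SUM image), response amplitude (F1/F0 map) and response phase — so an
end-to-end pipeline can run unattended on synthetic data; both paths produce
identical downstream types.

Cross-session tracking matches segmented cells between two visits to the
same retinal location by mutual-nearest-neighbour centroid distance after a
rigid between-session translation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import closing, disk, remove_small_objects
from skimage.segmentation import watershed

from .datatypes import ImagingSession
from .fourier_maps import ActivityMaps

__all__ = [
    "RoiMask",
    "CellRecord",
    "TrackedCell",
    "validate_mask",
    "auto_segment",
    "extract_timecourses",
    "match_cells",
]

logger = logging.getLogger(__name__)


@dataclass
class RoiMask:
    """Integer label image: 0 = background, k = cell k."""

    label_image: np.ndarray
    relabel_map: dict[int, int] | None = None  # old -> new ids, set by validate_mask

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ValueError("label_image must be 2-D")
        if np.any(self.label_image < 0):
            raise ValueError("labels must be non-negative")

    @property
    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.label_image)
        return ids[ids > 0]


@dataclass
class CellRecord:
    """One segmented cell: time course plus derived response statistics.

    Statistics (F0, F1, phase, noise, significance, polarity) are unset until
    :func:`facile.response_stats.quantify_cell` fills them. ``valid`` is
    cleared when F0 <= 0 (the normalized response is undefined).
    """

    cell_id: int
    centroid: tuple[float, float]  # (x, y) px
    n_pixels: int
    timecourse: np.ndarray
    f0: float | None = None
    f1: float | None = None
    phase: float | None = None
    norm_response: float | None = None
    noise_mean: float | None = None
    noise_sd: float | None = None
    significant: bool | None = None
    polarity: str = "UNCLASSIFIED"
    valid: bool = True


@dataclass
class TrackedCell:
    """A cell identified in two sessions."""

    session_a_id: int
    session_b_id: int
    match_distance: float  # micrometers


def validate_mask(
    mask: RoiMask, session: ImagingSession | None = None, min_area: int = 4
) -> RoiMask:
    """Check shape, drop undersized ROIs, relabel to consecutive ids.

    ROIs smaller than ``min_area`` pixels are removed (count logged);
    remaining labels are renumbered 1..n preserving their original order,
    with the mapping recorded on the returned mask.
    """
    img = mask.label_image
    if session is not None and img.shape != session.frame_shape:
        raise ValueError(
            f"mask shape {img.shape} != frame shape {session.frame_shape}"
        )
    ids, counts = np.unique(img[img > 0], return_counts=True)
    keep = ids[counts >= min_area]
    n_dropped = ids.size - keep.size
    if n_dropped:
        logger.info("dropped %d ROIs smaller than %d px", n_dropped, min_area)
    out = np.zeros_like(img, dtype=np.uint16)
    mapping: dict[int, int] = {}
    for new_id, old_id in enumerate(keep, start=1):
        out[img == old_id] = new_id
        mapping[int(old_id)] = new_id
    return RoiMask(label_image=out, relabel_map=mapping)


def _circular_sd(phases: np.ndarray, weights: np.ndarray | None = None) -> float:
    """sqrt(-2 ln r), r = mean resultant length (optionally weighted)."""
    z = np.exp(1j * phases)
    if weights is not None and weights.sum() > 0:
        r = np.abs(np.sum(weights * z) / weights.sum())
    else:
        r = np.abs(z.mean())
    r = min(max(r, 1e-12), 1.0)
    return float(np.sqrt(-2.0 * np.log(r)))


def auto_segment(
    maps: ActivityMaps,
    smoothing_sigma: float = 1.5,
    amplitude_weight: float = 1.0,
    min_area: int = 12,
    max_area: int = 1200,
    min_distance: int = 8,
    closing_radius: int = 4,
    phase_split_sd: float = 1.0,
) -> RoiMask:
    """Segment somata from the SUM image and activity maps.

    A composite cue image (normalized SUM image + ``amplitude_weight`` x
    normalized F1 amplitude map) is grey-closed (radius ``closing_radius``,
    filling the darkened-nucleus dip so each soma is one blob) and smoothed;
    cells are detected as local maxima and grown by watershed within an
    Otsu-thresholded support, constrained to [min_area, max_area] pixels. Candidates whose internal
    response phase is incoherent (circular SD above ``phase_split_sd`` rad,
    amplitude-weighted) are split into phase-homogeneous parts — two somata
    of opposite polarity fused by the intensity cue separate cleanly because
    their phases differ by half a cycle.
    """
    def _norm(img: np.ndarray) -> np.ndarray:
        rng_ = np.ptp(img)
        return (img - img.min()) / rng_ if rng_ > 0 else np.zeros_like(img)

    cue = _norm(maps.sum_image) + amplitude_weight * _norm(maps.f1_amp_map)
    if np.ptp(cue) == 0:
        return RoiMask(label_image=np.zeros(maps.sum_image.shape, dtype=np.uint16))
    if closing_radius > 0:
        cue = closing(cue, disk(closing_radius))
    cue = gaussian(cue, sigma=smoothing_sigma, preserve_range=True)
    support = cue > threshold_otsu(cue)
    support = remove_small_objects(support, max_size=min_area - 1)
    if not support.any():
        return RoiMask(label_image=np.zeros(cue.shape, dtype=np.uint16))
    peaks = peak_local_max(
        cue, min_distance=min_distance, labels=support, exclude_border=False
    )
    if peaks.size == 0:
        return RoiMask(label_image=np.zeros(cue.shape, dtype=np.uint16))
    markers = np.zeros(cue.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-cue, markers=markers, mask=support)

    labels = _split_by_phase(
        labels, maps.f1_phase_map, maps.f1_amp_map, phase_split_sd, min_area
    )

    # area bounds + renumber
    out = np.zeros_like(labels, dtype=np.uint16)
    next_id = 1
    for lab in np.unique(labels[labels > 0]):
        region = labels == lab
        area = int(region.sum())
        if min_area <= area <= max_area:
            out[region] = next_id
            next_id += 1
    return RoiMask(label_image=out)


def _split_by_phase(
    labels: np.ndarray,
    phase_map: np.ndarray,
    amp_map: np.ndarray,
    sd_threshold: float,
    min_area: int,
) -> np.ndarray:
    """Split phase-incoherent candidates along their dominant phase axis."""
    out = labels.copy()
    next_id = int(labels.max()) + 1
    for lab in np.unique(labels[labels > 0]):
        region = labels == lab
        phases = phase_map[region]
        weights = amp_map[region]
        if phases.size < 2 * min_area:
            continue
        if _circular_sd(phases, weights) <= sd_threshold:
            continue
        # an antiphase pair is incoherent at the fundamental but coherent at
        # the doubled angle; incoherent noise (unresponsive cells) is not —
        # only split when the doubled-angle axis is well defined
        w_sum = weights.sum()
        z2 = np.sum(weights * np.exp(2j * phases))
        if w_sum <= 0 or np.abs(z2) / w_sum < 0.5:
            continue
        # dominant axis from the doubled-angle resultant; assign each pixel
        # to the nearer of the two antipodal poles
        axis = 0.5 * np.angle(z2)
        d = np.cos(phases - axis)  # >0: near axis pole, <0: near antipole
        side_a = np.zeros_like(region)
        side_a[region] = d >= 0
        side_b = region & ~side_a
        # keep only spatially connected, sufficiently large parts
        parts = []
        for side in (side_a, side_b):
            lab_img, n = ndi.label(side)
            for k in range(1, n + 1):
                part = lab_img == k
                if part.sum() >= min_area:
                    parts.append(part)
        if len(parts) >= 2:
            out[region] = 0
            for part in parts:
                out[part] = next_id
                next_id += 1
    return out


def extract_timecourses(
    session: ImagingSession, mask: RoiMask
) -> list[CellRecord]:
    """Per-ROI mean time course over the ROI's pixels, one record per cell.

    Each record carries the unweighted mean of the ROI's pixel traces per
    frame, the ROI centroid (x, y) and pixel count; response statistics are
    left unset.
    """
    if mask.label_image.shape != session.frame_shape:
        raise ValueError(
            f"mask shape {mask.label_image.shape} != frame shape {session.frame_shape}"
        )
    frames = session.frames
    records = []
    for cell_id in mask.roi_ids:
        sel = mask.label_image == cell_id
        ys, xs = np.nonzero(sel)
        tc = frames[:, ys, xs].mean(axis=1, dtype=np.float64)
        records.append(
            CellRecord(
                cell_id=int(cell_id),
                centroid=(float(xs.mean()), float(ys.mean())),
                n_pixels=int(sel.sum()),
                timecourse=tc,
            )
        )
    return records


def match_cells(
    records_a: list[CellRecord],
    records_b: list[CellRecord],
    session_transform: tuple[float, float] = (0.0, 0.0),
    max_dist_um: float = 5.0,
    um_per_px: float = 1.0,
) -> list[TrackedCell]:
    """One-to-one greedy mutual-nearest-neighbour matching of two cell sets.

    ``session_transform`` (dx, dy) maps session-b pixel coordinates into the
    session-a frame (b + transform ~ a). Pairs are accepted closest-first;
    no pair exceeds ``max_dist_um``. Swapping the two sessions yields the
    same pairs (up to exact ties).
    """
    if not records_a or not records_b:
        return []
    a = np.array([r.centroid for r in records_a], dtype=np.float64)
    b = np.array([r.centroid for r in records_b], dtype=np.float64)
    b = b + np.asarray(session_transform, dtype=np.float64)
    dist = np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])
    dist = dist * um_per_px

    tracked: list[TrackedCell] = []
    d = dist.copy()
    while True:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if not np.isfinite(d[i, j]) or d[i, j] > max_dist_um:
            break
        tracked.append(
            TrackedCell(
                session_a_id=records_a[i].cell_id,
                session_b_id=records_b[j].cell_id,
                match_distance=float(d[i, j]),
            )
        )
        d[i, :] = np.inf
        d[:, j] = np.inf
    return tracked
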