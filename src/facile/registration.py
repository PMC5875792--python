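"""Frame-wise rigid (translation-only) motion estimation and correction.

Eye motion during in vivo retinal imaging displaces each video frame
relative to the retina. Over a small field the dominant component is a
per-frame translation; this module estimates it by phase cross-correlation
against a reference image and resamples each frame back. When a co-registered
reflectance channel is available its (higher-contrast) vasculature is the
better registration target; shifts estimated on it can be applied to the
fluorescence channel.

Limitations: no rotation or shear, and no intra-frame (scan-strip) distortion
correction — displacement is assumed constant within a frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation

from .datatypes import ImagingSession

__all__ = ["MotionTrace", "estimate_shifts", "correct_motion", "apply_motion"]


@dataclass
class MotionTrace:
    """Per-frame displacement of each frame relative to the reference.

    ``dx[i], dy[i]`` is the estimated translation of frame *i* in pixels
    (x = columns, y = rows); correction translates the frame by the negation.
    ``reference_frame_index`` is the frame used as reference, or -1 when the
    reference was a mean image. ``degenerate`` is set when the input was
    constant and correlation was undefined (shifts forced to zero).
    """

    dx: np.ndarray
    dy: np.ndarray
    reference_frame_index: int = -1
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=np.float64)
        self.dy = np.asarray(self.dy, dtype=np.float64)
        if self.dx.shape != self.dy.shape or self.dx.ndim != 1:
            raise ValueError("dx and dy must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.dx.size

    @property
    def displacements(self) -> np.ndarray:
        """(n_frames, 2) array of (dx, dy)."""
        return np.stack([self.dx, self.dy], axis=1)


def _reference_image(session: ImagingSession, reference) -> tuple[np.ndarray, int]:
    frames = session.frames
    if reference == "first":
        return frames[0].astype(np.float64), 0
    if reference == "mean":
        # mean of the first 10 frames: robust to single-frame noise
        return frames[: min(10, len(frames))].mean(axis=0, dtype=np.float64), -1
    idx = int(reference)
    if not 0 <= idx < len(frames):
        raise ValueError(f"reference index {idx} out of range")
    return frames[idx].astype(np.float64), idx


def estimate_shifts(
    session: ImagingSession,
    reference="mean",
    upsample: int = 1,
) -> MotionTrace:
    """Estimate per-frame translation by phase cross-correlation.

    Parameters
    ----------
    reference : "first", "mean", or int
        Registration target: the first frame, the mean of the first 10
        frames (default), or a given frame index.
    upsample : int >= 1
        Subpixel precision of 1/upsample px.

    Returns
    -------
    MotionTrace
        Displacement of each frame relative to the reference. A constant
        (zero-contrast) stack yields all-zero shifts with ``degenerate=True``.
    """
    if session.n_frames < 2:
        raise ValueError("need at least 2 frames to estimate motion")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    ref, ref_idx = _reference_image(session, reference)
    n = session.n_frames
    if np.ptp(session.frames) == 0 or np.ptp(ref) == 0:
        return MotionTrace(
            dx=np.zeros(n), dy=np.zeros(n),
            reference_frame_index=ref_idx, degenerate=True,
        )
    dx = np.zeros(n)
    dy = np.zeros(n)
    for i in range(n):
        if i == ref_idx:
            continue
        # returned shift moves the frame onto the reference, i.e. the
        # negative of the frame's displacement
        (sy, sx), _, _ = phase_cross_correlation(
            ref, session.frames[i].astype(np.float64),
            upsample_factor=upsample, normalization=None,
        )
        dx[i] = -sx
        dy[i] = -sy
    return MotionTrace(dx=dx, dy=dy, reference_frame_index=ref_idx)


_FILL_MODES = {"edge": "nearest", "zero": "constant"}


def correct_motion(
    session: ImagingSession, trace: MotionTrace, fill: str = "edge"
) -> ImagingSession:
    """Translate each frame by the negated trace displacement.

    ``fill`` chooses how exposed borders are filled: ``"edge"`` replicates
    edge pixels, ``"zero"`` fills with 0. Acquisition metadata is preserved
    and the output is flagged registered.
    """
    if len(trace) != session.n_frames:
        raise ValueError(
            f"trace length {len(trace)} != {session.n_frames} frames"
        )
    if fill not in _FILL_MODES:
        raise ValueError(f"fill must be one of {sorted(_FILL_MODES)}")
    mode = _FILL_MODES[fill]
    out = np.empty_like(session.frames, dtype=np.float64)
    for i in range(session.n_frames):
        dx, dy = trace.dx[i], trace.dy[i]
        if dx == 0 and dy == 0:
            out[i] = session.frames[i]
        else:
            out[i] = ndi.shift(
                session.frames[i].astype(np.float64),
                (-dy, -dx), order=1, mode=mode, cval=0.0,
            )
    return session.with_frames(out.astype(session.frames.dtype), registered=True)


def apply_motion(
    session: ImagingSession, displacements: np.ndarray, fill: str = "edge"
) -> ImagingSession:
    """Translate each frame by +(dx, dy): the inverse of correct_motion.

    Utility for constructing registration test cases from known trajectories.
    """
    disp = np.asarray(displacements, dtype=np.float64)
    trace = MotionTrace(dx=-disp[:, 0], dy=-disp[:, 1])
    moved = correct_motion(session, trace, fill=fill)
    return moved.with_frames(moved.frames, registered=False)
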