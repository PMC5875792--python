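"""Shared containers for imaging sessions and stimulus descriptions.

An :class:`ImagingSession` is the in-memory form of one recording: a
(frames, height, width) fluorescence stack plus the acquisition metadata
needed to interpret it (frame rate, pixel scale). A :class:`StimulusSpec`
describes the periodic visual stimulus that was presented while the video
was acquired; the analysis is locked to its fundamental frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class ImagingSession:
    """One fluorescence (or reflectance) video with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Pixel values in arbitrary fluorescence units; must be finite.
    frame_rate : float
        Acquisition rate in Hz (> 0).
    um_per_px : float
        Retinal sampling in micrometers per pixel.
    channel : str
        Either ``"fluorescence"`` or ``"reflectance"``.
    registered : bool
        True once motion correction has been applied.
    """

    frames: np.ndarray
    frame_rate: float
    um_per_px: float = 1.0
    channel: str = "fluorescence"
    registered: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n_frames, height, width); got shape {self.frames.shape}"
            )
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.channel not in ("fluorescence", "reflectance"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def with_frames(self, frames: np.ndarray, **changes) -> "ImagingSession":
        return replace(self, frames=frames, **changes)


@dataclass
class StimulusSpec:
    """Periodic uniform-field visual stimulus.

    The default is the 0.2 Hz square wave used for stimulus-locked retinal
    recordings; ``onset_frame`` marks the first video frame at which the
    stimulus cycle begins (light-on edge). Wavelength and power are carried
    as metadata only; they do not affect the frequency analysis.
    """

    frequency: float = 0.2
    waveform: str = "square"
    onset_frame: int = 0
    duty: float = 0.5
    wavelength_nm: float | None = None
    power_uw: float | None = None

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError(f"stimulus frequency must be > 0, got {self.frequency}")
        if self.waveform not in ("square", "sine"):
            raise ValueError(f"waveform must be 'square' or 'sine', got {self.waveform!r}")
        if self.onset_frame < 0:
            raise ValueError("onset_frame must be >= 0")
        if not 0 < self.duty < 1:
            raise ValueError("duty must be in (0, 1)")

    def validate_for(self, frame_rate: float) -> None:
        """Raise if the stimulus frequency is at or above Nyquist."""
        if self.frequency >= frame_rate / 2:
            raise ValueError(
                f"stimulus frequency {self.frequency} Hz >= Nyquist "
                f"({frame_rate / 2} Hz at {frame_rate} Hz sampling)"
            )
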