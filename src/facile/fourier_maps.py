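"""Stimulus-locked Fourier analysis of fluorescence time courses.

The core quantification is classical visual-electrophysiology harmonic
analysis: a response time course is truncated to a whole number of stimulus
cycles, and the amplitude and phase of its Fourier component at the stimulus
fundamental frequency (F1) are extracted, together with the mean level (F0).
The normalized response F1/F0 is the per-cell (or per-pixel) modulation
depth, unitless and comparable across cells with different absolute
brightness.

Amplitude convention
--------------------
Amplitudes are reported as ``2 |X_k| / N`` where ``X_k`` is the DFT
coefficient at bin ``k`` and ``N`` the number of samples analyzed, so a pure
cosine of amplitude *a* returns F1 = *a*. Phase is the complex argument of
``X_k`` in (−π, π], measured relative to the start of the analyzed segment
(stimulus onset); a cosine peaking at the light-on edge has phase 0.

Noise is characterized from the same record as the mean and SD of the
amplitude spectrum over a band well above the stimulus frequency
(10–12 Hz by default), which bounds the measurement floor for F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ImagingSession, StimulusSpec

__all__ = [
    "ActivityMaps",
    "NoiseEstimate",
    "compute_sum_image",
    "f1_analysis",
    "pixelwise_maps",
    "noise_spectrum",
]


@dataclass
class NoiseEstimate:
    """Mean/SD of spectral amplitude over a high-frequency noise band."""

    band: tuple[float, float]
    mean_amp: float
    sd_amp: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.n_bins < 3:
            raise ValueError(f"noise band must contain >= 3 bins, got {self.n_bins}")
        if self.mean_amp < 0 or self.sd_amp < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass
class ActivityMaps:
    """Per-pixel maps derived from one session at one stimulus frequency.

    ``norm_map`` is F1/F0 wherever F0 > 0; pixels with F0 <= 0 are zeroed in
    ``norm_map`` and marked False in ``valid_mask`` rather than producing
    infinities.
    """

    sum_image: np.ndarray
    f0_map: np.ndarray
    f1_amp_map: np.ndarray
    f1_phase_map: np.ndarray
    norm_map: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            m.shape
            for m in (
                self.sum_image,
                self.f0_map,
                self.f1_amp_map,
                self.f1_phase_map,
                self.norm_map,
                self.valid_mask,
            )
        }
        if len(shapes) != 1:
            raise ValueError(f"maps have inconsistent shapes: {shapes}")


def compute_sum_image(session: ImagingSession) -> np.ndarray:
    """Integrate all frames: the SUM image used as a segmentation cue."""
    if session.n_frames < 1:
        raise ValueError("session has no frames")
    return session.frames.sum(axis=0, dtype=np.float64)


def _whole_cycle_segment(
    n_samples: int, frame_rate: float, stimulus: StimulusSpec, n_cycles
) -> tuple[int, int, int]:
    """Return (start, length, n_cycles) covering whole stimulus cycles.

    The segment starts at ``stimulus.onset_frame`` and spans the largest
    (or requested) whole number of cycles that fits.
    """
    stimulus.validate_for(frame_rate)
    samples_per_cycle = frame_rate / stimulus.frequency
    start = stimulus.onset_frame
    available = n_samples - start
    max_cycles = int(np.floor(available / samples_per_cycle + 1e-9))
    if max_cycles < 1:
        raise ValueError(
            f"trace of {n_samples} samples holds no whole stimulus cycle "
            f"({samples_per_cycle:.1f} samples/cycle from onset {start})"
        )
    if n_cycles == "auto":
        n_cycles = max_cycles
    else:
        n_cycles = int(n_cycles)
        if not 1 <= n_cycles <= max_cycles:
            raise ValueError(
                f"requested {n_cycles} cycles but only {max_cycles} fit"
            )
    length = int(round(n_cycles * samples_per_cycle))
    return start, length, n_cycles


def _wrap_phase(phi: np.ndarray | float):
    """Map angles to (−π, π]."""
    phi = -np.mod(-np.asarray(phi, dtype=np.float64) + np.pi, 2 * np.pi) + np.pi
    return phi if np.ndim(phi) else float(phi)


def f1_analysis(
    trace: np.ndarray,
    frame_rate: float,
    stimulus: StimulusSpec,
    n_cycles="auto",
) -> tuple[float, float, float]:
    """F0, F1 amplitude, and F1 phase of one time course.

    Parameters
    ----------
    trace : 1-D array
        Fluorescence time course, finite values.
    frame_rate : float
        Sampling rate in Hz.
    stimulus : StimulusSpec
        Its frequency selects the DFT bin; its onset_frame anchors phase.
    n_cycles : "auto" or int
        Number of whole stimulus cycles to analyze; "auto" takes all that fit.

    Returns
    -------
    (F0, F1_amplitude, F1_phase)
        F0 = mean of the truncated trace; F1 in the 2|X_k|/N cosine-amplitude
        convention; phase in (−π, π] relative to stimulus onset.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1:
        raise ValueError("trace must be 1-D")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    start, length, ncyc = _whole_cycle_segment(trace.size, frame_rate, stimulus, n_cycles)
    seg = trace[start : start + length]
    n = seg.size
    k = int(round(stimulus.frequency * n / frame_rate))
    x = np.fft.rfft(seg)
    f0 = float(seg.mean())
    f1 = float(2.0 * np.abs(x[k]) / n)
    phase = _wrap_phase(np.angle(x[k]))
    return f0, f1, phase


def pixelwise_maps(
    session: ImagingSession,
    stimulus: StimulusSpec,
    n_cycles="auto",
) -> ActivityMaps:
    """Apply the F1/F0 analysis to every pixel's trace, plus the SUM image.

    Equivalent to calling :func:`f1_analysis` on each pixel independently,
    computed with one FFT over the time axis.
    """
    frames = session.frames.astype(np.float64, copy=False)
    start, length, _ = _whole_cycle_segment(
        session.n_frames, session.frame_rate, stimulus, n_cycles
    )
    seg = frames[start : start + length]
    n = seg.shape[0]
    k = int(round(stimulus.frequency * n / session.frame_rate))
    x = np.fft.rfft(seg, axis=0)
    f0 = seg.mean(axis=0)
    f1 = 2.0 * np.abs(x[k]) / n
    phase = _wrap_phase(np.angle(x[k]))
    valid = f0 > 0
    norm = np.zeros_like(f0)
    np.divide(f1, f0, out=norm, where=valid)
    return ActivityMaps(
        sum_image=compute_sum_image(session),
        f0_map=f0,
        f1_amp_map=f1,
        f1_phase_map=np.asarray(phase),
        norm_map=norm,
        valid_mask=valid,
    )


def noise_spectrum(
    trace: np.ndarray,
    frame_rate: float,
    band: tuple[float, float] = (10.0, 12.0),
) -> NoiseEstimate:
    """Mean and SD of spectral amplitude in a high-frequency noise band.

    Amplitudes use the same 2|X|/N convention as :func:`f1_analysis`, so the
    noise floor is directly comparable with F1. The band must lie strictly
    inside (0, Nyquist) and cover at least 3 DFT bins.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1:
        raise ValueError("trace must be 1-D")
    low, high = band
    nyq = frame_rate / 2
    if not (0 < low < high):
        raise ValueError(f"invalid band {band}")
    if high >= nyq:
        raise ValueError(f"band {band} reaches Nyquist ({nyq} Hz)")
    n = trace.size
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate)
    sel = (freqs >= low) & (freqs <= high)
    n_bins = int(sel.sum())
    if n_bins < 3:
        raise ValueError(
            f"band {band} contains only {n_bins} DFT bins at record length {n}; "
            "need >= 3"
        )
    amps = 2.0 * np.abs(np.fft.rfft(trace)[sel]) / n
    return NoiseEstimate(
        band=(float(low), float(high)),
        mean_amp=float(amps.mean()),
        sd_amp=float(amps.std(ddof=1)),
        n_bins=n_bins,
    )
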