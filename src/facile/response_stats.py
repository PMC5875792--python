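"""Per-cell response statistics and population summaries.

A cell responds significantly when its F1 amplitude exceeds the measurement
noise floor: the mean plus three standard deviations of the spectral
amplitude in a high-frequency band (10–12 Hz by default) of the same record.
Response polarity (ON vs OFF) follows from the F1 phase: the two classes sit
half a stimulus cycle apart, so cells are classified by circular distance to
an ON reference phase (supplied, or estimated from the population). Phase
uniformity across a population is tested with the Rayleigh test; a
significant departure from uniformity indicates stimulus-locked responses
even when individual amplitudes are small.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datatypes import StimulusSpec
from .fourier_maps import NoiseEstimate, f1_analysis, noise_spectrum
from .roi import CellRecord

__all__ = [
    "PopulationSummary",
    "quantify_cell",
    "rayleigh_test",
    "estimate_on_center",
    "classify_polarity",
    "classify_records",
    "phase_histogram",
    "summarize_population",
]

#: significance rule: F1 must exceed noise mean + NOISE_SD_FACTOR * noise SD
NOISE_SD_FACTOR = 3.0
#: population phase-uniformity rejection level
RAYLEIGH_ALPHA = 0.01


@dataclass
class PopulationSummary:
    """Descriptive statistics of one condition's cell population."""

    condition: str
    n_cells_analyzed: int
    n_significant: int
    mean_norm_response: float
    sd_norm_response: float
    rayleigh_z: float | None
    rayleigh_p: float | None

    def __post_init__(self) -> None:
        if not 0 <= self.n_significant <= self.n_cells_analyzed:
            raise ValueError("n_significant out of range")
        if self.sd_norm_response < 0:
            raise ValueError("sd must be >= 0")
        if self.rayleigh_p is not None and not 0 <= self.rayleigh_p <= 1:
            raise ValueError("p must be in [0, 1]")


def quantify_cell(
    record: CellRecord,
    frame_rate: float,
    stimulus: StimulusSpec,
    band: tuple[float, float] = (10.0, 12.0),
    n_cycles="auto",
) -> CellRecord:
    """Fill a cell record's F0/F1/phase, noise floor, and significance.

    The time course is analyzed at the stimulus fundamental; the noise floor
    is the mean and SD of the amplitude spectrum over ``band``. The cell is
    significant iff F1 strictly exceeds noise mean + 3 SD. Cells with
    F0 <= 0 are flagged invalid (normalized response undefined) and excluded
    from population summaries.
    """
    f0, f1, phase = f1_analysis(record.timecourse, frame_rate, stimulus, n_cycles)
    noise = noise_spectrum(record.timecourse, frame_rate, band)
    significant = f1 > noise.mean_amp + NOISE_SD_FACTOR * noise.sd_amp
    valid = f0 > 0
    return replace(
        record,
        f0=f0,
        f1=f1,
        phase=phase,
        norm_response=(f1 / f0) if valid else None,
        noise_mean=noise.mean_amp,
        noise_sd=noise.sd_amp,
        significant=bool(significant),
        valid=bool(valid),
    )


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns (z, p) with z = n r² (r the mean resultant length) and the
    large-sample approximation
    p = exp(sqrt(1 + 4n + 4(n² − R²)) − (1 + 2n)), clamped to [0, 1].
    """
    phases = np.asarray(phases, dtype=np.float64)
    if phases.ndim != 1 or phases.size < 2:
        raise ValueError("need at least 2 phases")
    if not np.all(np.isfinite(phases)):
        raise ValueError("phases must be finite")
    n = phases.size
    big_r = np.abs(np.sum(np.exp(1j * phases)))
    r = big_r / n
    z = n * r * r
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - big_r * big_r)) - (1.0 + 2.0 * n))
    return float(z), float(min(max(p, 0.0), 1.0))


def expected_on_phase(
    stimulus: StimulusSpec,
    frame_rate: float,
    kinetics=None,
    n_cycles: int = 4,
) -> float:
    """Phase an ON cell is expected to report under a given stimulus.

    Computed by synthesizing a noiseless indicator-filtered ON response to
    the stimulus and analyzing it the same way as the data. This anchors the
    ON/OFF label assignment physically: the two phase clusters sit half a
    cycle apart regardless, but which cluster is "ON" is only decidable with
    a model of the expected response lag.
    """
    from .synthetic_imaging import IndicatorKinetics, cell_trace

    kinetics = kinetics or IndicatorKinetics()
    n = int(round(n_cycles * frame_rate / stimulus.frequency)) + stimulus.onset_frame
    trace = cell_trace("ON", 0.5, 100.0, stimulus, kinetics, n, frame_rate)
    _, _, phase = f1_analysis(trace, frame_rate, stimulus)
    return phase


def estimate_on_center(phases: np.ndarray) -> float:
    """Dominant phase of a possibly bimodal (antiphase) phase population.

    The ON/OFF axis is the halved angle of the doubled-angle resultant
    Σ e^{2iφ}, which is insensitive to the antiphase split; of the two
    antipodal poles, the one carrying more cells (within a quarter cycle)
    is returned as the ON reference.
    """
    phases = np.asarray(phases, dtype=np.float64)
    if phases.size == 0:
        raise ValueError("no phases to estimate the ON reference from")
    axis = 0.5 * np.angle(np.sum(np.exp(2j * phases)))
    near_axis = np.cos(phases - axis) > 0
    if near_axis.sum() >= phases.size - near_axis.sum():
        return float(axis)
    return float(np.angle(np.exp(1j * (axis + np.pi))))


def _circ_dist(a: float, b: float) -> float:
    return abs(np.angle(np.exp(1j * (a - b))))


def classify_polarity(
    phase: float, on_center: float, half_width: float = np.pi / 2
) -> str:
    """ON / OFF / UNCLASSIFIED by circular distance to the ON reference."""
    if _circ_dist(phase, on_center) < half_width:
        return "ON"
    if _circ_dist(phase, on_center + np.pi) < half_width:
        return "OFF"
    return "UNCLASSIFIED"


def classify_records(
    records: list[CellRecord],
    on_center: float | None = None,
    half_width: float = np.pi / 2,
) -> list[CellRecord]:
    """Classify polarity of quantified records; estimates the ON reference
    from the significant cells' phases when not supplied."""
    if on_center is None:
        sig_phases = [r.phase for r in records if r.significant and r.phase is not None]
        if not sig_phases:
            return [replace(r, polarity="UNCLASSIFIED") for r in records]
        on_center = estimate_on_center(np.array(sig_phases))
    out = []
    for r in records:
        if r.phase is None or not r.significant:
            out.append(replace(r, polarity="UNCLASSIFIED"))
        else:
            out.append(replace(r, polarity=classify_polarity(r.phase, on_center, half_width)))
    return out


def phase_histogram(
    records: list[CellRecord],
    n_bins: int = 18,
    significant_only: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of response phases over a partition of (−π, π].

    Returns (bin_edges, counts); counts sum to the number of included cells.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    phases = [
        r.phase
        for r in records
        if r.phase is not None and r.valid and (r.significant or not significant_only)
    ]
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    if not phases:
        return edges, np.zeros(n_bins, dtype=int)
    # histogram over (−π, π]: values exactly at −π belong to the top bin
    ph = np.asarray(phases)
    ph = np.where(ph == -np.pi, np.pi, ph)
    counts, _ = np.histogram(ph, bins=edges)
    return edges, counts.astype(int)


def summarize_population(
    records: list[CellRecord],
    condition: str = "",
    rayleigh_significant_only: bool = True,
) -> PopulationSummary:
    """Mean ± SD of normalized response, significant count, Rayleigh test.

    Invalid records (F0 <= 0) are excluded. SD uses the n−1 denominator and
    is reported as 0 for a single cell. The Rayleigh test runs over the
    significant cells' phases by default (None when fewer than 2).
    """
    valid = [r for r in records if r.valid and r.norm_response is not None]
    if not valid:
        raise ValueError("no valid records to summarize")
    norms = np.array([r.norm_response for r in valid])
    n = norms.size
    sd = float(norms.std(ddof=1)) if n > 1 else 0.0
    sig = [r for r in valid if r.significant]
    phases = np.array(
        [r.phase for r in (sig if rayleigh_significant_only else valid) if r.phase is not None]
    )
    if phases.size >= 2:
        z, p = rayleigh_test(phases)
    else:
        z, p = None, None
    return PopulationSummary(
        condition=condition,
        n_cells_analyzed=n,
        n_significant=len(sig),
        mean_norm_response=float(norms.mean()),
        sd_norm_response=sd,
        rayleigh_z=z,
        rayleigh_p=p,
    )
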