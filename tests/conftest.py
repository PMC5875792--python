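import numpy as np
import pytest

from facile import (
    FieldSpec,
    IndicatorKinetics,
    MotionSpec,
    StimulusSpec,
    generate_cell_field,
    render_video,
)


@pytest.fixture(scope="session")
def stim():
    return StimulusSpec()  # 0.2 Hz square wave, onset frame 0


@pytest.fixture(scope="session")
def kinetics():
    return IndicatorKinetics()  # rise 0.2 s, decay 1.5 s


@pytest.fixture(scope="session")
def clean_session(stim):
    """Noiseless, motionless 3-cell field: one ON, one OFF, one silent."""
    from facile.synthetic_imaging import CellTruth, GroundTruth, _render_label_mask

    cells = [
        CellTruth(1, (20.0, 20.0), 7.0, "ON", 0.6, 100.0),
        CellTruth(2, (50.0, 20.0), 7.0, "OFF", 0.6, 100.0),
        CellTruth(3, (35.0, 45.0), 7.0, "NONE", 0.0, 100.0),
    ]
    fs = FieldSpec(width_px=72, height_px=64, n_cells=3)
    truth = GroundTruth(
        cells=cells, label_mask=_render_label_mask(cells, 64, 72), seed=0, field_spec=fs
    )
    session, truth = render_video(truth, stim, n_frames=375, noise_sd=0.0, seed=0)
    return session, truth


@pytest.fixture(scope="session")
def separated_field_video(stim):
    """20 well-separated cells with noise and no motion, plus ground truth."""
    fs = FieldSpec(width_px=256, height_px=256, n_cells=20)
    truth = generate_cell_field(
        fs, polarity_mix=(0.5, 0.3, 0.2), seed=11, min_spacing_factor=3.0
    )
    session, truth = render_video(truth, stim, n_frames=375, noise_sd=2.0, seed=11)
    return session, truth
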