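"""Generate the reference synthetic imaging session used by the analyses.

Renders a 160 x 215 um field of 20 ganglion-cell-layer somata (half ON, 30%
OFF, 20% unresponsive) under 0.2 Hz square-wave stimulation, with eye-motion
jitter and recording noise, and writes the video, the ground-truth label
mask, and the ground-truth JSON under results/session/.
"""

from pathlib import Path

from facile import (
    FieldSpec,
    MotionSpec,
    RoiMask,
    StimulusSpec,
    generate_cell_field,
    render_video,
)
from facile import io as fio

OUT = Path(__file__).resolve().parents[1] / "results" / "session"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    stim = StimulusSpec()  # 0.2 Hz square wave
    truth = generate_cell_field(
        FieldSpec(n_cells=20), polarity_mix=(0.5, 0.3, 0.2), seed=SEED
    )
    session, truth = render_video(
        truth,
        stim,
        n_frames=750,  # 30 s, 6 stimulus cycles
        noise_sd=2.0,
        motion=MotionSpec(jitter_sd=0.5, max_excursion=5),
        seed=SEED,
    )
    fio.write_stack(session, OUT / "video.tif")
    fio.write_mask(RoiMask(truth.label_mask), OUT / "truth_mask.tif")
    fio.write_ground_truth_json(truth, OUT / "ground_truth.json")
    n_resp = sum(c.polarity != "NONE" for c in truth.cells)
    print(
        f"wrote {session.n_frames}-frame video ({session.frame_shape[1]}x"
        f"{session.frame_shape[0]} px) with {len(truth.cells)} cells "
        f"({n_resp} responsive) to {OUT}"
    )


if __name__ == "__main__":
    main()
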