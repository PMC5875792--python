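# facile

Fourier-domain extraction of stimulus-locked calcium responses from in vivo
retinal imaging videos.

## The problem

Adaptive-optics ophthalmoscopy can resolve single GCaMP-labelled ganglion
cells in the living eye while a periodic visual stimulus (typically a 0.2 Hz
uniform-field square wave) is presented. Each recording is a fluorescence
video in which responsive somata brighten and dim in lock-step with the
stimulus, sitting on top of photon/readout noise and residual eye motion.
The analysis problem is to decide, cell by cell, whether there is a
stimulus-locked response, how large it is, and whether the cell is ON
(responds at light onset) or OFF — and to do it robustly enough that the
same cells can be followed across imaging sessions weeks apart.

This package implements that analysis chain for experimenters doing
functional retinal imaging (vision-restoration studies, degeneration
models), together with a synthetic video generator with full ground truth so
every stage is testable without animal data.

## The method

For a response time course *f(t)* sampled at rate *f_s*, truncated to a
whole number of stimulus cycles from stimulus onset:

- **F0** = mean of *f(t)* — the baseline fluorescence;
- **F1** = amplitude of the DFT component at the stimulus frequency,
  in the cosine-amplitude convention 2|X_k|/N (a pure cosine of
  amplitude *a* gives F1 = *a*);
- **F1/F0** — the normalized response, a unitless modulation depth
  comparable across cells;
- **phase** of X_k in (−π, π] — ON and OFF cells sit half a stimulus cycle
  apart.

Applied pixel-by-pixel this yields activity maps (F0, F1, phase, F1/F0) plus
the SUM image (per-pixel integral over frames); applied to ROI-averaged time
courses it yields per-cell statistics. The noise floor is measured from the
same record as the mean and SD of the amplitude spectrum over 10–12 Hz, far
above the stimulus band; a cell is **significant** when
F1 > mean + 3·SD of that band. Population phase coherence is tested with the
Rayleigh test (z = n·r², large-sample p), and polarity is assigned by
circular distance to the expected ON phase (a quadrant rule).

Modules: `synthetic_imaging` (ground-truth video generator), `registration`
(frame-wise rigid motion correction by phase cross-correlation),
`fourier_maps` (F1/F0 analysis and activity maps), `roi` (masks, automated
segmentation, time-course extraction, cross-session cell matching),
`response_stats` (significance, Rayleigh statistics, polarity, population
summaries), `photometry` (retinal irradiance, NA² power equivalence,
density-based cell counts), `pipeline` + `cli` (end-to-end orchestration).

## Worked example

```python
import numpy as np
from facile import (StimulusSpec, FieldSpec, generate_cell_field, render_video,
                    pixelwise_maps, auto_segment, extract_timecourses,
                    quantify_cell, classify_records, summarize_population,
                    expected_on_phase)

stim = StimulusSpec(frequency=0.2)            # 0.2 Hz square-wave stimulus
field = FieldSpec()                           # 160 x 215 um field at 1 um/px
truth = generate_cell_field(field, polarity_mix=(0.5, 0.3, 0.2), seed=7)
session, truth = render_video(truth, stim, n_frames=750, noise_sd=2.0, seed=7)

maps = pixelwise_maps(session, stim)          # SUM, F0, F1, phase, F1/F0 maps
mask = auto_segment(maps)                     # or load a manual label mask
records = [quantify_cell(r, session.frame_rate, stim)
           for r in extract_timecourses(session, mask)]
records = classify_records(records,
                           on_center=expected_on_phase(stim, session.frame_rate))
summary = summarize_population(records, condition="synthetic demo")

print(f"{summary.n_significant}/{summary.n_cells_analyzed} cells significant, "
      f"mean F1/F0 = {summary.mean_norm_response:.3f} ± {summary.sd_norm_response:.3f}")
```

Output:

```
17/19 cells significant, mean F1/F0 = 0.131 ± 0.056
```

The field was generated with 20 somata, 16 of them responsive (10 ON, 6
OFF, amplitudes drawn from 0.3–0.8 peak-to-trough drive). The segmenter
found 19 ROIs: all 16 responsive cells (one ON soma split into two ROIs on
this dense field) and two of the four silent cells. Every ROI on a
responsive cell passed the mean+3SD significance criterion and both silent
cells were correctly rejected. The mean normalized response of 0.131
reflects the generative amplitudes after low-pass filtering by the slow
indicator kinetics (rise 0.2 s, decay 1.5 s).

The same chain is scriptable from a shell:

```
facile simulate --out sim --seed 4
facile register sim/video.tif --out reg.tif --shifts shifts.csv
facile segment reg.tif --out mask.tif
facile quantify reg.tif mask.tif --out cells.csv
facile dosimetry
facile run config.yaml        # everything from one YAML config
```

The numbered scripts under `analysis/` run the same stages as a narrative:
simulate a reference session (`01`), analyze it end to end against ground
truth (`02`), calibrate the significance criterion and the Rayleigh test on
null data (`03`), recover population parameters from a synthetic cohort
(`04`), and print the light-dosimetry table (`05`). Each writes its tables
under `results/`.

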