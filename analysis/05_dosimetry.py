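"""Light-dosimetry table for the stimulus conditions.

Retinal irradiance of the 365 nm (20 uW) and 620 nm (100 uW) LED stimuli
over an 8 degree patch, the human-eye power equivalent of the 620 nm level
by NA^2 scaling, and the expected melanopsin-cell count per imaging field
from published areal density. Writes results/dosimetry.csv.
"""

from pathlib import Path

import pandas as pd

from facile.photometry import (
    ANSI_MPE_620NM_8H_UW,
    HUMAN_NA,
    MOUSE_GEOMETRY_DOSIMETRY,
    MOUSE_NA,
    expected_cell_count,
    na_equivalent_power,
    retinal_irradiance,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = [
        {"quantity": "uv_retinal_irradiance", "value":
            retinal_irradiance(20, 8, MOUSE_GEOMETRY_DOSIMETRY), "units": "mW/cm^2"},
        {"quantity": "red_retinal_irradiance", "value":
            retinal_irradiance(100, 8, MOUSE_GEOMETRY_DOSIMETRY), "units": "mW/cm^2"},
        {"quantity": "human_equivalent_of_100uW_mouse", "value":
            na_equivalent_power(100, MOUSE_NA, HUMAN_NA), "units": "uW"},
        {"quantity": "ansi_mpe_620nm_8h", "value": ANSI_MPE_620NM_8H_UW,
         "units": "uW"},
        {"quantity": "expected_melanopsin_cells_per_field", "value":
            expected_cell_count(60, (160, 215))[0], "units": "cells"},
    ]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "dosimetry.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
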