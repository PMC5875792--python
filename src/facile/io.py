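"""File I/O: multi-page TIFF stacks, label masks, CSV tables, JSON sidecars.

Videos and activity maps travel as 32-bit-float multi-page TIFF; label masks
as 16-bit unsigned integer TIFF; cell records, motion traces, tracks and
population summaries as CSV; ground truth and run manifests as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import ImagingSession
from .registration import MotionTrace
from .roi import CellRecord, RoiMask, TrackedCell
from .synthetic_imaging import CellTruth, FieldSpec, GroundTruth

__all__ = [
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "write_records_csv",
    "read_records_csv",
    "write_motion_csv",
    "read_motion_csv",
    "write_tracks_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
]


def _check_path(path) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return path


def read_stack(
    path, frame_rate: float = 25.0, um_per_px: float = 1.0, channel: str = "fluorescence"
) -> ImagingSession:
    """Read a multi-page TIFF into an ImagingSession.

    Acquisition metadata is not stored in plain TIFF, so frame rate and pixel
    scale are supplied by the caller (normally from the run config).
    """
    path = _check_path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # truncated / non-TIFF input
        raise ValueError(f"cannot read TIFF stack from {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"{path} holds a {frames.ndim}-D array, expected 2-D or 3-D")
    return ImagingSession(
        frames=frames, frame_rate=frame_rate, um_per_px=um_per_px, channel=channel
    )


def write_stack(session: ImagingSession, path) -> None:
    """Write the stack as 32-bit float multi-page TIFF (one page per frame)."""
    tifffile.imwrite(Path(path), session.frames.astype(np.float32))


def read_mask(path) -> RoiMask:
    path = _check_path(path)
    try:
        img = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read label TIFF from {path}: {exc}") from exc
    if img.ndim != 2:
        raise ValueError(f"label image in {path} is {img.ndim}-D, expected 2-D")
    return RoiMask(label_image=np.asarray(img).astype(np.uint16))


def write_mask(mask: RoiMask, path) -> None:
    tifffile.imwrite(Path(path), mask.label_image.astype(np.uint16))


_RECORD_COLUMNS = [
    "cell_id", "centroid_x", "centroid_y", "n_pixels", "f0", "f1", "phase",
    "norm_response", "noise_mean", "noise_sd", "significant", "polarity", "valid",
]


def write_records_csv(records: list[CellRecord], path) -> None:
    """One row per cell; the time course itself is not serialized."""
    rows = []
    for r in records:
        rows.append(
            {
                "cell_id": r.cell_id,
                "centroid_x": r.centroid[0],
                "centroid_y": r.centroid[1],
                "n_pixels": r.n_pixels,
                "f0": r.f0,
                "f1": r.f1,
                "phase": r.phase,
                "norm_response": r.norm_response,
                "noise_mean": r.noise_mean,
                "noise_sd": r.noise_sd,
                "significant": r.significant,
                "polarity": r.polarity,
                "valid": r.valid,
            }
        )
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(Path(path), index=False)


def read_records_csv(path) -> pd.DataFrame:
    return pd.read_csv(_check_path(path))


def write_motion_csv(trace: MotionTrace, path) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(trace)), "dx": trace.dx, "dy": trace.dy}
    ).to_csv(Path(path), index=False)


def read_motion_csv(path) -> MotionTrace:
    df = pd.read_csv(_check_path(path))
    return MotionTrace(dx=df["dx"].to_numpy(), dy=df["dy"].to_numpy())


def write_tracks_csv(tracks: list[TrackedCell], path) -> None:
    pd.DataFrame(
        [
            {"id_a": t.session_a_id, "id_b": t.session_b_id, "distance_um": t.match_distance}
            for t in tracks
        ],
        columns=["id_a", "id_b", "distance_um"],
    ).to_csv(Path(path), index=False)


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    """Ground truth as JSON: cell table, trajectory, seed (mask travels as TIFF)."""
    doc = {
        "seed": truth.seed,
        "field_spec": dataclasses.asdict(truth.field_spec) if truth.field_spec else None,
        "cells": [dataclasses.asdict(c) for c in truth.cells],
        "motion_trajectory": (
            truth.motion_trajectory.tolist() if truth.motion_trajectory is not None else None
        ),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_ground_truth_json(path, label_mask: np.ndarray | None = None) -> GroundTruth:
    doc = json.loads(_check_path(path).read_text())
    cells = [CellTruth(**{**c, "centroid": tuple(c["centroid"])}) for c in doc["cells"]]
    fs = FieldSpec(**doc["field_spec"]) if doc.get("field_spec") else None
    traj = (
        np.asarray(doc["motion_trajectory"], dtype=np.float64)
        if doc.get("motion_trajectory") is not None
        else None
    )
    if label_mask is None:
        from .synthetic_imaging import _render_label_mask

        if fs is None:
            raise ValueError("need either a label mask or a field_spec to rebuild one")
        label_mask = _render_label_mask(cells, fs.height_px, fs.width_px)
    return GroundTruth(
        cells=cells,
        label_mask=label_mask,
        seed=doc["seed"],
        field_spec=fs,
        motion_trajectory=traj,
    )
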