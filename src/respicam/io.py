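"""On-disk dialects: multi-page TIFF + JSON sidecar videos, CSV tracks.

A recording on disk is a directory holding, per view, ``view<k>.tif`` (one
page per frame, single channel) and ``view<k>.json`` with
``{"timestamps_s": [...], "view_id": k}``, plus optional ``annotations.csv``,
``reference.csv`` (timestamp_s, value) and ``truth.csv``.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocess import FrameStack
from .synthetic import SyntheticRecording

__all__ = [
    "write_framestack",
    "read_framestack",
    "read_recording_dir",
    "write_recording",
    "write_stft_csv",
]


def write_framestack(directory: str | Path, stack: FrameStack, name: str | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or f"view{stack.view_id}"
    tif = directory / f"{name}.tif"
    tifffile.imwrite(tif, stack.frames.astype(np.float32))
    sidecar = {"timestamps_s": stack.timestamps.tolist(), "view_id": int(stack.view_id)}
    (directory / f"{name}.json").write_text(json.dumps(sidecar))
    return tif


def read_framestack(tif_path: str | Path) -> FrameStack:
    tif_path = Path(tif_path)
    frames = tifffile.imread(tif_path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar_path = tif_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    return FrameStack(
        frames=np.asarray(frames, float),
        timestamps=np.asarray(sidecar["timestamps_s"], float),
        view_id=int(sidecar.get("view_id", 0)),
    )


def read_recording_dir(directory: str | Path) -> list[FrameStack]:
    """Load every view*.tif of a recording directory, ordered by view id."""
    directory = Path(directory)
    tifs = sorted(directory.glob("view*.tif"))
    if not tifs:
        raise FileNotFoundError(f"no view*.tif files in {directory}")
    stacks = [read_framestack(t) for t in tifs]
    return sorted(stacks, key=lambda s: s.view_id)


def write_recording(directory: str | Path, rec: SyntheticRecording) -> Path:
    """Write a synthetic recording in the pipeline's input dialects."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for stack in rec.stacks:
        write_framestack(directory, stack)
    rec.annotations.to_csv(directory / "annotations.csv", index=False)
    pd.DataFrame({"timestamp_s": rec.reference_t, "value": rec.reference_values}).to_csv(
        directory / "reference.csv", index=False
    )
    rec.truth.to_csv(directory / "truth.csv", index=False)
    return directory


def write_stft_csv(path: str | Path, stft: np.ndarray, freqs: np.ndarray) -> None:
    """Matrix export (windows x bins) with the frequency grid as header."""
    header = ",".join(f"{f:.6f}" for f in freqs)
    np.savetxt(path, stft, delimiter=",", header=header, comments="")
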