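"""Readers and writers for the pipeline's on-disk formats.

Load-displacement records travel as CSV (time_s, load_N, displacement_mm),
speckle frames as numbered 16-bit grayscale TIFFs, volumes as multi-page
TIFF stacks with a JSON sidecar (voxel size, phantom geometry, truth
summary), and tables/metrics as CSV. CSV floats use the shortest
round-trip representation, so writer/reader pairs are bit-exact.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .mechanics import LoadDisplacementRecord
from .synthetic.protocol import SpecimenGeometry
from .synthetic.volume import VoxelVolume


def write_record_csv(path: str | Path, record: LoadDisplacementRecord) -> None:
    df = pd.DataFrame(
        {"time_s": record.time, "load_N": record.load, "displacement_mm": record.displacement}
    )
    df.to_csv(path, index=False)


def read_record_csv(
    path: str | Path,
    geometry: SpecimenGeometry,
    reference_length: float,
    sampling_rate: float | None = None,
) -> LoadDisplacementRecord:
    # round_trip parsing: pandas' fast float parser is lossy in the last ulp
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time_s"].to_numpy()
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    return LoadDisplacementRecord(
        time=t,
        load=df["load_N"].to_numpy(),
        displacement=df["displacement_mm"].to_numpy(),
        sampling_rate=sampling_rate,
        geometry=geometry,
        reference_length=reference_length,
    )


def write_frames(dir_path: str | Path, frames: np.ndarray) -> list[Path]:
    """Write a float [0, 1] frame stack as numbered 16-bit grayscale TIFFs."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        arr = np.clip(frame, 0.0, 1.0)
        im = (arr * 65535.0).round().astype(np.uint16)
        p = dir_path / f"frame_{i:05d}.tif"
        tifffile.imwrite(p, im)
        paths.append(p)
    return paths


def read_frames(dir_path: str | Path) -> np.ndarray:
    dir_path = Path(dir_path)
    paths = sorted(dir_path.glob("frame_*.tif"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.tif files under {dir_path}")
    stack = np.stack([tifffile.imread(p) for p in paths])
    return stack.astype(float) / 65535.0


def write_volume(path: str | Path, volume: VoxelVolume, sidecar: dict | None = None) -> None:
    """Multi-page TIFF stack (float32 grayscale) plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, volume.data.astype(np.float32))
    meta = {"voxel_size_um": volume.voxel_size_um}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=_jsonify))


def read_volume(path: str | Path) -> tuple[VoxelVolume, dict]:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return VoxelVolume(data=data, voxel_size_um=float(meta["voxel_size_um"])), meta


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify))
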