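"""File interfaces: multi-page float TIFF stacks with JSON sidecars.

Frame stacks, energy sequences and feature maps are written as 32-bit
float multi-page TIFFs (NaN marks invalid pixels); every stack carries a
JSON sidecar echoing the exact configuration (lattice geometry,
timestamps, phase labels, seed) needed to regenerate it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .optics import FrameSequence, PhotoreceptorLattice


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_stack(path: str | Path, values: np.ndarray, *,
                lattice: PhotoreceptorLattice | None = None,
                dt: float | None = None,
                phase_labels=None,
                extra: dict | None = None) -> Path:
    """Write a (T, rows, cols) stack as multi-page TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32),
                     photometric="minisblack")
    sidecar = {"shape": list(values.shape), "dt_ms": dt,
               "phase_labels": list(phase_labels) if phase_labels else None}
    if lattice is not None:
        sidecar["lattice"] = _jsonable(lattice)
    if extra:
        sidecar.update(_jsonable(extra))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))
    return path


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack and its sidecar (empty dict if absent)."""
    path = Path(path)
    values = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return values, meta


def read_frame_sequence(path: str | Path) -> tuple[FrameSequence, dict]:
    values, meta = read_stack(path)
    dt = meta.get("dt_ms") or 1.0
    return FrameSequence(values, dt=dt, phase_labels=meta.get("phase_labels")), meta


def lattice_from_sidecar(meta: dict) -> PhotoreceptorLattice:
    lat = meta.get("lattice")
    if lat is None:
        return PhotoreceptorLattice()
    return PhotoreceptorLattice(
        spacing=lat["spacing"], acceptance_angle=lat["acceptance_angle"],
        elevation_min=lat["elevation_min"], elevation_max=lat["elevation_max"])
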