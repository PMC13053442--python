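"""Reading and writing the pipeline's file formats.

Image stacks are multi-page TIFFs (one page per z-slice) accompanied by a
JSON sidecar recording the voxel size and axial calibration — TIFF has no
reliable convention for anisotropic 3D voxel metadata. Graphs are stored as
JSON (node list + edge polylines in µm) and optionally as SWC-like text for
viewers; morphometry goes to CSV in the customary reporting units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .capmetrics import MorphometryResult
from .reconstruct import VoxelVolume

__all__ = [
    "write_tiff_stack",
    "read_tiff_stack",
    "write_metrics_csv",
    "read_metrics_csv",
]


def write_tiff_stack(volume: VoxelVolume, path) -> None:
    """Write a z-stack as multi-page TIFF plus a ``.json`` metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(volume.data))
    sidecar = {
        "voxel_size_um": list(map(float, volume.voxel_size)),
        "z_calibration": float(volume.z_calibration),
        "axes": "ZYX",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_tiff_stack(path) -> VoxelVolume:
    """Read a multi-page TIFF written by :func:`write_tiff_stack`."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, ...]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        voxel_size = tuple(meta.get("voxel_size_um", (1.0, 1.0, 1.0)))
        z_cal = float(meta.get("z_calibration", 1.0))
    else:
        voxel_size, z_cal = (1.0, 1.0, 1.0), 1.0
    return VoxelVolume(data, voxel_size, z_cal)


def write_metrics_csv(results: dict[str, MorphometryResult], path) -> None:
    """Per-field morphometry CSV in reporting units (LVm ×10⁻⁶ etc.)."""
    rows = []
    for field_id, res in results.items():
        row = {"field": field_id}
        row.update(res.to_table_row())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_metrics_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
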