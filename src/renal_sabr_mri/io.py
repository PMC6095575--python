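"""NIfTI/CSV readers-writers and the run manifest.

All writes are atomic (write to a temp name in the target directory, then
rename) so an interrupted run never leaves half-written outputs.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd


def _atomic(path: Path, write_fn) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
    os.close(fd)
    try:
        write_fn(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_nifti(
    path: str | Path,
    data: np.ndarray,
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    frame_interval_s: float | None = None,
) -> None:
    """Write a 3D/4D volume as NIfTI-1; time occupies the 4th dimension."""
    affine = np.diag([*voxel_spacing_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    if frame_interval_s is not None:
        img.header["pixdim"][4] = frame_interval_s
        img.header.set_xyzt_units(xyz="mm", t="sec")
    _atomic(Path(path), lambda p: nib.save(img, str(p)))


def read_nifti(path: str | Path) -> tuple[np.ndarray, nib.Nifti1Header]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.header


def write_mask(path: str | Path, mask: np.ndarray, voxel_spacing_mm=(1.0, 1.0, 1.0)) -> None:
    write_nifti(path, np.asarray(mask, dtype=np.uint8), voxel_spacing_mm)


def read_mask(path: str | Path) -> np.ndarray:
    data, _ = read_nifti(path)
    return data.astype(bool)


def write_bvals(path: str | Path, b_values) -> None:
    """Sidecar b-value text file: one value per line, aligned with the 4th axis."""
    text = "\n".join(str(float(b)) for b in b_values) + "\n"
    _atomic(Path(path), lambda p: p.write_text(text))


def read_bvals(path: str | Path) -> np.ndarray:
    return np.array([float(line) for line in Path(path).read_text().split()], dtype=float)


def write_csv(path: str | Path, df: pd.DataFrame) -> None:
    _atomic(Path(path), lambda p: df.to_csv(p, index=False))


def write_json(path: str | Path, obj: dict[str, Any]) -> None:
    _atomic(Path(path), lambda p: p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str)))


def read_json(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
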