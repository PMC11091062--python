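"""Shared containers and TIFF I/O.

Conventions used throughout the package:

* 3D arrays are indexed ``(z, y, x)``.
* ``voxel_size_um`` is the physical voxel pitch in micrometres, given in the
  same ``(z, y, x)`` order; anisotropic grids are supported everywhere.
* A voxel with index ``(k, j, i)`` has its centre at physical position
  ``(k*dz, j*dy, i*dx)`` micrometres.
* Binary masks are plain boolean ``numpy`` arrays on the same lattice as the
  grayscale volume they refer to; on disk they are stored as 8-bit TIFF
  stacks with values 0/255.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Volume3D",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
]


@dataclass
class Volume3D:
    """An anisotropy-aware 3D grayscale scalar grid.

    Parameters
    ----------
    data
        3D array of gray values, indexed ``(z, y, x)``.
    voxel_size_um
        Physical voxel pitch ``(dz, dy, dx)`` in micrometres.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("volume has a zero-length axis")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size_um))
        if len(vs) == 1:
            vs = (vs[0],) * 3
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_um must be 3 positive reals, got {self.voxel_size_um}")
        self.voxel_size_um = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    def same_lattice(self, other: "Volume3D | np.ndarray") -> bool:
        shape = other.shape if isinstance(other, np.ndarray) else other.data.shape
        return tuple(self.data.shape) == tuple(shape)

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.voxel_size_um)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_volume(volume: Volume3D, path: str | Path, dtype=np.uint16) -> Path:
    """Write a volume as a multi-page TIFF plus a JSON sidecar with the voxel size."""
    path = Path(path)
    data = volume.data
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.rint(data), info.min, info.max).astype(dtype)
    else:
        data = data.astype(dtype)
    tifffile.imwrite(path, data)
    _sidecar_path(path).write_text(
        json.dumps({"voxel_size_um": list(volume.voxel_size_um)}, sort_keys=True)
    )
    return path


def load_volume(path: str | Path, voxel_size_um=None) -> Volume3D:
    """Read a multi-page TIFF stack; voxel size from argument or JSON sidecar."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if voxel_size_um is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                f"no voxel size given and no sidecar {sidecar.name} next to {path.name}"
            )
        voxel_size_um = json.loads(sidecar.read_text())["voxel_size_um"]
    return Volume3D(data, tuple(voxel_size_um))


def save_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as an 8-bit 0/255 TIFF stack."""
    path = Path(path)
    tifffile.imwrite(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))
    return path


def load_mask(path: str | Path) -> np.ndarray:
    data = tifffile.imread(Path(path))
    if data.ndim == 2:
        data = data[None]
    return data > 0
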