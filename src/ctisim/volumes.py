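"""3-D scalar volumes with grid geometry, and NIfTI-1 reading/writing."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


class FormatError(ValueError):
    """Raised for inputs that are not single 3-D NIfTI scalar images."""


class AlignmentError(ValueError):
    """Raised when two volumes that must share a grid do not."""


def default_affine(grid_shape: tuple[int, int, int], voxel_mm: float = 1.0) -> np.ndarray:
    """Identity-scaled affine centring the grid on the origin (pseudo-MNI frame)."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (np.asarray(grid_shape) - 1) / 2.0
    return aff


@dataclass
class ParameterVolume:
    """A named 3-D scalar map (one micro-structure parameter) on a voxel grid."""

    name: str
    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"parameter volume {self.name!r} must be 3-D, got shape {self.data.shape}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {self.affine.shape}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def check_aligned(*vols, context: str = "") -> None:
    """Raise :class:`AlignmentError` unless all volumes share shape and affine."""
    ref = vols[0]
    for v in vols[1:]:
        if v.shape != ref.shape or not np.allclose(v.affine, ref.affine, atol=1e-6):
            where = f" at {context}" if context else ""
            raise AlignmentError(
                f"grid mismatch{where}: shape {ref.shape} / affine vs shape {v.shape}"
            )


def read_volume(path: str | Path, name: str | None = None) -> ParameterVolume:
    """Read a single 3-D NIfTI image.

    Raises
    ------
    FormatError
        If the image is not 3-D (e.g. a 4-D time series).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got shape {data.shape}")
    return ParameterVolume(name or Path(path).name.split(".")[0], data, img.affine)


def write_volume(vol: ParameterVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI, preserving dtype and affine exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.data, vol.affine)
    nib.save(img, str(path))
    return path
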