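"""3D scalar volumes with voxel spacing.

:class:`Volume3D` is the in-memory container for confidence maps (float
voxels in [0, 1]) and binary masks ({0, 1}).  Axis order is fixed as
(z, y, x) with 0-based indexing; ``spacing`` is in millimetres per axis in
the same order.  Volumes are read and written as MHA or NIfTI through
SimpleITK, taking spacing from the image header.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .exceptions import InputError

__all__ = ["Volume3D", "read_volume", "write_volume"]


@dataclasses.dataclass(frozen=True)
class Volume3D:
    """A 3D scalar field with voxel spacing.

    Parameters
    ----------
    values
        3D array indexed (z, y, x).
    spacing
        Voxel spacing in mm per axis, (z, y, x) order.  Strictly positive.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise InputError(f"expected a 3D array, got ndim={values.ndim}")
        object.__setattr__(self, "values", values)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise InputError(f"spacing must be 3 strictly positive floats, got {self.spacing!r}")
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0, 1)).all())

    def validate_confidence(self) -> "Volume3D":
        """Check all values lie in [0, 1]; returns self for chaining."""
        v = self.values
        if v.size and (float(v.min()) < -1e-9 or float(v.max()) > 1 + 1e-9):
            raise InputError(
                f"confidence values must lie in [0, 1]; got range "
                f"[{float(v.min()):.4g}, {float(v.max()):.4g}]"
            )
        return self

    def same_grid(self, other: "Volume3D", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing)
        )


def read_volume(path: str | Path) -> Volume3D:
    """Read an MHA or NIfTI volume; spacing is taken from the header.

    SimpleITK stores spacing in (x, y, z) order while arrays come out
    (z, y, x); the spacing is reversed on load so both agree.
    """
    image = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(image)
    if values.ndim != 3:
        raise InputError(f"{path}: expected a 3D image, got ndim={values.ndim}")
    spacing = tuple(reversed(image.GetSpacing()))
    return Volume3D(values=values, spacing=spacing)  # type: ignore[arg-type]


def write_volume(volume: Volume3D, path: str | Path) -> None:
    """Write a volume as MHA or NIfTI (format chosen from the file suffix)."""
    image = sitk.GetImageFromArray(np.ascontiguousarray(volume.values))
    image.SetSpacing(tuple(reversed(volume.spacing)))
    sitk.WriteImage(image, str(path), useCompression=False)
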