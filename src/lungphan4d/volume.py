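"""Voxel-grid container shared by every stage of the pipeline.

A :class:`CTVolume` is a 3D scalar field of CT numbers (Hounsfield units)
on a regular grid.  Axes are ordered (lateral, AP, SI) throughout the
package; voxel indices are 0-based and world coordinates refer to voxel
centers, so voxel ``(i, j, k)`` sits at ``origin + index * spacing`` mm.
The superior-inferior (SI) axis is the last axis and is the motion axis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume", "grids_match", "require_same_grid", "load_nifti", "AXIS_LATERAL", "AXIS_AP", "AXIS_SI"]

AXIS_LATERAL = 0
AXIS_AP = 1
AXIS_SI = 2

#: axis-order tag stamped into exported metadata
AXIS_ORDER = "lateral-AP-SI"


@dataclass
class CTVolume:
    """3D HU grid with spacing/origin metadata.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        HU per voxel, axes ordered (lateral, AP, SI).
    spacing : tuple of 3 floats
        Voxel spacing in mm per axis.
    origin : tuple of 3 floats
        World coordinate (mm) of the center of voxel (0, 0, 0).
    name : str
        Free-form tag (e.g. ``"AIP"``, ``"phase_3"``) carried into
        filenames and export metadata.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"CTVolume requires a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive on all axes, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CTVolume values must be finite")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def world_to_index(self, point_mm) -> np.ndarray:
        """Fractional voxel index of a world point (no rounding)."""
        p = np.asarray(point_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "CTVolume":
        """New volume on the same grid with different voxel data."""
        return dataclasses.replace(
            self, values=values, name=self.name if name is None else name, meta=dict(self.meta)
        )

    # -- I/O ---------------------------------------------------------------

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path) -> None:
        """Write as NIfTI-1; spacing/origin go into the affine, tags into the header."""
        import nibabel as nib

        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), self.affine())
        img.header["descrip"] = f"{self.name}|{AXIS_ORDER}".encode()[:80]
        nib.save(img, str(path))

    def to_dicom_series(self, directory, series_description: str | None = None) -> list:
        from .dicom_io import write_ct_series

        return write_ct_series(self, directory, series_description=series_description)


def load_nifti(path, name: str = "") -> CTVolume:
    """Read a NIfTI volume written by :meth:`CTVolume.to_nifti` (or any
    axis-aligned NIfTI with a diagonal affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ValueError(f"{path}: only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing = tuple(np.abs(np.diag(aff[:3, :3])))
    origin = tuple(aff[:3, 3])
    return CTVolume(np.asarray(img.dataobj), spacing=spacing, origin=origin, name=name)


def grids_match(a, b, tol: float = 1e-6) -> bool:
    """True when two grid-bearing objects share shape, spacing and origin."""
    return (
        a.values.shape == b.values.shape
        and np.allclose(a.spacing, b.spacing, atol=tol)
        and np.allclose(a.origin, b.origin, atol=tol)
    )


def require_same_grid(*objs, what: str = "inputs") -> None:
    first = objs[0]
    for other in objs[1:]:
        if not grids_match(first, other):
            raise ValueError(
                f"grid mismatch between {what}: "
                f"{first.values.shape}/{first.spacing}/{first.origin} vs "
                f"{other.values.shape}/{other.spacing}/{other.origin}"
            )
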