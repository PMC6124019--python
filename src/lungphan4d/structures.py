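"""Structure algebra: phase GTVs, ITV union, PTV margin expansion.

The gross tumor volume (GTV) at each phase is the target sphere at that
phase's position.  The internal target volume (ITV) is the Boolean OR of
the 10 phase GTVs; the planning target volume (PTV) expands the ITV by a
uniform isotropic margin (5 mm per RTOG 0915).  GTVs are generated
geometrically from the known sphere centers — contouring variability is
deliberately absent — with an optional HU-threshold contour for user data.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom_model import MotionModel, N_PHASES, PhantomSpec, sphere_mask_array, target_center_at_phase
from .volume import CTVolume, require_same_grid

__all__ = [
    "StructureMask",
    "gtv_mask_at_phase",
    "union_masks",
    "intersect_masks",
    "subtract_masks",
    "expand_margin",
    "threshold_contour",
    "volume_table",
]


@dataclass
class StructureMask:
    """Binary voxel mask on a CTVolume grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"StructureMask requires a 3D array, got ndim={self.mask.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    # grid-compat shim so require_same_grid works across volumes and masks
    @property
    def values(self) -> np.ndarray:
        return self.mask

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0

    def with_mask(self, mask: np.ndarray, name: str) -> "StructureMask":
        return dataclasses.replace(self, mask=mask, name=name)

    def to_nifti(self, path) -> None:
        """Unsigned 8-bit NIfTI, 1 = inside."""
        import nibabel as nib

        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), aff), str(path))


def gtv_mask_at_phase(
    spec: PhantomSpec, motion: MotionModel, phase_index: int
) -> StructureMask:
    """Target sphere mask at one phase position (strict center-distance rule)."""
    dz = target_center_at_phase(motion, phase_index)
    spec.validate_motion(motion)
    cx, cy, cz = spec.target_rest_center
    m = sphere_mask_array(spec, (cx, cy, cz + dz), spec.target_radius)
    return StructureMask(
        m, spacing=spec.grid_spacing, origin=spec.grid_origin(), name=f"GTV_ph{phase_index}"
    )


def _combine(masks: Sequence[StructureMask], op, name: str) -> StructureMask:
    if len(masks) < 1:
        raise ValueError("need at least one mask")
    require_same_grid(*masks, what="masks")
    out = masks[0].mask.copy()
    for m in masks[1:]:
        out = op(out, m.mask)
    return masks[0].with_mask(out, name)


def union_masks(masks: Sequence[StructureMask], name: str = "union") -> StructureMask:
    """Voxelwise logical OR (the Boolean union used to build the ITV)."""
    return _combine(masks, np.logical_or, name)


def intersect_masks(masks: Sequence[StructureMask], name: str = "intersection") -> StructureMask:
    return _combine(masks, np.logical_and, name)


def subtract_masks(a: StructureMask, b: StructureMask, name: str = "difference") -> StructureMask:
    """Voxels in ``a`` and not in ``b``."""
    require_same_grid(a, b, what="masks")
    return a.with_mask(a.mask & ~b.mask, name)


def expand_margin(mask: StructureMask, margin_mm: float = 5.0, name: str | None = None) -> StructureMask:
    """Isotropic margin expansion by Euclidean distance transform.

    The output contains every voxel whose center lies within ``margin_mm``
    (closed ball) of the input mask, matching TPS isotropic expansion
    semantics.  Raises if the expansion reaches the grid boundary — the
    grid must be padded enough to hold the expanded structure.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    if margin_mm == 0:
        return mask.with_mask(mask.mask.copy(), name or mask.name)
    dist = ndimage.distance_transform_edt(~mask.mask, sampling=mask.spacing)
    out = dist <= margin_mm
    boundary = np.zeros_like(out)
    boundary[[0, -1], :, :] = True
    boundary[:, [0, -1], :] = True
    boundary[:, :, [0, -1]] = True
    if np.any(out & boundary):
        raise ValueError(
            f"margin expansion by {margin_mm} mm exits the grid; pad the grid"
        )
    return mask.with_mask(out, name or f"{mask.name}+{margin_mm:g}mm")


def threshold_contour(
    volume: CTVolume, hu_threshold: float = -300.0, name: str = "contour"
) -> StructureMask:
    """HU-threshold contour for user-supplied data: voxels above the
    threshold, largest connected component."""
    above = volume.values > hu_threshold
    labels, n = ndimage.label(above)
    if n == 0:
        raise ValueError(f"no voxels above {hu_threshold} HU")
    largest = int(np.argmax(ndimage.sum_labels(above, labels, index=np.arange(1, n + 1)))) + 1
    return StructureMask(
        labels == largest, spacing=volume.spacing, origin=volume.origin, name=name
    )


def build_itv_ptv(
    spec: PhantomSpec, motion: MotionModel, margin_mm: float = 5.0
) -> tuple[list[StructureMask], StructureMask, StructureMask]:
    """Convenience: the 10 phase GTVs, their ITV union, and the expanded PTV."""
    gtvs = [gtv_mask_at_phase(spec, motion, p) for p in range(N_PHASES)]
    itv = union_masks(gtvs, name="ITV")
    ptv = expand_margin(itv, margin_mm, name="PTV")
    return gtvs, itv, ptv


def volume_table(rows: Sequence[tuple[float, StructureMask, StructureMask]]):
    """Structure-volume summary: one row per motion range.

    ``rows`` holds (amplitude_mm, itv, ptv) triples; the output mirrors a
    plan-parameter table with range of motion (cm, peak-to-peak), ITV and
    PTV volumes in cc.
    """
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "range_of_motion_cm": 2 * amp / 10.0,
                "itv_cc": round(itv.volume_cc, 2),
                "ptv_cc": round(ptv.volume_cc, 2),
            }
            for amp, itv, ptv in rows
        ]
    )
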