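"""Phase-weighted density (PWD) override.

A voxel inside the ITV is occupied by the tumor for some fraction t/T of
the respiratory period and by lung for the rest.  With 10-phase binning
that fraction is quantized to k/10, where k counts how many phase GTVs
cover the voxel.  The PWD override assigns each voxel the time-weighted
mixture density

    rho_PWD = (k/10) * rho_GTV + (1 - k/10) * rho_lung

and replaces the free-breathing dataset inside the ITV with it, leaving
everything outside the ITV untouched.  The occupancy level sets {k = c}
are exactly the Boolean add/subtract sub-regions a planner would build
from the 10 phase contours, so counting coverage is equivalent to (and
simpler than) an explicit Boolean construction.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structures import StructureMask
from .volume import CTVolume, require_same_grid

__all__ = [
    "OccupancyMap",
    "PWDParams",
    "compute_occupancy",
    "pwd_density",
    "apply_override",
    "build_pwd_dataset",
    "si_profile",
    "estimate_params_from_data",
]


@dataclass
class OccupancyMap:
    """Per-voxel count k of phase-GTV coverage, k in {0..n_phases}."""

    counts: np.ndarray
    n_phases: int
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.min() < 0 or self.counts.max() > self.n_phases:
            raise ValueError("occupancy counts must lie in [0, n_phases]")

    @property
    def values(self) -> np.ndarray:  # grid-compat shim
        return self.counts

    @property
    def occupancy_fraction(self) -> np.ndarray:
        """t/T per voxel: the fraction of the cycle the GTV spends there."""
        return self.counts / self.n_phases

    def itv_mask(self, name: str = "ITV") -> StructureMask:
        """{k >= 1}: identical to the Boolean OR of the phase GTVs."""
        return StructureMask(self.counts >= 1, spacing=self.spacing, origin=self.origin, name=name)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.counts.astype(np.int16), aff), str(path))


@dataclass(frozen=True)
class PWDParams:
    """Override densities (HU).  Defaults are the mean GTV and lung CT
    numbers of the study phantom."""

    rho_gtv: float = -50.0
    rho_lung: float = -625.0
    n_phases: int = 10

    def __post_init__(self):
        if not self.rho_gtv > self.rho_lung:
            raise ValueError(
                f"rho_gtv ({self.rho_gtv}) must exceed rho_lung ({self.rho_lung})"
            )
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")


def compute_occupancy(phase_gtv_masks: Sequence[StructureMask]) -> OccupancyMap:
    """Count, per voxel, how many phase GTV masks cover it."""
    if len(phase_gtv_masks) < 2:
        raise ValueError(f"need at least 2 phase masks, got {len(phase_gtv_masks)}")
    require_same_grid(*phase_gtv_masks, what="phase GTV masks")
    counts = np.zeros(phase_gtv_masks[0].mask.shape, dtype=np.int16)
    for m in phase_gtv_masks:
        counts += m.mask
    return OccupancyMap(
        counts,
        n_phases=len(phase_gtv_masks),
        spacing=phase_gtv_masks[0].spacing,
        origin=phase_gtv_masks[0].origin,
    )


def pwd_density(occupancy: OccupancyMap, params: PWDParams = PWDParams()) -> CTVolume:
    """Phase-weighted density volume: the k/P mixture of GTV and lung HU.

    Defined everywhere on the grid; its support (k >= 1) is the ITV, and
    voxels with k = 0 evaluate to rho_lung.
    """
    if params.n_phases != occupancy.n_phases:
        raise ValueError(
            f"params.n_phases ({params.n_phases}) != occupancy.n_phases ({occupancy.n_phases})"
        )
    frac = occupancy.occupancy_fraction
    rho = frac * params.rho_gtv + (1.0 - frac) * params.rho_lung
    return CTVolume(
        rho,
        spacing=occupancy.spacing,
        origin=occupancy.origin,
        name="PWD_density",
    )


def apply_override(fb: CTVolume, itv: StructureMask, pwd: CTVolume) -> CTVolume:
    """Override the FB dataset with the PWD density inside the ITV.

    Outside the ITV every voxel keeps its FB value bit-exactly.
    """
    require_same_grid(fb, itv, pwd, what="FB volume / ITV / PWD density")
    # promote so the override keeps the PWD density's full precision while
    # voxels outside the ITV keep their FB values bit-exactly
    out = fb.values.astype(np.result_type(fb.values, pwd.values))
    out[itv.mask] = pwd.values[itv.mask]
    return fb.with_values(out, name="PWD")


def build_pwd_dataset(
    fb: CTVolume,
    phase_gtv_masks: Sequence[StructureMask],
    params: PWDParams = PWDParams(),
) -> tuple[CTVolume, OccupancyMap]:
    """Occupancy -> PWD density -> override, in one step."""
    occ = compute_occupancy(phase_gtv_masks)
    pwd = pwd_density(occ, params)
    return apply_override(fb, occ.itv_mask(), pwd), occ


def si_profile(
    volume: CTVolume, lateral_mm: float = 0.0, ap_mm: float = 0.0
) -> pd.DataFrame:
    """HU sampled at voxel centers along the SI line through (lateral, AP).

    Returns a DataFrame with columns ``si_mm`` and ``hu`` — the profile a
    planner would inspect through the target center to see the PWD
    staircase.
    """
    idx = volume.world_to_index((lateral_mm, ap_mm, volume.origin[2]))
    i, j = int(round(idx[0])), int(round(idx[1]))
    nx, ny, _ = volume.values.shape
    if not (0 <= i < nx and 0 <= j < ny):
        raise ValueError(
            f"SI line at lateral={lateral_mm} mm, AP={ap_mm} mm lies outside the grid"
        )
    return pd.DataFrame(
        {"si_mm": volume.axis_coords(2), "hu": volume.values[i, j, :].astype(float)}
    )


def estimate_params_from_data(
    fb: CTVolume, gtv: StructureMask, lung_roi: StructureMask, n_phases: int = 10
) -> PWDParams:
    """Override constants from user data: mean FB HU over the GTV and over
    a lung ROI."""
    require_same_grid(fb, gtv, lung_roi, what="FB volume / ROIs")
    if gtv.voxel_count == 0 or lung_roi.voxel_count == 0:
        raise ValueError("GTV and lung ROI masks must be non-empty")
    return PWDParams(
        rho_gtv=float(fb.values[gtv.mask].mean()),
        rho_lung=float(fb.values[lung_roi.mask].mean()),
        n_phases=n_phases,
    )
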