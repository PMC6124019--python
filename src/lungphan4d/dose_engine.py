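"""Simplified attenuation-based photon dose proxy.

This engine exists to exercise plan geometry (AP/PA fields, PTV-fitted
apertures), the point-dose HU-sweep experiment, DVH metrics and the
percent-difference statistic — it is a *toy* model, not a clinical
algorithm.  Dose along a ray is

    D = (MU/500) * B(d_eff) * exp(-mu_w * (d_eff - d_max)) * L

with d_eff the water-equivalent (radiological) depth, B a saturating
buildup factor that reaches 1 at d_max, mu_w the water linear attenuation
coefficient, and L the aperture projection convolved with a Gaussian
penumbra.  Calibration is 1.0 arbitrary dose unit at d_max in water per
500 MU; only relative quantities (DVH shapes, percent differences, gamma)
are meaningful.  There is no scatter-kernel superposition and no electron
transport.

HU maps to relative density through the standard single-segment linear
ramp rho_rel = max(0, 1 + HU/1000); a two-segment ramp (different slope
above water) is available for users who want a tissue/bone distinction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .structures import StructureMask
from .volume import AXIS_AP, CTVolume, require_same_grid

__all__ = [
    "BeamSpec",
    "DoseGrid",
    "DVHMetrics",
    "hu_to_relative_density",
    "radiological_depth",
    "effective_depth_volume",
    "compute_field_dose",
    "combine_fields",
    "ap_pa_plan",
    "hu_sweep_experiment",
    "sweep_points",
    "dvh_metrics",
    "delta_d",
    "resample_volume",
    "extract_coronal_plane",
]


@dataclass(frozen=True)
class BeamSpec:
    """One static photon field.

    ``direction`` 'AP' enters the anterior surface and travels toward
    increasing AP coordinate; 'PA' the reverse.  The aperture is either a
    fixed square field (``field_size_mm``) centered on the isocenter or a
    beam's-eye-view projection of a structure (see :func:`ap_pa_plan`).
    """

    direction: str = "AP"
    field_size_mm: tuple[float, float] = (30.0, 30.0)  # (lateral, SI)
    monitor_units: float = 500.0
    energy: str = "6MV-FFF"
    mu_water_per_cm: float = 0.0495
    d_max_cm: float = 1.5
    buildup_beta_per_cm: float = 3.0
    penumbra_sigma_mm: float = 3.0

    def __post_init__(self):
        if self.direction not in ("AP", "PA"):
            raise ValueError(f"direction must be 'AP' or 'PA', got {self.direction!r}")
        if self.mu_water_per_cm <= 0:
            raise ValueError("mu_water_per_cm must be positive")
        if self.monitor_units <= 0:
            raise ValueError("monitor_units must be positive")


@dataclass
class DoseGrid:
    """Dose per voxel (arbitrary calibrated units) on a stated grid.

    2D planes (lateral × SI) reuse the same container with a 2-vector
    spacing/origin.
    """

    values: np.ndarray
    spacing: tuple
    origin: tuple
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise ValueError("DoseGrid must be 2D or 3D")
        if self.values.min() < 0:
            raise ValueError("dose must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.values.shape[axis])

    def to_nifti(self, path) -> None:
        import nibabel as nib

        sp = list(self.spacing) + [1.0] * (3 - len(self.spacing))
        aff = np.diag(sp + [1.0])
        aff[: len(self.origin), 3] = self.origin
        vals = self.values if self.values.ndim == 3 else self.values[:, :, None]
        nib.save(nib.Nifti1Image(np.asarray(vals, dtype=np.float32), aff), str(path))

    def to_csv(self, path) -> None:
        """2D plane as CSV (rows = lateral, cols = SI)."""
        if self.values.ndim != 2:
            raise ValueError("CSV export is for 2D planes")
        pd.DataFrame(self.values).to_csv(path, index=False, header=False)


@dataclass(frozen=True)
class DVHMetrics:
    d_max: float
    d_2: float
    d_mean: float
    d_95: float
    d_98: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# HU -> density and radiological depth


def hu_to_relative_density(hu: np.ndarray, ramp: str = "single") -> np.ndarray:
    """Relative (electron) density from CT number.

    ``single``: rho = max(0, 1 + HU/1000) everywhere.  ``two-segment``:
    same below water, reduced slope 1 + HU/1950 above 0 HU (a coarse
    tissue/bone break).
    """
    hu = np.asarray(hu, dtype=np.float64)
    if ramp == "single":
        rho = 1.0 + hu / 1000.0
    elif ramp == "two-segment":
        rho = np.where(hu <= 0, 1.0 + hu / 1000.0, 1.0 + hu / 1950.0)
    else:
        raise ValueError(f"unknown ramp {ramp!r}")
    return np.clip(rho, 0.0, None)


def radiological_depth(volume: CTVolume, start_mm, direction, length_mm: float, step_mm: float = 0.25) -> float:
    """Water-equivalent depth (cm) along a ray: integral of rho_rel ds.

    The ray is marched in ``step_mm`` increments sampling the nearest
    voxel at each midpoint.  Raises if the ray never enters the grid.
    """
    start = np.asarray(start_mm, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    n = max(1, int(round(length_mm / step_mm)))
    ts = (np.arange(n) + 0.5) * (length_mm / n)
    pts = start[None, :] + ts[:, None] * d[None, :]
    idx = np.rint((pts - np.asarray(volume.origin)) / np.asarray(volume.spacing)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(volume.values.shape)), axis=1)
    if not inside.any():
        raise ValueError("ray does not intersect the volume grid")
    hu = volume.values[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
    return float(hu_to_relative_density(hu).sum() * (length_mm / n) / 10.0)


def effective_depth_volume(volume: CTVolume, direction: str = "AP", ramp: str = "single") -> np.ndarray:
    """Per-voxel water-equivalent depth (cm) for an axis-aligned beam.

    Depth at a voxel is the cumulative rho_rel path length from the grid
    face to the voxel *center* (half of the voxel's own contribution).
    """
    rho = hu_to_relative_density(volume.values, ramp=ramp)
    ax = AXIS_AP
    if direction == "PA":
        rho = np.flip(rho, axis=ax)
    cum = np.cumsum(rho, axis=ax) - rho / 2.0
    if direction == "PA":
        cum = np.flip(cum, axis=ax)
    return cum * volume.spacing[ax] / 10.0


# ---------------------------------------------------------------------------
# field dose


def _buildup(d_eff_cm: np.ndarray, beam: BeamSpec) -> np.ndarray:
    b = beam.buildup_beta_per_cm
    sat = 1.0 - np.exp(-b * beam.d_max_cm)
    return np.where(
        d_eff_cm >= beam.d_max_cm, 1.0, (1.0 - np.exp(-b * np.clip(d_eff_cm, 0, None))) / sat
    )


def _aperture_from_field(volume: CTVolume, beam: BeamSpec, isocenter_mm) -> np.ndarray:
    x = volume.axis_coords(0) - isocenter_mm[0]
    z = volume.axis_coords(2) - isocenter_mm[2]
    half = (beam.field_size_mm[0] / 2.0, beam.field_size_mm[1] / 2.0)
    return ((np.abs(x) <= half[0])[:, None] & (np.abs(z) <= half[1])[None, :]).astype(np.float64)


def compute_field_dose(
    volume: CTVolume,
    beam: BeamSpec,
    isocenter_mm=(0.0, 0.0, 0.0),
    aperture: np.ndarray | None = None,
    ramp: str = "single",
) -> DoseGrid:
    """Dose for one AP or PA field on the volume's grid.

    ``aperture`` is a (lateral × SI) binary array in the beam's-eye view;
    when omitted the fixed square field of the beam spec is used.  The
    aperture is convolved with a Gaussian penumbra and applied as a
    depth-independent lateral fluence profile (parallel beam, no
    divergence).
    """
    if aperture is None:
        aperture = _aperture_from_field(volume, beam, isocenter_mm)
    aperture = np.asarray(aperture, dtype=np.float64)
    if aperture.shape != (volume.values.shape[0], volume.values.shape[2]):
        raise ValueError(
            f"aperture shape {aperture.shape} does not match the (lateral, SI) "
            f"grid {(volume.values.shape[0], volume.values.shape[2])}"
        )
    if not aperture.any():
        raise ValueError("aperture is empty")
    sigma = (beam.penumbra_sigma_mm / volume.spacing[0], beam.penumbra_sigma_mm / volume.spacing[2])
    fluence = ndimage.gaussian_filter(aperture, sigma=sigma)
    fluence[fluence < 1e-9] = 0.0
    d_eff = effective_depth_volume(volume, direction=beam.direction, ramp=ramp)
    axial = (
        (beam.monitor_units / 500.0)
        * _buildup(d_eff, beam)
        * np.exp(-beam.mu_water_per_cm * (d_eff - beam.d_max_cm))
    )
    dose = axial * fluence[:, None, :]
    return DoseGrid(
        dose,
        spacing=volume.spacing,
        origin=volume.origin,
        name=f"{volume.name}_{beam.direction}",
        meta={"beam": dataclasses.asdict(beam)},
    )


def combine_fields(doses: list[DoseGrid], name: str = "plan") -> DoseGrid:
    """Voxelwise sum of fields on a common grid."""
    if not doses:
        raise ValueError("need at least one field")
    require_same_grid(*doses, what="dose grids")
    total = np.zeros_like(doses[0].values, dtype=np.float64)
    for d in doses:
        total += d.values
    return DoseGrid(total, spacing=doses[0].spacing, origin=doses[0].origin, name=name)


def ap_pa_plan(
    volume: CTVolume,
    ptv: StructureMask,
    beam: BeamSpec = BeamSpec(),
    ramp: str = "single",
) -> DoseGrid:
    """Parallel-opposed AP/PA plan with the aperture fitted to the PTV
    beam's-eye-view projection (the MLC-fitted-field analogue)."""
    require_same_grid(volume, ptv, what="volume / PTV")
    aperture = ptv.mask.any(axis=AXIS_AP).astype(np.float64)
    fields = [
        compute_field_dose(volume, dataclasses.replace(beam, direction=d), aperture=aperture, ramp=ramp)
        for d in ("AP", "PA")
    ]
    plan = combine_fields(fields, name=f"{volume.name}_APPA")
    plan.meta["beam"] = dataclasses.asdict(beam)
    return plan


# ---------------------------------------------------------------------------
# point-dose HU sweep


def sweep_points(isocenter_mm) -> dict[str, tuple[float, float, float]]:
    """The four central-axis points of interest for an AP field:
    P1 3 cm anterior of the target center, P2 at the center, P3 3 cm
    posterior, P4 2 cm beyond P3 (past the lung cavity)."""
    x, y, z = isocenter_mm
    return {
        "P1": (x, y - 30.0, z),
        "P2": (x, y, z),
        "P3": (x, y + 30.0, z),
        "P4": (x, y + 50.0, z),
    }


def _sample_dose(dose: DoseGrid, point_mm) -> float:
    idx = (np.asarray(point_mm, dtype=float) - np.asarray(dose.origin)) / np.asarray(dose.spacing)
    if np.any(idx < 0) or np.any(idx > np.asarray(dose.values.shape) - 1):
        raise ValueError(f"point {tuple(point_mm)} mm lies outside the dose grid")
    return float(
        ndimage.map_coordinates(dose.values, idx.reshape(3, 1), order=1, mode="nearest")[0]
    )


def hu_sweep_experiment(
    volume: CTVolume,
    target_mask: StructureMask,
    beam: BeamSpec = BeamSpec(),
    isocenter_mm=None,
    overrides=None,
) -> pd.DataFrame:
    """Percent point-dose change vs target HU override, single AP field.

    The target structure's CT values are overridden to each absolute level
    in ``overrides`` (default −200 … +200 HU in 25 HU steps) and the dose
    at P1–P4 is compared with the unmodified volume:
    100·(D − D_nominal)/D_nominal.
    """
    require_same_grid(volume, target_mask, what="volume / target mask")
    if overrides is None:
        overrides = np.arange(-200.0, 225.0, 25.0)
    if isocenter_mm is None:
        com = ndimage.center_of_mass(target_mask.mask)
        isocenter_mm = tuple(
            volume.origin[a] + volume.spacing[a] * com[a] for a in range(3)
        )
    points = sweep_points(isocenter_mm)
    nominal = compute_field_dose(volume, beam, isocenter_mm=isocenter_mm)
    d_nom = {p: _sample_dose(nominal, xyz) for p, xyz in points.items()}
    rows = []
    for hu in overrides:
        vals = volume.values.copy()
        vals[target_mask.mask] = hu
        dose = compute_field_dose(volume.with_values(vals), beam, isocenter_mm=isocenter_mm)
        for p, xyz in points.items():
            d = _sample_dose(dose, xyz)
            rows.append(
                {
                    "override_hu": float(hu),
                    "point": p,
                    "pct_change": 100.0 * (d - d_nom[p]) / d_nom[p],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DVH metrics


def dvh_metrics(dose: DoseGrid, roi: StructureMask) -> DVHMetrics:
    """D_max, D_2%, D_mean, D_95%, D_98% over an ROI.

    D_x% is the dose exceeded by x% of the ROI volume (top-percentile
    convention): the 100−x percentile of the voxel doses with linear
    interpolation.
    """
    require_same_grid(dose, roi, what="dose / ROI")
    if roi.voxel_count == 0:
        raise ValueError(f"ROI {roi.name!r} is empty")
    d = np.asarray(dose.values[roi.mask], dtype=np.float64)
    return DVHMetrics(
        d_max=float(d.max()),
        d_2=float(np.percentile(d, 98.0)),
        d_mean=float(d.mean()),
        d_95=float(np.percentile(d, 5.0)),
        d_98=float(np.percentile(d, 2.0)),
    )


def delta_d(m_a: DVHMetrics, m_b: DVHMetrics) -> dict[str, float]:
    """Metric-wise percent difference 100·(A − B)/A between two plans'
    DVH metrics (A is the reference denominator)."""
    out = {}
    for k, a in m_a.as_dict().items():
        b = m_b.as_dict()[k]
        if a == 0:
            raise ValueError(f"delta_d: reference metric {k} is zero")
        out[k] = 100.0 * (a - b) / a
    return out


# ---------------------------------------------------------------------------
# grid utilities


def resample_volume(volume: CTVolume, new_spacing: tuple[float, float, float]) -> CTVolume:
    """Linear resample onto a coarser/finer grid sharing the same origin."""
    new_spacing = tuple(float(s) for s in new_spacing)
    shape = volume.values.shape
    new_shape = tuple(
        max(1, int(np.floor((shape[a] - 1) * volume.spacing[a] / new_spacing[a])) + 1)
        for a in range(3)
    )
    coords = np.meshgrid(
        *[np.arange(new_shape[a]) * new_spacing[a] / volume.spacing[a] for a in range(3)],
        indexing="ij",
    )
    vals = ndimage.map_coordinates(volume.values, coords, order=1, mode="nearest")
    return CTVolume(
        vals.astype(np.float32),
        spacing=new_spacing,
        origin=volume.origin,
        name=volume.name,
        meta=dict(volume.meta),
    )


def extract_coronal_plane(dose: DoseGrid, ap_mm: float) -> DoseGrid:
    """(lateral × SI) plane at a fixed AP position — the film-plane
    analogue used for gamma comparison."""
    if dose.values.ndim != 3:
        raise ValueError("need a 3D dose grid")
    j = int(round((ap_mm - dose.origin[1]) / dose.spacing[1]))
    if not 0 <= j < dose.values.shape[1]:
        raise ValueError(f"AP position {ap_mm} mm outside the dose grid")
    return DoseGrid(
        dose.values[:, j, :].copy(),
        spacing=(dose.spacing[0], dose.spacing[2]),
        origin=(dose.origin[0], dose.origin[2]),
        name=f"{dose.name}_coronal",
        meta={"ap_mm": ap_mm},
    )
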