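"""Digital twin of a respiratory lung phantom.

The physical device this emulates is a thorax-sized acrylic body holding a
low-density cedar insert (HU ≈ −750 … −600, mimicking lung) that encapsulates
an offset 3.0 cm polystyrene sphere (HU ≈ −100 … 0, the gross tumor volume).
A drive translates the target sinusoidally along the superior-inferior (SI)
axis.  Here the phantom is voxelized on a regular grid and rendered once per
respiratory phase, which is what a 4D-CT phase bin of the ideal, artifact-free
device would look like.

Texture model
-------------
Each material (lung, target) gets a spatial Gaussian random field — white
noise smoothed to a 5 mm correlation length, standardized, scaled to the
material sd and clipped to the material HU range.  Both fields are sampled
once per seed and are *frozen in the phantom frame*: the moving sphere
boundary selects which field a voxel shows at each phase.  A static texture
is what the physical cedar grain is; freezing it also keeps the MIP dataset
free of spurious order-statistic inflation that independent per-phase noise
would add.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .volume import AXIS_SI, CTVolume

__all__ = [
    "PhantomSpec",
    "MotionModel",
    "target_center_at_phase",
    "render_phase_volume",
    "render_fb_volume",
    "draw_fb_phase",
    "material_fields",
    "sphere_mask_array",
    "N_PHASES",
    "HU_AIR",
]

N_PHASES = 10
HU_AIR = -1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, materials and texture of the digital phantom.

    Lengths are mm, HU values are CT numbers.  The grid is axis-ordered
    (lateral, AP, SI) and centered on the phantom, so the world origin sits
    at the lung-insert axis midpoint.
    """

    grid_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_extent: tuple[float, float, float] = (300.0, 200.0, 260.0)

    hu_body: float = 0.0  # water-equivalent shell
    body_margin: float = 10.0  # air gap between body and grid edge, per side
    body_corner_radius: float = 20.0  # rounded edges in the axial plane

    lung_radius: float = 40.0
    lung_length: float = 220.0
    hu_lung_mean: float = -625.0
    lung_clip: tuple[float, float] = (-750.0, -600.0)

    target_diameter: float = 30.0
    hu_target_mean: float = -50.0
    target_clip: tuple[float, float] = (-100.0, 0.0)
    #: rest position of the sphere center, mm, relative to the insert axis
    #: midpoint (lateral offset mimics the off-axis bore of the insert)
    target_rest_center: tuple[float, float, float] = (10.0, 0.0, 0.0)

    texture_sd: float = 25.0
    #: grain scale: FWHM (mm) of the Gaussian autocorrelation of the texture
    texture_corr_mm: float = 5.0
    #: high-pass scale: drift at scales larger than this is removed so any
    #: material ROI of roughly the target size recovers the nominal material
    #: mean; 0 keeps the raw correlated field
    texture_highpass_mm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.grid_spacing):
            raise ValueError(f"grid_spacing must be positive, got {self.grid_spacing}")
        if any(e <= 0 for e in self.grid_extent):
            raise ValueError(f"grid_extent must be positive, got {self.grid_extent}")
        if self.target_diameter <= 0:
            raise ValueError("target_diameter must be positive")
        lo, hi = self.lung_clip
        if not lo < hi:
            raise ValueError(f"lung_clip must be an increasing interval, got {self.lung_clip}")
        lo, hi = self.target_clip
        if not lo < hi:
            raise ValueError(f"target_clip must be an increasing interval, got {self.target_clip}")

    @property
    def target_radius(self) -> float:
        return self.target_diameter / 2.0

    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(int(round(e / s)) for e, s in zip(self.grid_extent, self.grid_spacing))

    def grid_origin(self) -> tuple[float, float, float]:
        # voxel centers symmetric about the phantom center (world 0,0,0)
        return tuple(
            -s * (n - 1) / 2.0 for s, n in zip(self.grid_spacing, self.grid_shape())
        )

    def validate_motion(self, motion: "MotionModel") -> None:
        """The target sphere plus its full motion range must fit strictly
        inside the lung insert."""
        x0, y0, z0 = self.target_rest_center
        radial = math.hypot(x0, y0) + self.target_radius
        if radial >= self.lung_radius:
            raise ValueError(
                f"target (radial reach {radial:.1f} mm) does not fit inside the "
                f"lung insert (radius {self.lung_radius:.1f} mm)"
            )
        si_reach = abs(z0) + motion.amplitude_mm + self.target_radius
        si_limit = min(self.lung_length / 2.0, self.grid_extent[2] / 2.0)
        if si_reach >= si_limit:
            raise ValueError(
                f"target motion (SI reach {si_reach:.1f} mm) exits the lung insert "
                f"or grid (limit {si_limit:.1f} mm)"
            )


@dataclass(frozen=True)
class MotionModel:
    """Simple harmonic SI motion, z(t) = A·cos(2πt/T).

    Phase 0% is maximum inhalation (z = +A), phase 50% maximum exhalation
    (z = −A); the default period of 4.0 s is 15 breathing cycles per minute.
    ``amplitude_mm`` is half the peak-to-peak range (the study uses 5, 10
    and 15 mm).
    """

    amplitude_mm: float = 10.0
    period_s: float = 4.0
    axis: int = AXIS_SI

    def __post_init__(self):
        if self.amplitude_mm < 0:
            raise ValueError("amplitude must be non-negative")
        if self.period_s <= 0:
            raise ValueError("period must be positive")

    def displacement(self, t: float | np.ndarray) -> float | np.ndarray:
        """SI displacement (mm) at time t (s)."""
        return self.amplitude_mm * np.cos(2.0 * np.pi * np.asarray(t) / self.period_s)


def target_center_at_phase(motion: MotionModel, phase_index: int) -> float:
    """SI displacement (mm) of the target center at a 10-bin phase index.

    Phase bins sample the cycle uniformly: displacement = A·cos(2π·p/10),
    so phase 0 is +A (max inhalation) and phase 5 is −A (max exhalation).
    """
    if not (isinstance(phase_index, (int, np.integer)) and 0 <= phase_index <= 9):
        raise ValueError(
            f"phase_index must be an integer in [0, 9], got {phase_index!r}"
        )
    return float(motion.amplitude_mm * np.cos(2.0 * np.pi * phase_index / N_PHASES))


# ---------------------------------------------------------------------------
# geometry rasterization


def _axis_grids(spec: PhantomSpec):
    shape = spec.grid_shape()
    origin = spec.grid_origin()
    return [
        (origin[a] + spec.grid_spacing[a] * np.arange(shape[a])).astype(np.float32)
        for a in range(3)
    ]


def sphere_mask_array(
    spec: PhantomSpec, center: tuple[float, float, float], radius: float
) -> np.ndarray:
    """Boolean array of voxels whose *center* lies strictly within ``radius``
    of ``center`` (strict inequality: a voxel exactly at distance r is out)."""
    x, y, z = _axis_grids(spec)
    d2 = (
        (x[:, None, None] - center[0]) ** 2
        + (y[None, :, None] - center[1]) ** 2
        + (z[None, None, :] - center[2]) ** 2
    )
    return d2 < radius * radius


def _body_mask(spec: PhantomSpec) -> np.ndarray:
    """Rectangular body with rounded edges in the axial (lateral-AP) plane."""
    x, y, z = _axis_grids(spec)
    hx = spec.grid_extent[0] / 2.0 - spec.body_margin
    hy = spec.grid_extent[1] / 2.0 - spec.body_margin
    hz = spec.grid_extent[2] / 2.0
    rc = min(spec.body_corner_radius, hx, hy)
    # rounded-rectangle: distance to the inner rectangle shrunk by rc
    dx = np.maximum(np.abs(x) - (hx - rc), 0.0)
    dy = np.maximum(np.abs(y) - (hy - rc), 0.0)
    axial = dx[:, None] ** 2 + dy[None, :] ** 2 <= rc * rc
    return axial[:, :, None] & (np.abs(z) <= hz)[None, None, :]


def _lung_mask(spec: PhantomSpec) -> np.ndarray:
    x, y, z = _axis_grids(spec)
    radial = x[:, None] ** 2 + y[None, :] ** 2 < spec.lung_radius**2
    return radial[:, :, None] & (np.abs(z) < spec.lung_length / 2.0)[None, None, :]


# ---------------------------------------------------------------------------
# frozen material textures


def _gaussian_field(shape, spacing, corr_mm, highpass_mm, rng) -> np.ndarray:
    """Unit-variance correlated field: smoothed white noise, standardized.

    A correlated field keeps slow spatial drift that would make the mean of
    a small ROI wander several HU from the material mean; removing the
    component smoother than ``highpass_mm`` leaves the grain but pins local
    means, so the generator's material means are recoverable from any ROI
    at that scale.
    """
    noise = rng.standard_normal(shape).astype(np.float32)
    if corr_mm > 0:
        # corr_mm is the FWHM of the grain; FWHM = 2*sqrt(2 ln 2) * sigma
        sigma = [corr_mm / 2.3548 / s for s in spacing]
        noise = ndimage.gaussian_filter(noise, sigma=sigma)
    if highpass_mm > 0:
        sigma_hp = [highpass_mm / s for s in spacing]
        noise = noise - ndimage.gaussian_filter(noise, sigma=sigma_hp)
    sd = float(noise.std())
    if sd > 0:
        noise = (noise - float(noise.mean())) / sd
    return noise


@lru_cache(maxsize=4)
def material_fields(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Frozen (lung, target) HU fields for a spec, keyed by the spec itself.

    Independent sub-streams of the spec seed drive the two materials so the
    lung field does not change when only target texture parameters change.
    """
    shape = spec.grid_shape()
    ss = np.random.SeedSequence(spec.seed)
    lung_rng, target_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    lung = spec.hu_lung_mean + spec.texture_sd * _gaussian_field(
        shape, spec.grid_spacing, spec.texture_corr_mm, spec.texture_highpass_mm, lung_rng
    )
    np.clip(lung, *spec.lung_clip, out=lung)
    target = spec.hu_target_mean + spec.texture_sd * _gaussian_field(
        shape, spec.grid_spacing, spec.texture_corr_mm, spec.texture_highpass_mm, target_rng
    )
    np.clip(target, *spec.target_clip, out=target)
    lung.setflags(write=False)
    target.setflags(write=False)
    return lung, target


# ---------------------------------------------------------------------------
# rendering


def _base_volume(spec: PhantomSpec, lung_field: np.ndarray) -> np.ndarray:
    vol = np.full(spec.grid_shape(), HU_AIR, dtype=np.float32)
    vol[_body_mask(spec)] = spec.hu_body
    lung = _lung_mask(spec)
    vol[lung] = lung_field[lung]
    return vol


def _target_fraction(
    spec: PhantomSpec, center: tuple[float, float, float], supersample: int
) -> np.ndarray:
    """Per-voxel occupied fraction of the target sphere.

    ``supersample=1`` is the default strict center-in/out rule (fraction is
    0 or 1); ``supersample=2`` averages membership over 2×2×2 sub-voxel
    centers for anti-aliased boundaries.
    """
    if supersample <= 1:
        return sphere_mask_array(spec, center, spec.target_radius).astype(np.float32)
    x, y, z = _axis_grids(spec)
    frac = np.zeros(spec.grid_shape(), dtype=np.float32)
    n = supersample
    offsets = (np.arange(n) - (n - 1) / 2.0) / n
    r2 = spec.target_radius**2
    for ox in offsets:
        for oy in offsets:
            for oz in offsets:
                d2 = (
                    (x[:, None, None] + ox * spec.grid_spacing[0] - center[0]) ** 2
                    + (y[None, :, None] + oy * spec.grid_spacing[1] - center[1]) ** 2
                    + (z[None, None, :] + oz * spec.grid_spacing[2] - center[2]) ** 2
                )
                frac += d2 < r2
    frac /= n**3
    return frac


def render_phase_volume(
    spec: PhantomSpec,
    motion: MotionModel,
    phase_index: int,
    supersample: int = 1,
) -> CTVolume:
    """Render the phantom at one respiratory phase bin.

    The lung/body texture is identical across phases; only the target sphere
    translates (target-only motion).  The sphere boundary follows the strict
    center-distance rule unless ``supersample`` > 1.
    """
    dz = target_center_at_phase(motion, phase_index)
    spec.validate_motion(motion)
    lung_field, target_field = material_fields(spec)
    vol = _base_volume(spec, lung_field)
    cx, cy, cz = spec.target_rest_center
    frac = _target_fraction(spec, (cx, cy, cz + dz), supersample)
    if supersample <= 1:
        inside = frac > 0
        vol[inside] = target_field[inside]
    else:
        vol += frac * (target_field - vol)
    return CTVolume(
        vol,
        spacing=spec.grid_spacing,
        origin=spec.grid_origin(),
        name=f"phase_{phase_index}",
        meta={"phase_index": phase_index, "si_displacement_mm": dz, "seed": spec.seed},
    )


def draw_fb_phase(spec: PhantomSpec) -> int:
    """Seeded draw of the free-breathing snapshot phase (the helical scan
    catches the target at an arbitrary, unrecorded point of the cycle)."""
    ss = np.random.SeedSequence(spec.seed)
    fb_rng = np.random.default_rng(ss.spawn(3)[2])
    return int(fb_rng.integers(0, N_PHASES))


def render_fb_volume(
    spec: PhantomSpec,
    motion: MotionModel,
    fb_phase_index: int | None = None,
    supersample: int = 1,
) -> CTVolume:
    """Free-breathing dataset: a single-phase snapshot of the moving phantom.

    No helical-acquisition artifacts are simulated, so this is an idealized
    FB scan.  When ``fb_phase_index`` is None it is drawn reproducibly from
    the spec seed and recorded in the volume metadata.
    """
    if fb_phase_index is None:
        fb_phase_index = draw_fb_phase(spec)
    vol = render_phase_volume(spec, motion, fb_phase_index, supersample=supersample)
    vol.name = "FB"
    vol.meta["fb_phase_index"] = fb_phase_index
    return vol
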