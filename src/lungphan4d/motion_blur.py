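"""Dose smearing under sinusoidal motion.

A detector (film) riding on the moving phantom samples the static dose
distribution at every position of the cycle.  For simple harmonic motion
the time-averaged position density is the arcsine law

    p(x) = 1 / (pi * sqrt(A^2 - x^2)),   |x| < A,

so a static plane convolved with this kernel along the motion (SI) axis
is what the moving film records.  The kernel is discretized by *exact*
bin integration of the CDF F(x) = 1/2 + asin(x/A)/pi, so it sums to 1 by
construction; an empirical trajectory histogram can be substituted for
non-ideal traces.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .dose_engine import DoseGrid

__all__ = ["shm_pdf_kernel", "kernel_from_trace", "convolve_dose_plane"]


def _arcsine_cdf(x: np.ndarray, amplitude: float) -> np.ndarray:
    return 0.5 + np.arcsin(np.clip(x / amplitude, -1.0, 1.0)) / np.pi


def shm_pdf_kernel(amplitude_mm: float, step_mm: float) -> np.ndarray:
    """Discretized arcsine position density for SHM of amplitude A.

    Bin i (center i*step) receives the exact probability mass
    F(min(edge_hi, A)) − F(max(edge_lo, −A)); the bins tile [−A, A] so the
    kernel sums to 1 up to roundoff.  A = 0 returns the identity kernel.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude must be non-negative")
    if step_mm <= 0:
        raise ValueError("step must be positive")
    if amplitude_mm == 0:
        return np.array([1.0])
    if step_mm > 2 * amplitude_mm:
        warnings.warn(
            f"step ({step_mm} mm) exceeds the motion range ({2 * amplitude_mm} mm); "
            "kernel collapses to a single bin"
        )
    # outermost bin center c must satisfy c - step/2 < A (nonzero mass)
    half_n = max(0, int(np.ceil(amplitude_mm / step_mm + 0.5)) - 1)
    centers = np.arange(-half_n, half_n + 1) * step_mm
    lo = _arcsine_cdf(centers - step_mm / 2, amplitude_mm)
    hi = _arcsine_cdf(centers + step_mm / 2, amplitude_mm)
    kernel = hi - lo
    return kernel / kernel.sum()


def kernel_from_trace(positions_mm: np.ndarray, step_mm: float) -> np.ndarray:
    """Empirical position-density kernel from a recorded motion trace,
    on the same centered-bin convention as :func:`shm_pdf_kernel`."""
    positions_mm = np.asarray(positions_mm, dtype=float)
    if positions_mm.size == 0:
        raise ValueError("empty trace")
    mx = float(np.abs(positions_mm).max())
    half_n = max(0, int(np.ceil(mx / step_mm + 0.5)) - 1)
    edges = (np.arange(-half_n, half_n + 2) - 0.5) * step_mm
    counts, _ = np.histogram(positions_mm, bins=edges)
    return counts / counts.sum()


def convolve_dose_plane(plane: DoseGrid, kernel: np.ndarray, axis: int = 1) -> DoseGrid:
    """1D convolution of a 2D dose plane along the motion axis.

    The plane is zero-padded by the kernel half-width before convolving,
    so the total integral dose is conserved exactly (the smeared tails are
    kept, not clipped).  The returned plane is wider than the input by one
    kernel half-width per side and its origin is shifted accordingly.
    """
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.ndim != 1 or kernel.size == 0:
        raise ValueError("kernel must be a non-empty 1D array")
    if abs(kernel.sum() - 1.0) > 1e-9:
        raise ValueError("kernel must be normalized to sum 1")
    if plane.values.ndim != 2:
        raise ValueError("need a 2D dose plane")
    half = kernel.size // 2
    n_axis = plane.values.shape[axis] + 2 * half
    if kernel.size > n_axis:
        raise ValueError("kernel is wider than the padded plane")
    pad = [(0, 0), (0, 0)]
    pad[axis] = (half, half)
    padded = np.pad(np.asarray(plane.values, dtype=np.float64), pad)
    out = ndimage.convolve1d(padded, kernel, axis=axis, mode="constant", cval=0.0)
    out[out < 0] = 0.0  # clip convolution roundoff at -1e-20 level
    origin = list(plane.origin)
    origin[axis] -= half * plane.spacing[axis]
    return DoseGrid(
        out,
        spacing=plane.spacing,
        origin=tuple(origin),
        name=f"{plane.name}_blurred",
        meta={**plane.meta, "kernel_size": int(kernel.size)},
    )
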