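"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results through a different route than the
implementation: the gamma oracle searches a dense displacement set through
a continuous interpolant per reference point; the DVH oracle works on the
sorted dose vector directly.
"""

import numpy as np
from scipy.interpolate import RegularGridInterpolator


def gamma_oracle_pass_rate(
    reference,
    evaluated,
    dose_pct: float = 3.0,
    dta_mm: float = 3.0,
    threshold_pct: float = 10.0,
    step_fraction: float = 20.0,
) -> float:
    """Brute-force global-normalization gamma pass rate for 2D planes.

    For every reference point above threshold, evaluate the evaluated
    plane (linear interpolant) on a dense displacement disk of radius
    2*DTA sampled at DTA/step_fraction, and take the min of the gamma
    integrand.  O(points x displacements); for small planes only.
    """
    ref = np.asarray(reference.values, dtype=float)
    d_max = ref.max()
    delta = dose_pct / 100.0 * d_max
    cutoff = threshold_pct / 100.0 * d_max

    axes = [evaluated.axis_coords(a) for a in range(2)]
    interp = RegularGridInterpolator(
        axes, np.asarray(evaluated.values, dtype=float), bounds_error=False, fill_value=np.nan
    )

    step = dta_mm / step_fraction
    radius = 2.0 * dta_mm
    offs = np.arange(-radius, radius + step / 2, step)
    ox, oy = np.meshgrid(offs, offs, indexing="ij")
    keep = ox**2 + oy**2 <= radius**2
    disp = np.stack([ox[keep], oy[keep]], axis=-1)  # (n_disp, 2)
    dist2 = (disp**2).sum(axis=1)

    pts_i, pts_j = np.nonzero(ref >= cutoff)
    coords = np.stack(
        [reference.axis_coords(0)[pts_i], reference.axis_coords(1)[pts_j]], axis=-1
    )
    # one interpolation call over all (point, displacement) pairs
    query = coords[:, None, :] + disp[None, :, :]
    vals = interp(query.reshape(-1, 2)).reshape(len(coords), len(disp))
    g2 = dist2[None, :] / dta_mm**2 + (vals - ref[pts_i, pts_j][:, None]) ** 2 / delta**2
    gamma = np.sqrt(np.nanmin(g2, axis=1))
    return 100.0 * float((gamma <= 1.0).mean())


def dvh_percentile_oracle(doses, top_pct: float) -> float:
    """Dose exceeded by top_pct% of the ROI: sort-based linear
    interpolation on the order statistics (matches np.percentile's linear
    method, derived independently)."""
    d = np.sort(np.asarray(doses, dtype=float))
    n = d.size
    q = (100.0 - top_pct) / 100.0
    h = q * (n - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return float(d[lo] + (h - lo) * (d[hi] - d[lo]))


def arcsine_bin_mass_quadrature(center: float, step: float, amplitude: float) -> float:
    """Adaptive quadrature of the arcsine pdf over one kernel bin."""
    from scipy.integrate import quad

    lo = max(center - step / 2, -amplitude)
    hi = min(center + step / 2, amplitude)
    if hi <= lo:
        return 0.0
    val, _ = quad(
        lambda x: 1.0 / (np.pi * np.sqrt(amplitude**2 - x**2)), lo, hi, limit=200
    )
    return float(val)
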