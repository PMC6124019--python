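"""Computational CT datasets from the 10 respiratory phase volumes.

AIP (average intensity projection) is the voxelwise arithmetic mean of the
phase volumes; MIP (maximum intensity projection) the voxelwise maximum.
Both operate directly on CT numbers, matching how a 4D-CT workstation
derives them from the phase bins; phase weights are uniform (each bin is
1/10 of the cycle).  The free-breathing dataset passes through unchanged.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .volume import CTVolume, require_same_grid

__all__ = ["compute_aip", "compute_mip"]


def _check_phases(phases: Sequence[CTVolume]) -> None:
    if len(phases) < 2:
        raise ValueError(f"need at least 2 phase volumes, got {len(phases)}")
    require_same_grid(*phases, what="phase volumes")


def compute_aip(phases: Sequence[CTVolume]) -> CTVolume:
    """Voxelwise mean HU across phase volumes (uniform phase weights)."""
    _check_phases(phases)
    acc = np.zeros(phases[0].values.shape, dtype=np.float64)
    for p in phases:
        acc += p.values
    acc /= len(phases)
    return phases[0].with_values(acc, name="AIP")  # float64: the mean is exact arithmetic


def compute_mip(phases: Sequence[CTVolume]) -> CTVolume:
    """Voxelwise maximum HU across phase volumes."""
    _check_phases(phases)
    out = phases[0].values.copy()
    for p in phases[1:]:
        np.maximum(out, p.values, out=out)
    return phases[0].with_values(out, name="MIP")
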