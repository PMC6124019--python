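"""ROI Hounsfield-unit extraction, histograms and summary tables.

Histograms use fixed bins from −850 to +50 HU with width 20 (45 bins),
half-open [edge, edge+20) with the final bin closed at +50.  Values
outside the bin range are excluded from the counts but included in the
mean/sd, which are computed over all ROI voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import StructureMask
from .volume import CTVolume, require_same_grid

__all__ = [
    "HUHistogram",
    "HIST_EDGES",
    "extract_roi_values",
    "histogram_and_stats",
    "dataset_comparison_table",
]

#: fixed histogram support: −850 … +50 HU, 20 HU bins
HIST_EDGES = np.arange(-850.0, 50.0 + 20.0, 20.0)


@dataclass
class HUHistogram:
    edges: np.ndarray
    counts: np.ndarray
    n_in_range: int
    n_total: int
    mean: float
    sd: float
    sd_kind: str = "sample"  # sample (ddof=1) or population (ddof=0)

    def __post_init__(self):
        if self.counts.sum() != self.n_in_range:
            raise ValueError("histogram counts do not sum to n_in_range")
        if self.n_in_range > self.n_total:
            raise ValueError("n_in_range cannot exceed n_total")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.edges[:-1],
                "bin_right": self.edges[1:],
                "count": self.counts,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def extract_roi_values(volume: CTVolume, mask: StructureMask) -> np.ndarray:
    """All HU values at mask voxels (one value per voxel, order fixed by
    the array layout)."""
    require_same_grid(volume, mask, what="volume / mask")
    if mask.voxel_count == 0:
        raise ValueError(f"mask {mask.name!r} is empty")
    return np.asarray(volume.values[mask.mask], dtype=np.float64)


def histogram_and_stats(values, sd_kind: str = "sample") -> HUHistogram:
    """Fixed-bin histogram plus mean/sd of an HU value multiset."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("need at least one HU value")
    if sd_kind not in ("sample", "population"):
        raise ValueError(f"sd_kind must be 'sample' or 'population', got {sd_kind!r}")
    counts, _ = np.histogram(values, bins=HIST_EDGES)
    ddof = 1 if sd_kind == "sample" else 0
    sd = float(values.std(ddof=ddof)) if values.size > ddof else 0.0
    return HUHistogram(
        edges=HIST_EDGES,
        counts=counts,
        n_in_range=int(counts.sum()),
        n_total=int(values.size),
        mean=float(values.mean()),
        sd=sd,
        sd_kind=sd_kind,
    )


def dataset_comparison_table(
    datasets: dict[str, dict[str, CTVolume]],
    ptv_masks: dict[str, StructureMask],
    sd_kind: str = "sample",
) -> pd.DataFrame:
    """Mean ± sd of PTV HU per (motion range, dataset).

    ``datasets`` maps a range label to ``{dataset name: volume}``;
    ``ptv_masks`` maps the same range labels to the PTV mask of that range.
    A missing dataset is reported (row skipped) rather than fatal.
    """
    rows = []
    for range_label, vols in datasets.items():
        if range_label not in ptv_masks:
            raise ValueError(f"no PTV mask for range {range_label!r}")
        ptv = ptv_masks[range_label]
        for ds_name in vols:
            vol = vols[ds_name]
            if vol is None:
                import warnings

                warnings.warn(f"dataset {ds_name!r} missing for range {range_label!r}; row skipped")
                continue
            h = histogram_and_stats(extract_roi_values(vol, ptv), sd_kind=sd_kind)
            rows.append(
                {
                    "range_of_motion": range_label,
                    "dataset": ds_name,
                    "mean_hu": round(h.mean, 1),
                    "sd_hu": round(h.sd, 1),
                    "n_voxels": h.n_total,
                }
            )
    return pd.DataFrame(rows)
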