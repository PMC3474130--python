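"""Region-of-interest summaries of current-density norms.

Statistics (mean, median, 5th/95th percentile, max) are computed over the
unweighted set of voxel norms inside each labeled region — the grid is
regular, so every voxel carries the same volume — and are reported in
mA/cm^2.  Means drive the optimizer (their gradient is computable from the
basis fields); medians are what distributions of current density in tissue
are conventionally reported by, since those distributions are close to
log-normal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import EmptyRegionError
from .field_ops import CurrentDensityField
from .head_model import TissueLabelVolume
from .units import A_m2_to_mA_cm2

__all__ = [
    "RegionSummary",
    "region_summary",
    "skin_max",
    "export_table",
    "region_histogram",
    "export_histograms",
]


@dataclass(frozen=True)
class RegionSummary:
    """Current-density-norm statistics of one region, in mA/cm^2."""

    region: str
    pattern: str
    n_voxels: int
    mean: float
    median: float
    p5: float
    p95: float
    max: float


def _region_norms(
    field: CurrentDensityField, volume: TissueLabelVolume, region_labels, region_name: str
) -> np.ndarray:
    if field.shape != volume.shape:
        raise EmptyRegionError(
            f"field grid {field.shape} does not match volume {volume.shape}"
        )
    mask = volume.region_mask(region_labels)
    if not mask.any():
        raise EmptyRegionError(f"region {region_name!r} contains no voxels")
    return A_m2_to_mA_cm2(field.norm[mask])


def region_summary(
    field: CurrentDensityField,
    volume: TissueLabelVolume,
    region_labels,
    region_name: str | None = None,
    pattern: str = "",
) -> RegionSummary:
    """Summarise norm statistics over the voxels carrying the given labels."""
    if region_name is None:
        labels = np.atleast_1d(region_labels)
        region_name = "+".join(volume.label_names.get(int(l), str(int(l))) for l in labels)
    norms = _region_norms(field, volume, region_labels, region_name)
    return RegionSummary(
        region=region_name,
        pattern=pattern,
        n_voxels=int(norms.size),
        mean=float(norms.mean()),
        median=float(np.median(norms)),
        p5=float(np.percentile(norms, 5)),
        p95=float(np.percentile(norms, 95)),
        max=float(norms.max()),
    )


def _labels_named(volume: TissueLabelVolume, name: str) -> list[int]:
    return [l for l, n in volume.label_names.items() if n == name]


def skin_max(
    field: CurrentDensityField, volume: TissueLabelVolume, skin_name: str = "skin"
) -> float:
    """Maximum voxel current-density norm over the skin (mA/cm^2)."""
    labels = _labels_named(volume, skin_name)
    if not labels:
        raise EmptyRegionError(f"no label named {skin_name!r} in the volume")
    return float(_region_norms(field, volume, labels, skin_name).max())


_COLUMNS = ["region", "pattern", "n_voxels", "mean", "median", "p5", "p95", "max"]


def summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries], columns=_COLUMNS)


def export_table(summaries, path) -> None:
    """Write one CSV row per (region, pattern) with all statistics."""
    summaries = list(summaries)
    if not summaries:
        raise EmptyRegionError("no summaries to export")
    summaries_frame(summaries).to_csv(path, index=False)


def region_histogram(
    field: CurrentDensityField,
    volume: TissueLabelVolume,
    region_labels,
    region_name: str | None = None,
    bins: int = 50,
) -> dict:
    """Histogram (bin edges + counts, mA/cm^2) of a region's norms."""
    if region_name is None:
        labels = np.atleast_1d(region_labels)
        region_name = "+".join(volume.label_names.get(int(l), str(int(l))) for l in labels)
    norms = _region_norms(field, volume, region_labels, region_name)
    counts, edges = np.histogram(norms, bins=bins)
    return {
        "region": region_name,
        "unit": "mA/cm^2",
        "bin_edges": edges.tolist(),
        "counts": counts.tolist(),
    }


def export_histograms(histograms, path) -> None:
    with open(path, "w") as fh:
        json.dump(list(histograms), fh, indent=1)
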