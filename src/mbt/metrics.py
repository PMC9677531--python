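"""Volume and dose-volume summary statistics.

Mask volumes and growth ratios follow the study's CT follow-up
semantics; dose-volume histograms (DVH) and the coverage percentages
V60/V100 (percent of the gross tumor volume receiving at least 60 or
100 Gy) and D95 (dose exceeded by 95% of GTV voxels) follow standard
radiotherapy reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .volume import VoxelVolume


@dataclass(frozen=True)
class DVHResult:
    """Cumulative DVH over the GTV plus the scalar coverage summaries."""

    dose_edges: np.ndarray  # Gy
    cumulative_volume_fraction: np.ndarray  # fraction of GTV at >= edge
    v60: float  # %
    v100: float  # %
    d95: float  # Gy


def mask_volume(mask: VoxelVolume) -> float:
    """Volume (mm³) of a binary mask: voxel count × per-voxel volume."""
    data = mask.data
    if data.dtype != bool and not np.isin(data, (0, 1)).all():
        raise ConfigurationError("mask must be binary")
    return float(np.count_nonzero(data)) * mask.voxel_volume_mm3


def volume_ratio(v_later: float, v_ref: float) -> float:
    """Growth ratio of two volumes (e.g. euthanasia day vs treatment day)."""
    if v_ref <= 0:
        raise ConfigurationError("reference volume must be > 0")
    return v_later / v_ref


def coverage_at(dose: VoxelVolume, gtv: VoxelVolume, threshold_gy: float) -> float:
    """Percent of GTV voxels with dose >= threshold (Table-style V_x)."""
    dose.require_same_geometry(gtv)
    g = gtv.data.astype(bool)
    if not g.any():
        raise ConfigurationError("empty GTV")
    return 100.0 * float((dose.data[g] >= threshold_gy).mean())


def d_at_volume(dose: VoxelVolume, gtv: VoxelVolume, volume_fraction: float = 0.95) -> float:
    """Dose (Gy) exceeded by ``volume_fraction`` of GTV voxels (D95 by default).

    Read off the exact voxel dose multiset: the largest dose d with at
    least the given fraction of voxels at >= d.
    """
    dose.require_same_geometry(gtv)
    g = gtv.data.astype(bool)
    if not g.any():
        raise ConfigurationError("empty GTV")
    return float(np.quantile(dose.data[g], 1.0 - volume_fraction, method="inverted_cdf"))


def compute_dvh(dose: VoxelVolume, gtv: VoxelVolume, bin_width_gy: float = 1.0) -> DVHResult:
    """Cumulative DVH over the GTV; v60/v100/d95 use the exact dose multiset."""
    if bin_width_gy <= 0:
        raise ConfigurationError("bin width must be > 0")
    dose.require_same_geometry(gtv)
    g = gtv.data.astype(bool)
    if not g.any():
        raise ConfigurationError("empty GTV")
    doses = dose.data[g]
    top = max(float(doses.max()), bin_width_gy)
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    cumulative = (doses[None, :] >= edges[:, None]).mean(axis=1)
    return DVHResult(
        dose_edges=edges,
        cumulative_volume_fraction=cumulative,
        v60=coverage_at(dose, gtv, 60.0),
        v100=coverage_at(dose, gtv, 100.0),
        d95=d_at_volume(dose, gtv, 0.95),
    )


def healthy_tissue_coverage(dose: VoxelVolume, gtv: VoxelVolume, threshold_gy: float = 10.0) -> float:
    """Percent of non-GTV grid voxels at >= threshold (context statistic).

    Reported alongside the GTV coverages to quantify sparing of the
    surrounding parenchyma; no reference value is attached to it.
    """
    dose.require_same_geometry(gtv)
    h = ~gtv.data.astype(bool)
    if not h.any():
        return 0.0
    return 100.0 * float((dose.data[h] >= threshold_gy).mean())


def dvh_to_csv(dvh: DVHResult, path: str) -> None:
    arr = np.column_stack([dvh.dose_edges, dvh.cumulative_volume_fraction])
    np.savetxt(path, arr, delimiter=",", header="dose_gy,volume_fraction", comments="")
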