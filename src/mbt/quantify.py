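"""CT-based Ho quantification.

The dosimetry chain needs the spatial distribution of the injected Ho,
recovered from the post-operative CT: a linear calibration curve maps Ho
concentration (mg/ml) to Hounsfield-unit excess over the local tissue
baseline, and inverting it voxel-by-voxel yields a concentration map,
then an activity map via the suspension's Ho weight fraction, specific
activity and physical decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dose import ActivityMap
from .errors import ConfigurationError
from .nuclide import RadionuclideSpec, Suspension, decay_factor
from .synthetic import CTModel, render_ct
from .volume import VoxelVolume


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear HU-vs-concentration calibration: HU = intercept + slope · C."""

    slope: float  # HU per (mg Ho)/ml
    intercept: float  # HU
    fit_residual_sd: float  # HU
    n_points: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ConfigurationError("calibration slope must be > 0")
        if self.n_points < 2:
            raise ConfigurationError("calibration needs at least 2 points")


def fit_calibration(concentrations_mg_per_ml, hu_values) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, HU) pairs."""
    c = np.asarray(concentrations_mg_per_ml, dtype=float)
    hu = np.asarray(hu_values, dtype=float)
    if c.shape != hu.shape or c.ndim != 1:
        raise ConfigurationError("concentrations and HU values must be 1-D and aligned")
    if len(c) < 2 or len(np.unique(c)) < 2:
        raise ConfigurationError("need at least 2 distinct concentrations")
    fit = stats.linregress(c, hu)
    residuals = hu - (fit.intercept + fit.slope * c)
    ddof = 2 if len(c) > 2 else 0
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        fit_residual_sd=float(np.sqrt((residuals**2).sum() / max(len(c) - ddof, 1))),
        n_points=len(c),
    )


def calibration_phantom(
    concentrations_mg_per_ml,
    ct: CTModel,
    seed: int = 0,
    insert_shape: tuple[int, int, int] = (8, 8, 8),
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic calibration scan: one uniform insert per known concentration.

    Each insert is rendered through the CT forward model on a brain-like
    baseline and summarized by its mean HU; returns (concentrations,
    mean HU) ready for :func:`fit_calibration`.
    """
    conc = np.asarray(concentrations_mg_per_ml, dtype=float)
    hu_means = np.empty_like(conc)
    for k, c in enumerate(conc):
        mask = VoxelVolume(np.ones(insert_shape, dtype=bool), spacing=(1.0, 1.0, 1.0))
        conc_map = mask.copy(data=np.full(insert_shape, c))
        # inserts sit in a tumor-free background: use a brain-baseline render
        hu = render_ct(mask.copy(data=np.zeros(insert_shape, dtype=bool)), conc_map, ct, seed=seed + k)
        hu_means[k] = float(hu.data.mean())
    return conc, hu_means


def ho_concentration_map(
    ct_volume: VoxelVolume,
    curve: CalibrationCurve,
    baseline_hu: VoxelVolume,
    min_excess_hu: float = 0.0,
) -> VoxelVolume:
    """Invert a CT volume to Ho concentration (mg/ml) per voxel.

    C = max(0, (HU − baseline) / slope); voxels whose HU excess falls
    below ``min_excess_hu`` (a noise floor, e.g. 5·noise_sd) are zeroed.
    """
    ct_volume.require_same_geometry(baseline_hu)
    excess = ct_volume.data - baseline_hu.data
    conc = np.maximum(excess, 0.0) / curve.slope
    if min_excess_hu > 0:
        conc[excess < min_excess_hu] = 0.0
    return ct_volume.copy(data=conc)


def total_ho_mass_mg(conc: VoxelVolume) -> float:
    """Integrate a concentration map (mg/ml) over the lattice to total Ho mass (mg)."""
    voxel_ml = conc.voxel_volume_mm3 * 1e-3
    return float(conc.data.sum() * voxel_ml)


def activity_map_from_concentration(
    conc: VoxelVolume,
    susp: Suspension,
    spec: RadionuclideSpec,
    at_hours: float = 0.0,
    tissue_density: float = 1.0,
) -> ActivityMap:
    """Ho concentration map -> activity map (MBq per voxel).

    Per voxel: Ho mass = C · voxel volume; particle mass = Ho mass /
    ho_weight_fraction; activity = particle mass · specific activity ·
    decay factor at ``at_hours`` after the reference time.
    """
    if at_hours < 0:
        raise ConfigurationError("elapsed time must be >= 0")
    voxel_ml = conc.voxel_volume_mm3 * 1e-3
    particle_mass = conc.data * voxel_ml / susp.ho_weight_fraction
    activity = particle_mass * susp.specific_activity * decay_factor(spec, at_hours)
    return ActivityMap(volume=conc.copy(data=activity), tissue_density=tissue_density)
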