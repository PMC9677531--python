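"""Synthetic tumor phantoms, CT volumes and two-arm survival cohorts.

Emulates the study conditions of an induced intracerebral glioblastoma
model in minipigs so the whole planning/dosimetry/survival chain is
testable without any imaging download:

* plurilobed tumor masks (unions of overlapping ellipsoids, 1-30 mm
  equivalent diameter) on a regular voxel lattice;
* exponential tumor growth V(t) = V0 · 2^((t - t_ref)/Td) between
  implantation and treatment;
* contrast-enhanced CT forward model: per-tissue Hounsfield baselines
  (tumor hyperdense relative to brain), a linear Ho-concentration term,
  additive Gaussian noise and 12-bit saturation;
* a two-arm cohort whose untreated animals reach a volume-based
  surrogate endpoint 6-9 days after treatment while successfully
  treated animals are censored at the 66-day observation horizon.

All stochastic operations take an explicit integer seed; outputs are
bit-reproducible for a fixed (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError
from .volume import VoxelVolume

#: equivalent-diameter bounds (mm) the injection system was designed for
MIN_EQUIV_DIAMETER_MM = 1.0
MAX_EQUIV_DIAMETER_MM = 30.0


@dataclass(frozen=True)
class Lobe:
    """One ellipsoidal tumor lobe: center (mm), semi-axes (mm), Euler rotation (deg)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ConfigurationError("lobe semi-axes must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a plurilobed tumor phantom inside a brain-sized grid."""

    lobes: tuple[Lobe, ...]
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_radius: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lobes) == 0:
            raise ConfigurationError("phantom needs at least one lobe")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigurationError("voxel_spacing must be > 0")
        if any(n <= 0 for n in self.grid_shape):
            raise ConfigurationError("grid_shape must be positive")


@dataclass(frozen=True)
class GrowthModel:
    """Exponential tumor growth: V(day) = v0 · 2^((day - reference_day)/doubling_time)."""

    v0: float = 1050.0  # mm^3 at the reference day
    doubling_time: float = 3.0  # days
    reference_day: int = 14

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ConfigurationError("v0 must be > 0")
        if self.doubling_time <= 0:
            raise ConfigurationError("doubling_time must be > 0")


@dataclass(frozen=True)
class CTModel:
    """Forward CT signal model (Hounsfield units)."""

    background_hu: float = -1000.0
    brain_hu: float = 35.0
    tumor_hu: float = 60.0  # contrast-enhanced, hyperdense vs brain
    ho_slope: float = 8.0  # HU per (mg Ho)/ml
    noise_sd: float = 5.0  # HU
    saturation_hu: float = 3071.0  # 12-bit CT ceiling
    floor_hu: float = -1024.0
    kvp_metadata: float = 140.0  # acquisition setting, metadata only

    def __post_init__(self) -> None:
        if self.ho_slope <= 0:
            raise ConfigurationError("ho_slope must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Two-arm cohort: treated animals vs untreated (sham/control) animals."""

    n_treated: int = 5
    n_untreated: int = 3
    growth: GrowthModel = field(default_factory=GrowthModel)
    euthanasia_volume: float = 5000.0  # mm^3 surrogate endpoint
    horizon: int = 66  # days post-treatment
    treatment_day: int = 14
    sigma_log_v0: float = 0.15  # log-normal dispersion of per-animal v0
    sigma_log_td: float = 0.05  # log-normal dispersion of per-animal doubling time
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ConfigurationError("horizon must be > 0")
        if self.euthanasia_volume <= 0:
            raise ConfigurationError("euthanasia_volume must be > 0")
        if self.sigma_log_v0 < 0 or self.sigma_log_td < 0:
            raise ConfigurationError("dispersions must be >= 0")
        if self.n_treated < 0 or self.n_untreated < 0:
            raise ConfigurationError("arm sizes must be >= 0")


def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    """A three-lobed ~15 mm phantom centered in a 64³ 1 mm grid."""
    c = 31.5
    return PhantomSpec(
        lobes=(
            Lobe(center=(c, c, c), semi_axes=(7.0, 6.0, 6.0), rotation_deg=(0, 0, 20)),
            Lobe(center=(c + 4.5, c + 3.0, c), semi_axes=(5.0, 4.5, 4.0), rotation_deg=(30, 0, 0)),
            Lobe(center=(c - 4.0, c + 3.5, c - 2.0), semi_axes=(4.5, 4.0, 4.5), rotation_deg=(0, 25, 0)),
        ),
        seed=seed,
    )


def make_tumor_mask(spec: PhantomSpec) -> VoxelVolume:
    """Voxelize the union of the phantom's ellipsoidal lobes.

    Raises a configuration error if the union is empty, disconnected, or
    outside the 1-30 mm equivalent-diameter envelope the injection
    system was designed for.
    """
    grid = VoxelVolume(
        data=np.zeros(spec.grid_shape, dtype=bool),
        spacing=spec.voxel_spacing,
    )
    centers = grid.voxel_centers()  # (nx, ny, nz, 3)
    mask = np.zeros(spec.grid_shape, dtype=bool)
    for lobe in spec.lobes:
        rot = Rotation.from_euler("xyz", lobe.rotation_deg, degrees=True).as_matrix()
        rel = centers - np.asarray(lobe.center)
        local = rel @ rot  # rotate into the lobe frame
        r2 = ((local / np.asarray(lobe.semi_axes)) ** 2).sum(axis=-1)
        mask |= r2 <= 1.0
    if not mask.any():
        raise ConfigurationError("phantom mask is empty on this grid")
    _, n_comp = ndimage.label(mask)
    if n_comp != 1:
        raise ConfigurationError(f"phantom lobes form {n_comp} disconnected components; lobes must overlap")
    volume = float(mask.sum()) * grid.voxel_volume_mm3
    d_eq = (6.0 * volume / math.pi) ** (1.0 / 3.0)
    if not MIN_EQUIV_DIAMETER_MM <= d_eq <= MAX_EQUIV_DIAMETER_MM:
        raise ConfigurationError(f"tumor equivalent diameter {d_eq:.1f} mm outside [1, 30] mm")
    return grid.copy(data=mask)


def sphere_phantom(diameter_mm: float, spacing_mm: float = 1.0, margin_mm: float = 10.0) -> VoxelVolume:
    """Single-lobe spherical tumor mask centered on a voxel center."""
    r = diameter_mm / 2.0
    n = int(round(2 * (r + margin_mm) / spacing_mm)) | 1  # odd so a voxel center sits at the middle
    c = (n - 1) / 2.0 * spacing_mm
    spec = PhantomSpec(
        lobes=(Lobe(center=(c, c, c), semi_axes=(r, r, r)),),
        grid_shape=(n, n, n),
        voxel_spacing=(spacing_mm,) * 3,
    )
    return make_tumor_mask(spec)


def grow_volume(model: GrowthModel, day: float) -> float:
    """Tumor volume (mm³) at an absolute day index under exponential growth."""
    if day < model.reference_day:
        raise ConfigurationError(f"day {day} precedes the reference day {model.reference_day}")
    return model.v0 * 2.0 ** ((day - model.reference_day) / model.doubling_time)


def fit_doubling_time(v0: float, day0: float, v1: float, day1: float) -> float:
    """Doubling time (days) implied by two volume measurements."""
    if v0 <= 0 or v1 <= 0 or v1 == v0:
        raise ConfigurationError("need two positive, distinct volumes")
    if day1 <= day0:
        raise ConfigurationError("day1 must be after day0")
    return (day1 - day0) / math.log2(v1 / v0)


def render_ct(
    mask: VoxelVolume,
    ho_concentration: VoxelVolume | None,
    ct: CTModel,
    seed: int,
    brain_mask: VoxelVolume | None = None,
) -> VoxelVolume:
    """Forward-model a CT volume from tissue masks and a Ho concentration map.

    HU = tissue baseline + ho_slope · C(mg/ml) + N(0, noise_sd), clipped
    to the scanner's dynamic range.  Without a brain mask the whole
    non-tumor grid is treated as brain parenchyma.
    """
    if ho_concentration is not None:
        mask.require_same_geometry(ho_concentration)
    if brain_mask is not None:
        mask.require_same_geometry(brain_mask)
    hu = np.full(mask.shape, ct.brain_hu if brain_mask is None else ct.background_hu)
    if brain_mask is not None:
        hu[brain_mask.data.astype(bool)] = ct.brain_hu
    hu[mask.data.astype(bool)] = ct.tumor_hu
    if ho_concentration is not None:
        hu = hu + ct.ho_slope * ho_concentration.data
    if ct.noise_sd > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, ct.noise_sd, size=mask.shape)
    np.clip(hu, ct.floor_hu, ct.saturation_hu, out=hu)
    return mask.copy(data=hu)


def _days_to_endpoint(v0: float, doubling_time: float, threshold: float, horizon: int) -> tuple[int, bool]:
    """First integer day post-treatment the grown volume exceeds the threshold.

    Returns (time, event); censored at the horizon if never exceeded.
    """
    if v0 > threshold:
        return 1, True
    t = math.ceil(doubling_time * math.log2(threshold / v0))
    if v0 * 2.0 ** (t / doubling_time) <= threshold:  # exact-boundary guard
        t += 1
    t = max(t, 1)
    if t > horizon:
        return horizon, False
    return t, True


def simulate_cohort(spec: CohortSpec, coverage_treated: float, coverage_constraint: float = 0.95) -> pd.DataFrame:
    """Generate per-animal survival records for a two-arm cohort.

    Untreated animals grow exponentially from treatment day and reach the
    volume-based surrogate endpoint (event=1).  Treated animals whose
    planned coverage meets the planner's constraint are censored at the
    horizon (event=0); under-covered treated animals behave like
    untreated ones.  Per-animal v0 and doubling time carry log-normal
    jitter with the spec's dispersions and seed.

    Returns a DataFrame with columns animal_id, arm, time_days, event.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    growth = spec.growth
    treated_controlled = coverage_treated >= coverage_constraint
    for arm, n in (("treated", spec.n_treated), ("untreated", spec.n_untreated)):
        for i in range(n):
            v0 = growth.v0 * math.exp(rng.normal(0.0, spec.sigma_log_v0)) if spec.sigma_log_v0 > 0 else growth.v0
            td = (
                growth.doubling_time * math.exp(rng.normal(0.0, spec.sigma_log_td))
                if spec.sigma_log_td > 0
                else growth.doubling_time
            )
            if arm == "treated" and treated_controlled:
                time, event = spec.horizon, False
            else:
                time, event = _days_to_endpoint(v0, td, spec.euthanasia_volume, spec.horizon)
            rows.append(
                {
                    "animal_id": f"{arm}_{i + 1}",
                    "arm": arm,
                    "time_days": time,
                    "event": int(event),
                }
            )
    return pd.DataFrame(rows, columns=["animal_id", "arm", "time_days", "event"])
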