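"""Voxel absorbed-dose computation from unit-of-treatment deposits.

The absorbed dose delivered by the injected activity is computed with a
radial dose-point-kernel convolution in homogeneous soft tissue:

    D(v) = sum_s  Ã(s) · E_mean · k(|v − s|) / m(v)

where Ã(s) is the cumulated activity of source voxel s (physical decay
only, no biological clearance), E_mean the locally deposited energy per
decay, k the fraction of emitted energy absorbed in the target voxel as
resolved from the kernel's radial shells, and m(v) the voxel tissue mass.
The production path evaluates the sum as a dense FFT convolution; a
brute-force double summation over voxel pairs is provided as an oracle
for small grids.

Kernel-to-voxel resolution: a shell's energy fraction is split equally
among the lattice offsets whose center distance falls inside the shell;
the self voxel receives the whole 0-to-half-voxel shell mass; shells
containing no voxel center carry their mass forward to the next occupied
shell so that total energy is conserved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, GeometryError
from .kernel import DoseKernel
from .nuclide import MEV_TO_JOULE, RadionuclideSpec, Suspension, cumulated_activity, uot_activity
from .volume import VoxelVolume

_BRUTE_FORCE_MAX_VOXELS = 32**3


@dataclass
class ActivityMap:
    """Voxel lattice of activity (MBq per voxel) at injection time."""

    volume: VoxelVolume
    tissue_density: float = 1.0  # g/cm^3, water-equivalent brain

    def __post_init__(self) -> None:
        if self.tissue_density <= 0:
            raise ConfigurationError("tissue_density must be > 0")
        if np.any(self.volume.data < 0):
            raise ConfigurationError("activity map must be nonnegative")

    @property
    def total_mbq(self) -> float:
        return float(self.volume.data.sum())


@dataclass
class DoseMap:
    """Voxel lattice of absorbed dose (Gy), same geometry as its ActivityMap."""

    volume: VoxelVolume


def _shell_weights(kernel: DoseKernel, spacing: tuple[float, float, float]) -> tuple[np.ndarray, float]:
    """Per-voxel weight for each kernel shell on the offset lattice of ``spacing``.

    Returns ``(w_shell, w_self)``: ``w_shell[i]`` is the energy fraction a
    single voxel whose center distance falls in shell i receives, and
    ``w_self`` the fraction kept by the source voxel itself.
    """
    sp = np.asarray(spacing, dtype=float)
    half = float(sp.min()) / 2.0
    edges = kernel.shell_edges
    frac = kernel.shell_energy_fraction
    n_shell = len(frac)

    # occupancy of each shell by nonzero lattice offsets
    n = np.ceil(kernel.max_range / sp).astype(int)
    axes = [np.arange(-ni, ni + 1) * si for ni, si in zip(n, sp)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    d = np.sqrt(gx**2 + gy**2 + gz**2).ravel()
    d = d[(d > 0) & (d <= kernel.max_range)]
    sidx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_shell - 1)
    counts = np.bincount(sidx, minlength=n_shell)

    self_shells = edges[1:] <= half
    w_self = float(frac[self_shells].sum())

    w_shell = np.zeros(n_shell)
    carry = 0.0
    last_occupied = -1
    for i in range(n_shell):
        if self_shells[i]:
            continue
        if counts[i] > 0:
            w_shell[i] = (frac[i] + carry) / counts[i]
            carry = 0.0
            last_occupied = i
        else:
            carry += frac[i]
    if carry > 0.0:
        if last_occupied >= 0:
            w_shell[last_occupied] += carry / counts[last_occupied]
        else:
            w_self += carry
    return w_shell, w_self


def kernel_to_voxel_weights(kernel: DoseKernel, spacing: tuple[float, float, float]) -> np.ndarray:
    """Dense odd-shaped offset array of per-voxel energy fractions; sums to 1."""
    sp = np.asarray(spacing, dtype=float)
    w_shell, w_self = _shell_weights(kernel, spacing)
    n = np.ceil(kernel.max_range / sp).astype(int)
    axes = [np.arange(-ni, ni + 1) * si for ni, si in zip(n, sp)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    d = np.sqrt(gx**2 + gy**2 + gz**2)
    W = np.zeros(d.shape)
    inside = (d > 0) & (d <= kernel.max_range)
    sidx = np.clip(
        np.searchsorted(kernel.shell_edges, d[inside], side="right") - 1,
        0,
        len(w_shell) - 1,
    )
    W[inside] = w_shell[sidx]
    W[tuple(n)] = w_self
    return W


def _injection_fields(inj):
    """(site, volume_ul, activity_or_None) from an Injection or a tuple."""
    if hasattr(inj, "site"):
        return np.asarray(inj.site, dtype=float), float(inj.volume_ul), getattr(inj, "activity_mbq", None)
    site = np.asarray(inj[0], dtype=float)
    activity = float(inj[2]) if len(inj) > 2 and inj[2] is not None else None
    return site, float(inj[1]), activity


def deposit_sphere_indices(grid: VoxelVolume, site: np.ndarray, volume_ul: float) -> np.ndarray:
    """Voxel indices whose centers lie in the liquid sphere of one UoT.

    The deposit is a sphere of the injected liquid volume (1 µl = 1 mm³)
    centered at the site; if no voxel center falls inside, the containing
    voxel is used.  Returns an (n, 3) integer index array.
    """
    radius = (3.0 * volume_ul / (4.0 * np.pi)) ** (1.0 / 3.0)
    sp = np.asarray(grid.spacing)
    center_idx = grid.world_to_index(site)
    reach = np.ceil(radius / sp).astype(int) + 1
    lo = np.maximum(center_idx - reach, 0)
    hi = np.minimum(center_idx + reach + 1, np.asarray(grid.shape))
    ranges = [np.arange(lo[a], hi[a]) for a in range(3)]
    ix, iy, iz = np.meshgrid(*ranges, indexing="ij")
    idx = np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=-1)
    centers = grid.index_to_world(idx)
    inside = np.linalg.norm(centers - site, axis=1) <= radius
    if not inside.any():
        return center_idx[None, :]
    return idx[inside]


def deposit_activity(
    plan,
    grid: VoxelVolume,
    susp: Suspension,
    spec: RadionuclideSpec,
    at_hours: float = 0.0,
    tissue_density: float = 1.0,
) -> ActivityMap:
    """Spread each UoT's activity uniformly over its liquid-volume sphere.

    ``plan`` is an InjectionPlan or an iterable of injections (objects
    with site/volume_ul/activity_mbq, or (site, volume_ul[, activity])
    tuples).  Total activity is conserved exactly.
    """
    injections = getattr(plan, "injections", plan)
    data = np.zeros(grid.shape)
    for k, inj in enumerate(injections):
        site, volume_ul, activity = _injection_fields(inj)
        if not grid.contains_point(site):
            raise ConfigurationError(f"injection {k} at {tuple(site)} lies outside the grid")
        if activity is None:
            _, activity = uot_activity(volume_ul, susp, spec, at_hours)
        idx = deposit_sphere_indices(grid, site, volume_ul)
        data[idx[:, 0], idx[:, 1], idx[:, 2]] += activity / len(idx)
    return ActivityMap(
        volume=VoxelVolume(data=data, spacing=grid.spacing, origin=grid.origin),
        tissue_density=tissue_density,
    )


def _dose_scale(act: ActivityMap, spec: RadionuclideSpec) -> tuple[np.ndarray, float]:
    """(decay counts per voxel, Gy per MeV-fraction) for the dose sum."""
    decays = act.volume.data * 1e6 * cumulated_activity(1.0, spec)  # Bq·s == decays
    mass_kg = act.volume.voxel_volume_mm3 * act.tissue_density * 1e-6
    per_voxel_gy = spec.mean_energy_per_decay * MEV_TO_JOULE / mass_kg
    return decays, per_voxel_gy


def compute_dose(act: ActivityMap, kernel: DoseKernel, spec: RadionuclideSpec) -> DoseMap:
    """Absorbed-dose map by dense FFT convolution of the voxelized kernel."""
    extent = min(n * s for n, s in zip(act.volume.shape, act.volume.spacing))
    if kernel.max_range > extent / 2.0:
        warnings.warn(
            "kernel range exceeds half the smallest grid extent; "
            "energy leaving the grid is lost",
            stacklevel=2,
        )
    W = kernel_to_voxel_weights(kernel, act.volume.spacing)
    decays, per_voxel_gy = _dose_scale(act, spec)
    dose = fftconvolve(decays, W, mode="same") * per_voxel_gy
    np.maximum(dose, 0.0, out=dose)  # clip FFT round-off undershoot
    return DoseMap(volume=act.volume.copy(data=dose))


def brute_force_dose(act: ActivityMap, kernel: DoseKernel, spec: RadionuclideSpec) -> DoseMap:
    """Oracle: direct double summation over (target, source) voxel pairs.

    Guarded to grids of at most 32³ voxels; shares the kernel-to-voxel
    shell resolution convention with :func:`compute_dose` but evaluates
    the dose sum pairwise from voxel-center distances.
    """
    n_vox = int(np.prod(act.volume.shape))
    if n_vox > _BRUTE_FORCE_MAX_VOXELS:
        raise ConfigurationError(f"brute-force oracle limited to 32^3 voxels, got {n_vox}")
    w_shell, w_self = _shell_weights(kernel, act.volume.spacing)
    decays, per_voxel_gy = _dose_scale(act, spec)

    src_idx = np.argwhere(decays > 0)
    dose = np.zeros(act.volume.shape)
    if len(src_idx) == 0:
        return DoseMap(volume=act.volume.copy(data=dose))
    src_pos = act.volume.index_to_world(src_idx)
    src_decays = decays[src_idx[:, 0], src_idx[:, 1], src_idx[:, 2]]

    tgt_idx = np.argwhere(np.ones(act.volume.shape, dtype=bool))
    tgt_pos = act.volume.index_to_world(tgt_idx)
    d = cdist(tgt_pos, src_pos)
    w = np.zeros_like(d)
    inside = (d > 0) & (d <= kernel.max_range)
    sidx = np.clip(
        np.searchsorted(kernel.shell_edges, d[inside], side="right") - 1, 0, len(w_shell) - 1
    )
    w[inside] = w_shell[sidx]
    w[d == 0] = w_self
    dose_flat = (w * src_decays[None, :]).sum(axis=1) * per_voxel_gy
    dose[tgt_idx[:, 0], tgt_idx[:, 1], tgt_idx[:, 2]] = dose_flat
    return DoseMap(volume=act.volume.copy(data=dose))
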