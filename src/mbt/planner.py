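"""Treatment planning: fewest unit-of-treatment injections for coverage.

The planning objective is to deliver at least ``dose_fraction`` (95%) of
the target absorbed dose (100 Gy) to at least ``volume_fraction`` (95%)
of the gross tumor volume using as few 5-8 µl injections as possible.

The planner is a deterministic greedy maximum-marginal-coverage search:
candidate sites form a regular lattice inside the GTV (inset by a safety
margin from its surface), and at each step the (site, volume) pair that
newly covers the most GTV voxels is added, preferring larger injection
volumes, sites nearer the GTV centroid and lower candidate index on
ties.  Exact minimality of the injection count is not claimed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from .dose import ActivityMap, compute_dose, deposit_activity, deposit_sphere_indices, kernel_to_voxel_weights
from .errors import ConfigurationError
from .kernel import DoseKernel, build_default_kernel
from .metrics import coverage_at, d_at_volume
from .nuclide import MEV_TO_JOULE, RadionuclideSpec, Suspension, cumulated_activity, uot_activity
from .volume import VoxelVolume


@dataclass(frozen=True)
class PlanConfig:
    """Planning constraints and search discretization."""

    target_dose: float = 100.0  # Gy
    dose_fraction: float = 0.95
    volume_fraction: float = 0.95
    allowed_volumes: tuple[float, ...] = (5.0, 6.0, 7.0, 8.0)  # µl
    max_injections: int = 50
    candidate_pitch: float = 2.0  # mm
    min_site_spacing: float = 2.0  # mm
    site_margin: float = 1.0  # mm inset from the GTV surface
    injection_rate_ul_per_min: float = 50.0  # carried as metadata

    def __post_init__(self) -> None:
        if not (0 < self.dose_fraction <= 1 and 0 < self.volume_fraction <= 1):
            raise ConfigurationError("dose/volume fractions must be in (0, 1]")
        if any(not 5.0 <= v <= 8.0 for v in self.allowed_volumes) or not self.allowed_volumes:
            raise ConfigurationError("allowed volumes must lie in [5, 8] µl")
        if self.max_injections < 1:
            raise ConfigurationError("max_injections must be >= 1")
        if self.candidate_pitch <= 0 or self.min_site_spacing < 0 or self.site_margin < 0:
            raise ConfigurationError("pitch must be > 0; spacing and margin >= 0")

    @property
    def coverage_threshold_gy(self) -> float:
        return self.dose_fraction * self.target_dose


@dataclass(frozen=True)
class Injection:
    site: tuple[float, float, float]  # mm, world coordinates
    volume_ul: float
    activity_mbq: float


@dataclass
class InjectionPlan:
    """Ordered injections plus achieved coverage bookkeeping."""

    injections: list[Injection]
    achieved_coverage: float
    feasible: bool
    iteration_log: list[float]  # coverage after each greedy step
    config: PlanConfig
    tour: list[int] = field(default_factory=list)  # needle-track ordering (metadata)

    def validate(self) -> None:
        cfg = self.config
        for inj in self.injections:
            if not any(abs(inj.volume_ul - v) < 1e-9 for v in cfg.allowed_volumes):
                raise ConfigurationError(f"injection volume {inj.volume_ul} not allowed")
        sites = np.array([inj.site for inj in self.injections], dtype=float)
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                if np.linalg.norm(sites[i] - sites[j]) < cfg.min_site_spacing - 1e-9:
                    raise ConfigurationError(f"sites {i} and {j} violate min spacing")
        if not 0.0 <= self.achieved_coverage <= 1.0:
            raise ConfigurationError("coverage must lie in [0, 1]")


def _config_hash(cfg: PlanConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()[:16]


def _centroid(gtv: VoxelVolume) -> np.ndarray:
    idx = np.argwhere(gtv.data.astype(bool))
    return gtv.index_to_world(idx.mean(axis=0))


def candidate_sites(gtv: VoxelVolume, config: PlanConfig) -> np.ndarray:
    """Regular lattice of pitch ``candidate_pitch`` strictly inside the GTV margin.

    A lattice point (anchored at the GTV centroid) is kept when its
    containing voxel lies deeper than ``site_margin`` from the mask
    surface (Euclidean distance transform in mm).  If the inset empties
    the lattice, the GTV centroid is returned as the sole candidate.
    """
    mask = gtv.data.astype(bool)
    if not mask.any():
        raise ConfigurationError("empty GTV")
    edt = ndimage.distance_transform_edt(mask, sampling=gtv.spacing)
    centroid = _centroid(gtv)
    extent = np.asarray(gtv.shape) * np.asarray(gtv.spacing)
    n_steps = np.ceil(extent / config.candidate_pitch).astype(int)
    sites = []
    for kx in range(-n_steps[0], n_steps[0] + 1):
        for ky in range(-n_steps[1], n_steps[1] + 1):
            for kz in range(-n_steps[2], n_steps[2] + 1):
                p = centroid + config.candidate_pitch * np.array([kx, ky, kz], dtype=float)
                if not gtv.contains_point(p):
                    continue
                i, j, k = gtv.world_to_index(p)
                if edt[i, j, k] > config.site_margin:
                    sites.append(p)
    if not sites:
        return centroid[None, :]
    return np.array(sites)


def _crop_to_bbox(gtv: VoxelVolume, pad_mm: float) -> VoxelVolume:
    """Sub-grid covering the GTV bbox padded by ``pad_mm`` (world-aligned)."""
    idx = np.argwhere(gtv.data.astype(bool))
    pad = np.ceil(pad_mm / np.asarray(gtv.spacing)).astype(int)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, np.asarray(gtv.shape))
    sub = gtv.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    origin = gtv.index_to_world(lo)
    return VoxelVolume(data=sub, spacing=gtv.spacing, origin=tuple(origin))


def _uot_dose_field(
    grid: VoxelVolume, site: np.ndarray, volume_ul: float, activity_mbq: float, w_dose: np.ndarray
) -> np.ndarray:
    """Dose field (Gy, float32) of one UoT on ``grid`` via kernel-patch insertion."""
    idx = deposit_sphere_indices(grid, site, volume_ul)
    per_voxel = activity_mbq / len(idx)
    field32 = np.zeros(grid.shape, dtype=np.float32)
    half = (np.asarray(w_dose.shape) - 1) // 2
    shape = np.asarray(grid.shape)
    for v in idx:
        lo = v - half
        hi = v + half + 1
        glo = np.maximum(lo, 0)
        ghi = np.minimum(hi, shape)
        wlo = glo - lo
        whi = wlo + (ghi - glo)
        field32[glo[0] : ghi[0], glo[1] : ghi[1], glo[2] : ghi[2]] += (
            per_voxel * w_dose[wlo[0] : whi[0], wlo[1] : whi[1], wlo[2] : whi[2]]
        ).astype(np.float32)
    return field32


def greedy_plan(
    gtv: VoxelVolume,
    config: PlanConfig | None = None,
    susp: Suspension | None = None,
    spec: RadionuclideSpec | None = None,
    kernel: DoseKernel | None = None,
    tissue_density: float = 1.0,
) -> InjectionPlan:
    """Greedy fewest-injections plan meeting the coverage constraint.

    Iteratively adds the (site, volume) pair that newly brings the most
    GTV voxels to at least ``dose_fraction × target_dose``; stops when
    the covered fraction reaches ``volume_fraction`` (feasible) or the
    injection cap is hit (infeasible, coverage reported honestly).  The
    final achieved coverage is recomputed through the dose engine on the
    full grid, so re-simulating the emitted plan reproduces it exactly.
    """
    config = config or PlanConfig()
    susp = susp or Suspension()
    spec = spec or RadionuclideSpec()
    kernel = kernel or build_default_kernel()

    mask = gtv.data.astype(bool)
    if not mask.any():
        raise ConfigurationError("empty GTV")
    volume = mask.sum() * gtv.voxel_volume_mm3
    d_eq = (6.0 * volume / np.pi) ** (1.0 / 3.0)
    if d_eq > 30.0:
        warnings.warn(f"GTV equivalent diameter {d_eq:.1f} mm exceeds the 30 mm design envelope", stacklevel=2)

    work = _crop_to_bbox(gtv, kernel.max_range + max(gtv.spacing))
    wmask = work.data.astype(bool)
    n_gtv = int(wmask.sum())
    sites = candidate_sites(gtv, config)
    centroid = _centroid(gtv)
    site_dist = np.linalg.norm(sites - centroid, axis=1)

    # per-MBq voxel kernel in dose units
    w = kernel_to_voxel_weights(kernel, work.spacing)
    mass_kg = work.voxel_volume_mm3 * tissue_density * 1e-6
    w_dose = w * (1e6 * cumulated_activity(1.0, spec) * spec.mean_energy_per_decay * MEV_TO_JOULE / mass_kg)

    vols = tuple(sorted(config.allowed_volumes, reverse=True))
    activities = {v: uot_activity(v, susp, spec)[1] for v in vols}
    fields = {
        v: np.stack([_uot_dose_field(work, s, v, activities[v], w_dose) for s in sites])
        for v in vols
    }

    thr = config.coverage_threshold_gy
    dose = np.zeros(work.shape, dtype=np.float64)
    chosen: list[Injection] = []
    chosen_sites: list[np.ndarray] = []
    iteration_log: list[float] = []

    for _ in range(config.max_injections):
        covered = (dose >= thr) & wmask
        if covered.sum() / n_gtv >= config.volume_fraction:
            break
        eligible = np.ones(len(sites), dtype=bool)
        for s in chosen_sites:
            eligible &= np.linalg.norm(sites - s, axis=1) >= config.min_site_spacing - 1e-9
        if not eligible.any():
            break
        uncovered = wmask & ~covered
        dose_unc = dose[uncovered]
        deficit_unc = thr - dose_unc

        def _pick(scores: np.ndarray) -> tuple[float, int]:
            """Best eligible site: max score, ties to centroid, then index."""
            s = np.where(eligible, scores, -np.inf)
            cand = np.flatnonzero(s == s.max())
            k = cand[np.lexsort((cand, site_dist[cand]))[0]]
            return float(s[k]), int(k)

        best = None  # (gain, volume, site_index)
        for v in vols:  # largest volume first; strict > keeps the larger on ties
            fu = fields[v][:, uncovered]  # (n_sites, n_uncovered)
            gains = ((fu + dose_unc[None, :]) >= thr).sum(axis=1)
            gain, k = _pick(gains)
            if best is None or gain > best[0]:
                best = (gain, v, k)
        if best[0] == 0:
            # no new voxel reaches threshold in one step: pick the pair that
            # reduces the remaining dose deficit most (keeps greedy progressing)
            best = None
            for v in vols:
                fu = fields[v][:, uncovered]
                red = np.minimum(fu, deficit_unc[None, :]).sum(axis=1)
                score, k = _pick(red)
                if best is None or score > best[0]:
                    best = (score, v, k)
            if best[0] <= 0.0:
                break
        _, v, si = best
        dose += fields[v][si].astype(np.float64)
        site = sites[si]
        chosen.append(Injection(site=tuple(site), volume_ul=float(v), activity_mbq=float(activities[v])))
        chosen_sites.append(site)
        iteration_log.append(float(((dose >= thr) & wmask).sum() / n_gtv))

    # authoritative coverage: re-simulate the emitted plan on the input grid
    if chosen:
        act = deposit_activity(chosen, gtv, susp, spec, tissue_density=tissue_density)
        final_dose = compute_dose(act, kernel, spec)
        achieved = float((final_dose.volume.data[mask] >= thr).mean())
    else:
        achieved = 0.0
    plan = InjectionPlan(
        injections=chosen,
        achieved_coverage=achieved,
        feasible=achieved >= config.volume_fraction,
        iteration_log=iteration_log,
        config=config,
        tour=needle_tour([np.asarray(i.site) for i in chosen]),
    )
    plan.validate()
    return plan


def needle_tour(sites: list[np.ndarray]) -> list[int]:
    """Nearest-neighbor ordering of sites (single-needle track metadata)."""
    if not sites:
        return []
    remaining = list(range(len(sites)))
    tour = [remaining.pop(0)]
    while remaining:
        last = np.asarray(sites[tour[-1]])
        nxt = min(remaining, key=lambda i: float(np.linalg.norm(np.asarray(sites[i]) - last)))
        remaining.remove(nxt)
        tour.append(nxt)
    return tour


def evaluate_plan(plan: InjectionPlan, gtv: VoxelVolume, dose: VoxelVolume) -> dict:
    """Coverage report for an emitted plan against its simulated dose map."""
    cfg = plan.config
    thr = cfg.coverage_threshold_gy
    return {
        "n_injections": len(plan.injections),
        "total_volume_ul": sum(i.volume_ul for i in plan.injections),
        "total_activity_mbq": sum(i.activity_mbq for i in plan.injections),
        "v_constraint_pct": coverage_at(dose, gtv, thr),
        "v60_pct": coverage_at(dose, gtv, 60.0),
        "v100_pct": coverage_at(dose, gtv, 100.0),
        "d95_gy": d_at_volume(dose, gtv, 0.95),
        "feasible": plan.feasible,
    }


def plan_to_dict(plan: InjectionPlan) -> dict:
    return {
        "injections": [
            {
                "x_mm": inj.site[0],
                "y_mm": inj.site[1],
                "z_mm": inj.site[2],
                "volume_ul": inj.volume_ul,
                "activity_mbq": inj.activity_mbq,
            }
            for inj in plan.injections
        ],
        "coverage": plan.achieved_coverage,
        "feasible": plan.feasible,
        "iteration_log": plan.iteration_log,
        "tour": plan.tour,
        "config_hash": _config_hash(plan.config),
    }


def plan_from_dict(d: dict, config: PlanConfig | None = None) -> InjectionPlan:
    config = config or PlanConfig()
    injections = [
        Injection(
            site=(i["x_mm"], i["y_mm"], i["z_mm"]),
            volume_ul=i["volume_ul"],
            activity_mbq=i["activity_mbq"],
        )
        for i in d["injections"]
    ]
    return InjectionPlan(
        injections=injections,
        achieved_coverage=d["coverage"],
        feasible=d["feasible"],
        iteration_log=list(d.get("iteration_log", [])),
        config=config,
        tour=list(d.get("tour", [])),
    )
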