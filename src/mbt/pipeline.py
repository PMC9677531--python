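"""End-to-end orchestration: phantom → plan → dose → CT → quantify → survival.

``run_demo`` executes the whole chain on synthetic inputs and writes all
artifacts (volumes, plan JSON, cohort CSV, DVH CSV) plus a deterministic
JSON report.  Every stage seeds its randomness from the run seed with a
fixed offset, so a (config, seed) pair reproduces the report
byte-for-byte; the report carries a config hash and no timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.metadata
import importlib.resources
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import metrics, planner, quantify, survival
from .dose import compute_dose, deposit_activity
from .errors import ConfigurationError
from .kernel import build_default_kernel
from .nuclide import RadionuclideSpec, Suspension
from .synthetic import (
    CohortSpec,
    CTModel,
    GrowthModel,
    Lobe,
    PhantomSpec,
    default_phantom_spec,
    make_tumor_mask,
    render_ct,
    simulate_cohort,
)
from .volume import VoxelVolume, read_volume, write_volume  # noqa: F401  (re-exported I/O surface)


@dataclass(frozen=True)
class KernelConfig:
    max_range: float = 8.5
    shell_width: float = 0.05
    scale_mm: float = 0.9
    power: float = 2.0


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full demonstration run."""

    phantom: PhantomSpec = field(default_factory=default_phantom_spec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    suspension: Suspension = field(default_factory=Suspension)
    nuclide: RadionuclideSpec = field(default_factory=RadionuclideSpec)
    plan: planner.PlanConfig = field(default_factory=planner.PlanConfig)
    ct: CTModel = field(default_factory=CTModel)
    kernel: KernelConfig = field(default_factory=KernelConfig)

    def to_dict(self) -> dict:
        return {
            "synthetic": {"phantom": asdict(self.phantom), "cohort": asdict(self.cohort)},
            "suspension": asdict(self.suspension),
            "nuclide": asdict(self.nuclide),
            "plan": asdict(self.plan),
            "ct": asdict(self.ct),
            "kernel": asdict(self.kernel),
        }


def config_from_dict(d: dict) -> RunConfig:
    """Build (and thereby validate) a RunConfig from a nested JSON dict."""
    kwargs: dict = {}
    synth = d.get("synthetic", {})
    if "phantom" in synth:
        ph = dict(synth["phantom"])
        ph["lobes"] = tuple(
            Lobe(
                center=tuple(lb["center"]),
                semi_axes=tuple(lb["semi_axes"]),
                rotation_deg=tuple(lb.get("rotation_deg", (0, 0, 0))),
            )
            for lb in ph.get("lobes", ())
        )
        for key in ("grid_shape", "voxel_spacing"):
            if key in ph:
                ph[key] = tuple(ph[key])
        kwargs["phantom"] = PhantomSpec(**ph)
    if "cohort" in synth:
        co = dict(synth["cohort"])
        if "growth" in co:
            co["growth"] = GrowthModel(**co["growth"])
        kwargs["cohort"] = CohortSpec(**co)
    if "suspension" in d:
        kwargs["suspension"] = Suspension(**d["suspension"])
    if "nuclide" in d:
        kwargs["nuclide"] = RadionuclideSpec(**d["nuclide"])
    if "plan" in d:
        pl = dict(d["plan"])
        if "allowed_volumes" in pl:
            pl["allowed_volumes"] = tuple(pl["allowed_volumes"])
        kwargs["plan"] = planner.PlanConfig(**pl)
    if "ct" in d:
        kwargs["ct"] = CTModel(**d["ct"])
    if "kernel" in d:
        kwargs["kernel"] = KernelConfig(**d["kernel"])
    return RunConfig(**kwargs)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(json.load(fh))


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _version() -> str:
    try:
        return importlib.metadata.version("mbt")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def report_schema() -> dict:
    with importlib.resources.files("mbt").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


_JSON_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "integer": int,
}


def validate_report(report: dict, schema: dict | None = None, path: str = "report") -> None:
    """Minimal structural validation against the packaged report schema.

    Checks required keys and primitive types recursively; raises
    ConfigurationError on the first violation.
    """
    schema = schema if schema is not None else report_schema()
    typ = schema.get("type")
    if typ == "number":
        if not isinstance(report, (int, float)) or isinstance(report, bool):
            raise ConfigurationError(f"{path}: expected number, got {type(report).__name__}")
        return
    if typ in _JSON_TYPES and not isinstance(report, _JSON_TYPES[typ]):
        raise ConfigurationError(f"{path}: expected {typ}, got {type(report).__name__}")
    if typ == "object":
        for key in schema.get("required", []):
            if key not in report:
                raise ConfigurationError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{path}.{key}")


def run_demo(config: RunConfig, outdir: str | Path, seed: int = 0) -> dict:
    """Execute the full synthetic treatment chain and write all artifacts.

    Stages: tumor phantom → greedy plan → activity deposit → absorbed
    dose → post-operative CT forward model → calibration + CT
    quantification → DVH/coverage metrics → two-arm cohort → survival
    statistics.  Returns the report dict (also written as report.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_log: list[str] = []
    chash = _config_hash(config)

    def log(stage: str, msg: str) -> None:
        stage_log.append(f"[{chash}] {stage}: {msg}")

    # -- phantom ---------------------------------------------------------
    phantom = dataclasses.replace(config.phantom, seed=seed)
    mask = make_tumor_mask(phantom)
    vol_mm3 = metrics.mask_volume(mask)
    log("phantom", f"tumor volume {vol_mm3:.0f} mm3")
    write_volume(mask, outdir / "gtv_mask.nii.gz")

    # -- plan ------------------------------------------------------------
    kernel = build_default_kernel(**asdict(config.kernel))
    plan = planner.greedy_plan(mask, config.plan, config.suspension, config.nuclide, kernel)
    log("plan", f"{len(plan.injections)} injections, coverage {plan.achieved_coverage:.3f}")
    with open(outdir / "plan.json", "w") as fh:
        json.dump(planner.plan_to_dict(plan), fh, indent=2, sort_keys=True)

    # -- dose ------------------------------------------------------------
    act = deposit_activity(plan, mask, config.suspension, config.nuclide)
    dose = compute_dose(act, kernel, config.nuclide)
    write_volume(dose.volume, outdir / "dose_gy.nii.gz")
    dvh = metrics.compute_dvh(dose.volume, mask)
    metrics.dvh_to_csv(dvh, outdir / "dvh.csv")
    coverage_report = planner.evaluate_plan(plan, mask, dose.volume)
    coverage_report["healthy_v10_pct"] = metrics.healthy_tissue_coverage(dose.volume, mask, 10.0)
    log("dose", f"V60 {dvh.v60:.1f}%, V100 {dvh.v100:.1f}%")

    # -- synthetic post-operative CT ------------------------------------
    voxel_ml = mask.voxel_volume_mm3 * 1e-3
    particle_mass_mg = act.volume.data / config.suspension.specific_activity
    conc_true = mask.copy(data=particle_mass_mg * config.suspension.ho_weight_fraction / voxel_ml)
    post_ct = render_ct(mask, conc_true, config.ct, seed=seed + 1)
    write_volume(post_ct, outdir / "post_ct_hu.nii.gz")

    # -- quantification --------------------------------------------------
    cal_conc = np.array([0.0, 50.0, 100.0, 150.0, 200.0])
    curve = quantify.fit_calibration(*quantify.calibration_phantom(cal_conc, config.ct, seed=seed + 2))
    baseline = render_ct(mask, None, dataclasses.replace(config.ct, noise_sd=0.0), seed=0)
    conc_rec = quantify.ho_concentration_map(
        post_ct, curve, baseline, min_excess_hu=5.0 * config.ct.noise_sd
    )
    act_rec = quantify.activity_map_from_concentration(conc_rec, config.suspension, config.nuclide)
    injected = act.total_mbq
    recovered = act_rec.total_mbq
    log("quantify", f"recovered {recovered:.2f} of {injected:.2f} MBq")

    # -- cohort + survival ----------------------------------------------
    cohort_spec = dataclasses.replace(config.cohort, seed=seed + 3)
    cohort = simulate_cohort(cohort_spec, coverage_treated=plan.achieved_coverage,
                             coverage_constraint=config.plan.volume_fraction)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    groups = survival.records_from_frame(cohort)
    treated = groups.get("treated", [])
    untreated = groups.get("untreated", [])
    lr = survival.logrank_test(treated, untreated) if treated and untreated else None
    surv_report = {
        "mean_treated_days": survival.truncated_mean([r.time for r in treated]) if treated else math.nan,
        "mean_untreated_days": survival.truncated_mean([r.time for r in untreated]) if untreated else math.nan,
        "logrank_statistic": lr.statistic if lr else math.nan,
        "logrank_p": lr.p if lr else math.nan,
        "logrank_p_reported": lr.p_reported if lr else "",
    }
    log("survival", f"log-rank p {surv_report['logrank_p']:.4g}")

    report = {
        "config_hash": chash,
        "software_version": _version(),
        "seed": seed,
        "phantom": {"tumor_volume_mm3": vol_mm3},
        "plan": planner.plan_to_dict(plan),
        "dosimetry": coverage_report,
        "quantification": {
            "injected_mbq": injected,
            "recovered_mbq": recovered,
            "recovery_ratio": recovered / injected if injected else math.nan,
            "calibration_slope": curve.slope,
            "calibration_intercept": curve.intercept,
        },
        "survival": surv_report,
        "stage_log": stage_log,
    }
    validate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
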