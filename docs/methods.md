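# Methods

This note records the models implemented in `mbt`, their assumptions, the
defaults that matter, and the places where a genuine design choice had to
be made. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Radionuclide and suspension model

¹⁶⁶Ho decays with a physical half-life of 26.8 h. The toolkit assumes
**no biological clearance** of the injected microparticles: CT follow-up
of this therapy shows the hyperdense deposits fixed at their injection
sites for months, so the cumulated activity of a deposit is the full
physical-decay integral Ã = A₀·T½/ln 2 (≈ 1.39 × 10⁵ s per unit activity).

The suspension defaults describe the injectable: dry matter 550 g/L
(0.55 mg/µl), Ho weight fraction 0.28, density 1.38 g/ml and particle
mean size 470 nm (both metadata), specific activity 2.5 MBq/mg at the
injection reference time (midpoint of the 2–3 MBq/mg production window).
A 5 µl UoT therefore carries 2.75 mg of particles; at 2.5 MBq/mg that is
6.875 MBq.

`mean_energy_per_decay` defaults to **0.665 MeV**, the mean beta energy
of ¹⁶⁶Ho from standard nuclear-data compilations (ICRP-107-style tables).
It is a configuration input, not a measured quantity of this package.
Gamma emissions are excluded from the default local energy budget: at the
millimetre scale of intracerebral deposits the beta component dominates
local absorbed dose, and the gamma fraction largely escapes the head. A
user modelling gamma build-up can lower the energy constant or supply a
tabulated kernel.

## Dose engine

Monte Carlo radiation transport is replaced by an **isotropic radial
dose-point-kernel** in homogeneous water-equivalent tissue
(density 1.0 g/cm³, configurable). Rationale: determinism at desk scale,
an exact energy-conservation test, and the therapy's own premise of a
localized, non-clearing deposit in soft tissue.

The default parametric kernel has radial energy density
dE/dr ∝ r² e^(−r/0.9 mm), truncated and renormalized on [0, 8.5 mm]
(≈ the maximum ¹⁶⁶Ho beta range in soft tissue). Its cumulative profile
is a regularized incomplete gamma function, so shell-width refinement
never shifts the cumulative fraction at a fixed radius. The constants
(scale 0.9 mm, power 2) shape a soft-tissue-like profile with mean
deposition radius ≈ 2.7 mm; they are packaged defaults, not fitted to any
measurement, and a tabulated kernel CSV (radius, fraction) can replace
them.

Kernel-to-voxel resolution: a shell's energy fraction is split equally
among lattice offsets whose center distance falls in the shell; the
source voxel keeps the whole 0-to-half-voxel mass; shells containing no
voxel center carry forward to the next occupied shell. This makes the
voxelized kernel sum to exactly 1, so total absorbed energy equals total
emitted energy for any source at least 8.5 mm from the grid boundary (the
suite checks 1 %; the discretization is exact to round-off).

The production path is a dense FFT convolution; a brute-force double
summation over voxel pairs (guarded to ≤ 32³ voxels) serves as oracle and
agrees to better than 10⁻⁶ relative.

Deposit geometry: each UoT's activity is spread uniformly over the voxels
whose centers fall inside a sphere of the injected liquid volume
(1 µl = 1 mm³; an 8 µl UoT has radius ≈ 1.24 mm), minimum one voxel.

## Treatment planner

The planning problem — fewest 5–8 µl injections such that ≥ 95 % of the
GTV receives ≥ 95 % of the 100 Gy target — is solved with a **greedy
maximum-marginal-coverage heuristic**: candidate sites are a regular 2 mm
lattice anchored at the GTV centroid and inset 1 mm from the mask surface
(centroid fallback when the inset empties the lattice); each step adds
the (site, volume) pair newly covering the most GTV voxels, preferring
the largest allowed volume, then the site nearest the centroid, then the
lowest candidate index — all ties broken deterministically. When no
single injection can push a new voxel over threshold, the step maximizes
the reduction of the remaining dose deficit instead, so the search keeps
progressing. The cap of 50 injections is far above the 9–20 range typical
for 1–2 cm tumors, so the coverage constraint, not the cap, governs
default runs; a capped, infeasible plan reports its true coverage.

Exact minimality of the injection count is **not** claimed. The planner
works on a crop of the grid (GTV bounding box padded by the kernel range)
with float32 candidate fields for speed; the final achieved coverage is
recomputed with the full FFT engine on the original grid, so re-simulating
an emitted plan reproduces its reported coverage exactly. A
nearest-neighbor tour over the chosen sites is recorded as needle-track
metadata (single needle repositioned without withdrawal); it does not
constrain placement.

## CT forward model and quantification

The synthetic CT is piecewise-constant tissue baselines (brain 35 HU,
contrast-enhanced tumor 60 HU), a linear Ho term, additive Gaussian noise
(default sd 5 HU) and clipping to the 12-bit scanner range
[−1024, 3071] HU. The Ho slope defaults to 8 HU per (mg Ho)/ml, chosen so
single-UoT deposits render markedly hyperdense (~1.2–1.5 kHU excess)
while two overlapping deposits stay below saturation, keeping the
inversion linear.

Quantification fits an ordinary least-squares calibration line to
known-concentration phantom inserts (the module ships the insert
generator) and inverts C = max(0, (HU − baseline)/slope) per voxel, then
chains C → particle mass (÷ Ho weight fraction) → activity (× specific
activity × decay). In synthetic runs the baseline map is the noise-free
pre-operative render on the identical grid; registration of real scans is
out of scope. A noise floor (default 5 × noise sd of HU excess) excludes
background voxels whose positive half-noise would otherwise bias the
total; deposit voxels sit orders of magnitude above it. Partial-volume
effects beyond voxel-level linearity are not modelled.

## Synthetic cohort generator

The generator emulates the study conditions this pipeline assumes:

- **Phantoms**: unions of overlapping ellipsoids ("plurilobed" masks),
  1–30 mm equivalent diameter, voxelized at the mask's spacing; unions
  must form one connected component.
- **Growth**: exponential, V(t) = V₀·2^((t−t_ref)/Td). Defaults
  V₀ = 1050 mm³ at day 14 (geometric mean of the untreated-arm volumes at
  the treatment day) and Td = 3.0 d, inside the 2.2–5.8 d range implied
  by the printed day-14 → day-19 volume ratios.
- **Endpoint surrogate**: untreated animals reach the event when the
  grown volume first exceeds 5000 mm³ (pre-euthanasia volumes span
  roughly 1700–8000 mm³); clinical-sign endpoints are not modellable.
  Treated animals whose planned coverage meets the 95 % constraint are
  censored at the 66-day horizon; under-covered treated animals grow like
  untreated ones.
- **Dispersions**: per-animal V₀ and Td carry log-normal jitter with
  σ(ln V₀) = 0.15 and σ(ln Td) = 0.05. These are deliberately smaller
  than the spread of the printed day-14 volumes (σ ≈ 0.47): the observed
  endpoint window is tight (all untreated events at 6–9 days
  post-treatment) even though measured volumes vary several-fold, i.e.
  much of the volume spread is measurement/segmentation variability that
  a fixed-threshold surrogate must not inherit. With these defaults the
  per-cohort untreated mean stays inside [6, 9] days across 200 seeds.

What passing the cohort tests does **not** show: the generator has no
edema, hemorrhage, immune response, histology or scanner artifacts, so
agreement with it demonstrates internal consistency of the pipeline, not
fidelity to real minipig CT data.

## Survival statistics

Kaplan–Meier, truncated means and the Mantel–Cox log-rank test are
implemented from first principles (the `lifelines` implementation is used
only as an independent oracle in the tests).

- **Mean convention**: truncation toward zero at one decimal, because the
  study tables print mean(9, 8, 9) = 8.667 as 8.6 (rounding would give
  8.7). Medians are computed and labelled separately, since published
  summaries sometimes conflate the two.
- **p-value reporting**: raw p is always retained; the reported string
  truncates to two decimals ("0.09" from a computed 0.096) and prints
  "<0.01" below that threshold.
- **Log-rank**: hypergeometric variance, ties aggregated at their common
  time, no continuity correction; χ² with 1 df, upper tail via
  erfc(√(x/2)). "Different from both other arms" is evaluated as pairwise
  tests (each p < 0.01); pooled comparison is available by concatenating
  record lists.
- **Permutation caveat**: on cohorts of 3–8 animals the exact
  permutation distribution of the statistic has ~20–56 atoms, so its
  p-value is necessarily discrete (e.g. 0.30 where the asymptotic χ² tail
  gives 0.096). The suite therefore checks significance concordance on
  tiny inputs and numeric agreement within Monte-Carlo error at n = 15
  per arm, where the asymptotics hold.

## Numerical conventions

- World coordinates are right-handed mm; a voxel's position is its
  center; indices are 0-based in (x, y, z) array order; I/O via SimpleITK
  preserves spacing and origin to 10⁻⁶ mm.
- D95 is the largest dose d with ≥ 95 % of GTV voxels at ≥ d, read off
  the exact voxel dose multiset (inverted-CDF quantile), as are V₆₀ and
  V₁₀₀ — never off the binned DVH curve.
- Every stochastic operation takes an explicit integer seed; the pipeline
  derives per-stage seeds from the run seed with fixed offsets, and the
  run report contains no timestamps, so reports are byte-reproducible.
- Degenerate inputs fail fast with configuration errors (empty or
  disconnected phantoms, sites outside the grid — named by injection
  index, non-binary masks, empty survival groups, no events).

## Problem sizes

Default demonstration runs use a ~40–64³ grid at 1 mm voxels with a
9–15 mm tumor, ≈ 30–180 candidate sites and ≤ 50 injections; the
acceptance computation uses the 15 mm sphere on a 35³ grid (1791 GTV
voxels). These sizes were chosen so a complete run takes seconds on one
CPU while keeping ≥ 10 voxels across every deposit's 95 Gy isodose.

## Known limitations

Homogeneous-medium dosimetry only (no heterogeneity, photon build-up, or
dose-rate/radiobiology modelling); no microdosimetry at the 470 nm
particle scale; no beam-hardening or metal-artifact modelling around the
dense deposits; single-GTV planning without skull/ventricle avoidance;
the greedy planner is a heuristic, not an exact set-cover solver; the
cohort generator's endpoint is a volume surrogate for clinical signs.
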