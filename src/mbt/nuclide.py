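"""Radionuclide decay kinetics and the injectable microparticle suspension.

Models the physics of a Ho-166 siloxane microparticle suspension used for
intratumoral microbrachytherapy: exponential physical decay (half-life
26.8 h), the cumulated (time-integrated) activity under the assumption of
no biological clearance, and the conversion of an injected liquid volume
to particle mass and activity.

The mean energy emitted per decay is a configuration constant (default
0.665 MeV, the mean beta energy of Ho-166 from standard nuclear-data
compilations).  Gamma emissions are excluded from the default local energy
budget: at the millimetre scale of the deposits the locally absorbed beta
component dominates, and the gamma fraction largely escapes the head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError

#: J per MeV
MEV_TO_JOULE = 1.602e-13


@dataclass(frozen=True)
class RadionuclideSpec:
    """Decay and emission constants of the therapeutic radionuclide.

    half_life is in hours; mean_energy_per_decay in MeV is the locally
    deposited energy per disintegration.
    """

    name: str = "Ho-166"
    half_life: float = 26.8
    mean_energy_per_decay: float = 0.665

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ConfigurationError("half_life must be > 0")
        if self.mean_energy_per_decay <= 0:
            raise ConfigurationError("mean_energy_per_decay must be > 0")

    @property
    def decay_constant_per_hour(self) -> float:
        return math.log(2.0) / self.half_life


@dataclass(frozen=True)
class Suspension:
    """Physicochemical constants of the Ho microparticle suspension.

    dry_matter in g/L (equivalently mg/µl × 1000); ho_weight_fraction is
    the Ho mass fraction of the dry particles; specific_activity in MBq
    per mg of microparticles at the reference time (typically injection).
    density (g/ml) and particle_mean_size (nm) are carried as metadata.
    """

    dry_matter: float = 550.0
    ho_weight_fraction: float = 0.28
    density: float = 1.38
    particle_mean_size: float = 470.0
    specific_activity: float = 2.5
    activity_calibrator_accuracy: float = 0.05  # metadata, fractional

    def __post_init__(self) -> None:
        if not 0 < self.ho_weight_fraction < 1:
            raise ConfigurationError("ho_weight_fraction must be in (0, 1)")
        if self.dry_matter <= 0:
            raise ConfigurationError("dry_matter must be > 0")
        if self.specific_activity < 0:
            raise ConfigurationError("specific_activity must be >= 0")

    @property
    def dry_matter_mg_per_ul(self) -> float:
        # g/L == mg/ml; /1000 -> mg/µl
        return self.dry_matter / 1000.0


def decay_factor(spec: RadionuclideSpec, elapsed_hours: float) -> float:
    """Fraction of activity remaining after ``elapsed_hours`` of physical decay.

    Returns 2**(-elapsed / half_life); strictly decreasing in elapsed time.
    """
    if elapsed_hours < 0:
        raise ConfigurationError("elapsed time must be >= 0")
    return 2.0 ** (-elapsed_hours / spec.half_life)


def cumulated_activity(a0_mbq: float, spec: RadionuclideSpec) -> float:
    """Time-integrated activity (MBq·s) to infinity under physical decay only.

    With no biological clearance the cumulated activity is
    ``A0 · T½ / ln 2`` with T½ in seconds; linear in ``a0_mbq``.
    """
    if a0_mbq < 0:
        raise ConfigurationError("activity must be >= 0")
    return a0_mbq * spec.half_life * 3600.0 / math.log(2.0)


def uot_activity(
    volume_ul: float, susp: Suspension, spec: RadionuclideSpec, at_hours: float = 0.0
) -> tuple[float, float]:
    """Particle mass (mg) and activity (MBq) of one unit-of-treatment injection.

    ``volume_ul`` is the injected liquid volume; ``at_hours`` is the time
    elapsed since the suspension's specific-activity reference time.
    """
    if volume_ul < 0:
        raise ConfigurationError("injected volume must be >= 0")
    mass_mg = volume_ul * susp.dry_matter_mg_per_ul
    activity_mbq = mass_mg * susp.specific_activity * decay_factor(spec, at_hours)
    return mass_mg, activity_mbq
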