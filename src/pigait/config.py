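"""Cohort-generator configuration.

The defaults encode the study conditions the synthetic cohort emulates:
two birth-weight categories (AGA ~1.4 kg, SGA ~0.7 kg; a ~50% mass gap),
isometric body scaling, a saturating postural-maturation profile that
raises midstance hip height by ~28% between the first measurement and
day 2, and small group offsets in knee/tarsal mean joint angles.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import log
from typing import Optional

import yaml

from .errors import ConfigurationError, DomainError

__all__ = ["MaturationProfile", "CohortConfig", "load_config"]

#: longitudinal recording ages (hours postpartum) of the follow-up design
DEFAULT_AGES = (0.0, 1.0, 2.0, 6.0, 8.0, 24.0, 26.0, 28.0, 96.0)


@dataclass(frozen=True)
class MaturationProfile:
    """Saturating postural-maturation law.

    The relative hip-height extension at age ``t`` (hours pp) is

        m(t) = plateau * (1 - exp(-(t - onset)/tau))   for t > onset, else 0

    optionally frozen at ``m(stall_age)`` for ages beyond ``stall_age``
    (the behavioural-stall scenario).  ``tau`` is stored as
    ``time_constant``; :meth:`calibrated` sets it so that 90% of the
    plateau is reached at a given age (8 h by default).
    """

    plateau_fraction: float = 0.28
    time_constant: float = 7.0 / log(10.0)  # 90% of plateau at 8 h with onset 1 h
    onset: float = 1.0
    stall_age: Optional[float] = None

    def __post_init__(self) -> None:
        if self.plateau_fraction < 0:
            raise ConfigurationError("plateau_fraction must be >= 0")
        if self.time_constant <= 0:
            raise ConfigurationError("time_constant must be > 0")

    @classmethod
    def calibrated(
        cls,
        plateau: float = 0.28,
        onset: float = 1.0,
        t90: float = 8.0,
        stall_age: Optional[float] = None,
    ) -> "MaturationProfile":
        """Profile reaching 90% of ``plateau`` at age ``t90``."""
        if t90 <= onset:
            raise ConfigurationError("t90 must exceed onset")
        tau = (t90 - onset) / log(10.0)
        return cls(plateau_fraction=plateau, time_constant=tau, onset=onset, stall_age=stall_age)

    def value(self, age_hours: float) -> float:
        """Relative extension factor at ``age_hours`` (>= 0)."""
        import numpy as np

        if age_hours < 0:
            raise DomainError(f"age must be >= 0, got {age_hours}")
        t = age_hours if self.stall_age is None else min(age_hours, self.stall_age)
        dt = t - self.onset
        if dt <= 0:
            return 0.0
        return float(self.plateau_fraction * (1.0 - np.exp(-dt / self.time_constant)))

    def fraction(self, age_hours: float) -> float:
        """Maturation value as a fraction of the plateau (in [0, 1])."""
        if self.plateau_fraction == 0:
            return 1.0
        return self.value(age_hours) / self.plateau_fraction


# extension of joint mean angles (radians at full maturation) per joint;
# proximal joints carry the maturation extension, while knee and tarsal
# express only the static category offsets — so their group contrast is
# the configured offset, uncontaminated by maturation state
DEFAULT_EXTENSION_GAIN = {
    "shoulder": 0.08,
    "elbow": 0.04,
    "carpal": 0.04,
    "hip": 0.14,
    "knee": 0.0,
    "tarsal": 0.0,
}


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort generator."""

    # design
    n_aga: int = 14
    n_sga: int = 11
    ages: tuple = DEFAULT_AGES
    age_mode: str = "longitudinal"  # or "cross_sectional"
    age_range: tuple = (1.0, 10.0)  # used in cross-sectional mode
    strides_per_recording: int = 3

    # body size (kg); SGA threshold in the field is < 0.8 kg at birth
    aga_mass_mean: float = 1.4
    aga_mass_sd: float = 0.15
    sga_mass_mean: float = 0.7
    sga_mass_sd: float = 0.08

    # posture / hip height
    hip_height_coeff: float = 0.20  # m per kg^(1/3)
    flexion_penalty_sga: float = 0.06
    maturation: MaturationProfile = field(default_factory=MaturationProfile)
    sga_stall_age: Optional[float] = None  # behavioural-stall scenario (SGA only)

    # dimensionless gait targets (mature values)
    froude_base: float = 0.35
    rel_stride_length: float = 1.45
    rel_step_fore: float = 0.71
    rel_step_hind: float = 0.74
    duty_fore: float = 0.68
    duty_hind: float = 0.66
    phase_diagonal: float = 0.50
    phase_ipsilateral: float = 0.25
    phase_girdle: float = 0.75
    speed_immaturity: float = 0.12  # fractional Froude deficit at birth
    duty_immaturity: float = 0.05
    froude_age_slope: float = 0.004  # linear per-hour trend, capped at 12 h

    # noise scales (all >= 0)
    rel_noise: float = 0.04       # multiplicative, dimensionless gait variables
    h_noise: float = 0.015        # multiplicative, hip height
    phase_noise: float = 0.01     # additive, limb phases

    # joint kinematics
    n_cycle_samples: int = 100
    posture_noise_rad: float = 0.035     # per-stride mean-angle jitter
    individual_posture_sd: float = 0.02  # static per-piglet mean-angle offset
    amplitude_jitter: float = 0.05       # per-stride multiplicative
    amplitude_age_gain: float = 0.10     # fractional amplitude growth with maturation
    sga_knee_offset_rad: float = -0.192  # ~ -11 degrees
    sga_tarsal_offset_rad: float = -0.105  # ~ -6 degrees
    extension_gain: dict = field(default_factory=lambda: dict(DEFAULT_EXTENSION_GAIN))

    # ground reaction forces
    n_stance_nodes: int = 51
    grf_second_harmonic: float = 0.25  # double-hump depth
    share_fore: float = 0.30           # body-weight share per fore limb
    fore_aft_amp: float = 0.45         # fore-aft amplitude relative to limb share
    grf_noise: float = 0.02            # additive BW noise
    sga_grf_offset: float = 0.0        # injected vertical offset (BW)
    sga_grf_window: tuple = (0.6, 0.8)

    # muscle morphometrics
    muscle_noise_log: float = 0.05
    sga_relative_muscle_gain: float = 0.0

    # allometric body-part composition (part mass = a * BM^b)
    front_part_coeff: float = 0.41
    front_part_exp: float = 1.02
    hind_part_coeff: float = 0.38
    hind_part_exp: float = 1.16
    head_part_coeff: float = 0.20
    head_part_exp: float = 1.00
    part_noise_log: float = 0.05

    gravity: float = 9.81

    def __post_init__(self) -> None:
        if self.n_aga <= 0 or self.n_sga < 0:
            raise ConfigurationError("piglet counts must be positive")
        if self.strides_per_recording <= 0:
            raise ConfigurationError("strides_per_recording must be positive")
        for name in ("rel_noise", "h_noise", "phase_noise", "posture_noise_rad",
                     "individual_posture_sd",
                     "amplitude_jitter", "grf_noise", "muscle_noise_log", "part_noise_log"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"noise scale {name} must be >= 0")
        if not 0 < self.duty_fore <= 1 or not 0 < self.duty_hind <= 1:
            raise ConfigurationError("duty factors must lie in (0, 1]")
        if not 0 < self.share_fore < 0.5:
            raise ConfigurationError("share_fore must lie in (0, 0.5)")
        if self.age_mode not in ("longitudinal", "cross_sectional"):
            raise ConfigurationError(f"unknown age_mode {self.age_mode!r}")

    @property
    def share_hind(self) -> float:
        return 0.5 - self.share_fore

    def with_zero_noise(self) -> "CohortConfig":
        """Copy of the config with every stochastic scale set to zero."""
        cfg = self.copy()
        cfg.rel_noise = 0.0
        cfg.h_noise = 0.0
        cfg.phase_noise = 0.0
        cfg.posture_noise_rad = 0.0
        cfg.individual_posture_sd = 0.0
        cfg.amplitude_jitter = 0.0
        cfg.grf_noise = 0.0
        cfg.muscle_noise_log = 0.0
        cfg.part_noise_log = 0.0
        cfg.aga_mass_sd = 0.0
        cfg.sga_mass_sd = 0.0
        return cfg

    def copy(self) -> "CohortConfig":
        d = asdict(self)
        d["maturation"] = MaturationProfile(**d["maturation"])
        return CohortConfig(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> CohortConfig:
    """Load a :class:`CohortConfig` from a YAML/JSON mapping file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "maturation" in raw and isinstance(raw["maturation"], dict):
        raw["maturation"] = MaturationProfile(**raw["maturation"])
    for key in ("ages", "age_range", "sga_grf_window"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return CohortConfig(**raw)
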