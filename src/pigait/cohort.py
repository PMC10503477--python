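"""Synthetic piglet cohort generator.

Generates birth-weight-categorized piglet cohorts together with stride
tables, band-limited joint-angle cycles, stance-phase ground-reaction-force
curves, extensor-muscle morphometrics, body-part masses, and energetics
covariates.  The generator embodies the effect structure the downstream
analysis assumes:

* a ~50% body-mass gap between SGA and AGA categories, with isometric
  segment scaling (lengths proportional to body mass^(1/3));
* a saturating postural-maturation profile raising midstance hip height by
  ~28% between the first measurement and day 2, most of it by 8 h pp;
* dynamic similarity: with all noise scales zero, piglets of different
  size walking at the same maturation state have identical dimensionless
  gait variables;
* double-hump vertical GRFs in body weights whose per-limb stance
  averages, weighted by duty factor, sum to 1 BW over the four limbs;
* configurable SGA offsets of knee and tarsal mean joint angles.

All draws flow from named substreams of one root seed, so the output is
reproducible and insensitive to the addition of later stages.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import substream
from .config import CohortConfig, MaturationProfile
from .errors import ConfigurationError, DomainError
from .kinematics import JOINTS, JointTrace, fourier_reconstruct
from .templates import JointTemplate, default_template_bank

__all__ = [
    "PigletSpec",
    "GRFTrace",
    "ScalingTransform",
    "CohortData",
    "maturation_value",
    "generate_joint_traces",
    "generate_grf_trace",
    "generate_cohort",
    "apply_scaling",
    "hip_height_increase",
]

SEGMENTS = {
    # segment lengths (m) of a reference 1.4 kg neonate; isometric scaling
    "scapula": 0.070,
    "humerus": 0.065,
    "radius_ulna": 0.075,
    "metacarpus": 0.040,
    "femur": 0.070,
    "tibia_fibula": 0.080,
    "metatarsus": 0.050,
}
REFERENCE_MASS = 1.4  # kg

# extensor-muscle bank: (muscle, limb, mass fraction of BM, fibre length at
# the reference mass in m); masses scale with BM, fibre lengths with BM^(1/3)
MUSCLE_BANK = [
    ("triceps_brachii", "fore", 0.0046, 0.025),
    ("extensor_carpi_radialis", "fore", 0.0013, 0.018),
    ("supraspinatus", "fore", 0.0011, 0.020),
    ("quadriceps_femoris", "hind", 0.0054, 0.028),
    ("gastrocnemius", "hind", 0.0020, 0.020),
    ("tibialis_cranialis", "hind", 0.0011, 0.022),
]


@dataclass(frozen=True)
class PigletSpec:
    """One subject: identity, category, birth size, and segment lengths."""

    id: str
    category: str  # "SGA" | "AGA"
    sex: str       # "F" | "M"
    birth_mass: float  # kg
    segment_lengths: dict  # segment name -> m
    limb_length_anatomical: float  # m

    def __post_init__(self) -> None:
        if self.birth_mass <= 0:
            raise DomainError("birth_mass must be > 0")
        if any(v <= 0 for v in self.segment_lengths.values()):
            raise DomainError("segment lengths must be > 0")


@dataclass
class GRFTrace:
    """Stance-normalized single-limb force curve in body weights."""

    stride_id: str
    limb: str       # "fore" | "hind"
    component: str  # "vertical" | "fore_aft"
    sample_times: np.ndarray  # stance fractions, strictly increasing in [0, 1]
    samples: np.ndarray       # force in BW


@dataclass(frozen=True)
class ScalingTransform:
    """Single factors for lengths (alpha), times (beta), and forces (gamma).

    Dynamic similarity under constant gravity requires beta = sqrt(alpha)
    and gamma = alpha^3 (mass scales with volume).
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise DomainError("scaling factors must be > 0")

    @classmethod
    def dynamic_similarity(cls, alpha: float) -> "ScalingTransform":
        return cls(alpha=alpha, beta=math.sqrt(alpha), gamma=alpha**3)

    @classmethod
    def identity(cls) -> "ScalingTransform":
        return cls(1.0, 1.0, 1.0)


@dataclass
class CohortData:
    """All generated tables plus the configuration they came from."""

    piglets: pd.DataFrame
    strides: pd.DataFrame
    joint_traces: pd.DataFrame
    grf_traces: pd.DataFrame
    muscles: pd.DataFrame
    energetics: pd.DataFrame
    config: CohortConfig = field(repr=False, default=None)
    seed: Optional[int] = None

    TABLES = ("piglets", "strides", "joint_traces", "grf_traces", "muscles", "energetics")

    def write_csvs(self, outdir) -> dict:
        """Write all tables as CSV; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in self.TABLES:
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False, float_format="%.12g")
            paths[name] = path
        return paths

    def copy(self) -> "CohortData":
        return CohortData(
            *(getattr(self, name).copy() for name in self.TABLES),
            config=self.config,
            seed=self.seed,
        )


# ----------------------------------------------------------------- maturation

def maturation_value(age_hours: float, profile: MaturationProfile) -> float:
    """Relative hip-height extension at ``age_hours`` under ``profile``.

    Saturating exponential in [0, plateau]; 0 at birth; frozen beyond the
    profile's ``stall_age`` when configured.
    """
    return profile.value(age_hours)


# --------------------------------------------------------------- joint traces

def generate_joint_traces(
    template_bank: dict,
    posture_offsets: dict,
    amplitude_scale: float,
    noise_sd: float,
    n_samples: int,
    rng: np.random.Generator,
    amplitude_jitter: float = 0.0,
) -> dict:
    """Band-limited joint-angle cycles for the six limb joints.

    Noise is applied in the coefficient domain (a per-stride perturbation of
    the mean angle and a multiplicative amplitude jitter), so every output
    trace remains exactly 8-harmonic band-limited.
    """
    if n_samples < 17:
        raise ConfigurationError("n_samples must be >= 17 (2 x 8 harmonics + 1)")
    traces = {}
    for joint in JOINTS:
        template: JointTemplate = template_bank[joint]
        mean = template.mean_angle + posture_offsets.get(joint, 0.0)
        if noise_sd > 0:
            mean += rng.normal(0.0, noise_sd)
        scale = amplitude_scale
        if amplitude_jitter > 0:
            scale *= math.exp(rng.normal(0.0, amplitude_jitter))
        coeffs = np.concatenate([[mean + 0j], scale * template.harmonics])
        traces[joint] = fourier_reconstruct(coeffs, n_samples, joint)
    return traces


# ------------------------------------------------------------------ GRF model

def _vertical_shape(s: np.ndarray, q: float) -> np.ndarray:
    return np.sin(np.pi * s) + q * np.sin(3.0 * np.pi * s)


def generate_grf_trace(
    limb: str,
    duty_factor: float,
    mass_share: float,
    rng: np.random.Generator,
    noise_sd: float,
    stride_id: str = "",
    n_nodes: int = 51,
    second_harmonic: float = 0.25,
    fore_aft_amp: float = 0.45,
    vertical_offset: float = 0.0,
    offset_window: tuple = (0.6, 0.8),
):
    """One limb's (vertical, fore-aft) stance curves in body weights.

    The vertical curve is a two-peak shape scaled so that its stance
    average times the duty factor equals ``mass_share`` body weights —
    hence, summed over the four limbs, stance-averaged vertical load
    closes to 1 BW.  The fore-aft curve is a single braking-to-propulsion
    sine with zero net impulse over stance.
    """
    if not 0 < duty_factor <= 1:
        raise DomainError("duty_factor must lie in (0, 1]")
    if not 0 < mass_share < 1:
        raise DomainError("mass_share must lie in (0, 1)")
    s = np.linspace(0.0, 1.0, n_nodes)
    # normalize by the discrete node mean so stance-averaged closure is exact
    # on the sampled grid, not just in the continuum limit
    mean_shape = float(_vertical_shape(s, second_harmonic).mean())
    amp = mass_share / (duty_factor * mean_shape)
    vertical = amp * _vertical_shape(s, second_harmonic)
    if vertical_offset != 0.0:
        lo, hi = offset_window
        vertical = vertical + vertical_offset * ((s >= lo) & (s <= hi))
    fore_aft = -fore_aft_amp * mass_share / 0.3 * np.sin(2.0 * np.pi * s) * 0.1
    if noise_sd > 0:
        vertical = vertical + rng.normal(0.0, noise_sd, size=n_nodes)
        fore_aft = fore_aft + rng.normal(0.0, noise_sd, size=n_nodes)
        vertical = np.clip(vertical, 0.0, None)
    return (
        GRFTrace(stride_id, limb, "vertical", s, vertical),
        GRFTrace(stride_id, limb, "fore_aft", s, fore_aft),
    )


# --------------------------------------------------------------- cohort build

def _make_piglets(config: CohortConfig, rng: np.random.Generator) -> list:
    piglets = []
    specs = [("AGA", config.n_aga, config.aga_mass_mean, config.aga_mass_sd),
             ("SGA", config.n_sga, config.sga_mass_mean, config.sga_mass_sd)]
    idx = 0
    for category, n, mu, sd in specs:
        for _ in range(n):
            idx += 1
            mass = mu if sd == 0 else max(float(rng.normal(mu, sd)), 0.25)
            sex = "F" if rng.random() < 0.5 else "M"
            scale = (mass / REFERENCE_MASS) ** (1.0 / 3.0)
            seg = {k: v * scale for k, v in SEGMENTS.items()}
            limb = seg["femur"] + seg["tibia_fibula"] + seg["metatarsus"]
            piglets.append(
                PigletSpec(f"P{idx:03d}", category, sex, mass, seg, limb)
            )
    return piglets


def _recording_ages(config: CohortConfig, rng: np.random.Generator, n_piglets: int):
    if config.age_mode == "longitudinal":
        return [list(config.ages) for _ in range(n_piglets)]
    lo, hi = config.age_range
    return [[float(rng.uniform(lo, hi))] for _ in range(n_piglets)]


def generate_cohort(config: CohortConfig, seed: int) -> CohortData:
    """Generate a full synthetic cohort; deterministic for fixed seed."""
    if not isinstance(config, CohortConfig):
        raise ConfigurationError("config must be a CohortConfig")
    rng_piglets = substream(seed, "piglets")
    rng_strides = substream(seed, "strides")
    rng_joints = substream(seed, "joints")
    rng_grf = substream(seed, "grf")
    rng_muscles = substream(seed, "muscles")
    rng_parts = substream(seed, "parts")
    rng_energy = substream(seed, "energetics")

    piglets = _make_piglets(config, rng_piglets)
    rng_individual = substream(seed, "posture-individual")
    individual_offsets = {
        spec.id: {
            j: (rng_individual.normal(0.0, config.individual_posture_sd)
                if config.individual_posture_sd > 0 else 0.0)
            for j in JOINTS
        }
        for spec in piglets
    }
    ages_per_piglet = _recording_ages(config, rng_strides, len(piglets))
    bank = default_template_bank()
    g = config.gravity

    piglet_rows, stride_rows = [], []
    joint_rows, grf_rows = [], []

    for spec, rec_ages in zip(piglets, ages_per_piglet):
        noise = config.part_noise_log
        row = {
            "piglet_id": spec.id,
            "category": spec.category,
            "sex": spec.sex,
            "birth_mass_kg": spec.birth_mass,
            "limb_length_m": spec.limb_length_anatomical,
        }
        for k, v in spec.segment_lengths.items():
            row[f"seg_{k}_m"] = v
        bm = spec.birth_mass
        for part, a, b in (
            ("front", config.front_part_coeff, config.front_part_exp),
            ("hind", config.hind_part_coeff, config.hind_part_exp),
            ("head", config.head_part_coeff, config.head_part_exp),
        ):
            f = math.exp(rng_parts.normal(0.0, noise)) if noise > 0 else 1.0
            row[f"{part}_mass_kg"] = a * bm**b * f
        piglet_rows.append(row)

        stalled = spec.category == "SGA" and config.sga_stall_age is not None
        for age in rec_ages:
            a_eff = min(age, config.sga_stall_age) if stalled else age
            m_val = config.maturation.value(a_eff)
            mu = config.maturation.fraction(a_eff)
            for k_str in range(config.strides_per_recording):
                stride_id = f"{spec.id}_a{age:g}_s{k_str}"
                stride_rows.append(
                    _make_stride(
                        stride_id, spec, age, a_eff, m_val, mu, config, g, rng_strides
                    )
                )
                traces = _stride_joint_traces(
                    spec, mu, config, bank, rng_joints, individual_offsets[spec.id]
                )
                grid = np.arange(config.n_cycle_samples) / config.n_cycle_samples
                for joint in JOINTS:
                    th = traces[joint].angle
                    joint_rows.append((stride_id, joint, grid, th))
                grf_rows.extend(_stride_grf(stride_id, spec, stride_rows[-1], config, rng_grf))

    piglets_df = pd.DataFrame(piglet_rows)
    strides_df = pd.DataFrame(stride_rows)
    joint_df = _long_joint_frame(joint_rows)
    grf_df = _long_grf_frame(grf_rows)
    muscles_df = _make_muscles(piglets, config, rng_muscles)
    energy_df = _make_energetics(piglets, ages_per_piglet, config, rng_energy)

    return CohortData(
        piglets=piglets_df,
        strides=strides_df,
        joint_traces=joint_df,
        grf_traces=grf_df,
        muscles=muscles_df,
        energetics=energy_df,
        config=config,
        seed=seed,
    )


def _make_stride(stride_id, spec, age, a_eff, m_val, mu, config, g, rng):
    def jitter(scale):
        return math.exp(rng.normal(0.0, scale)) if scale > 0 else 1.0

    flex = config.flexion_penalty_sga if spec.category == "SGA" else 0.0
    h = (
        config.hip_height_coeff
        * spec.birth_mass ** (1.0 / 3.0)
        * (1.0 + m_val)
        * (1.0 - flex)
        * jitter(config.h_noise)
    )
    froude = (
        config.froude_base * (1.0 - config.speed_immaturity * (1.0 - mu))
        + config.froude_age_slope * min(a_eff, 12.0)
    ) * jitter(config.rel_noise)
    rel_l = config.rel_stride_length * jitter(config.rel_noise)
    duty_f = min(
        config.duty_fore * (1.0 + config.duty_immaturity * (1.0 - mu)) * jitter(config.rel_noise),
        0.95,
    )
    duty_h = min(
        config.duty_hind * (1.0 + config.duty_immaturity * (1.0 - mu)) * jitter(config.rel_noise),
        0.95,
    )
    speed = froude * math.sqrt(g * h)
    stride_length = rel_l * h
    freq = speed / stride_length  # enforces V = L * F exactly
    stride_time = 1.0 / freq
    stance_time = duty_f * stride_time

    def phase(base):
        p = base + (rng.normal(0.0, config.phase_noise) if config.phase_noise > 0 else 0.0)
        return p % 1.0

    return {
        "stride_id": stride_id,
        "piglet_id": spec.id,
        "category": spec.category,
        "sex": spec.sex,
        "age_h": age,
        "speed_ms": speed,
        "stride_length_m": stride_length,
        "step_length_fore_m": config.rel_step_fore * h * jitter(config.rel_noise),
        "step_length_hind_m": config.rel_step_hind * h * jitter(config.rel_noise),
        "stride_frequency_hz": freq,
        "stride_time_s": stride_time,
        "stance_time_s": stance_time,
        "duty_factor": duty_f,
        "duty_factor_hind": duty_h,
        "phase_diagonal": phase(config.phase_diagonal),
        "phase_ipsilateral": phase(config.phase_ipsilateral),
        "phase_girdle": phase(config.phase_girdle),
        "hip_height_midstance_m": h,
    }


def _stride_joint_traces(spec, mu, config, bank, rng, individual=None):
    offsets = {j: config.extension_gain.get(j, 0.0) * mu for j in JOINTS}
    if individual:
        for j in JOINTS:
            offsets[j] += individual[j]
    if spec.category == "SGA":
        offsets["knee"] += config.sga_knee_offset_rad
        offsets["tarsal"] += config.sga_tarsal_offset_rad
    amp = 1.0 - config.amplitude_age_gain * (1.0 - mu)
    return generate_joint_traces(
        bank,
        offsets,
        amplitude_scale=amp,
        noise_sd=config.posture_noise_rad,
        n_samples=config.n_cycle_samples,
        rng=rng,
        amplitude_jitter=config.amplitude_jitter,
    )


def _stride_grf(stride_id, spec, stride_row, config, rng):
    out = []
    injected = config.sga_grf_offset if spec.category == "SGA" else 0.0
    for limb, duty, share in (
        ("fore", stride_row["duty_factor"], config.share_fore),
        ("hind", stride_row["duty_factor_hind"], config.share_hind),
    ):
        vert, fa = generate_grf_trace(
            limb,
            duty,
            share,
            rng,
            config.grf_noise,
            stride_id=stride_id,
            n_nodes=config.n_stance_nodes,
            second_harmonic=config.grf_second_harmonic,
            fore_aft_amp=config.fore_aft_amp,
            vertical_offset=injected if limb == "hind" else 0.0,
            offset_window=config.sga_grf_window,
        )
        out.extend([vert, fa])
    return out


def _long_joint_frame(rows) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=["stride_id", "joint", "cycle_fraction", "angle_rad"])
    frames = []
    for stride_id, joint, grid, theta in rows:
        frames.append(
            pd.DataFrame(
                {
                    "stride_id": stride_id,
                    "joint": joint,
                    "cycle_fraction": grid,
                    "angle_rad": theta,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _long_grf_frame(traces) -> pd.DataFrame:
    if not traces:
        return pd.DataFrame(
            columns=["stride_id", "limb", "component", "stance_fraction", "force_bw"]
        )
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "stride_id": tr.stride_id,
                    "limb": tr.limb,
                    "component": tr.component,
                    "stance_fraction": tr.sample_times,
                    "force_bw": tr.samples,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _make_muscles(piglets, config, rng) -> pd.DataFrame:
    rows = []
    for spec in piglets:
        gain = 1.0 + (config.sga_relative_muscle_gain if spec.category == "SGA" else 0.0)
        scale = (spec.birth_mass / REFERENCE_MASS) ** (1.0 / 3.0)
        for muscle, limb, frac, fl_ref in MUSCLE_BANK:
            noise_m = (
                math.exp(rng.normal(0.0, config.muscle_noise_log))
                if config.muscle_noise_log > 0 else 1.0
            )
            noise_l = (
                math.exp(rng.normal(0.0, config.muscle_noise_log))
                if config.muscle_noise_log > 0 else 1.0
            )
            rows.append(
                {
                    "piglet_id": spec.id,
                    "limb": limb,
                    "muscle": muscle,
                    "mass_kg": frac * spec.birth_mass * gain * noise_m,
                    "fibre_length_m": fl_ref * scale * noise_l,
                }
            )
    return pd.DataFrame(rows)


def _make_energetics(piglets, ages_per_piglet, config, rng) -> pd.DataFrame:
    rows = []
    for spec, rec_ages in zip(piglets, ages_per_piglet):
        for age in rec_ages:
            if spec.category == "AGA":
                glucose = 55.0 * (1.0 + 1.5 * (1.0 - math.exp(-age / 2.0)))
                glycogen = 5.5 - 3.5 * (1.0 - math.exp(-age / 24.0))
            else:
                glucose = 55.0
                glycogen = 3.5
            f = math.exp(rng.normal(0.0, 0.05)) if config.muscle_noise_log > 0 else 1.0
            f2 = math.exp(rng.normal(0.0, 0.05)) if config.muscle_noise_log > 0 else 1.0
            rows.append(
                {
                    "piglet_id": spec.id,
                    "age_h": age,
                    "glucose_mg_dl": glucose * f,
                    "glycogen_pct": glycogen * f2,
                }
            )
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- scaling

def apply_scaling(data: CohortData, transform: ScalingTransform) -> CohortData:
    """Scale all lengths by alpha, times by beta, forces (masses) by gamma.

    Dimensionless traces (joint angles, BW-normalized GRFs, duty factors,
    phases) are untouched: both a force and the body weight normalizing it
    scale by gamma.  With beta = sqrt(alpha) the dimensionless gait
    variables of every stride are invariant.
    """
    a, b, c = transform.alpha, transform.beta, transform.gamma
    out = data.copy()

    pg = out.piglets
    pg["birth_mass_kg"] *= c
    pg["limb_length_m"] *= a
    for col in pg.columns:
        if col.startswith("seg_"):
            pg[col] *= a
        if col.endswith("_mass_kg") and col != "birth_mass_kg":
            pg[col] *= c

    st = out.strides
    for col in ("stride_length_m", "step_length_fore_m", "step_length_hind_m",
                "hip_height_midstance_m"):
        st[col] *= a
    for col in ("stride_time_s", "stance_time_s"):
        st[col] *= b
    st["speed_ms"] *= a / b
    st["stride_frequency_hz"] /= b

    mu = out.muscles
    if len(mu):
        mu["mass_kg"] *= c
        mu["fibre_length_m"] *= a
    return out


# -------------------------------------------------------------------- summary

def hip_height_increase(
    strides: pd.DataFrame, t0: float = 1.0, t1: float = 28.0
) -> dict:
    """Percent increase of category-mean midstance hip height from t0 to t1."""
    out = {}
    for cat, grp in strides.groupby("category"):
        h0 = grp.loc[np.isclose(grp["age_h"], t0), "hip_height_midstance_m"].mean()
        h1 = grp.loc[np.isclose(grp["age_h"], t1), "hip_height_midstance_m"].mean()
        if not (np.isfinite(h0) and np.isfinite(h1)):
            raise DomainError(f"no strides at ages {t0} / {t1} for category {cat}")
        out[cat] = 100.0 * (h1 / h0 - 1.0)
    return out
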