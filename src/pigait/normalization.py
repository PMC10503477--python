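"""Dynamic-similarity normalization of gait variables.

Absolute spatiotemporal variables are made dimensionless with midstance
hip height h as the length scale and gravity g:

    speed      V  ->  V / sqrt(h g)     (Froude-style dimensionless speed)
    lengths    L  ->  L / h
    frequency  F  ->  F / sqrt(g / h) = F sqrt(h / g)
    forces        ->  body weights, F / (BM g)

Duty factors and relative limb phases are dimensionless as measured.
Two motions are dynamically similar when these quantities coincide.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrityError

__all__ = [
    "dimensionless_speed",
    "dimensionless_length",
    "dimensionless_frequency",
    "duty_factor",
    "relative_phase",
    "normalize_force",
    "normalize_stride_table",
    "DIMENSIONLESS_COLUMNS",
]

logger = logging.getLogger(__name__)

G_DEFAULT = 9.81  # m/s^2

#: columns added by :func:`normalize_stride_table`
DIMENSIONLESS_COLUMNS = (
    "froude_speed",
    "rel_stride_length",
    "rel_step_fore",
    "rel_step_hind",
    "rel_frequency",
)


def _check_h_g(h: float, g: float) -> None:
    if h <= 0:
        raise DomainError(f"hip height must be > 0, got {h}")
    if g <= 0:
        raise DomainError(f"gravity must be > 0, got {g}")


def dimensionless_speed(v: float, h: float, g: float = G_DEFAULT) -> float:
    """V / sqrt(h g)."""
    _check_h_g(h, g)
    return v / math.sqrt(h * g)


def dimensionless_length(length: float, h: float) -> float:
    """L / h (stride or step length relative to hip height)."""
    if h <= 0:
        raise DomainError(f"hip height must be > 0, got {h}")
    return length / h


def dimensionless_frequency(f: float, h: float, g: float = G_DEFAULT) -> float:
    """F / sqrt(g / h) = F sqrt(h / g)."""
    _check_h_g(h, g)
    return f * math.sqrt(h / g)


def duty_factor(stance_time: float, stride_time: float) -> float:
    """Stance time over stride time; must lie in (0, 1]."""
    if stride_time <= 0 or stance_time <= 0:
        raise DomainError("times must be > 0")
    if stance_time > stride_time:
        raise IntegrityError(
            f"stance time {stance_time} exceeds stride time {stride_time}"
        )
    return stance_time / stride_time

def relative_phase(footfall_offset: float, stride_time: float) -> float:
    """Footfall timing offset as a fraction of stride time, wrapped to [0, 1)."""
    if stride_time <= 0:
        raise DomainError("stride_time must be > 0")
    return (footfall_offset / stride_time) % 1.0


def normalize_force(force: float, body_mass: float, g: float = G_DEFAULT) -> float:
    """Force in body weights; sign preserved (fore-aft braking stays negative)."""
    if body_mass <= 0:
        raise DomainError(f"body mass must be > 0, got {body_mass}")
    if g <= 0:
        raise DomainError(f"gravity must be > 0, got {g}")
    return force / (body_mass * g)


def normalize_stride_table(strides: pd.DataFrame, g: float = G_DEFAULT) -> pd.DataFrame:
    """Append dimensionless gait columns to a stride table.

    Rows with missing or non-positive midstance hip height cannot be
    normalized; they are dropped with a logged warning.  Absolute columns
    are preserved alongside the dimensionless ones.
    """
    if g <= 0:
        raise DomainError("gravity must be > 0")
    if len(strides) == 0:
        out = strides.copy()
        for col in DIMENSIONLESS_COLUMNS:
            out[col] = pd.Series(dtype=float)
        return out
    h = strides["hip_height_midstance_m"]
    ok = h.notna() & (h > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning(
            "normalize_stride_table: dropping %d stride(s) with missing or "
            "non-positive hip height", n_bad,
        )
    out = strides.loc[ok].copy()
    hh = out["hip_height_midstance_m"].to_numpy()
    root_hg = np.sqrt(hh * g)
    out["froude_speed"] = out["speed_ms"].to_numpy() / root_hg
    out["rel_stride_length"] = out["stride_length_m"].to_numpy() / hh
    out["rel_step_fore"] = out["step_length_fore_m"].to_numpy() / hh
    out["rel_step_hind"] = out["step_length_hind_m"].to_numpy() / hh
    out["rel_frequency"] = out["stride_frequency_hz"].to_numpy() * np.sqrt(hh / g)
    return out
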