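"""Band-limited joint-angle templates for the synthetic cohort.

Each template is a mean interior joint angle (radians; pi = fully
extended) plus up to 8 complex harmonics of a walking cycle anchored at
limb touchdown.  The shapes are plausible quadruped-walk profiles — a
single dominant harmonic with a swing-phase flexion wave and smaller
higher harmonics — and are configuration, not measurements: no values
are taken from any experimental recording.
"""
from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .kinematics import N_HARMONICS

__all__ = ["JointTemplate", "default_template_bank"]


class JointTemplate:
    """Mean angle plus complex harmonics (c_1 .. c_H) of one joint."""

    def __init__(self, joint: str, mean_angle: float, harmonics: dict):
        coeffs = np.zeros(N_HARMONICS, dtype=complex)
        for order, value in harmonics.items():
            if not 1 <= order <= N_HARMONICS:
                raise ConfigurationError(
                    f"template harmonic order {order} outside 1..{N_HARMONICS}"
                )
            coeffs[order - 1] = value
        self.joint = joint
        self.mean_angle = float(mean_angle)
        self.harmonics = coeffs

    def coeffs(self) -> np.ndarray:
        """Full coefficient vector c_0 .. c_H."""
        return np.concatenate([[self.mean_angle + 0j], self.harmonics])


def _polar(r: float, phi: float) -> complex:
    return r * np.exp(1j * phi)


def default_template_bank() -> dict:
    """Template bank for the six limb joints of a walking neonate."""
    return {
        "shoulder": JointTemplate("shoulder", 1.55, {
            1: _polar(0.10, -0.6), 2: _polar(0.030, 1.1), 3: _polar(0.010, 0.3),
        }),
        "elbow": JointTemplate("elbow", 2.00, {
            1: _polar(0.17, 2.0), 2: _polar(0.060, -1.0), 3: _polar(0.020, 0.8),
            4: _polar(0.006, 0.0),
        }),
        "carpal": JointTemplate("carpal", 2.20, {
            1: _polar(0.24, 1.2), 2: _polar(0.080, 0.1), 3: _polar(0.030, 0.6),
            4: _polar(0.010, -0.4),
        }),
        "hip": JointTemplate("hip", 1.70, {
            1: _polar(0.12, -2.0), 2: _polar(0.020, 0.5), 3: _polar(0.008, 1.5),
        }),
        "knee": JointTemplate("knee", 1.90, {
            1: _polar(0.15, 0.8), 2: _polar(0.050, -0.6), 3: _polar(0.015, 1.0),
        }),
        "tarsal": JointTemplate("tarsal", 1.95, {
            1: _polar(0.20, -1.2), 2: _polar(0.070, 0.9), 3: _polar(0.020, -0.2),
            4: _polar(0.007, 0.5),
        }),
    }
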