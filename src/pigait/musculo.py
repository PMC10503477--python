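"""Muscle force-generating capacity and allometric body-part scaling.

Physiological cross-sectional area (PCSA) of a muscle is mass divided by
tissue density (1060 kg/m^3) and mean fibre length; summed per limb and
multiplied by a maximum isometric muscle stress of 0.3 MPa it estimates
the limb's force-generating capacity, reported in body weights.  Under
isometric growth PCSA scales with BM^(2/3), so BW-normalized capacity
falls with BM^(-1/3): smaller animals are relatively stronger.

Body-part masses follow Huxley's allometric model, part = a * BM^b,
fitted by least squares on the log-log scale; b = 1 indicates isometry
for mass-on-mass relations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError

__all__ = [
    "MUSCLE_DENSITY",
    "MUSCLE_STRESS",
    "pcsa",
    "force_capacity",
    "capacity_in_bw",
    "limb_capacity_table",
    "AllometricFit",
    "allometric_fit",
    "isometry_test",
]

MUSCLE_DENSITY = 1060.0  # kg/m^3
MUSCLE_STRESS = 0.3e6    # Pa


def pcsa(muscle_mass, fibre_length, density: float = MUSCLE_DENSITY):
    """Physiological cross-sectional area, mass / (density * fibre length)."""
    m = np.asarray(muscle_mass, dtype=float)
    l = np.asarray(fibre_length, dtype=float)
    if np.any(m <= 0) or np.any(l <= 0) or density <= 0:
        raise DomainError("mass, fibre length, and density must be > 0")
    return m / (density * l)


def force_capacity(pcsa_values, stress: float = MUSCLE_STRESS) -> float:
    """Summed PCSA times maximum isometric muscle stress (N)."""
    a = np.asarray(pcsa_values, dtype=float)
    if a.size == 0:
        raise DomainError("empty PCSA set")
    if np.any(a <= 0):
        raise DomainError("PCSA values must be > 0")
    return float(stress * a.sum())


def capacity_in_bw(force: float, body_mass: float, g: float = 9.81) -> float:
    """Force capacity in body weights."""
    if body_mass <= 0 or g <= 0:
        raise DomainError("body mass and gravity must be > 0")
    return force / (body_mass * g)


def limb_capacity_table(
    muscles: pd.DataFrame,
    piglets: pd.DataFrame,
    stress: float = MUSCLE_STRESS,
    density: float = MUSCLE_DENSITY,
    g: float = 9.81,
) -> pd.DataFrame:
    """Per piglet and limb: summed PCSA, force capacity, and capacity in BW."""
    mm = muscles.copy()
    mm["pcsa_m2"] = pcsa(mm["mass_kg"], mm["fibre_length_m"], density)
    grouped = (
        mm.groupby(["piglet_id", "limb"], as_index=False)["pcsa_m2"].sum()
        .rename(columns={"pcsa_m2": "total_pcsa_m2"})
    )
    grouped["force_capacity_n"] = stress * grouped["total_pcsa_m2"]
    masses = piglets.set_index("piglet_id")["birth_mass_kg"]
    grouped["capacity_bw"] = grouped.apply(
        lambda r: capacity_in_bw(r["force_capacity_n"], masses[r["piglet_id"]], g), axis=1
    )
    return grouped


# ------------------------------------------------------------------ allometry

@dataclass
class AllometricFit:
    """Fitted power law part = a * BM^b with slope uncertainty."""

    a: float
    b: float
    b_ci: tuple       # (lo, hi), 95% by default
    b_se: float
    r_squared: float
    n: int
    log_space: bool = True


def allometric_fit(
    body_mass, part_mass, ci_level: float = 0.95, log_space: bool = True
) -> AllometricFit:
    """Least-squares fit of Huxley's model part = a * BM^b.

    Default: ordinary least squares on log(part) = log(a) + b log(BM),
    with a normal-theory confidence interval on the slope.  ``log_space=False``
    fits the power law in raw mass units by nonlinear least squares
    (slope CI from the asymptotic covariance).
    """
    bm = np.asarray(body_mass, dtype=float)
    pm = np.asarray(part_mass, dtype=float)
    if bm.shape != pm.shape:
        raise DomainError("body_mass and part_mass lengths differ")
    if bm.size < 3:
        raise DomainError("need at least 3 observations")
    if np.any(bm <= 0) or np.any(pm <= 0):
        raise DomainError("masses must be > 0")

    if log_space:
        x = sm.add_constant(np.log(bm))
        res = sm.OLS(np.log(pm), x).fit()
        lo, hi = res.conf_int(alpha=1 - ci_level)[1]
        return AllometricFit(
            a=float(np.exp(res.params[0])),
            b=float(res.params[1]),
            b_ci=(float(lo), float(hi)),
            b_se=float(res.bse[1]),
            r_squared=float(res.rsquared),
            n=bm.size,
            log_space=True,
        )

    from scipy.optimize import curve_fit

    def model(x, a, b):
        return a * x**b

    # log-space estimates as starting values
    start = allometric_fit(bm, pm, log_space=True)
    popt, pcov = curve_fit(model, bm, pm, p0=[start.a, start.b])
    se = float(np.sqrt(pcov[1, 1]))
    from scipy import stats

    t = stats.t.ppf(0.5 * (1 + ci_level), bm.size - 2)
    resid = pm - model(bm, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((pm - pm.mean()) ** 2))
    return AllometricFit(
        a=float(popt[0]),
        b=float(popt[1]),
        b_ci=(float(popt[1] - t * se), float(popt[1] + t * se)),
        b_se=se,
        r_squared=1.0 - ss_res / ss_tot,
        n=bm.size,
        log_space=False,
    )


def isometry_test(fit: AllometricFit, b_expected: float = 1.0) -> dict:
    """Whether the fitted exponent is consistent with isometry (b = 1)."""
    lo, hi = fit.b_ci
    return {
        "consistent": bool(lo <= b_expected <= hi),
        "deviation": fit.b - b_expected,
    }
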