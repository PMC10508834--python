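"""Proximal quantities of interest: wall shear stress, cyclic stretch, and
wave intensity analysis (WIA).

WIA decomposes sampled pressure/velocity increments into forward and backward
running waves via the water-hammer relations,

    dP+- = (dP +- rho c dU) / 2,      dU+- = +- dP+- / (rho c),
    dI+- = dP+- dU+-  (so dI+ >= 0 >= dI-),

with the local wave speed c from the elastic wall law, and classifies them as
forward/backward compression (pressure-increasing) or decompression waves
(FCW, FDW, BCW, BDW; decompression waves are also called expansion waves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rheology import BloodProperties
from .solver import WallLaw

__all__ = ["WIAResult", "proximal_wss", "cyclic_stretch", "wia"]

WAVE_TYPES = ("FCW", "FDW", "BCW", "BDW")


def proximal_wss(q, A, blood: BloodProperties | None = None):
    """WSS(t) = mu Ubar (gamma+2) / R from the power-law velocity profile.

    Ubar = q/A is the cross-sectional mean velocity and R = sqrt(A/pi); with
    the default blunt profile gamma = 9 the factor is (gamma+2) = 11.
    Returns dyn/cm^2.
    """
    blood = blood or BloodProperties()
    q = np.asarray(q, dtype=float)
    A = np.asarray(A, dtype=float)
    R = np.sqrt(A / np.pi)
    return blood.dynamic_viscosity * (q / A) * (blood.profile_exponent + 2.0) / R


def cyclic_stretch(R) -> float:
    """CS = (max R - min R) / min R over one period."""
    R = np.asarray(R, dtype=float)
    rmin = R.min()
    if rmin <= 0:
        raise ValueError("radius must stay positive over the cycle")
    return float((R.max() - rmin) / rmin)


@dataclass
class WIAResult:
    time: np.ndarray
    dP: np.ndarray
    dU: np.ndarray
    dP_plus: np.ndarray
    dP_minus: np.ndarray
    dU_plus: np.ndarray
    dU_minus: np.ndarray
    dI_plus: np.ndarray
    dI_minus: np.ndarray
    wave_speed: np.ndarray
    series: dict          # classified signed intensity series per wave type
    cumulative: dict      # summed |intensity| per wave type


def _centered_periodic_diff(x: np.ndarray) -> np.ndarray:
    return 0.5 * (np.roll(x, -1) - np.roll(x, 1))


def wia(
    p: np.ndarray,
    u: np.ndarray,
    A: np.ndarray,
    law: WallLaw,
    blood: BloodProperties | None = None,
    time: np.ndarray | None = None,
    fixed_wave_speed: float | None = None,
    dt_normalized: bool = False,
) -> WIAResult:
    """Wave-intensity analysis of one periodic cycle.

    Increments use centered periodic differences.  The wave speed is
    time-varying from the wall law, c(t) = sqrt((2K/3rho) sqrt(A/A0)), unless
    ``fixed_wave_speed`` pins it (e.g. to its diastolic value).  With
    ``dt_normalized`` the increments are divided by the sample spacing.
    """
    blood = blood or BloodProperties()
    p = np.asarray(p, dtype=float)
    u = np.asarray(u, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("area must be positive")
    n = p.size
    if time is None:
        time = np.arange(n, dtype=float)
    dt = float(time[1] - time[0]) if n > 1 else 1.0

    rho = blood.density
    if fixed_wave_speed is None:
        c = np.sqrt(
            (2.0 * law.stiffness / (3.0 * rho))
            * np.sqrt(A / law.reference_area)
        )
    else:
        c = np.full(n, float(fixed_wave_speed))

    dP = _centered_periodic_diff(p)
    dU = _centered_periodic_diff(u)
    if dt_normalized:
        dP = dP / dt
        dU = dU / dt

    rc = rho * c
    dPp = 0.5 * (dP + rc * dU)
    dPm = 0.5 * (dP - rc * dU)
    dUp = dPp / rc
    dUm = -dPm / rc
    dIp = dPp * dUp
    dIm = dPm * dUm

    series = {
        "FCW": np.where(dPp > 0, dIp, 0.0),
        "FDW": np.where(dPp < 0, dIp, 0.0),
        "BCW": np.where(dPm > 0, dIm, 0.0),
        "BDW": np.where(dPm < 0, dIm, 0.0),
    }
    cumulative = {k: float(np.abs(v).sum()) for k, v in series.items()}
    return WIAResult(
        time=time, dP=dP, dU=dU,
        dP_plus=dPp, dP_minus=dPm, dU_plus=dUp, dU_minus=dUm,
        dI_plus=dIp, dI_minus=dIm, wave_speed=c,
        series=series, cumulative=cumulative,
    )
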