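"""Synthetic boundary waveforms and miniature test networks.

The proximal model is driven by a periodic main-pulmonary-artery (MPA) flow
waveform at the arterial inlet and a left-atrial (LA) pressure waveform at the
four venous outlets.  The generators here emulate their physiological
structure: a single-peak systolic ejection pulse with near-zero diastolic
flow, and a two-peak atrial pressure with an a-wave (atrial contraction),
x-descent, v-wave (atrial filling) and y-descent.  Both are band-limited
harmonic syntheses, hence exactly periodic on any sampling grid.

Package defaults (period 0.85 s, stroke volume 70 cm^3, mean LA pressure
5 mmHg) are nominal adult resting values chosen as package defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import MMHG_TO_CGS

__all__ = [
    "InflowSpec",
    "LAPressureSpec",
    "make_inflow",
    "make_la_pressure",
    "default_waveforms",
    "make_toy_network",
    "fourier_resample",
]


def fourier_resample(x: np.ndarray, n: int) -> np.ndarray:
    """Resample a uniformly sampled periodic signal by trigonometric
    interpolation (exact for band-limited signals)."""
    x = np.asarray(x, dtype=float)
    X = np.fft.rfft(x) / x.size
    nf = min(X.size, n // 2 + 1)
    return np.fft.irfft(X[:nf] * n, n=n)


@dataclass(frozen=True)
class InflowSpec:
    period: float = 0.85            # T, s
    stroke_volume: float = 70.0     # cm^3 per beat
    systolic_fraction: float = 0.35  # ejection duration / T
    diastolic_offset: float = 0.0   # cm^3/s
    harmonic_cap: int = 10


@dataclass(frozen=True)
class LAPressureSpec:
    period: float = 0.85
    mean_pressure: float = 5.0 * MMHG_TO_CGS  # g/(cm s^2)
    a_amplitude: float = 2.0 * MMHG_TO_CGS    # atrial-contraction wave height
    v_amplitude: float = 1.5 * MMHG_TO_CGS    # atrial-filling wave height
    a_time: float = 0.88 * 0.85               # a-wave peak time, s
    v_time: float = 0.42 * 0.85               # v-wave peak time, s
    # von-Mises concentrations; kept small enough relative to the harmonic
    # cap that truncation ripple cannot create spurious extrema
    a_sharpness: float = 16.0
    v_sharpness: float = 10.0
    harmonic_cap: int = 24


def _bandlimit(x: np.ndarray, cap: int) -> np.ndarray:
    X = np.fft.rfft(x)
    X[cap + 1:] = 0.0
    return np.fft.irfft(X, n=x.size)


def make_inflow(spec: InflowSpec, n_samples: int = 1024) -> np.ndarray:
    """Sampled q_MPA(t) (cm^3/s) at t_k = k T / n, k = 0 ... n-1.

    Raised-cosine ejection pulse, band-limited to ``harmonic_cap`` harmonics
    and scaled so one period integrates exactly to the stroke volume.
    """
    if not 0.0 < spec.systolic_fraction < 1.0:
        raise ValueError("systolic_fraction must lie in (0, 1)")
    if spec.stroke_volume <= 0:
        raise ValueError("stroke volume must be positive")
    T, n = spec.period, n_samples
    t = np.arange(n) * T / n
    ts = spec.systolic_fraction * T
    bump = np.where(t < ts, 0.5 * (1.0 - np.cos(2.0 * np.pi * t / ts)), 0.0)
    bump = _bandlimit(bump, spec.harmonic_cap)
    target_mean = spec.stroke_volume / T - spec.diastolic_offset
    q = spec.diastolic_offset + bump * (target_mean / bump.mean())
    return q


def make_la_pressure(spec: LAPressureSpec, n_samples: int = 1024) -> np.ndarray:
    """Sampled p_LA(t) (g/cm/s^2): two-peak atrial waveform with exact mean."""
    if spec.a_amplitude < 0 or spec.v_amplitude < 0:
        raise ValueError("wave amplitudes must be nonnegative")
    T, n = spec.period, n_samples
    gap = abs(spec.a_time - spec.v_time) / T
    gap = min(gap, 1.0 - gap)  # circular separation
    if spec.a_amplitude > 0 and spec.v_amplitude > 0 and gap < 0.15:
        raise ValueError("a-wave and v-wave windows overlap")
    t = np.arange(n) * T / n

    def peak(t0: float, kappa: float) -> np.ndarray:
        b = np.exp(kappa * (np.cos(2.0 * np.pi * (t - t0) / T) - 1.0))
        b -= b.mean()
        return b / b.max() if b.max() > 0 else b

    p = (
        spec.mean_pressure
        + spec.a_amplitude * peak(spec.a_time, spec.a_sharpness)
        + spec.v_amplitude * peak(spec.v_time, spec.v_sharpness)
    )
    p = _bandlimit(p, spec.harmonic_cap)
    # band-limiting removes no mean; re-centering guards round-off only
    return p + (spec.mean_pressure - p.mean())


def default_waveforms(n_samples: int = 1024, period: float = 0.85):
    """(q_MPA, p_LA) sample arrays under the package default specs."""
    q = make_inflow(InflowSpec(period=period), n_samples)
    p = make_la_pressure(
        LAPressureSpec(period=period, a_time=0.88 * period, v_time=0.42 * period),
        n_samples,
    )
    return q, p


def make_toy_network(n_generations: int = 1):
    """Miniature artery/vein network with valid bed pairing, for fast tests.

    n_generations = 1: one artery, one vein, one bed.
    n_generations = 2: 3 arteries, 3 veins, 2 beds.
    """
    from .geometry import build_proximal_network
    import pandas as pd

    if n_generations == 1:
        rows = [
            ("A1", "artery", 4.0, 0.40, "", "V1"),
            ("V1", "vein", 4.0, 0.45, "", "A1"),
        ]
    elif n_generations == 2:
        rows = [
            ("A0", "artery", 4.0, 0.55, "", "A1;A2"),
            ("A1", "artery", 3.0, 0.40, "A0", "V1"),
            ("A2", "artery", 3.0, 0.35, "A0", "V2"),
            ("V0", "vein", 4.0, 0.60, "", "V1;V2"),
            ("V1", "vein", 3.0, 0.45, "V0", "A1"),
            ("V2", "vein", 3.0, 0.40, "V0", "A2"),
        ]
    else:
        raise ValueError("n_generations must be 1 or 2")
    table = pd.DataFrame(
        rows, columns=["name", "kind", "length_cm", "radius_cm", "parent", "daughters"]
    )
    return build_proximal_network(table)
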