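"""The eight uncertain model parameters and their prior bounds.

theta = {K_A, K_ST, K_V, alpha, beta, lrr_A, lrr_V, r_min}: proximal arterial,
structured-tree and proximal venous wall stiffness Eh/r0 (g/cm/s^2), the
major/minor daughter radius ratios, the arterial/venous length-to-radius
ratios, and the minimum structured-tree radius (cm).  Priors are independent
uniforms on the tabulated bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = ["ParameterVector", "PARAMETER_BOUNDS", "PARAMETER_NAMES"]

# name -> (lower, upper)
PARAMETER_BOUNDS: dict[str, tuple[float, float]] = {
    "k_a": (5.60e5, 1.04e6),
    "k_st": (1.75e5, 3.25e5),
    "k_v": (5.95e5, 1.11e6),
    "alpha": (0.80, 0.92),
    "beta": (0.60, 0.70),
    "lrr_a": (10.0, 50.0),
    "lrr_v": (10.0, 50.0),
    "r_min": (1.0e-3, 1.0e-2),
}

PARAMETER_NAMES = list(PARAMETER_BOUNDS)


@dataclass(frozen=True)
class ParameterVector:
    k_a: float    # proximal arterial stiffness, g/cm/s^2
    k_st: float   # structured-tree stiffness, g/cm/s^2
    k_v: float    # proximal venous stiffness, g/cm/s^2
    alpha: float  # major-daughter radius ratio
    beta: float   # minor-daughter radius ratio
    lrr_a: float  # arterial length-to-radius ratio
    lrr_v: float  # venous length-to-radius ratio
    r_min: float  # minimum structured-tree radius, cm

    def __post_init__(self):
        if not self.beta < self.alpha:
            raise ValueError("require beta < alpha")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @classmethod
    def from_array(cls, x) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        return cls(**{name: float(v) for name, v in zip(PARAMETER_NAMES, x)})

    @classmethod
    def nominal(cls) -> "ParameterVector":
        """Midpoint of every prior interval."""
        return cls.from_array([0.5 * (a + b) for a, b in PARAMETER_BOUNDS.values()])

    def within_bounds(self) -> bool:
        return all(
            PARAMETER_BOUNDS[n][0] <= getattr(self, n) <= PARAMETER_BOUNDS[n][1]
            for n in PARAMETER_NAMES
        )
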