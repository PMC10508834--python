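"""Frequency-domain hemodynamics of the structured-tree beds.

Distal flow is viscous-dominated and linear, so each tree vessel is a two-port
relating the Fourier coefficients of pressure and flow at its two ends,

    [Q(0); Q(L)] = Y(w) [P(0); P(L)],
    Y(w) = (i g / sin(wL/c)) [[-cos(wL/c), 1], [1, -cos(wL/c)]],

with both port flows counted positive INTO the vessel, g = sqrt(C A F / rho)
the characteristic admittance, c = g / C the complex wave speed, F the
Womersley profile factor and C = (3/2) pi r0^2 / K_ST the wall compliance per
unit length.  At w = 0 the matrix reduces to the Poiseuille conductance
pi r0^4 / (8 mu L) [[1, -1], [-1, 1]].

An entire two-sided bed (arterial tree + mirrored venous tree, joined at every
terminal) condenses to a single 2x2 "grand admittance" between the arterial
root inlet and the venous root outlet.  It is computed by eliminating all
interior junction pressures via two-port cascade/parallel composition (a Schur
complement), memoized over the distinct (i, j) subtrees; the elimination
closures are retained so interior pressures can be back-substituted later.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import StructuredTreeSpec
from .rheology import BloodProperties, viscosity_law, womersley_factor

__all__ = [
    "FrequencyGrid",
    "AdmittanceSpectrum",
    "BedAdmittance",
    "vessel_admittance",
    "grand_admittance",
    "assemble_bed_admittance_dense",
    "admittance_to_time_domain",
    "cascade",
    "cascade_interior_pressure",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Harmonics w_k = 2 pi k / T, k = 0 ... n_samples/2, of a T-periodic cycle."""

    period: float
    n_samples: int = 1024

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.n_samples % 2 or self.n_samples < 2:
            raise ValueError("n_samples must be even and >= 2")

    @property
    def omegas(self) -> np.ndarray:
        k = np.arange(self.n_samples // 2 + 1)
        return 2.0 * np.pi * k / self.period

    @property
    def n_freq(self) -> int:
        return self.n_samples // 2 + 1


@dataclass
class AdmittanceSpectrum:
    """2x2 admittance over a frequency grid, plus auxiliary per-vessel scalars."""

    grid: FrequencyGrid
    Y: np.ndarray  # (n_freq, 2, 2) complex
    label: str = ""
    aux: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Per-vessel two-port
# ---------------------------------------------------------------------------

def _vessel_Y(
    radius: float,
    length: float,
    k_st: float,
    omegas: np.ndarray,
    blood: BloodProperties,
    viscosity_mode: str = "radius-dependent",
    include_density: bool = True,
) -> np.ndarray:
    """Raw (n_freq, 2, 2) admittance of one tree vessel; omegas[0] must be 0."""
    mu = viscosity_law(radius, blood, mode=viscosity_mode)
    area = np.pi * radius**2
    compliance = 1.5 * area / k_st  # C = (3/2) pi r^2 / K_ST, per unit length

    Y = np.empty((omegas.size, 2, 2), dtype=complex)

    # Zeroth harmonic: Poiseuille conductance.
    g0 = np.pi * radius**4 / (8.0 * mu * length)
    Y[0] = g0 * np.array([[1.0, -1.0], [-1.0, 1.0]])

    w = omegas[1:]
    if w.size:
        F = womersley_factor(w, radius, blood, mu, include_density=include_density)
        g = np.sqrt(compliance * area * F / blood.density)
        c = g / compliance
        x = w * length / c  # Im(x) <= 0 with the principal sqrt branch
        # Evaluate via cot/csc; heavily damped vessels approach a matched
        # line (diagonal -> g, off-diagonal -> 0) and are clamped there to
        # avoid inf/inf in the trigonometric quotients.
        damped = np.imag(x) < -300.0
        xs = np.where(damped, -300.0j, x)
        diag = -1j * g / np.tan(xs)
        off = 1j * g / np.sin(xs)
        diag = np.where(damped, g, diag)
        off = np.where(damped, 0.0, off)
        Y[1:, 0, 0] = Y[1:, 1, 1] = diag
        Y[1:, 0, 1] = Y[1:, 1, 0] = off
    return Y


def vessel_admittance(
    radius: float,
    length: float,
    k_st: float,
    grid: FrequencyGrid,
    blood: BloodProperties | None = None,
    viscosity_mode: str = "radius-dependent",
    include_density: bool = True,
    label: str = "",
) -> AdmittanceSpectrum:
    """Two-port admittance spectrum of a single structured-tree vessel."""
    if radius <= 0 or length <= 0 or k_st <= 0:
        raise ValueError("radius, length and stiffness must be positive")
    blood = blood or BloodProperties()
    omegas = grid.omegas
    mu = viscosity_law(radius, blood, mode=viscosity_mode)
    area = np.pi * radius**2
    compliance = 1.5 * area / k_st
    F = womersley_factor(omegas, radius, blood, mu, include_density=include_density)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.sqrt(compliance * area * F / blood.density)
        c = g / compliance
    Y = _vessel_Y(radius, length, k_st, omegas, blood, viscosity_mode,
                  include_density)
    w0 = np.exp(3j * np.pi / 4) * radius * np.sqrt(
        omegas * (blood.density if include_density else 1.0) / mu
    )
    return AdmittanceSpectrum(
        grid=grid, Y=Y, label=label,
        aux={"g": g, "c": c, "compliance_per_length": compliance,
             "w0": w0, "mu": mu},
    )


# ---------------------------------------------------------------------------
# Two-port algebra (port convention: both flows positive into the network)
# ---------------------------------------------------------------------------

def cascade(Ya: np.ndarray, Yb: np.ndarray) -> np.ndarray:
    """Chain two two-ports sharing an interior node (Schur elimination)."""
    D = Ya[..., 1, 1] + Yb[..., 0, 0]
    Y = np.empty(np.broadcast_shapes(Ya.shape, Yb.shape), dtype=complex)
    Y[..., 0, 0] = Ya[..., 0, 0] - Ya[..., 0, 1] * Ya[..., 1, 0] / D
    Y[..., 0, 1] = -Ya[..., 0, 1] * Yb[..., 0, 1] / D
    Y[..., 1, 0] = -Yb[..., 1, 0] * Ya[..., 1, 0] / D
    Y[..., 1, 1] = Yb[..., 1, 1] - Yb[..., 1, 0] * Yb[..., 0, 1] / D
    return Y


def cascade_interior_pressure(
    Ya: np.ndarray, Yb: np.ndarray, P1: np.ndarray, P2: np.ndarray
) -> np.ndarray:
    """Pressure at the eliminated interior node of cascade(Ya, Yb)."""
    D = Ya[..., 1, 1] + Yb[..., 0, 0]
    return -(Ya[..., 1, 0] * P1 + Yb[..., 0, 1] * P2) / D


# ---------------------------------------------------------------------------
# Grand admittance of a two-sided bed
# ---------------------------------------------------------------------------

@dataclass
class BedAdmittance:
    """Condensed two-port of a whole bed plus per-node elimination data.

    ``Y`` is in the symmetric port convention (both port flows into the bed).
    Per-node caches (YA, YV, M, C1, S) support exact back-substitution of
    interior pressures along any pathway.
    """

    tree: StructuredTreeSpec
    grid: FrequencyGrid
    blood: BloodProperties
    k_st: float
    Y: np.ndarray                       # (n_freq, 2, 2)
    YA: dict[tuple[int, int], np.ndarray]
    YV: dict[tuple[int, int], np.ndarray]
    M: dict[tuple[int, int], np.ndarray | None]
    C1: dict[tuple[int, int], np.ndarray]
    S: dict[tuple[int, int], np.ndarray]
    viscosity_mode: str = "radius-dependent"

    @property
    def spectrum(self) -> AdmittanceSpectrum:
        return AdmittanceSpectrum(grid=self.grid, Y=self.Y, label="grand")

    def coupling_matrix(self) -> np.ndarray:
        """Admittance in the coupling sign convention.

        Row 1: flow out of the terminal proximal artery into the bed.
        Row 2: flow out of the bed into the terminal proximal vein (i.e. in
        the vein's +x direction), the negative of the port-convention flow.
        """
        K = self.Y.copy()
        K[:, 1, :] *= -1.0
        return K

    def kernels(self, n_samples: int | None = None) -> np.ndarray:
        """Periodic time-domain coupling kernels y_ij(t), shape (2, 2, N)."""
        return admittance_to_time_domain(
            self.coupling_matrix(), self.grid.period, n_samples
        )


def grand_admittance(
    tree: StructuredTreeSpec,
    k_st: float,
    grid: FrequencyGrid,
    blood: BloodProperties | None = None,
    viscosity_mode: str = "radius-dependent",
    include_density: bool = True,
    keep_cache: bool = True,
) -> BedAdmittance:
    """Condense a two-sided structured tree to its 2x2 grand admittance.

    Bottom-up over the distinct (i, j) node set: at a terminal node the
    arterial vessel chains directly into its mirrored venous vessel; at a
    junction the two daughter bed two-ports act in parallel between the
    arterial and venous junction nodes.  Work is O(#distinct nodes x n_freq).
    """
    blood = blood or BloodProperties()
    omegas = grid.omegas
    scale = tree.vein_scale

    YA: dict = {}
    YV: dict = {}
    M: dict = {}
    C1: dict = {}
    S: dict = {}

    order = sorted(tree.nodes, key=lambda ij: -(ij[0] + ij[1]))
    for (i, j) in order:
        node = tree.nodes[(i, j)]
        r = node.radius
        ya = _vessel_Y(r, r * tree.lrr_artery, k_st, omegas, blood,
                       viscosity_mode, include_density)
        rv = r * scale
        yv = _vessel_Y(rv, rv * tree.lrr_vein, k_st, omegas, blood,
                       viscosity_mode, include_density)
        if node.terminal:
            m = None
            c1 = yv
        else:
            m = S[(i + 1, j)] + S[(i, j + 1)]
            c1 = cascade(m, yv)
        s = cascade(ya, c1)
        if not np.all(np.isfinite(s)):
            bad = np.argwhere(~np.isfinite(s))[0][0]
            raise FloatingPointError(
                f"non-finite bed admittance at node {(i, j)}, frequency index {bad}"
            )
        YA[(i, j)], YV[(i, j)], M[(i, j)], C1[(i, j)], S[(i, j)] = ya, yv, m, c1, s

    bed = BedAdmittance(
        tree=tree, grid=grid, blood=blood, k_st=k_st, Y=S[(0, 0)],
        YA=YA, YV=YV, M=M, C1=C1, S=S, viscosity_mode=viscosity_mode,
    )
    if not keep_cache:
        bed.YA = bed.YV = bed.M = bed.C1 = bed.S = {}
    return bed


# ---------------------------------------------------------------------------
# Brute-force reference: explicit binary-tree nodal assembly
# ---------------------------------------------------------------------------

def assemble_bed_admittance_dense(
    tree: StructuredTreeSpec,
    k_st: float,
    grid: FrequencyGrid,
    blood: BloodProperties | None = None,
    viscosity_mode: str = "radius-dependent",
    include_density: bool = True,
    max_branches: int = 4096,
) -> np.ndarray:
    """Grand admittance by direct nodal assembly of every physical branch.

    Enumerates the full binary tree (no subtree memoization), stamps each
    vessel two-port into a dense nodal-admittance system, and eliminates all
    interior nodes by a single Schur complement per frequency.  Exponential in
    tree depth; intended as an independent cross-check on small beds.
    """
    blood = blood or BloodProperties()
    omegas = grid.omegas
    scale = tree.vein_scale

    stamps: list[tuple[int, int, np.ndarray]] = []  # (node_in, node_out, Y)
    n_nodes = 2  # 0 = arterial root inlet, 1 = venous root outlet
    n_branches = 0

    def new_node() -> int:
        nonlocal n_nodes
        n_nodes += 1
        return n_nodes - 1

    def vy(r: float, lrr: float) -> np.ndarray:
        return _vessel_Y(r, r * lrr, k_st, omegas, blood, viscosity_mode,
                         include_density)

    stack = [(0, 0, 0, 1)]  # (i, j, arterial inlet node, venous outlet node)
    while stack:
        i, j, a_in, v_out = stack.pop()
        node = tree.nodes[(i, j)]
        n_branches += 2
        if n_branches > max_branches:
            raise ValueError("tree too large for dense reference assembly")
        r = node.radius
        if node.terminal:
            cross = new_node()
            stamps.append((a_in, cross, vy(r, tree.lrr_artery)))
            stamps.append((cross, v_out, vy(r * scale, tree.lrr_vein)))
        else:
            a_out = new_node()
            v_in = new_node()
            stamps.append((a_in, a_out, vy(r, tree.lrr_artery)))
            stamps.append((v_in, v_out, vy(r * scale, tree.lrr_vein)))
            stack.append((i + 1, j, a_out, v_in))
            stack.append((i, j + 1, a_out, v_in))

    full = np.zeros((omegas.size, n_nodes, n_nodes), dtype=complex)
    for a, b, Y in stamps:
        full[:, a, a] += Y[:, 0, 0]
        full[:, a, b] += Y[:, 0, 1]
        full[:, b, a] += Y[:, 1, 0]
        full[:, b, b] += Y[:, 1, 1]

    Ypp = full[:, :2, :2]
    Ypi = full[:, :2, 2:]
    Yip = full[:, 2:, :2]
    Yii = full[:, 2:, 2:]
    return Ypp - Ypi @ np.linalg.solve(Yii, Yip)


# ---------------------------------------------------------------------------
# Time-domain kernels
# ---------------------------------------------------------------------------

def admittance_to_time_domain(
    Y: np.ndarray, period: float, n_samples: int | None = None
) -> np.ndarray:
    """Real T-periodic kernels y(t) from a half-spectrum admittance.

    Scaled so that the discrete periodic convolution
    q_n = (T/N) * sum_m y_m p_{n-m} reproduces Q_k = Y_k P_k for every
    retained harmonic (P_k, Q_k being DFT coefficients normalized by 1/N).
    Input shape (n_freq, ...); output (..., N) with N = n_samples.
    """
    nf = Y.shape[0]
    if n_samples is None:
        n_samples = 2 * (nf - 1)
    need = n_samples // 2 + 1
    if need > nf:
        raise ValueError("admittance spectrum has too few harmonics")
    Yt = np.moveaxis(Y[:need], 0, -1)
    y = np.fft.irfft(Yt, n=n_samples, axis=-1) * (n_samples / period)
    return y
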