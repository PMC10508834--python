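"""Nonlinear 1D pulse-wave solver for the proximal pulmonary network.

Mass and momentum balance per vessel,

    A_t + q_x = 0,
    q_t + ((gamma+2)/(gamma+1)) (q^2/A)_x + (A/rho) p_x = -2 pi nu (gamma+2) q/A,

closed by the linearly elastic wall law p = (4/3) K (sqrt(A/A0) - 1) with a
single arterial stiffness K_A and venous stiffness K_V.  The system is
advanced by the two-step Lax-Wendroff scheme to a periodic steady state.
Boundary conditions: prescribed periodic inflow at the arterial root,
prescribed left-atrial pressure at the venous roots, flow conservation with
static-pressure continuity at junctions, and convolution coupling against the
two-sided structured-tree grand admittance at the terminal artery/vein pairs.

Coordinates follow the flow: x runs root->terminal in arteries and
structured-tree->atrium in veins, so each bed couples an arterial x = L face
to a venous x = 0 face.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .admittance import BedAdmittance, FrequencyGrid, grand_admittance
from .geometry import ProximalNetwork, StructuredTreeSpec, generate_tree
from .parameters import ParameterVector
from .rheology import BloodProperties
from .synthetic import fourier_resample

__all__ = [
    "WallLaw",
    "wall_pressure",
    "wall_area",
    "BoundaryWaveforms",
    "SolverConfig",
    "ProximalSolution",
    "SimulationError",
    "simulate",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class WallLaw:
    stiffness: float       # K = Eh/r0, g/cm/s^2
    reference_area: float  # A0, cm^2

    def __post_init__(self):
        if self.stiffness <= 0 or self.reference_area <= 0:
            raise ValueError("stiffness and reference area must be positive")


def wall_pressure(A, law: WallLaw):
    """Transmural pressure p(A) = (4/3) K (sqrt(A/A0) - 1)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("area must be positive")
    return (4.0 / 3.0) * law.stiffness * (np.sqrt(A / law.reference_area) - 1.0)


def wall_area(p, law: WallLaw):
    """Inverse wall law; raises below the collapse pressure -(4/3) K."""
    p = np.asarray(p, dtype=float)
    s = 1.0 + 0.75 * p / law.stiffness
    if np.any(s <= 0):
        raise ValueError("pressure at or below vessel collapse")
    return law.reference_area * s * s


@dataclass(frozen=True)
class BoundaryWaveforms:
    """One period of inlet flow (cm^3/s) and left-atrial pressure (g/cm/s^2)."""

    q_inflow: np.ndarray
    p_la: np.ndarray
    period: float

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        for x in (self.q_inflow, self.p_la):
            if not np.all(np.isfinite(x)):
                raise ValueError("waveform contains non-finite samples")


@dataclass(frozen=True)
class SolverConfig:
    dx_max: float = 0.25          # cm
    min_interior: int = 8         # interior nodes per vessel
    cfl: float = 0.5
    n_coupling: int = 1024        # kernel samples per period (frequency grid)
    max_cycles: int = 30
    conv_tol: float = 1e-3        # cycle-to-cycle relative change
    newton_tol: float = 1e-10
    newton_maxit: int = 50
    c_headroom: float = 1.25      # wave-speed margin in the CFL time step
    u_headroom: float = 150.0     # advective margin, cm/s
    store_full: bool = False
    viscosity_mode: str = "radius-dependent"

    @classmethod
    def coarse(cls) -> "SolverConfig":
        """Study-grade resolution for large parameter sweeps."""
        return cls(dx_max=0.55, min_interior=2, n_coupling=512, max_cycles=20,
                   cfl=0.75)


@dataclass
class ProximalSolution:
    network: ProximalNetwork
    theta: ParameterVector
    config: SolverConfig
    time: np.ndarray                     # final-cycle sample times, s
    vessel_names: list
    p: np.ndarray                        # (n_vessels, 3, n_steps): x = 0, L/2, L
    q: np.ndarray
    A: np.ndarray
    p_terminal: np.ndarray               # (n_beds, 2, n_steps) bed-face pressures
    beds: list                           # BedAdmittance per bed
    trees: list                          # StructuredTreeSpec per bed
    dt: float = 0.0
    n_cycles: int = 0
    converged: bool = True
    convergence_history: list = field(default_factory=list)
    full: dict | None = None

    def vessel_index(self, name: str) -> int:
        return self.vessel_names.index(name)

    def trace(self, name: str, fld: str = "p", pos: str = "mid") -> np.ndarray:
        arr = {"p": self.p, "q": self.q, "A": self.A}[fld]
        ipos = {"inlet": 0, "mid": 1, "outlet": 2}[pos]
        return arr[self.vessel_index(name), ipos]

    def mean_inflow(self) -> float:
        return float(self.q[self.vessel_index(self.network.root_artery), 0].mean())

    def mean_vein_outflow(self) -> float:
        return float(
            sum(self.q[self.vessel_index(v), 2].mean() for v in self.network.vein_roots)
        )

    def mass_conservation_error(self) -> float:
        """|mean inflow - total mean venous outflow| / mean inflow."""
        qin = self.mean_inflow()
        return abs(qin - self.mean_vein_outflow()) / abs(qin)


def _grid_for(network: ProximalNetwork, config: SolverConfig):
    names = list(network.vessels)
    nv = len(names)
    nn = np.empty(nv, dtype=np.int64)
    dx = np.empty(nv)
    for i, nname in enumerate(names):
        L = network[nname].length
        segs = max(config.min_interior + 1, math.ceil(L / config.dx_max))
        nn[i] = segs + 1
        dx[i] = L / segs
    off = np.concatenate(([0], np.cumsum(nn)))[:-1].astype(np.int64)
    return names, nn, dx, off


def simulate(
    network: ProximalNetwork,
    theta: ParameterVector,
    waveforms: BoundaryWaveforms,
    config: SolverConfig | None = None,
    blood: BloodProperties | None = None,
    beds: list[BedAdmittance] | None = None,
) -> ProximalSolution:
    """Run the coupled multiscale model to a periodic steady state.

    Precomputed ``beds`` (grand admittances matching ``theta``) may be passed
    to skip tree condensation, e.g. when re-simulating with identical distal
    parameters.
    """
    config = config or SolverConfig()
    blood = blood or BloodProperties()
    T = waveforms.period

    names, nn, dx, off = _grid_for(network, config)
    nv = len(names)
    ntot = int(nn.sum())
    index = {n: i for i, n in enumerate(names)}

    K = np.empty(nv)
    A0 = np.empty(nv)
    for i, nm in enumerate(names):
        v = network[nm]
        K[i] = theta.k_a if v.kind == "artery" else theta.k_v
        A0[i] = v.reference_area
    c0 = np.sqrt(2.0 * K / (3.0 * blood.density))

    # time step from CFL with headroom for pressurization and advection
    c_max = float(c0.max()) * config.c_headroom + config.u_headroom
    dt_cfl = config.cfl * float(dx.min()) / c_max
    M = config.n_coupling
    n_steps = int(math.ceil(T / dt_cfl))
    n_steps = M * math.ceil(n_steps / M)
    dt = T / n_steps
    stride = n_steps // M
    dtau = T / M

    q_in = fourier_resample(waveforms.q_inflow, n_steps)
    p_la = fourier_resample(waveforms.p_la, n_steps)

    # boundary tables ------------------------------------------------------
    inlet_v = index[network.root_artery]
    # prescribed-pressure outlets: vein roots, plus dangling arteries
    # (no daughters, no bed pairing; used by single-vessel test problems)
    outlet_names = list(network.vein_roots) + [
        nm for nm, v in network.vessels.items()
        if v.kind == "artery" and not v.daughters and v.paired_terminal is None
    ]
    out_v = np.array([index[v] for v in outlet_names], dtype=np.int64)
    p_out = np.tile(p_la, (max(1, out_v.size), 1))
    if out_v.size == 0:
        out_v = np.empty(0, dtype=np.int64)
        p_out = np.empty((0, n_steps))

    jn_rows = []
    for nm, v in network.vessels.items():
        if not v.daughters:
            continue
        if v.kind == "artery":  # parent at L, daughters at 0
            members = [(index[nm], 1)] + [(index[d], 0) for d in v.daughters]
        else:  # venous confluence: daughters at L, parent at 0
            members = [(index[d], 1) for d in v.daughters] + [(index[nm], 0)]
        jn_rows.append(members)
    n_jn = len(jn_rows)
    jn_n = np.array([len(r) for r in jn_rows], dtype=np.int64) if n_jn else np.empty(0, dtype=np.int64)
    jn_vs = np.zeros((max(1, n_jn), 3), dtype=np.int64)
    jn_end = np.zeros((max(1, n_jn), 3), dtype=np.int64)
    for j, row in enumerate(jn_rows):
        for k, (vi, e) in enumerate(row):
            jn_vs[j, k] = vi
            jn_end[j, k] = e
    if n_jn == 0:
        jn_n = np.empty(0, dtype=np.int64)

    # beds -----------------------------------------------------------------
    grid = FrequencyGrid(period=T, n_samples=M)
    trees: list[StructuredTreeSpec] = []
    bed_adm: list[BedAdmittance] = []
    nbeds = len(network.beds)
    for bi, (art, vein) in enumerate(network.beds):
        tree = generate_tree(
            network[art].radius, theta.alpha, theta.beta,
            theta.lrr_a, theta.lrr_v, theta.r_min,
            root_radius_vein=network[vein].radius,
        )
        trees.append(tree)
        if beds is not None:
            bed_adm.append(beds[bi])
        else:
            bed_adm.append(
                grand_admittance(
                    tree, theta.k_st, grid, blood,
                    viscosity_mode=config.viscosity_mode,
                )
            )
    if nbeds:
        bed_art = np.array([index[a] for a, _ in network.beds], dtype=np.int64)
        bed_vein = np.array([index[v] for _, v in network.beds], dtype=np.int64)
        kern = np.stack([b.kernels(M) for b in bed_adm])  # (nb, 2, 2, M)
        h = dtau * kern[:, :, :, 0].copy()
    else:
        bed_art = np.empty(0, dtype=np.int64)
        bed_vein = np.empty(0, dtype=np.int64)
        kern = np.zeros((0, 2, 2, max(1, M)))
        h = np.zeros((0, 2, 2))

    # state ----------------------------------------------------------------
    A = np.concatenate([np.full(nn[i], A0[i]) for i in range(nv)])
    q = np.zeros(ntot)
    Anew = A.copy()
    qnew = q.copy()
    Ah = np.zeros(ntot)
    qh = np.zeros(ntot)
    p_hist = np.zeros((max(1, nbeds), 2, n_steps))
    monA = np.zeros((nv, 3, n_steps))
    monQ = np.zeros((nv, 3, n_steps))
    if config.store_full:
        fullA = np.zeros((ntot, n_steps))
        fullQ = np.zeros((ntot, n_steps))
    else:
        fullA = np.zeros((1, 1))
        fullQ = np.zeros((1, 1))

    gamma = blood.profile_exponent
    prevA = None
    prevQ = None
    history: list[float] = []
    converged = False
    cycles = 0
    for cyc in range(config.max_cycles):
        status, info, _ = _kernel.run_cycle(
            A, q, Anew, qnew, Ah, qh,
            off, nn, dx, K, A0, c0,
            dt, n_steps, blood.density, blood.kinematic_viscosity, gamma,
            q_in, inlet_v,
            out_v, p_out,
            jn_n, jn_vs, jn_end,
            bed_art, bed_vein, kern, h, stride, dtau, p_hist,
            config.newton_tol, config.newton_maxit,
            monA, monQ, config.store_full, fullA, fullQ,
        )
        cycles = cyc + 1
        if status == _kernel.STATUS_CFL:
            raise SimulationError(f"CFL violation during cycle {cycles}")
        if status == _kernel.STATUS_AREA:
            raise SimulationError(
                f"nonpositive area in vessel {names[info]} during cycle {cycles}"
            )
        if status == _kernel.STATUS_NEWTON:
            where = (
                f"bed {info - 1000}" if info >= 1000
                else f"junction {-info - 1}" if info < 0
                else f"inlet {names[info]}"
            )
            raise SimulationError(f"boundary solve diverged at {where}, cycle {cycles}")

        if prevA is not None and cyc >= 1:  # first cycle excluded
            pscale = np.abs(_p_from_A(monA, K, A0)).max() + 1e-30
            qscale = np.abs(monQ).max() + 1e-30
            dp = np.abs(_p_from_A(monA, K, A0) - _p_from_A(prevA, K, A0)).max()
            dq = np.abs(monQ - prevQ).max()
            metric = max(dp / pscale, dq / qscale)
            history.append(metric)
            if metric < config.conv_tol:
                converged = True
                prevA = monA.copy()
                prevQ = monQ.copy()
                break
        prevA = monA.copy()
        prevQ = monQ.copy()

    p_mon = _p_from_A(monA, K, A0)
    time = np.arange(n_steps) * dt + dt
    full = None
    if config.store_full:
        full = {
            "A": fullA, "q": fullQ,
            "offsets": off, "counts": nn, "dx": dx,
        }
    return ProximalSolution(
        network=network, theta=theta, config=config, time=time,
        vessel_names=names, p=p_mon, q=monQ.copy(), A=monA.copy(),
        p_terminal=p_hist[: nbeds].copy(), beds=bed_adm, trees=trees,
        dt=dt, n_cycles=cycles, converged=converged,
        convergence_history=history, full=full,
    )


def _p_from_A(monA: np.ndarray, K: np.ndarray, A0: np.ndarray) -> np.ndarray:
    s = np.sqrt(monA / A0[:, None, None])
    return (4.0 / 3.0) * K[:, None, None] * (s - 1.0)
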