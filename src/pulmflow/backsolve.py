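"""Back-substitution of distal hemodynamics along structured-tree pathways.

Once the proximal solver has converged, the Fourier coefficients of the
pressures at each bed's arterial and venous root faces determine the linear
distal solution everywhere.  Using the junction data cached during the
grand-admittance condensation, pressures at the interior arterial and venous
junction nodes are recovered exactly (the same Schur eliminations run in
reverse), and per-branch pressure/flow spectra follow from each vessel's
two-port.  Profiles are reported along the alpha-only (most generations) and
beta-only (fewest generations) pathways, through the terminal crossover and
back up the mirrored venous tree.

Mean (zeroth-harmonic) quantities give the distal QoIs: Poiseuille wall shear
stress 4 mu Qbar / (pi Rbar^3) and cyclic stretch from the linearized
compliance A(t) = A0 + C p(t), C = (3/2) pi r0^2 / K_ST.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .admittance import BedAdmittance, cascade_interior_pressure
from .rheology import viscosity_law
from .solver import ProximalSolution

__all__ = ["PathwayBranch", "PathwayProfile", "root_spectra", "propagate_pathway",
           "distal_qoi"]


@dataclass
class PathwayBranch:
    kind: str       # "artery" | "vein"
    i: int
    j: int
    radius: float   # cm (side-specific reference radius)
    length: float   # cm
    P_in: np.ndarray   # complex spectra; "in" = root side (artery) /
    P_out: np.ndarray  # crossover side (vein)
    Q_in: np.ndarray   # physical flow spectra in the +flow direction
    Q_out: np.ndarray
    compliance: float  # C per unit length, cm^2 per (g/cm/s^2)
    mu: float          # local dynamic viscosity


@dataclass
class PathwayProfile:
    side: str  # "alpha" | "beta"
    branches: list


def root_spectra(solution: ProximalSolution, bed_index: int):
    """DFT coefficients (normalized so c0 = mean) of the terminal artery
    outlet pressure and paired vein inlet pressure of one bed."""
    if not solution.converged:
        import warnings

        warnings.warn("solution not periodic; distal spectra approximate")
    pa = solution.p_terminal[bed_index, 0]
    pv = solution.p_terminal[bed_index, 1]
    n = pa.size
    return np.fft.rfft(pa) / n, np.fft.rfft(pv) / n


def propagate_pathway(
    bed: BedAdmittance,
    Pa_hat: np.ndarray,
    Pv_hat: np.ndarray,
    side: str = "alpha",
) -> PathwayProfile:
    """March root pressure spectra down one side of a bed and back up the vein.

    ``side`` selects the alpha-only (major daughters) or beta-only pathway.
    Returns branches ordered arterial root -> terminal crossover -> venous
    root.
    """
    if not bed.S:
        raise ValueError(
            "bed admittance has no cached junction data; recompute the grand "
            "admittance with keep_cache=True"
        )
    if side not in ("alpha", "beta"):
        raise ValueError("side must be 'alpha' or 'beta'")
    nf = bed.Y.shape[0]
    Pa = np.asarray(Pa_hat)[:nf]
    Pv = np.asarray(Pv_hat)[:nf]
    if Pa.size != nf or Pv.size != nf:
        raise ValueError("root spectra have fewer harmonics than the bed grid")

    tree = bed.tree
    scale = tree.vein_scale
    arteries: list[PathwayBranch] = []
    veins: list[PathwayBranch] = []

    ij = (0, 0)
    while True:
        i, j = ij
        node = tree.nodes[ij]
        YA, YV = bed.YA[ij], bed.YV[ij]
        C1, M = bed.C1[ij], bed.M[ij]
        r = node.radius
        rv = r * scale

        # arterial junction-node pressure (vessel outlet)
        Pm = cascade_interior_pressure(YA, C1, Pa, Pv)
        if node.terminal:
            Pn = Pm  # crossover: artery outlet is the vein's distal node
        else:
            Pn = cascade_interior_pressure(M, YV, Pm, Pv)

        arteries.append(
            PathwayBranch(
                kind="artery", i=i, j=j, radius=r, length=r * tree.lrr_artery,
                P_in=Pa, P_out=Pm,
                Q_in=YA[:, 0, 0] * Pa + YA[:, 0, 1] * Pm,
                Q_out=-(YA[:, 1, 0] * Pa + YA[:, 1, 1] * Pm),
                compliance=1.5 * np.pi * r**2 / bed.k_st,
                mu=viscosity_law(r, bed.blood, mode=bed.viscosity_mode),
            )
        )
        veins.append(
            PathwayBranch(
                kind="vein", i=i, j=j, radius=rv, length=rv * tree.lrr_vein,
                P_in=Pn, P_out=Pv,
                Q_in=YV[:, 0, 0] * Pn + YV[:, 0, 1] * Pv,
                Q_out=-(YV[:, 1, 0] * Pn + YV[:, 1, 1] * Pv),
                compliance=1.5 * np.pi * rv**2 / bed.k_st,
                mu=viscosity_law(rv, bed.blood, mode=bed.viscosity_mode),
            )
        )
        if node.terminal:
            break
        ij = (i + 1, j) if side == "alpha" else (i, j + 1)
        Pa, Pv = Pm, Pn

    return PathwayProfile(side=side, branches=arteries + veins[::-1])


def distal_qoi(profile: PathwayProfile) -> pd.DataFrame:
    """Per-branch mean hemodynamics and mechanobiological stimuli.

    Columns: side-of-tree, (i, j), radius, distance from the terminal
    crossover (cm, negative = arterial side), mean pressure/flow, Poiseuille
    WSS, and cyclic stretch from the linearized distal wall law.
    """
    rows = []
    branches = profile.branches
    n_art = sum(1 for b in branches if b.kind == "artery")
    # cumulative distance from the crossover, arterial side negative
    pos = 0.0
    dists = []
    for b in branches[:n_art][::-1]:
        pos -= b.length
        dists.append(pos + 0.5 * b.length)
    dists = dists[::-1]
    pos = 0.0
    for b in branches[n_art:]:
        dists.append(pos + 0.5 * b.length)
        pos += b.length

    for b, dist in zip(branches, dists):
        mean_p = 0.5 * float(np.real(b.P_in[0] + b.P_out[0]))
        mean_q = float(np.real(b.Q_in[0]))
        A0 = np.pi * b.radius**2
        # mean radius from the linearized wall law at the mean pressure
        Abar = A0 + b.compliance * mean_p
        Rbar = np.sqrt(max(Abar, 1e-30) / np.pi)
        if Rbar <= 0:
            raise ValueError("nonpositive mean radius in distal branch")
        wss = 4.0 * b.mu * mean_q / (np.pi * Rbar**3)

        # cyclic stretch from the reconstructed periodic radius
        n = 2 * (b.P_in.size - 1)
        p_t = np.fft.irfft(0.5 * (b.P_in + b.P_out) * n, n=n)
        A_t = A0 + b.compliance * p_t
        if np.any(A_t <= 0):
            cs = np.nan
        else:
            R_t = np.sqrt(A_t / np.pi)
            cs = float((R_t.max() - R_t.min()) / R_t.min())

        rows.append(
            {
                "kind": b.kind, "i": b.i, "j": b.j, "radius_cm": b.radius,
                "distance_cm": dist, "mean_p": mean_p, "mean_q": mean_q,
                "wss": wss, "cs": cs,
            }
        )
    return pd.DataFrame(rows)
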