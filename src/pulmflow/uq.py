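"""Polynomial-chaos uncertainty quantification and Sobol' sensitivity.

Model outputs Z = M(theta) over the independent uniform prior on the eight
parameters are emulated by a total-degree-K Legendre expansion

    M(theta) ~ sum_j c_j Psi_j(xi(theta)),   J = C(n+K, K) terms,

with xi the affine map of each parameter to [-1, 1] and Psi_j tensorized
Legendre polynomials (orthogonal under the uniform measure with
normalization gamma_j = prod 1/(2 d_i + 1)).  Coefficients are fitted by
ordinary least squares on simulated training data; the surrogate then yields
moments (E[Z] = c_0, Var[Z] = sum_{j>0} c_j^2 gamma_j), first- and
total-order Sobol' indices directly from the coefficient groups, and
time-integrated generalized Sobol' indices for dynamic outputs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre
from scipy.stats import qmc

from .parameters import PARAMETER_BOUNDS, PARAMETER_NAMES, ParameterVector

__all__ = [
    "sample_prior",
    "PCEBasis",
    "build_basis",
    "PCESurrogate",
    "fit_pce_ols",
    "surrogate_moments",
    "sobol_from_pce",
    "generalized_sobol",
    "validation_mse",
    "UQStudyConfig",
    "UQStudyResult",
    "run_uq_study",
]


def sample_prior(
    n_samples: int,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 2023,
) -> np.ndarray:
    """Latin-hypercube samples of the uniform prior; shape (n, n_params)."""
    bounds = bounds or PARAMETER_BOUNDS
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    lo = np.array([b[0] for b in bounds.values()])
    hi = np.array([b[1] for b in bounds.values()])
    if np.any(lo >= hi):
        raise ValueError("invalid bounds: need a < b for every parameter")
    # correlation-minimized LHS keeps the OLS design well conditioned when
    # the training size is only a small multiple of the basis size
    sampler = qmc.LatinHypercube(d=lo.size, seed=seed, optimization="random-cd")
    u = sampler.random(n_samples)
    return lo + u * (hi - lo)


@dataclass(frozen=True)
class PCEBasis:
    n_params: int
    degree: int
    indices: np.ndarray  # (J, n_params) multi-indices, total degree <= K
    gammas: np.ndarray   # (J,) normalization E[Psi_j^2]

    @property
    def n_terms(self) -> int:
        return self.indices.shape[0]

    def evaluate(self, xi: np.ndarray) -> np.ndarray:
        """Design matrix Psi (n_points, J) on inputs already scaled to [-1, 1]."""
        xi = np.atleast_2d(xi)
        max_deg = int(self.indices.max())
        # one-dimensional Legendre values P_d(xi_i) for all degrees at once
        P = np.stack(
            [eval_legendre(d, xi) for d in range(max_deg + 1)], axis=0
        )  # (max_deg+1, n_points, n_params)
        Psi = np.ones((xi.shape[0], self.n_terms))
        for jterm, midx in enumerate(self.indices):
            for ip, d in enumerate(midx):
                if d:
                    Psi[:, jterm] *= P[d, :, ip]
        return Psi


def build_basis(n_params: int, degree: int) -> PCEBasis:
    """All multi-indices of total degree <= K; J = C(n+K, K)."""
    if degree < 1:
        raise ValueError("degree must be >= 1")
    idx = [
        m
        for m in itertools.product(range(degree + 1), repeat=n_params)
        if sum(m) <= degree
    ]
    idx.sort(key=lambda m: (sum(m), m))
    indices = np.array(idx, dtype=np.int64)
    gammas = np.prod(1.0 / (2.0 * indices + 1.0), axis=1)
    return PCEBasis(n_params=n_params, degree=degree, indices=indices, gammas=gammas)


def _scale_to_unit(X: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return 2.0 * (X - lo) / (hi - lo) - 1.0


@dataclass
class PCESurrogate:
    basis: PCEBasis
    lower: np.ndarray
    upper: np.ndarray
    coeffs: np.ndarray  # (J, n_outputs)
    condition: float = np.nan

    @property
    def n_outputs(self) -> int:
        return self.coeffs.shape[1]

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        Psi = self.basis.evaluate(_scale_to_unit(X, self.lower, self.upper))
        return Psi @ self.coeffs


def fit_pce_ols(
    X: np.ndarray,
    Z: np.ndarray,
    degree: int,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> PCESurrogate:
    """Ordinary-least-squares PCE fit (via QR/SVD, mathematically the normal
    equations C = (Psi^T Psi)^-1 Psi^T Z)."""
    bounds = bounds or PARAMETER_BOUNDS
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    lo = np.array([b[0] for b in bounds.values()])
    hi = np.array([b[1] for b in bounds.values()])
    basis = build_basis(X.shape[1], degree)
    if X.shape[0] < basis.n_terms:
        raise ValueError(
            f"need at least {basis.n_terms} training points for degree {degree}"
        )
    if X.shape[0] < 2 * basis.n_terms:
        warnings.warn(
            f"training size {X.shape[0]} < 2x basis size {basis.n_terms}; "
            "OLS coefficients may be noisy"
        )
    Psi = basis.evaluate(_scale_to_unit(X, lo, hi))
    coeffs, _, rank, sv = np.linalg.lstsq(Psi, Z, rcond=None)
    if rank < basis.n_terms:
        raise np.linalg.LinAlgError(
            f"rank-deficient PCE design: rank {rank} < {basis.n_terms} terms, "
            f"condition {sv[0] / sv[-1]:.3e}"
        )
    return PCESurrogate(
        basis=basis, lower=lo, upper=hi, coeffs=coeffs,
        condition=float(sv[0] / max(sv[-1], 1e-300)),
    )


def surrogate_moments(s: PCESurrogate):
    """(mean, variance) per output coordinate, from the coefficients."""
    mean = s.coeffs[0].copy()
    var = np.einsum("jo,j->o", s.coeffs[1:] ** 2, s.basis.gammas[1:])
    return mean, var


@dataclass
class SobolIndices:
    names: list
    first: np.ndarray   # (n_params, n_outputs)
    total: np.ndarray
    variance: np.ndarray
    degenerate: np.ndarray = field(default=None)  # outputs with ~zero variance


def sobol_from_pce(s: PCESurrogate, names: list | None = None) -> SobolIndices:
    """First- and total-order Sobol' indices from coefficient groups.

    S_i sums c_j^2 gamma_j over multi-indices supported on {i} alone; S_Ti
    over all multi-indices involving i.  Outputs with (near-)zero variance
    are flagged and their indices set to zero.
    """
    names = names or PARAMETER_NAMES[: s.basis.n_params]
    _, var = surrogate_moments(s)
    idx = s.basis.indices
    w = s.coeffs**2 * s.basis.gammas[:, None]  # (J, n_out)
    n = s.basis.n_params
    first = np.zeros((n, s.n_outputs))
    total = np.zeros((n, s.n_outputs))
    support = idx > 0
    for i in range(n):
        only_i = support[:, i] & (support.sum(axis=1) == 1)
        any_i = support[:, i]
        first[i] = w[only_i].sum(axis=0)
        total[i] = w[any_i].sum(axis=0)
    degenerate = var <= 1e-14 * np.maximum(1.0, s.coeffs[0] ** 2)
    safe = np.where(degenerate, 1.0, var)
    first = np.where(degenerate, 0.0, first / safe)
    total = np.where(degenerate, 0.0, total / safe)
    return SobolIndices(
        names=list(names), first=first, total=total, variance=var,
        degenerate=degenerate,
    )


def generalized_sobol(
    indices: SobolIndices, time: np.ndarray
):
    """Time-integrated (generalized) Sobol' indices for a dynamic output.

    GS_i(t_j) = int_0^tj S_i Var dt / int_0^tj Var dt, cumulative
    trapezoidal; the value at the final time is the parameter-importance
    scalar.  Returns (GS, GST) with shape (n_params, n_times).
    """
    from scipy.integrate import cumulative_trapezoid

    var = indices.variance
    cum_var = cumulative_trapezoid(var, time, initial=0.0)
    if cum_var[-1] <= 0:
        raise ValueError("zero cumulative variance; generalized indices undefined")
    # avoid 0/0 at the first sample
    cum_var = np.where(cum_var <= 0, np.nan, cum_var)
    GS = cumulative_trapezoid(indices.first * var, time, initial=0.0) / cum_var
    GST = cumulative_trapezoid(indices.total * var, time, initial=0.0) / cum_var
    return GS, GST


def validation_mse(s: PCESurrogate, X_val: np.ndarray, Z_val: np.ndarray):
    """(per-output MSE vector, scalar mean) on held-out data."""
    Z_val = np.asarray(Z_val, dtype=float)
    if Z_val.ndim == 1:
        Z_val = Z_val[:, None]
    if Z_val.shape[0] == 0:
        raise ValueError("validation set is empty")
    err = s(X_val) - Z_val
    mse = (err**2).mean(axis=0)
    return mse, float(mse.mean())


# ---------------------------------------------------------------------------
# Full study: sample -> simulate -> QoI -> PCE -> indices
# ---------------------------------------------------------------------------

@dataclass
class UQStudyConfig:
    degrees: tuple = (2, 3)
    n_train: int = 200
    n_val: int = 50
    seed: int = 2023
    n_time_points: int = 64     # downsampled MPA pressure series
    max_failure_fraction: float = 0.05
    bounds: dict | None = None


@dataclass
class UQStudyResult:
    config: UQStudyConfig
    theta_train: np.ndarray
    theta_val: np.ndarray
    Z_train: np.ndarray
    Z_val: np.ndarray
    output_index: dict          # name -> slice into output columns
    time: np.ndarray            # downsampled cycle times
    surrogates: dict            # degree -> PCESurrogate
    val_mse: dict               # degree -> mean held-out MSE (standardized)
    val_mse_by_output: dict     # degree -> per-named-output mean MSE
    sobol: SobolIndices         # at the highest degree
    gs_pressure: np.ndarray     # generalized S_i(T) for MPA pressure, (8,)
    gst_pressure: np.ndarray
    n_failed: int

    def columns(self, name: str):
        return self.output_index[name]


def _study_outputs(solution, n_time_points):
    """Flatten one simulation into the study output vector."""
    from .synthetic import fourier_resample

    net = solution.network
    p_mpa = fourier_resample(solution.trace(net.root_artery, "p", "mid"),
                             n_time_points)
    cs_art = []
    cs_vein = []
    for name in solution.vessel_names:
        A = solution.A[solution.vessel_index(name), 1]
        R = np.sqrt(A / np.pi)
        cs = (R.max() - R.min()) / R.min()
        (cs_art if net[name].kind == "artery" else cs_vein).append(cs)
    vec = np.concatenate([p_mpa, cs_art, cs_vein])
    index = {
        "p_mpa": slice(0, n_time_points),
        "cs_arteries": slice(n_time_points, n_time_points + len(cs_art)),
        "cs_veins": slice(
            n_time_points + len(cs_art), n_time_points + len(cs_art) + len(cs_vein)
        ),
    }
    return vec, index


def run_uq_study(
    network,
    waveforms,
    solver_config=None,
    study: UQStudyConfig | None = None,
    progress: bool = False,
) -> UQStudyResult:
    """Run the full pipeline on scaled-down settings.

    Draws training and (independent) validation parameter sets from the
    prior, simulates each, extracts the proximal QoIs (MPA pressure series,
    per-vessel cyclic stretch), fits PCE surrogates at the requested degrees,
    and computes validation MSE plus Sobol'/generalized-Sobol' indices at the
    highest degree.  Failed simulations are excluded (capped at
    ``max_failure_fraction``).
    """
    from .solver import SimulationError, SolverConfig, simulate

    study = study or UQStudyConfig()
    solver_config = solver_config or SolverConfig.coarse()
    bounds = study.bounds or PARAMETER_BOUNDS

    theta_train = sample_prior(study.n_train, bounds, seed=study.seed)
    theta_val = sample_prior(study.n_val, bounds, seed=study.seed + 1)

    def run_set(thetas):
        rows, keep = [], []
        index = None
        for k, th in enumerate(thetas):
            try:
                sol = simulate(
                    network, ParameterVector.from_array(th), waveforms,
                    config=solver_config,
                )
                vec, index = _study_outputs(sol, study.n_time_points)
                rows.append(vec)
                keep.append(k)
            except SimulationError:
                continue
            if progress and (k + 1) % 25 == 0:
                print(f"  {k + 1}/{len(thetas)} simulations done")
        return np.array(rows), np.array(keep, dtype=int), index

    Z_train, keep_tr, index = run_set(theta_train)
    Z_val, keep_va, _ = run_set(theta_val)
    n_failed = (study.n_train - keep_tr.size) + (study.n_val - keep_va.size)
    if n_failed > study.max_failure_fraction * (study.n_train + study.n_val):
        raise RuntimeError(f"{n_failed} simulations failed; study aborted")
    theta_train = theta_train[keep_tr]
    theta_val = theta_val[keep_va]

    # standardize outputs for a comparable aggregate MSE
    scale = Z_train.std(axis=0)
    scale[scale == 0] = 1.0

    surrogates, val_mse, val_mse_by_output = {}, {}, {}
    for K in study.degrees:
        s = fit_pce_ols(theta_train, Z_train, K, bounds)
        surrogates[K] = s
        mse_vec, _ = validation_mse(s, theta_val, Z_val)
        val_mse[K] = float((mse_vec / scale**2).mean())
        val_mse_by_output[K] = {
            name: float((mse_vec[sl] / scale[sl] ** 2).mean())
            for name, sl in index.items()
        }

    K_best = max(study.degrees)
    sob = sobol_from_pce(surrogates[K_best], list(bounds))
    tsl = index["p_mpa"]
    t = np.linspace(0, waveforms.period, study.n_time_points, endpoint=False)
    sub = SobolIndices(
        names=sob.names,
        first=sob.first[:, tsl], total=sob.total[:, tsl],
        variance=sob.variance[tsl], degenerate=sob.degenerate[tsl],
    )
    GS, GST = generalized_sobol(sub, t + t[1])
    return UQStudyResult(
        config=study,
        theta_train=theta_train, theta_val=theta_val,
        Z_train=Z_train, Z_val=Z_val, output_index=index, time=t,
        surrogates=surrogates, val_mse=val_mse,
        val_mse_by_output=val_mse_by_output,
        sobol=sob, gs_pressure=GS[:, -1], gst_pressure=GST[:, -1],
        n_failed=n_failed,
    )
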