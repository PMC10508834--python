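# Methods

## Model overview

`pulmflow` simulates pulsatile blood flow through the pulmonary circulation on
two coupled scales.

**Proximal scale.** The 15 large pulmonary arteries (to the segmental level)
and 12 large veins (two generations) are one-dimensional impermeable
cylinders. Cross-sectional area A(x,t), flow q(x,t) and pressure p(x,t) obey

    A_t + q_x = 0
    q_t + ((γ+2)/(γ+1)) (q²/A)_x + (A/ρ) p_x = −2πν(γ+2) q/A

with a power-law axial velocity profile (γ = 9, blunt core, no slip), blood
density ρ = 1.055 g/cm³ and kinematic viscosity ν = 3.03×10⁻² cm²/s. The wall
is thin, homogeneous and linearly elastic,

    p = (4/3) K (√(A/A0) − 1),  K = Eh/r0,

with one stiffness K_A for all arteries and K_V for all veins. The linearized
pulse-wave speed is c = √(2K/3ρ) (A/A0)^{1/4}.

**Distal scale.** Each terminal artery–vein pair is closed by a two-sided
structured tree: a self-similar binary tree with daughter radii α·r (major)
and β·r (minor), vessel length ℓrr·r, truncated where the minor daughter
would fall below r_min; there the arterial tree crosses over into a mirrored
venous tree (same index set, radii rescaled by the venous/arterial root-radius
ratio). Distal flow is viscous-dominated and periodic, so each branch is a
linear frequency-domain two-port Y(ω) (transmission line with Womersley
profile factor and wall compliance C = (3/2)πr²/K_ST per unit length; the
zero-frequency limit is the Poiseuille conductance πr⁴/8μL). The whole bed
condenses to a 2×2 "grand admittance" between the arterial root and venous
root by cascade/parallel two-port composition — a Schur complement of the
nodal system — memoized over the distinct (i, j) subtree classes, which turns
an exponentially large tree into a few hundred unique evaluations. The
elimination data are cached so interior pressures can be back-substituted
exactly along the α-only and β-only pathways.

**Coupling.** The grand admittance, inverse-Fourier-transformed to periodic
kernels y_ij(t), closes the nonlinear proximal problem through convolution
boundary conditions: the terminal arterial outflow and venous inflow are
periodic convolutions of the kernel matrix with the two face pressures over
the preceding cycle.

## Numerical scheme

The proximal system is advanced with the two-step (Richtmyer) Lax–Wendroff
scheme in conservative form; the pressure-gradient term integrates to the
flux B(A) = (4K/9ρ)(A^{3/2} − A0^{3/2})/√A0 with B′ = c². Boundary closures
use the outgoing Riemann invariants W± = u ± 4(c − c0) extrapolated along the
characteristic foot (linear interpolation in space, friction source
integrated along the characteristic):

- inlet: prescribed periodic flow, scalar Newton for the area;
- venous outlets: prescribed left-atrial pressure (area from the wall law);
- junctions: flow conservation with continuity of static pressure, reduced to
  a scalar Newton iteration in the junction pressure (handles bifurcations,
  confluences and pass-through junctions);
- beds: a 2×2 Newton solve coupling both face areas through the lag-zero
  kernel term, with the history part of the convolution evaluated on a
  stride-subsampled pressure ring buffer.

A measured convergence study (smooth single-vessel problem, fixed probe
location, time-aligned traces) gives observed order ≈ 2.1.

Each simulation starts from A = A0, q = 0, zero convolution history, and runs
whole cycles until the maximum cycle-to-cycle relative change of p and q over
all vessels falls below 10⁻³ (cap 30 cycles fine / 20 coarse; the first cycle
is excluded). Non-converged runs are returned flagged.

Two resolutions are used. The default: Δx ≤ 0.25 cm with ≥ 8 interior nodes
per vessel, CFL number 0.5, 1024 coupling samples per period. The study grid
(`SolverConfig.coarse()`): Δx ≤ 0.55 cm with ≥ 2 interior nodes, CFL 0.75,
512 coupling samples, chosen so one coupled simulation costs a few seconds
while agreeing with the fine grid to ~0.01% in MPA pressure. Coupling kernels
truncated below 256 harmonics were observed to destabilize a small fraction
of prior draws (growing cycle-to-cycle oscillations at individual
high-resistance beds); 512 samples removed every observed instability, so
that value is the study floor.

The discrete convolution uses rectangle-rule weights on the periodic ring —
spectrally accurate for band-limited pressures — with the current-time sample
entering the boundary Newton implicitly.

## Rheology

Bulk dynamic viscosity is μ = ρν ≈ 0.032 g/cm/s. In the structured tree the
apparent viscosity is radius dependent (Fåhræus–Lindqvist effect), by default
the Pries et al. in-vitro fit at discharge hematocrit 0.45 scaled by a plasma
viscosity of 0.01 g/cm/s; its large-diameter limit (3.2 cP) matches bulk μ
within 1%. A constant-μ mode exists for ablation. The Womersley argument uses
the physical form w0² = i³r²ωρ/μ; a `literal` switch reproduces the
density-free variant for comparison.

## Quantities of interest

- Proximal WSS: μ·Ū·(γ+2)/R with Ū = q/A (γ = 9 gives the factor 11).
- Distal WSS: Poiseuille form 4μQ̄/(πR̄³) at the zeroth harmonic, with R̄
  from the linearized distal wall law A̅ = A0 + C·p̄.
- Cyclic stretch: (max R − min R)/min R over the cycle; distal radii are
  reconstructed through the linearized compliance, consistent with the
  linearity of the distal model.
- Wave intensity: centered periodic differences of p and u; water-hammer
  split dP± = (dP ± ρc·dU)/2 with the time-varying wave speed from the wall
  law (a fixed-speed option exists); dI± = dP±·dU±; classification into
  FCW/FDW (forward, pressure rising/falling) and BCW/BDW (backward) by the
  sign of dP±. Intensities are per-sample by default with a dt-normalized
  option, since the normalization convention differs between published
  analyses.

## Uncertainty quantification

Eight uncertain parameters θ = {K_A, K_ST, K_V, α, β, ℓrrA, ℓrrV, r_min} have
independent uniform priors (K_A ∈ [5.6e5, 1.04e6], K_ST ∈ [1.75e5, 3.25e5],
K_V ∈ [5.95e5, 1.11e6] g/cm/s²; α ∈ [0.80, 0.92]; β ∈ [0.60, 0.70];
ℓrr ∈ [10, 50]; r_min ∈ [10⁻³, 10⁻²] cm). Outputs are emulated by
total-degree-K tensorized Legendre expansions on the affinely scaled cube,
J = C(8+K, K) terms, fitted by ordinary least squares (via `lstsq`;
mathematically the normal equations). Moments follow from the coefficients
(E = c₀, Var = Σ c_j²γ_j with γ_j = Π 1/(2d+1)); first-/total-order Sobol'
indices from the coefficient groups supported on {i} / containing i; dynamic
outputs use generalized (variance-weighted time-integrated) indices evaluated
at the cycle end. Training designs are Latin hypercube with
correlation-minimizing optimization and a fixed seed (default 2023);
validation sets are drawn independently. Failed simulations are excluded,
capped at 5%.

The packaged study is deliberately scaled down: 200 training + 40 validation
coarse-grid simulations at degrees 2 and 3 (the full-scale analogue would be
degree 4 with 1900 training runs). At 200 training points the degree-3 basis
(165 terms) is fitted from only 1.2× as many points as coefficients: the
held-out MSE of the MPA pressure emulator still improves from degree 2 to 3,
but scalar outputs with near-saturated degree-2 fits (per-vessel cyclic
stretch) can overfit, which is why the study reports per-quantity MSE
alongside the aggregate.

## Synthetic boundary data

The inflow generator produces a raised-cosine systolic ejection pulse
(default period 0.85 s, stroke volume 70 cm³, ejection fraction of the cycle
0.35, ≤ 10 harmonics) normalized to integrate exactly to the stroke volume.
The left-atrial generator superposes two periodic von-Mises bumps — an a-wave
(peak at 0.88T) and a v-wave (0.42T) with x- and y-descents between them — on
a mean of 5 mmHg, band-limited to 24 harmonics with bump concentrations small
enough that truncation ripple cannot create spurious extrema. These are
package defaults representing a nominal resting adult; they emulate the
*structure* of MRI-derived inflow and lumped-model atrial pressure, not any
specific recording. Consequently all amplitude-dependent outputs (pressure
levels, CS magnitudes, WSS magnitudes, wave timings) are properties of these
study conditions; what the tests establish about real data is the model's
structural behavior (conservation, limits, orderings, sensitivity rankings),
not calibrated magnitudes.

## Design choices on genuinely open points

- **Tree termination.** A node is terminal as soon as its minor daughter
  would fall below r_min; every pathway then ends at a true artery–vein
  crossover. The alternative (per-node pruning with single-daughter chains)
  leaves dead-end stubs with no venous connection, which a two-sided bed
  cannot support physically.
- **Junction pressure.** Static-pressure continuity (not total pressure).
- **Venous mirror.** Same (i, j) topology as the arterial tree, radii scaled
  by the venous/arterial root ratio, lengths from ℓrrV.
- **Bed conductance vs r_min.** DC conductance is monotone increasing in
  r_min across the prior box: with conductance-weighted branching
  α³ + β³ ≲ 1, each added generation raises series resistance faster than
  parallelization lowers it.
- **Wave speed in the distal line.** c = g/C with characteristic admittance
  g = √(CAF/ρ), derived by reducing the linear system to a wave equation.
- **Resonances.** The two-port is evaluated through cot/csc of the complex
  phase; viscous damping keeps the argument off the real axis, and heavily
  damped vessels are clamped to the matched-line limit (diagonal g,
  off-diagonal 0) to avoid overflow.

## Known limitations

- Elastic (not viscoelastic) walls; no collapse, gravity, or respiratory
  pressure modulation; rigid junction geometry.
- Stiffness is radius independent within each compartment.
- The bed terminates at r_min with no explicit capillary model.
- Boundary waveforms are synthetic; no patient calibration is attempted.
- The coarse study grid trades ~0.01% pressure accuracy and occasional slow
  convergence (runs flagged, still used) for tractable sweep cost.
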