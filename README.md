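# pulmflow

Multiscale hemodynamics of the pulmonary circulation, with uncertainty
quantification.

Pulmonary hypertension involves remodeling at every scale of the lung
vasculature — proximal arteries, microvascular beds and veins — yet the
quantities that drive endothelial mechanobiology (wall shear stress, cyclic
stretch) cannot be measured in the microcirculation and must be computed.
`pulmflow` is a research code for exactly that computation, plus a global
sensitivity/uncertainty pipeline over its physiological parameters. It is
aimed at cardiovascular modelers who want a tested, reusable implementation
of the two-sided pulmonary pulse-wave model and its variance-based
sensitivity analysis.

## The model

- **Proximal vasculature** — 15 pulmonary arteries and 12 veins, solved as a
  nonlinear 1D system per vessel (area A, flow q):

      A_t + q_x = 0,
      q_t + ((γ+2)/(γ+1))(q²/A)_x + (A/ρ) p_x = −2πν(γ+2) q/A,
      p = (4/3)(Eh/r₀)(√(A/A₀) − 1),

  advanced by the two-step Lax–Wendroff scheme, with prescribed periodic
  inflow at the main pulmonary artery and a left-atrial pressure at the four
  vein roots.

- **Distal vasculature** — each terminal artery/vein pair is closed by a
  *two-sided structured tree*: a self-similar binary tree (daughter radii
  α·r and β·r, lengths ℓrr·r, truncated at r_min) whose arterial side meets
  a mirrored venous side at every terminal. Linearized viscous flow in the
  frequency domain condenses the whole bed into a 2×2 **grand admittance**
  relating root pressures to root flows, computed by memoized two-port
  elimination (verified against brute-force assembly of every branch) and
  coupled to the 1D solver through periodic convolution kernels.

- **Outputs** — pressure, flow, wall shear stress (power-law profile
  proximally, Poiseuille distally), cyclic stretch, and wave-intensity
  analysis (forward/backward compression and decompression waves).

- **UQ/SA** — eight uncertain parameters θ = {K_A, K_ST, K_V, α, β, ℓrrA,
  ℓrrV, r_min} with uniform priors; Legendre polynomial-chaos surrogates
  fitted by ordinary least squares; moments, first-/total-order Sobol'
  indices from the coefficients, and generalized (time-integrated) indices
  for dynamic outputs.

See `docs/methods.md` for formulations, numerics and design decisions.

## Worked example

```python
import pulmflow as pf

net = pf.load_reference_network()            # 15 arteries, 12 veins, 8 beds
q, p = pf.default_waveforms(1024, 0.85)      # SV 70 cm^3; mean p_LA 5 mmHg
wf = pf.BoundaryWaveforms(q_inflow=q, p_la=p, period=0.85)
sol = pf.simulate(net, pf.ParameterVector.nominal(), wf,
                  pf.SolverConfig.coarse())
pm = sol.trace("MPA", "p", "mid") / pf.MMHG_TO_CGS
print(f"MPA {pm.mean():.1f} mmHg mean ({pm.min():.1f}-{pm.max():.1f}), "
      f"mass error {100 * sol.mass_conservation_error():.2f}%")
```

prints

    MPA 14.6 mmHg mean (7.2-31.3), mass error 0.44%

a normotensive pulmonary pressure under the default synthetic boundary
conditions, with inflow and venous outflow balanced at periodic convergence.
Back-substituting the same solution through one bed
(`pulmflow.backsolve.propagate_pathway`) gives the microvascular profile: the
sparse β-pathway reaches its terminal with mean flow 3.0×10⁻⁴ cm³/s and wall
shear stress 23.4 dyn/cm², against 2.4×10⁻⁵ cm³/s and 1.6 dyn/cm² at the end
of the dense α-pathway — the β side carries more flow per terminal vessel,
hence the larger shear.

The `analysis/` scripts run the full narrative in order — network build,
baseline simulation, wave-intensity analysis, distal profiles, and the
scaled-down UQ study — writing their tables under `results/`.

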