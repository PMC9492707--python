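# liqprop

Ensemble-property analysis of liquid-solution molecular-dynamics
trajectories, solvation-shell cluster extraction, and the thermochemistry
arithmetic that turns parsed quantum-chemistry results into bond
dissociation energies, binding energies, redox potentials, pKa values, and
NMR chemical shifts.

## Who this is for

Simulators of liquid electrolytes and molecular solutions who run classical
MD (LAMMPS-style text dumps, logs, and data files) and electronic-structure
calculations, and need the post-processing layer between them: structural
and dynamical observables from trajectories, representative solvation
clusters to feed into quantum workflows, and the cycle arithmetic on the
quantum results themselves.  Everything is scriptable from Python; a
`liqprop` CLI wraps each analysis for shell pipelines.

## What it computes

**Structure** — radial distribution functions g(r) from minimum-image pair
histograms; running coordination numbers CN(r) = 4πρ_B ∫₀ʳ g(s)s² ds; number
densities; automatic first-shell cutoffs from the first minimum of a
smoothed g(r).

**Dynamics** — exact (image-flag) and heuristic coordinate unwrapping;
multiple-time-origin mean-squared displacement by a direct O(T²) route and
an FFT route that agree to rounding; self-diffusion from the Einstein
relation D = slope/6; Nernst–Einstein ionic conductivity
σ = (e²/V k_B T) Σᵢ Nᵢ zᵢ² Dᵢ; Green–Kubo shear viscosity
η = (V/k_B T) ∫ ⟨P_αβ(0)P_αβ(t)⟩ dt from off-diagonal pressure series;
intermittent and continuous shell residence correlation functions C(t) with
integral and exponential-fit residence times; the static dielectric constant
ε = 1 + (⟨M²⟩−⟨M⟩²)/(3ε₀ V k_B T) from whole-molecule dipole fluctuations.

**Solvation** — extraction of solvation-shell clusters around a target
species (nearest-atom or center-of-mass criterion, fixed or RDF-derived
cutoff), emitted whole across periodic boundaries as XYZ files with a JSON
manifest, plus exact speciation statistics over shell compositions.

**Thermochemistry** — bond dissociation enthalpy
BDE = (H_frag1 + H_frag2) − H_principal (ring-opening: single-product
difference); binding energy BE = E_complex − (E₁ + E₂) with an exergonic
flag; molecular-graph fragmentation that cuts every bridge bond and
deduplicates symmetry-equivalent cuts by canonical graph hashing; redox
state-tree planning (HOMO/LUMO, vertical, adiabatic, sequential PCET;
single- or multi-step electron transfer) and thermodynamic-cycle potentials
E = −ΔG/(nF) with conversion to named reference scales (Li⁺/Li by a 1.4 V
shift, SHE by a configurable 4.44 V); pKa = ΔG_deprot/(RT ln 10); chemical
shift δ = σ_ref − σ_sample.

**Synthetic fixtures** — seeded generators with analytic ground truth
(uniform gases, Brownian walkers, lattices, dipole gases, Markov binding
pairs, Ornstein–Uhlenbeck stress series, additive-energy toy molecules), so
every estimator can be validated against a known answer.

## Worked example

Generate a Brownian trajectory with a known diffusivity, then recover it
from the written dump file:

```sh
$ liqprop synth brownian --seed 7 --param n_atoms=50 --param n_frames=300 \
      --dump bd.lammpstrj --manifest man.json
$ liqprop diffusion --dump bd.lammpstrj --unit-style si --dt 1e-12
{
  "D": 9.789108457189573e-10,
  "D_si": 9.789108457189573e-10,
  "stderr": 3.1724842326189395e-12,
  "r_squared": 0.99938070776127,
  "linear": true
}
```

The generator planted D = 1.0e-9 m²/s (recorded in `man.json`); the Einstein
fit over the default 20–60 % lag window recovers 0.98e-9 m²/s — within the
~4 % statistical precision this trajectory length supports — with the fit's
standard error and R² alongside.  The same computation in Python:

```python
from liqprop import dynamics, synthetic

fx = synthetic.gen_brownian(n_atoms=50, n_frames=300, D=1e-9, dt=1e-12, seed=7)
traj = dynamics.unwrap(fx.trajectory)
fit = dynamics.fit_diffusion(dynamics.compute_msd(traj))
print(fit.D_si, fit.r_squared)
```

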