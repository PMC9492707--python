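# Methods

This note records the models and estimators liqprop implements, the
assumptions behind them, the defaults that matter, what the synthetic
fixtures do and do not emulate, and the numerical choices made where the
design was genuinely open.

## Trajectories, units, and indexing

Trajectories are ordered periodic snapshots with a constant atom-id set.
Per-atom arrays are stored sorted by ascending atom id, so every module
shares one indexing convention regardless of the order the engine wrote the
atoms.  Only orthorhombic cells are supported; dumps with triclinic tilt
factors are rejected with a clear error rather than silently mis-measuring
distances.  Coordinates stay in the trajectory's native unit style (`real`,
`metal`, `si`, or reduced `lj`); conversion to SI happens only where a
physical observable is assembled (conductivity, viscosity, dielectric
constant).  Reduced units carry no absolute scale, so converting them
requires an explicit reference-scale mapping and otherwise raises a
configuration error.  Missing optional dump columns (charge, molecule id)
are represented as absent, not as zeros; missing image flags default to
(0,0,0) with a logged notice, since a dump without flags is conventionally
in the home cell.

The force-field document schema (`Elements/Masses/Charges/Nonbond/Bonds/
Angles/Dihedrals/Impropers` with explicit 0-based index tuples) is this
package's own JSON dialect.  Data files are written in atom_style-full
layout with 1-based ids, as that format requires.  Coefficient rows
identical across species merge into one global type by exact tuple equality
— a numeric tolerance would make type assignment depend on input order, and
predictability was preferred over compactness.

## Radial distribution function and coordination number

g(r) is a histogram of minimum-image pair distances, normalized per frame by
the ideal-gas expectation N_A · 4πr²Δr · ρ_B and averaged over frames.  When
the two selections overlap, self-pairs are excluded and the partner density
uses N_B − 1 (identical selections count each unordered pair once).  Per-
frame volumes are used, so constant-pressure trajectories normalize
correctly frame by frame.

The ideal-shell factor 4πr²Δr is used deliberately instead of the exact
shell volume (4π/3)(r₊³−r₋³): the two differ by O(Δr²/r²), far below
counting noise at any usable bin width, and the ideal form cancels exactly
against the 4πρ_B g s² integrand of CN(r) — so the cumulative-trapezoid
coordination number of an isolated histogram spike reproduces the integer
neighbor count exactly (a simple-cubic lattice gives CN = 6 at 1.2 lattice
spacings to machine precision).

Defaults: bin width 0.1 native length units; r_max = half the smallest box
edge, which is also its hard limit (beyond it minimum-image distances are
ambiguous).

First-shell detection smooths a copy of g(r) with a moving average (default
5 bins; the reported g is never modified), finds the first local maximum
exceeding 1 + 3σ_bin — σ_bin estimated from the accumulated raw counts, so
pure noise cannot fake a shell — and returns the first local minimum after
it.  Profiles without a qualifying peak raise a detection error advising a
manual cutoff instead of guessing.

## Mean-squared displacement and diffusion

MSD averages over all time origins.  Two routes exist: a direct O(T²)
reference and an FFT decomposition (autocorrelation plus a running
sum-of-squares recursion) that is algebraically identical; they agree to
~1e-12 relative on every fixture, and the direct route is retained as the
oracle the fast path is tested against.  When the selection names a species,
displacements are of mass-weighted molecular centers; otherwise per-atom.
Wrapped input is detected (any inter-frame jump beyond half a box edge) and
rejected with advice to unwrap first.  Unwrapping uses image flags exactly
when present, and otherwise a jump heuristic (fold displacements into
(−L/2, L/2]) that is exact whenever no particle moves half a box between
stored frames — the fixtures verify the two routes coincide on paths where
both are valid.

Lags are reported up to half the trajectory length by default: beyond that
fewer than half the origins contribute and the estimate is statistically
unreliable.  The diffusion fit takes the least-squares slope over 20–60 % of
the reported maximum lag (avoiding both the short-time regime and the
noisiest tail), divides by 6, and reports the fit standard error and R².
R² below 0.98 flags a non-diffusive shape (ballistic or confined motion)
rather than failing.  At the validation fixture size (200 walkers, 2000
frames) the intrinsic statistical precision of the recovered D is about 4 %
relative (the long-lag MSD fluctuations are strongly correlated across the
fit window), which is why the recovery tests use a 5 % band with pinned
seeds.

## Conductivity, viscosity, residence time, dielectric constant

Nernst–Einstein conductivity σ = (e²/V k_BT) Σ N z² D deliberately ignores
ion–ion correlations; the collective (Einstein–Helfand) form is a documented
non-goal of this version, so reported values are upper-bound estimates for
associating electrolytes.

Green–Kubo viscosity integrates the multiple-time-origin autocorrelation of
the off-diagonal pressure components (Pxy, Pxz, Pyz averaged; any subset
works) with a cumulative trapezoid, and reports the mean of the running
integral over the plateau window [0.8 t_cut, t_cut] — a single-point reading
of a noisy running integral is far less stable.  Non-uniform sampling
intervals are rejected.  The validation uses an exactly discretized
Ornstein–Uhlenbeck stress series (ACF = c·e^{−t/τ_c}, integral c·τ_c) with
τ_c = 10 sampling intervals, t_cut = 5τ_c, and 10⁵ samples: the truncated
tail contributes <1 % and the statistical error of the plateau stays within
a 10 % band.

Residence correlation: h(t) = 1 when any ligand atom is within the cutoff of
any center atom (molecule pairs; periodic KD-tree neighbor search).
`intermittent` counts re-entries, C(t) = ⟨h(0)h(t)⟩/⟨h(0)⟩; `continuous`
requires unbroken occupancy, so it is bounded above by the intermittent
curve, and C(0) = 1 exactly for both.  Two times are reported: the integral
of C to its first crossing of 0.05 (flagged unconverged if it never
crosses), and an exponential fit over C ∈ [0.1, 1] — the fit is the headline
number, as the integral depends on the arbitrary floor.  The Markov fixture
uses an absorbing leave process, so each pair contributes one departure
event; its default size (1600 pairs, 120 frames) was chosen so the 1/√n
counting precision (~2.5 %) sits inside the 5 % validation band.

Dielectric constant: conducting-boundary fluctuation formula with the total
dipole assembled from whole (molecule-wise unwrapped) molecules, so boundary
straddlers contribute their physical dipole.  Systems containing any
net-charged species are rejected: their molecular-dipole sum is origin-
dependent and the ionic conduction contribution is missing, and a partial ε
would be worse than an explicit refusal.

## Solvation-shell clusters

A molecule belongs to a center's shell when its criterion distance is within
the cutoff under minimum image — nearest atom pair by default (captures the
coordinating atoms of large, floppy anions), centers of mass as the coarse
alternative.  The cutoff is a number or "auto" (first RDF minimum; detection
failures propagate).  Cluster geometries are made whole molecule-by-
molecule, translated into the center's nearest image, and recentered on the
center's centroid; no rotation is applied, since downstream electronic-
structure tools orient structures themselves.  Membership is validated
against an all-pairs minimum-image oracle on ≤100-molecule frames, and
member sets are monotone in the cutoff.  Speciation statistics are exact
multiset counts with deterministically ordered keys.

## Thermochemistry

Each observable uses the energy field its definition calls for: BDE uses
enthalpies H, BE uses electronic energies E, redox and pKa use Gibbs free
energies G; every operation validates the field is present and enforces the
true-minimum gate (documents with imaginary frequencies are rejected) and
charge conservation across the reaction.

Fragmentation cuts bridge bonds (found by cycle analysis); each cut's
fragment pair is canonicalized by an iterative neighborhood-refinement
(Weisfeiler–Lehman) hash over (element, formal charge, degree) and
deduplicated, with symmetry-equivalent bonds recorded on the surviving
entry.  The test suite keeps an exhaustive VF2-isomorphism dedup as the
independent oracle on graphs up to 16 atoms.  Ring-opening cuts a non-bridge
bond and yields one connected product.  Bond perception from bare geometry
uses single-bond covalent radii × 1.2; explicit bond lists always win.

The redox state tree is enumerated deterministically from the requested
method: the reference state per phase; charge steps of ±1 per level
(single-step keeps only the terminal ±n state, multi-step every
intermediate); vertical children are marked to reuse the parent geometry;
sequential PCET enumerates the (electron, proton) grid up to n of each, a
reduction gaining electrons and protons and an oxidation the mirror image,
each node's parent differing by exactly one transfer.  Output order is
sorted and independent of how the specification was assembled.

Solution-phase reaction free energies prefer directly computed solution
documents and otherwise assemble the standard Born–Haber cycle
G(sol) = G(gas) + ΔG_solv from a per-state solvation correction; absent both
routes, the computation fails listing the missing states.  The absolute
potential is E = −ΔG_red/(nF) (0.2 hartree for one electron ⇒ 5.4423 V);
converted potentials subtract each registered scale offset exactly, with
Li⁺/Li = 1.4 V and SHE = 4.44 V as defaults — both conventions, both
overridable, and the free-electron free energy is an optional additive term
with zero default.  pKa = ΔG_deprot/(RT ln 10) with the solvated-proton free
energy supplied by the caller (it is a convention-laden constant no gas-
phase calculation provides).  Chemical shifts are δ = σ_ref − σ_sample with
a nucleus-label match enforced when labels are given.

Physical constants are CODATA-2018, kept in one registry
(`liqprop.constants`).

## Synthetic fixtures: what they do and do not show

Every generator is reproducible from (kind, parameters, seed) alone, uses
its own random generator (no global state), and embeds its analytic ground
truth in a manifest so tests assert against declared truth.  Trajectory
generators can write the same dump dialect the readers parse, so file I/O is
exercised in the loop.

The fixtures are deliberately interaction-free: uniform gases (g ≡ 1),
independent Brownian walkers (known D), rigid freely rotating dipoles
(⟨M²⟩ = Nμ²), absorbing Markov binding pairs (geometric survival), OU stress
series (exponential ACF), and additive-energy toy molecules (every bridge
bond's BDE equals its assigned strength; a linked complex's BE equals minus
the linking strength).  Passing these tests demonstrates estimator
correctness — normalization, origin averaging, unwrapping, integration,
graph canonicalization — not force-field or sampling adequacy for any real
liquid: real electrolytes add correlated motion, finite-size effects, and
ion pairing that these fixtures intentionally exclude.

## Default MD protocol

The recipe emitter renders a six-stage control script: steepest-descent then
conjugate-gradient minimization, NPT equilibration (1 ns, 298.15 K, 1 atm),
a melt to 500.15 K for 500 ps and a 2 ns quench back to 298.15 K (to escape
metastable packings), and a 5 ns NVT production run sampled every 50 ps —
exactly 100 stored configurations — with Nosé–Hoover thermostat/barostat
directives and a 1 fs timestep.

## Known limitations

Binary dump formats, triclinic cells, and velocity/force-based analyses are
out of scope.  Conductivity is Nernst–Einstein only.  The dielectric module
refuses ionic systems rather than approximating them.  Geometric
deduplication of near-identical clusters is not attempted (duplicate
suppression is by frame and center only).  Spin bookkeeping in homolytic vs
heterolytic cleavage is not modeled; fragment charges are the caller's
assignment, checked only for conservation.  The Gaussian/LAMMPS execution
layer, RESP fitting, and continuum-solvation physics are external concerns:
this package starts from their parsed outputs.
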