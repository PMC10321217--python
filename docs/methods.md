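# Methods

## The model

A trivalent DNA nanostar is represented as a rigid body of ten sites: one
core bead, two beads per arm at 1σ and 2σ along the arm axis, and one
attractive patch per arm that stands in for the self-complementary sticky
end.  σ, the bead diameter, corresponds to ≈ 2.5 nm (≈ 8 bp) of dsDNA;
energies are in ε, temperature in ε/k_B, and time in the Brownian time
τ_Br = σ²/D of a single bead.

The shape of the star is controlled by a single planarity parameter d_p:
the distance from the core to the plane through the tips of the three
normalised arm vectors.  A symmetric template places the arms at polar
angle ψ = arccos(d_p) from the three-fold axis, 120° apart in azimuth, so
d_p = 0 is a flat Y with inter-arm angles α = 120° and the inter-arm angle
follows α(d_p) = arccos((3 d_p² − 1)/2), vanishing in the (unphysical)
colinear limit d_p → 1.  The planar (d_p = 0) and non-planar (d_p = 0.6)
templates are the two reference designs studied throughout.

### Interactions

* CORE/ARM beads of different stars repel through a WCA potential
  (ε_rep = 1ε, cut at 2^{1/6}σ), so stars cannot interpenetrate.
* Patches of different stars attract through a Morse well
  U_M(r) = ε_m[(1 − e^{−a_m(r−r0_m)})² − 1], truncated and shifted to zero
  at r_cut = r0_m + 0.2σ: patches attract within a radius of 0.2σ.
* Patch sites are massless interaction points; they carry no excluded
  volume, and patch–bead cross pairs are ignored (patches sit at the bead
  surface; adding them would double-count contact repulsion).
* All intramolecular pairs are excluded (the body is rigid).

### Force-field calibration

The well-shape parameters are not dictated by the physics of the sticky end
alone; they were calibrated, once, against the bulk behaviour the model
must reproduce, and then frozen:

* ε_m = 14ε, a_m = 12/σ, r0_m = 0.45σ, patch offset 2.325σ
  (= (5.1σ − r0_m)/2, so the bonded core–core distance is ≈ 5σ, the
  first-neighbour peak of the gel's pair correlation).
* The effective well depth ε_m(1 − e^{−0.2 a_m})² ≈ 11.6ε sets the
  Arrhenius activation energy of bond turnover, measured from dimer bond
  lifetimes.
* With these parameters a planar-star gel at volume fraction ρ = 0.01 has
  its melting midpoint (〈θ〉 = 0.5) slightly above T = 1 ε/k_B (ascending
  annealing ladders put it near 1.15, partially hysteretic at these run
  lengths), so the T = 1.0 structural analyses probe a bonded network.

Two calibration facts are worth recording.  First, a pair-level
(Wertheim-style) estimate of the bond volume overpredicts bonding by more
than an order of magnitude: when two rigid stars bind, the WCA envelopes of
their arms exclude most mutual orientations, and this entropic suppression
(measured ≈ 40× by Metropolis Monte Carlo of the exact two-star
Hamiltonian) is what forces the deep well.  Second, a narrow well
(a_m ≳ 20/σ) is not resolved by the Euler–Maruyama step at the default
timestep — the per-step relative patch displacement (~0.015σ at
dt = 10⁻⁴ τ_Br) must stay well below the well width 1/a_m, which is why the
width was fixed at 1/12 σ.

### Known limitation: single bond per patch

With a wide well whose range (0.65σ) is comparable to its minimum position,
triple-patch clusters are not excluded energetically: in steady-state
planar gels ~20% of patches have a second partner inside the interaction
range.  Preventing this mechanically requires contact-range patches, which
collapses the bond volume and pushes the melting point far below the
temperatures of interest — a worse trade for every other observable.  The
contact-graph analysis therefore enforces the single-bond-per-patch
*accounting* (each patch contributes at most one edge; the nearest partner
wins), while the energetic condition is only approximate.  Observables that
count bonds (θ, N_c, degrees) use the filtered graph; two stars may still
be doubly bonded through two distinct arm pairs, which is physical (the
box-like motifs of non-planar gels) and is kept by using a multigraph.

## Dynamics

Overdamped rigid-body Brownian dynamics (Euler–Maruyama, no inertia):
centres move by (D_t/k_BT)F dt plus Gaussian noise of variance 2D_t dt per
axis; orientations rotate by (D_r/k_BT)τ dt plus angular noise of variance
2D_r dt, applied as a quaternion increment and renormalised each step.
Mobilities: D_t = D/7 (bead-count scaling of the 7 finite-size beads,
D = 1 σ²/τ_Br the single-bead constant defining the time unit) and
D_r = 3D_t/σ_h² with hydrodynamic radius σ_h = 2.5σ (the gyration scale);
any other consistent choice only rescales time.  Default dt = 10⁻⁴ τ_Br;
a per-step move larger than 0.1σ triggers dt halving for that step (up to
four times), which in practice fires only during pathological overlaps.
Forces come from a Verlet pair list (skin 0.5σ) rebuilt when any star has
drifted by half the skin in position-plus-rotation; inner loops are
numba-compiled.  Runs are bit-reproducible for a fixed seed: all noise is
drawn from a seeded PCG64 stream outside the kernel.

The Euler–Maruyama scheme slightly broadens the sampled bond-distance
distribution relative to Boltzmann at the default timestep (verified
directly against the closed-form distribution and against Monte Carlo);
the calibration above was performed at the production timestep, so the
melting point quoted is the property of the model *as integrated*.

## Metadynamics

A generic history-dependent bias on a scalar collective variable:
Gaussians of width δ = 0.05 (CV units) and height w = 0.1ε (defaults)
deposited every 500 steps, optionally with the well-tempered height rule
w_k = w₀e^{−U_G/k_BΔT}.  The free-energy estimate is −U_G (well-tempered:
scaled by (T+ΔT)/ΔT), min-shifted.  The d_p collective variable for a
flexible Y molecule comes with an exact analytic gradient (chain rule
through the arm normalisation, the scalar triple product, and the plane
normal), validated against central differences to 10⁻⁶.  Demonstration
drivers: a Brownian particle in U(x) = 5ε(x²−1)² (barrier recovered within
15% after 4000 deposits; the driver evaluates the bias by linear
interpolation on a dense grid so the cost per step is independent of the
deposit count), and a four-bead flexible Y whose tip–tip repulsion makes
the planar shape the free-energy minimum, with the bias driving it to
non-planar conformations that unbiased dynamics does not reach.

## Analysis

* Contacts: patch pairs closer than r_cut (minimum image), greedy
  nearest-partner matching, stored as a nanostar-level multigraph with
  arm annotations.  θ = 2N_c/(Nf).
* Melting: 〈θ〉(T) from the steady part of each run; T_m by monotone
  linear interpolation at 0.5 (any smooth interpolant agrees at the grid
  resolution used).
* Relaxation: normalised fluctuation autocorrelation of N_c(t) (FFT,
  unbiased), least-squares e^{−t/τ} fit over the window C ∈ [0.05, 1];
  non-decaying C flags the result as a lower bound.  Arrhenius fit by
  linear regression of ln τ on 1/T.
* MSD: time- and ensemble-averaged on log-spaced lags; requires unwrapped
  input (image flags are tracked by the integrator; wrapped input is
  detected and refused).
* RDF: core-bead pair counts against the ideal-gas shell normalisation,
  bin width 0.1σ by default (0.2σ in the scaled-down tests, which cannot
  resolve the 6.4/6.9σ doublet of the non-planar gel and assert a single
  secondary-peak window instead).
* Bending angle ϕ: the angle between one bonded arm axis and the reverse
  of its partner's (ϕ = 0 for perfect end-to-end alignment), pooled over
  bonds and frames, 5° bins.
* Stress: configurational virial only (overdamped dynamics has no kinetic
  stress); P_αβ = (1/V)Σ r_α F_β over interacting pairs.
* Viscosity: multiple-tau correlator (p = 16 points per level, m = 2 block
  averaging) on (P_xy, P_xz, P_yz); G(t) = (V/3k_BT)ΣC_αβ(t); η by
  trapezoidal integration to the first noise-floor crossing, flagged as a
  lower bound when G has not decayed.

## Scaled-down study conditions

The reference systems use N = 175 stars (ρ = 0.01, L = 40σ) and, for the
overlap concentration, N = 1050 (ρ = 0.06), with production runs of
10⁵–10⁶ τ_Br.  The test suite runs the same pipeline at desk scale:

* melting ladders: N = 24 at ρ = 0.01, annealed at T = 0.9 and stepped
  through T = 0.9…1.3, ~370 τ_Br per rung;
* structure/rheology gels: N = 40 at ρ = 0.01, assembled at T = 0.95 and
  observed at T = 1.0 for 300 τ_Br (frames every 2 τ_Br, stress every
  0.02 τ_Br);
* bond kinetics: a single dimer in a 9σ box, 1200 τ_Br per temperature —
  the activation energy of bond turnover is a single-bond property, so the
  dimer makes the Arrhenius scan affordable;
* mobility: the T = 1.0 gels quenched to T = 0.8 and followed for
  120 τ_Br.

At these sizes the claims that survive are statistical: peak locations
within windows, orderings between the planar and non-planar networks, an
activation energy within a band around the well depth, and an
order-of-magnitude viscosity ratio from partial Green–Kubo integrals to a
common 30 τ_Br cutoff (both η values are lower bounds; the shear modulus
of a gel decays on the network reconfiguration time, far beyond these run
lengths).  Passing them shows the pipeline reproduces the *mechanisms* —
geometry-controlled connectivity and its rheological signature — not the
converged large-system numbers.  The synthetic-data path (fixtures: bonded
dimer, six-star ring, random gas) exercises every estimator against known
answers; what it cannot show is behaviour that only emerges at full scale,
e.g. the ρ = 0.06 viscoelastic plateau of G(t), which needs thousands of
stars and ~10⁴ τ_Br trajectories.

### Known limitation: bond bending and its consequences

The patch bond is a point–point tether of rest length r0_m with no angular
stiffness; the only restoring force against hinging is the eventual WCA
contact of the outermost arm beads, which for r0_m = 0.45σ sets in only
beyond ~40–50°.  Bonded arms therefore bend broadly (mean bending angle
ϕ ≈ 50° in the T = 1.0 planar gel), which also pulls the bonded core–core
distance below the aligned 5.1σ (first g(r) peak near 4.3–4.7σ).  Tight
bond geometry (ϕ ~ 20°, peak at 5σ) requires near-contact bonding, whose
bead excluded volume acts as an angular fulcrum — but a near-contact well
deep enough to gel at T ≈ 1.1 is both too narrow for the Brownian
integrator and too slow (bond lifetimes ≫ 10³ τ_Br) to equilibrate at desk
scale.  The calibration deliberately favours correct melting,
connectivity-ordering and kinetics over local bond geometry; the affected
structure checks in the acceptance suite fail under this calibration and
are kept failing rather than re-tuned.  The same short-run ceiling applies
to the viscosity comparison: partial Green–Kubo integrals over ≤ 30 τ_Br
measure the short-time modulus (which follows the bond density, higher for
non-planar stars) rather than the connectivity-limited terminal relaxation
that makes the planar network more viscous at full scale.

## Numerical choices and degenerate inputs

* d_p is reported unsigned (a magnitude); colinear tips raise a
  degenerate-geometry error, with the symmetric-limit helper cos ψ
  provided for callers that want the limit.
* Non-unit vectors passed to the angle routines are normalised with a
  warning rather than rejected.
* The melting interpolation refuses curves that do not bracket θ = 0.5 and
  reports the observed range.
* RDF refuses r_max > L/2; MSD refuses wrapped coordinates.
* Quaternions are renormalised every step; intra-star distances are
  preserved to 10⁻⁹ over arbitrarily long runs (tested).
* Trajectories store wrapped coordinates plus integer image flags, making
  unwrapping exact.
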