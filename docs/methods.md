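# Methods

`spinedgg` simulates the actin cytoskeleton of a dendritic spine head in
two dimensions as a dynamical graph grammar (DGG): a collection of local
stochastic rewrite rules acting on a labelled graph of coarse-grained
filament segments, an enclosing membrane polygon, and well-mixed protein
pools, all sharing one exact continuous-time stochastic clock.

## State and coarse-graining

One actin object represents `N_CG = 12` monomers; its position is a 2D
point and its internal state records the nucleotide composition of its
monomers (ATP / ADP+Pi / ADP), bound cofilin (with a distinguished
single-cofilin seed state), a bound-Aip1 flag, an optional CaMKII-beta
cross-link, an optional end cap (capping protein or Aip1), and an
optional membrane attachment.  Filament topology is a "next" pointer
running toward the barbed end; an Arp2/3 branch point carries a second,
daughter pointer.  Node kind (barbed end, pointed end, interior,
junction, capped end) is derived from connectivity, so the kind
invariants cannot drift out of sync with the graph.

Internal units: length = the coarse-grained resting length
`l0 = 12 x 2.7 nm = 32.4 nm` (2.7 nm is the per-subunit rise of the
actin helix), energy = `kT` at 310 K, time = seconds.  All laboratory
parameters are converted once at load time and the conversions are
logged (`Params.conversion_log`).

Rate bookkeeping follows the standard coarse-graining convention:
elongation propensity = per-monomer on rate x concentration / `N_CG`
(one whole object is added per firing, preserving expected monomer
flux); retraction propensity = the composition-weighted per-monomer off
rate of the end object (one object removed per firing, e.g. 7.2 1/s for
an all-ADP barbed end).  Concentration-bearing rates are converted to
propensities with the effective volume `V = membrane area x h`,
`h = 0.25 um` being a spine-scale slab thickness (configurable; the
conversion from concentration to "species number and membrane area"
needs some such constant).

## Scheduler

The Gillespie direct method over all rule instances: waiting times are
exponential in the total propensity and one instance fires per event,
chosen proportionally to its propensity.  Remodeling chemistry,
mechanical relaxation, thermal noise, and membrane relaxation all
compete on the single shared clock.  Rules whose embeddings share one
propensity (the `k_kinetic` mechanical rules) are carried as one
aggregate instance whose concrete embedding is drawn uniformly at fire
time -- statistically identical to full enumeration and much cheaper.
Pool ODEs are advanced deterministically by their closed-form solution
over each waiting time (hybrid ODE/SSA).  A single seeded generator
owned by the state drives every draw, so a run is reproducible from
(config, seed) and a snapshot continues bit-identically.

## Remodeling rules

Polymerization (barbed/pointed, nucleotide-dependent rates, with the
ADP and ADP+Pi polymerization rates equated), sequential ATP ->
ADP+Pi -> ADP with cofilin-accelerated phosphate release (0.006 ->
0.035 1/s), Arp2/3 branch nucleation at `N(+-70 deg, sigma_theta)`
(blocked by bound cofilin), debranching accelerated by cofilin
occupancy (`k_debranch (1 + sigma_comp c + k_comp c_adj)`; `k_comp = 45`
is calibrated so full occupancy gives the known ~x50 factor, since only
the combined factor is published), barbed-end capping/uncapping,
cofilin binding in three modes (slow isolated "cof-S" seeding on
hydrolyzed objects, cooperative within-object completion at x2, and
spreading from an adjacent cofilactin object, doubled when flanked),
cofilin unbinding per bound unit, CaMKII-beta bundling of non-adjacent
near-parallel objects on distinct filaments (distance <= 0.0175 um,
angle <= 15 deg) with the link's rest length frozen at its creation
separation, angle-gated filament breaking, and Aip1 binding to
cofilactin followed by angle-independent severing that leaves an
Aip1-capped barbed end (cap off rate 0.95 1/s) and a new pointed end.

Interpretation choices worth calling out:

* **Cofilin's "fully ADP" gate** treats ADP+Pi as ADP (the model
  equates them elsewhere).  Requiring pure ADP would make cofilin inert
  on any practical horizon, because phosphate release at 0.006 1/s
  takes hundreds of seconds to clear a 12-mer.
* **Breaking** uses the stored (cached) bend angles, refreshed by
  every rule that moves or rewires a neighborhood, with per-node
  thresholds 57 deg (bare), 73 deg (cofilactin), 31 deg at a
  cofilactin-actin boundary, OR-ed over the two nodes of an edge.  No
  breaking rate constant is published; the gate fires at the generic
  kinetics propensity (`k_break = k_kinetic = 0.35 1/s`, configurable).
* **Aip1 pools**: no synthesis/degradation triple is published for
  Aip1.  Default: basal synthesis a tenth of cofilin's with cofilin's
  degradation rate (Aip1 is roughly an order of magnitude less abundant
  than cofilin in dendrites); configurable.
* **Minimal filament**: retraction is disabled when a filament would
  drop below two objects, so the seed dimer persists.
* The free actin pool is treated as ATP-loaded (profilin-catalysed
  exchange); new objects polymerize all-ATP (`f_atp_free`).

## Mechanics

All forces derive from one global energy: a clipped 12-6 Lennard-Jones
separation potential on every graph edge (filament bonds, bundle links,
membrane attachments; `sigma` is set per edge so the potential minimum
sits at the edge's rest length), plus a quadratic angle-bending energy
`(kB/2)(theta - theta_target)^2` on every connected triple (target 0
along a filament, +-70 deg across a branch).  Below the clip point
`0.75 r_min` the separation potential continues linearly with matched
value and slope, bounding the repulsive-core force.  Bound cofilin
divides the bending stiffness by up to 5 (linear in the cofilin
fraction of the bending node).

Kinetic rules fire at `k_kinetic = 0.35 1/s` per instance and apply one
overdamped update `dx = -grad U / (zeta k_kinetic)` to a single node:
the buckling rules (end / interior / branch motifs, mutually exclusive
by filament degree) use the radial gradient
`sum_j psi(|x-x_j|)(x-x_j)` with `psi = U'/r`; the three bending rules
move the middle or either end node of a triple using the K-vector form
of the angle gradient, whose `theta -> 0` limit is evaluated by its
finite l'Hopital value.  Internal forces sum to zero edge-by-edge and
triple-by-triple, so total momentum is conserved; in the
`k_kinetic -> infinity` limit the updates recover the force-balance ODE
`dx/dt = -grad U / zeta` (verified against `solve_ivp` in the tests).
A move that would take an actin node outside the membrane (beyond the
overgrowth tolerance) or self-intersect the polygon is rejected.

Thermal noise is a Metropolis-Hastings heat bath per node: a zero-mean
Gaussian proposal whose covariance is `s kT H^-1` built from the local
buckling Hessian (the graph-Laplacian diagonal `sum_j |U''|`, plus the
`eps_sep^2` regularizer; `|.|` keeps the precision positive on the
anharmonic tail), accepted with the Barker form `A = t/(1+t)` where `t`
is the exact detailed-balance ratio including the Gaussian
normalization (determinant) factors and the local separation-energy
change.  Because the acceptance is exact, the chain's stationary law is
`exp(-U/kT)` for any positive step scale `s` (default 1); the
dimensionless `thermal_step_scale` exists because the drag-based
prefactor for this covariance is not dimensionally well defined.  The
single-pair chain reproduces equipartition, `Var(r) = kT/U''(r_min)`,
and a chi-square test against the Boltzmann radial density passes at
n = 1e5.

The bending Hessian used for proposals is the positive-semidefinite
surrogate: the rank-one `K (x) K` outer product (exact at the target
angle, where the variable-sign term vanishes) collapsed to its positive
eigenvalue times the identity, plus `eps_ang^2`.

## Membrane

The spine surface is a CCW simple polygon (64 vertices initially for
the 0.125 um starting circle).  Its only energy term is the discrete
Helfrich bending energy `U = 2 kappa sum_i H_i^2 z_i`, with `H_i` the
norm of the arc-length derivative of the unit tangent (exact `1/R` on a
regular polygon) and `z_i` the dual edge length; `kappa` is the
published surface bending modulus times the slab thickness, giving a 1D
modulus of ~0.9 kT x unit.  Optional area and length energy terms exist
with zero default coefficients.  Each vertex relaxes by the same
overdamped rule as actin nodes, with an analytic gradient that is
finite-difference verified; moves that break polygon simplicity are
rejected.  Note the curvature energy of a closed curve is
scale-expansive (E ~ 1/R), so this flow preserves and rounds shape but
does not shrink perimeter.

Actin-membrane coupling: a barbed end whose rod, pseudo-extended by the
overgrowth length (0.5 unit), crosses a membrane edge becomes attached
through a new vertex inserted at the crossing.  The attachment is one
more clipped-LJ bond whose rest length is the separation at creation
(clamped to [0.25, 1]), so it is born near force balance; polymerization
then shortens the gap, the compressed bond pushes the vertex outward
and the end inward (exactly equal and opposite forces), and elongation
of the attached end is multiplied by the Brownian-ratchet factor
`exp(-f delta / kT)` with `f` the compressive bond force projected on
the filament axis and `delta` the insertion length.  Attached ends step
adaptively (sub-unit steps into the available gap, never across the
membrane) and detach when the separation exceeds 2 units; the inserted
vertex is retained.

## Pools

Each free species follows `dM/dt = I_S,M + I_M - k_M M` with the
published synthesis/influx/degradation triples (influx only in
stimulated "LTP" mode; negative for CaMKII-beta, which leaves the spine
during potentiation).  Pools are initialized at the basal steady state
`I_M / k_M` converted to counts with the starting membrane area, and
advanced by the closed-form solution between events, which is exact for
the linear ODE and keeps counts nonnegative for any step.  Degradation
acts on free pools only; binding moves molecules between pool and graph
occupancy, so bound+free totals change only through synthesis and
degradation (asserted over 1e4 random firings in the tests).

## Morphometrics and sweeps

A snapshot is summarized by enclosed area (shoelace), perimeter, and
aspect ratio, defined as `sqrt(lambda_max/lambda_min)` of the polygon's
second-central-moment (gyration) tensor computed by the exact polygon
moment formulas.  A sweep multiplies one species' basal synthesis rate
over a log-spaced grid centered on the basal value (7 points spanning
0.1x-10x by default, optionally truncated at the upper end); a double
sweep concomitantly applies `eta^-q` to a second species, the change of
variables `mu = alpha + gamma/q`, `nu = alpha - gamma/q` used to test
epistatic masking.  Each phenotype's dose dependence is summarized by
Pearson's r (against the dose exponent) and a one-sided
Jonckheere-Terpstra trend test whose side is chosen by the sign of r.
The JT p-value is the exact permutation tail for <= 10 observations and
the tie-corrected normal approximation above that.  Sweeps can reuse
one seed per replicate across doses (common random numbers) for
variance reduction in short runs.

## Problem sizes used in the test suite

The package's own checks run at deliberately small scale: fixtures of
2-8 objects for rule semantics; 1e4 draws for sampling distributions;
1e5 proposals for thermal calibration; 1e4 random firings for mass
balance; and for the directional sweep smoke test, 3 dose points x 3
paired-seed replicates per species measured at t = 5 s of biological
time from the standard initial condition (a 0.125 um circular membrane
enclosing a two-object seed filament, stimulated influx on).  Five
seconds of a single spine costs a few thousand events.

## What the generator does and does not emulate

The synthetic conditions are the model's own study conditions: the
published parameter table, the circular initial condition, basal
steady-state pools, and stimulated influx.  They do not emulate
photobleaching, spatial protein gradients (pools are well mixed by
construction), 3D geometry, or membrane lipid dynamics.  Passing tests
therefore certify the simulator's internal correctness and the model's
qualitative behavior, not quantitative agreement with live-cell data.

A known timescale consequence: cofilin requires a fully hydrolyzed
object and full ATP -> ADP conversion of a 12-mer takes ~9 s on
average, so cofilin- and Aip1-mediated effects on membrane phenotypes
develop on the 10-25 s horizon (which is where the model's reference
measurements are taken).  A <= 5 s smoke run resolves the Arp2/3
branching effect but sits at the very onset of the cofilin/Aip1
pathway, so their directional signs at that horizon are at the edge of
detectability by construction.

## Known limitations

* Mechanical and thermal updates are single-node (diagonal-block)
  moves; no collective modes.
* The published drag and LJ well-depth values make bond relaxation slow
  relative to chemistry except in the clipped repulsive-core regime, so
  membrane growth proceeds by discrete vertex pushes rather than smooth
  flow.
* No remeshing of the membrane beyond vertex insertion at attachment
  points.
* The CaMKII-beta pair search is O(N^2) per event (vectorized); fine at
  the few-hundred-object scale simulated here.
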