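# Methods

## Model

The bulk is a rectangle carrying `n` chemical fields
`u_s(x, t) ≥ 0` that obey reaction–diffusion equations
`∂u_s/∂t − D_s ∇²u_s = R_s(u)`.  Diffusion is isotropic and may differ
between labelled subdomains; each subdomain may also carry its own bulk
reaction system, so reactions can be confined to a compartment (a
biofilm patch inside a well, say).  Cells are point agents: each has a
position, a type, an intracellular concentration vector, its own
reaction network (SRN), and two kinds of coupling reactions evaluated
at the mesh node nearest the cell.  The per-step ordering is fixed:
(1) every cell advances its SRN one `dt`; (2) the bulk
reaction–diffusion system advances one `dt`; (3) transport and membrane
coupling fire at each cell's bound node; (4) cell rules run — division,
death, then an overdamped position update.

## Spatial discretisation

Structured triangulation: an `nx × ny` grid of squares of side `h`,
each split along its lower-left → upper-right diagonal into two
counter-clockwise P1 triangles (area `h²/2` each).  Node indexing is
row-major from the lower-left origin.  The subdomain topology matrix is
stretched to the mesh extent; a node takes the label of the closed
topology cell containing it, with ties resolved toward the lower-left
cell (the matrix fixes labels, not resolution — mesh resolution comes
from the configured domain dimensions and element size).

The stiffness matrix uses exact linear-basis gradients with the element
diffusivity taken from the subdomain of the element's lowest-index
(lower-left) node.  The mass matrix is lumped to the nodal "volume
shares" — one third of each node's incident element areas — which
partition the domain exactly and double as the concentration↔amount
conversion factor for cell coupling.  Reactions are evaluated **at
nodes** on this lumped mass rather than interpolated to interior
quadrature points: for linear elements the two assemblies agree to
discretisation order on smooth fields (checked by the convergence
tests), and nodal evaluation makes the conservation and fixed-point
properties exact rather than approximate.

## Time stepping

IMEX with fixed `dt`: reactions advance explicitly by one classical
RK4 step applied simultaneously to all nodes of a subdomain; diffusion
advances implicitly (backward Euler), one sparse LU solve per species
per step with the factorisation cached.  Zero-flux boundaries are
natural; a nonzero Neumann flux `q` adds a boundary source
`q × (adjacent boundary-edge length)/2` per boundary node, so the
injected mass is exactly `q × perimeter × dt` per step; Dirichlet
conditions replace boundary rows with identity; periodic conditions
fold opposite-edge nodes onto shared unknowns.  The scheme is
unconditionally stable in the diffusion term; `dt` is limited only by
reaction stiffness and accuracy.  Concentrations are clipped at zero
inside every RK4 stage — explicit stepping of stiff kinetics can
undershoot, and the rate laws are only defined for non-negative states.
Non-finite values abort the run with the failure time.

Intracellular networks use the same fixed-step RK4 integrator
(one step per simulation `dt`).

## Reaction grammar and kinetics

One reaction per line, `#` comments:
`law : equation ; name = value, name = value, ...` with `->` / `<->`
arrows, integer coefficients, `+`-separated terms, an empty side for
the empty set, and `spectators = A B` naming species that multiply the
rate linearly (exponent 1 — a documented convention) without entering
the stoichiometry.  Four rate laws are built in — zeroth-order (`k`),
irreversible mass action (`k Π c^ν`), reversible mass action
(`k_f Π_react − k_r Π_prod`, which with an empty reactant side doubles
as the zeroth-order-production / first-order-removal pair), and
Michaelis–Menten (`k_cat E S / (K_M + S)` with the enzyme as first
spectator).  C++-class-style names (`MassActionReaction`,
`ZerothOrderReversibleReaction`, ...) are accepted as aliases, and
`chemistry.register_rate_law` adds user laws.  Species properties
(mass, valence, Gibbs formation energy) are parsed and stored but do
not modify rates; linking them to kinetics is an extension point.

Transport reactions read bulk species on the left and cell species on
the right; the rate is evaluated on the joint state and moves amount
across the membrane, with the bulk concentration change scaled by
1/(nodal volume share) so that `bulk_conc × share + cell_conc` is
conserved exactly for balanced stoichiometries (cells are treated as
unit-volume compartments; units are fixed by this convention and
verified by the conservation tests).  Membrane reactions pair an outer
and inner equation around `|`; one shared rate (mass action over the
union of both reactant sides) advances the outer equation on the bulk
and the inner on the cell, with no exchange.  Multiple cells bound to
one node apply sequentially in cell-id order; updates that would drive
a concentration negative are rescaled to stop at zero.

## Cell rules

Division triggers when any species reaches its max threshold: the
parent keeps a fraction ρ (default 0.5) of every species, the daughter
the rest — totals conserved to machine precision, no additional reset —
and the daughter is placed one mesh spacing away at a uniformly random
(seeded) angle.  Death removes a cell when any species falls strictly
below its min threshold; a zero min threshold never fires.  Motion is
passive shunting: pairwise Hookean springs with rest length cutoff/2
act below the cutoff distance, integrated overdamped with unit drag,
and positions are clamped to the domain.  Forces are equal and
opposite, so the population's centre of mass moves only through
boundary clamping.

## Exemplars and the synthetic-data generator

`write_exemplar` emits complete model directories; they are the
package's test corpus and the reproduction targets.

* **fisher_kpp** — `{D, r, κ} = 1`, a one-unit strip of invader at the
  left edge of a 100 × 10 domain (propagation along x), zero-flux
  boundaries; logistic growth is encoded as the mass-action pair
  `U → 2U` (rate r) and `2U → U` (rate r/κ).  Front measurement: the
  mid-height (U = κ/2) level-set position on the mid-domain slice,
  linearly interpolated, speed fitted by least squares over the last
  half of samples to skip the accelerating transient.
* **schnakenberg_oscillation / schnakenberg_pattern** — the two-species
  production/interconversion/removal network at the oscillatory
  (k₁ = 0.5, k₋₁ = 2.2, k₂ = 1.5, k₃ = 1.0, D_U = D_V = 0.5, start
  (0.91, 1.67)) and patterning (k₁ = 0.1, k₋₁ = 1.0, k₂ = 0.9,
  k₃ = 1.0, D_U = 1, D_V = 40, start (1.0, 1.0)) parameter sets, on a
  100 × 100 domain with zero-flux boundaries and seeded
  Uniform(−1, 1) nodal perturbations of the initial values (clipped at
  zero).  The steady state is U* = (k₁+k₂)/k₋₁, V* = k₂/(k₃U*²); the
  Hopf point solves trace J = −k₋₁ + 2k₂/U − k₃U² = 0 (strictly
  decreasing in U, so the positive root is unique; Brent bracketing,
  tolerance 1e-10, determinant checked positive); the Turing band is
  the positive-root interval of D_U D_V q⁴ − (D_V f_U + D_U g_V) q² +
  det J.
* **cooperator_cheater** — two cell types on a 20 × 20 domain with
  diffusing `{E, S, ES, O₂}`.  The intracellular network (complex
  hydrolysis, catabolism, reversible respiration, biomass synthesis,
  enzyme synthesis) uses rate constant 1 throughout except the
  enzyme-synthesis step, which is 0 in the cheater.  Bulk chemistry is
  enzyme–substrate binding `ES ⇌ E + S` and enzyme decay `E → ∅`;
  substrate and oxygen are replenished by Neumann influx (0.1).  The
  quantitative defaults are *synthetic* — the published description
  leaves them open — and were chosen once for a secreted-hydrolase
  regime in which the public good stays local: the enzyme and complex
  diffuse slowly (D = 0.01) against D = 1 for the small molecules,
  binding is tight (association 5, dissociation 0.05), decay slow
  (0.01), complex uptake fast (5).  Cells start with a minimal internal
  substrate store (0.1) and the producer with a standing enzyme stock
  (0.3): the enzyme-synthesis pathway needs precursor, precursor needs
  substrate, and substrate uptake needs the enzyme, so some standing
  stock is required to close the loop, and a large shared store would
  instead hand the non-producer (which skips the synthesis cost) a
  transient growth advantage that masks the cooperative dynamics at
  practical run lengths.  Division triggers at biomass 1.0 with a
  symmetric split; the emitted config carries the long published end
  time, while the test suite and analyses run a scaled 150-time-unit
  version (dt = 0.02) in which the qualitative behaviour — enzyme
  localised around producers, producers growing at least as fast as
  non-producers by mid-run — is already established.

What the exemplars do **not** emulate about real systems: kinetics are
deterministic and continuous (no molecular noise, no stochastic
division timing), cells are volumeless points with purely passive
motion, and the toy metabolism conserves its carrier pools only up to
division dilution.  Passing tests therefore certify the numerics and
the coupling bookkeeping, not biological parameter realism.

## Numerical choices and problem sizes

Defaults: `dt = 0.01`, `h = 1.0` where a model does not specify them;
sampling every `dt` unless a sampling interval is given; sparse LU
(SuperLU) with library-default pivoting for the implicit solves; seeded
`numpy` Generator streams for every random draw (initial perturbations,
daughter placement), seed 0 by default and configurable.  Verification
runs use reduced problem sizes chosen as the package's own test
protocol: the front-speed run uses `h = 0.5, dt = 0.01` to `t = 40` on
the 100-long axis; the patterning run a 50 × 50 domain at `dt = 0.05`
to `t = 200`; the convergence sweep a 3 × 3 grid of
`h ∈ {2, 1, 0.5} × dt ∈ {0.2, 0.1, 0.05}` on a 60 × 2 strip to
`t = 20`, scored as the RMS difference against the first-order
traveling-wave expansion after aligning mid-heights (scores capped at
0.5; failed runs report 1.0).

## Known limitations

2D only; structured meshes only; no Gauss-point reaction assembly (see
above); no stochastic kinetics, SBML, thermodynamic rate corrections,
or active motility laws; juxtacrine (cell–cell contact) transport is
not represented; membrane/transport coupling supports the built-in
rate laws but not user-registered ones.  The reaction grammar pins
conventions (case-sensitive tokens, integer coefficients, linear
spectators) that the file format's prose description leaves open.
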