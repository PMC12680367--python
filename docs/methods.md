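# Model and methods

## Governing equations

All dynamics are overdamped (inertia neglected): velocities are forces
divided by damping coefficients.

**ECM.** The matrix is a graph of crosslinks (nodes) and fibres (edges)
built from the Voronoi tessellation of uniformly random seed points; edge
lengths at generation become the rest lengths, so networks start load-free.
Voronoi networks have nodal connectivity 3, typical of fibrous gels, and no
preferred orientation. A fibre of rest length `L0` carries a signed axial
tension `E_t·A·s` for strain `s = (ℓ−L0)/L0 ≥ 0` and `ρ·E_t·A·s` when
compressed (buckling approximated by the reduced modulus `ρ·E_t`). With
1 Pa = 1 pN/µm², `E_t [Pa] × A [µm²] × s` is a force in pN. Crosslinks obey
`η_e dx/dt = F_el + F_ec`; crosslinks on the domain boundary are pinned
(fibres crossing the boundary are clipped there and the cut point pinned).

**Cells.** A cell is an organising centre plus vertices joined to it by
Kelvin–Voigt segments; harmonic angle springs `½k_ang(θ−θ0)²` act between
consecutive segments (forces are the exact analytic gradient, so internal
forces sum to zero and the dynamics conserve momentum). Contraction applies
a constant-magnitude force `F_co` from each vertex toward the centre; the
centre receives minus the sum of all structural and contractile vertex
forces. The Kelvin–Voigt dashpot acts on the segment elongation rate, which
makes cell velocities implicit; the per-cell linear system (a few degrees of
freedom) is solved exactly at every right-hand-side evaluation.

**Adhesions.** A focal adhesion links one vertex to one crosslink through
`N` parallel integrin springs with common extension
`ε = ‖x_vertex − x_crosslink‖ − L0_i`. The bound count `N_b ∈ [0, N]` is a
continuous mean-field variable with constant on-rate `K_on` and catch–slip
off-rate `K_off(F_i)` evaluated at the tensile per-integrin force
`F_i = k_i·max(ε, 0)` (compressed integrins push but do not unbind faster).
The cluster force `N_b·k_i·ε` acts on the vertex and, with opposite sign, on
the crosslink. An adhesion whose `N_b` falls below one integrin detaches
permanently (no de novo adhesion formation).

**Reduced adhesion system and bifurcation.** Under a constant external load
`ℱ` the pair `(ε_b, N_b)` obeys `η dε_b/dt = −2k_i N_b ε_b + ℱ` coupled to
the binding equation. The fold (saddle-node) satisfies
`k_i ε·K_off′ = K_on + K_off` at `F = k_i ε`; the implicit equation is
solved by bracketed root finding on the slip side of the off-rate minimum,
after which `N_b^BP/N = K_on/(K_on+K_off)` and `F_BP = 2k_i ε_BP N_b^BP`
follow in closed form. `ε_BP` and the bound fraction depend only on the
kinetic constants; `F_BP` is proportional to `N`.

## Metrics

- **Orientation tensor** at a crosslink: `Θ = Σ p⊗p / Σ‖p‖²` over incident
  fibres with `p = (x_m − x_l)/L0`. Alignment angle = principal eigenvector
  direction folded to (−90°, 90°]; anisotropy `σ_al = 1 − λ_min/λ_max`.
  Crosslinks with fewer than two incident fibres are excluded; an exact
  eigen-tie reports `σ_al = 0` with a degeneracy flag.
- **Region statistics**: mean and bias-corrected Fisher–Pearson skewness of
  `σ_al` over crosslinks inside a polygon, histograms (18 angle bins, 20
  anisotropy bins), and Welch's unequal-variance two-sided t-test for
  before/after comparisons (pooled-variance variant available). Because
  contraction piles probability mass toward `σ_al → 1`, the skewness becomes
  more negative as the region aligns. The dominant direction of an angle
  sample is estimated as the circular mean of doubled angles (axial data),
  which is the stable estimator of the histogram's central tendency on the
  broad distributions that moderate deformations produce.
- **Percolation path**: fibres count as stress-carrying when their length
  exceeds the length recorded at the start of contraction by a relative
  `10⁻⁴`; their tensile stress is `σ = E_t(ℓ−L0)/L0`. On this subgraph,
  Dijkstra's algorithm minimises `Σ 1/σ` (equal-cost ties broken toward the
  lexicographically smallest node sequence, for reproducibility). Reported:
  total and mean path stress, geometric path length, and tortuosity
  (end-to-end distance over path length, in (0, 1]). The `10⁻⁴` threshold
  separates mechanically loaded fibres from the far tail of numerically tiny
  elongations: genuine transmission paths in all scenarios studied carry
  strains above `10⁻³`, while the quasi-static far field and integrator
  tolerances produce ubiquitous sub-`10⁻⁴` length changes that would make a
  "path" exist trivially.

## Numerical methods

Scenario initialization places each cell, adheres every vertex to the
nearest free crosslink within a capture radius (default 2× the mean fibre
length in the named scenarios), positions the vertex one integrin rest
length from its crosslink, and re-sets the cell's rest lengths and natural
angles to the attached geometry. The coupled passive state is therefore
load-free by construction — fibres carry no initial load — and a guarded
L-BFGS energy minimisation (gradient = −forces) enforces the relaxed start
below a force tolerance (default 1 pN), iterating `N_b` to its binding
equilibrium. Initialization is deterministic for a fixed seed.

Time integration uses scipy's BDF with an explicit Jacobian sparsity pattern
(network adjacency + per-cell blocks + adhesion couplings), `rtol = 10⁻⁵`,
`atol = 10⁻⁶`, which handles the stiffness range from kPa to 100 MPa fibre
moduli. Detachment events terminate the current integration segment via a
root-finding event on `N_b − 1` (downward crossing); the adhesion force is
removed from both coupled equations and integration restarts at the event
time. A fixed-step Heun integrator (`step`) is provided for convergence
checks. Pure-network relaxation (`relax_network`) uses forward Euler with an
adaptive step bounded by `0.2·η_e/k_max` and energy-descent step rejection.

Contraction activates through a 1 s linear ramp and is constant thereafter.
A true step input would transmit a damping-ratio-determined fraction of
`F_co` through the adhesion instantaneously as viscous drag, putting a
parameter-artifact spike at the top of every force curve; the ramp
(physically, myosin recruitment is not instantaneous) leaves the force
build-up to the mechanics.

## Parameters

The mechanical constants are reconstructions chosen once and flagged as such
in the configuration; they are not published values.

| parameter | default | unit | rationale |
|---|---|---|---|
| `E_t` | 10⁴–10⁸ (scenario) | Pa | span from soft gels to stiff collagen |
| `ρ` | 0.1 | – | buckled fibres resist weakly |
| `A` | 0.01 | µm² | collagen-fibril scale (~56 nm radius) |
| `η_e` (ECM) | 2000 | pN·s/µm | sets ECM transmission times of O(0.1–10 s) |
| `η_c` (cell) | 10⁴ | pN·s/µm | cell contracts over ~1 s |
| `k_seg` | 1.5·10⁴ | pN/µm | isolated cell with F_co=2·10⁴ pN contracts ~13% of its radius |
| `γ_seg` | 4·10³ | pN·s/µm | Kelvin–Voigt dashpot, smooths segment dynamics |
| `k_ang` | 10⁴ | pN·µm/rad | maintains polygonal shape |
| `K_on` | 0.5 | 1/s | binding slower than stretching |
| `k_c`, `F_c` | 0.5, 30 | 1/s, pN | catch pathway |
| `k_s`, `F_s` | 0.05, 30 | 1/s, pN | slip pathway; off-rate minimum at 55 pN |
| `k_i` | 10³ | pN/µm | effective integrin-complex stiffness |
| `L0_i` | 0.02 | µm | integrin rest length |

With these values `F_BP = 65.8·N` pN (N = 857 → 5.6·10⁴ pN), the zero-force
bound fraction is 0.48, and the binding relaxation time (~1 s) exceeds the
integrin stretch time (~10 ms) as the scale separation requires.

The damping constants for ECM and cells are configured separately although
the governing equations use one symbol. With a single shared constant, the
onset of contraction transmits roughly half of `F_co` through the adhesion
instantaneously as viscous drag on the crosslink, which swamps the elastic
force build-up that the model is meant to resolve; a crosslink's drag
against the surrounding medium is plausibly much smaller than the effective
friction of a whole cell body.

## Scenarios and problem sizes

Named scenarios reproduce the study configurations at desk scale: the
two-elongated-cell scenario keeps the 80 µm cell separation on a
120×120 µm domain with 500 Voronoi seeds (~1000 crosslinks); the single
round cell uses 350 seeds on 100×100 µm at matched density. Sweeps default
to 5 random-network realizations. Sparser networks sit deep in the floppy
(sub-isostatic) regime of central-force Voronoi networks, where the force
response is strongly superlinear and peak-timing statistics are
noise-dominated; central-force networks have no bending stiffness, so some
floppiness is inherent at any density.

The simplified-topology scenarios (zigzag path vs rungs-coupled double rail,
both pulled apart with `F_pu = 3.5·10⁴ pN`) use `N = 1200` integrins per
adhesion, an initial bound fraction of 0.25 (below both the zero-force
equilibrium and the saddle), and stiff, lightly damped cells
(`k_seg = 2·10⁵`, `η_c = 2·10³`) so the ECM topology — not the cell body —
sets the adhesion loading rate. Geometry (zigzag pitch 2 µm, amplitude 8 µm,
10 segments, pinned 10 µm laterals; ladder with 4 rungs spaced 8 µm, rail
gap 4 µm) is parameterised, with defaults placing the quasistatic
detachment threshold (`F_BP/2 ≈ 3.95·10⁴ pN`) just above `F_pu`: detachment
can then only happen dynamically, when a stiff topology loads the adhesion
faster than integrin binding can recruit.

## What the synthetic scenarios do and do not show

The generator emulates random fibrous gels with low connectivity, load-free
initial states, and cells adhering at discrete vertices. It does not emulate
fibre bending stiffness, crosslink remodelling or rupture, strain-stiffening
beyond the bilinear law, three-dimensional geometry, cell migration, or
adhesion re-formation after detachment. Passing tests therefore demonstrate
the internal consistency of the model and the qualitative phenomenology
(force build-up and relaxation, alignment between contracting cells,
stiffness-dependent percolation, topology-induced detachment), not
quantitative agreement with any particular experimental system.

## Known limitations

- The adhesion-force rise time is limited by the cell's damped contraction
  against the network's effective stiffness, which grows with `E_t`; the
  stiffest networks therefore reach their (larger) force peak slightly
  later rather than earlier. A regime where ECM transmission is
  rate-limiting at all stiffnesses was incompatible with the frozen-soft-
  network behaviour and the strong stiff-network realignment under a shared
  parameter set.
- Mean-field `N_b` is invalid for small integrin counts; no stochastic
  binding is implemented.
- The percolation "stretched" classification needs the `10⁻⁴` relative
  threshold described above; results are insensitive to its exact value
  within an order of magnitude in either direction.
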