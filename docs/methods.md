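# Methods

`actomyo` is an agent-based Brownian-dynamics model of thin actomyosin
networks: actin filaments, two-armed transient cross-linkers (ACPs, modeled
on filamin), and myosin-II thick-filament ensembles, all represented as
interconnected cylindrical segments in a rectangular slab that is periodic
along y and walled in x and z.  Motor walking transforms an initially
homogeneous network into a contractile bundle aligned with y; the package
measures the tension the bundle transmits, how fast and how tightly the
network compacts, filament buckling, and orientation sorting.

## Mechanics

Every element endpoint obeys the overdamped Langevin equation

    zeta_i dr_i/dt = F_i + F_i^T,

integrated by explicit Euler at a fixed time step dt = 1.5e-5 s.  The
thermal force is Gaussian with `<F^T F^T> = 2 kBT zeta / dt` per component
(fluctuation-dissipation); Gaussianity is a modeling choice, the theorem
fixes only the second moment.  Drag coefficients use the cylinder
approximation `zeta = 3 pi mu rc (3 + 2 r0/rc)/5`.

Deterministic forces derive from harmonic potentials:

- extension: `U_s = 1/2 ks (r - r0)^2` for actin segments (r0 = 140 nm),
  ACP arms (23.5 nm), motor backbone segments (42 nm), and the motor arms'
  transverse spring (13.5 nm);
- bending: `U_b = 1/2 kb (theta - theta0)^2` at actin joints, the ACP
  hinge, and motor backbone joints, with all theta0 = 0 (straight);
- actin-actin volume exclusion: `U_r = 1/2 kr (r12 - rc)^2` when the
  minimum distance r12 between two segments falls below the actin
  diameter rc = 7 nm, zero otherwise.  Nearest-neighbor segments of one
  filament are excluded (their spacing is already set by the bonded terms);
- walls: harmonic restoring force on points beyond the x or z boundary.

Forces exerted at points interior to a segment (arm attachments, repulsion
closest points) are lever-distributed onto the segment endpoints in
proportion to the arc position, so the force and torque on the segment are
preserved.  The bending force uses the `theta/sin(theta)` regularized exact
gradient, smooth through theta = 0 and clamped within 1e-8 of theta = pi.
Each motor arm additionally carries a longitudinal spring of zero rest
length that penalizes the component of the arm vector along the bound actin
segment's axis, keeping arm and track perpendicular; its force is evaluated
with the current axis direction held fixed (the small torque from axis
rotation is neglected), so the exact-gradient guarantee applies to the
extension/bending/repulsion terms only.

## Parameter choices

Printed reference values are used directly: segment geometry (140 / 23.5 /
42 / 13.5 nm, 7-nm binding-site spacing), dt = 1.5e-5 s, C_A = 40 uM, ACP
unbinding (k0 = 0.115 1/s, lambda = 0.104 nm), motor anchors (140 nm/s,
5.7 pN, 0.049 1/s, 40 x 8 = 320 1/s arm binding), turnover rates
30-120 1/s, and the 4 x 8 x 0.5 um domain.

The remaining stiffnesses and the medium viscosity are this package's own
parameterization, chosen once under three constraints: (i) the actin
bending stiffness must reproduce the filament persistence length, so
`kb_A = Lp kBT / r0 = 9000 * 4.114 / 140 = 264.5 pN nm/rad^2` exactly;
(ii) the explicit Euler scheme must be stable at the fixed dt, which bounds
every stiffness/drag ratio (`k dt / zeta < ~0.25` for the stiffest
connection of any point class); (iii) motor stall forces (~6 pN) must
produce sub-segment spring extensions.  This gives ks_A = 1 pN/nm for actin
and motor backbones, 0.25 pN/nm for ACP arms and motor arm springs,
kr = 1.63 pN/nm (so a half-diameter overlap resists with ~f_stall), wall
stiffness equal to ks_A, and an effective medium viscosity of 0.5 Pa s
(coarse-grained cytoplasm; also what makes local bending modes of a
filament equilibrate in ~10 ms, so persistence-length estimates converge
within seconds of model time).  The drag diameter of actin is 7 nm; ACP
hinges carry the whole two-armed linker, motor points a 42-nm backbone
segment, both with 10-nm diameters.

Molecule counts: R_ACP and R_M are molar ratios to actin monomers.  One
actin segment books 52 monomers (140 nm / 2.7 nm rise, rounded); one motor
ensemble represents 8 arms x 8 heads = 32 two-headed myosin molecules.

## Kinetics

Events are sampled per kinetics interval (default 10 integration steps for
library calls, 40 in the bundled scenario presets; every stated rate k
satisfies k dt << 1 even at the longer interval) with probability
`1 - exp(-k dt)`:

- ACP arms bind to unoccupied 7-nm sites.  First arms of implicit-pool
  ACPs land on uniformly drawn sites (well-mixed pool); the dangling second
  arm binds only to sites on a *different* filament within a capture radius
  (arm length + 10 nm), forming a functional cross-link.  Unbinding follows
  the Bell slip bond `k = k0 exp(lambda |F_s| / kBT)` for stretched arms
  and k0 for compressed ones; arms losing their site (depolymerization)
  are force-released, and fully detached ACPs return to the pool.
- Motor arms bind at 320 1/s within a capture radius of their backbone
  anchor and walk in 7-nm steps toward the barbed end, blocked by occupied
  sites and at the terminal site.  Walking and unbinding rates depend on
  the longitudinal-spring force projected on the barbed direction
  (positive = resisting): `k_w = k_w0 (1 - f/f_stall)` clipped at zero, and
  a single-exponential catch bond `k_u = k_u0 exp(-lambda_M f / kBT)`
  (lambda_M = 1 nm) that slows unbinding up to stall.  The full
  mechanochemical cycle behind these rates is not modeled; the parametric
  form is anchored to the three printed set points (140 nm/s, 5.7 pN,
  0.049 1/s), and `MotorRateModel.from_table` accepts tabulated
  (F, k_w, k_u) curves as a drop-in replacement.  Assisting loads beyond
  4 pN release the arm immediately; the threshold sits ~4 thermal standard
  deviations of the spring force (sqrt(kBT ks) ~ 1 pN) below zero so
  thermal jitter does not shake arms off, while genuinely pushed arms let
  go at once.  A lower-duty-ratio motor variant (stall 5.3 pN, unbinding
  0.49 1/s) is provided as a preset.

## Actin turnover

Treadmilling adds one segment at the barbed end and removes the pointed
segment at equal reference rates, drawing on and returning to a conserved
monomer pool.  The turnover rate is specified in monomers per second (the
physiological 30-120 1/s range of actin end kinetics); since one event
moves a whole 52-monomer segment, segment events fire at k_t/52 per end,
giving a ~10 s turnover time for a 1.56-um filament at k_t = 60 1/s.  Removal of a pointed segment that carries any
bound arm is slowed by the inhibition factor: `k_d = k_d0 (1 - xi)`,
xi in [0, 1].  Released arms count as unbinding events.  A proportional
controller keeps the mean filament length at its 1.56-um target by
nucleating single 140-nm segments (oriented +/-y, positioned near existing
actin) at a rate proportional to the fractional length excess; the gain (4
per filament per unit fractional excess, times the turnover rate) is set
high because roughly half of all one-segment nuclei depolymerize before
their first growth step, and at this gain the closed loop holds the mean
within ~15% of target at k_t = 60 1/s.

## Network assembly

Assembly produces the homogeneous pre-contraction state: filament count and
per-filament segment counts (roughly exponential, mean 11 segments
= 1.54 um) consume the monomer budget implied by C_A and the domain volume;
each filament grows from a seed direction drawn from the requested
orientation spec (isotropic, +y cone, quadrant/half-plane biases, ...) with
joint angles sampled directly from the equilibrium Boltzmann bend
distribution and bond lengths from the equilibrium extension distribution
— the exact stationary ensemble of an isolated filament, obtained without
integrating.  Growth reflects off the x/z walls.  Motor backbones are
placed uniformly with random in-plane orientation.  A short dynamic phase
(default 0.5 s) with thermal motion and binding on but walking off then
forms cross-links and docks motor arms; the clock is reset to zero when
walking starts.  Orientation-biased networks ("+y", "+x/+y", "+x/±y",
"±x/+y", ...) differ only in the seed-direction ranges.

## Measurements

- **Bundle tension**: 10 cross-sections normal to y, regularly spaced.
  Every force-carrying element (actin bond, ACP arm, motor backbone bond,
  motor transverse and longitudinal spring) whose endpoints straddle a
  plane (minimum image in y) contributes the axial component of its
  extensional force, positive when stretched; the reported tension is the
  mean over sections.  A relaxed network reports zero; a uniformly
  strained spanning filament reports exactly `ks delta` (oracle test).
- **Microscopic forces**: per bound ACP arm, the extensional force
  projected on the bound filament's pointed-to-barbed unit vector; per
  motor arm, the longitudinal-spring force so projected, divided by the 8
  heads per arm.  Positive values point toward the barbed end.
- **Compaction**: sigma_x is the population standard deviation of all
  actin endpoint x positions.  The compaction time is the first time,
  after a baseline window (default 5 s; reduced-scale analyses use
  shorter windows, stated per run), at which the moving-linear-fit rate
  of change of sigma_x exceeds 1% of its baseline-window mean; the sigma_x
  value there is sigma_x^c.  Series whose baseline rate is not negative
  are flagged "not reached".
- **Buckling**: a filament is buckled in a frame when its end-to-end over
  contour ratio (computed on y-unwrapped coordinates) is strictly below
  0.6; the census reports both filaments-ever-buckled and per-frame
  counts.
- **Orientation**: filament orientation is the pointed-to-barbed
  end-to-end unit vector; the antiparallel fraction counts pairs with
  negative orientation dot product among pairs whose midpoints lie within
  250 nm (configurable).
- **Sustainability**: mean tension over the final quarter of a run divided
  by the peak recorded tension, clipped to [0, 1]; runs without positive
  peak are flagged.  The specific window is a package choice and is
  isolated in one function so alternatives can be swapped in.
- **Persistence length**: `Lp = -a / ln <cos theta>` from the
  time-and-ensemble average of adjacent tangent cosines of a free
  filament, with a = 140 nm; for the reference stiffness the discretization
  bias is below 1%.

## Problem sizes and reproducibility

Full-scale runs (4 x 8 x 0.5 um, ~7,400 actin segments) reproduce the
original geometry and are exposed through the `reference` preset; they are
overnight-scale on one core.  The bundled analyses and tests use
reduced-scale presets (1 x 2 x 0.15 um, ~140 segments, 3-6 s of model
time, densities unchanged) chosen so that each condition runs in minutes;
at this scale trend directions (orderings between conditions) are the
meaningful output, not absolute magnitudes.  Every run is driven by a
single seeded PCG64 stream covering assembly, thermal forces, and kinetic
events, so trajectories are bitwise reproducible given (state, seed,
schedule); checkpoints store the RNG state and round-trip exactly.

## What the reduced-scale conditions do not show

Small domains have few filaments per cross-section, so tension series are
spiky (single-element crossings dominate) and compaction statistics carry
large seed-to-seed variance; wall effects are proportionally stronger; and
3-6 s windows capture bundle formation but not long-time bundle
maintenance.  Conclusions at this scale are restricted to directions of
change between conditions.  The model itself omits, by design: filament
severing and annealing, branching nucleation, capping, excluded volume for
ACPs and motors, hydrodynamic coupling between segments, and explicit
per-head motor mechanochemistry.

## Numerical notes

- Explicit Euler with the parameterization above runs at ~5x safety from
  the stiffest relaxation time; a displacement guard reports the largest
  single-step move and non-finite positions abort the run with
  diagnostics.
- Coincident spring endpoints (r < 1e-9 nm) are separated along a fixed
  axis; overlapping segments at exactly zero distance repel along +x.
- The repulsion neighbor list is rebuilt on every topology change and
  every 10 kinetics passes with a 30-nm margin over the geometric cutoff;
  a midpoint early-exit inside the kernel skips far pairs.
- Binding searches prefilter segments by midpoint distance (vectorized)
  before per-site tests; at most one site is accepted per arm per
  interval, chosen uniformly among the Bernoulli successes.
- Walking moves that change only an arm's attachment update the flattened
  force tables in place; bind/unbind/turnover events trigger a rebuild.
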