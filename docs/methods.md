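# Methods

`toxkil` simulates an evolving population of lattice bacteria that can
produce an anticompetitor toxin, be resistant to it, and regulate either
trait by a secreted total-cell-density cue. This note documents the model,
the unit conventions, the numerical choices, and what the synthetic test
beds do and do not establish.

## Model

**Cells and genotypes.** Cells occupy at most one site of an N x N lattice
with periodic boundaries. A genotype is a toxin gene and a resistance
gene, each Off / On / Reg(ulated), plus a toxin production rate
`pi_T in [0, 1]` and — whenever at least one gene is Reg — a response
threshold `theta >= 0`. Gene pairs that could ever express toxin without
resistance ((On,Off), (Reg,Off), (On,Reg)) are nonviable: mutants of that
kind are discarded at birth. The six viable pairs are (Off,Off), (Off,On),
(Off,Reg), (On,On), (Reg,On) and (Reg,Reg).

**Fields.** The cue is produced by every cell at rate `p_cue`, the toxin at
rate `pi_T` by cells currently expressing their toxin gene. Both molecules
degrade (rate `d`) and diffuse (rate `D`) much faster than cells divide,
so each time step the quasi-steady state of

    P - d c - 4 D c + D (c_north + c_south + c_east + c_west) = 0

is solved exactly on the torus by elementwise division in Fourier space
(the production pattern transformed with `rfft2`, divided by the cached
transform of the degradation–diffusion kernel, and inverted). The solver
is checked against a direct sparse solve of the explicit N^2 x N^2 system
and satisfies mass balance (`d * sum(c) = sum(P)`), positivity, linearity
and translation equivariance to 1e-8.

**Phenotypes.** Each step every cell senses its local cue concentration.
On genes express always, Off never, Reg iff cue >= theta. (Reg,Reg) cells
additionally wait out a delay of `tau_delay` consecutive above-threshold
steps (default 50) between expressing resistance and toxin, so clone mates
with marginally lower cue readings are not killed. Two optional
perturbations: i.i.d. Gaussian sensing noise per site (clamped at zero
concentration), and an expression lag — the realised phenotype follows the
instantaneous target only after the target has persisted for `lag_steps`
consecutive steps (the counter resets if the target reverts; newborns
adopt their target immediately at their first update).

**Demography.** Cells die with probability
`delta + (1 - phi_R) * delta_tox * c_tox` (clamped at 1). Every empty site
then fills with probability `1 - exp(-(gamma/8) * sum R_i)` over its eight
Moore neighbours, the parent drawn proportionally to its reproductive
fitness `R = max(0, 1 - phi_T (C_T0 + b_T pi_T) - phi_R C_R - phi_C C_C)`.
Births are resolved synchronously; a parent may seed several empty sites
in one sweep. Within a step the order is: optional position shuffle
(well-mixed control) -> cue solve (+noise) -> phenotype update -> toxin
solve -> deaths -> fitness of survivors -> births into all currently empty
sites (including sites emptied this step) -> offspring mutation/placement.
The ordering is a design choice (freshly emptied sites are immediately
contestable and each molecule is solved once per step); the underlying
update rules do not pin it down.

**Mutation.** On reproduction each gene independently gains
(Off->On, Off->Reg, On->Reg, each `mu_gain = 5e-5`) or loses
(On->Off, Reg->Off, Reg->On, each `mu_loss = 5e-4`) function; at most one
transition fires per gene (the two options are disjoint slices of one
uniform draw — exact to O(mu^2)). `theta` and `pi_T` each mutate with
probability `mu = 5e-4`: uniform within +-`sigma_mu = 0.05` of the parent
value, clamped below at 0, except with probability `p_largemut = 1e-3`
resampled uniformly on [0, 1]. A child gaining its first Reg allele draws
`theta ~ U[0,1]`; a child gaining a toxin gene from a toxin-Off parent
draws `pi_T ~ U[0,1]` (the latter mirrors the stated rule for theta).
`pi_T` is carried and mutated by all cells but expressed only when
`phi_T = 1`; `theta` is carried only by Reg-bearing cells.

## Parameters and unit conventions

Behaviour is fully determined by six lumped parameters:
`L_cue = sqrt(2 D_cue / d_cue)` and `L_tox` (profile length scales, lattice
sites), `R0_inv = delta/gamma` (inverse of the maximal expected offspring
number; a cost-free population equilibrates at density `1 - R0_inv`),
`bT_hat = gamma d_tox b_T / delta_tox` (scaled toxin-cost slope), and the
costs `C_R`, `C_C`. Expanding them into raw rates requires conventions,
chosen once:

- `gamma = ln(2)/10` per step, so the minimal doubling time is ~10 steps
  (5 steps of expression lag then equal half a doubling time);
- degradation rates `d_cue = d_tox = 1` per step, so `D = L^2/2`;
- `p_cue = d_cue`: a fully occupied lattice yields cue concentration 1;
- per-cell toxin production `pi_T * d_tox`: a fully producing lattice
  yields toxin concentration `pi_T`;
- `delta_tox = gamma`, which collapses `b_T = bT_hat`.

Any equivalent convention (e.g. doubled degradation rates with the kill
slope rescaled to keep `bT_hat` fixed) leaves every death and birth
probability unchanged; the test suite asserts bit-identical trajectories
for such a pair. Absolute time and concentration scales are conventions
only; comparisons with other implementations should be made through the
lumped parameters.

Default sweep ranges: `L_cue in [2,20]`, `L_tox in [2,38]`,
`R0_inv in [0,0.5]` (carrying capacity at least 50%),
`bT_hat in [0.01,0.8]`, `C_R in [0.01,0.25]`, `C_C in [0.01,0.1]`; fixed
block as listed above. Sweep points are sampled independently and
uniformly per coordinate.

## Regimes and experiments

- **Fixed habitat**: 10% random occupancy with uniform-random viable
  genotypes (`theta`, `pi_T ~ U[0,1]`), run undisturbed (reference
  protocol: 400,000 steps on a 512 lattice).
- **Serial transfers**: growth cycles of `tau_transfer` steps (default
  500; optionally geometric with that mean, minimum 1), after each of
  which `n_founders` (default 1000) cells are sampled uniformly without
  replacement and placed at random sites of a fresh lattice; delay/lag
  counters reset on transfer. End-of-cycle abundances are recorded per
  cycle (within-cycle population sizes vary enormously).
- **Well-mixed control**: cell positions are uniformly re-permuted every
  step, destroying all spatial structure.
- **Single colony**: one founder of a constructed genotype at the lattice
  centre, grown for one cycle without mutation; per recorded step the
  colony's edge cells, radius and cue levels are measured.
- **Strip invasion**: a 20-column strip of an invader strain in a resident
  background drawn site-wise Bernoulli at the resident's carrying-capacity
  density; run without mutation, recording per-step strain counts.

**Carrying capacity of a resident strain** is the mean-field fixed point
`K = 1 - delta / (gamma R(K))`, where `R(K)` is the strain's fitness at
the phenotype it expresses when the cue equals `K`; this recovers
`K_S = 1 - delta/gamma` for sensitives and
`K_R = 1 - delta/(gamma(1 - C_R))` for constitutive resistants, and
handles regulating residents (which may sit just below their threshold at
equilibrium) by iteration.

**Invasion speed** is the ordinary least-squares slope `beta` of a strain
count on time, converted to a front speed `v = -beta/(K_S N)` (killer
front, from the sensitive count's decline) or `v = +beta/(K_R N)`
(resistant front, from the resistant count's rise). The regression window
opens when the tracked count has moved by 2% of its initial value (front
establishment) and closes when it passes 50% of its initial value (150%
for a rising count) or at the end of the series; this excludes the
initialisation transient and saturation. Note the periodic strip has two
interfaces, so `v` aggregates both fronts — it is a comparative statistic,
not a single-front measurement.

## Outcome classification

From the mean abundances over the tail window of a run (reference: last
50,000 steps; for serial transfers the end-of-cycle rows): phenotype
classes are killer (`phi_T = 1`), resistant (`phi_R = 1, phi_T = 0`) and
sensitive (neither). A class above 98% is a fixation (only sensitive
fixation gets its own label; killer/resistant fixation would be classed
OTHER with the fixation flag set). Otherwise, all three classes above 2%
is a KRS system; within KRS, a regulating genotype at >= 2% abundance is
*potential* regulation, and *true* regulation (label KRS_REG) additionally
requires at least 10% of that genotype's cells in each of its active (some
regulated gene expressed) and inactive phenotypes — cells classified as
regulators must actually switch.

## Colony edge concentration

For a uniform disk of cue producers of radius `a` and interior density
`rho`, the continuum steady state gives the rim concentration

    c(a) = rho * x * I1(x) * K0(x),   x = a / lambda,  lambda = L_cue/sqrt(2),

strictly increasing from 0 to the half-space value `rho/2`. Evaluated with
exponentially scaled Bessel functions (`ive`, `kve`) so large radii do not
overflow; validated against a direct numerical solve of an explicit disk.

Two measured quantities are reported for a growing colony, and they differ
systematically:

- the **edge-cell mean** — mean cue over occupied sites on the outer
  boundary of the colony's largest 8-connected component (boundary =
  component cells with an empty Moore neighbour in the exterior; interior
  holes excluded; colony radius defined as `sqrt(area/pi)`). Edge cells
  are occupied sites, so their own production and the rough boundary bias
  this mean ~10-15% above the smooth-disk value; it approaches ~0.47-0.49
  at the reference parameters, consistent with an upper bound of 0.49.
- the **rim-annulus mean** — mean cue over the full width-1 annulus at the
  geometric rim radius (mean distance of edge cells from the centre),
  occupied and empty sites alike. This unbiased profile measurement tracks
  the analytic curve within ~10% for radii beyond ~3 `L_cue`.

The analytic formula is descriptive/diagnostic only; it plays no role in
the dynamics.

## Numerical and implementation choices

- One seeded `numpy.random.Generator` per run; every stochastic
  sub-operation draws in a fixed documented order, so runs are
  bit-reproducible at fixed (config, seed). Sub-experiments (colony retry
  attempts, acceptance seeds) use `SeedSequence` spawning.
- Field solves cache the kernel transform per `(N, d, D)`; residual
  tolerance 1e-8 relative to `max(1, max P)`.
- Death probabilities are clamped at 1 (logged once per process); noisy
  cue values are clamped at 0 (negative concentrations would act as a
  survival bonus in the death law).
- `pi_T` and `theta` are clamped below at 0 only; large-mutation jumps
  resample within [0, 1], so values drift above 1 only via repeated small
  steps under positive selection.
- Empty lattices, extinct populations and zero-fitness neighbourhoods are
  exact fixed points / no-ops; serial transfer of an extinct population
  raises an extinction signal and the run record is flagged.

## What the test beds show — and problem sizes

The suite's simulations are scaled to single-CPU desk runs; the reference
protocol sizes (512 lattice, 400,000 steps, 2,000-point sweeps) are listed
above but are cluster-scale. Sizes used by the tests, chosen as this
package's standard desk-scale conditions:

- carrying-capacity recovery: 128 lattice, 5,000 steps (last 1,000
  averaged), within 5% of `1 - R0_inv`;
- colony edge: 256 lattice, one 500-step cycle recorded every 5 steps for
  the edge-cue bound; a 1,200-step growth (radii to ~8 L_cue) for the
  analytic-profile comparison, testing the run-averaged measured/analytic
  ratio because single rim snapshots fluctuate ~+-7%;
- invasion ordering: 256 lattice, 10 replicates per strain pair, 2,500
  steps per experiment;
- KRS persistence: 128 lattice, 40,000 steps, 3 seeds (all three
  phenotype classes above 2% over the final 10,000 steps in at least 2);
- well-mixed control: 48 lattice, 40,000 steps, five KRS-favourable
  parameter sets, sensitive-phenotype fixation in all (the killer and
  resistant purges take tens of thousands of steps even at small size).

These synthetic conditions probe the model's internal consistency (rate
laws, field solver, estimator recovery, qualitative regime contrasts).
They do not emulate features of real bacterial systems — nutrient
gradients, continuous space and time, non-linear toxin dose response,
horizontal gene transfer, or measurement noise other than the cue-sensing
term — so passing tests demonstrate a faithful implementation of the
model, not predictions about any particular organism.

## Known limitations

- At small lattice sizes, KRS wave patterns with long toxin ranges
  (`L_tox` approaching N/8) are cramped; persistence outcomes there are
  noisier than at the reference scale.
- The auto-selected invasion regression window assumes a single monotone
  front regime; for near-neutral pairs the window can degenerate to the
  full series (speeds then hover near 0, as they should).
- The colony edge detector assumes the colony does not wrap the torus;
  callers must size the lattice to the intended growth time.
- Genotype classes in run records aggregate over `theta` and `pi_T`;
  trait distributions are summarised (means), not stored per cell over
  time, except in lattice snapshots.
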