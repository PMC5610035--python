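# Model and methods

## The model

`pelage` simulates the mouse hair-follicle growth cycle as an excitable
system built from three coupled pieces: ligand–receptor signaling for one
activator and one inhibitor pathway (WNT-like and BMP-like, respectively),
the physical elongation and retraction of each follicle, and diffusive
ligand exchange between neighboring follicles through the near-surface skin
macro-environment.

### Single follicle

A follicle is a 1D depth axis, x = 0 at the skin surface, of length
ℓ(t) ∈ [ℓ_min, ℓ_max].  Two fixed compartments structure the axis:

* **Region I** (bulge), a static interval near the surface — the
  signal-receiving niche, where receptors are expressed;
* **Region II** (dermal papilla with hair germ in telogen, with matrix in
  anagen), a band of fixed width glued to the moving distal end — the
  signaling source.

Each pathway p ∈ {act, inh} carries a free-ligand field L_p(x, t) and a
bound-receptor field LR_p(x, t):

    ∂L/∂t  = D ∂²L/∂x² + s(x, phase) − k_on·L·(R(x) − LR) + k_off·LR
    ∂LR/∂t = k_on·L·(R(x) − LR) − k_off·LR − k_deg·LR + e₁·1_I(x) + noise

with no-flux ends, receptor density R(x) = R_tot on Region I (zero
elsewhere), constant Region-I production, and a Region-II production rate
that switches with the cycle phase.  The optional noise term is additive
Gaussian on the Region-I bound fields with √dt scaling, one independent
seedable stream per follicle.

The scalar growth signal is the Region-I average

    C(t) = ⟨LR_act − LR_inh⟩_I ,

and two checkpoints define the model's coarse phases: an upward crossing of
the activation threshold starts **~anagen** (activator amplification, late
competent telogen through anagen), a downward crossing of the termination
threshold starts **~telogen** (catagen, refractory and early competent
telogen).  A minimum dwell of 1 day per phase guards against threshold
chattering under noise.  During ~anagen the follicle elongates with the
saturating, phase-gated law v = v_max·max(C − θ_term, 0)/(c_half + |C|);
during ~telogen it retracts at the constant catagen speed to ℓ_min.  The
growth law is an injectable callable.

### Why it cycles

In telogen the short follicle's source sits near the bulge: bound activator
recovers (τ = 1/k_deg,act) while the inhibitor left from the previous cycle
decays (slower, τ = 1/k_deg,inh), so C rises and eventually crosses the
activation checkpoint.  In ~anagen, Region-II production of both ligands is
amplified, but the source also recedes from the bulge as the follicle
grows; the inhibitor (produced in excess of what the bulge can absorb)
accumulates and eventually pulls C below the termination checkpoint.
Catagen retraction destroys the distal tissue together with its ligand
content, resetting the geometry.  Cycling is autonomous — no clock is
built in — and exists only in a band of inhibitor strengths: scaling all
inhibitor sources down ~2× locks the follicle in extended anagen, scaling
up ~1.5× and beyond locks it in an extended telogen.  With the default
parameters the noise-free limit cycle has ~anagen ≈ 33 d, ~telogen ≈ 58 d,
period ≈ 91 d, with cycle-to-cycle period variation below 0.1%.

The inhibitor-strength scan reproduces the expected monotone structure
(~anagen shortens, ~telogen lengthens with stronger inhibition) at the
default scan ladder (0.5, 0.75, 1.0, 1.25, 1.4, 4.0).  One caveat is
disclosed here rather than hidden: in a narrow band just above baseline
(levels ≈ 1.05–1.15) the telogen duration dips by < 2% before rising,
because the telogen length is a competition between the leftover inhibitor
bound during the (shortening) anagen and the telogen-phase source; the
monotone trend holds at and beyond the default ladder's spacing.

### Coupling and the excitable-medium behavior

Neighboring follicles exchange free ligand over the fixed near-surface
band every follicle always possesses (depth 0 to ℓ_min), at rate
κ·Σ_neighbors(L_n − L_s) on a 4-neighbor lattice; barrier and hole sites
carry no state and pass no flux.  The exchange operator is symmetric and
conserves the lattice-total ligand mass to round-off.

Because the amplified early-~anagen activator production exceeds the
bulge's absorption capacity (the receptor pool runs close to saturation),
a follicle entering anagen exports a surplus of free activator while its
Region II is still inside the shared band.  Imported activator binds in a
competent neighbor's bulge and advances its activation crossing: anagen
propagates.  Refractory neighbors (bound inhibitor still high) ignore the
pulse, and deep-anagen follicles (source far below the band) no longer
export — the propagating/autonomous/refractory/competent structure of the
hair-wave literature emerges from the geometry rather than being coded.

Two regimes of the activation checkpoint matter for population behavior:

* at the default threshold (0.25), follicles cross mid-rise of C; coupling
  then biases onset times by a few days (enough to entrain domains over
  cycles);
* with the threshold raised close to the competent-telogen plateau of C
  (0.42 in the wave presets), follicles sit quasi-stationary below the
  checkpoint and an arriving pulse fires them promptly: anagen fronts
  travel as genuine excitable-medium waves at a constant speed of roughly
  1.4 sites/day.  The barrier, aperture and ear presets use this operating
  point.

### Domains

A `DomainSpec` overrides parameters per lattice region.  Three stock
domains:

* **Dorsal** — the baseline.
* **Ventral** — total receptor levels of both pathways ×2 *and* a uniform
  speed-up of all non-diffusive kinetic rates (×1.3 by default, period
  ratio 0.70; the two-domain preset uses ×1.4, ratio 0.65).  In the tuned
  excitable regime the receptor
  elevation alone shortens the period only mildly (the telogen approach is
  binding-rate-limited, but the anagen brake must fill a proportionally
  larger receptor pool), so the faster ventral clock is carried by the
  kinetic speed-up; receptor elevation is retained as the domain's
  signature and remains an independent dial.
* **Ear (hyper-refractory)** — all inhibitor sources elevated ≥4×, past
  the high-inhibitor excitability boundary: follicles complete at most
  their first cycle, equilibrate in extended telogen, and arriving anagen
  waves stop at the domain boundary (the inhibitor leaking out of the
  domain also suppresses a 1–2 follicle buffer zone just outside it).

### Initial conditions

Initial phase offsets are implemented by placing each follicle on its
domain's solitary-follicle limit cycle: a snapshot library over one settled
cycle is indexed by time-to-next-anagen-onset, and each site receives the
snapshot matching its assigned offset (head-to-tail gradient, lateral
gradient, per-domain delay, per-site Gaussian jitter, and explicit wave
source sites).  In the decoupled noise-free limit, cycle-1 onset times equal
the assigned offsets exactly, which the tests exploit.  For non-cycling
(hyper-refractory) domains the library degenerates to the terminal
equilibrium state.

## Numerics

Explicit Euler with central-difference diffusion; ghost nodes mirror the
first interior node, which conserves the trapezoidal ligand mass exactly in
the closed limit.  dt must satisfy dt ≤ dx²/(2·max D); violations raise an
error naming the admissible bound (defaults: dx = 0.1, dt = 0.0125,
bound 0.0167).  The moving boundary uses a fixed grid with node
insertion/removal at the distal end: the Region-II source weights are
computed from the continuous length with partial-cell overlap (so source
mass is exact in ℓ), the receptor profile uses partial-cell weights of the
Region-I indicator, and the distal active cell extends to the true length.
On elongation a new node takes the extrapolated distal value (the freshly
built matrix derives from the producing compartment); on retraction the
removed nodes' ligand is discarded with the apoptotic tissue.  Interpolation
never redistributes mass over the surviving domain.  Negative
concentrations are clipped to zero and logged; the run aborts if a step
clips more than 1% of nodes by a non-trivial margin (zero-floor noise
undershoots are benign and only counted).  Halving dt alone changes the
settled period by < 0.1%; halving both dt and dx changes it by ≈ 1.5%
(the components converge more slowly than the period, first order in dx).

Determinism: per-site random streams are spawned from the master seed with
a counter-based key (site index), so identical seeds give bit-identical
trajectories, a zero-coupling lattice factorizes bit-exactly into
single-follicle runs, and adding sites never perturbs existing streams.
Reductions in the growth-signal average run along the node axis so results
are bitwise independent of how many sites share the state arrays.

## Scenario presets and their calibration

All presets live in `pelage.scenarios` and are ordinary configurations —
every number below can be overridden from a config file.

* `single_follicle`, `inhibitor_scan` — the solitary-follicle surface.
* `homogeneous_grid` — 16×16 uniform lattice, head-to-tail onset gradient
  of 8 d, jitter 0.3 d, κ = 0.25, dynamics noise 0.0015.  The imposed
  onset order survives all 12 simulated cycles (the compressing gradient
  stays above the noise floor), mirroring the observation that a
  homogeneous field preserves its initial asynchrony for ≥ 10 cycles.
* `two_domain` — 16×18 lattice, two 5-column Ventral stripes flanking an
  8-column Dorsal stripe; dorsal head-to-tail gradient 6 d with 2 d
  jitter, ventral onset delayed 3.5 d (within the observed 3–4 d range),
  κ = 0.55, noise 0.002.  The flank-driven waves make the dorsal onset
  map mirror-symmetric in cycle 2 (masked mirror correlation > 0.7,
  evaluated over the dorsal domain whose pattern the flanks reorganize),
  and the head-to-tail rank correlation falls below 0.5 in cycle 3
  (simulated day ≈ 150 at this reduced lattice scale).  The breakdown
  mechanism is physical: coupling compresses the dorsal gradient each
  cycle while the stochastic signaling term sets a scatter floor; by the
  third cycle the residual gradient is below the floor.  Without noise
  the compressed gradient survives as unmeasurably small but perfectly
  ordered microstructure — a rank statistic is scale-free, so the
  stochastic term is not optional for this comparison.
* `barrier`, `aperture`, `hyper_refractory_ear` — wave operating point (activation
  threshold 0.42, all sites placed 25 d before intrinsic onset, head row
  forced); a planar front launched at the head row passes around a
  partial barrier's ends (arrival behind the center delayed by several
  days, V-shaped iso-arrival contours), squeezes through an aperture and
  bows outward behind it (distortion metric ≈ 4–6 site units against
  < 1 for the unobstructed control), and never enters the
  hyper-refractory stripe.

## Pattern statistics

* **Onset map**: per-site k-th ~anagen entry time (per-site cycle
  indexing, so drifting sites keep well-defined cycles); sites lacking the
  cycle are masked.
* **Asynchrony persistence**: largest k such that Spearman's ρ between
  onset time and the head-to-tail coordinate exceeds 0.5 for every cycle
  1..k.  Chosen as a rank statistic for robustness to nonlinear gradients.
* **Bilateral symmetry**: Pearson correlation between the onset map and
  its lateral mirror, computed after removing per-row means (a pure
  head-to-tail gradient is trivially mirror-equal; the residual isolates
  lateral structure), over jointly valid — optionally masked — sites.
  Emergence = first cycle with score > 0.7.  The row-centering introduces
  an O(1/columns) negative bias under the null, negligible at the lattice
  widths used.  The thresholds (0.5, 0.7) are calibration choices of this
  package, reported with the outputs, not literature-derived constants.
* **Wave front**: arrival-time field with column-wise interpolated
  iso-arrival contours; distortion = the largest per-contour spread of
  contour row positions, in site units (0 up to discretization for a
  planar front).

## What the synthetic scenarios do and do not show

The generator produces idealized skin: rectangular lattices, at most three
parameter domains with sharp boundaries, initial conditions drawn from the
model's own limit cycle, and Gaussian signaling noise.  Real skin has
curved anatomy, graded domain boundaries, developmental morphogen
patterning of the first cycle, hair-type heterogeneity within domains, and
seasonal/systemic modulation — none of which are modeled.  Passing tests
therefore demonstrate that the coupled signaling–growth mechanism is
*sufficient* to produce cycling, waves, domain dominance, bilateral
symmetry, hyper-refractory blocking and wave-breaker distortion under the
stated conditions; they do not validate parameter values against
measurements, and all kinetic constants here are a tuned, dimensionless
parameterization (1 time unit = 1 simulated day; lengths in units where
the telogen follicle is 1.2 long) rather than fitted biology.

## Known limitations

* The anagen/telogen component durations converge more slowly under grid
  refinement than the period does; quantitative duration claims should be
  checked at dx ≤ 0.05.
* Receptor elevation alone does not shorten the cycle in this regime (see
  Domains above); the ventral preset's speed is carried by the kinetic
  rate scale.
* The telogen-duration dip just above baseline inhibitor strength (< 2%)
  limits how finely the scan's monotone claim may be sampled.
* No pathway cross-talk is modeled (an explicit simplification); the
  coupling hook for it is absent by design.
* Wave propagation at the default activation threshold is entrainment-like
  (few-day onset advances), not a constant-speed front; the wave presets
  use the raised-threshold operating point for front experiments.
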