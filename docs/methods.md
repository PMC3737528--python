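# Methods

## The model

DNA is represented as a discrete wormlike chain: `n_bp` rigid segments of
length `l` (default 0.34 nm, one base-pair rise) joined at `n_bp - 1`
joints (`n_bp` joints for a circle).  Each joint carries a bending energy
`E(theta)` in units of kT as a function of the bend angle `theta` between
successive segment tangents.  Four families are implemented:

* **quadratic** — `E = (g/2) theta^2`, the classical wormlike chain with
  dimensionless rigidity `g`;
* **linear** — `E = alpha theta`, a control family used to probe how
  little the small-angle shape of the potential matters beyond about one
  helical turn (central-limit washing-out of the joint distribution);
* **kinkable** — a harmonic stack in parallel with a kink branch: the
  joint energy is the *minimum* of `(g/2) theta^2` and a flat plateau of
  height `h` (kT) extending up to `theta_cut`, closed by a harmonic wall
  `h + (g_wall/2)(theta - theta_cut)^2`.  The plateau models a Crick-Klug
  kink or an opened base pair: an energetically costly but angularly
  floppy disruption;
* **nick** — the same functional form tagged for a single-strand break;
  the standard parametrisation `h = 8`, `b = 1.0` reproduces measured
  kink probabilities at nicks in 0.2 M NaCl.

The angular-range parameter `b` fixes `theta_cut` through the linear map
`theta_cut = pi (b + 0.4) / 1.4`, anchored at the two values the model is
actually used with: `b = 0.3 -> pi/2` (kinks bend up to ~90 degrees) and
`b = 1.0 -> pi` (a nick bends freely).  Intermediate `b` have no
experimental anchor; the map is a convenience interpolation.  The wall
rigidity `g_wall` defaults to the stack rigidity `g`; it is exposed as a
parameter because nothing pins it down empirically (see *Limitations*).

A joint is classified as **kinked** when its kink branch lies strictly
below the stack branch at the current angle; for the harmonic stack the
crossover is at `theta* = sqrt(2h/g)`.

### Calibration

The rigidity of any family is calibrated to a persistence length `a`
(default 48 nm) through the discrete-chain identity
`a = l / (1 - <cos theta>)`, with `<cos theta>` computed by quadrature
over `p(theta) ~ sin(theta) exp(-E)` and the rigidity found by Brent
root-finding (relative tolerance 1e-6 on the realised `a`).  In the stiff
limit this reduces to `g ~ a/l ~ 141` for `a = 48 nm`.  For kinkable
joints with `h >= 12` the kink branch carries so little weight that the
exact calibration differs from calibrating the bare stack by < 0.5%; for
cheap kinks (`h <~ 10` on every joint) the exact calibration has **no
solution** — the kink branch caps the attainable `<cos theta>` — so chain
builders calibrate the intact stack harmonically and attach the kink
branch on top.  This matches the physical reading: the persistence length
of intact DNA fixes `g`; disruptions are rare excitations.

One-joint thermodynamics follow from
`Z_branch = int exp(-E) sin(theta) dtheta` restricted to the region where
the branch attains the minimum.  The kink formation free energy is
`dF = -kT ln(Z_kink / Z_stack)`; because the plateau is angularly much
wider than the thermal width `1/sqrt(g)` of the stack well, `dF` sits
~5 kT below `h` (for `h = 12`, `b = 0.3`, `a = 48 nm`).  Unit conversions
use kT = 0.593 kcal/mol (25 C).

## Sampling

**Linear chains** are sampled exactly: joint angles are independent draws
from `p(theta) ~ sin(theta) exp(-E)` via a 4096-point tabulated inverse
CDF, azimuths are uniform, and tangents are built by sequential rotation
(a numba kernel consumes precomputed vectorised trig).  No Markov chain
is involved.

**Circular chains** are sampled by Metropolis Monte Carlo over closed
conformations.  The only conformational move is the crankshaft: rotate
the block of segments between two ring vertices rigidly about the chord
through them.  The block's tangent sum is parallel to the rotation axis,
so closure is preserved exactly (up to floating-point rotation error,
squeezed out by periodic renormalisation; the closure defect stays below
1e-6 l).  Only the two boundary joints change energy.  Rotation angles
mix a tuned proposal (`[-delta, delta]`, `delta` adapted during burn-in to
30-50% acceptance) with occasional wild proposals uniform on `[-pi, pi]`.
The initial state is the regular polygon; an energy-trace trend test
(first-half vs second-half means, block standard errors, |z| <= 4) flags
unequilibrated runs with a warning.

Two measures address the rare-event structure of kink formation, whose
saddle sits near the branch crossover at an energy of order `h` above the
basin:

* *nick targeting* — when a designated nick joint exists, a fixed fraction
  of moves anchors one pivot at it (state-independent selection, so
  detailed balance is untouched);
* *Hamiltonian replica exchange* — for chains with kinkable joints, K
  replicas run with kink energies scaled across
  `[h_scale_min, h_scale_max]` and neighbouring replicas swap
  conformations with the standard exchange acceptance; the replica with
  scale 1 is the unmodified target ensemble.  Cheap-kink rungs cross the
  barrier freely and ferry kink *creation* events towards the target;
  rungs with kink energies *above* the target (scale > 1) favour the
  low-kink basins and ferry kink *annihilation* events.  A one-sided
  (downward only) ladder visibly biases the kink-count occupancy of a
  stressed minicircle towards high counts, so kink-count estimates use a
  bidirectional ladder (default for the headline 70-bp computation:
  10 rungs spanning 1.5 h down to 0.3 h).

Convergence of the kink-count observable was verified by running
independent seeds and ladder layouts to agreement (and, for the nicked
circle, by comparing nick-targeted single-replica runs against exchange
runs).

## Cyclization j-factors

The j-factor is the effective molar concentration of one fragment end in
the reaction volume of the other; conventions differ in what orientation
condition is imposed at contact:

* **free / sticky-ended** — ends within a capture radius `r0`, any mutual
  orientation.  Long single-stranded ends (>= 8 nt) join at any
  orientation and can bridge a notable gap; `r0 = 5 nm` is the default.
* **axially aligned** — ends juxtaposed and terminal tangents within a
  cap angle gamma, normalised by the isotropic cap measure
  `(1 - cos gamma)/2` so uncorrelated tangents give a factor of 1.
  Torsional alignment is *not* modelled: the torsional rigidity behind a
  full twist-register condition is not part of this package's parameter
  set, and all headline numbers are torsion-free.

The Monte Carlo estimator uses **half-chain convolution**: conditioned on
the direction of the middle segment, the two chain halves are independent,
so `N` sampled half-chains provide `N^2` effective closure trials.  The
(rho, z) end-position densities of the halves (azimuthal symmetry about
the middle-segment axis) are histogrammed on a shared 200 x 400 grid and
convolved analytically over the free relative azimuth, giving the
probability of landing in a capture shell in closed form.  Contact
densities come from three shrinking shells (base radius
`min(0.08 contour, 2 nm)`) extrapolated linearly in `r0^2`; if the
extrapolation turns non-positive (strong curvature at very short, stiff
chains) the smallest-shell density is used, which biases the density *up*
— conservative wherever the quantity serves as the denominator of an
enhancement ratio.  Statistical errors come from the scatter of ten
sample blocks.

The axial factor is estimated from explicitly matched contact pairs
(spatial hashing of stored end states; pairs that juxtapose are draws from
the contact-conditioned ensemble).  The cumulative aligned fraction over
shrinking caps is fitted as `p(c) = a c + b c^2` through the origin and
the factor is the slope `a`; with too few pairs the fixed-cap
(gamma = 30 degrees) ratio is used, and when *no* aligned pair is observed
the rule-of-three style bound `1/(n+1)` replaces the zero count so that
downstream ratios remain finite and conservative.

**Validation against the closed form.**  The Shimada-Yamakawa
approximation `G = 28.01 N^-5 exp(0.492 N - 7.027/N)` per Kuhn-length
cubed (`N = L/2a`) is implemented as an independent oracle.  Its
exponential constant is the teardrop ground-state energy `14.055 kT a/L`,
i.e. it describes the *end-contact* (orientation-free) closure density;
the package's free-end MC reproduces it to a few percent at 200-600 bp,
and to better than 2x across the tested range, while the axially aligned
j lies a further 3-12x lower there (the circle-minus-teardrop bending
cost).  Comparisons are therefore made in the matching (free-end)
convention.

**Kink enhancement ratios.**  The headline enhancement — how much more
readily a kinkable 70-bp fragment cyclizes than a harmonic one — is
reported as the ratio of orientation-free j-factors.  At 70 bp the
harmonic chain's axial factor is a rare event stacked on a rare event
(no aligned pair among hundreds of contact pairs at 10^7 half-chains per
side), so an aligned-convention ratio is not statistically resolvable;
the orientation-free ratio is, and it is a *lower bound* on the aligned
one, because kinked closures are ring-like (measured axial factor ~1e-3)
while the harmonic chain's rare contacts are ~80-degree-apex teardrops
(axial factor ~1e-4 from the circle-minus-teardrop bending cost).
Conditioning on alignment therefore boosts the kinkable j relative to the
harmonic j.

## Minicircle kink statistics

`nick_kink_probability` reports the time-average of the nick joint's
kink-branch indicator in a nicked circle (harmonic joints + one nick,
`h = 8`, `b = 1.0`); `mean_kinks_per_circle` reports the mean kink count
of a covalently closed circle in which *every* joint is kinkable
(`h = 16`, `b = 0.3` — the ~7 kcal/mol base-pair opening free energy).
Torsional stress is ignored in both, per the model's scope: the circle is
a bending-only ring.  The large-circle limits are the one-joint
(unstressed) branch probabilities computed by quadrature, to which the MC
curves decay from ~1 at 70 bp.

`equivalent_sigma` implements the twist/writhe bookkeeping: a flat
minicircle converts its whole linking deficit into twist, whereas large
circular DNA writhes away ~75% of it, so a minicircle density sigma is
equivalent to `sigma / (1 - writhe_fraction)` in large DNA.

## Ligation kinetics

With permissive ligase, circles and dimers accumulate in proportion to
the equilibrium fractions of cyclized and dimerized sticky-end pairs, so
`j = 2 M0 lim_{t->0} C(t)/D(t)`.  The limit is the intercept of a linear
fit of `C/D` against time over the early window (points with
`C + 2D <= 0.1 M0`).  The prefactor 2 (two distinguishable end pairings
per fragment pair) is exposed as `DIMER_FACTOR` since the formula is
method-defined.  The permissive-range diagnostic is a weighted
least-squares trend of apparent j against log ligase concentration,
tested against zero slope at a configurable level; its type-I error is
checked on flat synthetic titrations.  The synthetic fixture generator
produces early-time linear accumulation with multiplicative log-normal
noise of chosen coefficient of variation; it emulates only the early-time
regime the estimator uses — no product depletion, sticky-end
joining/dissociation kinetics, or kink-induced circle/dimer asymmetry —
so round-trip tests validate the estimator, not the assay itself.

## Problem sizes and numerical choices

Default statistics were chosen so the reported quantities resolve their
tolerances comfortably: quadrature to scipy defaults (relative ~1e-8);
minicircle runs of 2-3 x 10^4 retained sweeps (nicked circles,
nick-targeted moves) or 2 x 10^5 sweeps with an 8-replica ladder (the
70-bp all-kinkable circle, where the kink count's integrated
autocorrelation is long); j-factor runs of 4 x 10^6 to 10^7 half-chains
per side at 70 bp and ~10^5-10^6 at 200-600 bp.  Standard errors are
reported alongside every stochastic estimate (autocorrelation-aware for
MC time series, block scatter for the convolution estimator).  All
randomness flows from explicit integer seeds; fixed seed, move schedule
and thinning reproduce runs bit-for-bit.

## Limitations

* **The kink potential is a surrogate.**  The piecewise
  min[harmonic, plateau + wall] form reproduces the one-joint anchors it
  was built on (the ~5 kT entropy offset of the kink free energy at
  h = 12, an unstressed opening probability ~1.6e-5 and an opening free
  energy ~6.6 kcal/mol at h = 16, and a nick-kink plateau with a
  large-circle limit of ~0.09 at h = 8).  It does *not* reproduce one
  published-scale ring statistic: in a covalently closed 70-bp circle it
  yields ~2.0 open joints per molecule rather than ~1.  The reason is
  structural: with the plateau capped near 90 degrees, a single kink
  cannot absorb enough of the 2 pi turning and gets pinned against the
  wall (losing all plateau entropy), so the two-kink state wins.  No wall
  stiffness fixes this within the family — walls soft enough to favour a
  single >120-degree kink push the unstressed opening probability above
  2e-5, violating the better-anchored one-joint calibration.  A kink
  branch whose energy keeps falling more gently beyond 90 degrees would
  be needed; absent data on that region, the package keeps the simple
  form and reports the value honestly: 1.9-2.0 across seeds and ladder
  layouts (the two-kink state carries ~85-95% of the weight; the residual
  seed scatter reflects the still-long relaxation of the few-percent
  zero/one-kink occupancies).
* The nick-kink probability at 600 bp is ~0.12-0.13, a ~1.5x stress
  enhancement over the one-joint limit of 0.084; it keeps decaying slowly
  with size (~0.12 at 700 bp).
* Torsional alignment and twist/writhe dynamics are out of scope: no
  torsional rigidity is parametrised, and supercoiled closure is not
  simulated (only the sigma-equivalence arithmetic is provided).
* Sequence dependence, intrinsic curvature, bending anisotropy, excluded
  volume and electrostatics are not modelled; salt enters only as the
  provenance tag of the h = 8 nick calibration (0.2 M NaCl).
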