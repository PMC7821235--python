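# Methods

## Representation and conventions

A waveform lives on a uniform grid covering two encoding periods (`delta1`,
`delta2`) separated by a refocusing gap (`gap`) during which the gradient is
identically zero; the gradient also vanishes at the first and last sample.
Samples are the *effective* gradient: the sign flip imparted by the
refocusing pulse is absorbed, so the physical gradient is `sign_profile * g`
with the sign flipping once, at the gap midpoint. All internal quantities
are SI (T/m, s, rad); mT/m, ms, ms/µm² and (mT/m)² ms appear only at the
I/O boundary.

Samples are interpreted as a first-order hold (piecewise-linear gradient).
Integrals use the trapezoid rule on the grid, with two deliberate
exceptions:

* **Moments.** On a uniform grid with zero gradient endpoints the trapezoid
  rule is *exact* for `m₀` of the interpolant, and — given `m₀ = 0` — its
  per-interval errors telescope to zero for `m₁` and `m₂` as well. Moment
  constraints enforced on the optimization grid therefore survive
  verification at 10 µs unchanged, which matters because the thresholds
  (10⁻⁴ rad sⁿ/m) sit eight orders of magnitude below typical
  non-compensated moments.
* **Maxwell matrix.** `∫ s g gᵀ dt` is integrated exactly per interval
  (products of linear segments); plain trapezoid carries an
  `O(dt² s²max τ)` error that can reach thousands of (mT/m)² ms on a 0.5 ms
  grid — far above the 100 (mT/m)² ms limit being enforced.

The moment time origin is the start of the encoding window and is exposed
as an offset. Nulling is origin-invariant only when all lower orders are
nulled too; the Monte-Carlo simulator uses the same origin so that the
per-spin phase decomposes exactly as `φ = Σₙ mₙ·fₙ/n!`.

The Maxwell index is the Frobenius norm of the signed outer-product
integral, reported in (mT/m)² ms. This choice reproduces the customary
printed units; a waveform whose physical gradient after refocusing mirrors
the pattern before has index zero by sign cancellation.

b-tensor shapes are classified from eigenvalues with tolerance `1e-3 · b`:
one nonzero eigenvalue is linear, two equal nonzero ones planar, three
equal spherical.

## Optimization

Decision variables are the free gradient samples per active axis (one for
linear, two for planar, three for spherical encoding), normalized by
`gmax`. Constraints:

* amplitude: per-axis box (max-norm) or per-sample Euclidean ball
  (L2-norm). The L2 ball has radius `gmax` by default — conservative and
  rotation-safe; the literal interpretation of a sphere with diameter
  `2·gmax` is available via `l2_full_sphere=True`.
* slew: finite differences over every inter-sample interval, including the
  ramps into the pinned zeros at the boundaries and the gap.
* moments: both the magnitude-threshold form `|mₙ| ≤ Lₙ` and exact nulling
  `mₙ = 0` are implemented. Thresholds below `1e-6` of the natural moment
  scale `γ gmax τⁿ⁺¹` are numerically indistinguishable from zero at solver
  precision and are eliminated *exactly*: the variables are parametrized in
  the null space of the (linear) moment functionals, so the nulled moments
  vanish to machine precision by construction and the stated threshold is
  satisfied trivially. Larger thresholds become per-component linear bounds
  `|mₙ,ᵢ| ≤ Lₙ/√(n_axes)` (a box inscribed in the magnitude ball —
  slightly conservative, but linear).
* Maxwell: `‖M‖²F ≤ limit²`, a smooth quartic with analytic gradient.
* shape: hard quadratic equalities on the b-tensor entries (spherical:
  equal diagonal, zero off-diagonal; planar: two equal in-plane diagonal
  entries with the third axis carrying no gradient; linear: one active
  axis).
* energy (optional): `∫ g²ₐ dt ≤ limit` per axis; disabled by default, so
  the standard runs carry no heat-dissipation constraint.

The objective (maximize trace B, a quadratic form in the samples) and all
constraint Jacobians are analytic; the problem is solved with SLSQP from
seeded smooth random starts (`restarts`, default 5; sums of low-order
sinusoids projected into the null space and scaled inside the bounds). The
best start that passes *independent verification* wins: every candidate is
resampled at 10 µs and every constraint recomputed with the generic metric
routines, with feasibility tolerance `1e-3` of each bound (moment
residuals: `1e-7` of the natural scale when the bound is zero). If no start
is feasible the least-infeasible waveform is returned with
`converged=False`. Results are deterministic given `(seed, restarts)`.

Being a smooth local method with restarts, the solver makes no global
claim; occasional local optima are expected (visible, for instance, as
non-strict monotonicity of achievable b across nulled orders in symmetric
linear designs).

**Duration minimization** holds the gap and the timing asymmetry
`delta1 − delta2` fixed and searches the second period's duration: an
initial multi-start solve at the requested starting timing, then
warm-started re-solves (the previous solution stretched period-by-period
onto the new grid) at durations predicted from the approximately cubic
growth of b with duration, refined by bisection to 1 ms. The scan runs on a
half-resolution grid for speed and targets a 2 % margin above the requested
b; the chosen duration is then re-solved on the full grid (default 100
points across the encoding periods, split in proportion to the periods) and
the amplitude is scaled down so that the b-value recomputed at 10 µs equals
the target to 1e-6 relative. Scaling down by `s ≤ 1` preserves every
constraint (b and Maxwell scale as `s²`, moments as `s`).

The grid spacing is `(delta1 + delta2) / n_points`; the gap is rounded to
whole intervals, so the realized refocusing duration can differ from the
request by up to half a sample (≤ 0.3 ms at default resolution).

## Reference waveforms

Monopolar (Stejskal-Tanner) and bipolar (velocity-compensated) fixtures are
trapezoid lobes described by breakpoint lists, with the convention that a
lobe of amplitude `g`, duration `delta` and ramp `rise` has footprint
`delta + rise` and area `g·delta`, under which
`b = γ²g²[δ²(Δ − δ/3) + ε³/30 − δε²/6]` holds exactly and `|m₁| = γgδΔ`
for any lobe shape. "Rectangles" are rendered with one-sample
area-preserving edges. A grid-free oracle integrates the breakpoint
segments with 3-point Gauss-Legendre (exact for the quartic b-value
integrand), so closed forms are validated rather than assumed. The bipolar
design reverses the second period's lobe pair, cancelling `m₁` exactly for
any lobe shape while `m₂` remains — velocity-only compensation.

## Monte-Carlo simulator

Spins follow `r(t) = Σₙ fₙ tⁿ/n!` with `f₀ = 0` and each component of
`fₙ` drawn independently from `N(0, σₙ²)`. The phase integral
`φ = γ ∫ g·r dt` uses the trapezoid rule on the waveform grid resampled to
≤ 50 µs; because `r` is polynomial and quadrature is linear in the
integrand, the integral factorizes into per-order weights and the ensemble
is evaluated without materializing trajectories. Default ensemble size is
10⁵ spins. The Monte-Carlo standard error is the spread of the complex
spin vectors projected on their mean direction, scaled by `1/√n`.

What the simulator emulates — and what it does not: ballistic (polynomial)
motion only. Diffusion enters analytically through the `B:D` term of the
signal model, not through random walks; pulsatile or direction-changing
motion is outside the model, and real cardiac motion is neither normal nor
independent across orders. Passing tests therefore demonstrate correctness
of the encoding algebra and the cumulant model under its own assumptions,
not fidelity to any particular organ's motion spectrum.

## Signal model and fit

`S = S₀ exp(−B:D − Σₙ Mₙ:Fₙ/(2(n!)²))` with `Mₙ = mₙ ⊗ mₙ`. The
`1/(2(n!)²)` factor follows from `φ = Σ mₙ·fₙ/n!` and second-cumulant
truncation; it is validated against the Monte-Carlo engine rather than
assumed (the two agree within Monte-Carlo error across nulling levels,
which is the package's check of the exponent convention). `Fₙ` defaults to
`σₙ² I`; anisotropic `Fₙ` is accepted but the normality/independence
assumptions become the user's responsibility.

The diffusion-tensor fit regresses `log S` on the six unique b-tensor
components plus intercept, with WLS weights equal to the squared predicted
signal (standard log-linear heteroscedasticity correction; OLS available).
Rank-deficient designs raise an error naming the unresolved tensor
components. Direction sets come from icosahedral geometry: 6 vertex
directions (all pairwise angles equal), 15 edge midpoints, 30 edge
trisection points.

## Problem sizes used in tests and reproduction runs

The shipped tests and the acceptance script use the protocol grid of 100
points across the encoding periods with 5 restarts for duration-minimized
runs, 40–100 points and 1–3 restarts for unit-level optimizations, and
4·10⁴–10⁵ spins per Monte-Carlo node on reduced σ-grids (4 nodes per axis);
these sizes were chosen so the full loop — optimize, verify, simulate,
fit — reproduces the study-scale quantities in minutes on a single CPU.

## Known limitations

* Local optimization: reported b-values are best-found, not certified
  global optima.
* The max-norm amplitude bound is not rotation-safe (by definition); the
  rotation helper flags violations rather than preventing them.
* K-nulling (the alternative concomitant-field strategy) and
  sequence-timing computations (TE, trigger delays) are out of scope.
* The energy bound is the plain `∫g² dt` proxy, not a coil-specific heat
  model.
* Gradient nonlinearity and eddy-current behavior are not modelled.
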