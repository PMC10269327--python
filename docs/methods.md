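# Methods

This note records the model conikit implements, the numerical choices made
where the design was genuinely open, and what the shipped tests do and do
not demonstrate.

## Two-state representation and conventions

A crossing between two electronic states is described by the symmetric 2×2
Hamiltonian H = [[α, γ], [γ, β]] in a pseudodiabatic basis.  With
τ = (α+β)/2, δ = (α−β)/2, λ = √(δ²+γ²) and ω = atan2(γ, δ), the adiabatic
energies are E^A = τ+λ ≥ E^B = τ−λ and the gradient-level quantities are

    s = ∇τ,
    g = cos ω ∇δ + sin ω ∇γ        (equal to ∇λ, half the gradient difference),
    h = −sin ω ∇δ + cos ω ∇γ       (the difference-scaled coupling, finite on the seam).

Conventions that matter downstream:

* **g carries the factor ½**: g = (∇E^A − ∇E^B)/2.  This makes g = ∇λ with
  λ the *half* gap, so the gauge choice k_δ = g(q_ref) is consistent with
  δ = (α−β)/2, and the first-order restoration step has length λ/‖g‖.
* **h** is the coupling scaled by (E^A − E^B), which cancels the 1/(E^A−E^B)
  divergence of the raw derivative coupling; h is finite and well defined on
  the seam.  Its *sign* is not defined — electronic-structure codes return
  either phase — and nothing in the package ever assumes one.
* Degeneracy: λ < 10⁻⁹ hartree is treated as an exact crossing.  ω (an
  atan2 of two vanishing arguments) is taken as 0 there and the point is
  flagged; the ω→0 limit of (g, h) is returned.

## Gauge-fixed pseudodiabatization

The map (α, β, γ) → (E^A, E^B, s, g, h) loses one angle: every in-plane
rotation of (∇δ, ∇γ) produces the same adiabatic data.  The package fixes
the gauge by a reference structure — the *latest* point of the history —
with k_δ = g(q_ref), k_γ = h(q_ref), ω(q_ref) = 0.  For any other point:

1. The local pair (g, h) is rotated minimally onto span{k_δ, k_γ} via the
   SVD of the 2×2 inner-product matrix between orthonormal bases of the two
   planes; the singular values φ₁, φ₂ are the cosines of the principal
   angles.  When φ₁φ₂ < 0.1 the rotation is flagged (a warning, not an
   abort): far from q_ref the transform may stop being consistent, and the
   caller — usually the macro loop, which rebuilds the gauge from the newest
   point anyway — decides what to do.
2. ω is fitted from both rotated vectors.  The coordinates of g′ and h′ in
   the (generally non-orthogonal) frame (k_δ, k_γ) are obtained with the
   Moore–Penrose inverse of [k_δ k_γ]; ω_g is the angle of g′'s coordinate
   pair and ω_h is the angle of h′'s pair shifted by −π/2 so both estimate
   the same ω.  On data from an exactly linear model the two estimates
   coincide and the whole fit reduces to extracting the rotation from the
   pinv solve — the tests hold this to 10⁻¹⁰.  The final ω is the circular
   mean (the angle equidistant from both on the shorter arc; the antipodal
   tie, which only arises in pathological gauges, breaks deterministically
   to ω_g + π/2).
3. If ω_g and ω_h disagree by more than π/2, h's phase is deemed flipped:
   h → −h (shifting ω_h by π) and the flip is recorded.  The rule is an
   involution and makes the diabatic surfaces independent of random
   per-point phases.
4. δ = λ cos ω, γ = λ sin ω; (∇δ, ∇γ) by the inverse in-plane rotation of
   (g, h); α, β, ∇α, ∇β from τ, s.  The round trip reproduces the
   adiabatic data exactly, h up to the recorded sign.

One *gauge property* deserves a note: the overall sign of the γ surface is
tied to the phase of the reference point's h, because that phase defines
k_γ itself.  Flipping the reference phase flips γ → −γ globally — a pure
gauge change with identical adiabats.  The phase-robustness tests therefore
hold the reference phase fixed and randomize all the others (surfaces must
match exactly), plus assert the γ → −γ behavior for the reference flip.

Spin crossings skip all of this: with no coupling, γ ≡ 0, α = E^A, β = E^B
directly, and only two surfaces are built.  In this mode α − β is allowed
to change sign (the surfaces genuinely cross), which keeps the constraint
E^A − E^B signed and smooth for the optimizer.

## Gradient-enhanced Kriging

Each surface is a GEK interpolant E*(q) = μ + v(q)·w with the Matérn-5/2
kernel f(d) = (1 + √5 d + 5d²/3) e^{−√5 d} over the length-scaled distance
d² = Σ_k((q_k − q'_k)/l_k)².  The covariance between n points with all
gradients is an n(m+1) × n(m+1) matrix (per-point ordering: energy first,
then the m gradient components, points in history order); w solves M w = y
once per fit via Cholesky.  The predicted variance is 1 − vᵀM⁻¹v (unit
prior variance; the trend μ absorbs the energy offset, and the variance is
only ever used relatively, to restrict steps).

Fixed-by-construction hyperparameters:

* **Characteristic lengths.**  A one-point model with baseline offset
  μ − y has Hessian (5/3)(μ−y)/l_k² at its data point (the kernel's third
  derivatives vanish at zero separation, so the gradient datum contributes
  nothing).  Matching a supplied approximate diagonal Hessian H_kk gives
  l_k = √((5/3)(μ−y)/H_kk).  Non-positive Hessian entries are floored at
  0.025 hartree/bohr² (lengths must stay positive; the caller owns the
  quality of the approximate Hessian).  One set of lengths, computed from
  the Hessian at the first point, is shared by all three surfaces.
* **Baselines.**  μ_α and μ_β sit 10 hartree above the maximum of their
  respective data values — far enough above that the surface bends upward
  away from the data (this is also what makes the length calibration
  meaningful) — while μ_γ = 0 so the coupling decays to zero where there is
  no information.
* **Nugget.**  10⁻¹² on the covariance diagonal.  The interpolation
  residual at a data point equals nugget × weight exactly, so the nugget
  directly bounds how "exact" the exact interpolator is; 10⁻¹² keeps the
  residual near 10⁻¹⁰ for typical weight magnitudes while still
  regularizing.  If Cholesky fails, the nugget is raised ×100 (twice)
  before an error naming the closest pair of data points.
* No maximum-likelihood tuning of anything.

## Restricted-variance optimization

The optimizer alternates backend calls (macroiterations) with walks on the
surrogate (microiterations).  Each microiteration:

* **Constrained subspace.**  For a conical intersection the gap
  2√(δ²+γ²) vanishes only where *both* δ and γ do, so the constrained
  subspace is span{g, h} and the restoration solves the linearized pair
  (λ + g·Δ, h·Δ) = (0, 0) with the minimum-norm solution in that span.
  For spin crossings the constraint is one-dimensional (span{g}) and the
  restoration is the Newton step −(λ/‖g‖²)g.  Both are capped by the trust
  radius (0.3 a₀ by default).
* **Optimized subspace.**  The orthogonal complement (with rigid-body
  translations/rotations also projected out when the coordinates are 3N
  Cartesians of a molecule) minimizes the average energy τ with a
  restricted-step rational-function step.  The Hessian of τ on the
  surrogate is obtained by central differences of the predicted average
  gradient — the surrogate is analytic, so this costs nothing and is
  accurate to the differencing step (10⁻⁴ a₀).
* **Variance restriction.**  If the candidate's largest per-surface
  predicted variance exceeds the limit, the step is shortened by bisection
  (60 halvings) onto the variance boundary and the microiterations stop
  there.  The limit is expressed as a 95% confidence half-width:
  1.96·σ ≤ 0.3 hartree by default, i.e. σ² ≤ (0.3/1.96)².  The choice of
  *stepping back onto the boundary* (rather than rejecting the step
  outright) is the package's own; either policy bounds every accepted
  geometry by the same variance limit, which is the property the tests
  assert.
* Microiterations also stop at surrogate stationarity — thresholds are the
  macro convergence thresholds scaled by 10⁻² so a macroiteration lands
  essentially on the surrogate's constrained stationary point — or at the
  iteration cap (100).

Convergence of the macro loop uses the conventional thresholds (rms step
1.2·10⁻³ a₀, rms projected gradient 3.0·10⁻⁴ E_h/a₀, maxima 1.5× those, all
inclusive) plus the crossing condition |E^A − E^B| ≤ 10⁻⁵ E_h.  The
projected gradient removes the constrained directions (and rigid modes)
from s.  The rms "step size" threshold in E_h/a₀ is applied to the
gradient, as its units indicate.  When the surrogate is already stationary
at the newest data point the remaining step is identically zero and
convergence is judged on the gradient and gap criteria alone; failing that,
the run reports `converged = False` with its full trace rather than raising.

**Data selection.**  Optimization histories cluster as they converge, and
tightly clustered gradient-enhanced data make the covariance numerically
singular.  Before each surrogate build the history is pruned newest-first:
the newest point (the gauge reference) is always kept, older points closer
than 10⁻³ kernel-scaled distance units to a kept point are dropped, and at
most 20 points are retained.  This is a conditioning device, not a model
change — the surrogate still interpolates every retained point exactly.

## The analytic model backends

The models emulate what the method consumes from a quantum-chemistry
program — two energies, two gradients, a coupling vector, all from smooth
underlying diabats — with full analytic derivatives and known answers:

* `linear_cone`: linear diabats; in 2-D the seam is the cone apex itself.
* `quadratic_cone`: quadratic diabats drawn from a seed.  Slopes of δ and γ
  are 0.4–1.0 hartree/bohr with a branching-plane opening angle of at least
  35° (so the gap grows healthily in every direction and the crossing is
  well determined), curvatures up to ~0.12 (δ) and 0.08 (γ) hartree/bohr²
  on top of an SPD average-energy curvature of 0.6–1.4.  The curvatures are
  deliberately moderate relative to the slopes: strong enough that a linear
  model degrades visibly within ~0.1 a₀ of the seam, small enough that the
  gap has no spurious non-crossing local minima inside the ~0.25 a₀ basin
  the tests start from.  (A gap minimum with g → 0 but λ > 0 is a genuine
  failure mode of *any* degeneracy-restoring optimizer, not something a
  surrogate can repair; the asymmetric variant used in the
  surrogate-versus-linear comparison raises `delta_curv` to 0.5.)
* `spin_harmonic`: two isotropic paraboloids with γ ≡ 0; the constrained
  minimum of the average energy on the crossing hyperplane has a closed
  Lagrange form, kept as `known_mecp`.
* `random_poly`: unconstrained random quadratics for property tests.

Backends can randomize the sign of h per call, which is how the tests
exercise the phase-flip rule under realistic conditions.

The independent MECP oracle (`brute_force_mecp`) never touches the
package's optimizer: a grid scan locates the seam neighborhood, then the
smooth penalty function τ + c(δ² + γ²) is minimized (trust-region Newton
with the models' analytic Hessians) for c increasing 10² → 10¹⁰, with the
final answer insensitive (≤10⁻⁷) to doubling c.

**What the models do not emulate:** real molecules have 3N-dimensional
surfaces, anharmonicity beyond second order in the diabats, near-parallel
g/h regions, state crossings with third states, and numerical noise in
gradients and couplings.  Passing tests demonstrate the correctness of the
transforms, the interpolant, and the optimization logic under the stated
conditions — not performance on molecular systems, for which the backend
interface exists but is untested against a real electronic-structure code.

## Problem sizes used in tests and the acceptance script

Dimensionalities 2–9; GEK fits of up to 8–20 points; 200-point round-trip
batches; 100 random linear models; 10-seed optimization sweeps on the 2-D
quadratic-cone family with starts drawn within 0.2 a₀ of the apex.  These
sizes exercise every code path (including the n(m+1) covariance assembly at
m = 9) while keeping the whole suite in seconds.

## Known limitations

* Two states only; no spin–orbit coupling, no three-state intersections.
* Cartesian coordinates with rigid-mode projection; no internal-coordinate
  machinery (curvilinear effects on large-amplitude motions are absorbed by
  extra macroiterations, as the trust radius and variance limit allow).
* The gauge may become inconsistent far from the reference point (flagged
  via φ₁φ₂, not repaired); the macro loop's per-iteration gauge rebuild is
  the practical mitigation.
* The surrogate is a local optimization device: it is not suitable for
  dynamics, and its γ surface's global sign is a gauge artifact of the
  reference phase.
* A fixed trust radius and a fixed variance limit; no overshooting or
  adaptive trust-region logic.
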