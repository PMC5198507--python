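# Methods

## Model and assumptions

The package implements a five-compartment within-host infection model —
uninfected target cells x, infected cells y, free virus v, CTLs z,
antibodies w — with three discrete delays: an eclipse delay τ1 between
cell infection and virion production, a virion maturation delay τ2, and a
CTL activation delay τ3.  Mortality during the first two lags is folded
into survival factors e^{−m1·τ1} and e^{−m2·τ2}.  The nonlinearities are
kept general behind three interfaces:

* growth `s(x)` — must have a unique positive zero x̄ with s′(x̄) < 0
  (assumption H1), i.e. the uninfected cell pool has a carrying state;
* incidence `f(x, v)` — nonnegative, vanishing exactly on the axes,
  nondecreasing in both arguments, with ∂f(x,0)/∂v nondecreasing in x
  (H2);
* removals `g1..g4` — strictly increasing, g(0) = 0, g′(0) = 1,
  g(ξ) ≥ k·ξ (H3); and f(x,v)/g2(v) nonincreasing in v (H4), which is the
  saturation property that makes the infected regimes globally ordered.

H1–H4 are semialgebraic or transcendental statements about user-chosen
functions; the package certifies them on a dense grid (default ≥ 120
points per axis over (0, 2x̄] × (0, v_max], v_max = 10 by default)
rather than symbolically, and reports the first violating point.  The
grid box is an explicit parameter because some shipped forms satisfy the
monotonicity assumptions only on the biologically visited range: the
exponential-shift incidence β·x·((v−b1)e^{−c1·v}+b1) has ∂f/∂v < 0 for
v > 1/c1 + b1, far above the virus levels its example parameters reach.

Time and concentration units are abstract throughout: the model fixes
none, so rates are "per unit time" and states "amount" in whatever units
the user's parameters imply.

## Thresholds and equilibria

Every construction reduces to closed-form inversions of the removal laws
plus one bracketed scalar root on (0, x̄), which is provably unique under
H1–H4; roots are found with Brent's method at 1e−12 relative tolerance on
the bracket (ε, x̄ − δ), δ halved adaptively until the sign straddles
(the immune-free construction's defining function G also vanishes at x̄
itself, so the right endpoint must stay strictly inside).  Removal-law
inverses are analytic for the shipped forms and fall back to monotone
bisection on an adaptively doubled bracket otherwise.

Two algebraic points deserve note because the source material for these
threshold formulas is typo-prone in the literature:

* the antibody-establishment number is implemented as
  R1 = k·e^{−m1τ1−m2τ2}·f(x2,v2)/(a·u·g2(v2)) — with the infected-cell
  death rate a in the denominator.  This is forced by internal
  consistency: it is exactly what makes w2 = g3⁻¹(u(R1−1)/q) solve the
  steady-state system, keeps R1 < R0, and yields the sign relation
  sign(x2−x1) = sign(v1−v2) = sign(R1−1) that the tests verify.
* the antibody-competition number is implemented from its derivation as
  R4 = k·e^{−m2τ2}·g1(y4)/(u·g2(v4)) (equal to k·b·r·e^{−m2τ2}/(u·c·h)
  for identity removals), which reproduces both worked examples.

Boundary equalities (a threshold exactly 1) count as "≤ 1": the interior
component of the gated equilibrium does not exist there, matching the
weak inequalities of the stability theory.  Regime classification is the
threshold pattern {R0 ≤ 1 → E0; R1, R2 ≤ 1 → E1; R1 > 1, R3 ≤ 1 → E2;
R2 > 1, R4 ≤ 1 → E3; R3, R4 > 1 → E4}, with the last two contingent on
τ3 = 0 — for τ3 > 0 those regimes can destabilise, so the classifier
returns "indeterminate" listing the satisfied conditions instead of
overclaiming.

The worked-example fixtures reproduce the published values to ~1e−3
relative; the residual discrepancies are printed-rounding artifacts of
the source (its E3/E4 tuples were evidently computed from 4-decimal
intermediate values; its printed z3 and v4/w4 entries are internally
inconsistent with its own constructions and are reported from the
constructions instead).

## Linear stability

Linearisation at an equilibrium gives the characteristic matrix
M(λ) = λI − J0 − J1·e^{−λτ1} − J2·e^{−λτ2} − J3·e^{−λτ3}, with all
Jacobian blocks assembled from the analytic partials of the registered
forms.  At E0–E3 the determinant factors into scalar terms and a reduced
determinant; both routes are implemented and agree to machine precision,
which functions as a structural cross-check of the generic matrix (the
only route available at E4).

Root location is numerical: Newton iterations (finite-difference
derivative — legitimate since Δ is entire) from a coarse grid of starts,
deduplicated at 1e−6, plus an argument-principle winding count over the
right-half search rectangle.  Two numerical details matter:

* phase tracking along the contour must not alias: the e^{−λτ} factors
  rotate the phase along the vertical edges at rate ≈ Στ, and a zero just
  off the contour can spin it by 2π+ε within one segment while the
  wrapped increment looks small.  The initial sampling density is
  therefore tied to the total delay (spacing ≈ 1.2/(1 + Στ)), and a
  segment is accepted only when a midpoint split reproduces its phase
  increment exactly (each part ≤ π/2 and summing to the whole);
  otherwise both halves are refined recursively;
* the default rectangle extends to
  σmax = 1 + max(rates, c·g1(y) − b, r·g2(v) − h) at the analysed
  equilibrium — the two scalar-factor roots can exceed every individual
  rate constant (the antibody-only equilibrium of the first worked
  example has c·y2 − b ≈ 13.5 against a largest rate of 3).

Verdicts: a refined root with Re λ > 1e−7 ⇒ unstable; winding count 0 ⇒
stable; a located root within 1e−7 of the imaginary axis ⇒ marginal
(Hopf candidate); otherwise inconclusive.  The analytic instability
shortcuts of the theory (λ* = r·g2(v)−h at E1/E3; the sign-change
certificate of λ + b − c·g1(y)e^{−λτ3} at E1/E2) are exposed separately
and cross-checked against the numerical verdicts.

## Delay integration

The integrator is the method of steps: classical RK4 with a fixed step,
where delayed arguments are read from the cubic-Hermite dense extension
of the already-computed solution (or from the initial history before
t = 0).  The step must satisfy h ≤ min(positive τ)/4, which guarantees
every delayed stage argument lies in the computed region, so no implicit
iteration is needed; the default is h = min(positive τ)/20 capped at
0.05.  Cubic Hermite interpolation with exact node values and
derivatives carries the full fourth order through the delayed reads; the
test suite measures the global order on the scalar problem
y′(t) = −y(t−1) against its exact piecewise-polynomial solution
(y(6) = −41/720) and obtains slope 4.0.

A fixed, delay-aligned step was chosen over an adaptive embedded pair
deliberately: derivative discontinuities propagate from t = 0 at the
delay lattice, a fixed divisor-aligned step keeps them on grid nodes,
and runs are bit-reproducible — which the scan machinery relies on.
Stiffness does not arise at the parameter scales of the shipped
examples; this is a documented limitation, not a checked invariant.
States dipping below −1e−6 trigger a warning and a retry at half the
step; smaller negative round-off excursions are tolerated and clipped
inside the nonlinearities.

Histories are constant vectors by default.  Because the CTL and antibody
equations carry their own state as a factor (g4(z), g3(w)), a compartment
starting at exactly 0 remains 0 forever; basin checks therefore use an
"equilibrium + 10%" history with a floor of 0.1 on absent compartments.

## Oscillation detection and τ3 scans

For τ3 > 0 the CTL-involving equilibria can undergo Hopf bifurcations
and stability switches; the package treats this regime empirically,
matching the numerical character of the underlying theory (no
normal-form analysis).  A trajectory is classified on its post-transient
window (default: the last 30% of the run): converged if every
component's relative amplitude is below ε_conv = 1e−3, oscillatory if
the virus amplitude exceeds ε_osc = 1e−2 *and* does not decay across the
last two quarters of the window (final-quarter amplitude ≥ 0.5× the
previous quarter's), undecided otherwise.  The thresholds separate the
clearly damped from the clearly sustained cases of both worked examples
by more than an order of magnitude and are configurable.  The dominant
period is the median peak-to-peak spacing of the virus component — a
spectral estimate would add a dependency without adding precision at
these amplitudes.  A τ3 scan is one integration plus one classification
per grid point (default T = 3000 with the default step), with switch
points reported as the grid intervals where the classification changes;
scans are deterministic, so reruns reproduce classifications
bit-identically.

## Lyapunov functionals

The five regime-certifying functionals V1–V5 are evaluated numerically
along trajectories.  Each combines Volterra compartment terms
Φ(u) = u − u* − ∫_{u*}^{u} ĝ(u*)/ĝ(θ) dθ and delay-window integrals of
H(ξ) = ξ − 1 − ln ξ over [−τi, 0].  Compartment terms are anchored at the
reference equilibrium (the additive constants conventionally omitted in
derivations are included) so each functional is ≥ 0 and vanishes exactly
at its equilibrium.  State-space integrals use adaptive Gauss–Kronrod
quadrature; delay-window integrals use composite Simpson on the dense
interpolant with node spacing ≤ h (the integrands are smooth along
trajectories).  In V5, the antibody term's coefficient is
q·f(x4,v4)/(r·g2(v4)(u + q·g3(w4))) — including the activation rate r,
which the delayed-term cancellation in dV5/dt requires; the
monotonicity tests confirm this numerically.  The suite checks, per
regime (τ3 = 0 where the theory requires it), that the matching
functional is nonnegative and nonincreasing along simulated trajectories
within 1e−6·(1+V), and that dV1/dt respects its analytic bound
(a·u·e^{m1τ1+m2τ2}/k)·g2(v)·(R0 − 1) below the infection threshold.

## Random model families

Property suites draw admissible models from a seeded generator.
Unconstrained draws use linear growth (λ ∈ [5, 20], d ∈ [0.05, 0.2] —
fast cell turnover keeps convergence horizons short at desk scale), one
of four incidence forms with β scaled to the carrying state, identity
removals, and rates of order one.  Regime-steered draws exploit the
closed threshold algebra of the bilinear/linear/identity family
(R1 = R0·d/(d + βv2), R4 = v3/v2, R3 = R1/R4) to place (R1, R2, R3, R4)
patterns by solving for h and b, then verify the achieved pattern and
reject failures.  Steering targets stay ≥ 10% away from the threshold
value 1 so that convergence and root-sign checks are not run at
near-marginal parameters.  These families emulate the structural
variety of the model class, not any biological data set: passing suites
demonstrate internal consistency of thresholds, trajectories, roots and
functionals across the family, not fidelity to measured viral kinetics.

## Problem sizes

Default suite scales: τ3-scan classification runs use T = 3000 at the
default step; regime-convergence checks use T = 800 on the fast-turnover
random families; Lyapunov monotonicity uses T = 150 with 12 sample
times; winding contours sample a few thousand points.  These sizes were
chosen as the smallest at which the measured quantities are stable under
doubling (T, grid density) for the shipped examples.
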