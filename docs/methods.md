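# Methods

## Model and assumptions

The package implements a stage-focused (nymphal) tick population model in
which the feeding population on hosts is structured by time since
attachment a ∈ [0, T].  The structured density n(t, a) obeys transport
with loss at the grooming rate ν(F(t)) and boundary inflow
ρ(F(t)) Q(t), where Q(t) = η E(t − τ) is the questing inflow generated by
engorged ticks one development cycle earlier.  Integration along
characteristics turns the structured model into an algebraic (integral)
equation for F(t), coupled to a delay differential equation for E(t).
Standing assumptions: ρ, ν are C¹ and nonnegative on [0, ∞); host
abundance is static (absorbed into ρ); all rates are time-invariant
(no seasonality); demography is deterministic.

The algebraic equation is equivalent to a differentiated form provided the
initial data lies on the constraint manifold — the matching condition that
F(0) equals the integral of surviving past attachments.  On that manifold
the trailing distributed-delay term collapses to ν(F(t)) F(t), which is
the form the simulator integrates; a residual monitor (below) guards
against drift off the manifold.  Solutions from nonnegative matched
histories remain nonnegative; the integrator enforces this as a runtime
invariant.

## Parameters

| name | meaning | units | preset values (bi / quadri) |
|------|---------|-------|------------------------------|
| δ | exit rate of engorged nymphs | 1/day | 0.033 / 0.2 |
| η₁, η₂, σ | stage survivals and egg production | –, –, eggs/day | 0.15, 0.3, 1000 / 0.05, 0.1, 300 |
| η = η₂ση₁ | composite life-cycle factor | – | 45 / 1.5 |
| τ | development delay | days | 700 |
| T | mean feeding duration | days | 7 |
| p, c | Ricker attachment scale and capacity | –, ticks | 0.002, 100 (bi) |
| μ, μ₀ | grooming slope and baseline | 1/(tick·day), 1/day | 0.0014, 0.4 (bi) |
| k | grooming per attachment (ν = kρ) | days | 2/7 (quadri) |
| r, j | Holling-III attack rate and shape | 1/(tick·day), ticks | 0.02, 120 (quadri) |

The preset values follow the field and laboratory estimates cited in
`Preset.documented_sources`.  The reactive-grooming stability analysis
treats k as large compared with 1/T and works with k₀ = kT (here
k₀ = 2, so (e k T)⁻¹ = 0.18 > δ/η = 0.13 and four equilibria exist); the
first-order coefficient k₁ of that scaling is not determined by the
parameterisation and is set to 0, which makes the first-order equilibrium
corrections vanish while leaving the leading-order verdicts unchanged.

## Equilibrium solvers

Each scenario reduces the equilibrium condition to a root problem for a
unimodal function g (g₁(x) = x e^{−(1/c+μT)x} for Ricker + linear
grooming; g₂(ρ) = ρ e^{−kTρ} for the reactive case, followed by inversion
of the Holling-III curve).  Roots are found by bracketed Brent iteration
on the two monotone segments split at the analytic maximizer, with the
upper bracket doubled until it clears the right-hand side; this captures
all roots deterministically because g is unimodal.  Numerical choices:

* root refinement to relative 4·2.2e-16 (machine-level) so the g-residual
  check (absolute 1e-12, scaled by the right-hand side) sits at its
  floating-point floor;
* tangency (double-root) detection when |g(argmax) − rhs| < 1e-9·rhs;
  the equality case returns a single equilibrium labelled `critical`
  rather than two coincident roots;
* every returned nontrivial equilibrium is re-checked against both
  equilibrium lines to relative 1e-10 (a hard error otherwise);
* the Holling-III quadratic inversion is evaluated in the
  cancellation-free form (larger root via the plus branch, smaller via the
  root product F₋F₊ = j²); the textbook minus-branch expression loses
  about seven digits when ρ* ≪ rj/2.

## Stability classification

The linearized spectral problem has a 2×2 characteristic matrix whose
entries mix point delays (e^{−λτ}, e^{−λT}) with distributed kernels
Φ(s) = (1 − e^{−sT})/s; removable singularities at λ = 0 and λ = −ν(F*)
are replaced by series/derivative limits below |λT| = 1e-8.  Because
locating the rightmost zero of the full transcendental determinant is out
of reach in general, verdicts come from the small-feeding-duration
perturbation (feeding lasts a week against a two-year life cycle,
T/(τ+T) ≈ 0.01; a warning is emitted if that ratio exceeds 0.1, since the
verdict is first-order in T):

* Ricker + linear grooming: λ₀ solves −(F₀/c)λ₀ + δe^{−λ₀τ} = (F₀/c)δ;
  its sign is positive exactly on the branch F₀ < c.
* Holling-III + reactive grooming: λ₀ solves
  λ₀ + δ − (δ − A)e^{−λ₀τ} = 0 with the closed-form feedback constant A;
  stable iff A > 0, *gated* on the positive-feedback hypotheses δ > A and
  ηE₀ρ̃₀ < min{e^{k₀ρ₀}, ρ₀k₀/(k₀ρ₀ + e^{−k₀ρ₀} − 1)} — when either
  fails the verdict is `undetermined` rather than a guess.

Sign tolerances: |A| or |λ₀| below 1e-9 also yields `undetermined`, so
stability is never asserted at a numerical boundary.  Beyond the
perturbation formulas, the characteristic determinant is exposed directly
with a real-axis sign-change scan and an argument-principle contour count
over a user-chosen rectangle; these are diagnostics, not a spectral
certification.  As a cross-check, the full determinant's real root on the
lowest quadri branch (0.00192/day) agrees with the perturbation λ₀
(0.00198/day) to 3%.

## Simulator

Method of steps with classical RK4 on the differentiated system, with the
grooming-survival exponent S(t) = ∫_{t−T}^t ν(F) carried as an auxiliary
state (dS/dt = ν(F(t)) − ν(F(t−T))) and re-synchronised by full Simpson
quadrature every 10⁴ steps to bound drift.  The step h must divide both T
and τ (default h = T/70 = 0.1 day for the presets, for which τ/h is also
integral), so every delayed argument the RK4 stages need falls on a grid
point or exactly mid-interval; mid-interval values use 4-point cubic
interpolation of the stored history.  Near the breaking points
t = aT + bτ — where the initial history joins the solution with a
derivative jump that gains one order of smoothness per delay
propagation — a centred stencil would straddle the kink and degrade the
scheme to second order, so one-sided stencils are used at the finite set
a + b ≤ 4.  Measured convergence order on the presets is ≈ 4.0, and the
constraint residual shrinks ×16 when h is halved.

The algebraic identity is monitored by recomputing the integral right-hand
side on the stored grid (inner exponent by cumulative Simpson, outer
integral by Simpson) on a subsampled time grid; with matched histories the
relative residual stays below 1e-5 at h = T/70 over 20 life cycles on both
presets.  Histories: constant levels, a callable E-profile, or two matched
modes — fixed-point iteration of the constant-F-survival right-hand side
for F given E, or the closed form E₀ = F₀/(ηρ(F₀)Φ(ν(F₀), T)) for E given
F.  The second form is how "initial feeding load = X" experiments are set
up: it keeps F(0) = X exactly while placing the pair on the constraint
manifold.  Convergence detection declares an attractor reached when the
relative distance to a known equilibrium stays below 1e-4 for a full
life-cycle window; default horizon 50(τ+T) ≈ 35,350 days (delays of 707
days mean transients span decades).

The integrator is explicit by design (stiff solvers are out of scope).
Histories far outside the plausible load range can make the attachment
feedback stiffer than the step resolves — e.g. a matched Ricker history at
F₀ ≈ 700 implies E₀ ≈ 1.6·10⁴ because ρ decays like e^{−F/c} — and such
runs abort with positivity diagnostics rather than integrate garbage.

## What the case studies show — and don't

The two presets are point parameterisations, not fitted models: passing
tests show that the solvers, classifiers and integrator agree with the
analytic structure (root counts, verdicts, basin assignments, conservation
laws) at those parameters, not that real tick populations are bi- or
quadri-stable.  Real systems add seasonality, host dynamics, stochasticity
and stage overlap, all outside this model class.

Two documented numerical caveats about the reference values attached to
the presets: (i) the quadri reference coordinates embed 4-decimal rounded
attachment roots, so the solver agrees with them to ~0.1% but not to all
printed digits; (ii) the bi reference equilibria (5.1798, 7.0223) /
(37.1687, 164.9135) and the fold value T* = 9.3718 are not simultaneous
roots of the stated equilibrium equation at the stated parameters — the
solver yields (5.1718, 6.9144), (38.3470, 168.0625) and T* = 9.4187, and
the reported fold load 135.9141 contradicts the tangency identity
F = (1/c + μT*)⁻¹ = 43.129.  Reports therefore show computed and reference
columns side by side with their relative deviation instead of reconciling
them.

A quantitative limit worth knowing: at criticality (R₀ = 1) the
constant-scenario dynamics converges to the asymptotic constant E_c at the
rate of the slowest nonzero root of λ + δ = δe^{−λ(τ+T)}, which at
δ = 0.033 and τ + T = 707 is Re λ ≈ −4.4·10⁻⁵/day — an oscillatory
history retains ≈ 21% of its non-constant amplitude even after 50 life
cycles.  The test suite verifies convergence *at that predicted rate*
(window-amplitude ratio 0.46 over 25 life cycles, matching e^{25L·Reλ});
a fixed accuracy target such as 0.1% of E_c within 50 life cycles is
attainable only for histories that are already nearly constant.

## Known limitations

Hopf bifurcation detection, continuation of periodic orbits and global
dynamics are not attempted (the perturbation verdicts are local and
first-order in T).  Equilibrium solvers cover the four named behaviour
pairings only.  The bifurcation scan varies one parameter at a time.  The
CLI is a thin veneer; programmatic use through the library API is the
primary interface.
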