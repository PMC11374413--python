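# Methods

## Model

The package models a two-stage ectotherm life cycle: a non-reproductive
juvenile stage maturing into a reproductive adult stage over a
temperature-dependent duration.  Juveniles recruited at time t were
born one developmental delay earlier, so the dynamics are delay
differential equations with a state-dependent delay τ(t).  The delay
and the through-stage survivorship S_J(t) carry their own dynamics,
derived from the bookkeeping identity that an individual maturing at
time t has accumulated exactly one unit of the maturation index:
∫ over (t−τ(t), t) of m_J[T(x)] dx = 1.  Differentiating that identity
gives τ' = 1 − m_J[T(t)]/m_J[T(t−τ)], and the analogous survival
integral gives the S_J equation.  At constant temperature τ = 1/m_J and
S_J = e^(−d_J τ) are fixed points of both equations.

Assumptions worth stating explicitly:

* a single, well-mixed population; no space, no interspecific dynamics
  (species are compared through their separate single-species models);
* one juvenile class — adequate when density dependence acts on adults
  or on all juvenile stages equally, since pre-reproductive stages then
  act as a pure lag;
* trait responses measured at constant temperatures transfer to the
  dynamic setting instantaneously (no acclimation);
* density dependence, when present, acts multiplicatively on one rate:
  fecundity B = b(T) e^(−q_b(T) A) or adult mortality
  D_A = d_A(T)(1 + q_d(T) A).  The mortality form is read as mortality
  increasing linearly with density; the alternative divisive reading
  admits no positive equilibrium and contradicts the published
  equilibrium abundances.

## Thermal response families

* Boltzmann–Arrhenius, v(T) = v_ref e^{A(1/T_ref − 1/T)} — mortality
  rates and the monotonic competition hypothesis.  A (Kelvin) is the
  activation enthalpy over the gas constant; v_ref is the rate at the
  reference temperature T_ref = 297 K, inside the full-activity range.
* Gaussian, b(T) = b_peak e^{−(T−T_opt)²/(2s²)} — birth rate and the
  unimodal competition hypothesis; s (Kelvin) is the response breadth.
* Sharpe–Schoolfield, m(T) = (T/T_ref) v_ref e^{A(1/T_ref−1/T)} /
  (1 + e^{A_L(1/T_L½−1/T)} + e^{A_H(1/T_H½−1/T)}) — maturation.  When
  the low-temperature inactivation pair cannot be estimated the low
  term is dropped; when neither side can, the response degenerates to
  a plain exponential without the T/T_ref prefactor.

Competition strength q(T) reuses the Arrhenius/Gaussian evaluators
(identical functional forms, per-individual units).  The baseline
configurations used for the two-species comparisons are: unimodal
competition on fecundity with q = 0.1 at the birth optimum and the
birth breadth; monotonic competition on adult mortality with q = 0.1
at 297 K and the species' adult-mortality Arrhenius constant.  Only the
unimodal mapping for the fecundity case reproduces the published
equilibrium abundances; both remain user-selectable.

## Temperature scale

All internal temperatures are Kelvin.  Celsius conversion uses an
offset of 273.0 K, not 273.15: the shipped parameter sets place the
24 °C rearing treatment at exactly 297 K and the freezing point at
273 K, i.e. the parameters were constructed on the rounded scale, and
reporting on the same scale keeps every temperature self-consistent
(the choice moves reported Celsius values by 0.15 °C).

## Closed forms

Growth rate: substituting an exponential ansatz into the constant-
environment adult equation gives λ + d_A = b S_J e^{−λτ} e^{... }, whose
dominant solution is r(T) = −d_A + W(b τ e^{τ(d_A−d_J)})/τ with W the
principal Lambert-W branch; the argument is positive, so r is real.
For arguments beyond floating-point range the package solves
w + ln w = ln(arg) by Newton iteration in log space.

Equilibria: with x = b S_J / d_A the lifetime replacement ratio,
A* = ln(x)/q_b (DD fecundity) or A* = (x−1)/q_d (DD adult mortality),
both requiring x > 1; J* = B* A* (1 − S_J)/d_J from the juvenile
balance.  Both A* expressions vanish continuously at the r = 0 niche
boundary.

Stability: at constant temperature S_J and τ are constants and
juveniles do not feed back on the adult equation, so the linearization
about A* closes on the scalar delayed characteristic equation
λ = −a + c e^{−λτ}, with (a, c) = (d_A, d_A(1 − q_b A*)) under DD
fecundity and (d_A(1 + 2 q_d A*), b S_J) under DD mortality.  All roots
are λ_k = −a + W_k(cτe^{aτ})/τ over the Lambert-W branches.  The
dominant root comes from the principal branch — a complex-conjugate
pair when the argument falls below −1/e, in which case no real roots
exist at all.  Roots are Newton-polished to a characteristic residual
below 1e−10·(|a|+|c|), and dominance is cross-checked by
argument-principle root counting in a rectangle to the right of the
reported root (widened once on disagreement).  This reduction, rather
than a four-variable Jacobian, is guarded by a simulation oracle: the
fitted decay rate and ring-down period of a 10% perturbation match
−Re λ and 2π/|Im λ| to within a few percent in the test suite.  The
recovery time is t_rec = −Re λ/|λ|².  Note that the published
recovery-time optima for the fecundity-regulated cases coincide with
the temperature where the dominant pair first becomes real; with the
true (complex) dominant root the optima sit a couple of degrees cooler.
Absolute recovery-time magnitudes in the source table are not
reproducible from the printed rates and are treated as qualitative.

## Numerics

* DDE integration: method of steps with classical fixed-step RK4 and
  cubic-Hermite dense output over the stored solution, which doubles as
  the history interpolant for delayed lookups.  Default step 0.05 day;
  the delay (weeks) always vastly exceeds the step, so delayed lookups
  never land in the step being taken.  Step-halving changes
  end-of-horizon abundance by < 0.01% in the tested scenarios.
* Initial conditions: constant pre-history at the initial abundances;
  τ(0) and S_J(0) solve the maturation-index and survival integrals
  over that history (reducing to 1/m_J and e^{−d_J/m_J} at constant
  temperature).  This keeps the maturation-index identity conserved to
  ~1e−14 under seasonal forcing; initializing τ(0) = 1/m_J(T(0)) under
  forcing would freeze an O(amplitude) violation into the identity.
* Unbounded growth: the density-independent system is linear in (J, A),
  so trajectories renormalize exactly into log space when they approach
  floating-point limits.  The density-independent envelope exploits the
  same structure to integrate all temperatures in one vectorized pass.
* Niche metrics: optimum by bounded scalar maximization (1e−4 K) seeded
  from a 0.05 K sampled curve; T_min/T_max by bracketed root finding
  (1e−6 K) from the curve's sign changes, taking the bracket nearest the
  optimum (with a logged warning) if tails produce multiple crossings.
  Default search window 274–323 K.
* Overlap: intersection by bisection to |r_a − r_b| ≤ 1e−6; integrals
  by adaptive quadrature (absolute tolerance 1e−8).  The shared-niche
  area is the sum of the two one-sided growth-rate integrals split at
  the intersection — equivalently the area under the lower of the two
  r curves on the overlap interval — and each species' overlap fraction
  divides that area by its full-niche r integral.  Interval-width
  ratios would overstate both fractions and do not reproduce the
  published percentages.
* Envelope/recovery extrema on temperature grids are refined by bounded
  maximization to 1e−3 K.

## Fitting

`ThermalResponseModel` fits one family to per-temperature mean trait
values by unweighted nonlinear least squares (trust-region reflective
with positivity/box bounds; multi-start over a coarse grid of the
skewed maturation surface, ties broken by lower SSR then smaller
parameter norm).  Standard errors are the nls-convention asymptotic
ones — residual-variance-scaled inverse normal matrix — with t and
two-sided p-values on the residual degrees of freedom.  Reference-value
parameters are conventionally measured rather than estimated and can be
pinned via `fixed`; pins are echoed in the results.  A near-singular
normal matrix triggers a rank-deficiency warning naming the weakest
parameter and falls back to a pseudoinverse rather than reporting
confident nonsense.

Caveat: with multiplicative measurement noise the homoscedasticity
assumption behind the nls standard errors fails for traits spanning a
wide dynamic range (the adult-mortality rate varies ~25-fold across the
experimental temperatures), and the reported errors are then
anticonservative by tens of percent; for narrow-range traits
(juvenile mortality, ~2.5-fold) the calibration is good.  This is a
property of the estimation convention being reproduced, not of the
implementation.

## Synthetic data generator

`generate_trait_data` emulates the constant-temperature rearing design:
replicate individual measurements at the experimental treatment sets
(24–36 °C for the bagrada, 15–35 °C for the harlequin), drawn as
truth·(1 + Normal(0, σ)) truncated at zero and aggregated to
mean/SE/n.  Defaults: 20 individuals per temperature, σ = 5% —
a realistic cohort size and scatter for insect life-history assays.
It does not emulate: count-valued or censored observations (death and
molt times are interval-censored in real assays), between-individual
heterogeneity beyond the common noise term, temperature-dependent
noise, or missing treatments where no individuals survive.  Passing
tests therefore certify the estimation machinery under the stated
error model, not robustness to those real-data features.

## Known limitations

* Closed-form equilibria and stability cover density dependence on
  fecundity and adult mortality; juvenile-stage density dependence is
  simulated but has no closed-form analysis.
* No steady-state analysis under time-varying forcing (no equilibrium
  exists there); the simulator is the tool for forced scenarios.
* Eigenvalue analysis assumes the scalar adult-equation reduction,
  valid at constant temperature; it is simulation-checked but not
  proved against a full delayed Jacobian.
* The recovery-time metric inherits the scale ambiguity noted above;
  only its location along the temperature axis should be compared
  across studies.
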