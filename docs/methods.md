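# Methods

## Model and reduction

The package treats the spread of a piece of news as a mass-action SIR
process on a closed population of N individuals: potential spreaders S,
active spreaders I, and individuals who have lost interest R, with

    dS/dt = -(τ/N) S I,   dI/dt = (τ/N) S I - ρ I,   dR/dt = ρ I.

τ (transmission rate) and ρ (recovery rate) are constants; time units are
abstract (none of the analytic structure depends on them). S + I + R = N is
conserved. All initial-value handling assumes R(0) = 0; a non-zero R(0) is
folded into the susceptible pool by the exact substitution
S(0)* = S(0)·exp[τR(0)/(ρN)], after which the shifted R starts at zero
(`SIRParams.effective_S0`).

From dR/dt = ρI and the exact first integral S = S(0)·exp[−τ(R−R(0))/(ρN)],
the system collapses to one equation for R. Expanding the exponential to
Taylor order M gives the polynomial chain

    dR/dt = Σ_{j=0}^{M} α_j R^j,
    α₀ = ρ[N−S(0)],  α₁ = τS(0)/N − ρ,
    α_j = −(−1)^j τ^j S(0) / (j! ρ^{j−1} N^j)   (j ≥ 2),

so even-order coefficients (j ≥ 2) are negative and odd ones positive. The
truncation is controlled by the Lagrange remainder

    bound(M, R) = (e/(M+1)!) · x^{M+1},   x = τR/(ρN),

exposed both as the prefactored bound and as the raw ratio x, since both
forms are useful in practice. "Much smaller than one" is operationalized as
a default threshold of 0.1 on the bound; exceeding it produces a warning,
not an error, because the cubic family's own large-t bound e/4! ≈ 0.113 is
still acceptable in this framework. Polynomials are evaluated in Horner
form — the coefficients span ~15 orders of magnitude at realistic
parameters.

## Closed forms

### Quadratic (M = 2, Riccati) family

The order-2 chain is a Riccati equation. With
θ = sqrt[(τS(0)/N − ρ)² + 2τ²S(0)(N−S(0))/N²] (always the positive root;
identically sqrt(α₁² − 4α₀α₂)), the general solution is

    R(t) = −α₁/(2α₂) − (θ/(2α₂)) tanh φ + D / {cosh²φ · [E − (2α₂D/θ) tanh φ]},
    φ = θ(t+C)/2,

with the time shift C fixed by R(0) = 0:
C = (2/θ)·atanh[θ(α₁E − 2α₂D)/(2α₁α₂D − θ²E)]. Construction fails
(`ConstantsInfeasibleError`) if that atanh argument leaves (−1, 1). Only
the ratio D/E matters when E ≠ 0; the formal E = 0 branch is rejected. I(t)
is evaluated from the explicit derivative of the closed form (not by
numerical differentiation), and S(t) from the first-order S(R) relation.

The canonical wave is D = 0: a sech² pulse with

    t_m = (2/θ)·atanh(α₁/θ),   I_m = θ²N²/(2τ²S(0)),

and large-t limit R → −α₁/(2α₂) − θ/(2α₂). When α₁ ≤ 0 (R_n(0) ≤ 1) the
pulse centre falls at negative time: on t ≥ 0 the wave only decays, and the
horizon is reported as 0 with I_m = I(0).

For D > 0, E > 0 and α₁ > 0, D/E is bounded by θ/(−2α₂), and the value of
R at the pulse centre t = −C interpolates linearly in D/E between the D = 0
reference −α₁/(2α₂) and the upper bound −α₁/(2α₂) − θ/(2α₂)
(`correction_at_minus_C`).

**Numerical form.** The centred-tanh expression is numerically stable for
growing waves but suffers catastrophic cancellation for strongly decaying
ones (both terms ~θ/(2|α₂|) while R is orders of magnitude smaller). For
α₁ ≤ 0 the package therefore evaluates the algebraically identical
logistic-type form

    R(t) = 2α₀ tanh(θt/2) / [θ − α₁ tanh(θt/2)],
    I(t) = (α₀/ρ) · sech²(θt/2) · θ² / [θ − α₁ tanh(θt/2)]²,

obtained from the tanh addition law together with θ² − α₁² = −4α₀α₂. This
form gives I(0) = α₀/ρ = N − S(0) exactly and keeps certification residuals
at the 1e-12 level on decaying waves.

### Cubic (M = 3) family

Substituting R = −α₂/(3α₃) + v·y with y' = p·y + q·y³ into the order-3
chain shows a closed form exists only under one constraint among the
coefficients, α₀ = (α₂/(3α₃))(α₁ − 2α₂²/(9α₃)), which for the SIR-derived
coefficients pins the recovery rate to

    ρ = τ·(1 − S(0)/(3N)).

Solving the Bernoulli equation for y then gives, with A = 6N − 5S(0) and
g = Aτ/(3N),

    R(t) = (N − S(0)/3) · {1 − sqrt[A / (S(0) + 6(N−S(0))·e^{gt})]},
    I(t) = (N−S(0)) · A^{3/2} · e^{gt} / [S(0) + 6(N−S(0))·e^{gt}]^{3/2},

which satisfies R(0) = 0, I(0) = N − S(0) and I = (1/ρ)dR/dt identically;
the certification residual of the cubic chain is ~1e-11 on the reference
grids, and perturbing ρ off the constraint by 10% degrades it to ~0.4 — the
constraint is necessary, and the residual check is the arbiter of the
implemented form. ρ is therefore *not* a free input for this family.

Properties worth noting: the large-t limit is R → N − S(0)/3, where
x = τR/(ρN) = 1 exactly, so the validity bound tends to e/4! ≈ 0.113 in the
far tail of every cubic-family wave. The wave is only *monotonically*
decaying when S(0) ≤ 3N/4 (initial spreaders ≥ N/4); for smaller seeds it
rises briefly to I_m = A^{3/2}/(3^{5/2}·sqrt(S(0))) at
t_m = (3N/(Aτ))·ln[S(0)/(3(N−S(0)))] before the fast decay. The horizon
t_m shrinks with I(0) and reaches 0 at I(0) = N/4 — the family models
short-lived waves that require a large initial push.

## Certification

Closed forms are never trusted blindly. `residual_m2` / `residual_m3`
evaluate R on a uniform grid, differentiate it with a 5-point (4th-order)
central stencil, and report max|dR/dt − Σα_jR^j| normalized by α₀; a wave
is certified when this is below 1e-5. Second-order differences are not
accurate enough (≈3.5e-5 discretization error on the reference grids);
4th-order stencils reach 3e-8 (quadratic) and 4e-12 (cubic). The
normalization degenerates as S(0) → N (α₀ → 0), so the degenerate limit is
checked by the trajectory itself vanishing instead. Scenario runs certify
the *emitted window*: residual on a dedicated 50,001-point grid and the
validity bound maximized over the sampled trajectory.

## Numerical oracles

Two independent oracles back every closed form: adaptive integration of the
full SIR system and of the truncated chain (`scipy.integrate.solve_ivp`,
LSODA, rtol 1e-9, atol 1e-9·N capped at 1e-6), both sampled on uniform
grids from dense output. The oracle error must sit far below the truncation
error being measured; at these tolerances the full-SIR peak reproduces the
conserved-quantity closed form I_max = I(0)+S(0)−(ρN/τ)[1+ln(τS(0)/(ρN))]
to ~7 digits. Closed form and chain integration agree to sup-norm relative
error < 1e-6 (they solve the same ODE). Against the *full* model the gap is
real truncation error: at the basic scenario (N = 10⁷, one seed,
τ = 0.00825, ρ = 0.00775, x reaching 0.12 in the tail) the quadratic
family's peak sits 2.04% below the full-SIR peak and the peak time agrees
to 0.44%; at x_max ≤ 0.02 the peak error drops below ~0.3%. The cubic
family at its reference scenario agrees to 0.12% at the peak.

## Metrics, sweeps, typology

`compute_metrics` reports I_m, t_m, the R_n = 1 downcrossing, the large-t
limit of R, and the maximum validity bound. For closed-form waves the
closed-form peak is used (cross-checked against bounded scalar maximization
in the tests); for sampled trajectories the grid argmax is refined
parabolically, σ is computed by central differences of ln I (exact for
exponentials; undefined below an extinction floor of 1e-12·N), and the
R_n = 1 crossing by linear interpolation of the sign change. Windows whose
I is still rising auto-extend by doubling up to 2¹⁰×.

Parameter sweeps expose the directional laws: I_m increases with I(0), N
and τ and decreases with ρ; t_m decreases with I(0) and τ and increases
with N. On the shipped ρ-grid the two largest rates give R_n(0) < 1 (no
wave: I_m = I(0), t_m = 0), so monotonicity in ρ is strict among growing
waves and non-strict overall.

The A–E typology quantizes the (τ, ρ) plane: A high-τ/low-ρ, B high/high,
C low-τ/high-ρ, D low/low, E the intermediate band. The theory gives no
numeric cut-offs, so they are user configuration; the shipped defaults
(0.004 / 0.012 for both rates) bracket the basic-scenario rates
symmetrically. Boundary values resolve away from E toward the adjacent
corner (ties in A < B < C < D order), making the map total and
deterministic.

## Wavetrains

A wavetrain chains waves by seeding wave k+1 with the active spreaders of
wave k at a splice time: I(0) = I_prev(t_splice), R(0) = 0,
S(0) = N − I(0). The reset of R and S encodes that each wave carries a
*new* (similar but different) piece of news: nobody has yet lost interest
in it, so the susceptible pool refills. This is the only initialization
that supports indefinitely increasing trains; carrying R over would cap the
growth. I is exactly continuous at splices by construction; S and R jump.

Splice times are either absolute durations or a fraction f of the running
segment's peak time. The default f = 1.5 ∈ (1, 2) splices after the peak
while I(t) still exceeds the segment's own seed (the sech² pulse is
symmetric about its centre, returning to I(0) at 2t_m), which yields
distinct humps of strictly increasing amplitude; f = 2 exactly reproduces
the seed and leaves amplitudes invariant (autonomous-system time shift);
later splices give decreasing trains. Trains are classified
increasing/decreasing/mixed by strict amplitude ordering; segment metrics
are reported on each segment's own clock, with global-clock peak times
alongside.

## Scenarios

The shipped scenarios encode the canonical parameterizations: the basic
wave (N = 10⁷, S(0) = 9,999,999, τ = 0.00825, ρ = 0.00775), seed/population/
rate sweeps around it, the cubic-family reference (N = 10⁶, S(0) = 9×10⁵,
τ = 0.009, ρ implied) with its seed and rate sweeps, and a four-wave
increasing wavetrain on the basic parameters (splice policy f = 1.5 for the
first three waves; the published construction states only that splices
happen before the previous wave vanishes, so this fixture is approximate by
design). One transmission-rate value circulates in two versions — 0.0875 as
printed and 0.00875 as the plausible intended value — and both ship,
labelled; the printed value drives the wave far outside the Taylor validity
range and honestly fails certification. Scenario time windows are not part
of the parameterization; they auto-extend to 3t_m (quadratic family) or
t_m + 6 decay e-foldings (cubic family), and the chosen window is recorded
in the output metadata.

## Limitations

* τ and ρ are constants; no behavioural feedback, networks, or agents.
* No inference: the package maps parameters to waves, it does not fit τ, ρ
  to observed data.
* The closed forms assume the wave touches a small fraction of the
  population (x = τR/(ρN) small). At x ≈ 0.1 the quadratic family's
  amplitude error against the full model is ~2%; the regime R/N → 1 is out
  of scope and needs the numerical oracle only.
* The scenarios are analytic parameterizations, not data; passing tests
  demonstrates internal consistency of the theory and its implementation,
  not agreement with any empirical news dataset.
* The first-order S(R) reconstruction can go negative outside the validity
  range (it warns); the exact exponential form is available via
  `susceptibles_from_R`.
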