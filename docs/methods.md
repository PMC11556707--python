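# Methods

## Model

The perceiver tracks a scalar latent state — actual or potential tissue
damage on the clinical 0–10 scale — with a Kalman filter.  The posterior
mean x̂ is identified with perceived pain and the prior mean x̄̂ with
expected pain.  Control inputs **u** are anything that predicts a change in
pain (cues, context, actions); they enter the prediction through gains B̂
and inflate the process noise, Q = Q₀ + ‖u‖² Qᵤ, reflecting that predicted
transitions are more uncertain than quiescent ones.  The observation map is
H = 1: sensation lives on the same scale as damage, and the mapping between
the two is assumed linear throughout (a known simplification; see
Limitations).

The hierarchical layer treats the parameter vector p̂ = [Â, b̂₁ … b̂ₘ]ᵀ as a
random-walk latent state with diagonal drift covariance Q_p and updates it
from the pain prediction error ê = x̂ − x̄̂.  Two choices depart from the
textbook dual filter, deliberately:

- **Error variance** R_p = P + P̄, the sum of the variances of the two
  estimates being differenced (older variants used R, Q + R or Q + P).
  Consequence: R_p stays moderate even when R → ∞, so the parameter gain
  K_p does not vanish with sensory noise — instead the *error itself*
  vanishes (ê = K(z − x̄̂) with K → 0), which is what makes the persistence
  estimate collapse onto a pure random walk in the no-information limit.
- **Gain-scaled covariance update** P_p = (I − K K_p H_p) P̄_p.  Without
  the K factor, P_p → 0 as R → ∞: the model would grow *certain* of its
  internal parameters exactly when sensation provides no evidence about
  them.  Both behaviours are exposed (`legacy=True` gives the unscaled
  update) and asserted in the tests.

### Numerical form of the covariance update

The scaled update is implemented as the left-multiplied form
P_p = P̄_p − K·w wᵀ/S with w = P̄_p H_pᵀ and S = H_p P̄_p H_pᵀ + R_p.
Because the subtrahend is a scaled Gram matrix with K ≤ 1 and
S ≥ H_p P̄_p H_pᵀ, positive semidefiniteness of P_p is preserved by
construction; at K = 1 the expression is the textbook covariance update.
The right-multiplied alternative P̄_p(I − K K_p H_p), read literally,
subtracts the non-symmetric matrix K P̄_p² H_pᵀ H_p / S and is not
PSD-safe — in practice it renders P_p indefinite within a few steps and the
filter diverges.  The result is symmetrised (tolerance 10⁻¹⁰) to suppress
floating-point asymmetry; a property test checks symmetry and the smallest
eigenvalue over 10⁵ covariance updates under rough random schedules.

### Ordering and lag conventions

Within one step: parameter prior → state prior → state update (yields K) →
fresh H_p = (1 − K)[x̂⁽ᵏ⁻¹⁾, u⁽ᵏ⁾] → prediction error with R_p = P + P̄ →
parameter update.  The parameters consuming the step-k error are therefore
in place before the step-k+1 prediction.  The parameter-uncertainty term in
the state-prior variance, H_p P_p H_pᵀ, needs the current-step H_p, which
needs the current-step K, which needs the prior variance — a circularity.
We break it by using the H_p computed at the end of the *previous* step
(initialised to zero at step 0); K varies slowly once the filter has
settled, so the lag is immaterial except in the first few steps, where the
term is dominated by the initial variances anyway.

### Process noise in the prior mean

The prior-mean equation carries an explicit noise term ε(0, Q) in addition
to Q entering the prior variance.  Sampling that term (flag
`sample_process_noise`, default on in scenarios) makes each replicate's
expectation trajectory stochastic and is one source of the reported
interquartile bands; switching it off gives the deterministic textbook
recursion used by the unit tests and by the exactness checks.  The two
noise sources (and the parameter drift, and individual-level draws) are
drawn from independent seeded streams, so toggling one never shifts the
draws of another — this is also what makes the degenerate hierarchy
(Q_p = 0, P_p⁽⁰⁾ = 0) reproduce the single-layer trajectory bit-for-bit.

## World model and sensory sampling

True damage follows x(k) = A x(k−1) + B ũ(k) with recovery rate A and gain
B = 0.8 from the damage input ũ; the state is defensively clipped to
[0, 10], though under every shipped protocol the clip never engages (unit
tested).  Sensory input is N(H x, R) conditioned on [0, 10], sampled by
redrawing out-of-bounds values.  Naive redrawing stalls when the acceptance
probability is tiny (R = 800² accepts ≈ 0.5 % of draws), so the sampler
draws candidates in rounds of 64 per open slot — distributionally identical
to one-at-a-time redraws — and after 1024 candidates falls back to
inverse-CDF truncated sampling, guaranteeing termination without changing
the distribution (KS-tested against the analytic CDF).

Because truncation skews the distributions, replicate-based protocols
report per-step medians with 25–75 % interquartile bands
(linear-interpolation quantile convention) over 100 replicates;
individual-based protocols report cell means with standard errors
sd/√n over 28 simulated individuals.

## Default constants

Single-layer filter: Â = 0.8, B̂ᵢ = 0.6, H = 1, R = 0.8², Q₀ = 0.4²,
Qᵤ = 0.4², P⁽⁰⁾ = 10⁶ (the first update then defers almost entirely to
sensation, making the arbitrary x̂⁽⁰⁾ = 0 immaterial — verified by test).
Hierarchical filter: as above but Q₀ = 0.1², because the parameter
-uncertainty term now carries part of the prediction variability
explicitly; Q_p = 0.002² I, P_p⁽⁰⁾ = 10⁶ I.  Cue magnitude |u| = 3.7 with
orthogonal two-dimensional cue vectors where two cues are in play.

### Initial uncertainties in cue-bearing protocols

Protocols that start *mid-life* — conditioning, the adaptive
sensory-disruption sweep, offset analgesia, and the pain-history runs — use
the settled-perceiver initialisation P = 1, P_p = I rather than the
uninformative defaults.  For the sweep this is stated protocol (a baseline
period would itself move Â); for the others it is this package's choice,
for a structural reason: with P_p ≈ 10⁶ I and a nonzero cue, the term
H_p P_p H_pᵀ in the prior variance saturates K at 1, and since
H_p = (1 − K)[x̂, u], observability of the parameters vanishes; the rare
nearly-observable steps then apply essentially unregularised one-shot
corrections (‖K_p‖ ≈ 1/‖H_p‖ with H_p ≈ 0) that strand the parameters at
arbitrary values from which K = 1 offers no recovery.  A perceiver with a
lifetime of experience has settled parameter uncertainty; only the
cue-gain *values* are protocol-specific draws (N(0.9, 0.8²) truncated at 0
for conditioning).  The long pain-history runs additionally get 3000
pre-injury steps, long enough for Â to reach its quasi-equilibrium from
any of the histories (its relaxation time under baseline noise is a few
hundred steps).

## Protocol-specific choices

- **Discrete trials** (placebo/nocebo, conditioning): Â = 0 — each trial's
  expectation comes from the cue alone — and the prior variance is then
  simply Q.  Test phases use a balanced 2 (cue) × 2 (heat) factorial, 10
  trials per cell, order shuffled per individual; heat levels map to
  damage 3.1 (47 °C) and 4.3 (48 °C), and this linear anchor is reused
  wherever a temperature must be converted to damage.
- **Condition-keyed randomness**: draws that belong to a cue condition are
  keyed by the condition's distribution parameters, not by slot position,
  so relabelling symmetries hold exactly (swapping which cue carries which
  gain law swaps the output cells bit-for-bit; regression-tested).
- **Pain-history runs**: cued impulses (ũ = u = 3.7) every 50 steps during
  a 3000-step history, injury (R → 800²) 50 steps after the last impulse,
  1000 post-injury steps, summary = median pain over the last 25 % of the
  post-injury window.  Only ordinal contrasts between histories are
  asserted; the impulse cadence is configurable.
- **Offset analgesia**: damage is taken as proportional to the applied
  temperature, i.e. a step function through T1 = 49 steps at 3.1,
  T2 = 49 at 4.3, T3 = 4 × 25 back at 3.1 (control: 3.1 throughout); the
  internal model starts matched to the world (persistence 1 between
  temperature changes), u = 0, and interval summaries drop the Δ = 5 steps
  after each temperature ramp.  Only the qualitative undershoot-and-recover
  pattern is asserted; all interval lengths and levels are configurable.
- **Reporting clip**: x̂ is never clipped inside the recursion (escalation
  dynamics under Â > 1 would be distorted); scenario summaries clip to
  [0, 10] for reporting.

## What the synthetic world does and does not capture

The generator reproduces the *statistical* structure of the protocols:
bounded noisy sensation, linear damage kinetics, cue–stimulus pairings,
and population variability through truncated-Gaussian parameter draws.  It
does not model peripheral/spinal transduction, sensitisation or
habituation, nonlinear temperature–damage mappings, or rating-scale
behaviour of human participants.  Passing tests therefore establish the
internal consistency and the qualitative phenomenology of the inference
model, not quantitative agreement with human ratings — consistent with
that, the simulated offset-analgesia undershoot (≈ 0.13 scale units) is
smaller than typical experimental effects.  One consequence of bounded
sensation worth flagging: with true damage at 0 and R = 0.8², truncated
draws average ≈ 0.64, so tracked pain never reports below ≈ 0.6 under
reliable sensation — a floor set by the observation model itself.

## Known limitations

- Scalar pain state; no smoothing (backward pass); R and Q are set, not
  estimated.
- Negative Â is rejected at configuration time (never used by any
  protocol).
- The random-walk limit of Â is exact only in the no-information idealised
  mode (process-noise sampling off); with sampled process noise the
  wandering x̂ keeps H_p slightly informative and the walk acquires a weak
  mean-reverting correction near the escalation boundary.
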