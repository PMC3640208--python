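# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, the numerical conventions, and the limits of
what the synthetic experiments can show.

## Event model

Events are a finite alphabet `E_0..E_{n-1}`; time is discrete and exactly
one event occurs per step. The chain is specified by a column-stochastic
matrix `T[i,j] = P(E_j -> E_i)`; this orientation is used for every
matrix in the package (weights, pair frequencies, predictions all index
`[post, pre]`), and the file formats state it explicitly. Physical time
enters only through `dt_event` (default 0.6 s per step), used for unit
conversion of timescales.

Random chains are generated column by column: a successor count drawn
uniformly from {2, 3, 4} (few successors avoid columns made only of small
probabilities), successors drawn uniformly without replacement, weights
uniform on (0,1) and normalized. Chains whose support graph is not
strongly connected are resampled (up to 1000 attempts) because the theory
layer needs a unique stationary distribution. Two consequences worth
knowing:

* the *accepted* ensemble is not exactly uniform in successor count — at
  n = 12 roughly 40% of raw draws are reducible and rejection shifts the
  accepted degree shares by one or two points away from degree 2;
* self-transitions are allowed by default (`allow_self=False` disables
  them). They leave within-population synapses untouched, but they do
  shape the *statistics* seen by outgoing synapses: a strong
  self-transition makes that event's occurrences bursty, which matters
  for the accuracy of the mean-field formulas (below).

Stationary frequencies are computed as the null space of `T - I` (SVD)
and checked to satisfy `T f = f` within 1e-10.

## Plasticity

Synapses have `m >= 2` stable states with hard bounds: transition
probabilities do not depend on the distance to the bounds. Eligibility at
a step with previous event `a` and current event `b`, for the pair
`pre=j -> post=i` (diagonal pairs are fixed and excluded):

* potentiation: `a == j and b == i`;
* depression: `b == j` (PRE), `b == i` (POST), or always (UNSPECIFIC).

Because one event occurs per step, pre and post are never co-active, so
the "post not active" / "pre not active" clauses of the PRE/POST rules
are automatic.

The large-population fraction dynamics move occupancy `q+ ρ_k` up from
every non-maximal state and `q- ρ_k` down from every non-minimal state,
both fluxes computed from the pre-update occupancies. When a pair is
eligible for potentiation and depression on the same step (possible under
POST and UNSPECIFIC), the update is the exact expectation of independent
per-synapse attempts: interior states move up with `q+(1-q-)` and down
with `q-(1-q+)` (simultaneous attempts cancel), boundary states with the
plain rates. This choice was made because the naive purely additive form
sends interior occupancies negative when `q+ + q- > 1`; for `m = 2` there
are no interior states and both forms coincide with the scalar recursion
`J' = J + q+(1-J)ξ⁺ - q- J ξ⁻`, which is what the simulator integrates.
It also makes the fraction update the exact mean of the finite-N sampled
dynamics (`step_sampled`), which the tests exploit. Differences are
O(q+q-) per step and invisible in the slow-learning regime where the
theory applies.

Default initial condition is all synapses maximally depressed (the
statistics are initially unknown). Simulations record `J` for a chosen
set of pairs at every step; the m = 2 case runs on a specialized scalar
path verified against the generic occupancy update to machine precision.

## Mean-field theory and its accuracy

In the slow-learning limit the sequence-averaged strength obeys
`<dJ> = q+ (1-<J>) f⁺ - q- <J> f⁻`, giving

* steady state `J̄ = F(f⁺/f⁻)` with `F(x) = rx/(1+rx)`, `r = q+/q-`
  (m = 2), and for general m the mean of the truncated geometric
  stationary distribution with ratio `y = rx` — evaluated by direct
  summation of the m power terms, using the symmetry `F(1/y) = 1 - F(y)`
  for `y > 1`. This is algebraically identical to the closed-form
  expression with the `y -> 1` singularity removed, exact at `y = 1`
  (value 1/2), and stable for all arguments, which is why the series
  cutoff approach was not used. The closed form and a numerically solved
  birth–death chain serve as independent cross-checks in the tests.
* timescale `τ = J̄/(q+ f_AB) = 1/(q+ f⁺ + q- f⁻)` in event steps.

The formulas neglect correlations between consecutive modifications,
which is exact as `q -> 0`. At the working point `q+ = 0.06, q- = 0.03`
the residual bias is real but small: across random 12-event chains the
bulk of pairs sits within ~0.01 of `F(x)`, while pairs whose presynaptic
event has a strong self-transition (bursty depression) can deviate
systematically by up to ~0.035 — measured against multi-million-step
simulations, not sampling noise. Steady-state comparisons therefore use a
per-pair tolerance `max(0.03, 3ΔJ)` with ΔJ the predicted fluctuation
std, rather than a flat band that the rarest pairs would dominate.

Transient validation fits `J(t) = J̄(1 - exp(-t/τ))` by nonlinear least
squares over the first five predicted timescales, starting from the
all-depressed state, with the fit initialized at the predicted values;
transients are ensemble-averaged over independent sequences before
fitting. Pairs whose fit window exceeds the simulated horizon are
reported as unfitted rather than extrapolated.

## Sliding-window estimator

The effective model counts potentiating (`N⁺`) and depressing (`N⁻`)
events in the trailing `round(τ)` steps (rectangular window, minimum 1,
τ computed from the true chain statistics) and reports `F(N⁺/N⁻)`.
Conventions: step 0 has no predecessor and never counts; windows are
clipped at the sequence start; a window with `N⁻ = 0` carries the last
defined estimate forward (an estimator with no evidence should not move),
and before any evidence the estimate is 0, matching the simulator's
initial state. Its steady-state fluctuation prediction
`ΔJ² = F′(P)² P(1-P) / (2 f_A τ)` is implemented exactly as stated
(including the factor 2, which is validated empirically, not derived
here) and applies to the PRE rule with bistable synapses; for the other
rules the same counting-noise construction with the rule's own `f⁻` is
used internally as a noise scale only.

Correlations between full and effective time series are plain Pearson
coefficients on the post-burn-in overlap (burn-in: five timescales per
pair, never less than the window); pairs with a constant series — in
practice pairs essentially never potentiated — have no defined
correlation and are excluded from medians.

## Rate network

`n` excitatory populations and one linear, instantaneous inhibitory
population, which collapses to a single effective strength `g_I`
subtracted from every weight. Dynamics per population:
`τ_m dr/dt = -r + Φ(Σ_j (J[i,j] - g_I) S_j + h_i) + σ η`,
`τ_s dS/dt = -S + g_s r`, with `Φ(x) = g max(x, 0)`. Defaults:
`τ_m = 10 ms`, `g = 450`, `τ_s = 100 ms`, `g_s = 0.02`, self-weight 0.02,
pulses of amplitude 0.05 for 100 ms. Integration is explicit Euler at
`dt = 0.5 ms` (an order of magnitude below `τ_m`; construction rejects
`dt > τ_m/10`), noise added as `σ sqrt(dt)/τ_m` per step
(Euler–Maruyama); halving `dt` moves peak rates by well under 1%. Rates
are not clipped: rectification acts on the input current, so noise can
drive rates transiently negative.

Learned weights are `J[post, pre] = F(P(pre -> post))` with the diagonal
set to the fixed recurrent value. The bundled 5-event demonstration
scheme uses the transition set A→{B:0.65, C:0.35}, B→{D:0.9, E:0.1},
C→{D:0.55, E:0.55} at `q+/q- = 1`; as printed the C column sums to 1.1,
so by default columns are renormalized, with a flag to reproduce the raw
values — the package does not silently pick one of the two plausible
typo corrections. D and E return to A so the scheme closes into a chain.

Behavioral regimes at the three inhibition strengths (0.5 / 0.4 / 0.3):
isolated responses; one-step prospective activation with amplitude
growing in `J - g_I`; prediction plus competition. One quantitative
caveat found in simulation: with a *single* input pulse, the global
inhibition contributed by the driven population's slowly decaying gating
suppresses the second prediction step at `g_I = 0.3` under the
demonstration weights — multi-step predicted sequences (attenuating,
elongating transients) appear robustly at weaker inhibition
(e.g. `g_I ≈ 0.1`), which is where the attenuation property is tested.

Winner-take-all: a source excites two targets, both above `g_I`; the
winner of a trial is the target with the larger time-integrated rate over
the 500 ms after pulse onset (ties broken uniformly at random). The noise
amplitude is not dictated by the model; the defaults σ ∈ {0.2, 0.5, 1.0}
were chosen by a scale argument (input-weight differences of order
0.01–0.1 times gating ~0.4, against rate noise σ/sqrt(2τ_m)) so the
psychometric curves span the full range, and the qualitative claims —
certainty without noise, chance at equal weights, monotonicity in the
weight difference, steepening as noise falls — hold for any σ.

## Synthetic experiments: scales and what they show

All campaigns generate their own chains; there is no external data.
Steady-state quantities are time averages over one long run per matrix
(200,000 steps, burn-in five times the slowest pair timescale) — at
steady state this is equivalent to averaging many independent trials, and
far cheaper; per-pair precision is `ΔJ sqrt(2τ/T_avg)`, which the tables
let the reader reconstruct. Problem sizes (10–12 events, 10 matrices,
2×10⁵ steps, 20 transient trials, 200 winner-take-all trials per
condition) were chosen so each campaign completes in minutes on one core
while leaving the acceptance statistics' Monte-Carlo error well inside
the bands they are checked against.

What passing these experiments does *not* show about real data: events
here are discrete, non-overlapping, perfectly detected, and Markov;
neural populations are noiseless during learning and non-overlapping;
plasticity has no spike-level structure, no heterogeneity, and no
multiple timescales. The claims validated are about the model's internal
consistency (simulation vs closed form vs estimator), not about fits to
biological measurements.

## Known limitations

* The slow-learning formulas carry an uncorrected O(q) correlation bias,
  largest for bursty (high self-transition) presynaptic events; the
  exact correlation-aware steady state is not implemented.
* The fluctuation formula is implemented for the PRE rule with m = 2
  only; other rules report simulated stds without a closed-form partner.
* Soft-bound multi-state synapses are not simulated; their steady state
  coincides with the bistable case, which the m = 2 theory covers.
* The estimator reproduces fluctuations on the timescale τ and misses
  faster ones, which is why full-vs-effective correlations plateau
  around 0.85 rather than 1.
* Winner-take-all probabilities are not calibrated to reproduce the
  event transition probabilities themselves; that would require tuning
  the noise amplitude or an additional mechanism.
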