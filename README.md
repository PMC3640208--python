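# contiguity

Simulation and theory of how populations of bounded synapses encode
*temporal contiguity* — the tendency of one event to follow another — and
how a simple firing-rate network reads that code back out as predictions.

The package is aimed at computational neuroscientists studying synaptic
plasticity and sequence learning: it generates Markov sequences of
discrete events, drives populations of stochastic multi-state synapses
with them, predicts the resulting steady-state weights, relaxation
timescales and fluctuations in closed form, and simulates a
threshold-linear readout network with global inhibition.

## The model

Events `E_1 .. E_n` occur one per time step, following a Markov chain with
column-stochastic transition matrix `T[i,j] = P(E_j -> E_i)`. Each event
activates one neural population. Synapses between populations `j -> i`
have `m` stable states and move up one state with probability `q+` when
the potentiating sequence (`j` at `t-1`, `i` at `t`) occurs, and down one
state with probability `q-` when a depressing event occurs — where a
depressing event is an occurrence of the presynaptic event (PRE rule), of
the postsynaptic event (POST rule), or any event (UNSPECIFIC rule).

For a large synaptic population, the fraction dynamics of the mean
normalized state `J` relax (in the slow-learning limit) to

    J̄ = F(f⁺/f⁻),      F(x) = (q₊/q₋)x / (1 + (q₊/q₋)x)   (m = 2)

with `f⁺`, `f⁻` the frequencies of potentiating and depressing events, so
the steady-state weight encodes the transition probability `P(A→B)` (PRE),
the conditional probability `f_AB/f_B` (POST), or the pair frequency
`f_AB` (UNSPECIFIC). For `m`-state hard-bound synapses, `F` is the mean of
the truncated geometric stationary distribution of the associated
birth–death chain and sharpens toward a step at `q₋/q₊` as `m` grows. The
relaxation timescale is

    τ = J̄ / (q₊ f_AB) = 1 / (q₊ f⁺ + q₋ f⁻)     [event steps],

and the synapse behaves like a sliding-window estimator: counting
potentiating and depressing events over the trailing `τ` steps and
mapping the ratio through `F` reproduces the slow fluctuations of the
full dynamics, with steady-state standard deviation

    ΔJ = |F′(P)| · sqrt( P(1−P) / (2 f_A τ) )        (PRE rule).

A readout network of threshold-linear populations with NMDA-like gating
and collapsed global inhibition `g_I` turns the learned weights into
behavior: presenting one event transiently activates the populations whose
incoming weight exceeds `g_I` — one-step prediction, attenuated predicted
sequences, or noise-resolved winner-take-all competition between likely
successors, depending on `g_I`.

## Worked example

Generate a random 5-event chain and ask the theory what its synapses will
encode (`q+ = 0.06`, `q- = 0.03`, PRE depression):

```
$ contiguity gen-matrix --n 5 --seed 7 --out T.csv
$ contiguity theory --matrix T.csv --q-plus 0.06 --q-minus 0.03
pre,post,x,J_bar,tau_steps,tau_seconds
0,1,0.43673011196597217,0.4662283259469265,61.34720068944874,36.80832041366924
0,2,0.15006712629726224,0.23084866197131715,88.39974803517194,53.03984882110316
0,3,0.0026323713386709677,0.005237170323232703,114.32962428897393,68.59777457338436
0,4,0.4105703903980945,0.4508936318680385,63.10964070059722,37.86578442035833
1,0,0.5211595790852261,0.5103605643616355,113.54612203877933,68.12767322326759
...
```

Each row is one ordered population pair: `x` is the transition probability
`P(pre -> post)`, `J_bar = F(x)` the predicted steady-state fraction of
potentiated synapses (e.g. the pair `0 -> 1` with `P = 0.437` settles at
`J̄ = 0.466`), and `tau` the relaxation/integration timescale — here tens
of seconds at one event per 600 ms. Simulating the actual dynamics
(`contiguity simulate --matrix T.csv --steps 200000 --seed 1 ...`) gives
time-averaged weights matching `J_bar` to a few parts in a thousand for
well-sampled pairs.

Winner-take-all readout — two populations receiving weights 0.38 and 0.33
from a common source, inhibition 0.3, moderate noise:

```
$ contiguity wta --j-strong 0.38 --j-weak 0.33 --sigma 0.5 --trials 200 --seed 3
{"p_win": 0.68, "stderr": 0.03298484500494128}
```

The more strongly driven population wins 68% of trials; with `--sigma 0`
it wins always, and at equal weights the probability is 1/2.

Python API equivalents live in `contiguity.markov`, `.plasticity`,
`.theory`, `.estimator`, `.network`, and desk-scale experiment campaigns
in `contiguity.experiments` (also exposed as `contiguity reproduce ...`).

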