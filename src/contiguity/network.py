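"""Threshold-linear rate network reading out the learned weights.

``n`` excitatory populations (one per event) interact through the learned
weights ``J[post, pre] = F(P(pre -> post))`` and through a global
inhibitory population that responds linearly and instantaneously, so the
inhibitory loop collapses to a single effective strength ``g_I``
subtracted from every excitatory weight.  Each population's rate obeys

    ``tau_m dr_i/dt = -r_i + Phi(I_i) + sigma eta_i(t)``
    ``I_i = sum_j (J[i, j] - g_I) S_j + h_i(t)``

with a threshold-linear gain ``Phi(x) = g max(x, 0)`` and slow synaptic
gating (NMDA-like) variables

    ``tau_s dS_j/dt = -S_j + g_s r_j``.

External events deliver rectangular input pulses to their population.
Whether presenting one event transiently activates the populations coding
the likely next events is set by the sign of ``J - g_I``: lowering the
inhibition moves the network from isolated responses, to one-step
prospective activation (with amplitude growing with ``J - g_I``), to
attenuated predicted sequences and noise-resolved winner-take-all
competition between likely successors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .markov import TransitionMatrix
from .theory import transfer_bistable, transfer_multistate

__all__ = [
    "RateNetworkParams",
    "RateTrace",
    "weights_from_probabilities",
    "effective_connectivity",
    "simulate_rates",
    "winner_probability",
    "fig_sequence_probabilities",
]


@dataclass(frozen=True)
class RateNetworkParams:
    """Constants of the rate network (times in seconds).

    Defaults follow the readout demonstration: ``tau_m = 10 ms``,
    gain ``g = 450``, NMDA time constant ``tau_s = 100 ms``, gating scale
    ``g_s = 0.02``, recurrent self-weight ``J_rec = 0.02``, input pulses
    of amplitude 0.05 lasting 100 ms.  ``g_I`` is the collapsed strength
    of the global inhibition; ``sigma`` the rate-noise amplitude.
    """

    tau_m: float = 0.010
    g: float = 450.0
    sigma: float = 0.0
    tau_s: float = 0.100
    g_s: float = 0.02
    g_I: float = 0.4
    J_rec: float = 0.02
    h_amp: float = 0.05
    h_dur: float = 0.100
    dt: float = 0.0005

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_s", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.g_I < 0:
            raise ValueError("g_I must be non-negative")
        if self.dt > self.tau_m / 10:
            raise ValueError(
                f"dt={self.dt} too large for stability; need dt <= tau_m/10 = {self.tau_m / 10}"
            )


@dataclass
class RateTrace:
    """Simulated firing-rate and gating time courses."""

    t: np.ndarray
    r: np.ndarray
    S: np.ndarray
    schedule: list[tuple[float, int]] = field(default_factory=list)

    def peak(self, population: int, after: float = 0.0) -> float:
        """Maximum rate of a population at times ``>= after``."""
        mask = self.t >= after
        return float(self.r[mask, population].max())


def weights_from_probabilities(
    T: TransitionMatrix | np.ndarray,
    q_plus: float = 1.0,
    q_minus: float = 1.0,
    j_rec: float = 0.02,
    m: int = 2,
) -> np.ndarray:
    """Learned weight matrix ``J[post, pre] = F(P(pre -> post))``.

    Off-diagonal entries pass the transition probabilities through the
    synaptic transfer function (with potentiation/depression ratio
    ``q_plus / q_minus``); the diagonal is the fixed recurrent weight.
    ``T`` may be a raw probability array (same column-oriented convention)
    for schemes that do not form a complete chain.
    """
    P = T.T if isinstance(T, TransitionMatrix) else np.asarray(T, dtype=float)
    if m == 2:
        J = transfer_bistable(P, q_plus, q_minus)
    else:
        J = transfer_multistate(P, q_plus, q_minus, m)
    J = np.asarray(J, dtype=float).copy()
    np.fill_diagonal(J, j_rec)
    return J


def effective_connectivity(J: np.ndarray, g_I: float) -> np.ndarray:
    """Boolean matrix of effectively excitatory connections.

    Presenting the presynaptic event drives the postsynaptic population
    iff the direct excitation beats the feed-forward inhibition,
    ``J - g_I > 0``.  Diagonal entries are False (self-terms do not
    mediate prediction).
    """
    eff = np.asarray(J, dtype=float) - g_I > 0
    np.fill_diagonal(eff, False)
    return eff


def fig_sequence_probabilities(renormalize: bool = True) -> np.ndarray:
    """Transition probabilities of the 5-event demonstration scheme.

    Events A..E (indices 0..4): A -> B (0.65) / C (0.35); B -> D (0.9) /
    E (0.1); C -> D (0.55) / E (0.55).  As printed, column C sums to 1.1;
    with ``renormalize=True`` (default) each column is normalized, with
    ``renormalize=False`` the raw values are returned unchanged.  D and E
    return to A so the scheme forms a closed chain.
    """
    P = np.zeros((5, 5))
    A, B, C, D, E = range(5)
    P[B, A], P[C, A] = 0.65, 0.35
    P[D, B], P[E, B] = 0.9, 0.1
    P[D, C], P[E, C] = 0.55, 0.55
    P[A, D] = 1.0
    P[A, E] = 1.0
    if renormalize:
        P = P / P.sum(axis=0, keepdims=True)
    return P


def _pulse_input(
    schedule: list[tuple[float, int]], n: int, t: np.ndarray, h_amp: float, h_dur: float
) -> np.ndarray:
    h = np.zeros((t.size, n))
    for onset, ev in schedule:
        if not 0 <= ev < n:
            raise ValueError(f"scheduled event index {ev} out of range")
        mask = (t >= onset) & (t < onset + h_dur)
        h[mask, ev] += h_amp
    return h


def _integrate(
    params: RateNetworkParams,
    W: np.ndarray,
    h: np.ndarray,
    rng: np.random.Generator | None,
    n_trials: int = 1,
):
    """Euler / Euler-Maruyama forward integration; returns (r, S) arrays.

    ``W`` is the effective weight matrix ``J - g_I``; ``h[t, i]`` the
    external input.  With ``n_trials > 1`` independent noise realizations
    are integrated in parallel (shape ``(steps, trials, n)``).
    """
    steps, n = h.shape
    dt, tau_m, tau_s = params.dt, params.tau_m, params.tau_s
    shape = (n_trials, n) if n_trials > 1 else (n,)
    r = np.zeros(shape)
    S = np.zeros(shape)
    out_r = np.zeros((steps,) + shape)
    out_S = np.zeros((steps,) + shape)
    noise_scale = params.sigma * np.sqrt(dt) / tau_m
    for k in range(steps):
        out_r[k] = r
        out_S[k] = S
        I = S @ W.T + h[k]
        phi = params.g * np.maximum(I, 0.0)
        dr = (dt / tau_m) * (-r + phi)
        if noise_scale > 0:
            if rng is None:
                raise ValueError("noise requires a seeded generator")
            dr = dr + noise_scale * rng.standard_normal(shape)
        r = r + dr
        S = S + (dt / tau_s) * (-S + params.g_s * r)
    return out_r, out_S


def simulate_rates(
    params: RateNetworkParams,
    J: np.ndarray,
    schedule: list[tuple[float, int]],
    duration: float,
    seed=None,
) -> RateTrace:
    """Simulate the rate network driven by timed event pulses.

    ``schedule`` lists ``(onset_seconds, event_index)`` pulses, each a
    rectangle of amplitude ``h_amp`` and duration ``h_dur``.  Rates start
    at zero and are not clipped: the rectification acts on the input
    current, so noise can make rates transiently negative.  With
    ``sigma = 0`` the trace is deterministic.
    """
    J = np.asarray(J, dtype=float)
    n = J.shape[0]
    for onset, _ in schedule:
        if onset < 0 or onset > duration:
            raise ValueError("scheduled pulse outside the simulated interval")
    steps = int(round(duration / params.dt))
    t = np.arange(steps) * params.dt
    h = _pulse_input(schedule, n, t, params.h_amp, params.h_dur)
    rng = np.random.default_rng(seed) if params.sigma > 0 else None
    r, S = _integrate(params, J - params.g_I, h, rng)
    return RateTrace(t=t, r=r, S=S, schedule=list(schedule))


def winner_probability(
    params: RateNetworkParams,
    j_strong: float,
    j_weak: float,
    sigma: float,
    trials: int,
    seed=None,
    *,
    decision_window: float = 0.5,
) -> tuple[float, float]:
    """Probability that the strongly-driven population wins the competition.

    A source population excites two targets with weights ``j_strong`` and
    ``j_weak``, both stronger than the inhibition (``params.g_I``), so
    that after a pulse to the source the targets compete through the
    global inhibition.  The winner of a trial is the target with the
    larger time-integrated rate over ``decision_window`` seconds after
    pulse onset (ties are broken uniformly at random).  Returns the
    Monte-Carlo estimate and its binomial standard error.
    """
    if trials < 1:
        raise ValueError("need at least one trial")
    params = replace(params, sigma=sigma)
    J = np.array(
        [
            [params.J_rec, 0.0, 0.0],
            [j_strong, params.J_rec, 0.0],
            [j_weak, 0.0, params.J_rec],
        ]
    )
    duration = params.h_dur + decision_window
    steps = int(round(duration / params.dt))
    t = np.arange(steps) * params.dt
    h = _pulse_input([(0.0, 0)], 3, t, params.h_amp, params.h_dur)
    rng = np.random.default_rng(seed)
    n_trials = trials if sigma > 0 else 1
    r, _ = _integrate(params, J - params.g_I, h, rng, n_trials=n_trials)
    if sigma == 0:
        r = r[:, np.newaxis, :]
    window = t < decision_window
    scores = r[window].sum(axis=0)  # (trials, 3)
    strong, weak = scores[:, 1], scores[:, 2]
    wins = np.where(
        strong > weak, 1.0, np.where(strong < weak, 0.0, rng.random(strong.size) < 0.5)
    )
    p = float(wins.mean())
    if sigma == 0:
        return p, 0.0
    stderr = float(np.sqrt(p * (1 - p) / trials))
    return p, stderr
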