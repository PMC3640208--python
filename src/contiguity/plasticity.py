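"""Stochastic plasticity of bounded multi-state synapses.

Each ordered pair of event-selective populations ``(pre=j, post=i)``,
``j != i``, is connected by a large number of equivalent synapses with
``m`` stable states (``m = 2``: depressed / potentiated).  Potentiation is
sequence-dependent: a synapse is eligible for potentiation at step ``t``
when its presynaptic event occurred at ``t - 1`` and its postsynaptic
event occurs at ``t``.  Eligibility for depression depends on the chosen
rule:

* ``PRE`` -- the presynaptic population is active at ``t``;
* ``POST`` -- the postsynaptic population is active at ``t``;
* ``UNSPECIFIC`` -- every time step.

When eligible, each synapse moves up one state with probability ``q_plus``
(if not at the upper bound) and/or down one state with probability
``q_minus`` (if not at the lower bound); the transition probabilities do
not depend on the distance to the bounds (hard bounds).  In the
large-population limit the per-pair state occupancies evolve
deterministically: a fraction ``q_plus`` of the occupancy of each
non-maximal state moves up and a fraction ``q_minus`` of each non-minimal
state moves down, both fluxes computed from the pre-update occupancies and
applied additively.  For ``m = 2`` this reduces to the scalar recursion

    ``J(t+1) = J(t) + q_plus * (1 - J(t)) * xi_plus - q_minus * J(t) * xi_minus``

for the fraction ``J`` of potentiated synapses.

Within-population (diagonal) synapses are assumed to have equilibrated
during familiarization with the individual events; they are excluded from
the dynamics and only enter the rate network as a fixed constant.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import DEFAULT_DT_EVENT, EventSequence, TransitionMatrix, event_statistics, sample_sequence

__all__ = [
    "DepressionMode",
    "PlasticityRule",
    "SynapticStateMatrix",
    "WeightTrace",
    "eligibility",
    "step_fraction",
    "step_sampled",
    "simulate",
    "simulate_sampled",
]


class DepressionMode(str, enum.Enum):
    """Which events make a synapse eligible for depression."""

    PRE = "pre"
    POST = "post"
    UNSPECIFIC = "unspecific"


@dataclass(frozen=True)
class PlasticityRule:
    """Plasticity parameters of a population of bounded synapses.

    Parameters
    ----------
    q_plus, q_minus
        Probabilities that an eligible synapse moves up / down one state,
        in ``(0, 1]``.  They set the learning rate: the inverse is the
        average number of eligible events between modifications.
    m
        Number of stable synaptic states (``>= 2``).
    depression
        Depression eligibility rule.
    """

    q_plus: float
    q_minus: float
    m: int = 2
    depression: DepressionMode = DepressionMode.PRE

    def __post_init__(self) -> None:
        if not 0 < self.q_plus <= 1:
            raise ValueError("q_plus must be in (0, 1]")
        if not 0 < self.q_minus <= 1:
            raise ValueError("q_minus must be in (0, 1]")
        if int(self.m) != self.m or self.m < 2:
            raise ValueError("m must be an integer >= 2")
        object.__setattr__(self, "m", int(self.m))
        object.__setattr__(self, "depression", DepressionMode(self.depression))

    @property
    def ratio(self) -> float:
        """Potentiation/depression balance ``q_plus / q_minus``."""
        return self.q_plus / self.q_minus


def eligibility(
    prev_event: int, cur_event: int, pre: int, post: int, mode: DepressionMode
) -> tuple[int, int]:
    """Potentiation/depression eligibility of the pair ``pre -> post``.

    Returns ``(xi_plus, xi_minus)`` for the step at which ``cur_event``
    occurs, ``prev_event`` having occurred at the previous step.  Since one
    event occurs per step, the pre- and postsynaptic populations are never
    simultaneously active, so e.g. under ``PRE`` depression ``xi_minus`` is
    simply ``cur_event == pre``.
    """
    if pre == post:
        raise ValueError("within-population synapses are fixed; pre must differ from post")
    mode = DepressionMode(mode)
    xi_plus = int(prev_event == pre and cur_event == post)
    if mode is DepressionMode.PRE:
        xi_minus = int(cur_event == pre)
    elif mode is DepressionMode.POST:
        xi_minus = int(cur_event == post)
    else:
        xi_minus = 1
    return xi_plus, xi_minus


def _state_weights(m: int) -> np.ndarray:
    """Weights ``(k - 1)/(m - 1)`` mapping occupancies to strength."""
    return np.arange(m) / (m - 1)


def _reset_diagonal(rho: np.ndarray) -> None:
    n = rho.shape[0]
    idx = np.arange(n)
    rho[idx, idx, :] = 0.0
    rho[idx, idx, 0] = 1.0


@dataclass
class SynapticStateMatrix:
    """Per-pair synaptic state occupancies for all ordered pairs.

    ``rho[i, j, k]`` is the fraction of synapses of the pair ``j -> i``
    occupying state ``k`` (0-indexed; state 0 is maximally depressed).
    Diagonal entries are placeholders pinned to the all-depressed vector
    and are excluded from the dynamics.
    """

    rho: np.ndarray

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        if rho.ndim != 3 or rho.shape[0] != rho.shape[1] or rho.shape[2] < 2:
            raise ValueError("rho must have shape (n, n, m) with m >= 2")
        if np.any(rho < -1e-12):
            raise ValueError("occupancies must be non-negative")
        sums = rho.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            raise ValueError("occupancies must sum to 1 per pair")
        self.rho = rho

    @classmethod
    def all_depressed(cls, n: int, m: int = 2) -> "SynapticStateMatrix":
        rho = np.zeros((n, n, m))
        rho[:, :, 0] = 1.0
        return cls(rho)

    @property
    def n(self) -> int:
        return self.rho.shape[0]

    @property
    def m(self) -> int:
        return self.rho.shape[2]

    @property
    def J(self) -> np.ndarray:
        """Strength matrix ``J[i, j] = J_{j->i}``; NaN on the diagonal."""
        J = self.rho @ _state_weights(self.m)
        np.fill_diagonal(J, np.nan)
        return J


def _joint_update(v: np.ndarray, qp: float, qm: float) -> np.ndarray:
    """One-step update of a single pair eligible for BOTH transitions.

    Exact expectation of independent per-synapse up/down attempts: the
    bottom state moves up with probability ``qp``, the top state down with
    ``qm``, and interior states move up with ``qp (1 - qm)`` / down with
    ``qm (1 - qp)`` (simultaneous attempts cancel).  For m = 2 there are
    no interior states and this is the plain additive update.
    """
    m = v.size
    up = np.empty(m - 1)
    down = np.empty(m - 1)
    up[:] = qp * (1.0 - qm)
    down[:] = qm * (1.0 - qp)
    up[0] = qp  # bottom state cannot also move down
    down[-1] = qm  # top state cannot also move up
    new = v.copy()
    fu = up * v[:-1]
    fd = down * v[1:]
    new[:-1] += fd - fu
    new[1:] += fu - fd
    return new


def _apply_step(rho: np.ndarray, prev_event: int, cur_event: int, rule: PlasticityRule) -> None:
    """In-place one-step update of the occupancy tensor (parallel fluxes)."""
    a, b = prev_event, cur_event
    qp, qm = rule.q_plus, rule.q_minus
    mode = rule.depression
    # at most one pair (a -> b) is eligible for potentiation; under POST and
    # UNSPECIFIC depression that same pair is also depression-eligible and
    # gets the joint (both-transitions) update
    joint = a != b and mode is not DepressionMode.PRE
    pot = None
    if a != b and not joint:
        pot = qp * rho[b, a, :-1].copy()
    if joint:
        joint_new = _joint_update(rho[b, a, :], qp, qm)
    if mode is DepressionMode.PRE:
        view = rho[:, b, :]
    elif mode is DepressionMode.POST:
        view = rho[b, :, :]
    else:
        view = rho.reshape(-1, rho.shape[2])
    dep = qm * view[:, 1:]
    view[:, 1:] -= dep
    view[:, :-1] += dep
    if pot is not None:
        rho[b, a, 1:] += pot
        rho[b, a, :-1] -= pot
    if joint:
        rho[b, a, :] = joint_new
    _reset_diagonal(rho)


def step_fraction(
    state: SynapticStateMatrix, prev_event: int, cur_event: int, rule: PlasticityRule
) -> SynapticStateMatrix:
    """One deterministic (infinite-population) update of all pairs.

    All fluxes are computed from the pre-update occupancies and applied
    in parallel, so that for ``m = 2`` the update is exactly the scalar
    fraction recursion.  Under the POST and UNSPECIFIC rules the same
    step can be eligible for both potentiation and depression; that pair
    then takes the exact expectation of independent per-synapse attempts
    (interior states move with ``q_plus (1 - q_minus)`` and
    ``q_minus (1 - q_plus)``, simultaneous attempts cancelling), which
    keeps the occupancies a probability vector for any
    ``q_plus, q_minus <= 1`` and makes this update the exact mean of
    :func:`step_sampled`.
    """
    if state.m != rule.m:
        raise ValueError(f"state has m={state.m} but rule has m={rule.m}")
    rho = state.rho.copy()
    _apply_step(rho, prev_event, cur_event, rule)
    return SynapticStateMatrix(rho)


def step_sampled(
    states: np.ndarray,
    prev_event: int,
    cur_event: int,
    pre: int,
    post: int,
    rule: PlasticityRule,
    rng: np.random.Generator,
) -> np.ndarray:
    """One stochastic update of ``N`` individual synapses of one pair.

    ``states`` holds integer states in ``[0, m)``.  Each synapse draws
    independent potentiation and depression attempts (independent parallel
    draws; the large-``N`` mean converges to :func:`step_fraction`).
    """
    states = np.asarray(states)
    xi_plus, xi_minus = eligibility(prev_event, cur_event, pre, post, rule.depression)
    if not (xi_plus or xi_minus):
        return states.copy()
    up = np.zeros(states.shape, dtype=np.int64)
    down = np.zeros(states.shape, dtype=np.int64)
    if xi_plus:
        up = ((states < rule.m - 1) & (rng.random(states.shape) < rule.q_plus)).astype(np.int64)
    if xi_minus:
        down = ((states > 0) & (rng.random(states.shape) < rule.q_minus)).astype(np.int64)
    return states + up - down


@dataclass
class WeightTrace:
    """Recorded strength time series for a subset of population pairs.

    ``J[t, p]`` is the strength of pair ``pairs[p] = (pre, post)`` after
    the event at step ``t`` was processed.
    """

    times: np.ndarray
    J: np.ndarray
    pairs: list[tuple[int, int]]
    rule: PlasticityRule
    dt_event: float = DEFAULT_DT_EVENT
    meta: dict = field(default_factory=dict)

    def series(self, pre: int, post: int) -> np.ndarray:
        """Strength time series of a single recorded pair."""
        try:
            p = self.pairs.index((pre, post))
        except ValueError:
            raise KeyError(f"pair ({pre}, {post}) was not recorded") from None
        return self.J[:, p]

    def time_average(self, burn_in: int = 0) -> dict[tuple[int, int], float]:
        """Per-pair mean strength after discarding ``burn_in`` steps."""
        return {
            pair: float(self.J[burn_in:, p].mean()) for p, pair in enumerate(self.pairs)
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns ``step, pre, post, J``."""
        records = []
        for p, (j, i) in enumerate(self.pairs):
            records.append(
                pd.DataFrame(
                    {"step": self.times, "pre": j, "post": i, "J": self.J[:, p]}
                )
            )
        return pd.concat(records, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
        with open(str(path) + ".json", "w") as fh:
            json.dump(
                {
                    "q_plus": self.rule.q_plus,
                    "q_minus": self.rule.q_minus,
                    "m": self.rule.m,
                    "depression": self.rule.depression.value,
                    "dt_event": self.dt_event,
                    **{k: v for k, v in self.meta.items() if isinstance(v, (int, float, str))},
                },
                fh,
            )


def _resolve_pairs(record, n: int, T: np.ndarray | None) -> list[tuple[int, int]]:
    if record == "all":
        return [(j, i) for j in range(n) for i in range(n) if i != j]
    if record == "connected":
        if T is None:
            raise ValueError("record='connected' requires a transition matrix source")
        return [(j, i) for j in range(n) for i in range(n) if i != j and T[i, j] > 0]
    pairs = [(int(j), int(i)) for j, i in record]
    for j, i in pairs:
        if j == i:
            raise ValueError("within-population synapses are fixed; cannot record diagonal pairs")
        if not (0 <= j < n and 0 <= i < n):
            raise ValueError(f"pair ({j}, {i}) out of range")
    return pairs


def simulate(
    source: TransitionMatrix | EventSequence,
    rule: PlasticityRule,
    steps: int | None = None,
    *,
    seed=None,
    record="connected",
    initial: str | np.ndarray = "all-depressed",
    return_state: bool = False,
):
    """Simulate the large-population fraction dynamics along a sequence.

    Parameters
    ----------
    source
        A :class:`TransitionMatrix` (a sequence of ``steps`` events is then
        sampled with ``seed``) or a pre-sampled :class:`EventSequence`.
    rule
        Plasticity parameters.
    record
        ``"connected"`` (all off-diagonal pairs with nonzero transition
        probability; requires a matrix source), ``"all"``, or an explicit
        list of ``(pre, post)`` pairs.
    initial
        ``"all-depressed"`` (the default: the statistics are initially
        unknown and every synapse starts in the lowest state) or an
        ``(n, n, m)`` occupancy array.

    Returns
    -------
    WeightTrace
        Recorded strengths at every step, ``J[0]`` being the initial state.
    """
    if isinstance(source, TransitionMatrix):
        if steps is None or steps < 2:
            raise ValueError("steps >= 2 required when simulating from a matrix")
        seq = sample_sequence(source, steps, seed=seed)
        T = source.T
    else:
        seq = source
        T = None
    ev = seq.events
    n = seq.n
    m = rule.m
    pairs = _resolve_pairs(record, n, T)

    if isinstance(initial, str):
        if initial != "all-depressed":
            raise ValueError(f"unknown initial state {initial!r}")
        state = SynapticStateMatrix.all_depressed(n, m)
    else:
        state = SynapticStateMatrix(np.array(initial, dtype=float))
        if state.n != n or state.m != m:
            raise ValueError("initial occupancy array has wrong shape")
    rho = state.rho.copy()
    _reset_diagonal(rho)

    w = _state_weights(m)
    rec_post = np.array([i for _, i in pairs])
    rec_pre = np.array([j for j, _ in pairs])
    L = ev.size
    out = np.empty((L, len(pairs)))
    out[0] = rho[rec_post, rec_pre] @ w
    if m == 2:
        # scalar fraction recursion on the J matrix (same update, faster)
        J = rho[:, :, 1].copy()
        np.fill_diagonal(J, 0.0)
        flat_idx = rec_post * n + rec_pre
        qp, qm = rule.q_plus, rule.q_minus
        keep = 1.0 - qm
        mode = rule.depression
        for t in range(1, L):
            a, b = ev[t - 1], ev[t]
            pot = qp * (1.0 - J[b, a]) if a != b else 0.0
            if mode is DepressionMode.PRE:
                J[:, b] *= keep
            elif mode is DepressionMode.POST:
                J[b, :] *= keep
            else:
                J *= keep
            if a != b:
                J[b, a] += pot
            out[t] = J.take(flat_idx)
        rho[:, :, 1] = J
        rho[:, :, 0] = 1.0 - J
        _reset_diagonal(rho)
    else:
        for t in range(1, L):
            _apply_step(rho, ev[t - 1], ev[t], rule)
            out[t] = rho[rec_post, rec_pre] @ w
    trace = WeightTrace(
        times=np.arange(L),
        J=out,
        pairs=pairs,
        rule=rule,
        dt_event=seq.dt_event,
        meta={"seed": seq.seed, "steps": L},
    )
    if return_state:
        return trace, SynapticStateMatrix(rho)
    return trace


def simulate_sampled(
    sequence: EventSequence,
    rule: PlasticityRule,
    pre: int,
    post: int,
    n_synapses: int,
    seed=None,
    initial_state: int = 0,
) -> np.ndarray:
    """Finite-``N`` stochastic simulation of a single pair.

    Returns the strength series ``mean(states) / (m - 1)`` of length
    ``len(sequence)``; companion of the fraction dynamics for checking
    large-``N`` convergence.
    """
    if n_synapses < 1:
        raise ValueError("need at least one synapse")
    rng = np.random.default_rng(seed)
    ev = sequence.events
    states = np.full(n_synapses, initial_state, dtype=np.int64)
    out = np.empty(ev.size)
    out[0] = states.mean() / (rule.m - 1)
    for t in range(1, ev.size):
        states = step_sampled(states, ev[t - 1], ev[t], pre, post, rule, rng)
        out[t] = states.mean() / (rule.m - 1)
    return out
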