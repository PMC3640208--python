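"""Sliding-window effective model of the synaptic dynamics.

The relaxation timescale ``tau`` of a pair doubles as its evidence
integration window: the synapses behave like an estimator that counts, in
the trailing ``tau`` steps, the potentiating occurrences ``N_plus`` and
the depressing occurrences ``N_minus`` of the pair and reports
``F(N_plus / N_minus)`` through the synaptic transfer function.  This
surrogate reproduces the slow fluctuations of the full dynamics (it
misses the fast ones) and yields a closed-form prediction for the
steady-state fluctuation standard deviation

    ``dJ^2 = F'(P)^2 * P (1 - P) / (2 f_pre tau)``

for the PRE depression rule, ``P`` being the encoded transition
probability -- binomial counting noise on ``~2 f_pre tau`` effective
samples, propagated through the transfer function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import EventSequence, EventStatistics
from .plasticity import DepressionMode, PlasticityRule
from .theory import transfer_bistable, transfer_bistable_deriv, transfer_multistate

__all__ = [
    "EffectiveTrace",
    "effective_trace",
    "compare_traces",
    "fluctuation_std",
    "fluctuation_std_matrix",
]


@dataclass
class EffectiveTrace:
    """Sliding-window estimate of a pair's synaptic strength over time."""

    times: np.ndarray
    J_eff: np.ndarray
    window: int
    pre: int
    post: int
    N_plus: np.ndarray | None = None
    N_minus: np.ndarray | None = None


def _trailing_counts(ind: np.ndarray, window: int) -> np.ndarray:
    """Count of True entries of ``ind`` in the trailing ``window`` steps.

    ``ind[t]`` marks the step at which the current event occurs
    (``ind[0]`` is always False: no predecessor).  Windows are clipped at
    the start of the sequence.
    """
    c = np.concatenate([[0], np.cumsum(ind)])
    lo = np.maximum(np.arange(1, ind.size + 1) - window, 0)
    return c[1:] - c[lo]


def effective_trace(
    sequence: EventSequence,
    rule: PlasticityRule,
    pre: int,
    post: int,
    window: int,
    *,
    keep_counts: bool = False,
) -> EffectiveTrace:
    """Effective weight series ``F(N_plus / N_minus)`` for one pair.

    ``window`` is the integration window in steps (normally
    ``round(tau)`` from the mean-field timescale, minimum 1).  Counts use
    the same eligibility predicates as the full dynamics.  Steps whose
    window contains no depressing event carry the last defined estimate
    forward (an estimator with no evidence should not move); before any
    evidence the estimate is 0, matching the all-depressed start of the
    full model.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if pre == post:
        raise ValueError("within-population synapses are fixed; pre must differ from post")
    ev = sequence.events
    if ev.size <= window:
        raise ValueError("sequence must be longer than the window")
    plus = np.zeros(ev.size, dtype=bool)
    plus[1:] = (ev[:-1] == pre) & (ev[1:] == post)
    minus = np.zeros(ev.size, dtype=bool)
    if rule.depression is DepressionMode.PRE:
        minus[1:] = ev[1:] == pre
    elif rule.depression is DepressionMode.POST:
        minus[1:] = ev[1:] == post
    else:
        minus[1:] = True
    N_plus = _trailing_counts(plus, window)
    N_minus = _trailing_counts(minus, window)

    if rule.m == 2:
        F = lambda x: transfer_bistable(x, rule.q_plus, rule.q_minus)  # noqa: E731
    else:
        F = lambda x: transfer_multistate(x, rule.q_plus, rule.q_minus, rule.m)  # noqa: E731
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(N_minus > 0, N_plus / np.maximum(N_minus, 1), np.nan)
    J = np.where(np.isnan(ratio), np.nan, F(np.nan_to_num(ratio)))
    # carry the last defined value forward through evidence-free windows
    defined = ~np.isnan(J)
    idx = np.where(defined, np.arange(J.size), 0)
    np.maximum.accumulate(idx, out=idx)
    J = np.where(defined[idx], J[idx], 0.0)
    return EffectiveTrace(
        times=np.arange(ev.size),
        J_eff=J,
        window=window,
        pre=pre,
        post=post,
        N_plus=N_plus if keep_counts else None,
        N_minus=N_minus if keep_counts else None,
    )


def compare_traces(full: np.ndarray, eff: np.ndarray, burn_in: int = 0) -> float:
    """Pearson correlation between full and effective series past ``burn_in``.

    Returns NaN if either series is constant over the compared stretch
    (the correlation is then undefined).
    """
    a = np.asarray(full, dtype=float)[burn_in:]
    b = np.asarray(eff, dtype=float)[burn_in:]
    if a.size != b.size:
        raise ValueError("series must have equal length after alignment")
    if a.size < 2:
        raise ValueError("need at least two samples past the burn-in")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def fluctuation_std(
    stats: EventStatistics, rule: PlasticityRule, pre: int, post: int
) -> float:
    """Predicted steady-state fluctuation std of one pair (PRE rule, m=2).

    ``dJ = |F'(P)| * sqrt(P (1 - P) / (2 f_pre tau))`` with ``P`` the
    transition probability of the pair and ``tau`` its relaxation
    timescale.  Returns 0 at the boundaries ``P in {0, 1}`` (no counting
    noise).
    """
    dJ = fluctuation_std_matrix(stats, rule)
    out = dJ[post, pre]
    if np.isnan(out):
        raise ValueError(f"fluctuation std undefined for pair ({pre} -> {post})")
    return float(out)


def fluctuation_std_matrix(
    stats: EventStatistics, rule: PlasticityRule, tau: np.ndarray | None = None
) -> np.ndarray:
    """Matrix of predicted fluctuation stds, ``[post, pre]`` orientation.

    Only available for PRE-activated depression with bistable synapses
    (the closed form is written in transition-probability coordinates).
    NaN on the diagonal and where the presynaptic event never occurs.
    """
    if rule.depression is not DepressionMode.PRE or rule.m != 2:
        raise ValueError("fluctuation formula applies to the PRE rule with m = 2")
    f = stats.f
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(f[np.newaxis, :] > 0, stats.f_pair / f[np.newaxis, :], np.nan)
    if tau is None:
        Jb = transfer_bistable(np.nan_to_num(P), rule.q_plus, rule.q_minus)
        with np.errstate(divide="ignore", invalid="ignore"):
            tau = np.where(stats.f_pair > 0, Jb / (rule.q_plus * stats.f_pair), np.nan)
    dF = transfer_bistable_deriv(np.nan_to_num(P), rule.q_plus, rule.q_minus)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = dF**2 * P * (1.0 - P) / (2.0 * f[np.newaxis, :] * tau)
    dJ = np.sqrt(var)
    dJ = np.where(np.isnan(P), np.nan, dJ)
    dJ = np.where((P == 0) | (P == 1), 0.0, dJ)  # boundary: zero binomial variance
    np.fill_diagonal(dJ, np.nan)
    return dJ
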