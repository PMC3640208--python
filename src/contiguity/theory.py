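"""Mean-field theory of the bounded-synapse dynamics.

In the slow-learning limit (small ``q_plus``, ``q_minus``) the correlations
between consecutive synaptic modifications can be neglected and the
sequence-averaged strength of a pair obeys the linear relaxation

    ``<dJ>(t) = q_plus * (1 - <J>) * f_plus - q_minus * <J> * f_minus``

where ``f_plus`` and ``f_minus`` are the frequencies of potentiating and
depressing events.  Its fixed point is ``J_bar = F(f_plus / f_minus)``
with the synaptic transfer function

    ``F(x) = (q_plus/q_minus) x / (1 + (q_plus/q_minus) x)``        (m = 2)

and, for ``m``-state hard-bound synapses, the mean of the truncated
geometric stationary distribution of the associated birth-death chain,
which becomes an increasingly steep sigmoid centered at
``q_minus / q_plus`` as ``m`` grows.  The relaxation timescale is

    ``tau = J_bar / (q_plus * f_AB)  =  1 / (q_plus f_plus + q_minus f_minus)``

in event steps (``f_AB`` being the pair frequency of the potentiating
sequence).  What ``f_minus`` is depends on the depression rule: the
frequency of the presynaptic event (PRE), of the postsynaptic event
(POST), or 1 (UNSPECIFIC) -- hence the steady state encodes the transition
probability ``P(A -> B)``, the conditional probability ``f_AB / f_B``, or
the pair frequency ``f_AB`` respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .markov import DEFAULT_DT_EVENT, EventStatistics
from .plasticity import DepressionMode, PlasticityRule

__all__ = [
    "TheoryPrediction",
    "transfer_bistable",
    "transfer_bistable_deriv",
    "transfer_multistate",
    "steady_state",
    "averaged_trajectory",
    "transient_timescale",
    "fit_exponential_transient",
]


def _check_x(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("frequency ratio must be non-negative")
    return x


def transfer_bistable(x, q_plus: float, q_minus: float):
    """Bistable transfer function ``F(x) = rx / (1 + rx)``, ``r = q_plus/q_minus``.

    Maps the potentiating/depressing frequency ratio ``x >= 0`` to the
    steady-state fraction of potentiated synapses.  Strictly increasing,
    ``F(0) = 0``, saturating at 1.
    """
    x = _check_x(x)
    y = (q_plus / q_minus) * x
    out = y / (1.0 + y)
    return out if out.ndim else float(out)


def transfer_bistable_deriv(x, q_plus: float, q_minus: float):
    """Derivative ``F'(x) = r / (1 + rx)^2`` of the bistable transfer function."""
    x = _check_x(x)
    r = q_plus / q_minus
    out = r / (1.0 + r * x) ** 2
    return out if out.ndim else float(out)


def _trunc_geom_mean(y: np.ndarray, m: int) -> np.ndarray:
    """Mean state index of the truncated geometric distribution on 0..m-1.

    ``E[k] = sum_k k y^k / sum_k y^k`` for ``y <= 1``; exact at ``y = 1``
    where it equals ``(m - 1)/2``.
    """
    k = np.arange(m)
    Y = y[..., np.newaxis] ** k
    return (k * Y).sum(axis=-1) / Y.sum(axis=-1)


def transfer_multistate(x, q_plus: float, q_minus: float, m: int):
    """Transfer function of the ``m``-state hard-bound synapse.

    The per-pair occupancies form a birth-death chain with uniform up/down
    rates ``q_plus f_plus`` and ``q_minus f_minus``; detailed balance gives
    a truncated geometric stationary distribution with ratio
    ``y = (q_plus/q_minus) x`` and the strength is its normalized mean

        ``F(x) = E[k] / (m - 1),   k ~ y^k on {0, .., m-1}``.

    Evaluated by direct summation of the ``m`` power terms (using the
    ``y -> 1/y`` symmetry ``F(1/y) = 1 - F(y)`` for ``y > 1`` to avoid
    overflow), which is exact at the removable singularity ``y = 1`` where
    ``F = 1/2``.  For ``m = 2`` this reduces algebraically to
    :func:`transfer_bistable`.
    """
    if int(m) != m or m < 2:
        raise ValueError("m must be an integer >= 2")
    m = int(m)
    x = _check_x(x)
    y = (q_plus / q_minus) * x
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    out = np.empty_like(y)
    low = y <= 1.0
    if low.any():
        out[low] = _trunc_geom_mean(y[low], m) / (m - 1)
    if (~low).any():
        out[~low] = 1.0 - _trunc_geom_mean(1.0 / y[~low], m) / (m - 1)
    return float(out[0]) if scalar else out


@dataclass
class TheoryPrediction:
    """Mean-field predictions for every ordered population pair.

    All matrices follow the ``[post, pre]`` orientation of the transition
    matrix.  ``x`` is the argument of the transfer function for the rule
    (transition probability, conditional probability, or pair frequency);
    entries are NaN on the diagonal and wherever the prediction is
    undefined (``defined`` marks usable pairs: off-diagonal with nonzero
    pair frequency).
    """

    x: np.ndarray
    J_bar: np.ndarray
    tau_steps: np.ndarray
    dJ_std: np.ndarray | None
    defined: np.ndarray
    rule: PlasticityRule
    stats: EventStatistics
    dt_event: float = DEFAULT_DT_EVENT

    @property
    def tau_seconds(self) -> np.ndarray:
        return self.tau_steps * self.dt_event

    def pair(self, pre: int, post: int) -> dict:
        return {
            "x": float(self.x[post, pre]),
            "J_bar": float(self.J_bar[post, pre]),
            "tau_steps": float(self.tau_steps[post, pre]),
            "tau_seconds": float(self.tau_steps[post, pre] * self.dt_event),
            "dJ_std": None if self.dJ_std is None else float(self.dJ_std[post, pre]),
        }


def _rule_argument(stats: EventStatistics, rule: PlasticityRule) -> np.ndarray:
    """Argument ``x = f_plus / f_minus`` of the transfer function, per pair."""
    f = stats.f
    f_pair = stats.f_pair
    mode = rule.depression
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode is DepressionMode.PRE:
            # f_minus = f_pre;  x = f_AB / f_A = P(A -> B)
            x = np.where(f[np.newaxis, :] > 0, f_pair / f[np.newaxis, :], np.nan)
        elif mode is DepressionMode.POST:
            # f_minus = f_post;  x = f_AB / f_B
            x = np.where(f[:, np.newaxis] > 0, f_pair / f[:, np.newaxis], np.nan)
        else:
            # f_minus = 1;  x = f_AB
            x = f_pair.copy()
    return x


def steady_state(
    stats: EventStatistics, rule: PlasticityRule, dt_event: float = DEFAULT_DT_EVENT
) -> TheoryPrediction:
    """Steady-state strengths, relaxation timescales and fluctuation stds.

    ``J_bar = F(x)`` with the rule-dependent argument ``x`` and the
    bistable or multi-state transfer function as appropriate;
    ``tau = J_bar / (q_plus f_pair)``.  The fluctuation standard deviation
    (``dJ_std``) is the sliding-window estimator prediction and is filled
    for the PRE rule with bistable synapses only; see
    :func:`contiguity.estimator.fluctuation_std`.
    """
    x = _rule_argument(stats, rule)
    n = stats.n
    if rule.m == 2:
        F = transfer_bistable
        J_bar = np.where(np.isnan(x), np.nan, F(np.nan_to_num(x), rule.q_plus, rule.q_minus))
    else:
        J_bar = np.where(
            np.isnan(x),
            np.nan,
            transfer_multistate(np.nan_to_num(x), rule.q_plus, rule.q_minus, rule.m),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(stats.f_pair > 0, J_bar / (rule.q_plus * stats.f_pair), np.nan)
    defined = (stats.f_pair > 0) & ~np.eye(n, dtype=bool)
    np.fill_diagonal(J_bar, np.nan)
    np.fill_diagonal(x, np.nan)
    np.fill_diagonal(tau, np.nan)
    dJ = None
    if rule.depression is DepressionMode.PRE and rule.m == 2:
        from .estimator import fluctuation_std_matrix

        dJ = fluctuation_std_matrix(stats, rule, tau=tau)
    return TheoryPrediction(
        x=x, J_bar=J_bar, tau_steps=tau, dJ_std=dJ, defined=defined,
        rule=rule, stats=stats, dt_event=dt_event,
    )


def averaged_trajectory(
    J0: float, f_plus: float, f_minus: float, q_plus: float, q_minus: float, steps: int
) -> np.ndarray:
    """Sequence-averaged strength ``<J>(t)`` for ``t = 0 .. steps``.

    Closed form of the linear recursion
    ``<J>(t+1) = <J>(t) + q_plus (1 - <J>) f_plus - q_minus <J> f_minus``:

        ``<J>(t) = J_bar + (J0 - J_bar) * (1 - q_plus f_plus - q_minus f_minus)^t``.
    """
    for name, v in (("f_plus", f_plus), ("f_minus", f_minus)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    a = q_plus * f_plus
    b = q_minus * f_minus
    if a + b == 0:
        return np.full(steps + 1, float(J0))
    J_bar = a / (a + b)
    t = np.arange(steps + 1)
    return J_bar + (J0 - J_bar) * (1.0 - a - b) ** t


def transient_timescale(
    stats: EventStatistics, rule: PlasticityRule, pre: int, post: int
) -> float:
    """Relaxation timescale ``tau = J_bar / (q_plus f_AB)`` in event steps.

    Algebraically identical to ``1 / (q_plus f_plus + q_minus f_minus)``.
    Raises if the potentiating pair never occurs (no relaxation is driven).
    """
    pred = steady_state(stats, rule)
    if not pred.defined[post, pre]:
        raise ValueError(
            f"timescale undefined for pair ({pre} -> {post}): pair frequency is zero"
        )
    return float(pred.tau_steps[post, pre])


def fit_exponential_transient(
    times: np.ndarray,
    J: np.ndarray,
    J_bar_guess: float,
    tau_guess: float,
    window_factor: float = 5.0,
) -> tuple[float, float]:
    """Fit ``J(t) = J_bar (1 - exp(-t / tau))`` to a transient from zero.

    Nonlinear least squares over the first ``window_factor * tau_guess``
    steps, fitting both the asymptote and the timescale (initialized at
    the predicted values).  Returns ``(J_bar_fit, tau_fit)``.
    """
    cut = times <= window_factor * tau_guess
    if cut.sum() < 5:
        raise ValueError("transient window too short for a fit")
    t, y = times[cut].astype(float), J[cut]

    def model(t, J_bar, tau):
        return J_bar * (1.0 - np.exp(-t / tau))

    popt, _ = curve_fit(
        model, t, y, p0=[max(J_bar_guess, 1e-6), max(tau_guess, 1.0)],
        bounds=([0.0, 1e-6], [1.0, np.inf]), maxfev=10000,
    )
    return float(popt[0]), float(popt[1])
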