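"""Markov chains of external events.

Events ``E_0 .. E_{n-1}`` occur once per discrete time step.  The chain is
specified by a *column-stochastic* transition matrix with the convention

    ``T[i, j] = P(E_j -> E_i)``

i.e. column ``j`` holds the outgoing transition probabilities of event
``j``.  Every function and file format in this package uses this
orientation; transposing the matrix silently changes the meaning of every
downstream quantity, so the I/O helpers state the convention in their
docstrings and the JSON format stores it explicitly.

The stationary event frequencies are the eigenvector of ``T`` associated
with the unit eigenvalue, normalized to sum to one.  Irreducibility of the
chain is enforced at construction so that this eigenvector is unique.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TransitionMatrix",
    "EventSequence",
    "EventStatistics",
    "random_transition_matrix",
    "stationary_distribution",
    "sample_sequence",
    "event_statistics",
]

#: Default physical interval between events, in seconds.
DEFAULT_DT_EVENT = 0.6

_COLSUM_ATOL = 1e-12


def _is_irreducible(T: np.ndarray) -> bool:
    """True if the support graph of ``T`` is strongly connected."""
    n_comp, _ = connected_components(csr_matrix(T > 0), connection="strong")
    return n_comp == 1


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic transition matrix of an irreducible Markov chain.

    Parameters
    ----------
    T
        Square array with ``T[i, j] = P(E_j -> E_i)``.  Every column must
        sum to one, all entries must lie in ``[0, 1]``, and the chain must
        be irreducible (strongly connected support).
    """

    T: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError(f"transition matrix must be square, got shape {T.shape}")
        if T.shape[0] < 2:
            raise ValueError("need at least 2 events")
        if np.any(T < 0) or np.any(T > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        colsums = T.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _COLSUM_ATOL):
            raise ValueError(
                f"columns must sum to 1 within {_COLSUM_ATOL}; "
                f"worst deviation {np.abs(colsums - 1).max():.3e}"
            )
        if not _is_irreducible(T):
            raise ValueError("chain is not irreducible (support graph not strongly connected)")
        T.setflags(write=False)
        object.__setattr__(self, "T", T)

    @property
    def n(self) -> int:
        """Number of events."""
        return self.T.shape[0]

    def probability(self, pre: int, post: int) -> float:
        """``P(E_pre -> E_post)``, i.e. ``T[post, pre]``."""
        return float(self.T[post, pre])

    # ---------------------------------------------------------------- I/O
    @classmethod
    def from_csv(cls, path) -> "TransitionMatrix":
        """Read an ``n x n`` comma-separated matrix (``T[i,j] = P(j -> i)``).

        Lines starting with ``#`` are ignored.
        """
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                rows.append([float(x) for x in line.split(",")])
        return cls(np.array(rows, dtype=float))

    def to_csv(self, path) -> None:
        """Write the matrix as comma-separated text at full precision."""
        with open(path, "w") as fh:
            fh.write("# column-stochastic transition matrix, T[i,j] = P(E_j -> E_i)\n")
            for row in self.T:
                fh.write(",".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def from_json(cls, path) -> "TransitionMatrix":
        with open(path) as fh:
            obj = json.load(fh)
        T = np.array(obj["T"], dtype=float)
        if "n" in obj and obj["n"] != T.shape[0]:
            raise ValueError("JSON field 'n' inconsistent with matrix shape")
        return cls(T)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n": self.n,
                    "convention": "T[i][j] = P(E_j -> E_i) (column-stochastic)",
                    "T": self.T.tolist(),
                },
                fh,
                indent=1,
            )


@dataclass(frozen=True)
class EventSequence:
    """A realized sequence of event indices, one event per time step."""

    events: np.ndarray
    dt_event: float = DEFAULT_DT_EVENT
    seed: int | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=np.int64)
        if ev.ndim != 1 or ev.size < 2:
            raise ValueError("sequence must be 1-D with length >= 2")
        n = self.n if self.n is not None else int(ev.max()) + 1
        if ev.min() < 0 or ev.max() >= n:
            raise ValueError("event indices out of range")
        ev.setflags(write=False)
        object.__setattr__(self, "events", ev)
        object.__setattr__(self, "n", n)

    def __len__(self) -> int:
        return self.events.size

    def to_txt(self, path, sidecar: bool = True) -> None:
        """Write one event index per line; optional JSON sidecar with metadata."""
        np.savetxt(path, self.events, fmt="%d")
        if sidecar:
            with open(str(path) + ".json", "w") as fh:
                json.dump({"dt_event": self.dt_event, "seed": self.seed, "n": self.n}, fh)

    @classmethod
    def from_txt(cls, path, dt_event: float | None = None) -> "EventSequence":
        ev = np.loadtxt(path, dtype=np.int64)
        meta: dict = {}
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            pass
        if dt_event is None:
            dt_event = meta.get("dt_event", DEFAULT_DT_EVENT)
        return cls(ev, dt_event=dt_event, seed=meta.get("seed"), n=meta.get("n"))


@dataclass(frozen=True)
class EventStatistics:
    """First- and second-order event statistics.

    Attributes
    ----------
    f
        Length-``n`` event frequencies.
    f_pair
        ``f_pair[i, j]`` is the frequency of the consecutive pair
        ``(E_j at t-1, E_i at t)``; analytically ``f[j] * T[i, j]``.
    f_cond
        ``f_cond[i, j] = f_pair[i, j] / f[i]``: the conditional probability
        that ``E_j`` occurred at ``t-1`` given ``E_i`` at ``t``.  Each row
        sums to one.
    analytic
        Whether the statistics were derived from a transition matrix
        (exact) or counted from a finite sequence (empirical).
    """

    f: np.ndarray
    f_pair: np.ndarray
    f_cond: np.ndarray
    analytic: bool = True
    T: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.f.size


def random_transition_matrix(
    n: int,
    out_degree_range: tuple[int, int] = (2, 4),
    seed=None,
    *,
    allow_self: bool = True,
    max_attempts: int = 1000,
) -> TransitionMatrix:
    """Generate a random transition matrix with sparse columns.

    For each event, a number of possible successors is drawn uniformly from
    ``out_degree_range`` (default 2-4, which avoids columns made only of
    small probabilities), the successors are chosen uniformly at random
    among all ``n`` events, and their weights are drawn uniformly in (0, 1)
    and normalized.  Matrices whose support is not strongly connected are
    resampled, so the returned chain always has a unique stationary
    distribution.

    Parameters
    ----------
    n
        Number of events (``>= max(out_degree_range)`` and ``>= 2``).
    out_degree_range
        Inclusive interval for the per-event successor count.
    seed
        Seed or :class:`numpy.random.Generator`.
    allow_self
        Whether an event may follow itself.  Self-transitions only touch
        within-population synapses, which are held fixed, so they are
        allowed by default.
    """
    lo, hi = out_degree_range
    if n < 2:
        raise ValueError("n must be >= 2")
    if lo < 1 or hi < lo:
        raise ValueError("invalid out-degree range")
    pool = n if allow_self else n - 1
    if pool < hi:
        raise ValueError("out-degree range exceeds the number of available successors")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        T = np.zeros((n, n))
        for j in range(n):
            d = int(rng.integers(lo, hi + 1))
            candidates = np.arange(n)
            if not allow_self:
                candidates = np.delete(candidates, j)
            succ = rng.choice(candidates, size=d, replace=False)
            w = rng.uniform(0.0, 1.0, size=d)
            T[succ, j] = w / w.sum()
        if _is_irreducible(T):
            return TransitionMatrix(T)
    raise RuntimeError(
        f"failed to generate an irreducible chain in {max_attempts} attempts"
    )


def stationary_distribution(T: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Stationary event frequencies: the unit-eigenvalue eigenvector of ``T``.

    Computed as the null space of ``T - I`` (SVD), normalized to sum to one.
    Satisfies ``T @ f == f`` to 1e-10.
    """
    A = T.T if isinstance(T, TransitionMatrix) else np.asarray(T, dtype=float)
    if not isinstance(T, TransitionMatrix) and not _is_irreducible(A):
        raise ValueError("chain is not irreducible; stationary distribution not unique")
    ns = null_space(A - np.eye(A.shape[0]), rcond=1e-10)
    if ns.shape[1] != 1:  # pragma: no cover - construction should prevent this
        raise ValueError("stationary distribution is not unique")
    f = ns[:, 0].real
    f = np.abs(f)
    f = f / f.sum()
    resid = np.abs(A @ f - f).max()
    if resid > 1e-10:  # pragma: no cover
        raise ValueError(f"stationary solve failed, residual {resid:.2e}")
    return f


def sample_sequence(
    T: TransitionMatrix,
    length: int,
    initial: int | str = "stationary",
    seed=None,
    *,
    burn_in: int = 0,
    dt_event: float = DEFAULT_DT_EVENT,
) -> EventSequence:
    """Sample a stochastic event sequence from the chain.

    Parameters
    ----------
    length
        Number of steps returned (``>= 2``).
    initial
        Index of the first event, or ``"stationary"`` to draw it from the
        stationary distribution (so steady-state statistics hold from the
        first step).
    burn_in
        Extra leading steps simulated and discarded.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    n = T.n
    if initial == "stationary":
        f = stationary_distribution(T)
        cur = int(rng.choice(n, p=f))
    else:
        cur = int(initial)
        if not 0 <= cur < n:
            raise ValueError(f"initial event index {cur} out of range [0, {n})")
    total = length + burn_in
    cum = np.cumsum(T.T, axis=0)
    cum[-1, :] = 1.0  # guard against rounding in the last bin
    u = rng.random(total - 1)
    ev = np.empty(total, dtype=np.int64)
    ev[0] = cur
    for t in range(1, total):
        cur = int(np.searchsorted(cum[:, cur], u[t - 1], side="right"))
        ev[t] = cur
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return EventSequence(ev[burn_in:], dt_event=dt_event, seed=seed_int, n=n)


def event_statistics(source: TransitionMatrix | EventSequence) -> EventStatistics:
    """Event frequencies, pair frequencies, and conditional probabilities.

    Given a :class:`TransitionMatrix`, returns the analytic statistics
    ``f_pair[i, j] = f[j] * T[i, j]``; given an :class:`EventSequence`,
    returns their empirical counterparts counted from the realization.
    """
    if isinstance(source, TransitionMatrix):
        f = stationary_distribution(source)
        f_pair = source.T * f[np.newaxis, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            f_cond = np.where(f[:, None] > 0, f_pair / f[:, None], 0.0)
        return EventStatistics(f=f, f_pair=f_pair, f_cond=f_cond, analytic=True, T=source.T)
    if isinstance(source, EventSequence):
        ev = source.events
        n = source.n
        f = np.bincount(ev, minlength=n) / ev.size
        pair_counts = np.zeros((n, n))
        np.add.at(pair_counts, (ev[1:], ev[:-1]), 1)
        f_pair = pair_counts / (ev.size - 1)
        row = f_pair.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_cond = np.where(row > 0, f_pair / row, 0.0)
        return EventStatistics(f=f, f_pair=f_pair, f_cond=f_cond, analytic=False)
    raise TypeError(f"expected TransitionMatrix or EventSequence, got {type(source)!r}")
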