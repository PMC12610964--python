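"""Estimation and analysis of the discrete-state transition matrix.

A cattle activity chain is summarised by a row-stochastic transition matrix
``P`` whose entry ``(i, j)`` is the probability of moving from state ``i``
to state ``j`` in one step, and by its stationary distribution ``pi``
(``pi P = pi``), the long-run fraction of time spent in each state.  The
cumulative form ``C1..Cn`` of ``pi`` drives inverse-CDF sampling.

Published transition matrices are typically rounded to three decimals, so
their rows sum to slightly less than one; :func:`renormalize_rows` restores
exact stochasticity and records the original row sums for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.sparse import csgraph, csr_matrix

from .states import DEFAULT_STATE_SPACE, StateSequence, StateSpace

_ROW_TOL = 1e-12


@dataclass
class TransitionMatrix:
    """Row-stochastic matrix over a labelled state space.

    ``source`` tags how the matrix was obtained (``"printed"``,
    ``"sequence-mle"``, ``"composition"``, ...).  ``original_row_sums``
    records pre-renormalization row sums when renormalization was applied.
    """

    probs: np.ndarray
    states: StateSpace = field(default=DEFAULT_STATE_SPACE)
    source: str = "unspecified"
    original_row_sums: np.ndarray | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.probs, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError(f"transition matrix must be square, got {P.shape}")
        if P.shape[0] != self.states.n:
            raise ValueError(f"matrix size {P.shape[0]} does not match state "
                             f"space of size {self.states.n}")
        if np.any(P < 0):
            raise ValueError("transition probabilities must be non-negative")
        rows = P.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError(f"rows must sum to 1; got sums {rows}")
        self.probs = P

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    def __getitem__(self, key: tuple[str, str]) -> float:
        i, j = key
        return float(self.probs[self.states.index(i), self.states.index(j)])

    @property
    def raw_probs(self) -> np.ndarray:
        """Entries as they appeared before row renormalization (equals
        ``probs`` when no renormalization was recorded)."""
        if self.original_row_sums is None:
            return self.probs
        return self.probs * self.original_row_sums[:, None]

    def submatrix(self, labels: tuple[str, ...] | list[str]) -> "TransitionMatrix":
        """Sub-chain restricted to ``labels``, rows renormalized."""
        idx = [self.states.index(l) for l in labels]
        sub = self.probs[np.ix_(idx, idx)]
        return renormalize_rows(sub, states=StateSpace(tuple(labels)),
                                source=f"{self.source}-sub")


@dataclass
class StationaryDistribution:
    """Stationary probability vector with its cumulative form."""

    pi: np.ndarray
    states: StateSpace = field(default=DEFAULT_STATE_SPACE)

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 1 or pi.size != self.states.n:
            raise ValueError("pi must be a vector matching the state space")
        if np.any(pi < -_ROW_TOL):
            raise ValueError("pi must be non-negative")
        pi = np.clip(pi, 0.0, None)
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError(f"pi must sum to 1, got {pi.sum()}")
        self.pi = pi / pi.sum()

    @property
    def cumulative(self) -> np.ndarray:
        """Running partial sums C1..Cn; the last entry is exactly 1."""
        c = np.cumsum(self.pi)
        c[-1] = 1.0
        return c

    def __getitem__(self, label: str) -> float:
        return float(self.pi[self.states.index(label)])


def renormalize_rows(matrix: np.ndarray, states: StateSpace | None = None,
                     source: str = "renormalized") -> TransitionMatrix:
    """Divide each row of a non-negative square matrix by its sum.

    Raises on negative entries or an all-zero ("absorbing-defective") row.
    The original row sums are kept on the result for diagnostics.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix must be square, got shape {M.shape}")
    if np.any(M < 0):
        raise ValueError("matrix entries must be non-negative")
    rows = M.sum(axis=1)
    zero = np.flatnonzero(rows == 0)
    if zero.size:
        raise ValueError(f"absorbing-defective row(s) summing to 0 at "
                         f"index {zero.tolist()}")
    if states is None:
        states = (DEFAULT_STATE_SPACE if M.shape[0] == DEFAULT_STATE_SPACE.n
                  else StateSpace(tuple(f"S{i}" for i in range(M.shape[0]))))
    return TransitionMatrix(M / rows[:, None], states=states, source=source,
                            original_row_sums=rows)


def estimate_from_sequence(seq: StateSequence, smoothing: float = 0.0,
                           space: StateSpace | None = None) -> TransitionMatrix:
    """Maximum-likelihood transition matrix from an observed state sequence.

    ``P[i, j] = (count(i -> j) + smoothing) / (count(i -> .) + n * smoothing)``.

    With ``smoothing == 0`` a visited state must have at least one outgoing
    transition (a state seen only at the very end of the sequence has none);
    never-visited states receive a uniform row so the result is always a
    valid stochastic matrix, and the matrix is tagged accordingly.
    """
    if smoothing < 0:
        raise ValueError("smoothing pseudo-count must be >= 0")
    space = space or seq.space
    n = space.n
    if len(seq) < 2:
        raise ValueError("need a sequence of length >= 2 to estimate "
                         "transitions")
    lut = {l: i for i, l in enumerate(space.labels)}
    codes = np.array([lut[s] for s in seq.states])
    counts = np.zeros((n, n))
    np.add.at(counts, (codes[:-1], codes[1:]), 1.0)
    visited = np.zeros(n, dtype=bool)
    visited[codes] = True
    out = counts.sum(axis=1)
    if smoothing == 0.0:
        dangling = np.flatnonzero(visited & (out == 0))
        if dangling.size:
            labels = [space.labels[i] for i in dangling]
            raise ValueError(
                f"state(s) {labels!r} are visited but have no outgoing "
                f"transition; pass smoothing > 0 to regularize")
        # never-visited states get a uniform row so the matrix stays stochastic
        P = np.where(out[:, None] > 0,
                     counts / np.where(out == 0, 1.0, out)[:, None],
                     1.0 / n)
    else:
        P = (counts + smoothing) / (out + n * smoothing)[:, None]
    source = "sequence-mle" if visited.all() else "sequence-mle+uniform-rows"
    return TransitionMatrix(P, states=space, source=source)


def estimate_from_compositions(table, mode: str = "lagged") -> TransitionMatrix:
    """Transition matrix from per-interval activity compositions.

    Each record's nine values are normalized to a proportion vector
    ``q(d)``; ``lagged`` mode accumulates the outer products
    ``q(d) q(d+1)^T`` across consecutive records, ``co-occurrence`` mode
    accumulates ``q(d) q(d)^T``.  Row renormalization of the accumulated
    matrix gives the estimate.  This is a composition-level surrogate for a
    sequence-level count matrix; it is not expected to reproduce any
    particular published prior.

    The full nine-state matrix is built when all nine columns are present;
    a behavior-only table yields the 6x6 behavioral sub-chain.
    """
    from .io import ActivityTable  # local import to avoid a cycle

    if mode not in ("lagged", "co-occurrence"):
        raise ValueError(f"mode must be 'lagged' or 'co-occurrence', got {mode!r}")
    if isinstance(table, ActivityTable):
        frame = table.to_frame()
    else:
        frame = table
    cols = [c for c in DEFAULT_STATE_SPACE.labels if c in frame.columns]
    if len(cols) < 2:
        raise ValueError(f"activity table has no state columns among "
                         f"{DEFAULT_STATE_SPACE.labels!r}")
    space = StateSpace(tuple(cols))
    Q = frame[cols].to_numpy(dtype=float)
    if Q.shape[0] < 2:
        raise ValueError("need at least 2 records")
    sums = Q.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"record(s) at position {zero.tolist()} have "
                         f"all-zero values")
    Q = Q / sums[:, None]
    if mode == "lagged":
        M = Q[:-1].T @ Q[1:]
    else:
        M = Q.T @ Q
    return renormalize_rows(M, states=space, source="composition")


def _positive_digraph_components(P: np.ndarray) -> int:
    g = csr_matrix((P > 0).astype(np.int8))
    ncomp, _ = csgraph.connected_components(g, directed=True,
                                            connection="strong")
    return ncomp


def is_irreducible(matrix: TransitionMatrix | np.ndarray) -> bool:
    """True iff the digraph of positive entries is strongly connected."""
    P = matrix.probs if isinstance(matrix, TransitionMatrix) else np.asarray(matrix)
    return _positive_digraph_components(P) == 1


def stationary_distribution(matrix: TransitionMatrix, method: str = "eigen",
                            tol: float = 1e-12,
                            max_iter: int = 100_000) -> StationaryDistribution:
    """Solve ``pi P = pi`` for an irreducible chain.

    ``eigen`` takes the left eigenvector of eigenvalue 1 (handles periodic
    chains directly); ``power`` iterates ``v <- v P``, falling back to the
    average of two successive iterates when period-2 oscillation prevents
    convergence.  The two methods agree to high precision on irreducible
    chains.
    """
    P = matrix.probs
    if not is_irreducible(matrix):
        raise ValueError("stationary distribution not unique: the chain is "
                         "reducible (positive-entry digraph is not strongly "
                         "connected)")
    if method == "eigen":
        w, v = sla.eig(P.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        pi = np.clip(pi, 0.0, None) if pi.sum() > 0 else np.clip(-pi, 0.0, None)
        pi = pi / pi.sum()
    elif method == "power":
        n = P.shape[0]
        v = np.full(n, 1.0 / n)
        pi = None
        for _ in range(max_iter):
            nxt = v @ P
            if np.max(np.abs(nxt - v)) < tol:
                pi = nxt
                break
            # Cesaro pair-average handles period-2 oscillation exactly
            avg = 0.5 * (v + nxt)
            if np.max(np.abs(avg @ P - avg)) < tol:
                pi = avg
                break
            v = nxt
        if pi is None:
            raise RuntimeError(f"power iteration did not converge within "
                               f"{max_iter} iterations (tol={tol})")
        pi = pi / pi.sum()
    else:
        raise ValueError(f"method must be 'eigen' or 'power', got {method!r}")
    resid = np.max(np.abs(pi @ P - pi))
    if resid > 1e-8:
        raise RuntimeError(f"stationary solve residual {resid} too large")
    return StationaryDistribution(pi, states=matrix.states)


def n_step_matrix(matrix: TransitionMatrix, n: int) -> TransitionMatrix:
    """``n``-step transition probabilities ``P^n``."""
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    Pn = np.linalg.matrix_power(matrix.probs, n)
    # guard against drift from repeated multiplication
    Pn = Pn / Pn.sum(axis=1, keepdims=True)
    return TransitionMatrix(Pn, states=matrix.states,
                            source=f"{matrix.source}^({n})")
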