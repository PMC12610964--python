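"""Sequence generation: direct chain simulation and Metropolis-Hastings.

Two samplers are provided because both views of "MCMC simulation of the
activity chain" are useful and they share one evaluation harness:

* :func:`simulate_direct` runs the Markov chain itself, drawing each next
  state by inverse-CDF sampling on the cumulative probabilities of the
  current state's row.
* :func:`simulate_metropolis_hastings` samples the stationary distribution
  ``pi`` directly with a Metropolis-Hastings chain: propose ``j`` uniformly
  over all states (the proposal may equal the current state — a lazy,
  symmetric proposal, still valid), accept with probability
  ``min(1, pi_j / pi_i)``, repeat the current state on rejection.

Both discard a burn-in prefix (burn-in counts proposals, not acceptances)
and are bit-for-bit reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markov import StationaryDistribution, TransitionMatrix, \
    stationary_distribution
from .states import StateSequence, StateSpace


@dataclass
class SimulationConfig:
    """Settings for one simulation run.

    ``initial_state`` is a state label or ``"stationary-draw"`` (one
    inverse-CDF draw from the target/stationary distribution); the default
    is the first state of the space, which keeps short runs reproducible
    without an extra random draw.
    """

    n_iterations: int
    burn_in: int = 1000
    seed: int = 0
    sampler: str = "direct"
    initial_state: str | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.sampler not in ("direct", "metropolis-hastings", "mh"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


@dataclass
class SimulationResult:
    """Retained (post-burn-in) samples plus summary frequencies."""

    sequence: StateSequence
    empirical: np.ndarray
    config: SimulationConfig
    acceptance_rate: float | None = None

    @property
    def states(self) -> StateSpace:
        return self.sequence.space

    def empirical_of(self, label: str) -> float:
        return float(self.empirical[self.states.index(label)])


def _initial_index(space: StateSpace, config: SimulationConfig,
                   cumulative: np.ndarray, rng: np.random.Generator) -> int:
    init = config.initial_state
    if init is None:
        return 0
    if init == "stationary-draw":
        return int(np.searchsorted(cumulative, rng.random(), side="right"))
    return space.index(init)


def _package(codes: np.ndarray, space: StateSpace, config: SimulationConfig,
             acceptance_rate: float | None = None) -> SimulationResult:
    retained = codes[config.burn_in:]
    freqs = np.bincount(retained, minlength=space.n) / retained.size
    seq = StateSequence([space.labels[c] for c in retained], space=space)
    return SimulationResult(seq, freqs, config, acceptance_rate)


def simulate_direct(matrix: TransitionMatrix,
                    config: SimulationConfig) -> SimulationResult:
    """Simulate the chain itself via per-row inverse-CDF sampling."""
    rng = np.random.default_rng(config.seed)
    space = matrix.states
    row_cum = np.cumsum(matrix.probs, axis=1)
    row_cum[:, -1] = 1.0
    if config.initial_state == "stationary-draw":
        pi_cum = stationary_distribution(matrix).cumulative
    else:
        pi_cum = np.ones(space.n)
    total = config.burn_in + config.n_iterations
    u = rng.random(total)
    codes = np.empty(total, dtype=np.int64)
    state = _initial_index(space, config, pi_cum, rng)
    for t in range(total):
        state = int(np.searchsorted(row_cum[state], u[t], side="right"))
        codes[t] = state
    return _package(codes, space, config)


def simulate_metropolis_hastings(target: StationaryDistribution,
                                 config: SimulationConfig) -> SimulationResult:
    """Sample ``target`` with a uniform-proposal Metropolis-Hastings chain."""
    pi = target.pi
    if np.any(pi <= 0):
        raise ValueError("Metropolis-Hastings with a uniform proposal "
                         "requires a strictly positive target distribution")
    rng = np.random.default_rng(config.seed)
    space = target.states
    n = space.n
    total = config.burn_in + config.n_iterations
    proposals = rng.integers(0, n, size=total)
    u = rng.random(total)
    codes = np.empty(total, dtype=np.int64)
    state = _initial_index(space, config, target.cumulative, rng)
    accepted = 0
    for t in range(total):
        j = proposals[t]
        if u[t] * pi[state] < pi[j]:
            state = int(j)
            accepted += 1
        codes[t] = state
    return _package(codes, space, config, acceptance_rate=accepted / total)


def run_sampler(config: SimulationConfig,
                matrix: TransitionMatrix | None = None,
                target: StationaryDistribution | None = None
                ) -> SimulationResult:
    """Dispatch on ``config.sampler``; derives the target from the matrix
    (or vice versa is not needed) when only one input is given."""
    if config.sampler == "direct":
        if matrix is None:
            raise ValueError("direct sampler needs a transition matrix")
        return simulate_direct(matrix, config)
    if target is None:
        if matrix is None:
            raise ValueError("metropolis-hastings sampler needs a target "
                             "distribution or a matrix to derive it from")
        target = stationary_distribution(matrix)
    return simulate_metropolis_hastings(target, config)
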