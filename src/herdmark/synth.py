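"""Synthetic herd generation.

Emulates the aggregated output of a neck-mounted multi-sensor collar on a
small dairy herd: per-cow categorical behavior sequences sampled at a fixed
step, their per-interval duration aggregates in the standard activity-table
schema, and correlated daily temperature/humidity series with a derived
temperature-humidity index (THI).

A cow physically occupies exactly one behavioral state per step, so
sequences are drawn from the 6x6 behavioral sub-chain (F, M, L, S, RS, RL)
of the ground-truth matrix; environmental variables are generated as
parallel continuous AR(1) series rather than chain states.  The full
nine-state matrix remains available for analysis.

Default condition: 5 cows observed for 30 days at 1-minute resolution, the
packaged prior matrix as ground truth, and August-like hot-humid weather
(T ~ 31.5 +/- 0.9 deg C, H ~ 77.5 +/- 4 %RH) matching the ranges of the
packaged 30-day sample table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import TransitionMatrix, stationary_distribution
from .simulate import SimulationConfig, simulate_direct
from .states import BEHAVIORAL_LABELS, StateSequence
from .io import ActivityRecord, ActivityTable


@dataclass
class HerdSpec:
    """Ground-truth conditions for one synthetic herd."""

    n_cows: int = 5
    days: int = 30
    step_seconds: float = 60.0
    ground_truth: TransitionMatrix | None = None
    temp_mean: float = 31.5
    temp_sd: float = 0.9
    hum_mean: float = 77.5
    hum_sd: float = 4.0
    env_autocorr: float = 0.5
    initial_state: str | None = "stationary-draw"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cows < 1 or self.days < 1:
            raise ValueError("n_cows and days must be positive")
        if self.step_seconds <= 0:
            raise ValueError("step_seconds must be positive")
        if not -1.0 < self.env_autocorr < 1.0:
            raise ValueError("env_autocorr must lie in (-1, 1)")

    def resolved_ground_truth(self) -> TransitionMatrix:
        if self.ground_truth is not None:
            return self.ground_truth
        from .io import load_prior_transition_matrix
        return load_prior_transition_matrix()

    def behavioral_chain(self) -> TransitionMatrix:
        """The 6x6 behavioral sub-chain of the ground truth, renormalized."""
        gt = self.resolved_ground_truth()
        labels = [l for l in BEHAVIORAL_LABELS if l in gt.states.labels]
        if len(labels) < 2:
            raise ValueError("ground truth has no behavioral sub-chain")
        return gt.submatrix(tuple(labels))

    @property
    def steps_per_day(self) -> int:
        steps = 86400.0 / self.step_seconds
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("step_seconds must divide one day")
        return int(round(steps))


def thi(T, H):
    """Temperature-humidity index from temperature (deg C) and RH (%).

    ``THI = 0.8 T + (H/100) (T - 14.4) + 46.4`` — the standard livestock
    heat-stress index.  Field instruments apply proprietary placement
    corrections, so logged THI columns can differ from this by a few tenths;
    treat logged values as data rather than recomputing them.
    """
    T = np.asarray(T, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any((H < 0) | (H > 100)):
        raise ValueError("relative humidity must lie in [0, 100]")
    out = 0.8 * T + (H / 100.0) * (T - 14.4) + 46.4
    return float(out) if out.ndim == 0 else out


def generate_cow_sequence(spec: HerdSpec, cow_index: int = 0) -> StateSequence:
    """One cow's behavioral state sequence over ``spec.days`` days.

    Drawn from the behavioral sub-chain, seeded per cow
    (``spec.seed + cow_index``); the initial state follows
    ``spec.initial_state`` (stationary draw by default).
    """
    chain = spec.behavioral_chain()
    n_steps = spec.days * spec.steps_per_day
    config = SimulationConfig(n_iterations=n_steps, burn_in=0,
                              seed=spec.seed + cow_index, sampler="direct",
                              initial_state=spec.initial_state)
    result = simulate_direct(chain, config)
    seq = result.sequence
    seq.step_seconds = spec.step_seconds
    return seq


def aggregate_sequence(seq: StateSequence,
                       interval_minutes: float = 1440.0,
                       cow_id: str = "") -> ActivityTable:
    """Per-interval duration aggregates (minutes) of a behavior sequence.

    The sequence length must divide evenly into intervals; each output row's
    durations sum to the interval length in minutes.
    """
    steps_per_interval = interval_minutes * 60.0 / seq.step_seconds
    if abs(steps_per_interval - round(steps_per_interval)) > 1e-9:
        raise ValueError("interval must be a whole number of steps")
    spi = int(round(steps_per_interval))
    if len(seq) % spi != 0:
        raise ValueError(f"sequence length {len(seq)} is not divisible by "
                         f"{spi} steps per {interval_minutes:g}-minute "
                         f"interval")
    minutes_per_step = seq.step_seconds / 60.0
    codes = np.asarray(seq.indices())
    n_intervals = len(seq) // spi
    labels = seq.space.labels
    counts = np.zeros((n_intervals, len(labels)))
    for k in range(n_intervals):
        chunk = codes[k * spi:(k + 1) * spi]
        counts[k] = np.bincount(chunk, minlength=len(labels))
    durations = counts * minutes_per_step
    by_label = {l: durations[:, i] for i, l in enumerate(labels)}
    records = []
    for k in range(n_intervals):
        records.append(ActivityRecord(
            index=k + 1,
            F=by_label.get("F", np.zeros(n_intervals))[k],
            M=by_label.get("M", np.zeros(n_intervals))[k],
            L=by_label.get("L", np.zeros(n_intervals))[k],
            S=by_label.get("S", np.zeros(n_intervals))[k],
            RS=by_label.get("RS", np.zeros(n_intervals))[k],
            RL=by_label.get("RL", np.zeros(n_intervals))[k],
            total_min=float(interval_minutes)))
    return ActivityTable(records, cow_id=cow_id,
                         interval_minutes=float(interval_minutes))


def generate_environment(spec: HerdSpec, days: int | None = None,
                         rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Daily (T, H, THI) triples with mild AR(1) day-to-day autocorrelation.

    Marginals are Normal(temp_mean, temp_sd) and Normal(hum_mean, hum_sd)
    (humidity clipped to [0, 100]); innovations are scaled so the stated
    sds are the stationary marginal sds.  THI is derived from the same
    row's T and H.
    """
    days = days if days is not None else spec.days
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    rho = spec.env_autocorr
    scale = np.sqrt(1.0 - rho * rho)

    def ar1(mean: float, sd: float) -> np.ndarray:
        z = np.empty(days)
        z[0] = rng.normal()
        eps = rng.normal(size=days - 1) * scale if days > 1 else np.empty(0)
        for t in range(1, days):
            z[t] = rho * z[t - 1] + eps[t - 1]
        return mean + sd * z

    T = ar1(spec.temp_mean, spec.temp_sd)
    H = np.clip(ar1(spec.hum_mean, spec.hum_sd), 0.0, 100.0)
    return pd.DataFrame({"T": T, "H": H, "THI": thi(T, H)})


def generate_herd(spec: HerdSpec,
                  interval_minutes: float = 1440.0
                  ) -> dict[str, tuple[StateSequence, ActivityTable]]:
    """Sequences plus full-schema activity tables for every cow.

    Environmental columns are attached when the aggregation interval is a
    whole number of days (environment is generated per day); sub-daily
    tables stay behavior-only.
    """
    out: dict[str, tuple[StateSequence, ActivityTable]] = {}
    daily = abs(interval_minutes - 1440.0) < 1e-9
    for c in range(spec.n_cows):
        cow_id = f"cow{c + 1}"
        seq = generate_cow_sequence(spec, c)
        table = aggregate_sequence(seq, interval_minutes, cow_id=cow_id)
        if daily:
            env = generate_environment(
                spec, rng=np.random.default_rng(spec.seed + 10_000 + c))
            for rec, (_, row) in zip(table.records, env.iterrows()):
                rec.T = float(row["T"])
                rec.H = float(row["H"])
                rec.THI = float(row["THI"])
        out[cow_id] = (seq, table)
    return out
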