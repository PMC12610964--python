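"""Reading, validating and writing activity tables, matrices and sequences.

File formats
------------
* Activity table: CSV (comma, ``.`` decimal, UTF-8) or TSV with the header
  ``No, T, H, THI, F, M, L, S, RS, RL, TOTAL_MIN`` (case-insensitive).
  One row per aggregation interval; the six behavior columns hold durations
  in minutes and must sum to ``TOTAL_MIN``.  Row ids (``No``) are 1-based
  in files and 0-based internally.
* Transition matrix: CSV with a header row and a leading label column, both
  matching the state space order.
* State sequence: plain text, one state label per line.

The package ships small reference fixtures: a prior nine-state transition
matrix for a Holstein dairy herd, its stationary distribution, a 30-day
daily activity table for one cow, and a per-cow simulation error table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .markov import TransitionMatrix, renormalize_rows
from .states import (BEHAVIORAL_LABELS, DEFAULT_STATE_SPACE, StateSequence,
                     StateSpace)

ACTIVITY_COLUMNS = ("No", "T", "H", "THI", "F", "M", "L", "S", "RS", "RL",
                    "TOTAL_MIN")


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


@dataclass
class ActivityRecord:
    """One aggregation interval of a cow's day.

    ``F``..``RL`` are durations in minutes; ``T`` (deg C), ``H`` (% RH) and
    ``THI`` are the contemporaneous environmental readings and may be
    absent for behavior-only tables.
    """

    index: int
    F: float
    M: float
    L: float
    S: float
    RS: float
    RL: float
    total_min: float
    T: float | None = None
    H: float | None = None
    THI: float | None = None

    @property
    def durations(self) -> tuple[float, ...]:
        return (self.F, self.M, self.L, self.S, self.RS, self.RL)


@dataclass
class ActivityTable:
    """Ordered collection of :class:`ActivityRecord` for one cow."""

    records: list[ActivityRecord]
    cow_id: str = ""
    interval_minutes: float = 1440.0

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("no records")
        idx = [r.index for r in self.records]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("record indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def has_environment(self) -> bool:
        return all(r.T is not None for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({"No": r.index, "T": r.T, "H": r.H, "THI": r.THI,
                         "F": r.F, "M": r.M, "L": r.L, "S": r.S,
                         "RS": r.RS, "RL": r.RL, "TOTAL_MIN": r.total_min})
        frame = pd.DataFrame(rows, columns=list(ACTIVITY_COLUMNS))
        if not self.has_environment:
            frame = frame.drop(columns=["T", "H", "THI"])
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cow_id: str = "",
                   interval_minutes: float | None = None) -> "ActivityTable":
        has_env = all(c in frame.columns for c in ("T", "H", "THI"))
        records = []
        for _, row in frame.iterrows():
            records.append(ActivityRecord(
                index=int(row["No"]),
                F=float(row["F"]), M=float(row["M"]), L=float(row["L"]),
                S=float(row["S"]), RS=float(row["RS"]), RL=float(row["RL"]),
                total_min=float(row["TOTAL_MIN"]),
                T=float(row["T"]) if has_env else None,
                H=float(row["H"]) if has_env else None,
                THI=float(row["THI"]) if has_env else None))
        if interval_minutes is None:
            interval_minutes = float(frame["TOTAL_MIN"].iloc[0])
        return cls(records, cow_id=cow_id, interval_minutes=interval_minutes)


def _detect_sep(path: Path) -> str:
    head = path.read_text(encoding="utf-8").splitlines()
    return "\t" if head and "\t" in head[0] else ","


def read_activity_table(path: str | Path, schema: StateSpace | None = None,
                        sep: str | None = None,
                        cow_id: str = "") -> ActivityTable:
    """Read a Table-schema activity CSV/TSV.

    Raises :class:`SchemaError` naming any missing column and
    :class:`ParseError` with the (1-based) row number of a non-numeric cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = sep or _detect_sep(path)
    frame = pd.read_csv(path, sep=sep, dtype=str)
    frame.columns = [c.strip() for c in frame.columns]
    lower = {c.lower(): c for c in frame.columns}
    required = list(ACTIVITY_COLUMNS)
    optional = {"T", "H", "THI"}
    missing = [c for c in required
               if c.lower() not in lower and c not in optional]
    if missing:
        raise SchemaError(f"missing column(s) {missing!r} in {path.name}")
    frame = frame.rename(columns={lower[c.lower()]: c for c in required
                                  if c.lower() in lower})
    if len(frame) == 0:
        raise ValueError(f"no records in {path.name}")
    present = [c for c in required if c in frame.columns]
    for col in present:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()
                              & frame[col].notna()]
            rownum = int(bad[0]) + 1 if len(bad) else "?"
            raise ParseError(f"non-numeric value in column {col!r} at data "
                             f"row {rownum} of {path.name}") from None
    return ActivityTable.from_frame(frame, cow_id=cow_id or path.stem)


def write_activity_table(table: ActivityTable, path: str | Path,
                         sep: str = ",") -> None:
    table.to_frame().to_csv(path, sep=sep, index=False)


@dataclass
class RowValidation:
    index: int
    ok: bool
    message: str = ""


@dataclass
class ValidationReport:
    rows: list[RowValidation]

    @property
    def ok(self) -> bool:
        return all(r.ok for r in self.rows)

    @property
    def failures(self) -> list[RowValidation]:
        return [r for r in self.rows if not r.ok]


def validate_activity_table(table: ActivityTable,
                            atol: float = 1e-9) -> ValidationReport:
    """Per-row consistency report (pure; the table is not modified).

    A row passes iff its six behavior durations are non-negative and sum to
    its own ``total_min`` (not a fixed 1440 — interval lengths may vary
    between rows), its environmental readings (if present) are finite, and
    humidity lies in [0, 100].
    """
    rows = []
    for r in table.records:
        msgs = []
        if any(d < 0 for d in r.durations):
            msgs.append("negative duration")
        total = sum(r.durations)
        if not math.isclose(total, r.total_min, abs_tol=atol):
            msgs.append(f"duration sum {total:g} ≠ total {r.total_min:g}")
        if r.T is not None and not math.isfinite(r.T):
            msgs.append("non-finite T")
        if r.H is not None:
            if not math.isfinite(r.H):
                msgs.append("non-finite H")
            elif not 0.0 <= r.H <= 100.0:
                msgs.append(f"H {r.H:g} outside [0, 100]")
        rows.append(RowValidation(r.index, not msgs, "; ".join(msgs)))
    return ValidationReport(rows)


def load_transition_matrix(path: str | Path,
                           schema: StateSpace | None = None) -> TransitionMatrix:
    """Load a labelled square transition-matrix CSV.

    Entries must be non-negative and no row may sum to zero.  Rows are
    renormalized to sum exactly to 1 (3-decimal published matrices sum to
    ~0.995-0.997); the original row sums are recorded on the result and the
    as-printed entries stay available as ``TransitionMatrix.raw_probs``.
    """
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    if frame.shape[0] != frame.shape[1]:
        raise ValueError(f"matrix in {path.name} is not square: "
                         f"{frame.shape[0]}x{frame.shape[1]}")
    labels = tuple(str(c) for c in frame.columns)
    if tuple(str(i) for i in frame.index) != labels:
        raise SchemaError(f"row labels {tuple(frame.index)!r} do not match "
                          f"column labels {labels!r} in {path.name}")
    if schema is not None:
        want = tuple(schema.labels)
        if tuple(l.upper() for l in labels) != tuple(l.upper() for l in want):
            raise SchemaError(f"state labels {labels!r} do not match schema "
                              f"{want!r}")
        labels = want
    M = frame.to_numpy(dtype=float)
    if np.any(M < 0):
        raise ValueError(f"negative entry in matrix {path.name}")
    return renormalize_rows(M, states=StateSpace(labels), source="printed")


def write_transition_matrix(matrix: TransitionMatrix,
                            path: str | Path) -> None:
    labels = list(matrix.states.labels)
    pd.DataFrame(matrix.probs, index=labels, columns=labels).to_csv(
        path, index_label="state")


def read_state_sequence(path: str | Path, space: StateSpace | None = None,
                        step_seconds: float = 60.0) -> StateSequence:
    """Read a plain-text sequence file, one state label per line."""
    labels = [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()
              if ln.strip()]
    if space is None:
        space = (DEFAULT_STATE_SPACE
                 if set(labels) <= set(DEFAULT_STATE_SPACE.labels)
                 else StateSpace(tuple(dict.fromkeys(labels))))
    return StateSequence(labels, step_seconds=step_seconds, space=space)


def write_state_sequence(seq: StateSequence, path: str | Path) -> None:
    Path(path).write_text("\n".join(seq.states) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# packaged reference fixtures

def _data_path(name: str):
    return resources.files("herdmark.data").joinpath(name)


def load_prior_transition_matrix() -> TransitionMatrix:
    """The packaged prior nine-state transition matrix (rows renormalized)."""
    with resources.as_file(_data_path("prior_transition_matrix.csv")) as p:
        return load_transition_matrix(p, schema=DEFAULT_STATE_SPACE)


def load_prior_stationary() -> pd.DataFrame:
    """Reference stationary distribution (columns: state, pi, cumulative)."""
    with resources.as_file(_data_path("prior_stationary.csv")) as p:
        return pd.read_csv(p)


def load_prior_stationary_distribution():
    """The reference stationary distribution as a normalized
    :class:`~herdmark.markov.StationaryDistribution` (the shipped 3-decimal
    vector sums to 0.997; it is rescaled to sum exactly to 1)."""
    from .markov import StationaryDistribution

    frame = load_prior_stationary()
    pi = frame["pi"].to_numpy(dtype=float)
    return StationaryDistribution(pi / pi.sum(),
                                  states=StateSpace(tuple(frame["state"])))


def load_sample_activity_table() -> ActivityTable:
    """Packaged 30-day daily activity table for one cow (id 226)."""
    with resources.as_file(_data_path("sample_activity_cow226.csv")) as p:
        return read_activity_table(p, cow_id="226")


def load_simulation_error_table() -> pd.DataFrame:
    """Packaged per-cow AAE/AES/RMSE table at 3000/4000/5000 iterations."""
    with resources.as_file(_data_path("simulation_errors.csv")) as p:
        return pd.read_csv(p)
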