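"""State spaces and state sequences for the cattle activity chain.

The default chain mixes six behavioral activities with three environmental
variables, nine states in all, in the fixed order T, H, THI, F, M, L, S,
RS, RL.  All matrices and probability vectors in this package follow that
order unless a custom :class:`StateSpace` is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ENVIRONMENTAL_LABELS: tuple[str, ...] = ("T", "H", "THI")
BEHAVIORAL_LABELS: tuple[str, ...] = ("F", "M", "L", "S", "RS", "RL")
DEFAULT_LABELS: tuple[str, ...] = ENVIRONMENTAL_LABELS + BEHAVIORAL_LABELS


@dataclass(frozen=True)
class StateSpace:
    """Ordered, labelled set of chain states.

    Parameters
    ----------
    labels
        State names in matrix order.  Defaults to the nine-state space
        ``(T, H, THI, F, M, L, S, RS, RL)``: ambient temperature, relative
        humidity, temperature-humidity index, feeding, moving, lying,
        standing, rumination while standing, rumination while lying.
    """

    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) == 0:
            raise ValueError("state space must have at least one label")
        if len(set(labels)) != len(labels):
            raise ValueError(f"state labels must be unique, got {labels!r}")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def behavioral(self) -> tuple[str, ...]:
        """Labels among the six behavioral activities, in order."""
        return tuple(l for l in self.labels if l in BEHAVIORAL_LABELS)

    @property
    def environmental(self) -> tuple[str, ...]:
        """Labels among the three environmental variables, in order."""
        return tuple(l for l in self.labels if l in ENVIRONMENTAL_LABELS)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown state label {label!r}; "
                           f"known labels: {self.labels!r}") from None

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels


#: The canonical nine-state space.
DEFAULT_STATE_SPACE = StateSpace()

#: Behavioral sub-space (six activities).
BEHAVIORAL_STATE_SPACE = StateSpace(BEHAVIORAL_LABELS)


@dataclass
class StateSequence:
    """A categorical state sequence sampled at a fixed step.

    ``states`` holds one label per time step; ``step_seconds`` is the
    sampling interval (default one minute).
    """

    states: list[str]
    step_seconds: float = 60.0
    space: StateSpace = field(default=DEFAULT_STATE_SPACE)

    def __post_init__(self) -> None:
        unknown = set(self.states) - set(self.space.labels)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)!r} not in state space "
                             f"{self.space.labels!r}")

    def __len__(self) -> int:
        return len(self.states)

    def indices(self) -> list[int]:
        """States as 0-based integer codes in state-space order."""
        lut = {l: i for i, l in enumerate(self.space.labels)}
        return [lut[s] for s in self.states]
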