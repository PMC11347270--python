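"""Per-eye severity scale and the combined two-eye state space.

The model follows each eye through an ordered severity scale (by default
``advanced -> severe -> end_stage -> blind``, a modified glaucoma staging
convention in which entry to the model already requires advanced disease in
the index eye).  Disease is irreversible, so an eye can only stay put or move
to the immediate next level.  The cohort occupies *combined* states — an
ordered pair ``(index eye level, fellow eye level)`` — plus a single
absorbing death state, giving ``k**2 + 1`` states for a ``k``-level scale.

Combined states are named ``"<index>:<fellow>"`` (e.g. ``"advanced:blind"``)
and the death state is ``"dead"``.  The canonical ordering is row-major in
(index level, fellow level) with death last; it is stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEATH = "dead"

ARM_TRAB = "trabeculectomy"
ARM_MED = "medication"
ARMS = (ARM_TRAB, ARM_MED)

SEX_MALE = "male"
SEX_FEMALE = "female"


@dataclass(frozen=True)
class SeverityScale:
    """Ordered per-eye severity levels; the final level is blindness.

    Parameters
    ----------
    levels
        Severity levels from least to most severe.  At least two levels are
        required and the last one is designated "blind" — it is the level
        whose occupancy triggers the standardised-mortality-ratio adjustment.
    """

    levels: tuple[str, ...] = ("advanced", "severe", "end_stage", "blind")

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError("severity scale needs at least 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("severity levels must be unique")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def blind_level(self) -> str:
        """The most severe level; carries the mortality adjustment."""
        return self.levels[-1]

    @property
    def entry_level(self) -> str:
        """The least severe level on the scale ('advanced' by default)."""
        return self.levels[0]

    def index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise KeyError(f"unknown severity level {level!r}; scale is {self.levels}") from None

    def successor(self, level: str) -> str | None:
        """Next-worse level, or None if ``level`` is already blind."""
        i = self.index(level)
        return self.levels[i + 1] if i + 1 < self.n_levels else None

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        """All (from, to) single-step progressions on the scale."""
        return [(self.levels[i], self.levels[i + 1]) for i in range(self.n_levels - 1)]


DEFAULT_SCALE = SeverityScale()


def state_name(index_level: str, fellow_level: str) -> str:
    return f"{index_level}:{fellow_level}"


def parse_state(name: str) -> tuple[str, str]:
    if name == DEATH:
        raise ValueError("death state has no per-eye levels")
    index_level, fellow_level = name.split(":")
    return index_level, fellow_level


@dataclass(frozen=True)
class StateSpace:
    """Canonical combined state space for one severity scale."""

    scale: SeverityScale = field(default_factory=SeverityScale)

    @property
    def live_states(self) -> list[str]:
        k = self.scale.levels
        return [state_name(i, f) for i in k for f in k]

    @property
    def states(self) -> list[str]:
        return self.live_states + [DEATH]

    @property
    def n_live(self) -> int:
        return self.scale.n_levels**2

    @property
    def n_states(self) -> int:
        return self.n_live + 1

    def state_index(self, name: str) -> int:
        if name == DEATH:
            return self.n_live
        i, f = parse_state(name)
        return self.scale.index(i) * self.scale.n_levels + self.scale.index(f)

    def levels_of(self, name: str) -> tuple[int, int]:
        """Integer (index-eye, fellow-eye) level indices of a live state."""
        i, f = parse_state(name)
        return self.scale.index(i), self.scale.index(f)

    def n_blind_eyes(self, name: str) -> int:
        if name == DEATH:
            return 0
        i, f = parse_state(name)
        blind = self.scale.blind_level
        return int(i == blind) + int(f == blind)


def build_state_space(scale: SeverityScale | None = None) -> list[str]:
    """Ordered combined states (k*k live pairs then death) for ``scale``."""
    return StateSpace(scale or DEFAULT_SCALE).states
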