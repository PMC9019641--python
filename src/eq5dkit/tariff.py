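"""EQ-5D-3L health states, tariff scoring, and health-state grading.

The three-level EQ-5D instrument describes a health state by five
dimensions -- mobility (MO), self-care (SC), usual activities (UA),
pain or discomfort (PD) and anxiety or depression (AD) -- each at level
1 (no problems), 2 (some problems) or 3 (extreme problems), giving 243
distinct states conventionally written as five-digit strings
(``"11111"`` ... ``"33333"``).

A value set (tariff) maps each state to a utility index by subtracting
from 1 a constant term, one decrement per dimension level, and an extra
``N3`` decrement when any dimension is at level 3.  The Chinese time
trade-off value set ships as the default tariff
(:func:`china_tto_3l`).  Two conventions exist for the constant term:
subtracting it from every state, or only from states with some problem
(so that ``11111`` scores exactly 1).  The default here is to subtract
it always, which makes ``11111`` score 0.961 under the Chinese tariff;
pass ``constant_always=False`` for the other convention.

The module also implements a four-level severity grading of states
(``full`` / ``mild`` / ``moderate`` / ``severe``) driven by the
city-block distance between a state and full health together with the
state's level pattern; see :func:`grade`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import product
from typing import Iterator, Mapping, Union

__all__ = [
    "DIMENSIONS",
    "DIMENSION_NAMES",
    "LEVELS",
    "GRADES",
    "StateError",
    "HealthState",
    "ValueSet3L",
    "GradedState",
    "china_tto_3l",
    "utility",
    "distance_to_full",
    "grade",
    "grade_state",
]

#: Dimension keys in instrument order.
DIMENSIONS: tuple[str, ...] = ("mo", "sc", "ua", "pd", "ad")

DIMENSION_NAMES: Mapping[str, str] = {
    "mo": "mobility",
    "sc": "self-care",
    "ua": "usual activities",
    "pd": "pain or discomfort",
    "ad": "anxiety or depression",
}

LEVELS: tuple[int, ...] = (1, 2, 3)

#: Severity grades in increasing order of severity.
GRADES: tuple[str, ...] = ("full", "mild", "moderate", "severe")


class StateError(ValueError):
    """Raised for malformed health-state descriptions."""


@dataclass(frozen=True, order=True)
class HealthState:
    """An EQ-5D-3L health state: one level in {1, 2, 3} per dimension.

    Instances are immutable, ordered lexicographically, and round-trip
    exactly through their five-digit string form.
    """

    mo: int
    sc: int
    ua: int
    pd: int
    ad: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if not isinstance(level, int) or isinstance(level, bool) or level not in LEVELS:
                raise StateError(
                    f"level for {DIMENSION_NAMES[dim]} ({dim.upper()}) must be "
                    f"1, 2 or 3, got {level!r}"
                )

    @classmethod
    def from_string(cls, text: Union[str, "HealthState"]) -> "HealthState":
        """Parse a five-digit state string such as ``"12321"``.

        Surrounding whitespace is tolerated; anything else is a
        :class:`StateError` naming the offending dimension where the
        string length permits it.
        """
        if isinstance(text, cls):
            return text
        s = str(text).strip()
        if len(s) != 5:
            raise StateError(
                f"health state must be a 5-character digit string, got {s!r}"
            )
        for dim, ch in zip(DIMENSIONS, s):
            if ch not in "123":
                raise StateError(
                    f"level for {DIMENSION_NAMES[dim]} ({dim.upper()}) must be "
                    f"1, 2 or 3, got {ch!r} in state {s!r}"
                )
        return cls(*(int(ch) for ch in s))

    def __str__(self) -> str:
        return "".join(str(level) for level in self.levels)

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return (self.mo, self.sc, self.ua, self.pd, self.ad)

    def count(self, level: int) -> int:
        """Number of dimensions at ``level``."""
        return self.levels.count(level)

    @classmethod
    def all_states(cls) -> Iterator["HealthState"]:
        """Iterate over all 243 states in lexicographic order."""
        for levels in product(LEVELS, repeat=5):
            yield cls(*levels)


@dataclass(frozen=True)
class ValueSet3L:
    """A three-level EQ-5D value set: per-dimension decrements plus the
    constant and N3 terms.

    Parameters
    ----------
    decrements
        Mapping from dimension key to a length-3 tuple of decrements for
        levels 1..3.  Level 1 must carry decrement 0 and decrements must
        be non-decreasing in level.
    constant
        Decrement subtracted once per scored state (see
        :func:`utility` for the two conventions on when it applies).
    n3
        Extra decrement applied when any dimension is at level 3.
    n3_absent
        Decrement applied otherwise (normally 0).
    """

    decrements: Mapping[str, tuple[float, float, float]]
    constant: float
    n3: float
    n3_absent: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        missing = set(DIMENSIONS) - set(self.decrements)
        if missing:
            raise ValueError(f"value set missing dimensions: {sorted(missing)}")
        for dim in DIMENSIONS:
            d = tuple(float(v) for v in self.decrements[dim])
            if len(d) != 3:
                raise ValueError(f"dimension {dim!r} needs 3 level decrements")
            if d[0] != 0.0:
                raise ValueError(f"level-1 decrement for {dim!r} must be 0, got {d[0]}")
            if not (0.0 <= d[1] <= d[2]):
                raise ValueError(
                    f"decrements for {dim!r} must satisfy 0 <= level2 <= level3, got {d}"
                )

    def decrement(self, dim: str, level: int) -> float:
        return self.decrements[dim][level - 1]

    def to_csv(self, path) -> None:
        """Write the value set as a delimited term/level/value file."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["term", "level", "value"])
            for dim in DIMENSIONS:
                for level in LEVELS:
                    writer.writerow([dim, level, f"{self.decrement(dim, level):.3f}"])
            writer.writerow(["constant", "", f"{self.constant:.3f}"])
            writer.writerow(["n3", "", f"{self.n3:.3f}"])
            writer.writerow(["n3_absent", "", f"{self.n3_absent:.3f}"])

    @classmethod
    def from_csv(cls, path, name: str = "") -> "ValueSet3L":
        """Read a value set written by :meth:`to_csv`."""
        decrements: dict[str, list[float]] = {dim: [0.0, 0.0, 0.0] for dim in DIMENSIONS}
        scalars: dict[str, float] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                term = row["term"].strip().lower()
                value = float(row["value"])
                if term in DIMENSIONS:
                    decrements[term][int(row["level"]) - 1] = value
                elif term in ("constant", "n3", "n3_absent"):
                    scalars[term] = value
                else:
                    raise ValueError(f"unknown value-set term {term!r}")
        if "constant" not in scalars or "n3" not in scalars:
            raise ValueError("value set file must define 'constant' and 'n3'")
        return cls(
            decrements={dim: tuple(vals) for dim, vals in decrements.items()},
            constant=scalars["constant"],
            n3=scalars["n3"],
            n3_absent=scalars.get("n3_absent", 0.0),
            name=name,
        )


@lru_cache(maxsize=1)
def china_tto_3l() -> ValueSet3L:
    """The Chinese time trade-off value set for the EQ-5D-3L.

    Loaded from the packaged coefficient file ``data/china_tto_3l.csv``.
    """
    path = resources.files("eq5dkit").joinpath("data/china_tto_3l.csv")
    with resources.as_file(path) as fspath:
        return ValueSet3L.from_csv(fspath, name="china_tto_3l")


StateLike = Union[HealthState, str]


def utility(
    state: StateLike,
    value_set: ValueSet3L | None = None,
    *,
    constant_always: bool = True,
) -> float:
    """Utility index of ``state`` under ``value_set``.

    Computed as ``1 - constant - sum(level decrements) - n3_term``.

    Parameters
    ----------
    state
        A :class:`HealthState` or a five-digit string.
    value_set
        Tariff to apply; defaults to :func:`china_tto_3l`.
    constant_always
        If True (default) the constant decrement applies to every state,
        including full health (``11111`` then scores ``1 - constant``).
        If False it applies only when some dimension is above level 1,
        so ``11111`` scores exactly 1.

    Returns
    -------
    float
        The utility value (at most 1; can be negative for severe
        states).  Carried at full float precision; round for reporting.
    """
    s = HealthState.from_string(state)
    vs = value_set if value_set is not None else china_tto_3l()
    levels = s.levels
    total_decrement = sum(vs.decrement(dim, level) for dim, level in zip(DIMENSIONS, levels))
    any_problem = any(level > 1 for level in levels)
    constant = vs.constant if (constant_always or any_problem) else 0.0
    n3_term = vs.n3 if 3 in levels else vs.n3_absent
    return 1.0 - constant - total_decrement - n3_term


def distance_to_full(state: StateLike) -> int:
    """City-block distance between ``state`` and full health ``11111``.

    Equals the sum of the five levels minus 5; ranges over 0..10.
    """
    s = HealthState.from_string(state)
    return sum(s.levels) - 5


def grade(state: StateLike) -> str:
    """Four-level severity grade of a state.

    The rules, applied in order:

    * ``full``     -- distance 0 (the state is ``11111``);
    * ``mild``     -- distance 1..4, no dimension at level 3, and at
      most three dimensions at level 2;
    * ``severe``   -- distance 7..9, no dimension at level 1, and at
      least two dimensions at level 3;
    * ``moderate`` -- everything else.

    The four predicates partition all 243 states.
    """
    s = HealthState.from_string(state)
    dist = distance_to_full(s)
    if dist == 0:
        return "full"
    n1, n2, n3 = s.count(1), s.count(2), s.count(3)
    if 1 <= dist <= 4 and n3 == 0 and n2 <= 3:
        return "mild"
    if 7 <= dist <= 9 and n1 == 0 and n3 >= 2:
        return "severe"
    return "moderate"


@dataclass(frozen=True)
class GradedState:
    """A state together with its distance from full health and grade."""

    state: HealthState
    distance: int
    grade: str


def grade_state(state: StateLike) -> GradedState:
    """Bundle a state with its distance and grade."""
    s = HealthState.from_string(state)
    return GradedState(state=s, distance=distance_to_full(s), grade=grade(s))
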