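"""State space of geographic ranges over tumor sites.

A *range* is the set of tumor sites (biogeographic areas) a clone lineage
occupies.  The state space contains every non-empty subset of sites up to a
maximum size (default two); the empty "null" range is excluded so that every
clone is present in at least its sampling location.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Optional, Sequence


class NullRangeError(ValueError):
    """Raised when the (disallowed) empty range is requested."""


@dataclass(frozen=True)
class Area:
    """A tumor site treated as a biogeographic area.

    Parameters
    ----------
    id : int
        Dense non-negative index of the area within a dataset.
    label : str
        Site name, e.g. ``"P"``, ``"M3"``, ``"breast"``.
    is_primary : bool
        True for the primary tumor site.  Exactly one area per dataset
        carries this flag.
    """

    id: int
    label: str
    is_primary: bool = False


@dataclass(frozen=True, order=True)
class RangeState:
    """A non-empty, sorted tuple of area ids occupied by a lineage."""

    areas: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.areas) == 0:
            raise NullRangeError("the null (empty) range is not part of the state space")
        if tuple(sorted(set(self.areas))) != self.areas:
            raise ValueError(f"areas must be sorted and unique, got {self.areas}")
        if any(a < 0 for a in self.areas):
            raise ValueError("area ids must be non-negative")

    @property
    def size(self) -> int:
        return len(self.areas)

    def __contains__(self, area_id: int) -> bool:
        return area_id in self.areas

    def with_area(self, area_id: int) -> "RangeState":
        """Range expanded by one area."""
        return RangeState(tuple(sorted(set(self.areas) | {area_id})))

    def without_area(self, area_id: int) -> "RangeState":
        """Range contracted by one area (may raise NullRangeError)."""
        return RangeState(tuple(a for a in self.areas if a != area_id))


class RangeSpace:
    """Indexed set of allowed ranges over ``n_areas`` sites.

    States are ordered canonically: all singletons by ascending area id,
    then pairs in lexicographic order, then triples, etc.  This ordering is
    stable so matrix rows/columns and serialized output line up across runs.
    """

    def __init__(
        self,
        n_areas: int,
        max_range_size: int = 2,
        areas: Optional[Sequence[Area]] = None,
    ) -> None:
        if n_areas < 2:
            raise ValueError(f"need at least 2 areas, got {n_areas}")
        if max_range_size < 1:
            raise ValueError("max_range_size must be >= 1")
        if max_range_size > n_areas:
            raise ValueError(
                f"max_range_size ({max_range_size}) cannot exceed n_areas ({n_areas})"
            )
        if areas is not None:
            if len(areas) != n_areas:
                raise ValueError("areas list length must equal n_areas")
            labels = [a.label for a in areas]
            if len(set(labels)) != len(labels):
                raise ValueError("area labels must be unique")
            if sum(a.is_primary for a in areas) != 1:
                raise ValueError("exactly one area must be flagged primary")
        self.n_areas = n_areas
        self.max_range_size = max_range_size
        self.areas: Optional[tuple[Area, ...]] = tuple(areas) if areas is not None else None
        states: list[RangeState] = []
        for size in range(1, max_range_size + 1):
            for combo in combinations(range(n_areas), size):
                states.append(RangeState(combo))
        self.states: tuple[RangeState, ...] = tuple(states)
        self._index: dict[RangeState, int] = {s: k for k, s in enumerate(states)}
        if areas is not None:
            self._label_to_id = {a.label: a.id for a in areas}
        else:
            self._label_to_id = None

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[RangeState]:
        return iter(self.states)

    def __contains__(self, state: RangeState) -> bool:
        return state in self._index

    def index_of(self, state: RangeState) -> int:
        try:
            return self._index[state]
        except KeyError:
            raise KeyError(f"range {state} not in state space") from None

    def state_at(self, k: int) -> RangeState:
        return self.states[k]

    def label_of(self, state: RangeState) -> str:
        """Human-readable label like ``"P+M1"`` (requires areas)."""
        if self.areas is None:
            return "+".join(str(a) for a in state.areas)
        return "+".join(self.areas[a].label for a in state.areas)

    @property
    def primary(self) -> Area:
        if self.areas is None:
            raise ValueError("range space carries no area metadata")
        return next(a for a in self.areas if a.is_primary)


def build_range_space(
    n_areas: int, max_range_size: int = 2, areas: Optional[Sequence[Area]] = None
) -> RangeSpace:
    """Construct the range state space (null range removed, size capped)."""
    return RangeSpace(n_areas, max_range_size=max_range_size, areas=areas)


def state_of(labels: Iterable[str], space: RangeSpace) -> RangeState:
    """Canonical state for a set of site labels.

    Raises :class:`NullRangeError` for the empty set and ``KeyError`` for an
    unknown site label.
    """
    labels = set(labels)
    if not labels:
        raise NullRangeError("empty site set: the null range is disallowed")
    if space._label_to_id is None:
        raise ValueError("range space was built without area labels")
    ids = []
    for lab in labels:
        if lab not in space._label_to_id:
            raise KeyError(f"unknown site label {lab!r}")
        ids.append(space._label_to_id[lab])
    state = RangeState(tuple(sorted(ids)))
    if state not in space:
        raise KeyError(f"site set {sorted(labels)} exceeds max range size {space.max_range_size}")
    return state


def areas_from_labels(labels: Sequence[str], primary_label: str) -> list[Area]:
    """Build an ordered Area list with the primary site first.

    The primary site gets id 0; remaining sites follow in sorted label
    order.  This gives a deterministic area indexing for any dataset.
    """
    labels = list(dict.fromkeys(labels))
    if primary_label not in labels:
        raise ValueError(f"primary label {primary_label!r} not among site labels")
    rest = sorted(l for l in labels if l != primary_label)
    ordered = [primary_label] + rest
    return [Area(i, lab, is_primary=(lab == primary_label)) for i, lab in enumerate(ordered)]
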