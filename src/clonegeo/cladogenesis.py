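"""Cladogenetic (at-node) range inheritance for the six biogeographic models.

At an internal node a parent lineage with range R splits into two daughters.
Which daughter-range pairs are allowed, and with what probability, is what
distinguishes the model families:

* BAYAREALIKE — no range change at nodes: both daughters copy R.
* DEC — a singleton parent is copied; a widespread parent can undergo
  subset sympatry (one daughter keeps R, the other a single area of R) or
  vicariance (R split into two disjoint daughter ranges, one a singleton).
* DIVALIKE — singleton copied; widespread parents split only by vicariance.

The ``+J`` variants add founder-event speciation: one daughter jumps to a
single area *outside* the parent range while the other keeps R.  Each
allowed non-jump ordered event carries weight 1 and each jump event weight
j; weights are normalized per parent, so j acts as the relative propensity
of founder events at nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .range_space import RangeSpace, RangeState

FAMILIES = ("BAYAREALIKE", "DEC", "DIVALIKE")


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus the founder-event (+J) flag."""

    family: str
    founder: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")

    @property
    def name(self) -> str:
        return self.family + ("+J" if self.founder else "")

    @property
    def n_free_params(self) -> int:
        return 2 + (1 if self.founder else 0)


#: The six models fitted in a standard analysis, in canonical order.
ALL_MODELS = tuple(
    ModelSpec(fam, founder) for fam in FAMILIES for founder in (False, True)
)


def model_from_name(name: str) -> ModelSpec:
    base = name[:-2] if name.endswith("+J") else name
    return ModelSpec(base, founder=name.endswith("+J"))


@dataclass(frozen=True)
class CladoParams:
    """Founder-event weight; exactly 0 for models without +J."""

    j: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.j) or self.j < 0:
            raise ValueError(f"founder weight j must be finite and >= 0, got {self.j}")


@dataclass(frozen=True)
class CladoEvent:
    """One ordered daughter-pair event; weight is 1 or j (if is_jump)."""

    left: RangeState
    right: RangeState
    is_jump: bool = False


def enumerate_clado_events(
    parent: RangeState, spec: ModelSpec, space: RangeSpace
) -> list[CladoEvent]:
    """All ordered cladogenetic events allowed for ``parent`` under ``spec``.

    Jump events (founder) are included whenever ``spec.founder`` is true;
    they are flagged so that :func:`build_clado_table` can weight them by j.
    """
    if parent not in space:
        raise KeyError(f"parent range {parent} not in state space")
    events: list[CladoEvent] = []
    if spec.family == "BAYAREALIKE" or parent.size == 1:
        events.append(CladoEvent(parent, parent, False))
    else:
        if spec.family == "DEC":
            # subset sympatry: one daughter keeps the full range, the other
            # a single area of it
            for a in parent.areas:
                single = RangeState((a,))
                events.append(CladoEvent(single, parent, False))
                events.append(CladoEvent(parent, single, False))
        # vicariance: disjoint split of the parent range, smaller daughter a
        # singleton (with max range size 2 this is every disjoint split)
        for a in parent.areas:
            single = RangeState((a,))
            rest = parent.without_area(a)
            if rest in space:
                events.append(CladoEvent(single, rest, False))
    if spec.founder:
        for x in range(space.n_areas):
            if x not in parent:
                single = RangeState((x,))
                events.append(CladoEvent(parent, single, True))
                events.append(CladoEvent(single, parent, True))
    return events


class CladoTable:
    """Per-parent normalized cladogenetic transition table.

    Stored both as per-parent event lists (for inspection and sampling) and
    as flat index arrays (for vectorized pruning).
    """

    def __init__(
        self,
        space: RangeSpace,
        parent_idx: np.ndarray,
        left_idx: np.ndarray,
        right_idx: np.ndarray,
        prob: np.ndarray,
    ) -> None:
        self.space = space
        self.parent_idx = parent_idx
        self.left_idx = left_idx
        self.right_idx = right_idx
        self.prob = prob

    def events_for(self, parent: RangeState) -> list[tuple[RangeState, RangeState, float]]:
        k = self.space.index_of(parent)
        mask = self.parent_idx == k
        return [
            (self.space.state_at(l), self.space.state_at(r), p)
            for l, r, p in zip(self.left_idx[mask], self.right_idx[mask], self.prob[mask])
        ]

    def parent_sums(self) -> np.ndarray:
        return np.bincount(self.parent_idx, weights=self.prob, minlength=len(self.space))


def clado_event_arrays(
    spec: ModelSpec, space: RangeSpace
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flat (parent, left, right, is_jump) arrays over all parents."""
    pi, li, ri, jf = [], [], [], []
    for k, parent in enumerate(space.states):
        for ev in enumerate_clado_events(parent, spec, space):
            pi.append(k)
            li.append(space.index_of(ev.left))
            ri.append(space.index_of(ev.right))
            jf.append(ev.is_jump)
    return (
        np.asarray(pi, dtype=np.intp),
        np.asarray(li, dtype=np.intp),
        np.asarray(ri, dtype=np.intp),
        np.asarray(jf, dtype=bool),
    )


def normalized_probs(
    parent_idx: np.ndarray, is_jump: np.ndarray, j: float, n_states: int
) -> np.ndarray:
    """Event probabilities: weight 1 (non-jump) or j (jump), per-parent normalized."""
    w = np.where(is_jump, j, 1.0)
    sums = np.bincount(parent_idx, weights=w, minlength=n_states)
    return w / sums[parent_idx]


def build_clado_table(spec: ModelSpec, params: CladoParams, space: RangeSpace) -> CladoTable:
    """Normalized cladogenetic table for a model at founder weight j."""
    if params.j > 0 and not spec.founder:
        raise ValueError(f"j={params.j} > 0 is inconsistent with non-founder model {spec.name}")
    parent_idx, left_idx, right_idx, is_jump = clado_event_arrays(spec, space)
    prob = normalized_probs(parent_idx, is_jump, params.j, len(space))
    # drop zero-probability jump rows (j == 0) so the +J table at j=0 is
    # entrywise identical to the base-model table
    keep = prob > 0
    return CladoTable(space, parent_idx[keep], left_idx[keep], right_idx[keep], prob[keep])
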