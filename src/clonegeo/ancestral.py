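"""Ancestral range annotation and migration-path extraction.

Each internal node is annotated with its highest-probability range; tips
keep their observed sampling site (probability 1).  A directed migration
path is emitted on every tree edge whose parent and child annotations
differ, one path per area newly present in the child.  Paths are classified
by the primary-site flag of their endpoints: primary-to-metastasis (P→M),
metastasis-to-metastasis (M→M), and metastasis-to-primary reseeding (M→P).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np

from .inference import CloneTree, FitResult
from .range_space import Area, RangeSpace, RangeState

PATH_CLASSES = ("P->M", "M->M", "M->P")


@dataclass(frozen=True)
class NodeAnnotation:
    node_id: str
    best_state: RangeState
    probability: float
    is_multiple: bool
    tie_flag: bool = False


@dataclass(frozen=True)
class MigrationPath:
    """A directed source→recipient site movement implied by one tree edge.

    ``source`` is the full set of area ids annotated at the parent node
    (a single id in the usual singleton case); ``recipient`` is one area id
    newly occupied at the child.
    """

    source: tuple[int, ...]
    recipient: int
    edge: str  # id of the child node whose stem edge implies the path
    path_class: str

    @property
    def multi_source(self) -> bool:
        return len(self.source) > 1

    def candidate_pairs(self) -> list[tuple[int, int]]:
        return [(s, self.recipient) for s in self.source]


@dataclass
class MigrationGraph:
    """Directed multiset of migration paths over a fixed site set."""

    paths: list[MigrationPath]
    areas: tuple[Area, ...]

    @property
    def primary_id(self) -> int:
        return next(a.id for a in self.areas if a.is_primary)

    def class_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(PATH_CLASSES, 0)
        for p in self.paths:
            counts[p.path_class] += 1
        return counts

    def pair_multiset(self) -> Counter:
        """One site pair per path: the lexicographically first candidate."""
        return Counter(min(p.candidate_pairs()) for p in self.paths)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        labels = {a.id: a.label for a in self.areas}
        for a in self.areas:
            g.add_node(a.label, is_primary=a.is_primary)
        for p in self.paths:
            for s, r in p.candidate_pairs():
                g.add_edge(labels[s], labels[r], path_class=p.path_class, edge=p.edge)
        return g

    def to_dot(self) -> str:
        labels = {a.id: a.label for a in self.areas}
        lines = ["digraph migrations {"]
        for a in self.areas:
            shape = "doublecircle" if a.is_primary else "circle"
            lines.append(f'  "{a.label}" [shape={shape}];')
        for p in self.paths:
            src = "+".join(labels[s] for s in p.source)
            lines.append(
                f'  "{src}" -> "{labels[p.recipient]}" [label="{p.path_class}"];'
            )
        lines.append("}")
        return "\n".join(lines)


def classify_pair(source: int, recipient: int, primary_id: int) -> str:
    if recipient == primary_id:
        return "M->P"
    if source == primary_id:
        return "P->M"
    return "M->M"


def _classify_source_set(source: tuple[int, ...], recipient: int, primary_id: int) -> str:
    # multi-area sources containing the primary are classed P->M; the
    # per-candidate classification used in scoring refines this
    if recipient == primary_id:
        return "M->P"
    if primary_id in source:
        return "P->M"
    return "M->M"


def annotate_nodes(
    fit: FitResult,
    tree: CloneTree,
    locations: Mapping[str, str],
    tie_tol: float = 1e-9,
) -> dict[str, NodeAnnotation]:
    """Highest-probability range per node.

    Internal nodes take the argmax of the fitted marginal range
    probabilities (ties broken by canonical state order and flagged); tips
    keep their observed singleton range with probability 1.
    """
    space = fit.space
    if space.areas is None:
        raise ValueError("range space must carry area metadata")
    label_to_id = {a.label: a.id for a in space.areas}
    out: dict[str, NodeAnnotation] = {}
    for nd in tree.preorder():
        if nd.is_leaf():
            tip = nd.taxon.label
            state = RangeState((label_to_id[locations[tip]],))
            out[nd.node_id] = NodeAnnotation(nd.node_id, state, 1.0, False)
        else:
            if nd.node_id not in fit.node_probs:
                raise KeyError(f"no range probabilities for node {nd.node_id}")
            row = np.asarray(fit.node_probs[nd.node_id])
            k = int(np.argmax(row))
            best = space.state_at(k)
            p = float(row[k])
            tie = bool(np.sum(row >= p - tie_tol * max(p, 1.0)) > 1)
            out[nd.node_id] = NodeAnnotation(nd.node_id, best, p, best.size >= 2, tie)
    return out


def count_multiple_ranges(annotations: Mapping[str, NodeAnnotation]) -> int:
    """Number of internal nodes annotated with a range of two or more sites.

    Tip annotations are observed singletons, so counting over all
    annotations equals counting over internal nodes.
    """
    return sum(1 for a in annotations.values() if a.is_multiple)


def extract_migration_paths(
    annotations: Mapping[str, NodeAnnotation],
    tree: CloneTree,
    areas: Iterable[Area],
) -> MigrationGraph:
    """Derive the migration graph from parent–child annotation changes.

    For each edge whose annotations differ, one path is emitted per area
    present in the child but not the parent annotation; the source is the
    parent's full annotated area set.  Edges with identical annotations
    (including zero-length edges) emit nothing.
    """
    areas = tuple(areas)
    primary_id = next(a.id for a in areas if a.is_primary)
    paths: list[MigrationPath] = []
    for nd in tree.preorder():
        if nd.parent_node is None:
            continue
        parent_ann = annotations[nd.parent_node.node_id]
        child_ann = annotations[nd.node_id]
        parent_set = set(parent_ann.best_state.areas)
        for area_id in child_ann.best_state.areas:
            if area_id in parent_set:
                continue
            source = tuple(sorted(parent_set))
            paths.append(
                MigrationPath(
                    source=source,
                    recipient=area_id,
                    edge=nd.node_id,
                    path_class=_classify_source_set(source, area_id, primary_id),
                )
            )
    return MigrationGraph(paths=paths, areas=areas)


def migration_graph_from_pairs(
    pairs: Iterable[tuple[str, str]], areas: Iterable[Area]
) -> MigrationGraph:
    """Build a migration graph from labeled (source, recipient) site pairs.

    Used for ground-truth graphs and for ingesting externally produced path
    lists.
    """
    areas = tuple(areas)
    label_to_id = {a.label: a.id for a in areas}
    primary_id = next(a.id for a in areas if a.is_primary)
    paths = []
    for i, (s, r) in enumerate(pairs):
        sid, rid = label_to_id[s], label_to_id[r]
        paths.append(
            MigrationPath(
                source=(sid,),
                recipient=rid,
                edge=f"E{i}",
                path_class=classify_pair(sid, rid, primary_id),
            )
        )
    return MigrationGraph(paths=paths, areas=areas)
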