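"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np
import pytest

from clonegeo.anagenesis import AnageneticParams, build_rate_matrix, transition_probabilities
from clonegeo.cladogenesis import CladoParams, ModelSpec, build_clado_table
from clonegeo.inference import CloneTree
from clonegeo.range_space import Area, RangeSpace, areas_from_labels, build_range_space


def random_binary_tree(n_tips: int, rng: np.random.Generator, max_bl: float = 2.0) -> CloneTree:
    """Random rooted binary tree with uniform branch lengths, tips t1..tn.

    Built directly with dendropy (independent of the package's simulators).
    """
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    leaves = [tree.seed_node]
    while len(leaves) < n_tips:
        leaf = leaves.pop(int(rng.integers(len(leaves))))
        leaves.extend([leaf.new_child(), leaf.new_child()])
    for i, leaf in enumerate(leaves, start=1):
        leaf.taxon = taxa.new_taxon(f"t{i}")
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = float(rng.uniform(0.0, max_bl))
    return CloneTree(tree)


def random_dataset(n_tips: int, n_areas: int, rng: np.random.Generator):
    """Random tree + tip locations + areas over sites A, B, C, ..."""
    tree = random_binary_tree(n_tips, rng)
    labels = [chr(ord("A") + i) for i in range(n_areas)]
    areas = areas_from_labels(labels, "A")
    locations = {tip: labels[int(rng.integers(n_areas))] for tip in tree.tip_labels}
    return tree, locations, areas


def brute_force_likelihood(
    tree: CloneTree,
    locations: dict,
    spec: ModelSpec,
    d: float,
    e: float,
    j: float,
    space: RangeSpace,
):
    """Exhaustive-enumeration likelihood and per-node posteriors.

    Sums, over every assignment of a range state to every internal node, the
    product of the uniform root prior, the cladogenetic event probabilities
    (marginalizing the daughter states at the top of each child branch), and
    the branch transition probabilities down to each child's assigned (or
    observed) state.  Completely independent of the pruning recursion.
    """
    S = len(space)
    label_to_id = {a.label: a.id for a in space.areas}
    from clonegeo.range_space import RangeState

    tip_idx = {
        tip: space.index_of(RangeState((label_to_id[site],)))
        for tip, site in locations.items()
    }
    Q = build_rate_matrix(AnageneticParams(d, e), space)
    P = {
        id(nd): transition_probabilities(Q, nd.edge.length or 0.0)
        for nd in tree.preorder()
        if nd.parent_node is not None
    }
    table = build_clado_table(spec, CladoParams(j), space)
    # per-parent event arrays
    ev = {k: [] for k in range(S)}
    for pk, l, r, p in zip(table.parent_idx, table.left_idx, table.right_idx, table.prob):
        ev[int(pk)].append((int(l), int(r), float(p)))
    internal = [nd for nd in tree.preorder() if not nd.is_leaf()]
    # per-node table T[s, bottom_left, bottom_right]: the clado-event sum for
    # a fixed parent state and fixed child bottom states (precomputed once;
    # the enumeration below still sums explicitly over all assignments)
    T = {}
    for nd in internal:
        a, b = nd.child_nodes()
        t = np.zeros((S, S, S))
        for s in range(S):
            for l, r, p in ev[s]:
                t[s] += p * np.outer(P[id(a)][l], P[id(b)][r])
        T[id(nd)] = t
    total = 0.0
    post = {nd.node_id: np.zeros(S) for nd in internal}
    for assign in itertools.product(range(S), repeat=len(internal)):
        amap = {id(nd): s for nd, s in zip(internal, assign)}
        prob = 1.0 / S
        for nd, s in zip(internal, assign):
            a, b = nd.child_nodes()
            bot_a = amap[id(a)] if not a.is_leaf() else tip_idx[a.taxon.label]
            bot_b = amap[id(b)] if not b.is_leaf() else tip_idx[b.taxon.label]
            prob *= T[id(nd)][s, bot_a, bot_b]
            if prob == 0.0:
                break
        total += prob
        for nd, s in zip(internal, assign):
            post[nd.node_id][s] += prob
    lnl = math.log(total) if total > 0 else -math.inf
    if total > 0:
        for k in post:
            post[k] /= total
    return lnl, post


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def two_area_space():
    areas = areas_from_labels(["A", "B"], "A")
    return build_range_space(2, 2, areas)
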