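"""Seeding-scenario generator and model-based simulator properties."""

import itertools
from collections import Counter

import numpy as np
import pytest

from clonegeo.anagenesis import AnageneticParams
from clonegeo.cladogenesis import CladoParams, ModelSpec, build_clado_table
from clonegeo.inference import ModelParams
from clonegeo.range_space import build_range_space
from clonegeo.simulate import (
    CLONE_RANGE,
    SNV_RANGE,
    ScenarioConfig,
    make_benchmark,
    sample_clado_event,
    simulate_dataset,
    simulate_under_model,
)


def truth_pairs(ds):
    labels = {a.id: a.label for a in ds.areas}
    return [(labels[p.source[0]], labels[p.recipient]) for p in ds.truth.paths]


def check_scenario_postconditions(ds):
    cfg = ds.config
    pairs = truth_pairs(ds)
    metas = {a.label for a in ds.areas if not a.is_primary}
    recipients = Counter(r for _, r in pairs)
    assert CLONE_RANGE[0] <= ds.tree.n_tips <= CLONE_RANGE[1]
    assert SNV_RANGE[0] <= cfg.n_snvs <= SNV_RANGE[1]
    assert ds.tree.n_tips == cfg.n_clones
    # every site hosts at least one clone, and truth sites are tip sites
    sites_with_clones = set(ds.locations.values())
    assert sites_with_clones == {a.label for a in ds.areas}
    assert {s for p in pairs for s in p} <= sites_with_clones
    # all metastases are seeded (connected to the primary transitively)
    assert metas <= set(recipients)
    if cfg.scenario == "mS":
        assert all(recipients[m] == 1 for m in metas)
        assert all(s == "P" for s, _ in pairs)
        assert len(pairs) == len(metas)
    elif cfg.scenario == "pS":
        assert all(s == "P" for s, _ in pairs)
        assert all(recipients[m] >= 2 for m in metas)
    elif cfg.scenario == "pM":
        assert len({s for s, _ in pairs}) >= 2
    elif cfg.scenario == "pR":
        assert len({s for s, _ in pairs}) >= 2
        assert recipients.get("P", 0) >= 1  # reseeding into the primary


@pytest.mark.parametrize("scenario", ["mS", "pS", "pM", "pR"])
@pytest.mark.parametrize("n_sites", [5, 8, 11])
def test_scenario_postconditions(scenario, n_sites):
    for seed in range(5):
        ds = simulate_dataset(ScenarioConfig(scenario=scenario, n_sites=n_sites, seed=seed))
        check_scenario_postconditions(ds)


def test_same_seed_reproduces_identical_dataset():
    cfg = ScenarioConfig(scenario="pM", n_sites=6, seed=42)
    a, b = simulate_dataset(cfg), simulate_dataset(cfg)
    assert a.tree.as_newick() == b.tree.as_newick()
    assert a.locations == b.locations
    assert a.genotypes.equals(b.genotypes)
    assert truth_pairs(a) == truth_pairs(b)


def test_infeasible_config_rejected():
    with pytest.raises(ValueError):
        ScenarioConfig(scenario="xx", n_sites=5, seed=0)
    with pytest.raises(ValueError):
        ScenarioConfig(scenario="mS", n_sites=4, seed=0)
    with pytest.raises(ValueError):
        # 10 metastases need >= 11 clones
        simulate_dataset(ScenarioConfig(scenario="mS", n_sites=11, seed=0, n_clones=10))


def test_genotypes_are_homoplasy_free():
    """Infinite-sites columns must be laminar: carrier sets of any two SNVs
    are nested or disjoint, so the matrix admits a perfect phylogeny."""
    for seed in (0, 1):
        ds = simulate_dataset(ScenarioConfig(scenario="pS", n_sites=6, seed=seed))
        g = ds.genotypes.to_numpy()
        carriers = [frozenset(np.flatnonzero(g[:, k])) for k in range(g.shape[1])]
        for a, b in itertools.combinations(carriers, 2):
            assert a <= b or b <= a or not (a & b)


def _fitch_score(tree, genotypes):
    """Fitch parsimony score of a nested-tuple tree; leaves are row labels."""

    def down(node):
        if isinstance(node, str):
            states = genotypes[node]
            return states, 0
        (sa, ca), (sb, cb) = (down(ch) for ch in node)
        inter = sa & sb
        extra = (inter == 0).astype(int)
        return np.where(inter != 0, inter, sa | sb), ca + cb + int(extra.sum())

    _, score = down(tree)
    return score


def _rooted_topologies(leaves):
    """All rooted binary shapes on the leaf list (nested tuples)."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for sub in _rooted_topologies(rest):
        for t in _insert_everywhere(sub, first):
            yield t


def _insert_everywhere(tree, leaf):
    yield (tree, leaf)
    if not isinstance(tree, str):
        a, b = tree
        for t in _insert_everywhere(a, leaf):
            yield (t, b)
        for t in _insert_everywhere(b, leaf):
            yield (a, t)


def _clades(tree, acc):
    if isinstance(tree, str):
        return frozenset([tree])
    c = frozenset().union(*(_clades(ch, acc) for ch in tree))
    acc.add(c)
    return c


def test_parsimony_recovers_generating_topology():
    """Exhaustive MP search over all topologies: the generating tree attains
    the minimum score (= SNV count, no homoplasy) and is among the optima."""
    ds = simulate_dataset(
        ScenarioConfig(scenario="mS", n_sites=5, seed=7, n_clones=7, n_snvs=20)
    )
    g = ds.genotypes.to_numpy()
    # state sets as bitmasks (1 -> {0}, 2 -> {1}); outgroup O carries no mutations
    genotypes = {
        label: (g[i] + 1).astype(int) for i, label in enumerate(ds.genotypes.index)
    }
    genotypes["O"] = np.ones(g.shape[1], dtype=int)

    def true_tuple(nd):
        if nd.is_leaf():
            return nd.taxon.label
        a, b = nd.child_nodes()
        return (true_tuple(a), true_tuple(b))

    true_tree = (true_tuple(ds.tree.root), "O")
    true_score = _fitch_score(true_tree, genotypes)
    assert true_score == ds.config.n_snvs

    true_splits = set()
    _clades(true_tree, true_splits)
    clones = list(ds.genotypes.index)
    best = None
    optimal_split_sets = []
    for shape in _rooted_topologies(clones):
        tree = (shape, "O")
        score = _fitch_score(tree, genotypes)
        if best is None or score < best:
            best, optimal_split_sets = score, []
        if score == best:
            splits = set()
            _clades(tree, splits)
            optimal_split_sets.append(splits)
    assert best == true_score
    assert any(s == true_splits for s in optimal_split_sets)


def test_make_benchmark_design():
    datasets = make_benchmark(1, seed=11)
    assert len(datasets) == 8
    cells = Counter((d.config.m_group, d.config.scenario) for d in datasets)
    assert all(v == 1 for v in cells.values()) and len(cells) == 8
    datasets = make_benchmark(2, seed=11)
    assert len(datasets) == 16
    with pytest.raises(ValueError):
        make_benchmark(0, seed=1)


def test_model_simulation_without_events_keeps_root_area():
    ds = simulate_under_model(
        10, ModelSpec("BAYAREALIKE"),
        ModelParams(AnageneticParams(0.0, 0.0), CladoParams(0.0)), seed=5,
    )
    assert len(set(ds.locations.values())) == 1
    assert len({r for r in ds.tip_ranges.values()}) == 1
    assert ds.truth.paths == []


def test_clado_sampler_matches_table_probabilities():
    """Sampled event frequencies agree with the normalized table within 3
    sigma of the binomial standard error."""
    space = build_range_space(3, 2)
    table = build_clado_table(ModelSpec("DEC", founder=True), CladoParams(1.0), space)
    rng = np.random.default_rng(99)
    parent = space.index_of(space.states[3])  # a widespread pair
    n = 100_000
    counts = Counter(sample_clado_event(table, parent, rng) for _ in range(n))
    mask = table.parent_idx == parent
    for l, r, p in zip(table.left_idx[mask], table.right_idx[mask], table.prob[mask]):
        obs = counts[(int(l), int(r))] / n
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(obs - p) < 3 * sigma + 1e-12
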