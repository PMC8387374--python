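"""Simulated metastatic seeding benchmarks and model-based simulation.

Two generators live here:

* :func:`simulate_dataset` grows a clone phylogeny forward in time under an
  explicit metastatic seeding scenario — monoclonal single-source (mS),
  polyclonal single-source (pS), polyclonal multi-source (pM), or
  polyclonal reseeding (pR) — recording the realized migration events as
  the ground-truth migration graph.  Somatic SNVs are dropped uniformly on
  branches under the infinite-sites model, so genotypes are homoplasy-free
  and admit a perfect phylogeny; branch lengths are SNVs per branch divided
  by the total SNV count (mutations per site as a time proxy).  Dataset
  dimensions emulate the standard benchmark design: 5–7 ("m5") or 8–11
  ("m8") tumor sites, 1–3 migrating clones per seeding event, 7–28 clones,
  and 9–99 SNVs.

* :func:`simulate_under_model` is the generative counterpart of the
  likelihood: ranges evolve by the anagenetic CTMC along branches and by
  sampled cladogenetic events at nodes, for parameter-recovery experiments.

:func:`make_benchmark` assembles the full factorial benchmark: tumor-count
group (m5/m8) × seeding scenario, ``n_per_cell`` datasets per cell (10
reproduces the classic 80-dataset design).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .anagenesis import AnageneticParams, build_rate_matrix
from .ancestral import MigrationGraph, MigrationPath, classify_pair
from .cladogenesis import CladoParams, ModelSpec, build_clado_table
from .inference import CloneTree, ModelParams
from .range_space import Area, RangeSpace, RangeState, build_range_space

SCENARIOS = ("mS", "pS", "pM", "pR")
M_GROUPS = {"m5": (5, 7), "m8": (8, 11)}

CLONE_RANGE = (7, 28)
SNV_RANGE = (9, 99)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulated seeding dataset.

    ``n_clones`` and ``n_snvs`` may be None, in which case they are drawn
    uniformly from the benchmark ranges (subject to feasibility: the tree
    needs at least one split per migration event).
    """

    scenario: str
    n_sites: int
    seed: int
    n_clones: Optional[int] = None
    n_snvs: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if not (5 <= self.n_sites <= 11):
            raise ValueError(f"n_sites must be in [5, 11], got {self.n_sites}")
        if self.n_clones is not None and not (
            CLONE_RANGE[0] <= self.n_clones <= CLONE_RANGE[1]
        ):
            raise ValueError(f"n_clones must be in {CLONE_RANGE}, got {self.n_clones}")
        if self.n_snvs is not None and not (SNV_RANGE[0] <= self.n_snvs <= SNV_RANGE[1]):
            raise ValueError(f"n_snvs must be in {SNV_RANGE}, got {self.n_snvs}")

    @property
    def m_group(self) -> str:
        return "m5" if self.n_sites <= 7 else "m8"


@dataclass
class SimulatedDataset:
    tree: CloneTree
    locations: dict[str, str]
    genotypes: Optional[pd.DataFrame]  # clones x SNVs binary matrix
    truth: MigrationGraph
    config: Optional[ScenarioConfig]
    areas: tuple[Area, ...]
    #: realized tip range per tip (site labels); for model-based simulations a
    #: tip's range can span two sites even though one location is reported
    tip_ranges: Optional[dict[str, tuple[str, ...]]] = None

    @property
    def site_labels(self) -> list[str]:
        return [a.label for a in self.areas]


def _site_areas(n_sites: int) -> list[Area]:
    labels = ["P"] + [f"M{i}" for i in range(1, n_sites)]
    return [Area(i, lab, is_primary=(i == 0)) for i, lab in enumerate(labels)]


def _seeding_events(config: ScenarioConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Ordered (source_site, recipient_site) migration events for a scenario.

    Colonization order is a random permutation of the metastases; every
    event's source is already colonized at the time of the event, so the
    truth graph always connects the primary to every metastasis.
    """
    metas = [f"M{i}" for i in range(1, config.n_sites)]
    order = list(rng.permutation(metas))
    events: list[tuple[str, str]] = []
    colonized = ["P"]
    if config.scenario == "mS":
        for m in order:
            events.append(("P", m))
            colonized.append(m)
    elif config.scenario == "pS":
        for m in order:
            for _ in range(int(rng.integers(2, 4))):
                events.append(("P", m))
            colonized.append(m)
    else:  # pM / pR: sources drawn among already-colonized sites
        for m in order:
            k = int(rng.integers(2, 4))
            for _ in range(k):
                events.append((str(rng.choice(colonized)), m))
            colonized.append(m)
        if not any(s != "P" for s, _ in events):
            # force the multi-source property: reroute one seeding clone of
            # the last-colonized metastasis through an earlier metastasis
            last = order[-1]
            src = order[0] if len(order) > 1 else "P"
            idx = max(i for i, (_, r) in enumerate(events) if r == last)
            events[idx] = (src, last)
        if config.scenario == "pR":
            # reseeding: extra edges into already-colonized sites, always
            # including at least one back into the primary
            reseeds = [("P", True)] + (
                [(str(rng.choice(colonized[1:])), False)] if rng.random() < 0.5 else []
            )
            for recipient, _ in reseeds:
                src = str(rng.choice([c for c in colonized if c != recipient]))
                events.append((src, recipient))
    return events


def _cap_events(events: list[tuple[str, str]], max_splits: int, rng: np.random.Generator,
                scenario: str) -> list[tuple[str, str]]:
    """Drop surplus polyclonal seeding clones if the clone budget is tight.

    Each recipient keeps at least two seeding clones (polyclonality) where
    possible; monoclonal and reseeding edges are never dropped.
    """
    if len(events) <= max_splits or scenario == "mS":
        return events
    from collections import Counter

    counts = Counter(r for _, r in events)
    kept = list(events)
    i = len(kept) - 1
    while len(kept) > max_splits and i >= 0:
        _, r = kept[i]
        if counts[r] > 2:
            counts[r] -= 1
            kept.pop(i)
        i -= 1
    return kept


def simulate_dataset(config: ScenarioConfig) -> SimulatedDataset:
    """Generate one seeding-scenario dataset with known true migration graph."""
    rng = np.random.default_rng(config.seed)
    areas = tuple(_site_areas(config.n_sites))
    events = _seeding_events(config, rng)

    if config.n_clones is None:
        lo = max(CLONE_RANGE[0], len(events) + 1)
        if lo > CLONE_RANGE[1]:
            events = _cap_events(events, CLONE_RANGE[1] - 1, rng, config.scenario)
            lo = max(CLONE_RANGE[0], len(events) + 1)
        n_clones = int(rng.integers(lo, CLONE_RANGE[1] + 1))
    else:
        n_clones = config.n_clones
        if len(events) + 1 > n_clones:
            events = _cap_events(events, n_clones - 1, rng, config.scenario)
        if len(events) + 1 > n_clones:
            raise ValueError(
                f"infeasible config: {len(events)} migration events need at least "
                f"{len(events) + 1} clones, got {n_clones}"
            )
    n_snvs = (
        int(rng.integers(SNV_RANGE[0], SNV_RANGE[1] + 1))
        if config.n_snvs is None
        else config.n_snvs
    )

    # interleave within-site divergences among the migration events
    n_within = n_clones - 1 - len(events)
    ops: list[Optional[tuple[str, str]]] = list(events)
    for pos in rng.integers(0, np.arange(len(ops), len(ops) + n_within) + 1):
        ops.insert(int(pos), None)

    # grow the tree: active lineages are leaves carrying a site attribute
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.site = "P"
    leaves_by_site: dict[str, list] = {"P": [tree.seed_node]}

    migrant_nodes: list = []

    def split(leaf, site_a: str, site_b: str):
        leaves_by_site[leaf.site].remove(leaf)
        del leaf.site
        ca = leaf.new_child()
        cb = leaf.new_child()
        ca.site, cb.site = site_a, site_b
        leaves_by_site.setdefault(site_a, []).append(ca)
        leaves_by_site.setdefault(site_b, []).append(cb)
        return ca, cb

    for op in ops:
        if op is None:  # within-site divergence of a random lineage
            sites = [s for s, ls in leaves_by_site.items() if ls]
            weights = np.array([len(leaves_by_site[s]) for s in sites], dtype=float)
            site = str(rng.choice(sites, p=weights / weights.sum()))
            leaf = leaves_by_site[site][int(rng.integers(len(leaves_by_site[site])))]
            split(leaf, site, site)
        else:  # migration: one daughter stays, the other seeds the recipient
            src, dst = op
            leaf = leaves_by_site[src][int(rng.integers(len(leaves_by_site[src])))]
            _, migrant = split(leaf, src, dst)
            migrant_nodes.append(migrant)

    # label tips and record locations
    locations: dict[str, str] = {}
    leaves = list(tree.leaf_node_iter())
    for i, leaf in enumerate(leaves, start=1):
        name = f"C{i}"
        leaf.taxon = taxa.new_taxon(name)
        locations[name] = leaf.site

    # infinite-sites SNVs: a migrating (founding) clone is a genotypically
    # distinct clone, so each migration branch carries at least one private
    # SNV; the remaining variants arise once each on a uniformly chosen
    # branch.  Branch length = SNVs on branch / total SNVs.
    edges = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    n_snvs = max(n_snvs, len(migrant_nodes))
    migrant_edge_idx = [edges.index(nd) for nd in migrant_nodes]
    snv_edge = np.concatenate(
        [
            np.asarray(migrant_edge_idx, dtype=np.int64),
            rng.integers(0, len(edges), size=n_snvs - len(migrant_edge_idx)),
        ]
    )
    for k, nd in enumerate(edges):
        nd.edge.length = float(np.sum(snv_edge == k)) / n_snvs
    genotype = np.zeros((len(leaves), n_snvs), dtype=np.int8)
    for i, leaf in enumerate(leaves):
        nd = leaf
        while nd.parent_node is not None:
            genotype[i, snv_edge == edges.index(nd)] = 1
            nd = nd.parent_node
    genotypes = pd.DataFrame(
        genotype,
        index=[lf.taxon.label for lf in leaves],
        columns=[f"snv{k + 1}" for k in range(n_snvs)],
    )

    label_to_id = {a.label: a.id for a in areas}
    truth_paths = [
        MigrationPath(
            source=(label_to_id[s],),
            recipient=label_to_id[r],
            edge=f"T{i}",
            path_class=classify_pair(label_to_id[s], label_to_id[r], 0),
        )
        for i, (s, r) in enumerate(events)
    ]
    cfg = ScenarioConfig(
        scenario=config.scenario,
        n_sites=config.n_sites,
        seed=config.seed,
        n_clones=n_clones,
        n_snvs=n_snvs,
    )
    return SimulatedDataset(
        tree=CloneTree(tree),
        locations=locations,
        genotypes=genotypes,
        truth=MigrationGraph(paths=truth_paths, areas=areas),
        config=cfg,
        areas=areas,
    )


def make_benchmark(n_per_cell: int, seed: int) -> list[SimulatedDataset]:
    """Factorial benchmark: (m5, m8) x (mS, pS, pM, pR), n_per_cell each."""
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    ss = np.random.SeedSequence(seed)
    datasets = []
    for m_group, (lo, hi) in M_GROUPS.items():
        for scenario in SCENARIOS:
            for rep in range(n_per_cell):
                child = ss.spawn(1)[0]
                rng = np.random.default_rng(child)
                n_sites = int(rng.integers(lo, hi + 1))
                sub_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
                datasets.append(
                    simulate_dataset(
                        ScenarioConfig(scenario=scenario, n_sites=n_sites, seed=sub_seed)
                    )
                )
    return datasets


def _random_topology(n_tips: int, rng: np.random.Generator, mean_branch_length: float):
    """Yule-style topology: split a uniformly chosen lineage until n_tips."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    leaves = [tree.seed_node]
    while len(leaves) < n_tips:
        leaf = leaves.pop(int(rng.integers(len(leaves))))
        leaves.extend([leaf.new_child(), leaf.new_child()])
    for i, leaf in enumerate(leaves, start=1):
        leaf.taxon = taxa.new_taxon(f"C{i}")
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = float(rng.exponential(mean_branch_length))
    return tree


def sample_clado_event(table, state_idx: int, rng: np.random.Generator) -> tuple[int, int]:
    """Draw one (left, right) daughter-state pair from a cladogenetic table."""
    cache = getattr(table, "_sampling_cache", None)
    if cache is None:
        cache = {}
        table._sampling_cache = cache
    if state_idx not in cache:
        mask = table.parent_idx == state_idx
        probs = table.prob[mask]
        cache[state_idx] = (
            table.left_idx[mask],
            table.right_idx[mask],
            probs / probs.sum(),
        )
    left, right, probs = cache[state_idx]
    k = int(rng.choice(len(probs), p=probs))
    return int(left[k]), int(right[k])


def _evolve_branch(
    state_idx: int, t: float, Q: np.ndarray, rng: np.random.Generator
) -> int:
    """Gillespie simulation of the anagenetic CTMC for time t."""
    k = state_idx
    remaining = t
    while True:
        rate = -Q[k, k]
        if rate <= 0:
            return k
        wait = rng.exponential(1.0 / rate)
        if wait > remaining:
            return k
        remaining -= wait
        probs = np.clip(Q[k].copy(), 0, None)
        probs[k] = 0.0
        probs /= probs.sum()
        k = int(rng.choice(len(probs), p=probs))


def simulate_under_model(
    n_tips: int,
    spec: ModelSpec,
    params: ModelParams,
    seed: int,
    n_areas: int = 4,
    mean_branch_length: float = 1.5,
    max_range_size: int = 2,
) -> SimulatedDataset:
    """Simulate ranges on a random tree under a biogeographic model.

    The root range is drawn from the uniform prior, cladogenetic events are
    sampled from the model's normalized table, and along-branch evolution
    follows the dispersal–extinction CTMC.  Each tip's observed location is
    a uniformly sampled single site from its realized range, matching how
    clones are observed at one sampling site.  Realized range gains are
    recorded as the truth migration graph (source = full pre-gain range).
    """
    rng = np.random.default_rng(seed)
    areas = tuple(_site_areas(n_areas))
    space = build_range_space(n_areas, max_range_size, areas)
    Q = build_rate_matrix(params.anagenetic, space).Q
    table = build_clado_table(spec, params.clado, space)
    tree = _random_topology(n_tips, rng, mean_branch_length)

    events: list[tuple[tuple[int, ...], int]] = []

    def record_gains(before: RangeState, after: RangeState) -> None:
        gained = set(after.areas) - set(before.areas)
        for g in gained:
            events.append((before.areas, g))

    # per-parent sampling structure
    root_state = int(rng.integers(len(space)))
    tree.seed_node.state_idx = root_state
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        s_idx = nd.state_idx
        tops = sample_clado_event(table, s_idx, rng)
        parent_state = space.state_at(s_idx)
        for child, top in zip(nd.child_nodes(), tops):
            record_gains(parent_state, space.state_at(top))
            bottom = _evolve_branch(top, child.edge.length, Q, rng)
            # track along-branch expansions for the truth graph
            if bottom != top:
                record_gains(space.state_at(top), space.state_at(bottom))
            child.state_idx = bottom

    locations: dict[str, str] = {}
    tip_ranges: dict[str, tuple[str, ...]] = {}
    for leaf in tree.leaf_node_iter():
        st = space.state_at(leaf.state_idx)
        site_id = int(rng.choice(st.areas))
        locations[leaf.taxon.label] = areas[site_id].label
        tip_ranges[leaf.taxon.label] = tuple(areas[a].label for a in st.areas)

    truth_paths = [
        MigrationPath(
            source=src,
            recipient=rec,
            edge=f"T{i}",
            path_class=classify_pair(src[0], rec, 0),
        )
        for i, (src, rec) in enumerate(events)
    ]
    return SimulatedDataset(
        tree=CloneTree(tree),
        locations=locations,
        genotypes=None,
        truth=MigrationGraph(paths=truth_paths, areas=areas),
        config=None,
        areas=areas,
        tip_ranges=tip_ranges,
    )
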