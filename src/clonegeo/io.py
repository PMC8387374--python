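"""Readers, writers, clone pre-processing, and the pipeline driver.

On-disk formats: Newick trees, a PHYLIP-style geography presence matrix,
TSV tables (locations, genotypes, paths, fit results), DOT migration
diagrams, and JSON manifests / node probabilities.  Clones sampled in more
than one tumor site are pre-split into per-site tips attached by
zero-length branches before analysis, so every analyzed tip occupies
exactly one site.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .ancestral import (
    MigrationGraph,
    annotate_nodes,
    count_multiple_ranges,
    extract_migration_paths,
    migration_graph_from_pairs,
)
from .cladogenesis import ALL_MODELS, ModelSpec, model_from_name
from .evaluation import classify_counts, score_paths
from .inference import (
    CloneTree,
    FitResult,
    fit_model,
    likelihood_ratio_test,
    model_selection_table,
)
from .range_space import Area, areas_from_labels, build_range_space


class FormatError(ValueError):
    """Raised for unparseable or inconsistent input files."""


def read_tree(path) -> CloneTree:
    """Read a rooted Newick clone tree; zero-length tips flag ancestral clones."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick", rooting="force-rooted")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse Newick file {path}: {exc}") from exc
    return CloneTree(tree)


def write_tree(tree: CloneTree, path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


def read_locations(path) -> dict[str, set[str]]:
    """Read a clone→site TSV (columns: clone, site; repeated clones allowed).

    Returns each clone's full site set; clones in several sites are split
    downstream by :func:`split_multisite_clones`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "clone" not in cols or "site" not in cols:
        raise FormatError(f"{path}: expected columns 'clone' and 'site', got {list(df.columns)}")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        site = row[cols["site"]]
        if pd.isna(site) or site == "":
            raise FormatError(f"{path}: clone {row[cols['clone']]!r} has an empty site")
        out.setdefault(row[cols["clone"]], set()).add(site)
    return out


def write_locations(locations: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"clone": list(locations), "site": [locations[c] for c in locations]}
    ).to_csv(path, sep="\t", index=False)


def split_multisite_clones(
    tree: CloneTree, site_sets: Mapping[str, set[str]]
) -> tuple[CloneTree, dict[str, str]]:
    """Pre-split clones observed in several sites into per-site tips.

    A clone found in k > 1 sites is replaced by k tips named
    ``"<clone>@<site>"`` hanging from zero-length branches (a pectinate
    zero-length resolution keeps the tree binary); the likelihood is
    unchanged by the resolution order because P(0) = I.  Returns the new
    tree and the flat tip→site map.
    """
    for tip in tree.tip_labels:
        if tip not in site_sets:
            raise FormatError(f"tip {tip!r} missing from the locations table")
        if not site_sets[tip]:
            raise FormatError(f"tip {tip!r} has an empty site set (null range disallowed)")
    if all(len(s) == 1 for s in site_sets.values()):
        return tree, {c: next(iter(s)) for c, s in site_sets.items() if c in set(tree.tip_labels)}
    dtree = tree.tree.clone(depth=1)
    taxa = dtree.taxon_namespace
    flat: dict[str, str] = {}
    for leaf in list(dtree.leaf_node_iter()):
        clone = leaf.taxon.label
        sites = sorted(site_sets[clone])
        if len(sites) == 1:
            flat[clone] = sites[0]
            continue
        leaf.taxon = None
        attach = leaf
        for i, site in enumerate(sites):
            name = f"{clone}@{site}"
            flat[name] = site
            if i < len(sites) - 1:
                child = attach.new_child(edge_length=0.0)
                child.taxon = taxa.new_taxon(name)
                if i < len(sites) - 2:
                    attach = attach.new_child(edge_length=0.0)
            else:
                child = attach.new_child(edge_length=0.0)
                child.taxon = taxa.new_taxon(name)
    return CloneTree(dtree), flat


def write_geography(locations: Mapping[str, str], areas: Sequence[Area], path) -> None:
    """PHYLIP-style presence matrix: header ``n m (labels)``, 0/1 rows."""
    labels = [a.label for a in areas]
    lines = [f"{len(locations)}\t{len(areas)}\t({' '.join(labels)})"]
    for clone, site in locations.items():
        row = "".join("1" if lab == site else "0" for lab in labels)
        lines.append(f"{clone}\t{row}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_geography(path) -> tuple[list[str], dict[str, set[str]]]:
    """Read a presence matrix; returns (area labels, clone→site-set map)."""
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    header = lines[0].split("\t")
    if len(header) < 3 or "(" not in header[2]:
        raise FormatError(f"{path}: malformed geography header {lines[0]!r}")
    labels = header[2].strip("()").split()
    n_taxa, n_areas = int(header[0]), int(header[1])
    if n_areas != len(labels):
        raise FormatError(f"{path}: header says {n_areas} areas but lists {len(labels)} labels")
    out: dict[str, set[str]] = {}
    for line in lines[1:]:
        name, row = line.split("\t")
        if len(row) != n_areas or set(row) - {"0", "1"}:
            raise FormatError(f"{path}: bad presence row {line!r}")
        sites = {labels[i] for i, ch in enumerate(row) if ch == "1"}
        if not sites:
            raise FormatError(f"{path}: clone {name!r} present nowhere (null range)")
        out[name] = sites
    if len(out) != n_taxa:
        raise FormatError(f"{path}: header says {n_taxa} taxa but found {len(out)}")
    return labels, out


def write_paths(graph: MigrationGraph, path) -> None:
    labels = {a.id: a.label for a in graph.areas}
    rows = [
        {
            "source": "+".join(labels[s] for s in p.source),
            "recipient": labels[p.recipient],
            "class": p.path_class,
            "edge": p.edge,
        }
        for p in graph.paths
    ]
    pd.DataFrame(rows, columns=["source", "recipient", "class", "edge"]).to_csv(
        path, sep="\t", index=False
    )


def read_path_pairs(path) -> list[tuple[str, str]]:
    """Read (source, recipient) pairs from a paths TSV (e.g. a truth file).

    Multi-area sources (``"A+B"``) are not allowed in truth files.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "source" not in cols or "recipient" not in cols:
        raise FormatError(f"{path}: expected columns 'source' and 'recipient'")
    return [(r[cols["source"]], r[cols["recipient"]]) for _, r in df.iterrows()]


def write_node_probs(fit: FitResult, path) -> None:
    payload = {
        "model": fit.model_name,
        "states": [fit.space.label_of(s) for s in fit.space.states],
        "node_probs": {k: list(map(float, v)) for k, v in fit.node_probs.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class RunConfig:
    """Pipeline configuration with the analysis defaults."""

    models: tuple[str, ...] = tuple(m.name for m in ALL_MODELS)
    max_range_size: int = 2
    lrt_alpha: float = 0.05
    scoring_mode: str = "unique-pairs"
    primary_label: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one model must be requested")
        if not (0.0 < self.lrt_alpha < 1.0):
            raise ValueError(f"lrt_alpha must be in (0, 1), got {self.lrt_alpha}")
        for m in self.models:
            model_from_name(m)  # validates

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_CLASS_PREFIX = {"P->M": "PM", "M->M": "MM", "M->P": "MP"}


def run_benchmark(datasets, specs=None, scoring_mode: str = "unique-pairs") -> pd.DataFrame:
    """Fit, annotate, extract paths, and score every dataset under each model.

    Returns one row per (dataset, model) with fit statistics, F1 scoring
    against the dataset's truth graph, per-class path counts, and (on
    base-model rows) the LRT p-value against the +J counterpart — the input
    expected by :func:`clonegeo.evaluation.aggregate_benchmark`.
    """
    if specs is None:
        specs = ALL_MODELS
    rows = []
    for idx, ds in enumerate(datasets):
        space = build_range_space(len(ds.areas), 2, ds.areas)
        fits = {s.name: fit_model(ds.tree, ds.locations, s, space=space) for s in specs}
        lrt_p = {}
        for fam in ("BAYAREALIKE", "DEC", "DIVALIKE"):
            if fam in fits and fam + "+J" in fits:
                lrt_p[fam] = likelihood_ratio_test(fits[fam], fits[fam + "+J"]).p_value
        for name, fit in fits.items():
            ann = annotate_nodes(fit, ds.tree, ds.locations)
            graph = extract_migration_paths(ann, ds.tree, ds.areas)
            res = score_paths(graph, ds.truth, mode=scoring_mode)
            cls = classify_counts(graph, ds.truth)
            row = {
                "dataset": f"ds{idx:03d}",
                "model": name,
                "family": fit.spec.family,
                "founder": fit.spec.founder,
                "m_group": ds.config.m_group if ds.config else None,
                "scenario": ds.config.scenario if ds.config else None,
                "n_sites": len(ds.areas),
                "n_clones": ds.tree.n_tips,
                "lnL": fit.lnL,
                "AICc": fit.AICc,
                "BIC": fit.BIC,
                "TP": res.TP,
                "FP": res.FP,
                "FN": res.FN,
                "precision": res.precision,
                "recall": res.recall,
                "f1": res.f1,
                "multiple_ranges": count_multiple_ranges(ann),
                "lrt_p_value": lrt_p.get(name, float("nan")),
            }
            for cl, counts in cls.items():
                for kind, v in counts.items():
                    row[f"{_CLASS_PREFIX[cl]}_{kind}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    tree_path,
    locations_path,
    out_dir,
    truth_path=None,
) -> dict[str, object]:
    """Fit models, annotate nodes, extract paths, optionally evaluate.

    Writes per-model node probabilities and migration paths, a model
    selection table, an LRT table, and (when a truth path list is given) an
    evaluation TSV.  Output is a pure function of (inputs, config).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = read_tree(tree_path)
    site_sets = read_locations(locations_path)
    tree, locations = split_multisite_clones(tree, site_sets)
    labels = sorted({s for ss in site_sets.values() for s in ss})
    primary = config.primary_label or labels[0]
    areas = areas_from_labels(labels, primary)
    space = build_range_space(len(areas), config.max_range_size, areas)

    fits: dict[str, FitResult] = {}
    graphs: dict[str, MigrationGraph] = {}
    multi_counts: dict[str, int] = {}
    for name in config.models:
        spec = model_from_name(name)
        fit = fit_model(tree, locations, spec, space=space)
        fits[name] = fit
        ann = annotate_nodes(fit, tree, locations)
        multi_counts[name] = count_multiple_ranges(ann)
        graph = extract_migration_paths(ann, tree, areas)
        graphs[name] = graph
        safe = name.replace("+", "p")
        write_node_probs(fit, out / f"node_probs_{safe}.json")
        write_paths(graph, out / f"paths_{safe}.tsv")
        (out / f"migrations_{safe}.dot").write_text(graph.to_dot())

    sel = model_selection_table(list(fits.values()))
    sel["multiple_ranges"] = sel["model"].map(multi_counts)
    sel.to_csv(out / "model_selection.tsv", sep="\t", index=False)

    lrt_rows = []
    for fam in ("BAYAREALIKE", "DEC", "DIVALIKE"):
        base, alt = fam, fam + "+J"
        if base in fits and alt in fits:
            r = likelihood_ratio_test(fits[base], fits[alt])
            lrt_rows.append(
                {"family": fam, "stat": r.stat, "df": r.df, "p_value": r.p_value,
                 "delta_bic": r.delta_bic, "reject": r.p_value < config.lrt_alpha}
            )
    lrt_df = pd.DataFrame(lrt_rows)
    lrt_df.to_csv(out / "lrt.tsv", sep="\t", index=False)

    eval_df = None
    if truth_path is not None:
        truth = migration_graph_from_pairs(read_path_pairs(truth_path), areas)
        eval_rows = []
        for name, graph in graphs.items():
            res = score_paths(graph, truth, mode=config.scoring_mode)
            eval_rows.append(
                {"model": name, "TP": res.TP, "FP": res.FP, "FN": res.FN,
                 "precision": res.precision, "recall": res.recall, "f1": res.f1}
            )
        eval_df = pd.DataFrame(eval_rows)
        eval_df.to_csv(out / "evaluation.tsv", sep="\t", index=False)

    log = {
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in config.__dict__.items()},
        "config_hash": config.digest(),
        "n_tips": tree.n_tips,
        "sites": labels,
        "primary": primary,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return {"fits": fits, "graphs": graphs, "selection": sel, "lrt": lrt_df,
            "evaluation": eval_df, "multiple_ranges": multi_counts}
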