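"""Likelihood computation, ML fitting, and model comparison on clone trees.

The likelihood of tip tumor-site observations under a biogeographic model
is computed by Felsenstein pruning: tip conditionals are indicators of the
observed singleton range, anagenetic change along branches is propagated
through P(t) = exp(Qt), daughters are combined at internal nodes through
the model's cladogenetic table, and the root is integrated against a
uniform prior over range states.  Branch lengths are mutations per site,
used as a proxy for time ("ultrametric-like" trees); tips attached by
zero-length branches represent ancestral (unsampled-diversification)
clones and need no special handling because P(0) = I.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .anagenesis import AnageneticParams, BranchPropagator, build_rate_matrix
from .cladogenesis import (
    CladoParams,
    ModelSpec,
    clado_event_arrays,
    normalized_probs,
)
from .range_space import Area, RangeSpace, RangeState, areas_from_labels, build_range_space

__all__ = [
    "CloneTree",
    "ModelParams",
    "FitResult",
    "LrtResult",
    "log_likelihood",
    "fit_model",
    "fit_all_models",
    "likelihood_ratio_test",
    "model_selection_table",
    "information_criteria",
]

D_E_BOUNDS = (1e-9, 5.0)
J_BOUNDS = (1e-6, 10.0)
# deterministic multi-start grid (d, e) and j starts for +J models
START_GRID_2 = ((0.01, 0.01), (0.1, 0.1), (1.0, 0.01), (0.01, 1.0))
START_GRID_3 = ((0.01, 0.01, 0.01), (0.1, 0.1, 1.0), (1.0, 0.01, 1.0), (0.01, 1.0, 0.01))


class NonBinaryTreeError(ValueError):
    """Raised when an internal node does not have exactly two children."""


class CloneTree:
    """A rooted binary clone phylogeny with branch lengths.

    Thin wrapper around a :class:`dendropy.Tree` that validates the shape
    required for pruning (every internal node binary, non-negative branch
    lengths), collapses degree-2 pass-through nodes by branch-length
    addition, assigns stable node ids (tip label for tips, ``"N<k>"`` in
    preorder for internal nodes), and flags tips on zero-length branches as
    ancestral clones.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        self.tree = tree
        n_internal = 0
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("every tip must be labeled")
                nd.node_id = nd.taxon.label
            else:
                if len(nd.child_nodes()) != 2:
                    raise NonBinaryTreeError(
                        f"internal node with {len(nd.child_nodes())} children; "
                        "resolve polytomies before analysis"
                    )
                nd.node_id = f"N{n_internal}"
                n_internal += 1
            if nd.parent_node is not None:
                bl = nd.edge.length
                if bl is None:
                    raise ValueError(f"missing branch length above node {nd.node_id}")
                if bl < 0:
                    raise ValueError(f"negative branch length {bl} above node {nd.node_id}")

    @classmethod
    def from_newick(cls, newick: str) -> "CloneTree":
        tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        return cls(tree)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def zero_length_tips(self) -> list[str]:
        """Tips attached by zero-length branches (ancestral clones)."""
        return [
            lf.taxon.label
            for lf in self.tree.leaf_node_iter()
            if (lf.edge.length or 0.0) == 0.0
        ]

    def postorder(self):
        return self.tree.postorder_node_iter()

    def preorder(self):
        return self.tree.preorder_node_iter()

    @property
    def root(self):
        return self.tree.seed_node

    def internal_node_ids(self) -> list[str]:
        return [nd.node_id for nd in self.preorder() if not nd.is_leaf()]


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set (d, e, j) for a model."""

    anagenetic: AnageneticParams
    clado: CladoParams = field(default_factory=CladoParams)

    @property
    def d(self) -> float:
        return self.anagenetic.d

    @property
    def e(self) -> float:
        return self.anagenetic.e

    @property
    def j(self) -> float:
        return self.clado.j


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one dataset."""

    spec: ModelSpec
    params_hat: ModelParams
    lnL: float
    k: int
    n_obs: int
    AIC: float
    AICc: float
    BIC: float
    node_probs: dict[str, np.ndarray]
    converged: bool
    space: RangeSpace

    @property
    def model_name(self) -> str:
        return self.spec.name


@dataclass
class LrtResult:
    stat: float
    df: int
    p_value: float
    delta_bic: float


def information_criteria(lnL: float, k: int, n_obs: int) -> tuple[float, float, float]:
    """AIC, small-sample corrected AICc, and BIC."""
    aic = 2 * k - 2 * lnL
    denom = n_obs - k - 1
    aicc = aic + (2 * k * (k + 1)) / denom if denom > 0 else math.inf
    bic = k * math.log(n_obs) - 2 * lnL
    return aic, aicc, bic


def resolve_areas(
    locations: Mapping[str, str],
    areas: Optional[Sequence[Area]] = None,
    primary_label: Optional[str] = None,
) -> list[Area]:
    """Area list for a dataset; defaults to sites seen in the location map.

    Without an explicit primary label the lexicographically first site is
    flagged primary (the flag only matters for path classification, not for
    the likelihood).
    """
    if areas is not None:
        return list(areas)
    labels = sorted(set(locations.values()))
    if primary_label is None:
        primary_label = labels[0]
    return areas_from_labels(labels, primary_label)


class PruningEngine:
    """Reusable pruning state for one (tree, locations, model family) triple.

    Precomputes the postorder traversal, tip state indices, and the flat
    cladogenetic event arrays so that repeated likelihood evaluations during
    optimization only rebuild Q, the branch propagator, and the per-event
    probabilities.
    """

    def __init__(
        self,
        tree: CloneTree,
        locations: Mapping[str, str],
        spec: ModelSpec,
        space: RangeSpace,
    ) -> None:
        if space.areas is None:
            raise ValueError("range space must carry area metadata")
        self.tree = tree
        self.spec = spec
        self.space = space
        label_to_id = {a.label: a.id for a in space.areas}
        self.tip_state_idx: dict[str, int] = {}
        for tip in tree.tip_labels:
            if tip not in locations:
                raise KeyError(f"tip {tip!r} has no tumor-site assignment")
            site = locations[tip]
            if site not in label_to_id:
                raise KeyError(f"unknown site {site!r} for tip {tip!r}")
            self.tip_state_idx[tip] = space.index_of(RangeState((label_to_id[site],)))
        self.parent_idx, self.left_idx, self.right_idx, self.is_jump = clado_event_arrays(
            spec, space
        )
        self.nodes = list(tree.postorder())
        self.n_states = len(space)

    def _clado_probs(self, j: float) -> np.ndarray:
        return normalized_probs(self.parent_idx, self.is_jump, j, self.n_states)

    def _passes(self, d: float, e: float, j: float):
        """Down (conditional) pass; returns per-node arrays and log-likelihood."""
        S = self.n_states
        prob = self._clado_probs(j)
        propagate = BranchPropagator(build_rate_matrix(AnageneticParams(d, e), self.space))
        C: dict[int, np.ndarray] = {}  # node conditional (post-clado), scaled
        D: dict[int, np.ndarray] = {}  # child conditional propagated to branch top
        P: dict[int, np.ndarray] = {}  # branch transition matrix per child node
        log_scale = 0.0
        for nd in self.nodes:
            if nd.is_leaf():
                c = np.zeros(S)
                c[self.tip_state_idx[nd.taxon.label]] = 1.0
            else:
                a, b = nd.child_nodes()
                for ch in (a, b):
                    P[id(ch)] = propagate(ch.edge.length or 0.0)
                    D[id(ch)] = P[id(ch)] @ C[id(ch)]
                c = np.bincount(
                    self.parent_idx,
                    weights=prob * D[id(a)][self.left_idx] * D[id(b)][self.right_idx],
                    minlength=S,
                )
            s = c.sum()
            if s <= 0:
                return None, None, None, -math.inf
            c = c / s
            log_scale += math.log(s)
            C[id(nd)] = c
        # uniform root prior; C was normalized to sum 1 at each node, so the
        # root term reduces to log(1/S) plus the accumulated scale
        lnL = log_scale + math.log(1.0 / S)
        return C, D, P, lnL

    def loglik(self, d: float, e: float, j: float = 0.0) -> float:
        _, _, _, lnL = self._passes(d, e, j)
        return lnL

    def marginals(self, d: float, e: float, j: float = 0.0) -> dict[str, np.ndarray]:
        """Marginal ancestral range probabilities at each internal node.

        Standard two-pass (inside/outside) marginals: the outside pass
        distributes the parent's state distribution through the cladogenetic
        events and the sibling's propagated conditional, then through the
        branch transition matrix.
        """
        C, D, P, lnL = self._passes(d, e, j)
        if not math.isfinite(lnL):
            raise ValueError("data has zero likelihood at these parameters")
        S = self.n_states
        prob = self._clado_probs(j)
        U: dict[int, np.ndarray] = {}
        root = self.tree.root
        U[id(root)] = np.full(S, 1.0 / S)
        out: dict[str, np.ndarray] = {}
        for nd in self.tree.preorder():
            if nd.is_leaf():
                continue
            m = U[id(nd)] * C[id(nd)]
            out[nd.node_id] = m / m.sum()
            a, b = nd.child_nodes()
            for child, sibling, child_side in ((a, b, self.left_idx), (b, a, self.right_idx)):
                sib_side = self.right_idx if child_side is self.left_idx else self.left_idx
                contrib = prob * U[id(nd)][self.parent_idx] * D[id(sibling)][sib_side]
                o = np.bincount(child_side, weights=contrib, minlength=S)
                u = P[id(child)].T @ o
                s = u.sum()
                U[id(child)] = u / s if s > 0 else u
        return out


def log_likelihood(
    tree: CloneTree,
    locations: Mapping[str, str],
    spec: ModelSpec,
    params: ModelParams,
    space: Optional[RangeSpace] = None,
    areas: Optional[Sequence[Area]] = None,
) -> float:
    """Pruning log-likelihood of tip site observations under one model."""
    if space is None:
        area_list = resolve_areas(locations, areas)
        space = build_range_space(len(area_list), 2, area_list)
    engine = PruningEngine(tree, locations, spec, space)
    return engine.loglik(params.d, params.e, params.j)


def fit_model(
    tree: CloneTree,
    locations: Mapping[str, str],
    spec: ModelSpec,
    space: Optional[RangeSpace] = None,
    areas: Optional[Sequence[Area]] = None,
    n_obs: Optional[int] = None,
) -> FitResult:
    """Maximum-likelihood fit over (d, e[, j]) with a deterministic start grid.

    Bounded L-BFGS-B from four fixed starting points; the best of the four
    local optima is returned.  ``n_obs`` for AICc/BIC defaults to the number
    of tips (clones).
    """
    if space is None:
        area_list = resolve_areas(locations, areas)
        space = build_range_space(len(area_list), 2, area_list)
    engine = PruningEngine(tree, locations, spec, space)
    # large finite penalty keeps L-BFGS-B's finite differences well defined
    # when a parameter proposal has zero data probability
    PENALTY = 1e12

    def guarded(d, e, j=0.0):
        if not (np.isfinite(d) and np.isfinite(e) and np.isfinite(j)):
            return PENALTY
        lnl = engine.loglik(max(d, 0.0), max(e, 0.0), max(j, 0.0))
        return -lnl if math.isfinite(lnl) else PENALTY

    if spec.founder:
        starts = START_GRID_3
        bounds = [D_E_BOUNDS, D_E_BOUNDS, J_BOUNDS]

        def neg(x):
            return guarded(x[0], x[1], x[2])

    else:
        starts = START_GRID_2
        bounds = [D_E_BOUNDS, D_E_BOUNDS]

        def neg(x):
            return guarded(x[0], x[1])

    best = None
    any_success = False
    for x0 in starts:
        res = minimize(neg, np.asarray(x0), method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-10, "gtol": 1e-8})
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    d_hat, e_hat = float(x[0]), float(x[1])
    j_hat = float(x[2]) if spec.founder else 0.0
    lnL = -float(best.fun)
    k = spec.n_free_params
    n = n_obs if n_obs is not None else tree.n_tips
    aic, aicc, bic = information_criteria(lnL, k, n)
    node_probs = engine.marginals(d_hat, e_hat, j_hat)
    return FitResult(
        spec=spec,
        params_hat=ModelParams(AnageneticParams(d_hat, e_hat), CladoParams(j_hat)),
        lnL=lnL,
        k=k,
        n_obs=n,
        AIC=aic,
        AICc=aicc,
        BIC=bic,
        node_probs=node_probs,
        converged=any_success,
        space=space,
    )


def fit_all_models(
    tree: CloneTree,
    locations: Mapping[str, str],
    specs: Optional[Sequence[ModelSpec]] = None,
    space: Optional[RangeSpace] = None,
    areas: Optional[Sequence[Area]] = None,
) -> dict[str, FitResult]:
    """Fit a set of models (default: all six) to one dataset."""
    from .cladogenesis import ALL_MODELS

    if specs is None:
        specs = ALL_MODELS
    if space is None:
        area_list = resolve_areas(locations, areas)
        space = build_range_space(len(area_list), 2, area_list)
    return {s.name: fit_model(tree, locations, s, space=space) for s in specs}


def likelihood_ratio_test(
    null_fit: FitResult, alt_fit: FitResult, boundary_mixture: bool = False
) -> LrtResult:
    """LRT of a base model against its +J counterpart (df = 1).

    By default the p-value is the plain chi-square(1) upper tail.  Because
    j = 0 sits on the boundary of its parameter space, the conservative
    50:50 chi-square mixture is available via ``boundary_mixture``.
    """
    if null_fit.spec.family != alt_fit.spec.family:
        raise ValueError("LRT requires nested models from the same family")
    if null_fit.spec.founder or not alt_fit.spec.founder:
        raise ValueError("null must be the base model and alt its +J variant")
    stat = max(0.0, 2.0 * (alt_fit.lnL - null_fit.lnL))
    p = float(chi2.sf(stat, df=1))
    if boundary_mixture:
        p = 0.5 * p if stat > 0 else 1.0
    return LrtResult(stat=stat, df=1, p_value=p, delta_bic=null_fit.BIC - alt_fit.BIC)


def model_selection_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits by AICc (ascending), with AICc weights and BIC.

    Ties on AICc are broken by fewer free parameters, then family name.
    """
    if len(fits) == 0:
        raise ValueError("need at least one fit")
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.model_name,
                "lnL": f.lnL,
                "k": f.k,
                "d": f.params_hat.d,
                "e": f.params_hat.e,
                "j": f.params_hat.j,
                "AIC": f.AIC,
                "AICc": f.AICc,
                "BIC": f.BIC,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["AICc", "k", "model"], kind="stable").reset_index(drop=True)
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    rel = np.exp(-0.5 * df["dAICc"].to_numpy())
    df["aicc_weight"] = rel / rel.sum()
    return df
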