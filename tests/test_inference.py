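import math

import numpy as np
import pytest

from clonegeo.anagenesis import AnageneticParams
from clonegeo.cladogenesis import CladoParams, ModelSpec
from clonegeo.inference import (
    CloneTree,
    FitResult,
    ModelParams,
    NonBinaryTreeError,
    PruningEngine,
    fit_model,
    information_criteria,
    likelihood_ratio_test,
    log_likelihood,
    model_selection_table,
)
from clonegeo.range_space import areas_from_labels, build_range_space

from conftest import brute_force_likelihood, random_dataset


def make_fit(spec, lnl, k, n_obs=20):
    aic, aicc, bic = information_criteria(lnl, k, n_obs)
    return FitResult(
        spec=spec,
        params_hat=ModelParams(AnageneticParams(0.1, 0.1), CladoParams(0.0)),
        lnL=lnl, k=k, n_obs=n_obs, AIC=aic, AICc=aicc, BIC=bic,
        node_probs={}, converged=True, space=build_range_space(2, 2),
    )


def test_two_tip_zero_branch_worked_example():
    """Both tips in area A of a 2-area space, zero branches, DEC: only the
    root state {A} can generate the data, so lnL = ln(1/3)."""
    tree = CloneTree.from_newick("(a:0.0,b:0.0);")
    areas = areas_from_labels(["A", "B"], "A")
    lnl = log_likelihood(
        tree, {"a": "A", "b": "A"}, ModelSpec("DEC"),
        ModelParams(AnageneticParams(0.1, 0.05)), areas=areas,
    )
    assert lnl == pytest.approx(math.log(1.0 / 3.0), abs=1e-12)


def test_pruning_matches_enumeration_oracle(rng):
    for _ in range(15):
        n_tips = int(rng.integers(2, 7))
        n_areas = int(rng.integers(2, 4))
        tree, locations, areas = random_dataset(n_tips, n_areas, rng)
        space = build_range_space(n_areas, 2, areas)
        spec = ModelSpec(
            ("BAYAREALIKE", "DEC", "DIVALIKE")[int(rng.integers(3))],
            founder=bool(rng.integers(2)),
        )
        d, e = float(rng.uniform(0, 1)), float(rng.uniform(0, 1))
        j = float(rng.uniform(0, 2)) if spec.founder else 0.0
        expected, _ = brute_force_likelihood(tree, locations, spec, d, e, j, space)
        got = log_likelihood(
            tree, locations, spec,
            ModelParams(AnageneticParams(d, e), CladoParams(j)), space=space,
        )
        assert got == pytest.approx(expected, abs=1e-10)


def test_marginals_match_enumeration_posterior(rng):
    tree, locations, areas = random_dataset(4, 3, rng)
    space = build_range_space(3, 2, areas)
    spec = ModelSpec("DEC", founder=True)
    d, e, j = 0.3, 0.1, 0.8
    _, post = brute_force_likelihood(tree, locations, spec, d, e, j, space)
    engine = PruningEngine(tree, locations, spec, space)
    marg = engine.marginals(d, e, j)
    assert set(marg) == set(post)
    for node_id in marg:
        assert marg[node_id].sum() == pytest.approx(1.0, abs=1e-8)
        assert np.max(np.abs(marg[node_id] - post[node_id])) < 1e-8


def test_plus_j_at_zero_equals_base_model(rng):
    for _ in range(6):
        tree, locations, areas = random_dataset(5, 3, rng)
        space = build_range_space(3, 2, areas)
        d, e = float(rng.uniform(0, 1)), float(rng.uniform(0, 1))
        for fam in ("BAYAREALIKE", "DEC", "DIVALIKE"):
            base = log_likelihood(
                tree, locations, ModelSpec(fam),
                ModelParams(AnageneticParams(d, e)), space=space,
            )
            plus = log_likelihood(
                tree, locations, ModelSpec(fam, founder=True),
                ModelParams(AnageneticParams(d, e), CladoParams(0.0)), space=space,
            )
            assert plus == pytest.approx(base, abs=1e-12)


def test_likelihood_invariant_to_child_swap_and_passthrough():
    areas = areas_from_labels(["A", "B"], "A")
    locations = {"a": "A", "b": "B", "c": "A"}
    params = ModelParams(AnageneticParams(0.2, 0.1))
    newicks = [
        "((a:0.5,b:1.0):0.7,c:2.0);",
        "((b:1.0,a:0.5):0.7,c:2.0);",  # swapped children
        "(c:2.0,(a:0.5,b:1.0):0.7);",  # swapped at root
        "(((a:0.5,b:1.0):0.3):0.4,c:2.0);",  # degree-2 pass-through collapses
    ]
    vals = [
        log_likelihood(CloneTree.from_newick(nwk), locations, ModelSpec("DEC"), params, areas=areas)
        for nwk in newicks
    ]
    assert all(v == pytest.approx(vals[0], abs=1e-12) for v in vals)


def test_non_binary_tree_and_missing_location_rejected():
    with pytest.raises(NonBinaryTreeError):
        CloneTree.from_newick("(a:1,b:1,c:1);")
    tree = CloneTree.from_newick("(a:1,b:1);")
    areas = areas_from_labels(["A", "B"], "A")
    space = build_range_space(2, 2, areas)
    with pytest.raises(KeyError):
        PruningEngine(tree, {"a": "A"}, ModelSpec("DEC"), space)


def test_zero_length_tip_flagging():
    tree = CloneTree.from_newick("((a:0.0,b:1.0):1.0,c:2.0);")
    assert tree.zero_length_tips == ["a"]
    assert tree.n_tips == 3
    assert len(tree.root.child_nodes()) == 2


def test_information_criteria_arithmetic():
    aic, aicc, bic = information_criteria(-10.0, 2, 9)
    assert aic == pytest.approx(24.0)
    assert aicc == pytest.approx(24.0 + 12.0 / 6.0)
    assert bic == pytest.approx(2 * math.log(9) + 20.0)
    assert aicc >= aic


def test_fit_recovers_boundary_when_no_dispersal_signal():
    """All tips in one area: expansions only waste probability, so the ML
    dispersal rate sits at the lower bound."""
    tree = CloneTree.from_newick("((a:0.4,b:0.6):0.5,(c:0.3,d:0.7):0.2);")
    areas = areas_from_labels(["A", "B"], "A")
    locations = {t: "A" for t in "abcd"}
    fit = fit_model(tree, locations, ModelSpec("DEC"), areas=areas)
    assert fit.params_hat.d < 1e-6
    assert fit.converged
    for row in fit.node_probs.values():
        assert row.sum() == pytest.approx(1.0, abs=1e-8)


def test_lrt_statistic_and_pvalues():
    null = make_fit(ModelSpec("DEC"), -50.0, 2)
    alt = make_fit(ModelSpec("DEC", founder=True), -50.0, 3)
    r = likelihood_ratio_test(null, alt)
    assert r.stat == 0.0 and r.p_value == pytest.approx(1.0)
    # chi-square(1) upper tail oracle: p = erfc(sqrt(stat/2))
    for stat, expected in [(4.5, 0.0339), (10.0, 0.00157)]:
        alt = make_fit(ModelSpec("DEC", founder=True), -50.0 + stat / 2.0, 3)
        r = likelihood_ratio_test(null, alt)
        assert r.p_value == pytest.approx(math.erfc(math.sqrt(stat / 2.0)), rel=1e-10)
        assert r.p_value == pytest.approx(expected, rel=5e-3)
    assert r.delta_bic == pytest.approx(null.BIC - alt.BIC)


def test_lrt_requires_nested_pair():
    with pytest.raises(ValueError):
        likelihood_ratio_test(make_fit(ModelSpec("DEC"), -10, 2),
                              make_fit(ModelSpec("DIVALIKE", founder=True), -9, 3))
    with pytest.raises(ValueError):
        likelihood_ratio_test(make_fit(ModelSpec("DEC", founder=True), -9, 3),
                              make_fit(ModelSpec("DEC"), -10, 2))


def test_boundary_mixture_halves_pvalue():
    null = make_fit(ModelSpec("DEC"), -50.0, 2)
    alt = make_fit(ModelSpec("DEC", founder=True), -48.0, 3)
    plain = likelihood_ratio_test(null, alt).p_value
    mixed = likelihood_ratio_test(null, alt, boundary_mixture=True).p_value
    assert mixed == pytest.approx(plain / 2.0)


def test_model_selection_table_ordering():
    # equal lnL: the 2-parameter model wins on AICc
    fits = [make_fit(ModelSpec("DEC", founder=True), -30.0, 3),
            make_fit(ModelSpec("DEC"), -30.0, 2)]
    df = model_selection_table(fits)
    assert df["model"].tolist() == ["DEC", "DEC+J"]
    assert df["dAICc"].iloc[0] == 0.0
    assert df["aicc_weight"].sum() == pytest.approx(1.0)
    # three fits ordered by hand-computed AICc
    fits = [make_fit(ModelSpec("BAYAREALIKE"), -32.0, 2),
            make_fit(ModelSpec("DEC", founder=True), -28.0, 3),
            make_fit(ModelSpec("DIVALIKE"), -29.0, 2)]
    by_hand = sorted(fits, key=lambda f: f.AICc)
    df = model_selection_table(fits)
    assert df["model"].tolist() == [f.model_name for f in by_hand]
    # single model
    assert model_selection_table([fits[0]])["model"].tolist() == ["BAYAREALIKE"]
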