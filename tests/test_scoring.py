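"""Unit and property tests for the pathway activity score chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import scmetab as sm
from scmetab.errors import ConfigurationError, InputError

from conftest import random_instance
from oracles import group_mean, nested_loop_pathway_scores


def test_mean_expression_simple_examples():
    expr = pd.DataFrame(
        {"c1": [2.0, 1.0], "c2": [4.0, 3.0], "c3": [10.0, 7.0]}, index=["gA", "gB"]
    )
    types = pd.Series({"c1": "j", "c2": "j", "c3": "lone"})
    E = sm.mean_expression_by_celltype(expr, types)
    assert E.loc["gA", "j"] == 3.0  # arithmetic mean of {2, 4}
    assert E.loc["gA", "lone"] == 10.0  # single-cell type equals the cell's value


def test_mean_expression_matches_double_loop():
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(
        rng.gamma(2, 2, size=(50, 200)),
        index=[f"g{i}" for i in range(50)],
        columns=[f"c{i}" for i in range(200)],
    )
    types = pd.Series(rng.choice(["a", "b", "c", "d"], size=200), index=expr.columns)
    E = sm.mean_expression_by_celltype(expr, types)
    for gene in expr.index:
        for t in sorted(types.unique()):
            cells = types.index[types == t]
            expected = sum(expr.loc[gene, c] for c in cells) / len(cells)
            assert abs(E.loc[gene, t] - expected) < 1e-12


def test_mean_expression_input_errors():
    expr = pd.DataFrame({"c1": [1.0], "c2": [2.0]}, index=["g"])
    with pytest.raises(InputError):
        sm.mean_expression_by_celltype(expr, pd.Series({"c1": "a", "ghost": "b"}))
    with pytest.raises(InputError):
        sm.mean_expression_by_celltype(expr, pd.Series({"c1": "a", "c2": "a"}))


def test_relative_expression_forced_values_and_dropping():
    E = pd.DataFrame({"t1": [2.0, 1.0, 0.0], "t2": [4.0, 1.0, 0.0]},
                     index=["g1", "g2", "gzero"])
    r, dropped = sm.relative_expression(E)
    assert np.allclose(r.loc["g1"], [2 / 3, 4 / 3])
    assert np.allclose(r.loc["g2"], [1.0, 1.0])  # equal means -> r = 1 everywhere
    assert dropped == ["gzero"]


@settings(derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000), n_types=st.integers(2, 6))
def test_relative_expression_row_mean_is_one(seed, n_types):
    rng = np.random.default_rng(seed)
    E = pd.DataFrame(rng.gamma(1.5, 3.0, size=(20, n_types)))
    r, _ = sm.relative_expression(E)
    assert np.allclose(r.mean(axis=1), 1.0, atol=1e-9)


def test_gene_weights_reciprocal_membership():
    sets = sm.GeneSetCollection({f"p{i}": ["shared", f"own{i}"] for i in range(5)})
    w = sm.gene_weights(sets)
    assert w["shared"] == pytest.approx(0.2)
    assert w["own3"] == 1.0
    with pytest.raises(KeyError):
        w["outside_universe"]


def test_pathway_activity_degenerate_cases():
    r = pd.DataFrame({"t1": [2.0, 1.0], "t2": [0.5, 1.0]}, index=["g1", "g2"])
    sets = sm.GeneSetCollection({"solo": ["g1"], "pair": ["g1", "g2"]})
    w = sm.gene_weights(sets)
    pa = sm.pathway_activity(r, w, sets, min_genes=1)
    # single-gene pathway score equals that gene's relative expression
    assert np.allclose(pa.scores.loc["solo"], r.loc["g1"])
    # all-ones r gives all-ones scores
    ones = pd.DataFrame(1.0, index=["g1", "g2"], columns=["t1", "t2"])
    pa1 = sm.pathway_activity(ones, w, sets, min_genes=1)
    assert np.allclose(pa1.scores.to_numpy(), 1.0)


def test_pathway_activity_min_genes_filtering():
    r = pd.DataFrame({"t1": [1.0, 2.0], "t2": [1.0, 0.5]}, index=["g1", "g2"])
    sets = sm.GeneSetCollection({"small": ["g1"], "ok": ["g1", "g2"]})
    pa = sm.pathway_activity(r, sm.gene_weights(sets), sets, min_genes=2)
    assert "small" in pa.unscored and "min_genes=2" in pa.unscored["small"]
    assert list(pa.scores.index) == ["ok"]
    with pytest.raises(ConfigurationError):
        sm.pathway_activity(r, sm.gene_weights(sets), sets, min_genes=0)


def test_pathway_activity_weight_scale_invariance(small_instance):
    expr, types, sets = small_instance
    E = sm.mean_expression_by_celltype(expr, types, genes=sets.universe)
    r, _ = sm.relative_expression(E)
    w = sm.gene_weights(sets)
    pa = sm.pathway_activity(r, w, sets, min_genes=1)
    pa_scaled = sm.pathway_activity(r, w * 7.3, sets, min_genes=1)
    assert np.allclose(pa.scores.to_numpy(), pa_scaled.scores.to_numpy(), atol=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_scores_match_nested_loop_oracle(seed):
    expr, types, sets = random_instance(seed, n_genes=25, n_pathways=4, n_types=3)
    pa = sm.score_pathways(expr, types, sets, min_genes=1, normalize="none")
    oracle, retained = nested_loop_pathway_scores(expr, types.to_dict(), sets.sets)
    for pw in oracle:
        for t in oracle[pw]:
            assert pa.scores.loc[pw, t] == pytest.approx(oracle[pw][t], abs=1e-10)


def test_score_monotonic_in_member_gene_expression(small_instance):
    expr, types, sets = small_instance
    pw = next(iter(sets.sets))
    gene = sets.sets[pw][0]
    target_type = "T1"
    pa = sm.score_pathways(expr, types, sets, min_genes=1, normalize="none")
    bumped = expr.copy()
    bumped.loc[gene, types.index[types == target_type]] *= 3.0
    pa2 = sm.score_pathways(bumped, types, sets, min_genes=1, normalize="none")
    for name, members in sets.sets.items():
        if gene in members and name in pa.scores.index:
            assert pa2.scores.loc[name, target_type] >= pa.scores.loc[name, target_type] - 1e-12


def test_permutation_constant_matrix_gives_p_one():
    cells = [f"c{i}" for i in range(40)]
    expr = pd.DataFrame(3.0, index=[f"g{i}" for i in range(10)], columns=cells)
    types = pd.Series(np.repeat(["a", "b"], 20), index=cells)
    sets = sm.GeneSetCollection({"p1": ["g0", "g1", "g2"], "p2": ["g3", "g4", "g5"]})
    pa = sm.permutation_pvalues(expr, types, sets, n_perm=99, seed=0)
    assert np.allclose(pa.scores.to_numpy(), 1.0)
    assert np.all(pa.pvalues.to_numpy() == 1.0)


def test_permutation_pvalue_bounds_and_determinism(small_instance):
    expr, types, sets = small_instance
    pa1 = sm.permutation_pvalues(expr, types, sets, n_perm=49, seed=11, min_genes=1)
    pa2 = sm.permutation_pvalues(expr, types, sets, n_perm=49, seed=11, min_genes=1)
    p = pa1.pvalues.to_numpy()
    assert (p >= 1.0 / 50).all() and (p <= 1.0).all()
    assert np.array_equal(p, pa2.pvalues.to_numpy())
    with pytest.raises(ConfigurationError):
        sm.permutation_pvalues(expr, types, sets, n_perm=0, seed=1)


def test_permutation_observed_scores_match_reference_path(small_instance):
    expr, types, sets = small_instance
    pa_ref = sm.score_pathways(expr, types, sets, min_genes=1, normalize="none")
    pa = sm.permutation_pvalues(expr, types, sets, n_perm=1, seed=0,
                                min_genes=1, normalize="none")
    aligned = pa.scores.loc[pa_ref.scores.index, pa_ref.scores.columns]
    assert np.allclose(aligned.to_numpy(), pa_ref.scores.to_numpy(), atol=1e-10)


def test_permutation_bh_adjustment_monotone(small_instance):
    expr, types, sets = small_instance
    pa = sm.permutation_pvalues(expr, types, sets, n_perm=49, seed=5,
                                min_genes=1, adjust="bh")
    assert pa.pvalues_adj is not None
    assert (pa.pvalues_adj.to_numpy() >= pa.pvalues.to_numpy() - 1e-12).all()


def test_aggregate_categories_against_group_mean_oracle(small_instance):
    expr, types, sets = small_instance
    pa = sm.score_pathways(expr, types, sets, min_genes=1)
    cat = sm.aggregate_categories(pa, sets)
    by_pw = {p: pa.scores.loc[p].to_dict() for p in pa.scores.index}
    oracle = group_mean(by_pw, sets.categories)
    for c in oracle:
        for t in oracle[c]:
            assert cat.loc[c, t] == pytest.approx(oracle[c][t], abs=1e-12)


def test_aggregate_categories_single_member_and_missing_labels():
    scores = pd.DataFrame({"t1": [1.5, 0.5]}, index=["pA", "pB"])
    pa = sm.PathwayActivity(scores=scores, n_genes=pd.Series({"pA": 3, "pB": 3}))
    sets = sm.GeneSetCollection(
        {"pA": ["g1"], "pB": ["g2"]}, categories={"pA": "c1", "pB": "c2"}
    )
    cat = sm.aggregate_categories(pa, sets)
    assert cat.loc["c1", "t1"] == 1.5  # mean of one pathway is that pathway
    bare = sm.GeneSetCollection({"pA": ["g1"], "pB": ["g2"]})
    with pytest.raises(InputError):
        sm.aggregate_categories(pa, bare)


def test_library_size_normalization_equalizes_totals():
    expr = pd.DataFrame({"c1": [1.0, 1.0], "c2": [4.0, 4.0], "c3": [0.0, 0.0]},
                        index=["g1", "g2"])
    norm = sm.normalize_library_size(expr)
    totals = norm.sum(axis=0)
    assert totals["c1"] == pytest.approx(totals["c2"])
    assert totals["c3"] == 0.0  # empty cells stay empty
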