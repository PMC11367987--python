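"""Proportion comparison, co-expression networks, paired correlation."""

import numpy as np
import pandas as pd
import pytest

import scmetab as sm
from scmetab.errors import InputError

from oracles import pearson_closed_form, ranksum_enumeration_p, tally_proportions


def make_annotation(records, conditions):
    """records: list of (sample, cell_type); conditions: sample -> condition."""
    return pd.DataFrame(
        {
            "cell_type": [ct for _, ct in records],
            "sample_id": [s for s, _ in records],
            "condition": [conditions[s] for s, _ in records],
        },
        index=pd.Index([f"cell{i}" for i in range(len(records))], name="cell_id"),
    )


def test_proportions_basic_arithmetic_and_conservation():
    records = [("s1", "epithelial")] * 30 + [("s1", "fibroblast")] * 70
    ann = make_annotation(records, {"s1": "case"})
    pt = sm.proportions_by_sample(ann)
    assert pt.fractions.loc["s1", "epithelial"] == pytest.approx(0.3)
    assert pt.fractions.loc["s1", "fibroblast"] == pytest.approx(0.7)
    assert pt.fractions.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-9)


def test_proportions_match_tally_oracle():
    rng = np.random.default_rng(2)
    samples = [f"s{i}" for i in range(6)]
    conditions = {s: ("case" if i < 3 else "control") for i, s in enumerate(samples)}
    records = [
        (rng.choice(samples), rng.choice(["a", "b", "c"])) for _ in range(400)
    ]
    ann = make_annotation(records, conditions)
    pt = sm.proportions_by_sample(ann)
    counts, fractions = tally_proportions(records)
    for s, per in counts.items():
        for ct, c in per.items():
            assert pt.counts.loc[s, ct] == c
            assert pt.fractions.loc[s, ct] == pytest.approx(fractions[s][ct])
    assert np.allclose(pt.fractions.sum(axis=1), 1.0, atol=1e-9)


def test_proportions_requires_annotation_fields():
    ann = pd.DataFrame({"cell_type": ["a"]}, index=["c1"])
    with pytest.raises(InputError, match="sample_id"):
        sm.proportions_by_sample(ann)


def _ptable(case_fracs, control_fracs, cell_type="ct"):
    samples = [f"cs{i}" for i in range(len(case_fracs))] + [
        f"ct{i}" for i in range(len(control_fracs))
    ]
    vals = list(case_fracs) + list(control_fracs)
    fractions = pd.DataFrame(
        {cell_type: vals, "other": [1 - v for v in vals]}, index=samples
    )
    counts = (fractions * 100).round().astype(int)
    condition = pd.Series(
        ["case"] * len(case_fracs) + ["control"] * len(control_fracs), index=samples
    )
    return sm.ProportionTable(counts=counts, fractions=fractions, condition=condition)


def test_compare_proportions_all_ties_gives_p_one():
    pt = _ptable([0.4, 0.4, 0.4], [0.4, 0.4, 0.4])
    res = sm.compare_proportions(pt, "ct")
    assert res.method == "exact"
    assert res.p_value == 1.0


def test_compare_proportions_exact_branch_matches_enumeration_oracle():
    rng = np.random.default_rng(5)
    for _ in range(10):
        case = rng.uniform(0.2, 0.6, size=4)
        control = rng.uniform(0.2, 0.6, size=4)
        res = sm.compare_proportions(_ptable(case, control), "ct")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(ranksum_enumeration_p(case, control))


def test_compare_proportions_condition_relabel_keeps_p():
    case = [0.5, 0.55, 0.6, 0.52]
    control = [0.3, 0.35, 0.33, 0.4]
    res1 = sm.compare_proportions(_ptable(case, control), "ct")
    res2 = sm.compare_proportions(_ptable(control, case), "ct")
    assert res1.p_value == pytest.approx(res2.p_value)


def test_compare_proportions_detects_planted_shift():
    rng = np.random.default_rng(0)
    hits = 0
    for _ in range(20):
        control = np.clip(rng.normal(0.2, 0.03, size=6), 0.01, 0.9)
        case = np.clip(rng.normal(0.4, 0.03, size=6), 0.01, 0.9)
        res = sm.compare_proportions(_ptable(case, control), "ct")
        hits += res.p_value < 0.05
    assert hits >= 18


def test_compare_proportions_normal_branch_with_ties():
    case = [0.3] * 12
    control = [0.3] * 11 + [0.31]
    res = sm.compare_proportions(_ptable(case, control), "ct", exact_max_n=20)
    assert res.method == "normal"
    assert 0.0 < res.p_value <= 1.0


def test_compare_proportions_needs_two_samples_per_condition():
    with pytest.raises(InputError):
        sm.compare_proportions(_ptable([0.4], [0.3, 0.35]), "ct")


def _coexpr_fixture(n_cells=200, seed=8):
    rng = np.random.default_rng(seed)
    cells = [f"c{i}" for i in range(n_cells)]
    focal = rng.gamma(3, 2, size=n_cells)
    rows = {
        "focal": focal,
        "twin": focal.copy(),                       # identical values
        "flat": np.full(n_cells, 2.0),              # zero variance
        "noisy": focal * rng.lognormal(0, 0.35, n_cells),  # positively coupled
        "indep": rng.gamma(3, 2, size=n_cells),
    }
    expr = pd.DataFrame(rows, index=cells).T
    ann = pd.DataFrame(
        {"cell_type": ["clusterA"] * n_cells,
         "sample_id": ["s1"] * n_cells,
         "condition": ["case"] * n_cells},
        index=pd.Index(cells, name="cell_id"),
    )
    return expr, ann


def test_coexpression_classification_and_oracle():
    expr, ann = _coexpr_fixture()
    net = sm.coexpression_network(
        expr, ann, "clusterA", "focal", ["twin", "flat", "noisy", "indep", "focal"]
    )
    assert "focal" not in net.edges.index  # focal gene excluded from markers
    assert net.edges.loc["twin", "r"] == pytest.approx(1.0)
    assert net.edges.loc["twin", "classification"] == "positive"
    assert net.edges.loc["flat", "classification"] == "unclassified"
    assert net.edges.loc["flat", "reason"] == "zero variance"
    assert net.edges.loc["noisy", "classification"] == "positive"
    # closed-form oracle on the log2(x+1) values
    cells = ann.index
    x = np.log2(expr.loc["focal", cells].to_numpy() + 1)
    y = np.log2(expr.loc["noisy", cells].to_numpy() + 1)
    r_o, p_o = pearson_closed_form(x, y)
    assert net.edges.loc["noisy", "r"] == pytest.approx(r_o, abs=1e-9)
    assert net.edges.loc["noisy", "p_value"] == pytest.approx(p_o, abs=1e-9)
    # positive/negative counts equal a brute-force reclassification
    n_pos = sum(
        (row["r"] > 0) and (row["p_value"] < 0.05)
        for _, row in net.edges.iterrows() if np.isfinite(row["r"])
    )
    assert net.n_positive == n_pos


def test_coexpression_input_errors():
    expr, ann = _coexpr_fixture(n_cells=10)
    with pytest.raises(InputError, match="cluster"):
        sm.coexpression_network(expr, ann, "missing", "focal", ["twin"])
    with pytest.raises(InputError, match="focal"):
        sm.coexpression_network(expr, ann, "clusterA", "nope", ["twin"])
    with pytest.raises(InputError, match="marker"):
        sm.coexpression_network(expr, ann, "clusterA", "focal", ["ghost"])


def test_paired_pearson_limits_and_oracle():
    assert sm.paired_pearson([1, 2, 3, 4], [2, 4, 6, 8])[0] == pytest.approx(1.0)
    assert sm.paired_pearson([1, 2, 3, 4], [-1, -2, -3, -4])[0] == pytest.approx(-1.0)
    rng = np.random.default_rng(9)
    x = rng.normal(size=50)
    y = 0.6 * x + rng.normal(size=50)
    r, p, n = sm.paired_pearson(x, y)
    r_o, p_o = pearson_closed_form(x, y)
    assert r == pytest.approx(r_o, abs=1e-12)
    assert p == pytest.approx(p_o, abs=1e-12)
    assert n == 50
    # invariance under positive affine transforms
    r2, p2, _ = sm.paired_pearson(3.0 * x + 10.0, 0.5 * y - 2.0)
    assert r2 == pytest.approx(r, abs=1e-9)
    assert p2 == pytest.approx(p, abs=1e-9)


def test_paired_pearson_input_errors():
    with pytest.raises(InputError):
        sm.paired_pearson([1, 2], [1, 2])
    with pytest.raises(InputError):
        sm.paired_pearson([1, 1, 1], [1, 2, 3])
    with pytest.raises(InputError):
        sm.paired_pearson([1, 2, np.nan], [1, 2, 3])
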