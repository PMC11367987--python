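"""Cluster-level descriptive statistics.

Covers three operations run on annotated single-cell data: per-sample
cell-type composition compared between conditions (Wilcoxon rank-sum on
per-sample fractions, exact by enumeration at small n), focal-gene
co-expression networks within one cluster (per-marker Pearson correlation
on log2(x+1) values, classified by sign and significance), and a generic
paired Pearson correlation for clinical/protein tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import InputError

EXACT_MAX_N = 20  # combined sample count up to which the rank-sum p is enumerated


@dataclass
class ProportionTable:
    """Per-sample cell-type counts and within-sample fractions."""

    counts: pd.DataFrame      # samples x cell types, integer counts
    fractions: pd.DataFrame   # same shape, rows sum to 1
    condition: pd.Series      # sample -> condition label


@dataclass
class ProportionTestResult:
    cell_type: str
    statistic: float          # rank-sum of the case group (midranks)
    p_value: float
    median_case: float
    median_control: float
    n_case: int
    n_control: int
    method: str               # 'exact' or 'normal'


@dataclass
class CoexpressionNetwork:
    """Focal-gene correlation edges within one cluster."""

    focal_gene: str
    cluster: str
    alpha: float
    edges: pd.DataFrame       # marker x (r, p_value, classification, reason)

    @property
    def n_positive(self) -> int:
        return int((self.edges["classification"] == "positive").sum())

    @property
    def n_negative(self) -> int:
        return int((self.edges["classification"] == "negative").sum())


def proportions_by_sample(ann: pd.DataFrame) -> ProportionTable:
    """Exact per-(sample, cell type) counts and within-sample fractions.

    Cell types absent from a sample get fraction 0. Each sample must carry
    a single condition label.
    """
    for col in ("cell_type", "sample_id", "condition"):
        if col not in ann.columns:
            raise InputError(f"annotation lacks required column {col!r}")
    counts = pd.crosstab(ann["sample_id"], ann["cell_type"])
    fractions = counts.div(counts.sum(axis=1), axis=0)
    cond = ann.groupby("sample_id")["condition"].unique()
    bad = cond[cond.map(len) > 1]
    if len(bad):
        raise InputError(f"samples with conflicting condition labels: {list(bad.index)}")
    condition = cond.map(lambda v: v[0])
    condition.name = "condition"
    return ProportionTable(counts=counts, fractions=fractions, condition=condition)


def _ranksum_exact_p(ranks: np.ndarray, n_case: int, observed: float) -> float:
    """Two-sided exact p for the rank-sum by enumerating case-position choices.

    Uses midranks, so ties are handled; with all values tied every
    assignment gives the same statistic and p = 1.
    """
    mu = n_case * (len(ranks) + 1) / 2.0
    obs_dev = abs(observed - mu) - 1e-12
    hits = total = 0
    for idx in itertools.combinations(range(len(ranks)), n_case):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= obs_dev:
            hits += 1
    return hits / total


def compare_proportions(
    pt: ProportionTable, cell_type: str, exact_max_n: int = EXACT_MAX_N
) -> ProportionTestResult:
    """Wilcoxon rank-sum on per-sample fractions of one cell type, case vs control.

    The p-value is exact (full enumeration over rank assignments, midranks
    for ties) when the combined sample count is <= ``exact_max_n``, else a
    normal approximation with tie-corrected variance.
    """
    if cell_type not in pt.fractions.columns:
        raise InputError(f"cell type {cell_type!r} not present in the proportion table")
    frac = pt.fractions[cell_type]
    case = frac[pt.condition == "case"].to_numpy(dtype=float)
    control = frac[pt.condition == "control"].to_numpy(dtype=float)
    if len(case) < 2 or len(control) < 2:
        raise InputError("each condition needs at least 2 samples")
    pooled = np.concatenate([case, control])
    ranks = scipy.stats.rankdata(pooled)
    W = float(ranks[: len(case)].sum())
    n, n1, n2 = len(pooled), len(case), len(control)
    if n <= exact_max_n:
        p = _ranksum_exact_p(ranks, n1, W)
        method = "exact"
    else:
        mu = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (W - mu) / np.sqrt(var)
            p = min(1.0, 2.0 * scipy.stats.norm.sf(abs(z)))
        method = "normal"
    return ProportionTestResult(
        cell_type=cell_type,
        statistic=W,
        p_value=p,
        median_case=float(np.median(case)),
        median_control=float(np.median(control)),
        n_case=n1,
        n_control=n2,
        method=method,
    )


def coexpression_network(
    expr: pd.DataFrame,
    ann: pd.DataFrame,
    cluster: str,
    focal_gene: str,
    markers: list[str],
    alpha: float = 0.05,
) -> CoexpressionNetwork:
    """Pearson correlation of a focal gene with marker genes within a cluster.

    Computed across the cluster's cells on log2(x+1)-transformed values.
    Markers are classified 'positive' (r > 0, p < alpha), 'negative'
    (r < 0, p < alpha) or 'unclassified' (with the reason); the focal gene
    is excluded from the marker list.
    """
    if "cell_type" not in ann.columns:
        raise InputError("annotation lacks a 'cell_type' column")
    cells = ann.index[ann["cell_type"] == cluster]
    cells = cells.intersection(expr.columns)
    if len(cells) < 3:
        raise InputError(f"cluster {cluster!r} has fewer than 3 cells in the matrix")
    if focal_gene not in expr.index:
        raise InputError(f"focal gene {focal_gene!r} absent from the matrix")
    missing = [m for m in markers if m not in expr.index]
    if missing:
        raise InputError(f"marker genes absent from the matrix: {missing[:5]}")
    markers = [m for m in markers if m != focal_gene]
    x = np.log2(expr.loc[focal_gene, cells].to_numpy(dtype=float) + 1.0)
    rows = []
    focal_const = np.ptp(x) == 0
    for m in markers:
        y = np.log2(expr.loc[m, cells].to_numpy(dtype=float) + 1.0)
        if focal_const or np.ptp(y) == 0:
            rows.append((m, np.nan, np.nan, "unclassified", "zero variance"))
            continue
        r, p = scipy.stats.pearsonr(x, y)
        if p < alpha and r > 0:
            rows.append((m, r, p, "positive", ""))
        elif p < alpha and r < 0:
            rows.append((m, r, p, "negative", ""))
        else:
            rows.append((m, r, p, "unclassified", "not significant at alpha"))
    edges = pd.DataFrame(
        rows, columns=["marker", "r", "p_value", "classification", "reason"]
    ).set_index("marker")
    return CoexpressionNetwork(focal_gene=focal_gene, cluster=cluster, alpha=alpha, edges=edges)


def paired_pearson(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-sided t-distributed p on n - 2 degrees of freedom.

    Returns (r, p, n). Inputs must be equal-length finite vectors with
    n >= 3 and nonzero variance on both sides.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired correlation needs two equal-length vectors")
    if len(x) < 3:
        raise InputError("paired correlation needs n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("paired correlation inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("paired correlation undefined for a zero-variance vector")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p), len(x)
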