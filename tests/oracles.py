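"""Independent brute-force oracles used by the test suite.

Everything here is written as literal loops / closed forms, deliberately
sharing no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import scipy.stats


def nested_loop_pathway_scores(expr_df, type_of_cell, sets):
    """Literal translation of the three score equations, term by term.

    expr_df: genes x cells DataFrame; type_of_cell: dict cell -> type;
    sets: dict pathway -> member gene list. Returns (scores, retained)
    where scores is {pathway: {type: p}} over genes present in the matrix
    whose per-type means do not all vanish.
    """
    types = sorted(set(type_of_cell.values()))
    universe = []
    for members in sets.values():
        for g in members:
            if g in expr_df.index and g not in universe:
                universe.append(g)

    # E[i][j] = sum_{k in type j} g_ik / n_j
    E = {}
    for gene in universe:
        E[gene] = {}
        for t in types:
            cells = [c for c in expr_df.columns if type_of_cell[c] == t]
            total = 0.0
            for c in cells:
                total += float(expr_df.loc[gene, c])
            E[gene][t] = total / len(cells)

    # r[i][j] = E[i][j] / ((1/N) sum_j E[i][j]); zero-mean genes dropped
    N = len(types)
    r = {}
    for gene in universe:
        denom = sum(E[gene][t] for t in types) / N
        if denom > 0:
            r[gene] = {t: E[gene][t] / denom for t in types}

    # w_i = 1 / (number of pathways containing gene i)
    counts = {}
    for members in sets.values():
        for g in members:
            counts[g] = counts.get(g, 0) + 1

    # p[t][j] = sum_i w_i r_ij / sum_i w_i over retained members
    scores = {}
    for name, members in sets.items():
        retained = [g for g in members if g in r]
        if not retained:
            continue
        scores[name] = {}
        for t in types:
            num = 0.0
            den = 0.0
            for g in retained:
                w = 1.0 / counts[g]
                num += w * r[g][t]
                den += w
            scores[name][t] = num / den
    return scores, sorted(r)


def welch_t(a, b):
    """Textbook Welch statistic, Satterthwaite df, and two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return t, df, p


def pearson_closed_form(x, y):
    """r from the raw-moment formula; two-sided t-based p on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = math.sqrt(n * (x**2).sum() - sx**2) * math.sqrt(n * (y**2).sum() - sy**2)
    r = num / den
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * scipy.stats.t.sf(abs(t), n - 2)
    return r, p


def ranksum_enumeration_p(case, control):
    """Exact two-sided rank-sum p by enumerating every label assignment."""
    pooled = np.concatenate([np.asarray(case, float), np.asarray(control, float)])
    ranks = scipy.stats.rankdata(pooled)
    n1, n = len(case), len(pooled)
    mu = n1 * (n + 1) / 2.0
    observed = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for assignment in itertools.combinations(range(n), n1):
        total += 1
        if abs(sum(ranks[i] for i in assignment) - mu) >= observed - 1e-12:
            hits += 1
    return hits / total


def sign_consistent_intersection(tables):
    """Set/sign intersection over {gene: direction} dicts (non-ns calls only)."""
    common = set(tables[0])
    for t in tables[1:]:
        common &= set(t)
    up = sorted(g for g in common if all(t[g] == "up" for t in tables))
    down = sorted(g for g in common if all(t[g] == "down" for t in tables))
    conflict = sorted(common - set(up) - set(down))
    return up, down, conflict


def tally_proportions(records):
    """Brute-force per-(sample, type) tally from (sample, type) records."""
    counts = {}
    for sample, cell_type in records:
        counts.setdefault(sample, {})
        counts[sample][cell_type] = counts[sample].get(cell_type, 0) + 1
    fractions = {
        s: {ct: c / sum(per.values()) for ct, c in per.items()}
        for s, per in counts.items()
    }
    return counts, fractions


def group_mean(values_by_key, key_to_group):
    """Unweighted per-group mean of dict-of-dict values (pathway -> type -> x)."""
    groups = {}
    for key, vals in values_by_key.items():
        groups.setdefault(key_to_group[key], []).append(vals)
    out = {}
    for group, rows in groups.items():
        cols = rows[0].keys()
        out[group] = {c: sum(row[c] for row in rows) / len(rows) for c in cols}
    return out
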