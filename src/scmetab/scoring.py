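"""Cell-type-specific metabolic pathway activity scoring.

The score quantifies how active a pathway ``t`` is in a cell type ``j``
relative to all cell types in the dataset. It is built from three layers:

1. ``E[i, j]`` — the arithmetic mean expression of gene ``i`` over the
   ``n_j`` cells of type ``j``.
2. ``r[i, j] = E[i, j] / ((1/N) * sum_j E[i, j])`` — the gene's mean in
   type ``j`` relative to the average of its per-type means over all
   ``N`` types. ``r > 1`` means the gene is enriched in that type.
3. ``p[t, j] = sum_{i in t} w_i * r[i, j] / sum_{i in t} w_i`` — a
   weighted mean of relative expression over the pathway's member genes,
   the weight ``w_i = 1 / c_i`` being the reciprocal of the number of
   pathways containing gene ``i``, so promiscuous housekeeping-style
   genes contribute less.

Significance of "pathway t is specifically activated in type j" is
assessed with a one-sided permutation test that shuffles cell-type labels
across cells (type sizes preserved) and recomputes the full score each
round. Scores can finally be averaged within KEGG-style categories for a
coarse per-cell-type metabolic profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .gene_sets import GeneSetCollection

__all__ = [
    "PathwayActivity",
    "normalize_library_size",
    "mean_expression_by_celltype",
    "relative_expression",
    "gene_weights",
    "pathway_activity",
    "score_pathways",
    "permutation_pvalues",
    "aggregate_categories",
]


@dataclass
class PathwayActivity:
    """Pathway x cell-type activity scores with bookkeeping.

    Attributes
    ----------
    scores : DataFrame, pathway x cell type
        The activity score ``p[t, j]`` for every scored pathway.
    n_genes : Series
        Retained member-gene count per scored pathway (genes present in
        the expression matrix and not dropped as all-zero).
    unscored : dict
        Pathway -> human-readable reason it was not scored.
    dropped_genes : list of str
        Universe genes excluded because their per-type mean sums to zero
        (the relative-expression denominator would be zero).
    pvalues : DataFrame or None
        One-sided permutation p-values aligned with ``scores``; filled by
        :func:`permutation_pvalues`.
    pvalues_adj : DataFrame or None
        Benjamini-Hochberg adjusted p-values, when requested.
    n_perm : int or None
        Number of permutations behind ``pvalues``.
    """

    scores: pd.DataFrame
    n_genes: pd.Series
    unscored: dict[str, str] = field(default_factory=dict)
    dropped_genes: list[str] = field(default_factory=list)
    pvalues: pd.DataFrame | None = None
    pvalues_adj: pd.DataFrame | None = None
    n_perm: int | None = None


def _celltype_series(ann) -> pd.Series:
    """Accept an annotation DataFrame (column ``cell_type``) or a Series."""
    if isinstance(ann, pd.DataFrame):
        if "cell_type" not in ann.columns:
            raise InputError("annotation lacks a 'cell_type' column")
        return ann["cell_type"]
    return ann


def normalize_library_size(expr: pd.DataFrame, target: str = "median") -> pd.DataFrame:
    """Scale each cell so its total expression equals the median library size.

    Cells whose total is zero are left at zero. ``target='median'`` is the
    only supported policy; pass the raw matrix through where no
    normalization is wanted.
    """
    if target != "median":
        raise ConfigurationError(f"unknown normalization target {target!r}")
    libsize = expr.sum(axis=0).to_numpy(dtype=float)
    med = float(np.median(libsize[libsize > 0])) if (libsize > 0).any() else 0.0
    factors = np.divide(med, libsize, out=np.zeros_like(libsize), where=libsize > 0)
    return expr * factors


def mean_expression_by_celltype(
    expr: pd.DataFrame, ann, genes=None
) -> pd.DataFrame:
    """Mean expression of each gene over the cells of each type.

    Parameters
    ----------
    expr : DataFrame, genes x cells
        Nonnegative linear-scale expression.
    ann : DataFrame or Series
        Cell -> cell-type mapping (DataFrame uses its ``cell_type`` column);
        index must be cell ids present in ``expr``.
    genes : sequence of str, optional
        Restrict the result to these genes (those present in the matrix);
        typically the gene-set universe.

    Returns
    -------
    DataFrame, genes x cell types
        ``E[i, j] = sum_{k in type j} g[i, k] / n_j``.
    """
    types = _celltype_series(ann)
    unknown = types.index.difference(expr.columns)
    if len(unknown):
        raise InputError(f"annotation references cells absent from the matrix: {list(unknown[:5])}")
    if types.nunique() < 2:
        raise InputError("relative quantification needs at least 2 cell types")
    if genes is not None:
        genes = [g for g in genes if g in expr.index]
        if not genes:
            raise InputError("no overlap between requested genes and the expression matrix")
        expr = expr.loc[genes]
    sub = expr[types.index]
    E = sub.T.groupby(types).mean().T
    E.columns.name = "cell_type"
    return E


def relative_expression(E: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-type mean expression relative to the across-type average.

    Genes whose per-type means sum to zero are dropped (the formula is
    undefined there) and returned separately rather than divided.

    Returns
    -------
    (r, dropped) : DataFrame and list of gene ids
        For every retained gene the mean of ``r`` over types is 1.
    """
    if E.shape[1] < 2:
        raise InputError("relative expression needs at least 2 cell types")
    row_mean = E.mean(axis=1)
    retained = row_mean > 0
    dropped = E.index[~retained].tolist()
    r = E.loc[retained].div(row_mean[retained], axis=0)
    return r, dropped


def gene_weights(sets: GeneSetCollection) -> pd.Series:
    """Weight ``w_i = 1 / c_i`` for every gene in the collection's universe."""
    counts = sets.membership_counts()
    return pd.Series({g: 1.0 / c for g, c in counts.items()}, name="weight")


def pathway_activity(
    r: pd.DataFrame,
    weights: pd.Series,
    sets: GeneSetCollection,
    min_genes: int = 3,
) -> PathwayActivity:
    """Weighted-mean pathway activity score per cell type.

    A pathway is scored only when at least ``min_genes`` of its members
    survive in ``r``; smaller pathways are reported in ``unscored`` with
    the reason. The score is invariant to rescaling all weights by a
    positive constant (ratio form).
    """
    if min_genes < 1:
        raise ConfigurationError("min_genes must be >= 1")
    scores: dict[str, pd.Series] = {}
    n_genes: dict[str, int] = {}
    unscored: dict[str, str] = {}
    for name, members in sets.sets.items():
        retained = [g for g in members if g in r.index]
        if len(retained) < min_genes:
            unscored[name] = (
                f"{len(retained)} of {len(members)} member genes retained "
                f"(min_genes={min_genes})"
            )
            continue
        w = weights.loc[retained].to_numpy()
        scores[name] = pd.Series(w @ r.loc[retained].to_numpy() / w.sum(), index=r.columns)
        n_genes[name] = len(retained)
    if not scores:
        raise InputError("no pathway could be scored: empty overlap with the expression matrix")
    score_df = pd.DataFrame(scores).T
    score_df.index.name = "pathway"
    return PathwayActivity(
        scores=score_df,
        n_genes=pd.Series(n_genes, name="n_genes"),
        unscored=unscored,
    )


def score_pathways(
    expr: pd.DataFrame,
    ann,
    sets: GeneSetCollection,
    min_genes: int = 3,
    normalize: str = "median-libsize",
) -> PathwayActivity:
    """Convenience chain: normalize -> E -> r -> weighted pathway score."""
    if normalize not in ("median-libsize", "none"):
        raise ConfigurationError(f"unknown normalization {normalize!r}")
    if normalize == "median-libsize":
        expr = normalize_library_size(expr)
    E = mean_expression_by_celltype(expr, ann, genes=sets.universe)
    r, dropped = relative_expression(E)
    pa = pathway_activity(r, gene_weights(sets), sets, min_genes=min_genes)
    pa.dropped_genes = dropped
    return pa


def _score_matrix_setup(expr, types, sets, min_genes):
    """Precompute the fixed pieces of the score as dense arrays.

    Returns the genes x cells value block restricted to the universe,
    the per-type one-hot matrix, and a row-normalized weighted membership
    matrix A such that ``p = A @ r`` for the scored pathways. The set of
    retained genes (per-type means summing to zero) is label-permutation
    invariant because a gene's means sum to zero iff it is zero in every
    cell, so A is fixed across permutations.
    """
    genes = [g for g in sets.universe if g in expr.index]
    if not genes:
        raise InputError("no overlap between gene-set universe and the expression matrix")
    X = expr.loc[genes, types.index].to_numpy(dtype=float)
    type_labels = sorted(types.unique())
    codes = pd.Categorical(types, categories=type_labels).codes
    onehot = np.zeros((X.shape[1], len(type_labels)))
    onehot[np.arange(X.shape[1]), codes] = 1.0
    nonzero = X.sum(axis=1) > 0
    dropped = [g for g, keep in zip(genes, nonzero) if not keep]
    genes = [g for g, keep in zip(genes, nonzero) if keep]
    X = X[nonzero]
    gene_pos = {g: k for k, g in enumerate(genes)}
    counts = sets.membership_counts()
    rows, n_genes, unscored = [], {}, {}
    A_rows = []
    for name, members in sets.sets.items():
        retained = [g for g in members if g in gene_pos]
        if len(retained) < min_genes:
            unscored[name] = (
                f"{len(retained)} of {len(members)} member genes retained "
                f"(min_genes={min_genes})"
            )
            continue
        w = np.zeros(len(genes))
        for g in retained:
            w[gene_pos[g]] = 1.0 / counts[g]
        A_rows.append(w / w.sum())
        rows.append(name)
        n_genes[name] = len(retained)
    if not rows:
        raise InputError("no pathway could be scored: empty overlap with the expression matrix")
    return X, onehot, np.asarray(A_rows), rows, type_labels, n_genes, unscored, dropped


def _scores_from_onehot(X, onehot, A, n_types):
    """E -> r -> p for a block of stacked per-permutation one-hot columns.

    ``onehot`` holds ``b`` label assignments side by side (shape
    cells x b*n_types); the across-type normalization of r is applied
    within each assignment's block of columns. Returns shape
    (pathways, b, n_types).
    """
    n_j = onehot.sum(axis=0)
    E = (X @ onehot) / n_j
    E3 = E.reshape(X.shape[0], -1, n_types)
    r = E3 / E3.mean(axis=2, keepdims=True)
    return np.tensordot(A, r, axes=(1, 0))


def permutation_pvalues(
    expr: pd.DataFrame,
    ann,
    sets: GeneSetCollection,
    n_perm: int,
    seed: int,
    min_genes: int = 3,
    normalize: str = "median-libsize",
    adjust: str = "none",
    chunk: int = 64,
) -> PathwayActivity:
    """Permutation significance for cell-type-specific pathway activation.

    The null is generated by shuffling cell-type labels across all cells
    (the number of cells per type is preserved) and recomputing the full
    score chain each round. The one-sided empirical p-value for
    "specifically activated" counts permuted scores at least as large as
    the observed one, with the add-one correction::

        p = (1 + #{permuted p[t, j] >= observed p[t, j]}) / (n_perm + 1)

    so p is bounded below by ``1 / (n_perm + 1)`` and ties count toward
    the null. Deterministic given ``seed``.

    Parameters
    ----------
    n_perm : int
        Number of label shuffles; must be >= 1.
    seed : int
        Seed for the permutation stream (required; no hidden global state).
    adjust : {'none', 'bh'}
        Optional Benjamini-Hochberg adjustment across all scored
        (pathway, cell type) pairs, stored in ``pvalues_adj``.
    chunk : int
        Permutations evaluated per matrix product; a throughput knob with
        no effect on results.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if adjust not in ("none", "bh"):
        raise ConfigurationError(f"unknown adjustment {adjust!r}")
    if normalize not in ("median-libsize", "none"):
        raise ConfigurationError(f"unknown normalization {normalize!r}")
    types = _celltype_series(ann)
    unknown = types.index.difference(expr.columns)
    if len(unknown):
        raise InputError(f"annotation references cells absent from the matrix: {list(unknown[:5])}")
    if types.nunique() < 2:
        raise InputError("relative quantification needs at least 2 cell types")
    if normalize == "median-libsize":
        expr = normalize_library_size(expr)
    X, onehot, A, pathways, type_labels, n_genes, unscored, dropped = _score_matrix_setup(
        expr, types, sets, min_genes
    )
    n_cells, n_types = onehot.shape
    observed = _scores_from_onehot(X, onehot, A, n_types)[:, 0, :]

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        block = np.zeros((n_cells, n_types * b))
        for k in range(b):
            perm = rng.permutation(n_cells)
            block[:, k * n_types : (k + 1) * n_types] = onehot[perm]
        perm_scores = _scores_from_onehot(X, block, A, n_types)
        exceed += (perm_scores >= observed[:, None, :]).sum(axis=1)
        done += b

    pvals = (1.0 + exceed) / (n_perm + 1.0)
    scores = pd.DataFrame(observed, index=pathways, columns=type_labels)
    scores.index.name = "pathway"
    scores.columns.name = "cell_type"
    pa = PathwayActivity(
        scores=scores,
        n_genes=pd.Series(n_genes, name="n_genes"),
        unscored=unscored,
        dropped_genes=dropped,
        pvalues=pd.DataFrame(pvals, index=pathways, columns=type_labels),
        n_perm=n_perm,
    )
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        flat = pa.pvalues.to_numpy().ravel()
        adj = multipletests(flat, method="fdr_bh")[1].reshape(pa.pvalues.shape)
        pa.pvalues_adj = pd.DataFrame(adj, index=pathways, columns=type_labels)
    return pa


def aggregate_categories(
    pa: PathwayActivity, sets: GeneSetCollection, weight_by_size: bool = False
) -> pd.DataFrame:
    """Average member pathway scores within each category, per cell type.

    By default the category score is the unweighted mean over its scored
    member pathways; ``weight_by_size=True`` weights each pathway by its
    retained member-gene count instead.
    """
    if sets.categories is None:
        raise InputError("gene-set collection carries no category labels")
    missing = [p for p in pa.scores.index if p not in sets.categories]
    if missing:
        raise InputError(f"category labels missing for scored pathways: {sorted(missing)}")
    labels = pd.Series({p: sets.categories[p] for p in pa.scores.index})
    if weight_by_size:
        w = pa.n_genes.loc[pa.scores.index]
        weighted = pa.scores.mul(w, axis=0)
        out = weighted.groupby(labels).sum().div(w.groupby(labels).sum(), axis=0)
    else:
        out = pa.scores.groupby(labels).mean()
    out.index.name = "category"
    return out


def category_members(pa: PathwayActivity, sets: GeneSetCollection) -> dict[str, list[str]]:
    """Scored member pathways per category (each pathway in exactly one)."""
    if sets.categories is None:
        raise InputError("gene-set collection carries no category labels")
    members: dict[str, list[str]] = {}
    for p in pa.scores.index:
        members.setdefault(sets.categories[p], []).append(p)
    return members
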