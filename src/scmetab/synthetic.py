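"""Synthetic single-cell and bulk cohorts with known planted structure.

The generator emulates the shape of the data the scoring and DEG stages
consume, with ground truth recorded for recovery testing:

* pathways as overlapping gene sets (a controlled fraction of member
  slots is shared between pathways, so reciprocal-membership weights < 1
  actually occur), labelled round-robin with up to 11 KEGG-style
  metabolism categories;
* single-cell counts as negative binomial (gamma-Poisson) with per-cell
  log-normal library-size factors; planted (pathway, cell type, fold)
  effects multiply the member genes' means in that type before sampling;
* bulk cohorts as log2-normal expression with a cohort-specific global
  scale; planted DEGs shift the case group by a stated log2 magnitude
  with the same sign in every cohort.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .gene_sets import GeneSetCollection

# KEGG's top-level metabolism classes; pathway categories cycle over these.
KEGG_CATEGORIES = [
    "Carbohydrate metabolism",
    "Energy metabolism",
    "Lipid metabolism",
    "Nucleotide metabolism",
    "Amino acid metabolism",
    "Metabolism of other amino acids",
    "Glycan biosynthesis and metabolism",
    "Metabolism of cofactors and vitamins",
    "Metabolism of terpenoids and polyketides",
    "Biosynthesis of other secondary metabolites",
    "Xenobiotics biodegradation and metabolism",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Single-cell side: ``n_cell_types`` types x ``cells_per_type`` cells over
    ``n_genes`` genes, organized into ``n_pathways`` sets of
    ``genes_per_pathway`` genes with ``overlap_fraction`` of member slots
    shared between pathways. Counts are negative binomial around
    ``baseline_mean`` with shared ``dispersion``; per-cell library factors
    are log-normal with coefficient of variation ``libsize_cv``.
    ``celltype_baseline_sd`` (log2 units) optionally gives each type a
    distinct baseline profile; at 0 cells are exchangeable across types,
    the regime in which permutation p-values are calibrated.
    ``planted_effects`` multiplies the mean of a pathway's member genes in
    one cell type by a fold before sampling.

    Bulk side: ``n_bulk_cohorts`` cohorts of ``samples_per_group`` case and
    control samples each; log2 expression is normal with sd
    ``bulk_log2_sd`` around per-gene baselines (mean ``bulk_base_log2_mean``)
    plus a cohort-wide offset with sd ``bulk_scale_sd``. ``planted_degs``
    shifts case samples of a gene by +/- its log2 magnitude, same sign in
    every cohort.
    """

    n_cell_types: int = 5
    cells_per_type: int = 200
    n_genes: int = 500
    n_pathways: int = 20
    genes_per_pathway: int = 20
    overlap_fraction: float = 0.25
    baseline_mean: float = 2.0
    dispersion: float = 2.0
    celltype_baseline_sd: float = 0.0
    libsize_cv: float = 0.2
    n_samples_per_condition: int = 3
    planted_effects: list[tuple[str, str, float]] = field(default_factory=list)
    n_bulk_cohorts: int = 3
    samples_per_group: int = 10
    bulk_log2_sd: float = 0.2
    bulk_base_log2_mean: float = 6.0
    bulk_scale_sd: float = 0.5
    planted_degs: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    # -- deterministic naming of the generated universe ------------------
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def pathway_names(self) -> list[str]:
        width = len(str(self.n_pathways))
        return [f"P{i + 1:0{width}d}" for i in range(self.n_pathways)]

    def cell_type_names(self) -> list[str]:
        return [f"CT{i + 1}" for i in range(self.n_cell_types)]

    def n_borrowed(self) -> int:
        """Shared member slots borrowed per pathway after the first.

        Chosen so that roughly ``overlap_fraction`` of all membership slots
        belong to genes in >= 2 pathways: each borrowed gene makes 2 slots
        shared, hence k = f * P * g / (2 * (P - 1)).
        """
        if self.n_pathways < 2:
            return 0
        k = round(
            self.overlap_fraction
            * self.n_pathways
            * self.genes_per_pathway
            / (2 * (self.n_pathways - 1))
        )
        return min(int(k), self.genes_per_pathway)

    def validate(self) -> None:
        problems = []
        for name in (
            "n_cell_types", "cells_per_type", "n_genes", "n_pathways",
            "genes_per_pathway", "n_bulk_cohorts", "n_samples_per_condition",
        ):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if self.samples_per_group < 2:
            problems.append("samples_per_group must be >= 2 (a two-sample test is impossible)")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            problems.append("overlap_fraction must lie in [0, 1]")
        for name in ("baseline_mean", "dispersion"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        for name in ("libsize_cv", "celltype_baseline_sd", "bulk_log2_sd", "bulk_scale_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        distinct_needed = (
            self.n_pathways * self.genes_per_pathway
            - self.n_borrowed() * max(self.n_pathways - 1, 0)
        )
        if distinct_needed > self.n_genes:
            problems.append(
                f"infeasible pathway layout: {distinct_needed} distinct genes needed "
                f"for {self.n_pathways} pathways x {self.genes_per_pathway} genes at "
                f"overlap_fraction={self.overlap_fraction}, but n_genes={self.n_genes}"
            )
        pathways, types, genes = (
            set(self.pathway_names()), set(self.cell_type_names()), set(self.gene_names()),
        )
        for pw, ct, fold in self.planted_effects:
            if pw not in pathways:
                problems.append(f"planted effect references unknown pathway {pw!r}")
            if ct not in types:
                problems.append(f"planted effect references unknown cell type {ct!r}")
            if fold <= 0:
                problems.append(f"planted fold-change must be > 0, got {fold}")
        for gene, direction, mag in self.planted_degs:
            if gene not in genes:
                problems.append(f"planted DEG references unknown gene {gene!r}")
            if direction not in ("up", "down"):
                problems.append(f"planted DEG direction must be 'up' or 'down', got {direction!r}")
            if mag <= 0:
                problems.append(f"planted DEG log2 magnitude must be > 0, got {mag}")
        if problems:
            raise ConfigurationError("; ".join(problems))


@dataclass
class SyntheticTruth:
    """Record of every planted effect as realized in the emitted data."""

    planted_effects: list[dict] = field(default_factory=list)
    planted_degs: list[dict] = field(default_factory=list)
    library_factors: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(**d)


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    tag = int.from_bytes(stream.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def generate_pathway_sets(config: SimConfig) -> GeneSetCollection:
    """Overlapping pathway gene sets with round-robin category labels.

    Each pathway after the first borrows ``config.n_borrowed()`` genes
    from the pool of genes used exactly once so far, so the fraction of
    membership slots held by multi-pathway genes tracks
    ``overlap_fraction``; remaining members are fresh genes.
    """
    config.validate()
    rng = _child_rng(config.seed, "sets")
    genes = config.gene_names()
    order = list(rng.permutation(genes))
    fresh_iter = iter(order)
    k = config.n_borrowed()
    sets: dict[str, list[str]] = {}
    singletons: list[str] = []
    for name in config.pathway_names():
        members: list[str] = []
        if sets and k:
            n_borrow = min(k, len(singletons))
            picked = list(rng.choice(singletons, size=n_borrow, replace=False))
            for g in picked:
                singletons.remove(g)
            members.extend(picked)
        while len(members) < config.genes_per_pathway:
            g = next(fresh_iter)
            members.append(g)
            singletons.append(g)
        sets[name] = members
    n_cat = min(len(KEGG_CATEGORIES), config.n_pathways)
    categories = {
        name: KEGG_CATEGORIES[i % n_cat] for i, name in enumerate(config.pathway_names())
    }
    return GeneSetCollection(sets, categories)


def generate_sc_counts(
    config: SimConfig, sets: GeneSetCollection
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Negative-binomial single-cell counts with planted pathway effects.

    Returns (genes x cells count matrix, cell annotation, truth). Cells of
    every type are spread round-robin over the case and control samples;
    planted effects multiply member-gene means in the target type in all
    cells of that type.
    """
    config.validate()
    rng = _child_rng(config.seed, "sc")
    genes = config.gene_names()
    types = config.cell_type_names()
    n_cells = config.n_cell_types * config.cells_per_type

    base = config.baseline_mean * np.exp2(rng.normal(0.0, 1.0, size=config.n_genes))
    mean = np.tile(base[:, None], (1, config.n_cell_types))
    if config.celltype_baseline_sd > 0:
        mean = mean * np.exp2(
            rng.normal(0.0, config.celltype_baseline_sd, size=mean.shape)
        )
    gene_pos = {g: i for i, g in enumerate(genes)}
    type_pos = {t: j for j, t in enumerate(types)}
    truth = SyntheticTruth(seed=config.seed)
    for pw, ct, fold in config.planted_effects:
        members = [g for g in sets.sets[pw] if g in gene_pos]
        mean[[gene_pos[g] for g in members], type_pos[ct]] *= fold
        truth.planted_effects.append(
            {"pathway": pw, "cell_type": ct, "fold": float(fold), "genes": members}
        )

    # library-size factors: log-normal with unit mean and the stated CV
    if config.libsize_cv > 0:
        sigma = float(np.sqrt(np.log1p(config.libsize_cv**2)))
        lib = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_cells))
    else:
        lib = np.ones(n_cells)

    cell_type_codes = np.repeat(np.arange(config.n_cell_types), config.cells_per_type)
    mu = mean[:, cell_type_codes] * lib[None, :]
    lam = rng.gamma(shape=config.dispersion, scale=mu / config.dispersion)
    counts = rng.poisson(lam)

    cell_ids = [f"cell_{i + 1:05d}" for i in range(n_cells)]
    samples = [f"case_{i + 1}" for i in range(config.n_samples_per_condition)] + [
        f"control_{i + 1}" for i in range(config.n_samples_per_condition)
    ]
    # round-robin within each type so every sample sees every type
    sample_idx = np.concatenate(
        [np.arange(config.cells_per_type) % len(samples) for _ in types]
    )
    ann = pd.DataFrame(
        {
            "cell_type": [types[c] for c in cell_type_codes],
            "sample_id": [samples[i] for i in sample_idx],
            "condition": ["case" if samples[i].startswith("case") else "control" for i in sample_idx],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    truth.library_factors = {c: float(f) for c, f in zip(cell_ids, lib)}
    expr = pd.DataFrame(counts, index=genes, columns=cell_ids)
    return expr, ann, truth


def generate_bulk_cohorts(config: SimConfig):
    """Log2-normal bulk cohorts with consistent-sign planted DEGs.

    Returns (list of BulkCohort on linear scale, truth). Each cohort gets
    its own global log2 offset (nuisance scale); planted DEGs shift the
    case group by the stated magnitude with the same sign everywhere.
    """
    from .deg import BulkCohort  # local import to avoid a cycle

    config.validate()
    rng = _child_rng(config.seed, "bulk")
    genes = config.gene_names()
    gene_pos = {g: i for i, g in enumerate(genes)}
    base = rng.normal(config.bulk_base_log2_mean, 1.0, size=config.n_genes)
    shift = np.zeros(config.n_genes)
    truth = SyntheticTruth(seed=config.seed)
    for gene, direction, mag in config.planted_degs:
        delta = float(mag) if direction == "up" else -float(mag)
        shift[gene_pos[gene]] = delta
        truth.planted_degs.append(
            {
                "gene": gene,
                "direction": direction,
                "log2_effect": {f"cohort_{c + 1}": delta for c in range(config.n_bulk_cohorts)},
            }
        )
    cohorts = []
    n = config.samples_per_group
    for c in range(config.n_bulk_cohorts):
        cid = f"cohort_{c + 1}"
        offset = rng.normal(0.0, config.bulk_scale_sd)
        log2 = np.empty((2 * n, config.n_genes))
        log2[:n] = base + offset + shift + rng.normal(0.0, config.bulk_log2_sd, size=(n, config.n_genes))
        log2[n:] = base + offset + rng.normal(0.0, config.bulk_log2_sd, size=(n, config.n_genes))
        samples = [f"{cid}_case_{i + 1}" for i in range(n)] + [
            f"{cid}_control_{i + 1}" for i in range(n)
        ]
        values = pd.DataFrame(
            np.exp2(log2), index=pd.Index(samples, name="sample"), columns=genes
        )
        groups = pd.Series(["case"] * n + ["control"] * n, index=values.index, name="group")
        cohorts.append(BulkCohort(values=values, groups=groups, scale="linear", cohort_id=cid))
    return cohorts, truth
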