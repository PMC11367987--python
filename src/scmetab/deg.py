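"""Per-cohort differential expression and direction-consistent intersection.

Each bulk cohort (samples x genes, case vs control) is tested gene-by-gene
with a Welch two-sample t-test on log2-scale values. A gene is called
"up" when log2FC > fc_threshold and p < p_threshold, "down" when
log2FC < -fc_threshold and p < p_threshold (strict inequalities), else
"ns". The meta step intersects the calls across cohorts and keeps only
genes significant everywhere with the same sign; genes significant
everywhere but with conflicting signs are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigurationError, InputError

NEG_LOG10_P_CAP = 300.0  # cap for -log10(p) in volcano exports (p == 0 maps here)


@dataclass
class BulkCohort:
    """One case/control expression cohort.

    ``values`` is samples x genes on the declared ``scale`` ('linear' or
    'log2'); ``groups`` labels each sample 'case' or 'control'.
    """

    values: pd.DataFrame
    groups: pd.Series
    scale: str = "linear"
    cohort_id: str = "cohort"

    def __post_init__(self):
        if self.scale not in ("linear", "log2"):
            raise ConfigurationError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.values.columns.duplicated().any():
            raise InputError(f"cohort {self.cohort_id}: duplicate gene ids")
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise InputError(f"cohort {self.cohort_id}: unknown group labels {sorted(bad)}")
        for g in ("case", "control"):
            if (self.groups == g).sum() < 2:
                raise InputError(f"cohort {self.cohort_id}: group {g!r} has fewer than 2 samples")

    def log2_values(self) -> pd.DataFrame:
        """Values on log2 scale; linear inputs must be strictly positive."""
        if self.scale == "log2":
            return self.values
        arr = self.values.to_numpy()
        if (arr <= 0).any():
            s, g = np.argwhere(arr <= 0)[0]
            raise InputError(
                f"cohort {self.cohort_id}: nonpositive value for gene "
                f"{self.values.columns[g]!r} in sample {self.values.index[s]!r} "
                "on declared linear scale"
            )
        return pd.DataFrame(np.log2(arr), index=self.values.index, columns=self.values.columns)


@dataclass
class DEGTable:
    """Per-gene calls for one cohort: log2fc, p_value, direction."""

    table: pd.DataFrame
    cohort_id: str
    p_threshold: float
    fc_threshold: float

    def called(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "ns"]


@dataclass
class IntersectionResult:
    """Direction-consistent overlap across cohorts.

    ``up``/``down`` hold genes called with that direction in every cohort;
    ``conflicting`` holds genes significant everywhere but with mixed
    signs; ``any_direction`` is the unrestricted overlap of all three.
    ``evidence`` carries per-cohort log2fc and p for every overlapping gene.
    """

    up: list[str]
    down: list[str]
    conflicting: list[str]
    any_direction: list[str]
    evidence: pd.DataFrame
    per_cohort_counts: dict[str, dict[str, int]] = field(default_factory=dict)


def call_degs(
    cohort: BulkCohort, p_threshold: float = 0.05, fc_threshold: float = 1.0
) -> DEGTable:
    """Welch-t DEG calling for one cohort at the given cut-offs.

    log2FC is mean(case) - mean(control) on the log2 scale. Genes with
    zero variance in both groups and equal means get p = 1 (no evidence).
    """
    log2 = cohort.log2_values()
    case = log2.loc[cohort.groups == "case"].to_numpy()
    control = log2.loc[cohort.groups == "control"].to_numpy()
    logfc = case.mean(axis=0) - control.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, pval = scipy.stats.ttest_ind(case, control, axis=0, equal_var=False)
    pval = np.where(np.isnan(pval), 1.0, pval)
    stat = np.where(np.isnan(stat), 0.0, stat)
    direction = np.where(
        (pval < p_threshold) & (logfc > fc_threshold),
        "up",
        np.where((pval < p_threshold) & (logfc < -fc_threshold), "down", "ns"),
    )
    table = pd.DataFrame(
        {"log2fc": logfc, "t_statistic": stat, "p_value": pval, "direction": direction},
        index=log2.columns,
    )
    table.index.name = "gene"
    return DEGTable(table, cohort.cohort_id, p_threshold, fc_threshold)


def intersect_degs(tables: list[DEGTable]) -> IntersectionResult:
    """Cross-cohort overlap of DEG calls, partitioned by unanimous direction."""
    if len(tables) < 2:
        raise ConfigurationError("intersection needs at least 2 DEG tables")
    called = [set(t.called().index) for t in tables]
    overlap = sorted(set.intersection(*called))
    up, down, conflicting = [], [], []
    for gene in overlap:
        dirs = {t.table.loc[gene, "direction"] for t in tables}
        if dirs == {"up"}:
            up.append(gene)
        elif dirs == {"down"}:
            down.append(gene)
        else:
            conflicting.append(gene)
    evidence = pd.DataFrame(index=pd.Index(overlap, name="gene"))
    for t in tables:
        evidence[f"log2fc_{t.cohort_id}"] = t.table.loc[overlap, "log2fc"]
        evidence[f"p_{t.cohort_id}"] = t.table.loc[overlap, "p_value"]
    per_cohort = {
        t.cohort_id: {
            "n_deg": int((t.table["direction"] != "ns").sum()),
            "n_up": int((t.table["direction"] == "up").sum()),
            "n_down": int((t.table["direction"] == "down").sum()),
        }
        for t in tables
    }
    return IntersectionResult(
        up=up,
        down=down,
        conflicting=conflicting,
        any_direction=overlap,
        evidence=evidence,
        per_cohort_counts=per_cohort,
    )


def volcano_table(table: DEGTable, cap: float = NEG_LOG10_P_CAP) -> pd.DataFrame:
    """Per-gene (log2fc, -log10 p, direction) export; -log10 p capped at ``cap``."""
    with np.errstate(divide="ignore"):
        neglog = -np.log10(table.table["p_value"].to_numpy())
    out = pd.DataFrame(
        {
            "log2fc": table.table["log2fc"],
            "neg_log10_p": np.minimum(neglog, cap),
            "direction": table.table["direction"],
        },
        index=table.table.index,
    )
    return out
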