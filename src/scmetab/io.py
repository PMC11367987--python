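"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel either as a Matrix Market triplet directory
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, the 10x-style layout)
or as a dense genes x cells CSV. Cell annotations are TSV with columns
``cell_id, cell_type, sample_id, condition``. Pathways use GMT (one set per
line: name, description, tab-separated genes), with the category label
carried in the description field or in a separate two-column TSV. Bulk
cohorts are samples x genes CSV with a ``group`` column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import InputError
from .gene_sets import GeneSetCollection

ANNOTATION_COLUMNS = ["cell_id", "cell_type", "sample_id", "condition"]


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path, category_map: dict[str, str] | None = None) -> GeneSetCollection:
    """Read a GMT file; the description field, when non-empty and not 'na',
    is taken as the pathway's category label unless ``category_map`` overrides it."""
    sets: dict[str, list[str]] = {}
    categories: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InputError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
        name, desc, genes = fields[0], fields[1], fields[2:]
        if name in sets:
            raise InputError(f"duplicate pathway name in GMT: {name!r}")
        sets[name] = genes
        if desc and desc.lower() != "na":
            categories[name] = desc
    if category_map is not None:
        categories.update(category_map)
    return GeneSetCollection(sets, categories or None)


def write_gmt(sets: GeneSetCollection, path) -> None:
    lines = []
    for name, genes in sets.sets.items():
        desc = sets.categories.get(name, "na") if sets.categories else "na"
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_category_map(path) -> dict[str, str]:
    """Two-column TSV: pathway name, category label."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise InputError(f"category map lines need exactly 2 columns: {line!r}")
        out[fields[0]] = fields[1]
    return out


# ---------------------------------------------------------------------------
# Expression matrices

def read_expression_mtx(directory) -> pd.DataFrame:
    """Read a genes x cells matrix from matrix.mtx + features.tsv + barcodes.tsv."""
    directory = Path(directory)
    mat = scipy.io.mmread(directory / "matrix.mtx")
    genes = (directory / "features.tsv").read_text().split()
    cells = (directory / "barcodes.tsv").read_text().split()
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if dense.shape != (len(genes), len(cells)):
        raise InputError(
            f"matrix shape {dense.shape} does not match {len(genes)} features x {len(cells)} barcodes"
        )
    return pd.DataFrame(dense, index=genes, columns=cells)


def write_expression_mtx(expr: pd.DataFrame, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), scipy.sparse.csr_matrix(expr.to_numpy()))
    (directory / "features.tsv").write_text("\n".join(map(str, expr.index)) + "\n")
    (directory / "barcodes.tsv").write_text("\n".join(map(str, expr.columns)) + "\n")


def read_expression_csv(path) -> pd.DataFrame:
    """Dense genes x cells CSV, gene ids in the first column."""
    expr = pd.read_csv(path, index_col=0)
    validate_expression(expr)
    return expr


def validate_expression(expr: pd.DataFrame) -> None:
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate gene ids in expression matrix: {dupes[:5]}")
    if expr.columns.duplicated().any():
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise InputError(f"duplicate cell ids in expression matrix: {dupes[:5]}")
    values = expr.to_numpy()
    if not np.isfinite(values).all():
        raise InputError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise InputError("expression matrix contains negative values")


def read_expression(path) -> pd.DataFrame:
    """Dispatch on layout: a directory is MTX triplet, a file is dense CSV."""
    path = Path(path)
    expr = read_expression_mtx(path) if path.is_dir() else read_expression_csv(path)
    validate_expression(expr)
    return expr


# ---------------------------------------------------------------------------
# Cell annotation

def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise InputError(f"annotation file lacks required columns: {missing}")
    return ann.set_index("cell_id")


def write_annotation(ann: pd.DataFrame, path) -> None:
    out = ann.reset_index() if ann.index.name == "cell_id" else ann
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bulk cohorts

def read_bulk_csv(path, scale: str = "linear", cohort_id: str | None = None):
    """Samples x genes CSV with a ``group`` column; returns a BulkCohort."""
    from .deg import BulkCohort  # local import to avoid a cycle

    df = pd.read_csv(path, index_col=0)
    if "group" not in df.columns:
        raise InputError(f"bulk cohort CSV {path} lacks a 'group' column")
    groups = df["group"].astype(str)
    values = df.drop(columns="group").astype(float)
    cid = cohort_id if cohort_id is not None else Path(path).stem
    return BulkCohort(values=values, groups=groups, scale=scale, cohort_id=cid)


def write_bulk_csv(cohort, path) -> None:
    out = cohort.values.copy()
    out.insert(0, "group", cohort.groups)
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Simulation truth

def write_truth(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")


def read_truth(path):
    from .synthetic import SyntheticTruth

    return SyntheticTruth.from_dict(json.loads(Path(path).read_text()))
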