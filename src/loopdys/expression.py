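"""Cell-level count handling and the cell-averaged log fold-change.

The per-gene statistic used throughout is deliberately simple and
deterministic: depth-normalize every cell to a fixed library size,
average within (cell type, condition), and take a pseudocounted log2
ratio of the two condition means.  It is a point estimate of the
per-gene expression shift, not a significance test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CellByGeneMatrix",
    "GeneLogFC",
    "population_mean_expression",
    "cell_averaged_logfc",
]

DEFAULT_TARGET_SUM = 10_000.0


class CellByGeneMatrix:
    """Integer counts (cells x genes) with per-cell condition and cell-type labels.

    Parameters
    ----------
    counts
        Nonnegative integer matrix, cells in rows, genes in columns; dense
        ndarray or scipy sparse.
    cell_ids, gene_ids
        Unique barcodes / gene identifiers matching the matrix dimensions.
    cell_meta
        DataFrame indexed by barcode with columns ``condition`` and
        ``cell_type`` (one label each per cell).
    """

    def __init__(self, counts, cell_ids, gene_ids, cell_meta: pd.DataFrame):
        if sp.issparse(counts):
            counts = counts.tocsr()
        else:
            counts = np.asarray(counts)
        cell_ids = list(cell_ids)
        gene_ids = list(gene_ids)
        if counts.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(cell_ids)} cells x {len(gene_ids)} genes"
            )
        if len(set(cell_ids)) != len(cell_ids):
            raise ValueError("cell_ids must be unique")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("gene_ids must be unique")
        for col in ("condition", "cell_type"):
            if col not in cell_meta.columns:
                raise ValueError(f"cell_meta missing required column {col!r}")
        missing = set(cell_ids) - set(cell_meta.index)
        if missing:
            raise ValueError(f"cell_meta missing barcodes, e.g. {sorted(missing)[:3]}")
        data = counts.data if sp.issparse(counts) else counts
        if np.any(data < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(data, np.round(data)):
            raise ValueError("counts must be integers")
        self.counts = counts
        self.cell_ids = cell_ids
        self.gene_ids = gene_ids
        self.cell_meta = cell_meta.loc[cell_ids, ["condition", "cell_type"]].copy()

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def conditions(self) -> list[str]:
        return sorted(self.cell_meta["condition"].unique())

    def cell_types(self) -> list[str]:
        return sorted(self.cell_meta["cell_type"].unique())

    def select_mask(self, cell_type: str | None = None, condition: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_cells, dtype=bool)
        if cell_type is not None:
            mask &= (self.cell_meta["cell_type"] == cell_type).to_numpy()
        if condition is not None:
            mask &= (self.cell_meta["condition"] == condition).to_numpy()
        return mask


@dataclass
class GeneLogFC:
    """Per-gene log2 fold-change between two conditions within one population.

    ``values`` is a Series indexed by gene id; positive values mean higher
    expression in the numerator condition.
    """

    values: pd.Series
    condition_num: str
    condition_den: str
    population: str | None
    pseudocount: float
    log_base: int = 2

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("log fold-changes must be finite")

    def __getitem__(self, gene_id: str) -> float:
        return float(self.values[gene_id])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.values.index, "logfc": self.values.to_numpy()})


def _normalized(counts, target_sum: float) -> np.ndarray:
    """Scale each cell (row) to a fixed library size; all-zero cells stay zero."""
    if sp.issparse(counts):
        counts = np.asarray(counts.todense())
    counts = np.asarray(counts, dtype=float)
    depth = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(depth > 0, counts / depth * target_sum, 0.0)
    return scaled


def population_mean_expression(
    m: CellByGeneMatrix,
    population: str | None,
    condition: str | None,
    target_sum: float = DEFAULT_TARGET_SUM,
) -> pd.Series:
    """Per-gene mean of depth-normalized counts over one (cell type, condition).

    Each selected cell is scaled to ``target_sum`` total counts, then the
    arithmetic mean over cells is taken gene-wise.  Passing ``None`` for
    either label pools over that axis.
    """
    mask = m.select_mask(cell_type=population, condition=condition)
    if not mask.any():
        raise ValueError(
            f"no cells with cell_type={population!r}, condition={condition!r}"
        )
    sub = m.counts[mask]
    means = _normalized(sub, target_sum).mean(axis=0)
    return pd.Series(means, index=m.gene_ids)


def cell_averaged_logfc(
    m: CellByGeneMatrix,
    cond_num: str,
    cond_den: str,
    population: str | None = None,
    pseudocount: float = 1.0,
    target_sum: float = DEFAULT_TARGET_SUM,
) -> GeneLogFC:
    """log2 ratio of pseudocounted condition means of normalized expression.

    logfc(g) = log2((mean_num(g) + pc) / (mean_den(g) + pc)) with means from
    :func:`population_mean_expression`.  Antisymmetric in the condition pair.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    for cond in (cond_num, cond_den):
        if cond not in set(m.cell_meta["condition"]):
            raise ValueError(f"condition {cond!r} absent from cell metadata")
    mean_num = population_mean_expression(m, population, cond_num, target_sum)
    mean_den = population_mean_expression(m, population, cond_den, target_sum)
    logfc = np.log2((mean_num + pseudocount) / (mean_den + pseudocount))
    return GeneLogFC(
        values=logfc,
        condition_num=cond_num,
        condition_den=cond_den,
        population=population,
        pseudocount=pseudocount,
    )
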