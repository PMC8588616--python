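"""Ligand-receptor pairing between two annotated cell populations.

Given a curated table of ligand-receptor gene pairs, report for each
pair the mean normalized expression and detection fraction of the
ligand in a sender population and of the receptor in a receiver
population.  A pair is a candidate paracrine interaction
(``expressed_in_both``) when both genes are detected (count > 0) in at
least ``min_frac`` of the respective population's cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .expression import CellByGeneMatrix, population_mean_expression

__all__ = ["LRPairTable", "PairResult", "detect_pairs"]


class LRPairTable:
    """Unique (ligand, receptor) gene-id pairs."""

    def __init__(self, pairs: pd.DataFrame):
        for col in ("ligand", "receptor"):
            if col not in pairs.columns:
                raise ValueError(f"pair table missing column {col!r}")
        pairs = pairs[["ligand", "receptor"]].astype(str)
        if pairs.duplicated().any():
            raise ValueError("duplicate (ligand, receptor) rows in pair table")
        self.pairs = pairs.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def transposed(self) -> "LRPairTable":
        """Swap the ligand and receptor roles (for mirrored analyses)."""
        return LRPairTable(
            self.pairs.rename(columns={"ligand": "receptor", "receptor": "ligand"})
        )


@dataclass
class PairResult:
    ligand: str
    receptor: str
    ligand_mean: float
    ligand_frac: float
    receptor_mean: float
    receptor_frac: float
    expressed_in_both: bool


def _detection_fraction(m: CellByGeneMatrix, mask: np.ndarray) -> pd.Series:
    sub = m.counts[mask]
    if sp.issparse(sub):
        frac = np.asarray((sub > 0).mean(axis=0)).ravel()
    else:
        frac = (np.asarray(sub) > 0).mean(axis=0)
    return pd.Series(frac, index=m.gene_ids)


def detect_pairs(
    m: CellByGeneMatrix,
    ligand_pop: str,
    receptor_pop: str,
    pairs: LRPairTable,
    min_frac: float = 0.10,
) -> tuple[list[PairResult], list[tuple[str, str]]]:
    """Evaluate ligand-receptor pairs between a sender and receiver population.

    Returns (results sorted by descending ligand mean, skipped pairs whose
    genes are absent from the matrix).  ``min_frac`` is the detection
    fraction both genes must reach for ``expressed_in_both``.
    """
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError(f"min_frac must be in [0, 1], got {min_frac}")
    known = set(m.cell_meta["cell_type"])
    for pop in (ligand_pop, receptor_pop):
        if pop not in known:
            raise ValueError(f"unknown cell-type label {pop!r}; have {sorted(known)}")

    lig_mask = m.select_mask(cell_type=ligand_pop)
    rec_mask = m.select_mask(cell_type=receptor_pop)
    lig_mean = population_mean_expression(m, ligand_pop, None)
    rec_mean = population_mean_expression(m, receptor_pop, None)
    lig_frac = _detection_fraction(m, lig_mask)
    rec_frac = _detection_fraction(m, rec_mask)

    gene_index = set(m.gene_ids)
    results: list[PairResult] = []
    skipped: list[tuple[str, str]] = []
    for lig, rec in pairs.pairs.itertuples(index=False):
        if lig not in gene_index or rec not in gene_index:
            skipped.append((lig, rec))
            continue
        lf, rf = float(lig_frac[lig]), float(rec_frac[rec])
        results.append(
            PairResult(
                ligand=lig,
                receptor=rec,
                ligand_mean=float(lig_mean[lig]),
                ligand_frac=lf,
                receptor_mean=float(rec_mean[rec]),
                receptor_frac=rf,
                expressed_in_both=(lf >= min_frac) and (rf >= min_frac),
            )
        )
    results.sort(key=lambda r: (-r.ligand_mean, r.ligand, r.receptor))
    return results, skipped
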