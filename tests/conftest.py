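import numpy as np
import pandas as pd
import pytest

from loopdys.expression import CellByGeneMatrix
from loopdys.intervals import Gene, GeneSet, GenomicInterval, Peak, PeakSet


def make_matrix(counts, conditions, cell_types=None, gene_ids=None):
    """CellByGeneMatrix from a dense array plus per-cell labels."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cell_ids = [f"c{i}" for i in range(n_cells)]
    gene_ids = gene_ids or [f"g{j}" for j in range(n_genes)]
    cell_types = cell_types or ["neoplastic"] * n_cells
    meta = pd.DataFrame(
        {"condition": conditions, "cell_type": cell_types},
        index=pd.Index(cell_ids, name="barcode"),
    )
    return CellByGeneMatrix(counts, cell_ids, gene_ids, meta)


def make_peakset(intervals, label="A"):
    """PeakSet from (chrom, start, end) triples."""
    return PeakSet(
        [Peak(GenomicInterval(c, s, e)) for c, s, e in intervals], condition_label=label
    )


def make_geneset(entries):
    """GeneSet from (id, chrom, start, end[, strand]) tuples."""
    genes = []
    for entry in entries:
        gid, chrom, start, end = entry[:4]
        strand = entry[4] if len(entry) > 4 else "+"
        genes.append(Gene(gid, gid.upper(), GenomicInterval(chrom, start, end, strand)))
    return GeneSet(genes)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
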