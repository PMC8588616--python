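"""Readers and writers for the standard text formats the pipeline consumes.

BED/BEDPE intervals are 0-based half-open.  Count matrices use
MatrixMarket (``matrix.mtx``) with ``barcodes.tsv`` / ``features.tsv``
sidecars plus a ``cell_meta.tsv`` table (barcode, condition, cell_type).
All writers emit sorted, tab-delimited, newline-terminated files.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .expression import CellByGeneMatrix, GeneLogFC
from .intervals import CellQCRecord, Gene, GeneSet, GenomicInterval, Peak, PeakSet
from .loops import Loop, LoopSet
from .pairing import LRPairTable
from .profiles import FragmentTable

GENE_COLUMNS = ["chrom", "start", "end", "strand", "id", "symbol"]


# ---------------------------------------------------------------- BED peaks

def read_bed(path: str | Path, condition_label: str = "") -> PeakSet:
    """Read peaks from BED3 or BED6 (name/score/strand optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >= 3 columns, got {df.shape[1]}")
    peaks = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) >= 6 and row[5] in ("+", "-") else "."
        score = float(row[4]) if len(row) >= 5 and not pd.isna(row[4]) else None
        peaks.append(
            Peak(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand), score)
        )
    label = condition_label or Path(path).stem
    return PeakSet(peaks, condition_label=label)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            score = 0.0 if p.score is None else p.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t{score:g}\t{iv.strand}\n"
            )


# --------------------------------------------------------------- gene table

def read_gene_table(path: str | Path) -> GeneSet:
    """Read a TSV gene table (header: chrom, start, end, strand, id, symbol)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene table missing columns {missing}")
    genes = [
        Gene(
            id=str(r.id),
            symbol=str(r.symbol),
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end), str(r.strand)),
        )
        for r in df.itertuples(index=False)
    ]
    return GeneSet(genes)


def write_gene_table(genes: GeneSet, path: str | Path) -> None:
    rows = [
        {
            "chrom": g.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "strand": g.interval.strand,
            "id": g.id,
            "symbol": g.symbol,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- BEDPE loops

def read_bedpe(path: str | Path) -> LoopSet:
    """Read loops as BEDPE: chrom1 start1 end1 chrom2 start2 end2 name."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BEDPE needs >= 6 columns, got {df.shape[1]}")
    loops = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = str(row[6]) if len(row) >= 7 else f"loop_{i}"
        loops.append(
            Loop(
                id=name,
                anchor_a=GenomicInterval(str(row[0]), int(row[1]), int(row[2])),
                anchor_b=GenomicInterval(str(row[3]), int(row[4]), int(row[5])),
            )
        )
    return LoopSet(loops)


def write_bedpe(loops: LoopSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for l in loops:
            a, b = l.anchor_a, l.anchor_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{l.id}\n"
            )


# ------------------------------------------------------------- count matrix

def read_counts(directory: str | Path) -> CellByGeneMatrix:
    """Read MTX counts plus barcodes/features/cell_meta sidecars."""
    d = Path(directory)
    counts = sio.mmread(d / "matrix.mtx").tocsr()
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    features = pd.read_csv(d / "features.tsv", sep="\t", header=None)[0].astype(str).tolist()
    meta = pd.read_csv(d / "cell_meta.tsv", sep="\t").set_index("barcode")
    meta.index = meta.index.astype(str)
    return CellByGeneMatrix(counts, barcodes, features, meta)


def write_counts(m: CellByGeneMatrix, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    mat = m.counts if sp.issparse(m.counts) else sp.coo_matrix(m.counts)
    sio.mmwrite(str(d / "matrix.mtx"), mat.tocoo(), field="integer")
    pd.Series(m.cell_ids).to_csv(d / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(m.gene_ids).to_csv(d / "features.tsv", sep="\t", index=False, header=False)
    m.cell_meta.rename_axis("barcode").reset_index().to_csv(
        d / "cell_meta.tsv", sep="\t", index=False
    )


# ------------------------------------------------------------------- logFC

def write_logfc(logfc: GeneLogFC, path: str | Path) -> None:
    """Write per-gene log fold-changes with provenance comment lines."""
    with open(path, "w") as fh:
        fh.write(f"# condition_num={logfc.condition_num}\n")
        fh.write(f"# condition_den={logfc.condition_den}\n")
        fh.write(f"# population={logfc.population}\n")
        fh.write(f"# pseudocount={logfc.pseudocount:g}\n")
        fh.write(f"# log_base={logfc.log_base}\n")
        fh.write("gene_id\tlogfc\n")
        for gene, val in logfc.values.items():
            fh.write(f"{gene}\t{val:.10g}\n")


def read_logfc(path: str | Path) -> GeneLogFC:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    values = pd.Series(df["logfc"].to_numpy(), index=df["gene_id"].astype(str))
    pop = meta.get("population")
    return GeneLogFC(
        values=values,
        condition_num=meta.get("condition_num", "A"),
        condition_den=meta.get("condition_den", "B"),
        population=None if pop in (None, "None") else pop,
        pseudocount=float(meta.get("pseudocount", 1.0)),
        log_base=int(meta.get("log_base", 2)),
    )


# --------------------------------------------------------------- fragments

def read_fragments(path: str | Path) -> FragmentTable:
    """Read a 4-column fragment TSV (chrom, start, end, barcode); .gz allowed."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "barcode"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "barcode": str},
    )
    return FragmentTable(df)


def write_fragments(frags: FragmentTable, path: str | Path) -> None:
    frags.df.to_csv(path, sep="\t", index=False, header=False)


# ----------------------------------------------------------------- QC table

def read_qc_table(path: str | Path) -> list[CellQCRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        CellQCRecord(str(r.barcode), int(r.n_fragments), float(r.promoter_ratio))
        for r in df.itertuples(index=False)
    ]


def write_qc_table(records: list[CellQCRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"barcode": r.barcode, "n_fragments": r.n_fragments, "promoter_ratio": r.promoter_ratio}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------- LR pairs

def read_pair_table(path: str | Path) -> LRPairTable:
    return LRPairTable(pd.read_csv(path, sep="\t"))


def write_pair_table(pairs: LRPairTable, path: str | Path) -> None:
    pairs.pairs.to_csv(path, sep="\t", index=False)
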