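"""Coordinate-bearing record types and interval arithmetic.

All coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  Two intervals on the same chromosome overlap iff
``a.start < b.end and b.start < a.end``; abutting intervals do not
overlap and have gap distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Gene",
    "GeneSet",
    "Peak",
    "PeakSet",
    "CellQCRecord",
    "overlaps",
    "find_overlaps_batch",
    "differential_peaks",
    "assign_peaks_to_genes",
    "atac_cell_qc",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >= 1 bp on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in bp between two intervals; 0 if they overlap or abut.

    Returns None for intervals on different chromosomes.
    """
    if a.chrom != b.chrom:
        return None
    return max(0, a.start - b.end, b.start - a.end)


@dataclass(frozen=True)
class Gene:
    """A gene body with a strand-aware transcription start site."""

    id: str
    symbol: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        # strand-aware start: leftmost base for '+', rightmost for '-'
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class GeneSet:
    """Genes sorted by (chrom, tss) with unique ids."""

    def __init__(self, genes: Iterable[Gene]):
        genes = sorted(genes, key=lambda g: (g.chrom, g.tss, g.id))
        ids = [g.id for g in genes]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate gene ids: {sorted(dupes)[:5]}")
        self.genes: list[Gene] = genes
        self._by_id = {g.id: g for g in genes}
        self._chrom_index: dict[str, list[Gene]] = {}
        for g in genes:
            self._chrom_index.setdefault(g.chrom, []).append(g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chrom_index)

    def on_chrom(self, chrom: str) -> list[Gene]:
        """Genes on one chromosome, ascending TSS."""
        return self._chrom_index.get(chrom, [])


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    score: float | None = None

    def __post_init__(self) -> None:
        if self.score is not None and self.score < 0:
            raise ValueError(f"peak score must be >= 0, got {self.score}")


class PeakSet:
    """An ordered, deduplicated collection of peaks for one condition.

    Peaks are kept sorted by (chrom, start, end); identical intervals are
    rejected so that set arithmetic between conditions is well defined.
    """

    def __init__(self, peaks: Iterable[Peak], condition_label: str = ""):
        peaks = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
        keys = [(p.interval.chrom, p.interval.start, p.interval.end) for p in peaks]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate peak intervals in set {condition_label!r}")
        self.peaks: list[Peak] = peaks
        self.condition_label = condition_label
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for i, p in enumerate(peaks):
            by_chrom.setdefault(p.interval.chrom, []).append((p.interval.start, p.interval.end, i))
        self._chrom_arrays = {
            c: (
                np.array([t[0] for t in v], dtype=np.int64),
                np.array([t[1] for t in v], dtype=np.int64),
                np.array([t[2] for t in v], dtype=np.int64),
            )
            for c, v in by_chrom.items()
        }

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, global indices) for one chromosome, start-sorted."""
        return self._chrom_arrays.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int64)),
        )


def find_overlaps_batch(
    query: PeakSet, subject: PeakSet
) -> list[tuple[int, int]]:
    """All (query index, subject index) pairs of overlapping peaks.

    Output is sorted by query index then subject index.  Equivalent to the
    all-pairs test ``overlaps(q.interval, s.interval)`` but uses the
    start-sorted order for a prefix cut.
    """
    out: list[tuple[int, int]] = []
    for qi, q in enumerate(query.peaks):
        starts, ends, idx = subject.chrom_arrays(q.interval.chrom)
        if len(starts) == 0:
            continue
        # subject.start < q.end gives a sorted prefix; filter on end > q.start
        hi = int(np.searchsorted(starts, q.interval.end, side="left"))
        hit = ends[:hi] > q.interval.start
        for si in idx[:hi][hit]:
            out.append((qi, int(si)))
    return out


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def differential_peaks(
    set_a: PeakSet, set_b: PeakSet, min_overlap: int = 1
) -> PeakSet:
    """Peaks of A with no >= ``min_overlap`` bp overlap against any peak of B.

    A simplified differential-peak call: a site is condition-A specific if
    condition B shows no peak at that location.  ``min_overlap`` (bp) is the
    minimum shared length for two peaks to count as the same site.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1 bp, got {min_overlap}")
    shared: set[int] = set()
    for qi, si in find_overlaps_batch(set_a, set_b):
        if overlap_length(set_a[qi].interval, set_b[si].interval) >= min_overlap:
            shared.add(qi)
    label = f"{set_a.condition_label}_specific" if set_a.condition_label else "A_specific"
    return PeakSet(
        (p for i, p in enumerate(set_a.peaks) if i not in shared),
        condition_label=label,
    )


def assign_peaks_to_genes(
    peaks: PeakSet, genes: GeneSet, max_dist: int = 25_000
) -> list[tuple[Peak, str | None, int | None]]:
    """Assign each peak to the nearest gene body within ``max_dist`` bp.

    Distance is the gap between the half-open peak and gene-body intervals
    (0 when they overlap or abut).  Ties are broken by the lexicographically
    smallest gene id; peaks farther than ``max_dist`` from every gene get
    ``(peak, None, None)``.
    """
    if max_dist < 0:
        raise ValueError(f"max_dist must be >= 0, got {max_dist}")
    chrom_cache: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in genes.chroms:
        gl = sorted(genes.on_chrom(chrom), key=lambda g: (g.interval.start, g.id))
        chrom_cache[chrom] = (
            np.array([g.interval.start for g in gl], dtype=np.int64),
            np.array([g.interval.end for g in gl], dtype=np.int64),
            [g.id for g in gl],
        )
    out: list[tuple[Peak, str | None, int | None]] = []
    for p in peaks:
        entry = chrom_cache.get(p.interval.chrom)
        if entry is None:
            out.append((p, None, None))
            continue
        starts, ends, ids = entry
        dist = np.maximum(0, np.maximum(starts - p.interval.end, p.interval.start - ends))
        best = int(dist.min())
        if best > max_dist:
            out.append((p, None, None))
            continue
        tied = [ids[i] for i in np.flatnonzero(dist == best)]
        out.append((p, min(tied), best))
    return out


@dataclass(frozen=True)
class CellQCRecord:
    """Per-barcode QC summary for scATAC fragments."""

    barcode: str
    n_fragments: int
    promoter_ratio: float

    def __post_init__(self) -> None:
        if self.n_fragments < 0:
            raise ValueError(f"n_fragments must be >= 0, got {self.n_fragments}")
        if not 0.0 <= self.promoter_ratio <= 1.0:
            raise ValueError(
                f"promoter_ratio must be in [0, 1], got {self.promoter_ratio} "
                f"for barcode {self.barcode}"
            )


def atac_cell_qc(
    records: Sequence[CellQCRecord],
    min_fragments: int = 1000,
    min_promoter_ratio: float = 0.2,
) -> pd.DataFrame:
    """Apply strict fragment-count and promoter-ratio thresholds per barcode.

    A cell passes iff ``n_fragments > min_fragments`` AND
    ``promoter_ratio > min_promoter_ratio`` (both inequalities strict, so
    a cell sitting exactly on a threshold fails).
    """
    rows = [
        {
            "barcode": r.barcode,
            "n_fragments": r.n_fragments,
            "promoter_ratio": r.promoter_ratio,
            "qc_pass": (r.n_fragments > min_fragments)
            and (r.promoter_ratio > min_promoter_ratio),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["barcode", "n_fragments", "promoter_ratio", "qc_pass"])
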