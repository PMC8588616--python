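"""Chromatin loops: gene membership and boundary-peak classification.

A loop is a genomic span held together by two CTCF-bound anchor
(boundary) domains.  A loop is *direct* when a differential peak falls
in one of its own boundary domains, *indirect* when its span overlaps a
direct loop's span, and *unaffected* otherwise.  The three labels are
mutually exclusive with precedence direct > indirect > unaffected, so
the reported fractions partition the loop set.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Iterator

import numpy as np

from .intervals import GeneSet, GenomicInterval, PeakSet, overlaps

__all__ = ["Loop", "LoopSet", "LoopClassLabel", "genes_in_loop", "classify_loops"]

LABELS = ("direct", "indirect", "unaffected")


@dataclass(frozen=True)
class Loop:
    """A chromatin loop: two boundary anchors and the span between them."""

    id: str
    anchor_a: GenomicInterval
    anchor_b: GenomicInterval

    def __post_init__(self) -> None:
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValueError(f"loop {self.id}: anchors on different chromosomes")
        if self.anchor_a.end > self.anchor_b.start:
            raise ValueError(
                f"loop {self.id}: anchorA must end before anchorB starts "
                f"({self.anchor_a.end} > {self.anchor_b.start})"
            )

    @property
    def chrom(self) -> str:
        return self.anchor_a.chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.anchor_a.start, self.anchor_b.end)


class LoopSet:
    """Loops sorted by (chrom, span start) with unique ids."""

    def __init__(self, loops: Iterable[Loop]):
        loops = sorted(loops, key=lambda l: (l.chrom, l.span.start, l.span.end, l.id))
        ids = [l.id for l in loops]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate loop ids")
        self.loops: list[Loop] = loops
        self._by_id = {l.id: l for l in loops}

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self) -> Iterator[Loop]:
        return iter(self.loops)

    def __getitem__(self, loop_id: str) -> Loop:
        return self._by_id[loop_id]


@dataclass(frozen=True)
class LoopClassLabel:
    loop_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


def genes_in_loop(loop: Loop, genes: GeneSet) -> list[str]:
    """Ids of genes whose TSS lies in ``[span.start, span.end)``, by TSS order."""
    span = loop.span
    members = [
        g for g in genes.on_chrom(loop.chrom) if span.start <= g.tss < span.end
    ]
    members.sort(key=lambda g: (g.tss, g.id))
    return [g.id for g in members]


def _flanked(iv: GenomicInterval, flank: int) -> GenomicInterval:
    return GenomicInterval(iv.chrom, max(0, iv.start - flank), iv.end + flank, iv.strand)


def classify_loops(
    loops: LoopSet,
    diff_peaks: PeakSet,
    boundary_flank: int = 0,
) -> tuple[list[LoopClassLabel], dict]:
    """Label each loop direct / indirect / unaffected.

    direct
        a differential peak overlaps anchor A or anchor B, each extended by
        ``boundary_flank`` bp on both sides (the boundary domain);
    indirect
        not direct, but the loop's span overlaps the span of >= 1 direct loop;
    unaffected
        neither.

    Indirectness is computed against the final direct set only and does not
    chain through indirect loops.  Returns the per-loop labels plus a summary
    dict with counts and exact fractions (computed rationally; they sum to 1).
    """
    if boundary_flank < 0:
        raise ValueError(f"boundary_flank must be >= 0, got {boundary_flank}")

    direct_ids: set[str] = set()
    for loop in loops:
        domains = (_flanked(loop.anchor_a, boundary_flank), _flanked(loop.anchor_b, boundary_flank))
        for dom in domains:
            starts, ends, _ = diff_peaks.chrom_arrays(dom.chrom)
            hi = int(np.searchsorted(starts, dom.end, side="left"))
            if np.any(ends[:hi] > dom.start):
                direct_ids.add(loop.id)
                break

    direct_spans = [loops[i].span for i in direct_ids]
    labels: list[LoopClassLabel] = []
    for loop in loops:
        if loop.id in direct_ids:
            label = "direct"
        elif any(
            overlaps(loop.span, s)
            for s in direct_spans
        ):
            label = "indirect"
        else:
            label = "unaffected"
        labels.append(LoopClassLabel(loop.id, label))

    n = len(loops)
    counts = {lab: sum(1 for l in labels if l.label == lab) for lab in LABELS}
    fractions = {lab: (Fraction(c, n) if n else Fraction(0)) for lab, c in counts.items()}
    assert n == 0 or sum(fractions.values()) == 1
    summary = {
        "n_loops": n,
        "counts": counts,
        "fractions": {lab: float(f) for lab, f in fractions.items()},
        "fractions_exact": {lab: f"{f.numerator}/{f.denominator}" for lab, f in fractions.items()},
        "boundary_flank": boundary_flank,
        "indirect_rule": "span_overlap_with_direct_loop",
    }
    return labels, summary
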