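"""Seeded generators for every input the pipeline consumes.

The generator emulates the statistical structure the analysis assumes:

* evenly spaced genes on a small set of chromosomes, with non-overlapping
  chromatin loops each spanning a run of consecutive genes;
* negative-binomial single-cell counts in two conditions (WT / KO), with a
  multiplicative, loop-coordinated fold-change applied to the member genes
  of designated "effect" loops in the KO condition;
* per-condition CTCF peak sets in which every loop anchor carries a WT
  peak, KO loses anchor peaks at a configurable rate (always at effect
  loops), and background peaks are shared between conditions;
* fragment pile-ups enriched around site midpoints for meta-profile tests.

Every generator is a pure function of the configuration: the same seed
produces byte-identical outputs.  Counts follow NB(mu, theta) with
variance mu + mu^2/theta (theta is the size/dispersion parameter).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CellByGeneMatrix
from .intervals import CellQCRecord, Gene, GeneSet, GenomicInterval, Peak, PeakSet
from .loops import Loop, LoopSet, genes_in_loop
from .pairing import LRPairTable
from .profiles import FragmentTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome_and_loops",
    "simulate_counts",
    "simulate_peak_sets",
    "simulate_fragments",
    "simulate_qc_table",
    "simulate_pair_table",
    "simulate_all",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the default study conditions.

    Defaults give 4 chromosomes x 750 genes, 500 five-gene loops of which
    50 carry a 2-fold coordinated KO up-regulation, 200 cells per
    condition at ~10 mean counts/gene, NB size 0.5, and a 50% KO anchor
    peak loss (always lost at effect loops).
    """

    seed: int = 0
    # genome / loops
    n_chroms: int = 4
    genes_per_chrom: int = 750
    gene_spacing: int = 50_000
    gene_length: int = 5_000
    n_loops: int = 500
    genes_per_loop: int = 5
    n_effect_loops: int = 50
    anchor_width: int = 1_000
    # expression
    fold_change: float = 2.0
    effect_jitter_sd: float = 0.0
    n_cells_per_condition: int = 200
    n_extra_cells_per_condition: int = 0
    extra_cell_type: str = "myeloid"
    mean_depth: float = 30_000.0
    dispersion: float = 0.5
    base_mean_sigma: float = 0.5
    min_gene_mean: float = 5.0
    condition_a: str = "WT"
    condition_b: str = "KO"
    cell_type: str = "neoplastic"
    # peaks
    anchor_peak_loss_frac: float = 0.5
    background_peaks_per_chrom: int = 50
    peak_width: int = 400
    # fragments
    fragment_enrichment: float = 5.0
    n_fragments: int = 20_000
    fragment_length: int = 100
    fragment_site_sd: float = 50.0
    n_fragment_barcodes: int = 50
    # QC table
    n_qc_cells: int = 500
    # LR pairs
    n_lr_pairs: int = 20

    def __post_init__(self) -> None:
        positive = [
            "n_chroms", "genes_per_chrom", "gene_spacing", "gene_length",
            "n_loops", "genes_per_loop", "anchor_width", "n_cells_per_condition",
            "peak_width", "n_fragments", "fragment_length", "n_fragment_barcodes",
            "n_qc_cells",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion (NB size) must be > 0, got {self.dispersion}")
        if self.fragment_enrichment < 1.0:
            raise ValueError("fragment_enrichment must be >= 1")
        if not 0.0 <= self.anchor_peak_loss_frac <= 1.0:
            raise ValueError("anchor_peak_loss_frac must be in [0, 1]")
        if self.fold_change < 0:
            raise ValueError("fold_change must be >= 0")
        if self.n_effect_loops > self.n_loops:
            raise ValueError("n_effect_loops cannot exceed n_loops")
        if self.gene_spacing <= self.gene_length + self.anchor_width:
            raise ValueError(
                "gene_spacing must exceed gene_length + anchor_width so loop "
                "spans cannot capture neighboring genes"
            )
        # each loop occupies genes_per_loop genes plus one spacer gene
        capacity = self.n_chroms * (self.genes_per_chrom // (self.genes_per_loop + 1))
        if self.n_loops > capacity:
            raise ValueError(
                f"{self.n_loops} loops of {self.genes_per_loop} genes do not fit in "
                f"{self.n_chroms} x {self.genes_per_chrom} genes (capacity {capacity})"
            )

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream keyed on (seed, stream)."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """What the generator actually planted, for end-to-end checks."""

    effect_loop_ids: list[str]
    gene_fold_change: dict[str, float]
    peak_retention: dict[str, bool]  # WT anchor-peak key -> retained in KO

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def simulate_genome_and_loops(cfg: SimulationConfig) -> tuple[GeneSet, LoopSet, GroundTruth]:
    """Evenly spaced genes plus non-overlapping loops over consecutive genes.

    Loop anchors flank the first and last member gene; spacer genes between
    loops guarantee spans are pairwise disjoint and contain exactly
    ``genes_per_loop`` TSSs.
    """
    rng = cfg.rng(1)
    genes: list[Gene] = []
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        for i in range(cfg.genes_per_chrom):
            start = 100_000 + i * cfg.gene_spacing
            strand = "+" if (i + c) % 2 == 0 else "-"
            gid = f"g{c + 1}_{i:04d}"
            genes.append(
                Gene(gid, gid.upper(), GenomicInterval(chrom, start, start + cfg.gene_length, strand))
            )
    gene_set = GeneSet(genes)

    # distribute loops across chromosomes, then place each chromosome's
    # loops at jittered even strides of (L + 1) gene slots
    L = cfg.genes_per_loop
    per_chrom = [cfg.n_loops // cfg.n_chroms] * cfg.n_chroms
    for c in range(cfg.n_loops % cfg.n_chroms):
        per_chrom[c] += 1
    loops: list[Loop] = []
    for c, n_c in enumerate(per_chrom):
        if n_c == 0:
            continue
        chrom = f"chr{c + 1}"
        chrom_genes = gene_set.on_chrom(chrom)
        stride = len(chrom_genes) // n_c
        if stride < L + 1:
            raise ValueError(f"cannot fit {n_c} loops of {L} genes on {chrom}")
        for j in range(n_c):
            slack = stride - L - 1
            offset = int(rng.integers(0, slack + 1)) if slack > 0 else 0
            s = j * stride + offset
            first, last = chrom_genes[s], chrom_genes[s + L - 1]
            anchor_a = GenomicInterval(
                chrom, first.interval.start - cfg.anchor_width, first.interval.start
            )
            anchor_b = GenomicInterval(
                chrom, last.interval.end, last.interval.end + cfg.anchor_width
            )
            loops.append(Loop(id=f"loop_{chrom}_{j:04d}", anchor_a=anchor_a, anchor_b=anchor_b))
    loop_set = LoopSet(loops)

    loop_ids = [l.id for l in loop_set]
    effect_ids = sorted(
        rng.choice(loop_ids, size=cfg.n_effect_loops, replace=False).tolist()
    ) if cfg.n_effect_loops else []
    gene_fc: dict[str, float] = {g.id: 1.0 for g in gene_set}
    for lid in effect_ids:
        for gid in genes_in_loop(loop_set[lid], gene_set):
            fc = cfg.fold_change
            if cfg.effect_jitter_sd > 0:
                fc *= float(np.exp(rng.normal(0.0, cfg.effect_jitter_sd)))
            gene_fc[gid] = fc
    truth = GroundTruth(effect_loop_ids=list(effect_ids), gene_fold_change=gene_fc, peak_retention={})
    return gene_set, loop_set, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB(mu, size theta): variance mu + mu^2/theta."""
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def simulate_counts(
    cfg: SimulationConfig, genes: GeneSet, truth: GroundTruth
) -> CellByGeneMatrix:
    """Two-condition NB counts with the planted loop-coordinated fold-changes.

    Per-gene base means are drawn log-normally, scaled to ``mean_depth``
    total counts per cell, then floored at ``min_gene_mean`` so every gene
    stays detectable at the simulated depth.  Condition B multiplies the
    effect-loop member genes by their planted fold-change.
    """
    rng = cfg.rng(2)
    gene_ids = [g.id for g in genes]
    n_genes = len(gene_ids)
    raw = rng.lognormal(0.0, cfg.base_mean_sigma, n_genes)
    base = raw / raw.sum() * cfg.mean_depth
    base = np.maximum(base, cfg.min_gene_mean)
    fc = np.array([truth.gene_fold_change.get(g, 1.0) for g in gene_ids])

    blocks, ids, conds, types = [], [], [], []
    for cond, mu in ((cfg.condition_a, base), (cfg.condition_b, base * fc)):
        n = cfg.n_cells_per_condition
        blocks.append(_nb_draw(rng, np.broadcast_to(mu, (n, n_genes)), cfg.dispersion))
        ids += [f"{cond}_{i:04d}" for i in range(n)]
        conds += [cond] * n
        types += [cfg.cell_type] * n
        if cfg.n_extra_cells_per_condition:
            ne = cfg.n_extra_cells_per_condition
            # extra cell type: same base means, no planted effect
            blocks.append(_nb_draw(rng, np.broadcast_to(base, (ne, n_genes)), cfg.dispersion))
            ids += [f"{cond}_x{i:04d}" for i in range(ne)]
            conds += [cond] * ne
            types += [cfg.extra_cell_type] * ne
    counts = np.vstack(blocks).astype(np.int64)
    meta = pd.DataFrame({"condition": conds, "cell_type": types}, index=pd.Index(ids, name="barcode"))
    return CellByGeneMatrix(counts, ids, gene_ids, meta)


def _anchor_peak(anchor: GenomicInterval, width: int) -> Peak:
    mid = anchor.midpoint
    return Peak(GenomicInterval(anchor.chrom, mid - width // 2, mid - width // 2 + width))


def simulate_peak_sets(
    cfg: SimulationConfig, loops: LoopSet, truth: GroundTruth
) -> tuple[PeakSet, PeakSet]:
    """WT and KO peak sets over the loop anchors plus shared background.

    WT carries a peak in every anchor; KO retains each anchor peak with
    probability ``1 - anchor_peak_loss_frac``, except effect-loop anchors
    which are always lost.  Background peaks (placed clear of all anchors)
    are identical in both sets.  Retention flags are recorded in ``truth``.
    """
    rng = cfg.rng(3)
    effect = set(truth.effect_loop_ids)
    wt: list[Peak] = []
    ko: list[Peak] = []
    anchors: list[GenomicInterval] = []
    for loop in loops:
        for side, anchor in (("A", loop.anchor_a), ("B", loop.anchor_b)):
            peak = _anchor_peak(anchor, cfg.peak_width)
            anchors.append(anchor)
            wt.append(peak)
            if loop.id in effect:
                retained = False
            else:
                retained = bool(rng.random() >= cfg.anchor_peak_loss_frac)
            truth.peak_retention[f"{loop.id}:{side}"] = retained
            if retained:
                ko.append(peak)

    # shared background peaks, rejected if they touch any anchor
    chroms = sorted({l.chrom for l in loops})
    span_hi = {c: max(l.span.end for l in loops if l.chrom == c) + 100_000 for c in chroms}
    anchor_by_chrom: dict[str, list[GenomicInterval]] = {}
    for a in anchors:
        anchor_by_chrom.setdefault(a.chrom, []).append(a)
    occupied: set[tuple[str, int]] = set()
    for chrom in chroms:
        placed = 0
        while placed < cfg.background_peaks_per_chrom:
            start = int(rng.integers(0, span_hi[chrom] - cfg.peak_width))
            iv = GenomicInterval(chrom, start, start + cfg.peak_width)
            if any(iv.start < a.end and a.start < iv.end for a in anchor_by_chrom[chrom]):
                continue
            if (chrom, start) in occupied:
                continue
            occupied.add((chrom, start))
            wt.append(Peak(iv))
            ko.append(Peak(iv))
            placed += 1
    return (
        PeakSet(wt, condition_label=cfg.condition_a),
        PeakSet(ko, condition_label=cfg.condition_b),
    )


def simulate_fragments(cfg: SimulationConfig, sites: PeakSet) -> FragmentTable:
    """Fragments whose midpoints mix uniform background with site-centered Gaussians.

    A fraction ``1 - 1/fragment_enrichment`` of fragments are centered on a
    random site (Gaussian sd ``fragment_site_sd``); the rest are uniform, so
    enrichment 1 gives a flat profile.  All fragments have fixed length.
    """
    rng = cfg.rng(4)
    if len(sites) == 0:
        raise ValueError("need at least one site to scatter fragments around")
    centers = np.array([p.interval.midpoint for p in sites])
    chrom_of = [p.interval.chrom for p in sites]
    chroms = sorted(set(chrom_of))
    extent = {
        c: max(p.interval.end for p in sites if p.interval.chrom == c) + 50_000
        for c in chroms
    }
    p_site = max(0.0, 1.0 - 1.0 / cfg.fragment_enrichment)
    half = cfg.fragment_length // 2
    rows = []
    for i in range(cfg.n_fragments):
        if rng.random() < p_site:
            j = int(rng.integers(0, len(sites)))
            chrom = chrom_of[j]
            mid = int(round(rng.normal(centers[j], cfg.fragment_site_sd)))
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            mid = int(rng.integers(half, extent[chrom]))
        start = max(0, mid - half)
        rows.append(
            (chrom, start, start + cfg.fragment_length,
             f"BC{int(rng.integers(0, cfg.n_fragment_barcodes)):04d}")
        )
    return FragmentTable(pd.DataFrame(rows, columns=FragmentTable.COLUMNS))


def simulate_qc_table(cfg: SimulationConfig) -> list[CellQCRecord]:
    """Per-barcode QC metrics straddling the standard thresholds."""
    rng = cfg.rng(5)
    records = []
    for i in range(cfg.n_qc_cells):
        n_frag = int(rng.lognormal(np.log(2000), 0.8))
        ratio = float(np.clip(rng.beta(3.0, 7.0), 0.0, 1.0))
        records.append(CellQCRecord(f"QC{i:04d}", n_frag, ratio))
    return records


def simulate_pair_table(cfg: SimulationConfig, genes: GeneSet) -> LRPairTable:
    """Ligand-receptor pairs over the simulated gene ids (deterministic)."""
    ids = [g.id for g in genes]
    n = min(cfg.n_lr_pairs, len(ids) // 2)
    rows = [{"ligand": ids[2 * k], "receptor": ids[2 * k + 1]} for k in range(n)]
    return LRPairTable(pd.DataFrame(rows, columns=["ligand", "receptor"]))


def simulate_all(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit every pipeline input under ``outdir`` and return the path map."""
    from . import io as ldio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genes, loops, truth = simulate_genome_and_loops(cfg)
    counts = simulate_counts(cfg, genes, truth)
    peaks_wt, peaks_ko = simulate_peak_sets(cfg, loops, truth)
    fragments = simulate_fragments(cfg, peaks_wt)
    qc = simulate_qc_table(cfg)
    pairs = simulate_pair_table(cfg, genes)

    paths = {
        "genes": out / "genes.tsv",
        "loops": out / "loops.bedpe",
        "peaks_wt": out / f"peaks_{cfg.condition_a}.bed",
        "peaks_ko": out / f"peaks_{cfg.condition_b}.bed",
        "counts": out / "counts",
        "fragments": out / "fragments.tsv",
        "qc_table": out / "qc_table.tsv",
        "lr_pairs": out / "lr_pairs.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    ldio.write_gene_table(genes, paths["genes"])
    ldio.write_bedpe(loops, paths["loops"])
    ldio.write_bed(peaks_wt, paths["peaks_wt"])
    ldio.write_bed(peaks_ko, paths["peaks_ko"])
    ldio.write_counts(counts, paths["counts"])
    ldio.write_fragments(fragments, paths["fragments"])
    ldio.write_qc_table(qc, paths["qc_table"])
    ldio.write_pair_table(pairs, paths["lr_pairs"])
    truth.to_json(paths["ground_truth"])
    return paths
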