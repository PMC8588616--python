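"""Model/Results front end for the loop-dysregulation analysis.

:class:`LoopDysregulationModel` bundles the inputs of the analysis — a
two-condition cell-by-gene count matrix, gene annotation, chromatin
loops, and (optionally) per-condition CTCF peak sets — together with the
analysis parameters.  :meth:`LoopDysregulationModel.fit` runs the chain

    cell-averaged log2 fold-change
      -> differential boundary peaks -> loop classification
      -> loop-averaged logFC vs. sliding-window null -> percentiles
      -> Beta fit to the percentile inter-quartile range (Q-Q diagnostic)

and returns a :class:`LoopDysregulationResults` carrying the per-loop
score table, the class fractions, the Beta parameters, and a
``summary()`` report.  Plotting and synthetic-study construction hang
off these two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .expression import CellByGeneMatrix, GeneLogFC, cell_averaged_logfc
from .intervals import GeneSet, PeakSet, differential_peaks
from .loops import LoopClassLabel, LoopSet, classify_loops
from .scoring import BetaQQ, fit_beta_iqr, score_all_loops


class LoopDysregulationModel:
    """Loop-coordinated expression-change model for a two-condition contrast.

    Parameters
    ----------
    counts
        Cell-by-gene integer counts with condition and cell-type labels.
    loops
        Chromatin loops with two boundary anchors each.
    genes
        Gene annotation; TSS order defines the sliding-window null.
    peaks_num, peaks_den
        Per-condition peak sets (e.g. KO and WT CTCF peaks).  When both are
        given, loops are classified direct/indirect/unaffected from the
        denominator-specific differential peaks.
    condition_num, condition_den
        Condition labels forming the log fold-change contrast
        (numerator / denominator, e.g. KO / WT).
    population
        Cell-type label to restrict to (None pools all cells).
    """

    def __init__(
        self,
        counts: CellByGeneMatrix,
        loops: LoopSet,
        genes: GeneSet,
        peaks_num: PeakSet | None = None,
        peaks_den: PeakSet | None = None,
        *,
        condition_num: str = "KO",
        condition_den: str = "WT",
        population: str | None = None,
        pseudocount: float = 1.0,
        min_genes: int = 2,
        boundary_flank: int = 0,
        min_overlap: int = 1,
        include_own_window: bool = True,
        compute_pvalues: bool = False,
    ):
        self.counts = counts
        self.loops = loops
        self.genes = genes
        self.peaks_num = peaks_num
        self.peaks_den = peaks_den
        self.condition_num = condition_num
        self.condition_den = condition_den
        self.population = population
        self.pseudocount = pseudocount
        self.min_genes = min_genes
        self.boundary_flank = boundary_flank
        self.min_overlap = min_overlap
        self.include_own_window = include_own_window
        self.compute_pvalues = compute_pvalues

    @classmethod
    def from_files(
        cls,
        counts_dir: str | Path,
        loops_bedpe: str | Path,
        gene_table: str | Path,
        peaks_num_bed: str | Path | None = None,
        peaks_den_bed: str | Path | None = None,
        **kwargs,
    ) -> "LoopDysregulationModel":
        """Build the model from the standard on-disk formats."""
        from . import io as ldio

        return cls(
            counts=ldio.read_counts(counts_dir),
            loops=ldio.read_bedpe(loops_bedpe),
            genes=ldio.read_gene_table(gene_table),
            peaks_num=ldio.read_bed(peaks_num_bed) if peaks_num_bed else None,
            peaks_den=ldio.read_bed(peaks_den_bed) if peaks_den_bed else None,
            **kwargs,
        )

    @classmethod
    def from_simulation(cls, cfg=None, **kwargs) -> "LoopDysregulationModel":
        """Build the model from an in-memory synthetic study.

        The ground truth is attached as ``model.ground_truth``.
        """
        from .simulate import (
            SimulationConfig,
            simulate_counts,
            simulate_genome_and_loops,
            simulate_peak_sets,
        )

        cfg = cfg or SimulationConfig()
        genes, loops, truth = simulate_genome_and_loops(cfg)
        counts = simulate_counts(cfg, genes, truth)
        peaks_wt, peaks_ko = simulate_peak_sets(cfg, loops, truth)
        kwargs.setdefault("condition_num", cfg.condition_b)
        kwargs.setdefault("condition_den", cfg.condition_a)
        kwargs.setdefault("population", cfg.cell_type)
        model = cls(counts, loops, genes, peaks_num=peaks_ko, peaks_den=peaks_wt, **kwargs)
        model.ground_truth = truth
        return model

    def fit(self) -> "LoopDysregulationResults":
        """Run the full analysis chain and return the results object."""
        logfc = cell_averaged_logfc(
            self.counts,
            self.condition_num,
            self.condition_den,
            population=self.population,
            pseudocount=self.pseudocount,
        )

        labels: list[LoopClassLabel] | None = None
        class_summary: dict | None = None
        diff = None
        if self.peaks_num is not None and self.peaks_den is not None:
            # peaks lost in the numerator condition (e.g. WT-specific on KO)
            diff = differential_peaks(self.peaks_den, self.peaks_num, self.min_overlap)
            labels, class_summary = classify_loops(
                self.loops, diff, boundary_flank=self.boundary_flank
            )

        scores = score_all_loops(
            self.loops,
            logfc,
            self.genes,
            labels=labels,
            min_genes=self.min_genes,
            include_own_window=self.include_own_window,
            compute_pvalues=self.compute_pvalues,
        )

        beta: BetaQQ | None = None
        beta_error: str | None = None
        if len(scores):
            try:
                beta = fit_beta_iqr(scores["percentile"].to_numpy())
            except ValueError as exc:
                beta_error = str(exc)
        return LoopDysregulationResults(
            model=self,
            logfc=logfc,
            scores=scores,
            class_labels=labels,
            class_summary=class_summary,
            differential_peaks=diff,
            beta=beta,
            beta_error=beta_error,
        )


@dataclass
class LoopDysregulationResults:
    """Fitted loop scores, class fractions, and Q-Q diagnostics."""

    model: LoopDysregulationModel
    logfc: GeneLogFC
    scores: pd.DataFrame
    class_labels: list[LoopClassLabel] | None
    class_summary: dict | None
    differential_peaks: PeakSet | None
    beta: BetaQQ | None
    beta_error: str | None = None

    @property
    def n_loops_scored(self) -> int:
        return len(self.scores)

    def percentiles(self) -> np.ndarray:
        return self.scores["percentile"].to_numpy()

    def extreme_loops(self, threshold: float = 95.0) -> pd.DataFrame:
        """Loops whose percentile is >= ``threshold`` (coordinated up-shift)."""
        return self.scores[self.scores["percentile"] >= threshold]

    def summary_dict(self) -> dict:
        d: dict = {
            "version": __version__,
            "contrast": f"{self.logfc.condition_num}/{self.logfc.condition_den}",
            "population": self.logfc.population,
            "pseudocount": self.logfc.pseudocount,
            "n_genes": int(len(self.logfc.values)),
            "n_loops_total": len(self.model.loops),
            "n_loops_scored": self.n_loops_scored,
        }
        if self.n_loops_scored:
            pct = self.percentiles()
            d["mean_percentile"] = float(np.mean(pct))
            d["frac_percentile_ge_95"] = float(np.mean(pct >= 95.0))
            d["mean_loop_logfc"] = float(self.scores["mean_logfc"].mean())
        if self.class_summary is not None:
            d["class_counts"] = self.class_summary["counts"]
            d["class_fractions"] = self.class_summary["fractions"]
        if self.beta is not None:
            d["beta_alpha"] = self.beta.alpha
            d["beta_beta"] = self.beta.beta
        elif self.beta_error:
            d["beta_error"] = self.beta_error
        return d

    def summary(self) -> str:
        """Human-readable report of the fitted analysis."""
        d = self.summary_dict()
        lines = [
            "        Chromatin-Loop Dysregulation Analysis",
            "=" * 56,
            f"Contrast (log2, pc={d['pseudocount']:g}):  {d['contrast']}"
            + (f"  [{d['population']}]" if d["population"] else ""),
            f"Genes with logFC:            {d['n_genes']}",
            f"Loops scored / total:        {d['n_loops_scored']} / {d['n_loops_total']}",
        ]
        if "mean_percentile" in d:
            lines += [
                f"Mean loop percentile:        {d['mean_percentile']:.2f}",
                f"Loops at >= 95th percentile: {d['frac_percentile_ge_95'] * 100:.1f}%",
            ]
        if "class_fractions" in d:
            f = d["class_fractions"]
            c = d["class_counts"]
            lines += [
                "-" * 56,
                f"Direct loops (diff. boundary peak): {c['direct']:5d} ({100 * f['direct']:.1f}%)",
                f"Indirect loops (overlap a direct):  {c['indirect']:5d} ({100 * f['indirect']:.1f}%)",
                f"Unaffected loops:                   {c['unaffected']:5d} ({100 * f['unaffected']:.1f}%)",
            ]
        if "beta_alpha" in d:
            lines += [
                "-" * 56,
                f"Beta fit to percentile IQR:  alpha={d['beta_alpha']:.3f}, "
                f"beta={d['beta_beta']:.3f}",
            ]
        elif self.beta_error:
            lines += ["-" * 56, f"Beta fit unavailable: {self.beta_error}"]
        lines.append("=" * 56)
        return "\n".join(lines)

    def plot_qq(self, ax=None):
        """Q-Q plot of observed loop percentiles against the Beta fit."""
        if self.beta is None:
            raise ValueError(f"no Beta fit available: {self.beta_error}")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        qq = self.beta.qq_points
        ax.plot(qq["theoretical"], qq["observed"], ".", ms=3)
        lim = [0, 1]
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xlabel(f"Beta({self.beta.alpha:.2f}, {self.beta.beta:.2f}) quantile")
        ax.set_ylabel("observed loop percentile / 100")
        ax.set_title("Loop-averaged logFC percentiles vs. bulk-calibrated Beta")
        return ax
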