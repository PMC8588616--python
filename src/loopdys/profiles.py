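"""Cut-site meta-profiles around reference sites.

Fragments from tagmentation assays (scATAC, scCUT&Tag) mark two
transposase cut sites: the fragment start and ``end - 1`` (the last
covered base).  For a set of reference sites (peak or motif midpoints)
the profile matrix counts cut sites per ``bin_width`` bp bin inside a
``+/- window`` bp neighborhood of each site, one row per site.  Rows of
minus-strand sites are reversed so that all rows read 5'->3' relative to
the site.  A whole-fragment coverage mode is available as an
alternative to cut-site counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import PeakSet

__all__ = ["FragmentTable", "SignalProfileMatrix", "profile_matrix", "moving_average"]


class FragmentTable:
    """Sequenced fragments (chrom, start, end, barcode), sorted by (chrom, start)."""

    COLUMNS = ["chrom", "start", "end", "barcode"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"fragment table missing columns {missing}")
        df = df[self.COLUMNS].copy()
        if (df["start"] >= df["end"]).any():
            raise ValueError("fragments must satisfy start < end")
        if df["barcode"].astype(str).str.len().eq(0).any():
            raise ValueError("fragment barcodes must be non-empty")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self._cuts: dict[str, np.ndarray] = {}
        for chrom, grp in self.df.groupby("chrom", sort=True):
            cuts = np.concatenate(
                [grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64) - 1]
            )
            self._cuts[chrom] = np.sort(cuts)

    def __len__(self) -> int:
        return len(self.df)

    def cut_sites(self, chrom: str) -> np.ndarray:
        """Sorted Tn5 cut-site positions (both fragment ends) on one chromosome."""
        return self._cuts.get(chrom, np.empty(0, np.int64))


@dataclass
class SignalProfileMatrix:
    """Sites x bins cut-site counts around site midpoints."""

    matrix: np.ndarray
    site_ids: list[str]
    bin_width: int
    window: int
    strand_oriented: bool

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def column_means(self) -> np.ndarray:
        """Mean signal per bin across sites (the meta-profile)."""
        return self.matrix.mean(axis=0)

    def bin_centers(self) -> np.ndarray:
        """Bin-center offsets in bp relative to the site reference point."""
        edges = np.arange(self.n_bins) * self.bin_width - self.window
        return edges + self.bin_width / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=pd.Index(self.site_ids, name="site_id"))


def profile_matrix(
    frags: FragmentTable,
    sites: PeakSet,
    window: int = 1000,
    bin_width: int = 10,
    orient_by_strand: bool = True,
    mode: str = "cut_sites",
) -> SignalProfileMatrix:
    """Count cut sites per bin in a ``+/- window`` bp neighborhood of each site.

    Each site is reduced to its interval midpoint; a cut site at position p
    contributes to bin ``(p - (center - window)) // bin_width`` when
    ``center - window <= p < center + window``.  With
    ``mode="coverage"`` every base covered by a fragment is counted
    instead of its two cut sites.  Minus-strand site rows are reversed when
    ``orient_by_strand`` is set.
    """
    if window % bin_width != 0:
        raise ValueError(f"window {window} not divisible by bin_width {bin_width}")
    if mode not in ("cut_sites", "coverage"):
        raise ValueError(f"mode must be 'cut_sites' or 'coverage', got {mode!r}")
    n_bins = 2 * window // bin_width
    mat = np.zeros((len(sites), n_bins), dtype=np.int64)
    site_ids: list[str] = []
    frag_by_chrom = {
        chrom: grp for chrom, grp in frags.df.groupby("chrom", sort=True)
    }
    for row, peak in enumerate(sites):
        iv = peak.interval
        site_ids.append(f"{iv.chrom}:{iv.start}-{iv.end}")
        center = iv.midpoint
        lo, hi = center - window, center + window
        if mode == "cut_sites":
            cuts = frags.cut_sites(iv.chrom)
            sel = cuts[np.searchsorted(cuts, lo): np.searchsorted(cuts, hi)]
            if len(sel):
                mat[row] = np.bincount((sel - lo) // bin_width, minlength=n_bins)
        else:
            grp = frag_by_chrom.get(iv.chrom)
            if grp is not None:
                cover = np.zeros(2 * window, dtype=np.int64)
                starts = grp["start"].to_numpy(np.int64)
                ends = grp["end"].to_numpy(np.int64)
                keep = (starts < hi) & (ends > lo)
                for s, e in zip(np.clip(starts[keep] - lo, 0, None), np.clip(ends[keep] - lo, None, 2 * window)):
                    cover[s:e] += 1
                mat[row] = cover.reshape(n_bins, bin_width).sum(axis=1)
        if orient_by_strand and iv.strand == "-":
            mat[row] = mat[row][::-1]
    return SignalProfileMatrix(
        matrix=mat,
        site_ids=site_ids,
        bin_width=bin_width,
        window=window,
        strand_oriented=orient_by_strand,
    )


def moving_average(profile: np.ndarray, span_bins: int = 5) -> np.ndarray:
    """Centered moving average, truncated at the edges; length preserved."""
    if span_bins < 1 or span_bins % 2 == 0:
        raise ValueError(f"span_bins must be odd and >= 1, got {span_bins}")
    profile = np.asarray(profile, dtype=float)
    kernel = np.ones(span_bins)
    sums = np.convolve(profile, kernel, mode="same")
    counts = np.convolve(np.ones_like(profile), kernel, mode="same")
    return sums / counts
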