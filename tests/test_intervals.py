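"""Interval arithmetic, peak-set comparison, nearest-gene assignment, cell QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loopdys.intervals import (
    CellQCRecord,
    GenomicInterval,
    assign_peaks_to_genes,
    atac_cell_qc,
    differential_peaks,
    find_overlaps_batch,
    overlaps,
)

from conftest import make_geneset, make_peakset


def iv(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand)


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 100, 200), ("chr1", 150, 250), True),
            (("chr1", 100, 200), ("chr1", 200, 300), False),  # half-open abutting
            (("chr1", 100, 200), ("chr2", 100, 200), False),
            (("chr1", 100, 200), ("chr1", 199, 500), True),
            (("chr1", 100, 200), ("chr1", 0, 100), False),
        ],
    )
    def test_overlaps(self, a, b, expected):
        assert overlaps(iv(*a), iv(*b)) is expected
        assert overlaps(iv(*b), iv(*a)) is expected  # symmetric

    @pytest.mark.parametrize(
        "args",
        [("chr1", -1, 10), ("chr1", 10, 10), ("chr1", 10, 5), ("", 0, 10)],
    )
    def test_invalid_rejected(self, args):
        with pytest.raises(ValueError):
            GenomicInterval(*args)


def brute_force_overlaps(query, subject):
    return [
        (qi, si)
        for qi, q in enumerate(query)
        for si, s in enumerate(subject)
        if overlaps(q.interval, s.interval)
    ]


def random_peakset(rng, n, label):
    triples = set()
    while len(triples) < n:
        chrom = f"chr{rng.integers(1, 4)}"
        start = int(rng.integers(0, 5000))
        end = start + int(rng.integers(1, 400))
        triples.add((chrom, start, end))
    return make_peakset(sorted(triples), label)


class TestFindOverlapsBatch:
    def test_single_pair(self):
        q = make_peakset([("chr1", 100, 200)], "Q")
        s = make_peakset([("chr1", 150, 250), ("chr1", 300, 400)], "S")
        assert find_overlaps_batch(q, s) == [(0, 0)]

    def test_self_overlap(self):
        q = make_peakset([("chr1", 100, 200)], "Q")
        assert find_overlaps_batch(q, q) == [(0, 0)]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            q = random_peakset(rng, int(rng.integers(1, 51)), "Q")
            s = random_peakset(rng, int(rng.integers(1, 51)), "S")
            assert find_overlaps_batch(q, s) == sorted(brute_force_overlaps(q, s))


class TestDifferentialPeaks:
    def test_shared_site_removed(self):
        a = make_peakset([("chr1", 100, 200)], "WT")
        b = make_peakset([("chr1", 150, 250)], "KO")
        assert len(differential_peaks(a, b)) == 0

    def test_disjoint_site_kept(self):
        a = make_peakset([("chr1", 100, 200)], "WT")
        b = make_peakset([("chr1", 300, 400)], "KO")
        result = differential_peaks(a, b)
        assert [(p.interval.start, p.interval.end) for p in result] == [(100, 200)]
        assert result.condition_label == "WT_specific"

    def test_empty_b_returns_all_of_a(self, rng):
        a = random_peakset(rng, 20, "WT")
        b = make_peakset([], "KO")
        assert len(differential_peaks(a, b)) == len(a)

    def test_identities_and_partition(self, rng):
        for _ in range(20):
            a = random_peakset(rng, 30, "A")
            b = random_peakset(rng, 30, "B")
            diff = differential_peaks(a, b)
            diff_keys = {(p.interval.chrom, p.interval.start, p.interval.end) for p in diff}
            a_keys = {(p.interval.chrom, p.interval.start, p.interval.end) for p in a}
            # diff is a subset of A; its complement is exactly the overlapping part
            assert diff_keys <= a_keys
            overlapping = {
                (a[qi].interval.chrom, a[qi].interval.start, a[qi].interval.end)
                for qi, _ in find_overlaps_batch(a, b)
            }
            assert a_keys - diff_keys == overlapping
        assert len(differential_peaks(a, a)) == 0

    def test_min_overlap_knob(self):
        a = make_peakset([("chr1", 100, 200)], "A")
        b = make_peakset([("chr1", 199, 300)], "B")  # 1 bp shared
        assert len(differential_peaks(a, b, min_overlap=1)) == 0
        assert len(differential_peaks(a, b, min_overlap=2)) == 1


class TestAssignPeaksToGenes:
    GENES = [("gA", "chr1", 10000, 20000), ("gB", "chr1", 60000, 70000)]

    def test_within_max_dist(self):
        peaks = make_peakset([("chr1", 30000, 30200)])
        (_, gene, dist), = assign_peaks_to_genes(peaks, make_geneset(self.GENES))
        assert (gene, dist) == ("gA", 10000)

    def test_beyond_max_dist_unassigned(self):
        peaks = make_peakset([("chr1", 30000, 30200)])
        genes = make_geneset([("gB", "chr1", 60000, 70000)])
        (_, gene, dist), = assign_peaks_to_genes(peaks, genes)
        assert gene is None and dist is None
        # distance 29800 > 25000; a larger budget assigns it
        (_, gene, dist), = assign_peaks_to_genes(peaks, genes, max_dist=30000)
        assert (gene, dist) == ("gB", 29800)

    def test_overlapping_peak_distance_zero(self):
        peaks = make_peakset([("chr1", 15000, 15500)])
        (_, gene, dist), = assign_peaks_to_genes(peaks, make_geneset(self.GENES))
        assert (gene, dist) == ("gA", 0)

    def test_tie_broken_by_smaller_gene_id(self):
        genes = make_geneset([("gZ", "chr1", 0, 100), ("gA", "chr1", 300, 400)])
        peaks = make_peakset([("chr1", 150, 250)])  # 50 bp from both
        (_, gene, dist), = assign_peaks_to_genes(peaks, genes)
        assert (gene, dist) == ("gA", 50)

    def test_translation_invariance(self, rng):
        genes = [(f"g{i}", "chr1", int(s), int(s) + 500)
                 for i, s in enumerate(sorted(rng.integers(0, 100000, 10)))]
        peaks = sorted(
            ("chr1", int(s), int(s) + 200) for s in rng.integers(0, 100000, 15)
        )
        base = assign_peaks_to_genes(make_peakset(set(peaks)), make_geneset(genes))
        shift = 7919
        genes_s = [(g, c, s + shift, e + shift) for g, c, s, e in genes]
        peaks_s = [(c, s + shift, e + shift) for c, s, e in peaks]
        shifted = assign_peaks_to_genes(make_peakset(set(peaks_s)), make_geneset(genes_s))
        assert [(g, d) for _, g, d in base] == [(g, d) for _, g, d in shifted]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n_genes = int(rng.integers(1, 20))
            genes = []
            used = set()
            for i in range(n_genes):
                s = int(rng.integers(0, 60000))
                if s in used:
                    continue
                used.add(s)
                genes.append((f"g{i:02d}", f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(100, 5000))))
            gene_set = make_geneset(genes)
            peaks = random_peakset(rng, int(rng.integers(1, 15)), "P")
            got = assign_peaks_to_genes(peaks, gene_set, max_dist=25000)
            for peak, gene_id, dist in got:
                cands = []
                for g, c, s, e in genes:
                    if c != peak.interval.chrom:
                        continue
                    d = max(0, s - peak.interval.end, peak.interval.start - e)
                    cands.append((d, g))
                cands = [x for x in cands if x[0] <= 25000]
                if not cands:
                    assert gene_id is None
                else:
                    best = min(cands)
                    assert (dist, gene_id) == best


class TestAtacCellQC:
    @pytest.mark.parametrize(
        "n_frag, ratio, expected",
        [
            (1500, 0.25, True),
            (1000, 0.50, False),  # strict on fragments
            (5000, 0.20, False),  # strict on ratio
            (1001, 0.21, True),
            (0, 0.0, False),
        ],
    )
    def test_strict_thresholds(self, n_frag, ratio, expected):
        result = atac_cell_qc([CellQCRecord("bc", n_frag, ratio)])
        assert bool(result["qc_pass"].iloc[0]) is expected

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            CellQCRecord("bc", 10, 1.5)

    @given(
        frag_thresh=st.integers(0, 5000),
        ratio_thresh=st.floats(0, 1),
        bump_frag=st.integers(0, 2000),
        bump_ratio=st.floats(0, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_pass_set_monotone_in_thresholds(self, frag_thresh, ratio_thresh, bump_frag, bump_ratio):
        records = [
            CellQCRecord(f"b{i}", n, r)
            for i, (n, r) in enumerate(
                [(500, 0.1), (1200, 0.25), (3000, 0.9), (800, 0.5), (2500, 0.15)]
            )
        ]
        lo = atac_cell_qc(records, frag_thresh, ratio_thresh)["qc_pass"]
        hi = atac_cell_qc(
            records, frag_thresh + bump_frag, min(1.0, ratio_thresh + bump_ratio)
        )["qc_pass"]
        assert not (hi & ~lo).any()  # raising thresholds never adds a passing cell
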