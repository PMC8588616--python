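"""Sliding-window null, loop percentiles, and the Beta/Q-Q diagnostic."""

import numpy as np
import pandas as pd
import pytest

from loopdys.expression import GeneLogFC
from loopdys.intervals import GenomicInterval
from loopdys.loops import Loop, LoopSet
from loopdys.scoring import (
    fit_beta_iqr,
    loop_mean_logfc,
    loop_percentile,
    score_all_loops,
    window_null,
)

from conftest import make_geneset


def logfc_of(values: dict) -> GeneLogFC:
    return GeneLogFC(
        values=pd.Series(values, dtype=float),
        condition_num="KO",
        condition_den="WT",
        population=None,
        pseudocount=1.0,
    )


def chrom_layout(chrom, n, spacing=10_000, start0=1_000):
    """Evenly spaced single-chromosome genes g0..g{n-1}."""
    return [(f"g{i:03d}", chrom, start0 + i * spacing, start0 + i * spacing + 500)
            for i in range(n)]


def loop_over(chrom, genes, lo_idx, hi_idx, lid, spacing=10_000, start0=1_000):
    """A loop whose span contains exactly the TSSs of genes lo_idx..hi_idx."""
    a_end = start0 + lo_idx * spacing
    b_start = start0 + hi_idx * spacing + 500
    return Loop(
        id=lid,
        anchor_a=GenomicInterval(chrom, max(0, a_end - 500), a_end),
        anchor_b=GenomicInterval(chrom, b_start, b_start + 500),
    )


class TestLoopMeanAndWindowNull:
    @pytest.mark.parametrize(
        "vals, expected",
        [([2.0, 2.0, 2.0], 2.0), ([1.0, -1.0], 0.0), ([0.5, 1.5, 2.5], 1.5)],
    )
    def test_loop_mean(self, vals, expected):
        lf = logfc_of({f"g{i}": v for i, v in enumerate(vals)})
        assert loop_mean_logfc(list(lf.values.index), lf) == pytest.approx(expected)

    def test_window_enumeration(self):
        null = window_null([1, 2, 3, 4, 5], 2)
        np.testing.assert_allclose(null.values, [1.5, 2.5, 3.5, 4.5])
        assert null.n_windows == 4

    def test_window_full_length_is_chrom_mean(self):
        null = window_null([1, 2, 3, 4, 5], 5)
        np.testing.assert_allclose(null.values, [3.0])

    def test_window_length_one_is_identity(self):
        null = window_null([1, 2, 3], 1)
        np.testing.assert_allclose(null.values, [1, 2, 3])

    def test_window_too_long_errors(self):
        with pytest.raises(ValueError, match="chrX"):
            window_null([1, 2], 3, chrom="chrX")


class TestLoopPercentile:
    def test_counting_with_tie(self):
        null = window_null([1, 2, 3, 4, 5], 2)  # {1.5, 2.5, 3.5, 4.5}
        assert loop_percentile(3.5, null) == 75.0

    def test_maximum_gives_100(self):
        null = window_null([1, 2, 3, 4, 5], 2)
        assert loop_percentile(4.5, null) == 100.0

    def test_below_all_gives_0(self):
        null = window_null([1, 2, 3, 4, 5], 2)
        assert loop_percentile(-10.0, null) == 0.0

    def test_empty_null_errors(self):
        from loopdys.scoring import WindowNull

        with pytest.raises(ValueError, match="empty"):
            loop_percentile(0.0, WindowNull("chr1", 2, np.array([])))


class TestScoreAllLoops:
    def test_six_gene_worked_example(self):
        # 6 genes, logfc [0.0, 0.1, 2.0, 2.0, 2.0, -0.1]; loop = genes 2..4
        # L=3 null: {0.7, 1.3667, 2.0, 1.3}; loop mean 2.0 -> percentile 100
        genes = make_geneset(chrom_layout("chr1", 6))
        lf = logfc_of({f"g{i:03d}": v for i, v in enumerate([0.0, 0.1, 2.0, 2.0, 2.0, -0.1])})
        loops = LoopSet([loop_over("chr1", genes, 2, 4, "loop1")])
        df = score_all_loops(loops, lf, genes)
        row = df.iloc[0]
        assert row.n_genes == 3
        assert row.mean_logfc == pytest.approx(2.0)
        assert row.null_size == 4
        assert row.percentile == 100.0

    def test_all_equal_logfc_gives_100_everywhere(self):
        genes = make_geneset(chrom_layout("chr1", 10))
        lf = logfc_of({f"g{i:03d}": 0.3 for i in range(10)})
        loops = LoopSet([loop_over("chr1", genes, 1, 3, "l1"), loop_over("chr1", genes, 5, 8, "l2")])
        df = score_all_loops(loops, lf, genes)
        assert (df["percentile"] == 100.0).all()

    def test_shift_invariance(self, rng):
        genes = make_geneset(chrom_layout("chr1", 40))
        vals = {f"g{i:03d}": float(v) for i, v in enumerate(rng.normal(size=40))}
        loops = LoopSet([loop_over("chr1", genes, 3, 7, "l1"), loop_over("chr1", genes, 20, 24, "l2")])
        base = score_all_loops(loops, logfc_of(vals), genes)["percentile"]
        shifted_vals = {k: v + 3.7 for k, v in vals.items()}
        shifted = score_all_loops(loops, logfc_of(shifted_vals), genes)["percentile"]
        assert np.max(np.abs(base.to_numpy() - shifted.to_numpy())) < 1e-12

    def test_small_loops_skipped_not_fatal(self):
        genes = make_geneset(chrom_layout("chr1", 10))
        lf = logfc_of({f"g{i:03d}": float(i) for i in range(10)})
        loops = LoopSet([loop_over("chr1", genes, 2, 2, "tiny"), loop_over("chr1", genes, 4, 6, "ok")])
        df = score_all_loops(loops, lf, genes, min_genes=2)
        assert df["loop_id"].tolist() == ["ok"]
        empty = score_all_loops(loops, lf, genes, min_genes=99)
        assert empty.empty

    def test_exclude_own_window_floor_can_reach_zero(self):
        genes = make_geneset(chrom_layout("chr1", 6))
        lf = logfc_of({f"g{i:03d}": v for i, v in enumerate([5.0, 5.0, -9.0, -9.0, 5.0, 5.0])})
        loops = LoopSet([loop_over("chr1", genes, 2, 3, "low")])
        incl = score_all_loops(loops, lf, genes, include_own_window=True).iloc[0]
        excl = score_all_loops(loops, lf, genes, include_own_window=False).iloc[0]
        assert incl.percentile == pytest.approx(100.0 / incl.null_size)  # own-window floor
        assert excl.percentile == 0.0
        assert excl.null_size == incl.null_size - 1

    def test_pvalues_and_bh(self):
        genes = make_geneset(chrom_layout("chr1", 30))
        vals = {f"g{i:03d}": float(i % 7) for i in range(30)}
        loops = LoopSet([loop_over("chr1", genes, 2, 5, "l1"), loop_over("chr1", genes, 10, 13, "l2")])
        df = score_all_loops(loops, logfc_of(vals), genes, compute_pvalues=True)
        n = df["null_size"].to_numpy()
        r = np.round(df["percentile"].to_numpy() / 100 * n).astype(int)
        expected_p = np.minimum(1.0, 2.0 * np.minimum(r, n + 1 - r) / (n + 1))
        np.testing.assert_allclose(df["empirical_p"], expected_p)
        assert (df["q_value"] >= df["empirical_p"] - 1e-15).all()

    def test_matches_brute_force_oracle(self, rng):
        """Pipeline percentiles equal naive enumeration on random instances.

        logfc values are dyadic rationals (k/64) so that window means are
        exact in floating point and tie counting is unambiguous.
        """
        for _ in range(100):
            n_genes = int(rng.integers(10, 61))
            genes_raw = chrom_layout("chr1", n_genes)
            genes = make_geneset(genes_raw)
            vals = {f"g{i:03d}": float(int(rng.integers(-64, 65))) / 64.0
                    for i in range(n_genes)}
            lf = logfc_of(vals)
            loops, expected = [], {}
            for k in range(int(rng.integers(1, 11))):
                L = int(rng.integers(2, 7))
                lo = int(rng.integers(0, n_genes - L + 1))
                lid = f"loop{k}"
                loops.append(loop_over("chr1", genes, lo, lo + L - 1, lid))
            # drop duplicate spans (LoopSet allows them; keep the oracle simple)
            seen, uniq = set(), []
            for lp in loops:
                key = (lp.span.start, lp.span.end)
                if key not in seen:
                    seen.add(key)
                    uniq.append(lp)
            loops = uniq
            ordered_vals = [vals[f"g{i:03d}"] for i in range(n_genes)]
            for lp in loops:
                member_idx = [i for i in range(n_genes)
                              if lp.span.start <= genes_raw[i][2] < lp.span.end]
                L = len(member_idx)
                mean = sum(ordered_vals[i] for i in member_idx) / L
                null_vals = [sum(ordered_vals[j:j + L]) / L
                             for j in range(n_genes - L + 1)]
                expected[lp.id] = 100.0 * sum(v <= mean for v in null_vals) / len(null_vals)
            df = score_all_loops(LoopSet(loops), lf, genes)
            got = dict(zip(df["loop_id"], df["percentile"]))
            assert got == expected

    def test_null_cache_matches_uncached(self, rng):
        # many same-size loops share one cached null; scoring loops one at a
        # time (fresh caches) must give identical bytes
        genes = make_geneset(chrom_layout("chr1", 50))
        vals = {f"g{i:03d}": float(v) for i, v in enumerate(rng.normal(size=50))}
        lf = logfc_of(vals)
        loops = [loop_over("chr1", genes, s, s + 3, f"l{s}") for s in (0, 10, 20, 30, 40)]
        joint = score_all_loops(LoopSet(loops), lf, genes)
        single = pd.concat(
            [score_all_loops(LoopSet([lp]), lf, genes) for lp in loops],
            ignore_index=True,
        )
        assert joint.to_csv(index=False) == single.to_csv(index=False)


class TestFitBetaIQR:
    def test_uniform_percentiles_give_flat_beta(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 100, 10_000)
        bq = fit_beta_iqr(x)
        assert 0.8 <= bq.alpha <= 1.2
        assert 0.8 <= bq.beta <= 1.2

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="degenerate percentile distribution"):
            fit_beta_iqr([50.0] * 100)

    def test_too_few_distinct_values_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_beta_iqr([1.0, 2.0, 3.0] * 10)

    def test_qq_points_monotone_in_both_coordinates(self):
        rng = np.random.default_rng(7)
        bq = fit_beta_iqr(rng.uniform(0, 100, 500))
        theo = bq.qq_points["theoretical"].to_numpy()
        obs = bq.qq_points["observed"].to_numpy()
        assert (np.diff(theo) >= 0).all()
        assert (np.diff(obs) >= 0).all()
        assert obs.min() >= 0 and obs.max() <= 1
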