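"""Loop parsing, unique-loop matching, size stats, read-class percentages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from nucleomorph.hic import (
    LoopCall,
    classify_pairs,
    compare_conditions,
    loop_size_stats,
    mann_whitney_exact,
    match_loops,
    parse_loops,
    unique_loops,
)
from nucleomorph.synth import gen_toy_loops, write_bedpe


class TestLoopCall:
    def test_span_from_midpoints(self):
        loop = LoopCall("chr7", 1000, 6000, "chr7", 101000, 106000)
        assert loop.span == 100_000  # midpoints 3500 and 103500

    def test_trans_span_undefined(self):
        assert LoopCall("chr1", 0, 10, "chr2", 0, 10).span is None

    def test_anchor_order_normalized(self):
        loop = LoopCall("chr1", 5000, 6000, "chr1", 100, 200)
        assert loop.midpoint1 <= loop.midpoint2
        assert (loop.start1, loop.end1) == (100, 200)

    def test_bad_anchor_rejected(self):
        with pytest.raises(ValueError):
            LoopCall("chr1", 100, 100, "chr1", 200, 300)


class TestParseLoops:
    def test_roundtrip(self, tmp_path, rng):
        toy = gen_toy_loops(5, 2, 0, rng=rng)
        p = tmp_path / "a.bedpe"
        write_bedpe(toy["loops_a"], p)
        df = parse_loops(p)
        assert len(df) == 7
        assert df["span"].notna().all()

    def test_header_and_comments_tolerated(self, tmp_path):
        p = tmp_path / "h.bedpe"
        p.write_text(
            "# a comment\nchrom1\tstart1\tend1\tchrom2\tstart2\tend2\n"
            "chr1\t100\t200\tchr1\t5000\t5100\n"
        )
        assert len(parse_loops(p)) == 1

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.bedpe"
        p.write_text("chr1\t100\t200\tchr1\t5000\t5100\nchr1\t9\t5\tchr1\t1\t2\n")
        with pytest.raises(ValueError, match=":2"):
            parse_loops(p)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.bedpe"
        p.write_text("")
        with pytest.warns(UserWarning, match="no loops"):
            df = parse_loops(p)
        assert df.empty


class TestUniqueLoops:
    def test_toy_partition(self, rng):
        toy = gen_toy_loops(10, 5, 3, rng=rng)
        assert len(unique_loops(toy["loops_a"], toy["loops_b"], 0)) == 5
        assert len(unique_loops(toy["loops_b"], toy["loops_a"], 0)) == 3

    def test_identical_lists_nothing_unique(self, rng):
        toy = gen_toy_loops(8, 0, 0, rng=rng)
        assert unique_loops(toy["loops_a"], toy["loops_b"], 0).empty

    def test_tolerance_boundary(self):
        a = pd.DataFrame([{"chrom1": "chr1", "start1": 1000, "end1": 2000,
                           "chrom2": "chr1", "start2": 50_000, "end2": 51_000}])
        tol = 1000
        for offset, matched in [(tol // 2, True), (2 * tol, False)]:
            b = a.copy()
            b[["start1", "end1"]] += offset
            b[["start2", "end2"]] += offset
            assert unique_loops(a, b, tol).empty is matched

    def test_partition_invariant(self, rng):
        toy = gen_toy_loops(6, 4, 2, rng=rng)
        a, b = toy["loops_a"], toy["loops_b"]
        pairs = match_loops(a, b, 0)
        ua = unique_loops(a, b, 0)
        assert len(pairs) + len(ua) == len(a)
        # symmetric match count
        assert len(pairs) == len(match_loops(b, a, 0))


class TestLoopSizeStats:
    def test_mean_median(self):
        rows = [
            {"chrom1": "chr1", "start1": s, "end1": s + 10,
             "chrom2": "chr1", "start2": s + span, "end2": s + span + 10}
            for s, span in [(0, 100_000), (10_000_000, 200_000), (20_000_000, 300_000)]
        ]
        stats = loop_size_stats(pd.DataFrame(rows))
        assert stats["mean_span"] == pytest.approx(200_000)
        assert stats["median_span"] == pytest.approx(200_000)

    def test_single_loop(self):
        df = pd.DataFrame([{"chrom1": "chr2", "start1": 0, "end1": 10,
                            "chrom2": "chr2", "start2": 434_400, "end2": 434_410}])
        assert loop_size_stats(df)["mean_span"] == pytest.approx(434_400)

    def test_per_chromosome_counts_match_generator(self, rng):
        toy = gen_toy_loops(12, 0, 0, rng=rng)
        stats = loop_size_stats(toy["loops_a"])
        assert stats["per_chromosome"] == toy["per_chrom_a"]

    def test_empty_reported_missing(self):
        stats = loop_size_stats(pd.DataFrame(
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]))
        assert stats["n"] == 0 and stats["mean_span"] is None


class TestClassifyPairs:
    def test_cis_short_boundary(self):
        recs = pd.DataFrame({"chrom1": ["chr1"], "pos1": [100],
                             "chrom2": ["chr1"], "pos2": [15_000]})
        c = classify_pairs(records=recs)
        assert c.n_cis_short == 1  # distance 14900 < 20 kb

    def test_trans(self):
        recs = pd.DataFrame({"chrom1": ["chr1"], "pos1": [100],
                             "chrom2": ["chr2"], "pos2": [100]})
        assert classify_pairs(records=recs).n_trans == 1

    def test_percentages_from_counts(self):
        pct = classify_pairs(counts=(50, 30, 20)).percentages
        assert pct == pytest.approx((50.0, 30.0, 20.0))
        assert sum(pct) == pytest.approx(100.0, abs=1e-9)

    def test_negative_positions_rejected(self):
        recs = pd.DataFrame({"chrom1": ["chr1"], "pos1": [-5],
                             "chrom2": ["chr1"], "pos2": [100]})
        with pytest.raises(ValueError, match="negative"):
            classify_pairs(records=recs)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(counts=st.tuples(*[st.integers(0, 10_000)] * 3))
    def test_percentage_conservation(self, counts):
        if sum(counts) == 0:
            return
        assert sum(classify_pairs(counts=counts).percentages) == pytest.approx(
            100.0, abs=1e-9
        )


class TestMannWhitney:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        nx=st.integers(2, 6),
        ny=st.integers(2, 6),
        seed=st.integers(0, 1000),
    )
    def test_exact_enumeration_matches_scipy(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 20, nx).astype(float)  # ties included
        y = rng.integers(0, 20, ny).astype(float)
        u, p = mann_whitney_exact(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="exact" if len(np.unique(np.concatenate([x, y]))) == nx + ny else "asymptotic")
        assert u == pytest.approx(float(ref.statistic))
        if len(np.unique(np.concatenate([x, y]))) == nx + ny:  # scipy exact needs no ties
            assert p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_complete_separation(self):
        u, p = mann_whitney_exact(np.arange(1, 9), np.arange(101, 109))
        assert u == 0.0
        assert p < 0.001


class TestCompareConditions:
    def test_fold_change(self, rng):
        toy = gen_toy_loops(3, 10, 2, rng=rng)
        rep = compare_conditions(toy["loops_a"], toy["loops_b"])
        assert rep["n_unique_a"] == 10 and rep["n_unique_b"] == 2
        assert rep["fold_change_unique"] == pytest.approx(5.0)

    def test_identical_samples_null(self):
        spans = [100_000 + 10_000 * i for i in range(6)]
        rows = [
            {"chrom1": "chr1", "start1": 10_000_000 * i, "end1": 10_000_000 * i + 10,
             "chrom2": "chr1", "start2": 10_000_000 * i + s, "end2": 10_000_000 * i + s + 10}
            for i, s in enumerate(spans)
        ]
        a = pd.DataFrame(rows)
        b = a.copy()
        b[["start1", "end1", "start2", "end2"]] += 500_000_000  # all unique, same spans
        rep = compare_conditions(a, b)
        assert rep["mannwhitney_p"] == pytest.approx(1.0, abs=0.05)

    def test_empty_unique_reported_missing(self, rng):
        toy = gen_toy_loops(5, 0, 3, rng=rng)
        rep = compare_conditions(toy["loops_a"], toy["loops_b"])
        assert rep["n_unique_a"] == 0
        assert rep["fold_change_unique"] is None
        assert rep["mannwhitney_p"] is None
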