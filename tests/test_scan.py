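"""Scan-statistic p-value, window discovery, consolidation, quantification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endseq.annotations import GeneModel
from endseq.multimap import WeightedAssignment
from endseq.scan import (
    ScanConfig,
    ScanTest,
    consolidate_windows,
    discover_windows,
    pooled_scan,
    quantify,
    scan_pvalue,
)
from endseq.simdata import mc_scan_oracle


def _gene(symbol="G", blocks=((0, 1000),), strand="+", extension=None):
    return GeneModel(
        gene_symbol=symbol, chrom="chr1", strand=strand,
        exonic_blocks=list(blocks), extension_block=extension,
    )


class TestScanPvalue:
    def test_zero_count_is_certain(self):
        assert scan_pvalue(ScanTest(0, 100, 1000, 50)) == 1.0

    def test_count_above_n_impossible(self):
        assert scan_pvalue(ScanTest(101, 100, 1000, 50)) == 0.0

    def test_no_reads_gives_one(self):
        assert scan_pvalue(ScanTest(1, 0, 1000, 50)) == 1.0

    def test_single_read_always_in_some_window(self):
        assert scan_pvalue(ScanTest(1, 7, 1000, 50)) == 1.0

    def test_exhaustive_two_reads_four_positions(self):
        # enumeration of the 16 placements: 10/16 put both reads in one
        # 2-base window
        truth = mc_scan_oracle(2, 4, 2)[2]
        assert truth == pytest.approx(0.625)
        p = scan_pvalue(ScanTest(2, 2, 4, 2))
        assert truth / 2 <= p <= truth * 2

    def test_monotone_nonincreasing_in_k(self):
        for (N, L, w) in [(50, 2000, 50), (300, 1500, 100), (10, 5000, 50)]:
            ps = [scan_pvalue(ScanTest(k, N, L, w)) for k in range(0, N + 1)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_monotone_nondecreasing_in_n_at_fixed_k(self):
        ps = [scan_pvalue(ScanTest(8, N, 2000, 50)) for N in (20, 50, 100, 200, 400)]
        assert all(b >= a - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_within_factor_two_of_monte_carlo_spot_checks(self):
        # light calibration spot-checks; the full prescribed grid runs in
        # the acceptance suite
        for (N, L, w) in [(100, 1000, 50), (10, 1000, 100)]:
            tail = mc_scan_oracle(N, L, w, reps=20000, seed=5)
            for k in range(1, N + 1):
                if tail[k] < 5e-3:
                    break
                p = scan_pvalue(ScanTest(k, N, L, w))
                assert abs(math.log10(p) - math.log10(tail[k])) <= math.log10(2)

    def test_fractional_counts_rounded_up(self):
        assert scan_pvalue(ScanTest(4.5, 100, 1000, 50)) == scan_pvalue(
            ScanTest(5, 100, 1000, 50)
        )


class TestPooledScan:
    def test_point_pileup_found_and_significant(self):
        g = _gene()
        counts = {500: 50.0}
        config = ScanConfig(w_len=50, sig_test=0.05)
        cands = pooled_scan(g, counts, config)
        assert len(cands) == 1
        (s, e, k, p) = cands[0]
        assert s <= 500 < e and k == 50.0 and p < 1e-10

    def test_overlapping_windows_share_bases(self):
        g = _gene(blocks=[(0, 400)])
        counts = {i: 1.0 for i in range(0, 400, 4)}
        config = ScanConfig(w_len=100, w_olap=50, sig_test=1.0)
        cands = pooled_scan(g, counts, config)
        starts = [c[0] for c in cands]
        assert starts == [0, 50, 100, 150, 200, 250, 300]

    def test_sigtest_one_reports_every_window_with_a_read(self):
        g = _gene(blocks=[(0, 500)])
        counts = {10: 1.0, 260: 1.0}
        config = ScanConfig(w_len=50, sig_test=1.0)
        cands = pooled_scan(g, counts, config)
        covered = set()
        for s, e, k, _p in cands:
            assert k >= 1
            covered.update(range(s, e))
        assert {10, 260} <= covered

    def test_zero_count_windows_never_reported(self):
        g = _gene(blocks=[(0, 500)])
        cands = pooled_scan(g, {100: 5.0}, ScanConfig(w_len=50, sig_test=1.0))
        assert all(k > 0 for (_s, _e, k, _p) in cands)

    def test_uniform_reads_rarely_significant(self):
        # Monte-Carlo calibration: uniformly sprinkled genes should yield a
        # significant window in <= ~5% of genes at sigTest 0.05
        rng = np.random.default_rng(42)
        config = ScanConfig(w_len=50, sig_test=0.05)
        g = _gene(blocks=[(0, 2000)])
        hits = 0
        n_genes = 300
        for _ in range(n_genes):
            positions = rng.integers(0, 2000, size=100)
            counts = {}
            for p in positions:
                counts[p] = counts.get(p, 0.0) + 1.0
            if pooled_scan(g, counts, config):
                hits += 1
        assert hits / n_genes <= 0.08

    def test_minus_strand_transcript_orientation(self):
        # the 3'-most reads of a - strand gene sit at LOW genomic coords,
        # i.e. at the END of the transcript axis
        g = _gene(strand="-", blocks=[(0, 1000)])
        counts = {5: 30.0}
        cands = pooled_scan(g, counts, ScanConfig(w_len=50, sig_test=0.05))
        (s, e, k, p) = cands[0]
        assert e == 1000  # transcript-space end window


class TestConsolidation:
    def test_spike_centered_by_one_base_scan(self):
        g = _gene(blocks=[(0, 1000)])
        counts = {500: 30.0, 520: 5.0}
        config = ScanConfig(w_len=50, w_olap=25, sig_test=0.05)
        records = discover_windows(g, counts, config)
        assert len(records) == 1
        rec = records[0]
        assert rec.t_start <= 500 and 520 < rec.t_end
        assert rec.pooled_count == 35.0

    def test_tie_broken_toward_five_prime(self):
        g = _gene(blocks=[(0, 200)])
        counts = {100: 10.0}
        config = ScanConfig(w_len=50, w_olap=25, sig_test=0.5)
        records = discover_windows(g, counts, config)
        (rec,) = records
        # merged region [75, 150); every 50-base start in [75, 100] covers
        # the spike: the 5'-most wins the tie
        assert rec.t_start == 75

    def test_isolated_window_passes_through(self):
        g = _gene(blocks=[(0, 1000)])
        counts = {25: 20.0}
        config = ScanConfig(w_len=50, sig_test=0.05)
        cands = pooled_scan(g, counts, config)
        records = consolidate_windows(cands, counts, g, config)
        assert len(records) == 1
        assert records[0].t_end - records[0].t_start == 50

    def test_window_genomic_span_crosses_intron(self):
        g = _gene(blocks=[(0, 100), (200, 300)])
        counts = {95: 10.0, 205: 10.0}
        config = ScanConfig(w_len=20, sig_test=0.05)
        (rec,) = discover_windows(g, counts, config)
        # representative window spans the junction genomically
        assert rec.start < 100 and rec.end > 200


class TestQuantify:
    def _assign(self, exp_positions):
        return {
            exp: [
                WeightedAssignment("r%d" % i, "G", pos, 1.0)
                for i, pos in enumerate(positions)
            ]
            for exp, positions in exp_positions.items()
        }

    def test_single_window_holds_all_reads(self):
        g = _gene(blocks=[(0, 200)])
        counts = {100: 5.0, 110: 5.0}
        config = ScanConfig(w_len=50, sig_test=1.0)
        windows = discover_windows(g, counts, config)
        exp = self._assign({"e1": [100] * 5 + [110] * 5})
        gene_df, window_df = quantify(exp, windows, [g], config)
        assert gene_df.loc[0, "e1"] == 10.0
        assert window_df["e1"].sum() == 10.0

    def test_two_experiments_sum_to_pooled(self):
        g = _gene(blocks=[(0, 200)])
        pos_a, pos_b = [50] * 4, [60] * 6
        pooled = {50: 4.0, 60: 6.0}
        config = ScanConfig(w_len=50, sig_test=1.0)
        windows = discover_windows(g, pooled, config)
        exp = self._assign({"a": pos_a, "b": pos_b})
        gene_df, window_df = quantify(exp, windows, [g], config)
        assert gene_df.loc[0, "a"] == 4.0 and gene_df.loc[0, "b"] == 6.0
        for _, row in window_df.iterrows():
            rec = [w for w in windows if w.start == row["start"]][0]
            assert row["a"] + row["b"] == rec.pooled_count

    def test_extension_only_reads_counted(self):
        g = _gene(blocks=[(0, 1000)], extension=(1000, 1500))
        config = ScanConfig(w_len=50, w_ext=500, sig_test=1.0)
        exp = self._assign({"e1": [1200, 1210, 1220]})
        gene_df, _ = quantify(exp, [], [g], config)
        assert gene_df.loc[0, "e1"] == 3.0

    def test_gene_count_at_least_any_window_count(self, pipeline500):
        res = pipeline500["result"]
        gene_totals = res.gene_table.set_index("Symbol")["e1"]
        for _, row in res.window_table.iterrows():
            assert gene_totals[row["Symbol"]] >= row["e1"] - 1e-9

    def test_zero_read_experiment_warns_and_zero_rows(self, caplog):
        g = _gene(blocks=[(0, 200)])
        config = ScanConfig(w_len=50)
        gene_df, _ = quantify({"empty": []}, [], [g], config)
        assert gene_df.loc[0, "empty"] == 0.0
        assert any("no surviving reads" in m for m in caplog.messages)


@given(
    n=st.integers(min_value=1, max_value=60),
    seed=st.integers(min_value=0, max_value=10_000),
)
@settings(max_examples=25, deadline=None)
def test_candidate_windows_cover_every_read_at_sigtest_one(n, seed):
    rng = np.random.default_rng(seed)
    g = _gene(blocks=[(0, 700)])
    counts = {}
    for p in rng.integers(0, 700, size=n):
        counts[int(p)] = counts.get(int(p), 0.0) + 1.0
    cands = pooled_scan(g, counts, ScanConfig(w_len=50, sig_test=1.0))
    covered = set()
    for s, e, _k, _p in cands:
        covered.update(range(s, e))
    assert set(counts) <= covered
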