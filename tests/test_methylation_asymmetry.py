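import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from spinasym import (
    ThresholdConfig,
    adjust_fdr,
    call_diff_methylation,
    consensus_across_samples,
    fisher_cpg,
)


def cpg_table(rows, stage="wk8"):
    """rows: (chrom, pos, sample, side, coverage, methylated)."""
    return pd.DataFrame(
        [(c, p, "+", s, stage, side, cov, met) for c, p, s, side, cov, met in rows],
        columns=["chrom", "pos", "strand", "sample_id", "stage", "side",
                 "coverage", "methylated"],
    )


class TestFisher:
    def test_symmetric_table_p_one(self):
        assert fisher_cpg(5, 5, 5, 5) == pytest.approx(1.0)

    def test_strong_diagonal_vs_enumeration(self):
        expected = _oracles.fisher_two_sided_exact(9, 1, 1, 9)
        assert expected < 0.01
        assert fisher_cpg(9, 1, 1, 9) == pytest.approx(expected, abs=1e-12)

    def test_extreme_table_is_margin_minimum(self):
        expected = _oracles.fisher_two_sided_exact(0, 10, 10, 0)
        observed = fisher_cpg(0, 10, 10, 0)
        assert observed == pytest.approx(expected, abs=1e-12)
        # no table with these margins can have a smaller two-sided p
        others = [_oracles.fisher_two_sided_exact(a, 10 - a, 10 - a, a)
                  for a in range(11)]
        assert expected == min(others)

    @given(a=st.integers(0, 15), b=st.integers(0, 15),
           c=st.integers(0, 15), d=st.integers(0, 15))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_two_sidedness_side_swap_invariance(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        assert fisher_cpg(a, b, c, d) == pytest.approx(fisher_cpg(c, d, a, b),
                                                       abs=1e-12)

    def test_zero_coverage_side_rejected(self):
        with pytest.raises(ValueError):
            fisher_cpg(0, 0, 5, 5)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_cpg(-1, 5, 5, 5)


class TestAdjustFdr:
    def test_hand_computed_bh(self):
        q = adjust_fdr([0.01, 0.02, 0.03])
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones_stay_ones(self):
        assert adjust_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_never_decreases_and_matches_textbook_bh(self, ps):
        q = adjust_fdr(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert q == pytest.approx(_oracles.bh_adjust(ps), abs=1e-12)

    def test_permutation_equivariance(self):
        ps = [0.4, 0.01, 0.2, 0.05, 0.8]
        perm = [2, 0, 4, 1, 3]
        q = adjust_fdr(ps)
        q_perm = adjust_fdr([ps[i] for i in perm])
        assert q_perm == pytest.approx([q[i] for i in perm])


class TestCalling:
    def _family(self):
        # one strong CpG in a family of null CpGs (the FDR test family)
        rows = [("chr1", 100, "s1", "left", 10, 2),
                ("chr1", 100, "s1", "right", 10, 8)]
        for i in range(5):
            rows += [("chr1", 200 + i, "s1", "left", 20, 10),
                     ("chr1", 200 + i, "s1", "right", 20, 10)]
        return cpg_table(rows)

    def test_joint_rule_with_hand_bh(self):
        calls = call_diff_methylation(self._family(), "wk8", "s1")
        strong = calls[calls["pos"] == 100].iloc[0]
        assert strong["diff"] == pytest.approx(60.0)
        p = _oracles.fisher_two_sided_exact(2, 8, 8, 2)
        assert strong["p_raw"] == pytest.approx(p, abs=1e-12)
        q = _oracles.bh_adjust(list(calls.sort_values("pos")["p_raw"]))[0]
        assert strong["q"] == pytest.approx(q, abs=1e-12)
        assert bool(strong["significant"]) == (q < 0.01 and 60.0 > 25.0)

    def test_magnitude_gate_blocks_small_differences(self):
        # 50% vs 60% at very high coverage: tiny p but diff <= 25 points
        rows = [("chr1", 100, "s1", "left", 1000, 500),
                ("chr1", 100, "s1", "right", 1000, 600)]
        calls = call_diff_methylation(cpg_table(rows), "wk8", "s1")
        row = calls.iloc[0]
        assert row["q"] < 0.01
        assert not row["significant"]

    def test_identical_counts_p_one(self):
        rows = [("chr1", 100, "s1", "left", 30, 12),
                ("chr1", 100, "s1", "right", 30, 12)]
        row = call_diff_methylation(cpg_table(rows), "wk8", "s1").iloc[0]
        assert row["p_raw"] == pytest.approx(1.0)
        assert not row["significant"]

    def test_one_sided_coverage_excluded(self):
        rows = [("chr1", 100, "s1", "left", 10, 2)]
        calls = call_diff_methylation(cpg_table(rows), "wk8", "s1")
        assert calls.empty

    def test_joint_rule_monotonicity(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(80):
            cov = int(rng.integers(10, 60))
            ml = int(rng.integers(0, cov + 1))
            mr = int(rng.integers(0, cov + 1))
            rows += [("chr1", 100 + i, "s1", "left", cov, ml),
                     ("chr1", 100 + i, "s1", "right", cov, mr)]
        table = cpg_table(rows)
        base = call_diff_methylation(table, "wk8", "s1")["significant"].sum()
        stricter_diff = call_diff_methylation(
            table, "wk8", "s1", ThresholdConfig(meth_diff_min=40))["significant"].sum()
        stricter_q = call_diff_methylation(
            table, "wk8", "s1", ThresholdConfig(fdr_q=0.001))["significant"].sum()
        assert stricter_diff <= base
        assert stricter_q <= base


class TestConsensus:
    def _two_sample_calls(self, dir_a, dir_b, diff_a=30.0, diff_b=40.0):
        sign = {"left": -1, "right": 1, "none": 0}
        rows = []
        for sample, d, diff in (("s1", dir_a, diff_a), ("s2", dir_b, diff_b)):
            rows.append({
                "chrom": "chr1", "pos": 100, "strand": "+",
                "sample_id": sample, "stage": "wk8", "p_raw": 1e-5, "q": 1e-4,
                "pct_left": 50.0, "pct_right": 50.0 + sign[d] * diff,
                "diff": sign[d] * diff, "significant": d != "none",
                "direction": d,
            })
        return pd.DataFrame(rows)

    def test_direction_conflict_excluded(self):
        calls = self._two_sample_calls("right", "left")
        assert consensus_across_samples(calls, "wk8").empty

    def test_agreeing_samples_average_magnitude(self):
        calls = self._two_sample_calls("right", "right", 30.0, 40.0)
        consensus = consensus_across_samples(calls, "wk8")
        row = consensus.iloc[0]
        assert row["direction"] == "right"
        assert row["mean_abs_diff"] == pytest.approx(35.0)
        assert row["n_samples_support"] == 2

    def test_significant_in_one_sample_only_excluded(self):
        calls = self._two_sample_calls("right", "none")
        assert consensus_across_samples(calls, "wk8").empty

    def test_single_sample_passes_through(self):
        calls = self._two_sample_calls("right", "right").iloc[:1]
        consensus = consensus_across_samples(calls, "wk8")
        assert len(consensus) == 1
        assert consensus.iloc[0]["n_samples_support"] == 1

    def test_consensus_bounded_by_per_sample_counts(self, small_bundle):
        cfg = ThresholdConfig()
        samples = sorted(small_bundle.cpg.loc[
            small_bundle.cpg["stage"] == "wk8", "sample_id"].unique())
        per_sample = [call_diff_methylation(small_bundle.cpg, "wk8", s, cfg)
                      for s in samples]
        counts = [c["significant"].sum() for c in per_sample]
        consensus = consensus_across_samples(
            pd.concat(per_sample, ignore_index=True), "wk8")
        assert len(consensus) <= min(counts)
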