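import math

import numpy as np
import pandas as pd
import pytest

import _oracles
from spinasym import (
    SyntheticConfig,
    ThresholdConfig,
    assign_cpgs_to_genes,
    classify_gene,
    generate_dataset,
    methylation_lq,
    partition_summary_from_counts,
    run_pipeline,
)
from spinasym.errors import PipelineError


def consensus_frame(rows):
    """rows: (chrom, pos 1-based, direction)."""
    return pd.DataFrame(
        [(c, p, "+", d, 40.0, 2) for c, p, d in rows],
        columns=["chrom", "pos", "strand", "direction", "mean_abs_diff",
                 "n_samples_support"],
    )


def gene_frame(rows):
    """rows: (gene_id, chrom, start, end, strand), 0-based half-open."""
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


class TestWindowAssignment:
    GENES = gene_frame([("gA", "chr1", 1000, 2000, "+"),
                        ("gB", "chr1", 1000, 2000, "-")])

    @pytest.mark.parametrize("pos0,gene,assigned", [
        (999, "gA", True),    # inside the upstream window of a + gene
        (2000, "gA", False),  # half-open end, no downstream window
        (2100, "gB", True),   # upstream is rightward on the - strand
        (999, "gB", False),   # no upstream window left of a - gene
        (1500, "gA", True),   # gene body
        (1500, "gB", True),
    ])
    def test_strand_aware_window(self, pos0, gene, assigned):
        consensus = consensus_frame([("chr1", pos0 + 1, "left")])
        result = assign_cpgs_to_genes(consensus, self.GENES)
        assert (gene in result and not result[gene].empty) is assigned

    def test_ignore_strand_flag(self):
        consensus = consensus_frame([("chr1", 999 + 1, "left")])
        cfg = ThresholdConfig(ignore_strand=True)
        result = assign_cpgs_to_genes(consensus, self.GENES, cfg)
        assert "gA" in result and "gB" in result

    def test_agreement_with_naive_scan(self):
        rng = np.random.default_rng(6)
        genes = gene_frame([
            (f"g{i:03d}", "chr1", int(s), int(s + rng.integers(500, 3000)),
             rng.choice(["+", "-"]))
            for i, s in enumerate(np.sort(rng.integers(0, 400_000, size=150)))
        ])
        consensus = consensus_frame([
            ("chr1", int(p), rng.choice(["left", "right"]))
            for p in np.sort(rng.integers(1, 400_000, size=2000))
        ])
        result = assign_cpgs_to_genes(consensus, genes)
        expected = _oracles.naive_window_assignment(
            consensus.to_dict("records"), genes.to_dict("records"))
        assert set(result) == set(expected)
        for gene_id, idx in expected.items():
            got = result[gene_id][["chrom", "pos"]].values.tolist()
            want = [[consensus.iloc[i]["chrom"], consensus.iloc[i]["pos"]]
                    for i in idx]
            assert sorted(got) == sorted(want)


class TestLateralityQuotient:
    @pytest.mark.parametrize("left,right,expected", [
        (2, 2, 0.0),
        (1, 3, 50.0),
        (5, 0, -100.0),
        (0, 7, 100.0),
    ])
    def test_formula(self, left, right, expected):
        assert methylation_lq(left, right) == pytest.approx(expected)

    def test_undefined_when_no_cpgs(self):
        assert math.isnan(methylation_lq(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            methylation_lq(-1, 2)

    def test_bounded_and_antisymmetric(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            left, right = int(rng.integers(0, 50)), int(rng.integers(0, 50))
            if left + right == 0:
                continue
            lq = methylation_lq(left, right)
            assert -100.0 <= lq <= 100.0
            assert methylation_lq(right, left) == pytest.approx(-lq)


class TestClassification:
    @pytest.mark.parametrize("direction,lq,target,expected", [
        ("right", -60.0, False, "methylation_only"),
        ("right", -60.0, True, "both"),
        ("right", 60.0, False, "unexplained"),  # same-direction does not explain
        ("right", -25.0, False, "unexplained"),  # strict inequality
        ("left", 60.0, False, "methylation_only"),
        ("left", -60.0, True, "mirna_only"),
        ("left", float("nan"), True, "mirna_only"),
        ("right", float("nan"), False, "unexplained"),
    ])
    def test_rule_cells(self, direction, lq, target, expected):
        assert classify_gene(direction, lq, target) == expected

    def test_non_asymmetric_gene_rejected(self):
        with pytest.raises(ValueError):
            classify_gene("none", 50.0, False)


class TestPartitionSummary:
    def test_paper_style_rounding_large(self):
        summary = partition_summary_from_counts(451, 18, 47, 1690)
        assert summary["pct"] == {"methylation_only": 27, "both": 1,
                                  "mirna_only": 3, "unexplained": 69}

    def test_paper_style_rounding_small(self):
        summary = partition_summary_from_counts(2, 0, 6, 24)
        assert summary["pct"] == {"methylation_only": 8, "both": 0,
                                  "mirna_only": 25, "unexplained": 67}

    def test_nothing_explained(self):
        summary = partition_summary_from_counts(0, 0, 0, 50)
        assert summary["pct"] == {"methylation_only": 0, "both": 0,
                                  "mirna_only": 0, "unexplained": 100}

    def test_empty_total_rejected(self):
        with pytest.raises(PipelineError):
            partition_summary_from_counts(0, 0, 0, 0)

    def test_overfull_counts_rejected(self):
        with pytest.raises(PipelineError):
            partition_summary_from_counts(10, 0, 0, 5)


class TestPipeline:
    def _small_cfg(self, **kw):
        base = dict(n_genes=150, n_mirnas=30, cpgs_per_gene=2,
                    frac_asym_expr=0.2, seed=8)
        base.update(kw)
        return SyntheticConfig(**base)

    def test_rerun_is_deterministic(self):
        b = generate_dataset(self._small_cfg())
        r1 = run_pipeline(b.expression, b.mirna, b.targets, b.cpg, b.genes)
        r2 = run_pipeline(b.expression, b.mirna, b.targets, b.cpg, b.genes)
        assert r1.keys() == r2.keys()
        for stage in r1:
            assert r1[stage]["summary"] == r2[stage]["summary"]
            pd.testing.assert_frame_equal(r1[stage]["partitions"],
                                          r2[stage]["partitions"])

    def test_no_coupling_means_all_unexplained(self):
        b = generate_dataset(self._small_cfg(
            frac_meth_coupled=0.0, frac_mirna_coupled=0.0, both_overlap=0.0))
        report = run_pipeline(b.expression, b.mirna, b.targets, b.cpg, b.genes)
        pct = report["wk8"]["summary"]["partition"]["pct"]
        # planted couplings are absent; only chance false calls could explain
        assert pct["unexplained"] >= 95

    def test_partition_counts_conserve_asym_calls(self):
        b = generate_dataset(self._small_cfg())
        report = run_pipeline(b.expression, b.mirna, b.targets, b.cpg, b.genes)
        for stage, res in report.items():
            n_asym = res["summary"]["expression"]["n_asym"]
            if n_asym:
                assert sum(res["summary"]["partition"]["counts"].values()) == n_asym

    def test_report_written_to_disk(self, tmp_path):
        from spinasym import write_report

        b = generate_dataset(self._small_cfg())
        report = run_pipeline(b.expression, b.mirna, b.targets, b.cpg, b.genes)
        write_report(report, tmp_path)
        assert (tmp_path / "summary.json").exists()
        assert (tmp_path / "wk8_partitions.tsv").exists()
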