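"""Integration of expression, methylation, and miRNA asymmetries.

Consensus CpGs are assigned to genes over the gene body plus an upstream
promoter window (1500 nt 5' of the TSS by default, strand-aware).  Each
asymmetrically expressed gene gets a methylation laterality quotient

    LQ = 100 * (n_hyper_right - n_hyper_left) / (n_hyper_right + n_hyper_left)

over its assigned hyper-methylated CpG counts (undefined when it has
none), and is then partitioned into one of four mutually exclusive
categories: ``methylation_only`` when its promoter/body methylation is
strongly asymmetric (|LQ| beyond ``lq_threshold``) toward the side
*opposite* its expression, ``mirna_only`` when it is a predicted target
of an asymmetrically expressed miRNA, ``both``, or ``unexplained``.
Percentages per category are reported as the share of asymmetric genes
(the operational "variance explained"), rounded half-up to integers.
"""

from __future__ import annotations

import json
import logging
import math
from collections import defaultdict

import pandas as pd
from intervaltree import IntervalTree

from ._stats import percent
from .config import STAGES, ThresholdConfig
from .errors import PipelineError
from . import expression_asymmetry as ea
from . import methylation_asymmetry as ma
from . import mirna_asymmetry as mi

logger = logging.getLogger(__name__)

CATEGORIES = ("methylation_only", "both", "mirna_only", "unexplained")

PARTITION_COLUMNS = ["gene_id", "stage", "chrom", "expr_direction", "log2fc",
                     "n_cpg_hyper_left", "n_cpg_hyper_right", "lq",
                     "is_mirna_target", "category"]


def gene_windows(genes: pd.DataFrame, cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Half-open search window per gene: body plus the upstream promoter.

    Upstream is 5' of the TSS: left of ``start`` for plus-strand genes,
    right of ``end`` for minus-strand genes (always left of ``start`` when
    ``ignore_strand`` is set).  Window starts are clipped at zero.
    """
    cfg = cfg or ThresholdConfig()
    w = cfg.upstream_window
    out = genes.copy()
    if cfg.ignore_strand:
        out["win_start"] = (out["start"] - w).clip(lower=0)
        out["win_end"] = out["end"]
    else:
        minus = out["strand"] == "-"
        out["win_start"] = out["start"].where(minus, (out["start"] - w).clip(lower=0))
        out["win_end"] = (out["end"] + w).where(minus, out["end"])
    return out


def assign_cpgs_to_genes(consensus: pd.DataFrame, genes: pd.DataFrame,
                         cfg: ThresholdConfig | None = None) -> dict[str, pd.DataFrame]:
    """Map gene_id -> consensus CpGs falling in the gene's search window.

    A CpG may be assigned to several overlapping genes.  CpG positions are
    1-based in the table and compared on the 0-based axis.
    """
    cfg = cfg or ThresholdConfig()
    windows = gene_windows(genes, cfg)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for row in windows.itertuples(index=False):
        if row.win_start < row.win_end:
            trees[row.chrom][row.win_start:row.win_end] = row.gene_id
    hits: dict[str, list[int]] = defaultdict(list)
    for idx, row in enumerate(consensus.itertuples(index=False)):
        pos0 = row.pos - 1
        for iv in trees.get(row.chrom, IntervalTree())[pos0]:
            hits[iv.data].append(idx)
    return {gene: consensus.iloc[sorted(rows)].reset_index(drop=True)
            for gene, rows in hits.items()}


def methylation_lq(n_hyper_left: int, n_hyper_right: int) -> float:
    """Laterality quotient of hyper-methylated CpG counts; NaN when both zero."""
    if n_hyper_left < 0 or n_hyper_right < 0:
        raise ValueError("CpG counts must be non-negative")
    total = n_hyper_left + n_hyper_right
    if total == 0:
        return float("nan")
    return 100.0 * (n_hyper_right - n_hyper_left) / total


def classify_gene(expr_direction: str, lq: float, is_target: bool,
                  cfg: ThresholdConfig | None = None) -> str:
    """Four-way explanation category for one asymmetrically expressed gene.

    Methylation explains the gene when LQ is strongly asymmetric toward
    the side opposite the expression direction (strict inequalities);
    an undefined (NaN) LQ never explains.  miRNA explains when the gene is
    a target of an asymmetric miRNA.
    """
    cfg = cfg or ThresholdConfig()
    if expr_direction not in ("left", "right"):
        raise ValueError("classification applies only to asymmetric genes")
    if lq is None or math.isnan(lq):
        meth_flag = False
    elif expr_direction == "right":
        meth_flag = lq < -cfg.lq_threshold
    else:
        meth_flag = lq > cfg.lq_threshold
    if meth_flag and is_target:
        return "both"
    if meth_flag:
        return "methylation_only"
    if is_target:
        return "mirna_only"
    return "unexplained"


def partition_genes(expr_calls: pd.DataFrame, consensus: pd.DataFrame,
                    genes: pd.DataFrame, mirna_target_set: set[str],
                    cfg: ThresholdConfig | None = None,
                    directional_targets: dict[str, set[str]] | None = None,
                    ) -> pd.DataFrame:
    """Per-gene partition table for one stage's asymmetric expression calls.

    When ``cfg.strict_mirna_direction`` is set, ``directional_targets``
    (targets keyed by miRNA direction) restricts the miRNA flag to genes
    whose expression is down on the side the targeting miRNA is up.
    """
    cfg = cfg or ThresholdConfig()
    asym = expr_calls[expr_calls["direction"] != "none"]
    assignments = assign_cpgs_to_genes(consensus, genes, cfg)
    chrom_of = dict(zip(genes["gene_id"], genes["chrom"]))
    rows = []
    for call in asym.itertuples(index=False):
        assigned = assignments.get(call.feature_id)
        if assigned is None or assigned.empty:
            n_left = n_right = 0
        else:
            n_left = int((assigned["direction"] == "left").sum())
            n_right = int((assigned["direction"] == "right").sum())
        lq = methylation_lq(n_left, n_right)
        if cfg.strict_mirna_direction and directional_targets is not None:
            # a repressive miRNA up on one side explains a gene down on
            # that side, i.e. expressed toward the opposite side
            opposite = "left" if call.direction == "right" else "right"
            is_target = call.feature_id in directional_targets.get(opposite, set())
        else:
            is_target = call.feature_id in mirna_target_set
        rows.append({
            "gene_id": call.feature_id,
            "stage": call.stage,
            "chrom": chrom_of.get(call.feature_id, "NA"),
            "expr_direction": call.direction,
            "log2fc": call.log2fc,
            "n_cpg_hyper_left": n_left,
            "n_cpg_hyper_right": n_right,
            "lq": lq,
            "is_mirna_target": is_target,
            "category": classify_gene(call.direction, lq, is_target, cfg),
        })
    out = pd.DataFrame(rows, columns=PARTITION_COLUMNS)
    return out.sort_values(["gene_id"], kind="mergesort").reset_index(drop=True)


def partition_summary(partitions: pd.DataFrame, n_asym_total: int | None = None) -> dict:
    """Category counts and integer percentages of asymmetric genes."""
    counts = {cat: int((partitions["category"] == cat).sum()) for cat in CATEGORIES}
    n = len(partitions) if n_asym_total is None else n_asym_total
    return partition_summary_from_counts(
        counts["methylation_only"], counts["both"], counts["mirna_only"], n
    )


def partition_summary_from_counts(n_meth: int, n_both: int, n_mirna: int,
                                  n_asym_total: int) -> dict:
    """Summary from pre-tabulated category counts.

    The unexplained count is the remainder; each percentage is
    100 * count / n_asym_total rounded half-up to the nearest integer.
    """
    if n_asym_total == 0:
        raise PipelineError("no asymmetric genes: empty partition summary")
    explained = n_meth + n_both + n_mirna
    if explained > n_asym_total:
        raise PipelineError("explained counts exceed the asymmetric total")
    counts = {
        "methylation_only": n_meth,
        "both": n_both,
        "mirna_only": n_mirna,
        "unexplained": n_asym_total - explained,
    }
    pct = {cat: int(percent(c, n_asym_total, decimals=0))
           for cat, c in counts.items()}
    return {"n_asym": n_asym_total, "counts": counts, "pct": pct}


def run_pipeline(expression: pd.DataFrame,
                 mirna: pd.DataFrame | None,
                 targets: pd.DataFrame | None,
                 cpg: pd.DataFrame | None,
                 genes: pd.DataFrame,
                 cfg: ThresholdConfig | None = None,
                 total_transcripts: int | None = None) -> dict:
    """Run every stage of the analysis on validated input tables.

    Returns a report dict keyed by stage, each entry holding the
    expression calls, miRNA calls, consensus CpGs, per-gene partitions and
    the summary dict.  Deterministic for fixed inputs.
    """
    cfg = cfg or ThresholdConfig()
    if total_transcripts is None:
        total_transcripts = expression["feature_id"].nunique()
    report: dict[str, dict] = {}
    stages = [s for s in STAGES if s in set(expression["stage"])]
    if not stages:
        raise PipelineError("expression table covers no known stage")
    for stage in stages:
        try:
            report[stage] = _run_stage(
                expression, mirna, targets, cpg, genes, cfg,
                stage, total_transcripts,
            )
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage
            raise PipelineError(f"stage {stage}: {exc}") from exc
    return report


def _run_stage(expression, mirna, targets, cpg, genes, cfg, stage,
               total_transcripts) -> dict:
    expr_calls = ea.call_expression_asymmetry(expression, stage, cfg)
    expr_summary = ea.summarize_expression(expr_calls, total_transcripts)

    mirna_calls = pd.DataFrame(columns=mi.CALL_COLUMNS)
    target_set: set[str] = set()
    dir_targets: dict[str, set[str]] | None = None
    n_mirna_expressed = 0
    if mirna is not None and not mirna.empty:
        kept = mi.filter_low_count(mirna, stage, cfg)
        n_mirna_expressed = kept["mirna_id"].nunique()
        mirna_calls = mi.call_mirna_asymmetry(kept, stage, cfg)
        if targets is not None:
            target_set = mi.targets_of_asymmetric(mirna_calls, targets, cfg)
            dir_targets = mi.directional_targets(mirna_calls, targets, cfg)

    consensus = pd.DataFrame(columns=ma.CONSENSUS_COLUMNS)
    if cpg is not None and not cpg.empty:
        sample_ids = sorted(cpg.loc[cpg["stage"] == stage, "sample_id"].unique())
        per_sample = [ma.call_diff_methylation(cpg, stage, s, cfg)
                      for s in sample_ids]
        if per_sample:
            all_calls = pd.concat(per_sample, ignore_index=True)
            consensus = ma.consensus_across_samples(all_calls, stage)

    partitions = partition_genes(expr_calls, consensus, genes, target_set,
                                 cfg, dir_targets)
    summary = {
        "expression": expr_summary,
        "mirna": {
            "n_expressed": n_mirna_expressed,
            **(mi.summarize_mirna(mirna_calls, n_mirna_expressed)
               if n_mirna_expressed else
               {"n_asym": 0, "n_left": 0, "n_right": 0, "pct": 0.0}),
        },
        "methylation": ma.summarize_consensus(consensus),
        "partition": (partition_summary(partitions)
                      if len(partitions) else
                      {"n_asym": 0, "counts": {}, "pct": {}}),
    }
    return {
        "expression_calls": expr_calls,
        "mirna_calls": mirna_calls,
        "consensus_cpgs": consensus,
        "partitions": partitions,
        "summary": summary,
    }


def write_report(report: dict, out_dir) -> None:
    """Write per-stage TSVs and a combined summary.json under ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    summary = {}
    for stage, res in report.items():
        for name in ("expression_calls", "mirna_calls", "consensus_cpgs",
                     "partitions"):
            res[name].to_csv(os.path.join(out_dir, f"{stage}_{name}.tsv"),
                             sep="\t", index=False)
        summary[stage] = res["summary"]
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
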