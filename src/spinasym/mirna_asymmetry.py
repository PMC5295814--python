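"""Per-miRNA left/right asymmetry from raw counts, and target matching.

Raw read counts are filtered (a miRNA is dropped only when it has fewer
than ``mirna_min_reads`` reads on *both* sides, which is what inflates
fold changes), converted to RPKM, and called on the fold change of
per-side RPKM means with the *minimum* rule |log2fc| >= threshold —
inclusive, unlike the strict mRNA rule.  Asymmetric miRNAs are then
matched to the genes they are predicted to repress at interaction
probability strictly above ``target_prob_min``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import percent
from .config import ThresholdConfig

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["mirna_id", "stage", "rpkm_left", "rpkm_right",
                "log2fc", "direction", "floored"]


def filter_low_count(table: pd.DataFrame, stage: str,
                     cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Drop miRNAs whose stage-level counts are below the read floor.

    A miRNA's per-side count is summed across the stage's samples and the
    miRNA is removed iff it is below ``mirna_min_reads`` on both sides
    (mode ``"both"``), or on either side (mode ``"either"``).
    """
    cfg = cfg or ThresholdConfig()
    sub = table[table["stage"] == stage]
    if sub.empty:
        return sub.copy()
    side_counts = sub.pivot_table(index="mirna_id", columns="side",
                                  values="read_count", aggfunc="sum")
    low = side_counts < cfg.mirna_min_reads
    if cfg.mirna_filter_mode == "both":
        drop = low.all(axis=1)
    else:
        drop = low.any(axis=1)
    kept_ids = set(side_counts.index[~drop])
    n_dropped = int(drop.sum())
    if n_dropped:
        logger.info("stage %s: removed %d low-count miRNAs", stage, n_dropped)
    return sub[sub["mirna_id"].isin(kept_ids)].reset_index(drop=True)


def rpkm(read_count: float, transcript_length: float, library_size: float) -> float:
    """Reads per kilobase of transcript per million mapped reads.

    Exactly ``1e9 * read_count / (library_size * transcript_length)``.
    """
    if transcript_length <= 0 or library_size <= 0:
        raise ValueError("transcript_length and library_size must be positive")
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    return 1e9 * read_count / (library_size * transcript_length)


def call_mirna_asymmetry(table: pd.DataFrame, stage: str,
                         cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """One call per kept miRNA on the fold change of per-side mean RPKM.

    A side whose mean RPKM is zero after filtering is floored at the RPKM
    equivalent of ``rpkm_floor_reads`` reads so the ratio stays finite;
    such calls carry ``floored=True``.  Direction uses the inclusive rule
    |log2fc| >= ``lfc_threshold``.
    """
    cfg = cfg or ThresholdConfig()
    sub = table[table["stage"] == stage].copy()
    if sub.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    sub["rpkm"] = 1e9 * sub["read_count"] / (
        sub["library_size"].astype(float) * sub["transcript_length"].astype(float)
    )
    # floor in RPKM units, per row, then aggregated: use the per-miRNA mean
    # of the floor equivalents so libraries of different depth are respected
    sub["rpkm_floor"] = 1e9 * cfg.rpkm_floor_reads / (
        sub["library_size"].astype(float) * sub["transcript_length"].astype(float)
    )
    means = sub.pivot_table(index="mirna_id", columns="side", values="rpkm",
                            aggfunc="mean")
    floors = sub.groupby("mirna_id")["rpkm_floor"].mean()
    calls = pd.DataFrame({
        "mirna_id": means.index,
        "rpkm_left": means["left"].to_numpy(),
        "rpkm_right": means["right"].to_numpy(),
    })
    floor = floors.loc[means.index].to_numpy()
    left = calls["rpkm_left"].to_numpy(copy=True)
    right = calls["rpkm_right"].to_numpy(copy=True)
    floored = (left == 0) | (right == 0)
    if floored.any():
        logger.info("stage %s: %d miRNA(s) with a zero side floored",
                    stage, int(floored.sum()))
    left = np.where(left == 0, floor, left)
    right = np.where(right == 0, floor, right)
    calls["log2fc"] = np.log2(right / left)
    calls["floored"] = floored
    calls["direction"] = "none"
    calls.loc[calls["log2fc"] >= cfg.lfc_threshold, "direction"] = "right"
    calls.loc[calls["log2fc"] <= -cfg.lfc_threshold, "direction"] = "left"
    calls["stage"] = stage
    calls = calls.sort_values(
        ["log2fc", "mirna_id"],
        key=lambda s: -s.abs() if s.name == "log2fc" else s,
        kind="mergesort",
    )
    return calls[CALL_COLUMNS].reset_index(drop=True)


def targets_of_asymmetric(mirna_calls: pd.DataFrame, target_map: pd.DataFrame,
                          cfg: ThresholdConfig | None = None) -> set[str]:
    """Genes targeted (probability strictly above the floor) by any
    asymmetric miRNA of the stage."""
    cfg = cfg or ThresholdConfig()
    asym = set(mirna_calls.loc[mirna_calls["direction"] != "none", "mirna_id"])
    if not asym:
        return set()
    hits = target_map[
        target_map["mirna_id"].isin(asym)
        & (target_map["probability"] > cfg.target_prob_min)
    ]
    return set(hits["gene_id"])


def directional_targets(mirna_calls: pd.DataFrame, target_map: pd.DataFrame,
                        cfg: ThresholdConfig | None = None) -> dict[str, set[str]]:
    """Target genes keyed by the direction of the targeting miRNA.

    Used by the optional strict explanation mode, where a miRNA only
    explains a gene that is down on the side the miRNA is up.
    """
    cfg = cfg or ThresholdConfig()
    out: dict[str, set[str]] = {"left": set(), "right": set()}
    for direction in ("left", "right"):
        ids = set(mirna_calls.loc[mirna_calls["direction"] == direction, "mirna_id"])
        if not ids:
            continue
        hits = target_map[
            target_map["mirna_id"].isin(ids)
            & (target_map["probability"] > cfg.target_prob_min)
        ]
        out[direction] = set(hits["gene_id"])
    return out


def summarize_mirna(calls: pd.DataFrame, total_expressed: int) -> dict:
    """Asymmetric miRNA counts and their percentage of expressed miRNAs."""
    n_left = int((calls["direction"] == "left").sum())
    n_right = int((calls["direction"] == "right").sum())
    return mirna_summary_from_counts(n_left, n_right, total_expressed)


def mirna_summary_from_counts(n_left: int, n_right: int,
                              total_expressed: int) -> dict:
    n_asym = n_left + n_right
    return {
        "n_asym": n_asym,
        "n_left": n_left,
        "n_right": n_right,
        "pct": percent(n_asym, total_expressed, decimals=2),
    }
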