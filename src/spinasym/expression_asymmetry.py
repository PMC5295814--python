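"""Per-gene left/right expression asymmetry calling.

With two replicates per stage (one at the last stage) no per-gene variance
test is sensible, so asymmetry is called on the fold change of per-side
mean FPKM: a gene abundant on both sides (mean FPKM >= ``fpkm_min``) is
called rightward when log2(mean_right / mean_left) exceeds
``lfc_threshold`` (strict inequality), leftward when it falls below the
negative threshold.  Positive log2 fold change always means rightward.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import percent
from .config import ThresholdConfig
from .errors import PipelineError

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["feature_id", "stage", "mean_left", "mean_right",
                "log2fc", "direction", "abundant"]


def _side_means(table: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Per-feature mean FPKM for each side across the stage's samples."""
    sub = table[table["stage"] == stage]
    if sub.empty:
        logger.warning("stage %s has no expression rows", stage)
        return pd.DataFrame(columns=["feature_id", "mean_left", "mean_right"])
    means = (
        sub.pivot_table(index="feature_id", columns="side", values="fpkm",
                        aggfunc="mean")
        .rename(columns={"left": "mean_left", "right": "mean_right"})
        .reset_index()
    )
    means.columns.name = None
    return means


def abundance_filter(table: pd.DataFrame, stage: str,
                     cfg: ThresholdConfig | None = None) -> set[str]:
    """Features whose mean FPKM is at least ``fpkm_min`` on *both* sides."""
    cfg = cfg or ThresholdConfig()
    means = _side_means(table, stage)
    if means.empty:
        return set()
    keep = (means["mean_left"] >= cfg.fpkm_min) & (means["mean_right"] >= cfg.fpkm_min)
    return set(means.loc[keep, "feature_id"])


def fold_change_of_means(table: pd.DataFrame, feature_id: str, stage: str) -> float:
    """log2 of the right-side mean over the left-side mean for one feature.

    With a single sample per stage this reduces to the per-sample ratio.
    """
    means = _side_means(table, stage)
    row = means[means["feature_id"] == feature_id]
    if row.empty:
        raise PipelineError(f"feature {feature_id!r} absent at stage {stage}")
    left = float(row["mean_left"].iloc[0])
    right = float(row["mean_right"].iloc[0])
    if left == 0 or right == 0:
        raise PipelineError(
            f"undefined fold change for {feature_id!r}: zero mean on one side"
        )
    return float(np.log2(right / left))


def call_expression_asymmetry(table: pd.DataFrame, stage: str,
                              cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """One asymmetry call per abundant feature, sorted by |log2fc| descending.

    Returns a frame with columns ``feature_id, stage, mean_left, mean_right,
    log2fc, direction, abundant``; direction is ``right`` iff abundant and
    log2fc > threshold, ``left`` iff abundant and log2fc < -threshold,
    otherwise ``none``.
    """
    cfg = cfg or ThresholdConfig()
    means = _side_means(table, stage)
    if means.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    abundant = (means["mean_left"] >= cfg.fpkm_min) & (means["mean_right"] >= cfg.fpkm_min)
    calls = means[abundant].copy()
    calls["log2fc"] = np.log2(calls["mean_right"] / calls["mean_left"])
    calls["direction"] = "none"
    calls.loc[calls["log2fc"] > cfg.lfc_threshold, "direction"] = "right"
    calls.loc[calls["log2fc"] < -cfg.lfc_threshold, "direction"] = "left"
    calls["stage"] = stage
    calls["abundant"] = True
    calls = calls.sort_values(
        ["log2fc", "feature_id"],
        key=lambda s: -s.abs() if s.name == "log2fc" else s,
        kind="mergesort",
    )
    return calls[CALL_COLUMNS].reset_index(drop=True)


def summarize_expression(calls: pd.DataFrame, total_transcripts: int) -> dict:
    """Asymmetric counts and the percentage of all transcripts they represent."""
    n_left = int((calls["direction"] == "left").sum())
    n_right = int((calls["direction"] == "right").sum())
    return expression_summary_from_counts(n_left, n_right, total_transcripts)


def expression_summary_from_counts(n_left: int, n_right: int,
                                   total_transcripts: int) -> dict:
    """Summary from pre-tabulated directional counts.

    ``pct`` is 100 * (n_left + n_right) / total_transcripts, rounded half-up
    to two decimals.
    """
    n_asym = n_left + n_right
    if total_transcripts < n_asym:
        raise PipelineError("total_transcripts smaller than asymmetric count")
    return {
        "n_asym": n_asym,
        "n_left": n_left,
        "n_right": n_right,
        "pct": percent(n_asym, total_transcripts, decimals=2),
    }
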