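"""Per-CpG left-vs-right differential methylation and cross-sample consensus.

For each sample, every CpG covered on both sides is tested with a
two-sided Fisher exact test on the 2x2 methylated/unmethylated table
(two-sided in the point-probability sense: the p-value sums the
hypergeometric probabilities of all tables no more probable than the one
observed).  P-values are FDR-adjusted within the sample's test family by
Benjamini-Hochberg step-up, and a CpG is differentially methylated when
q < ``fdr_q`` and the absolute left-right methylation difference exceeds
``meth_diff_min`` percentage points.  The difference is right minus left,
so positive means hyper-methylated on the right, matching the fold-change
sign convention.

A consensus CpG is one called significant with the same direction in
every sample of a stage; a single-sample stage passes its calls through.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .config import ThresholdConfig

logger = logging.getLogger(__name__)

CPG_KEY = ["chrom", "pos", "strand"]
CALL_COLUMNS = CPG_KEY + ["sample_id", "stage", "p_raw", "q",
                          "pct_left", "pct_right", "diff",
                          "significant", "direction"]
CONSENSUS_COLUMNS = CPG_KEY + ["direction", "mean_abs_diff", "n_samples_support"]


@lru_cache(maxsize=1_000_000)
def _fisher_cached(meth_left: int, unmeth_left: int,
                   meth_right: int, unmeth_right: int) -> float:
    return float(fisher_exact(
        [[meth_left, unmeth_left], [meth_right, unmeth_right]],
        alternative="two-sided",
    ).pvalue)


def fisher_cpg(meth_left: int, unmeth_left: int,
               meth_right: int, unmeth_right: int) -> float:
    """Two-sided Fisher exact p for one CpG's 2x2 methylation table."""
    if min(meth_left, unmeth_left, meth_right, unmeth_right) < 0:
        raise ValueError("counts must be non-negative")
    if meth_left + unmeth_left == 0 or meth_right + unmeth_right == 0:
        raise ValueError("a side with zero coverage has no defined test")
    return _fisher_cached(int(meth_left), int(unmeth_left),
                          int(meth_right), int(unmeth_right))


def adjust_fdr(p_values, method: str = "bh") -> np.ndarray:
    """FDR-adjusted q-values (Benjamini-Hochberg step-up), order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    return multipletests(p, method="fdr_bh")[1]


def call_diff_methylation(cpg_table: pd.DataFrame, stage: str, sample_id: str,
                          cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Per-CpG differential-methylation calls for one sample at one stage.

    CpGs covered on one side only (or below ``min_coverage``) are excluded
    and tallied in the log.  The FDR family is all tested CpGs of this
    sample.
    """
    cfg = cfg or ThresholdConfig()
    sub = cpg_table[(cpg_table["stage"] == stage)
                    & (cpg_table["sample_id"] == sample_id)
                    & (cpg_table["coverage"] >= cfg.min_coverage)]
    if sub.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    wide = sub.pivot_table(index=CPG_KEY, columns="side",
                           values=["coverage", "methylated"], aggfunc="first")
    n_total = len(wide)
    for col in (("coverage", "left"), ("coverage", "right")):
        if col not in wide.columns:
            wide[col] = np.nan
    both = wide[("coverage", "left")].notna() & wide[("coverage", "right")].notna()
    n_one_sided = int(n_total - both.sum())
    if n_one_sided:
        logger.info("sample %s @ %s: %d CpG(s) covered on one side only excluded",
                    sample_id, stage, n_one_sided)
    wide = wide[both]
    if wide.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)

    cov_l = wide[("coverage", "left")].to_numpy(dtype=int)
    cov_r = wide[("coverage", "right")].to_numpy(dtype=int)
    met_l = wide[("methylated", "left")].to_numpy(dtype=int)
    met_r = wide[("methylated", "right")].to_numpy(dtype=int)

    p_raw = np.array([
        _fisher_cached(ml, cl - ml, mr, cr - mr)
        for ml, cl, mr, cr in zip(met_l, cov_l, met_r, cov_r)
    ])
    q = adjust_fdr(p_raw)
    pct_left = 100.0 * met_l / cov_l
    pct_right = 100.0 * met_r / cov_r
    diff = pct_right - pct_left
    significant = (q < cfg.fdr_q) & (np.abs(diff) > cfg.meth_diff_min)

    out = wide.index.to_frame(index=False)
    out["sample_id"] = sample_id
    out["stage"] = stage
    out["p_raw"] = p_raw
    out["q"] = q
    out["pct_left"] = pct_left
    out["pct_right"] = pct_right
    out["diff"] = diff
    out["significant"] = significant
    out["direction"] = np.where(
        ~significant, "none", np.where(diff > 0, "right", "left")
    )
    return (out[CALL_COLUMNS]
            .sort_values(CPG_KEY, kind="mergesort")
            .reset_index(drop=True))


def consensus_across_samples(per_sample_calls: pd.DataFrame,
                             stage: str) -> pd.DataFrame:
    """CpGs significant with the same direction in every sample of the stage.

    ``mean_abs_diff`` is the arithmetic mean of |diff| over the supporting
    samples.  A stage with a single sample passes through its significant set.
    """
    calls = per_sample_calls[per_sample_calls["stage"] == stage]
    if calls.empty:
        return pd.DataFrame(columns=CONSENSUS_COLUMNS)
    n_samples = calls["sample_id"].nunique()
    sig = calls[calls["significant"]]
    if sig.empty:
        return pd.DataFrame(columns=CONSENSUS_COLUMNS)
    grouped = sig.groupby(CPG_KEY, sort=True).agg(
        n_samples_support=("sample_id", "nunique"),
        n_directions=("direction", "nunique"),
        direction=("direction", "first"),
        mean_abs_diff=("diff", lambda d: float(np.mean(np.abs(d)))),
    ).reset_index()
    keep = (grouped["n_samples_support"] == n_samples) & (grouped["n_directions"] == 1)
    out = grouped[keep].drop(columns="n_directions")
    return out[CONSENSUS_COLUMNS].reset_index(drop=True)


def summarize_consensus(consensus: pd.DataFrame) -> dict:
    """Leftward / rightward consensus CpG counts for one stage."""
    return {
        "n_cpg_left": int((consensus["direction"] == "left").sum()),
        "n_cpg_right": int((consensus["direction"] == "right").sum()),
    }
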