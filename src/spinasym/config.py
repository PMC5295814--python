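"""Thresholds and stage vocabulary shared by every pipeline stage.

All numeric cut-offs used anywhere in the pipeline live in
:class:`ThresholdConfig` so a run is fully described by one object.
Developmental stages are labelled by post-conception (PC) week; the
equivalent gestational-age labels (PC + 2 weeks) are accepted on input
and normalized.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

from .errors import StageError

#: Canonical stage labels, in developmental order.
STAGES = ("wk8", "wk10", "wk12")

# Gestational age = PC age + 2 weeks; "ga" prefixed labels and week 14
# (which only exists on the gestational scale) map back to PC weeks.
_STAGE_ALIASES = {
    "wk8": "wk8", "wk10": "wk10", "wk12": "wk12",
    "8": "wk8", "10": "wk10", "12": "wk12",
    "ga10": "wk8", "ga12": "wk10", "ga14": "wk12",
    "wk14": "wk12", "14": "wk12",
}

SIDES = ("left", "right")


def normalize_stage(label: str) -> str:
    """Map a stage label (PC or gestational synonym) to its canonical PC form."""
    key = str(label).strip().lower()
    try:
        return _STAGE_ALIASES[key]
    except KeyError:
        raise StageError(
            f"unknown stage label {label!r}; expected one of {sorted(set(_STAGE_ALIASES))}"
        ) from None


class ThresholdConfig(BaseModel):
    """Every numeric constant of the analysis, with its published default.

    Parameters
    ----------
    lfc_threshold
        |log2 fold change| cut-off for calling asymmetric expression
        (strict ``>`` for mRNA, ``>=`` for miRNA), in log2 units.
    fpkm_min
        Minimum per-side mean FPKM for a gene to count as abundant.
    mirna_min_reads
        miRNAs with fewer raw reads than this on *both* sides are dropped.
    target_prob_min
        Minimum miRNA-target interaction probability (strict ``>``).
    fdr_q
        FDR-adjusted p-value cut-off for differential CpG methylation.
    meth_diff_min
        Minimum |left - right| methylation difference, in percentage points.
    lq_threshold
        |LQ| cut-off for calling a gene's promoter methylation strongly
        asymmetric; LQ = 100 * (right - left) / (right + left) over
        hyper-methylated CpG counts.
    upstream_window
        Nucleotides upstream of the TSS included when assigning CpGs to genes.
    min_coverage
        Minimum per-side read coverage for a CpG to enter the Fisher test.
    mirna_filter_mode
        ``"both"`` removes a miRNA only when below ``mirna_min_reads`` on both
        sides (default); ``"either"`` removes it when either side is low.
    rpkm_floor_reads
        Read-count equivalent used to floor a zero RPKM side so fold changes
        stay finite after low-count filtering.
    ignore_strand
        If True, the upstream window is always placed left of ``start``
        irrespective of gene strand.
    strict_mirna_direction
        If True, a miRNA only "explains" a target gene when the miRNA is up
        on the side where the gene is down.
    """

    model_config = ConfigDict(frozen=True)

    lfc_threshold: float = Field(default=1.5, gt=0)
    fpkm_min: float = Field(default=1.0, ge=0)
    mirna_min_reads: int = Field(default=10, gt=0)
    target_prob_min: float = Field(default=0.8, ge=0, le=1)
    fdr_q: float = Field(default=0.01, gt=0, le=1)
    meth_diff_min: float = Field(default=25.0, ge=0, le=100)
    lq_threshold: float = Field(default=25.0, ge=0, le=100)
    upstream_window: int = Field(default=1500, ge=0)
    min_coverage: int = Field(default=1, ge=1)
    mirna_filter_mode: str = Field(default="both", pattern="^(both|either)$")
    rpkm_floor_reads: float = Field(default=0.5, gt=0)
    ignore_strand: bool = False
    strict_mirna_direction: bool = False
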