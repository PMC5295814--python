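"""Independent brute-force oracles used only by the tests.

These re-derive expected values from first principles (exact integer
arithmetic, naive scans, literal rule tables) without touching the code
paths they check.
"""

from __future__ import annotations

from math import comb


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums, in exact integer arithmetic, the probabilities of every table
    with the observed margins whose probability does not exceed the
    observed table's.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    denom = comb(r1 + r2, c1)
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= w_obs:
            total += w
    return min(total / denom, 1.0)


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up by the textbook definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running_min = min(running_min, p_values[i] * m / rank)
        q[i] = running_min
    return q


def classify_rule_table(direction: str, lq: float | None, is_target: bool,
                        lq_threshold: float = 25.0) -> str:
    """Literal transcription of the explanation rule."""
    if lq is None or lq != lq:  # None or NaN
        opposite_methylation = False
    elif direction == "right":
        opposite_methylation = lq < -lq_threshold
    else:
        opposite_methylation = lq > lq_threshold
    if opposite_methylation and is_target:
        return "both"
    if opposite_methylation:
        return "methylation_only"
    if is_target:
        return "mirna_only"
    return "unexplained"


def naive_window_assignment(consensus_rows, gene_rows, window: int = 1500,
                            ignore_strand: bool = False):
    """O(n*m) scan: CpG -> genes whose body+promoter window contains it."""
    out: dict[str, list[int]] = {}
    for g in gene_rows:
        if ignore_strand or g["strand"] == "+":
            lo, hi = g["start"] - window, g["end"]
        else:
            lo, hi = g["start"], g["end"] + window
        lo = max(lo, 0)
        for i, cpg in enumerate(consensus_rows):
            if cpg["chrom"] == g["chrom"] and lo <= cpg["pos"] - 1 < hi:
                out.setdefault(g["gene_id"], []).append(i)
    return out
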