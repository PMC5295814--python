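# Methods

## The model and its assumptions

`spinasym` operationalizes "biologically relevant" left–right asymmetry
with threshold rules rather than inferential tests, because the target
study design has at most two replicate samples per developmental stage
(and one at the last stage). The package assumes:

- Expression is quantified per gene and side in FPKM; miRNA abundance in
  raw read counts convertible to RPKM; methylation as
  methylated/total read counts per CpG cytosine (strand-resolved, never
  collapsed to dinucleotide units).
- Samples at a stage are exchangeable: asymmetry is computed on the
  fold change of per-side *means* across the stage's samples
  (mean-then-ratio, not ratio-then-mean). With one sample this reduces
  to the per-sample ratio.
- Direction conventions are fixed throughout: positive log₂ fold change,
  positive methylation difference (right − left), and positive LQ all
  mean "right".

### Expression calling

A gene enters the analysis only if abundant — mean FPKM ≥ `fpkm_min` on
both sides — which suppresses the huge fold changes that near-zero
denominators produce. Abundance on the mean (rather than per sample)
keeps the rule aligned with the fold-change-of-means arithmetic and
guarantees a nonzero denominator. The call is strict:
log₂FC > `lfc_threshold` → rightward, < −threshold → leftward; a gene
exactly at the threshold is not called.

### miRNA calling

The low-count filter removes a miRNA only when *both* sides are below
`mirna_min_reads` (an `either` mode is available); one adequately
covered side is enough to keep it, which deliberately admits
one-side-zero miRNAs. Their RPKM ratio would be infinite, so the zero
side is floored at the RPKM equivalent of `rpkm_floor_reads` (default
0.5 reads) and the call is flagged `floored` — a deterministic cap on
exactly the "unrealistically high fold changes" the read filter exists
to prevent. The miRNA rule is inclusive (|log₂FC| ≥ threshold), unlike
the strict mRNA rule; both use the same default threshold of 1.5.

### Differential methylation

Each sample is its own test family: all CpGs covered ≥ `min_coverage`
on both sides are Fisher-tested (two-sided, point-probability
definition — the sum of hypergeometric probabilities not exceeding the
observed table's) and BH-adjusted within that family. BH is used as the
FDR procedure; π₀-adaptive estimators exist but are under-determined
here, and BH is conservative and exactly reproducible. The joint call
requires q < `fdr_q` *and* |Δ%| > `meth_diff_min`. Consensus across a
stage's samples requires significance with the same direction in every
sample; a direction conflict excludes the CpG outright.

### Integration and partition

CpG-to-gene assignment uses the gene body plus an `upstream_window`
(default 1500 nt) placed 5′ of the TSS — left of `start` on the plus
strand, right of `end` on the minus strand ("upstream" is read as
transcription-relative; `ignore_strand` reproduces the naive
left-of-start reading). A CpG inside two overlapping gene windows
counts for both genes. The laterality quotient counts CpG *sites*, not
methylation magnitude; `mean_abs_diff` is carried for reporting only.
Methylation explains a gene only when the LQ is strongly asymmetric
(strict |LQ| > `lq_threshold`) toward the side *opposite* the gene's
expression; same-direction methylation never explains. The miRNA flag
requires only target membership (probability strictly > 0.8 under an
asymmetric miRNA); an optional `strict_mirna_direction` mode
additionally requires the miRNA to be up on the side where the gene is
down. "Variance explained" is reported as what it operationally is — a
percentage of asymmetric genes per category — not a variance
decomposition.

### Rounding

Printed percentages use half-up rounding: two decimals for
transcript/miRNA/target-level percentages, nearest integer for
partition percentages. Python's built-in banker's rounding would differ
on exact halves.

## Parameters that matter

| Parameter | Default | Units | Why |
|---|---|---|---|
| `lfc_threshold` | 1.5 | log₂ | conventional cut-off for functionally relevant expression change |
| `fpkm_min` | 1 | FPKM | abundance floor against small-denominator blow-ups |
| `mirna_min_reads` | 10 | reads | low-count filter against unrealistic fold changes |
| `target_prob_min` | 0.8 | probability | strict gate on predicted miRNA–target interactions |
| `fdr_q` | 0.01 | q-value | per-sample FDR level for CpG calls |
| `meth_diff_min` | 25 | % points | minimal biologically meaningful methylation shift |
| `lq_threshold` | 25 | LQ units | "strongly asymmetric" promoter methylation |
| `upstream_window` | 1500 | nt | promoter region scanned upstream of the TSS |

## The synthetic generator

The generator emulates the study design end to end: three stages with
(2, 2, 1) samples, paired sides, ~3.3% of genes asymmetric at the focal
stage with a 1651:39 rightward:leftward split, exclusive coupling-class
shares of 0.27 (methylation), 0.03 (miRNA) and 0.01 (both), planted
|log₂FC| of 3, and a single toy chromosome tiled with genes whose
intergenic gaps (≥ 2000 nt) keep promoter windows from colliding. The
default `n_genes` is 2000 — a scaled working size chosen so the full
pipeline runs in seconds; the full ~51,408-transcript scale is a config
away.

Distributional choices (none are estimates from real tissue):

- FPKM: lognormal baselines with multiplicative lognormal noise
  (`expr_noise_sd`, natural-log sd, default 0.2) — strictly positive and
  heavy-tailed like real FPKM. Null genes are drawn around FPKM 3 with a
  wide spread so a realistic fraction falls below the abundance floor;
  planted asymmetric genes are drawn around FPKM 20 so their low side
  stays abundant at the planted fold change.
- miRNA counts: negative binomial (dispersion 0.1) around lognormal
  baselines, library size ~5·10⁶ reads per sample-side.
- CpGs: coverage Poisson around `cpg_coverage_mean` floored at 1;
  methylated reads binomial with the side's true proportion.
  Methylation-coupled genes get proportions differing by `meth_delta`
  (default 0.4) with the hyper-methylated side *opposite* the gene's
  expression direction; all other gene/stage combinations share one
  proportion on both sides.
- Targets: each miRNA-coupled gene is targeted (p ∈ (0.85, 0.99)) by a
  planted asymmetric miRNA of the direction opposite its expression
  (repression logic); background pairs involving asymmetric miRNAs are
  capped at p ≤ 0.8 so only planted couplings can explain a gene.

`cpg_coverage_mean` defaults to 100×. This is a power choice: for a
40-point methylation difference, a per-CpG Fisher p at 50× sits around
10⁻⁴, which does not reliably survive BH at q < 0.01 inside a
~10⁴-test family, whereas 100× gives p ≈ 10⁻⁸ and ~93% per-CpG
consensus power across two samples — so a planted gene with 5 promoter
CpGs is recovered essentially always, which is what a ground-truth
generator is for.

What passing tests on this generator show: the calling rules, the
threshold boundaries, the FDR bookkeeping, the interval arithmetic and
the partition logic are implemented correctly, and planted signal of
the configured strength is recovered. What they do not show: behaviour
on real tissue, where noise is not lognormal, coverage is not Poisson,
CpGs cluster in islands, miRNA target predictions are noisy, and
biological asymmetry is not a clean two-point effect.

## Numerical choices and degenerate inputs

- Fisher exact p-values come from `scipy.stats.fisher_exact`; the test
  suite verifies them against exact integer-arithmetic hypergeometric
  enumeration on every 2×2 table with total ≤ 40 (agreement ≤ 10⁻¹²).
- BH adjustment is order-preserving and never below the raw p.
- A CpG covered on one side only is excluded from testing and tallied
  in the log; a zero-coverage side passed directly to `fisher_cpg`
  raises.
- LQ with zero hyper-methylated CpGs on both sides is NaN and never
  sets the methylation flag.
- Calls are sorted by |log₂FC| descending with the feature id as a
  deterministic tie-break; all output tables have canonical column
  order and sort, so reruns are byte-identical.
- Stage labels are post-conception weeks (`wk8`, `wk10`, `wk12`);
  gestational synonyms (`ga10`, `ga12`, `ga14`, and bare `14`) are
  normalized on input. Week "14" only exists on the gestational scale
  and maps to `wk12`.

## Known limitations

- No per-gene variance test is offered; with n ≤ 2 the fold-change rule
  is the design, and its false-positive behaviour is governed entirely
  by the noise scale.
- The FDR procedure is BH, not a π₀-adaptive estimator; with many true
  nulls this is conservative.
- miRNA fold change is computed on mean RPKM across samples; per-sample
  ratios averaged would differ on unbalanced libraries.
- The library-size denominator is the raw library total, not a
  post-filter total.
- Per-chromosome stratification of the partition is available as a
  grouping column only; the headline report is genome-wide.
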