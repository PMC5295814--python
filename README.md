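# spinasym

Left–right asymmetry analysis for paired multi-omic tissue samples.

Developing nervous tissue can express genes at different levels on the
left and right side of the body axis, and such asymmetries are a
candidate substrate for lateralized behaviour (handedness being the
classic example). `spinasym` implements the full analysis chain for
paired left/right samples profiled at several developmental stages:

1. **Expression asymmetry (mRNA).** With only one or two replicates per
   stage, per-gene variance tests are hopeless, so a gene is called
   asymmetric by the fold change of per-side means: it must be abundant
   (mean FPKM ≥ 1 on *both* sides) and satisfy
   |log₂(FPKM_right / FPKM_left)| > 1.5 (strict). Positive log₂FC means
   rightward.
2. **miRNA asymmetry.** Raw counts are filtered (a miRNA is dropped only
   when it has < 10 reads on *both* sides), converted to
   RPKM = 10⁹ · reads / (library size × transcript length), and called
   with the inclusive rule |log₂FC| ≥ 1.5. Asymmetric miRNAs are matched
   to predicted target genes at interaction probability > 0.8.
3. **Differential CpG methylation.** Per sample, every CpG covered on
   both sides gets a two-sided Fisher exact test on its
   methylated/unmethylated 2×2 table; p-values are FDR-adjusted
   (Benjamini–Hochberg) within the sample, and a CpG is differentially
   methylated when q < 0.01 and the |right − left| methylation
   difference exceeds 25 percentage points. A *consensus* CpG is one
   significant with the same direction in every sample of a stage.
4. **Integration.** Consensus CpGs are assigned to genes over the gene
   body plus 1500 nt upstream of the TSS (strand-aware). Each gene gets
   a methylation laterality quotient over its hyper-methylated CpG
   counts, LQ = 100 · (right − left)/(right + left), and every
   asymmetrically expressed gene is placed in exactly one category:
   `methylation_only` (|LQ| > 25 toward the side *opposite* its
   expression), `mirna_only` (target of an asymmetric miRNA), `both`,
   or `unexplained`.

A synthetic-data module generates complete paired bundles (expression,
miRNA counts, CpG calls, gene models, target map) with planted
asymmetric gene sets and methylation/miRNA coupling, so the whole
pipeline can be exercised and scored against known ground truth without
any external data.

## Worked example

```python
import spinasym as sp

cfg = sp.SyntheticConfig(n_genes=150, n_mirnas=30, cpgs_per_gene=2,
                         frac_asym_expr=0.2, seed=42)
bundle = sp.generate_week8_like(cfg)   # strong rightward bias preset
report = sp.run_pipeline(bundle.expression, bundle.mirna, bundle.targets,
                         bundle.cpg, bundle.genes)
print(report["wk8"]["summary"])
```

prints (reformatted):

```
expression:  {'n_asym': 30, 'n_left': 1, 'n_right': 29, 'pct': 20.0}
mirna:       {'n_expressed': 30, 'n_asym': 7, 'n_left': 3, 'n_right': 4, 'pct': 23.33}
methylation: {'n_cpg_left': 16, 'n_cpg_right': 0}
partition:   counts {'methylation_only': 8, 'both': 0, 'mirna_only': 1, 'unexplained': 21}
             pct    {'methylation_only': 27, 'both': 0, 'mirna_only': 3, 'unexplained': 70}
```

Of 150 genes, 30 were called asymmetric (20%), 29 of them rightward —
the preset plants a strong rightward bias at the earliest stage. All 16
consensus CpGs are hyper-methylated on the *left*, i.e. opposite to the
dominant rightward expression, and 8 of the 30 asymmetric genes (27%)
are explained by methylation alone. The top of the per-gene call table:

```
  feature_id stage  mean_left  mean_right    log2fc direction  abundant
0       g096   wk8   7.232342   94.553389  3.708594     right      True
1       g066   wk8   6.393355   66.631538  3.381560     right      True
```

The same analysis is available from the shell:

```bash
spinasym simulate --out data/ --seed 42
spinasym run --expr data/expression.tsv --mirna data/mirna.tsv \
    --targets data/targets.tsv --cpg data/cpg.tsv \
    --genes data/genes.bed --out report/
```

which writes per-stage call tables and a `summary.json`.

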