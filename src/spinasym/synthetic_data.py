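"""Paired left/right multi-omic fixtures with known ground truth.

The generator emulates the study design the pipeline targets: a few
fetal samples per developmental stage (two at wk8 and wk10, one at
wk12), gene-level FPKM tables for both body sides, miRNA raw counts,
per-CpG bisulfite calls, gene models on a toy chromosome, and a
miRNA->gene target map.  A configurable fraction of genes is planted as
asymmetrically expressed at a focal stage (rightward-biased by default,
echoing the strong rightward skew the method is meant to detect), and
subsets of those genes are coupled to opposite-direction promoter
methylation and/or to an asymmetric miRNA that targets them, so every
downstream stage of the pipeline has a recoverable answer.

What it does not emulate: read-level noise, bisulfite conversion error,
mappability bias, or any real tissue expression profile.  Noise
magnitudes are chosen for testability, not biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._stats import round_half_up
from .config import STAGES
from .errors import ConfigError
from . import io_formats as iof

#: Planted rightward share among asymmetric genes at the focal stage,
#: matching the observed 1651-right : 39-left split the generator echoes.
WEEK8_RIGHT_BIAS = 1651 / 1690


class SyntheticConfig(BaseModel):
    """Knobs of the generator; defaults are the study-like conditions.

    Fractions ``frac_meth_coupled``, ``frac_mirna_coupled`` and
    ``both_overlap`` are *exclusive* class shares of the planted
    asymmetric genes (methylation-only, miRNA-only, both); their sum must
    not exceed 1.
    """

    model_config = ConfigDict(frozen=True)

    n_genes: int = Field(default=2000, gt=0)
    n_mirnas: int = Field(default=320, gt=0)
    n_samples_per_stage: tuple[int, int, int] = (2, 2, 1)
    frac_asym_expr: float = Field(default=0.0329, ge=0, le=1)
    right_bias: float = Field(default=WEEK8_RIGHT_BIAS, ge=0, le=1)
    planted_lfc: float = Field(default=3.0, gt=0)
    expr_noise_sd: float = Field(default=0.2, ge=0)
    frac_meth_coupled: float = Field(default=0.27, ge=0, le=1)
    frac_mirna_coupled: float = Field(default=0.03, ge=0, le=1)
    both_overlap: float = Field(default=0.01, ge=0, le=1)
    n_asym_mirnas: int = Field(default=6, ge=0)
    mirna_right_bias: float = Field(default=0.5, ge=0, le=1)
    cpgs_per_gene: int = Field(default=5, gt=0)
    cpg_coverage_mean: float = Field(default=100.0, gt=0)
    meth_delta: float = Field(default=0.4, gt=0, le=1)
    base_meth: float = Field(default=0.3, ge=0, le=1)
    library_size: int = Field(default=5_000_000, gt=0)
    mirna_dispersion: float = Field(default=0.1, gt=0)
    gene_length: int = Field(default=2000, gt=0)
    intergenic_gap: int = Field(default=2500, ge=2000)
    focal_stage: str = "wk8"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.frac_meth_coupled + self.frac_mirna_coupled + self.both_overlap > 1:
            raise ConfigError("coupling class shares exceed 1")
        if self.base_meth + self.meth_delta > 1:
            raise ConfigError("base_meth + meth_delta exceeds 1")
        if self.focal_stage not in STAGES:
            raise ConfigError(f"focal_stage must be one of {STAGES}")
        return self

    # planted counts, deterministic (half-up) so tests can predict them
    @property
    def n_asym_genes(self) -> int:
        return int(round_half_up(self.frac_asym_expr * self.n_genes))

    @property
    def n_right_genes(self) -> int:
        return int(round_half_up(self.right_bias * self.n_asym_genes))

    @property
    def n_meth_only(self) -> int:
        return int(round_half_up(self.frac_meth_coupled * self.n_asym_genes))

    @property
    def n_both(self) -> int:
        return int(round_half_up(self.both_overlap * self.n_asym_genes))

    @property
    def n_mirna_only(self) -> int:
        return int(round_half_up(self.frac_mirna_coupled * self.n_asym_genes))


@dataclass
class GroundTruth:
    """Planted answers: per-gene direction and coupling class, per-miRNA
    direction, and the per-CpG focal-stage methylation proportions."""

    genes: pd.DataFrame   # gene_id, true_direction, coupling_class
    mirnas: pd.DataFrame  # mirna_id, true_direction
    cpgs: pd.DataFrame    # chrom, pos, strand, gene_id, p_left, p_right


@dataclass
class SyntheticBundle:
    """One generated dataset plus its ground truth."""

    expression: pd.DataFrame
    mirna: pd.DataFrame
    cpg: pd.DataFrame
    genes: pd.DataFrame
    targets: pd.DataFrame
    truth: GroundTruth
    config: SyntheticConfig

    def write(self, out_dir) -> None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        iof.write_table(self.expression, os.path.join(out_dir, "expression.tsv"), "expression")
        iof.write_table(self.mirna, os.path.join(out_dir, "mirna.tsv"), "mirna")
        iof.write_table(self.cpg, os.path.join(out_dir, "cpg.tsv"), "cpg")
        iof.write_table(self.targets, os.path.join(out_dir, "targets.tsv"), "targets")
        iof.write_gene_models_bed(self.genes, os.path.join(out_dir, "genes.bed"))
        self.truth.genes.to_csv(os.path.join(out_dir, "ground_truth.tsv"),
                                sep="\t", index=False)


def _sample_ids(cfg: SyntheticConfig) -> dict[str, list[str]]:
    return {
        stage: [f"{stage}_s{i + 1}" for i in range(n)]
        for stage, n in zip(STAGES, cfg.n_samples_per_stage)
    }


def _plant_genes(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign each gene a true direction and coupling class."""
    width = len(str(cfg.n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(cfg.n_genes)]
    direction = np.array(["none"] * cfg.n_genes, dtype=object)
    coupling = np.array(["none"] * cfg.n_genes, dtype=object)
    n_asym = cfg.n_asym_genes
    asym_idx = rng.choice(cfg.n_genes, size=n_asym, replace=False)
    direction[asym_idx[: cfg.n_right_genes]] = "right"
    direction[asym_idx[cfg.n_right_genes:]] = "left"
    # coupling classes drawn from a direction-balanced shuffle of the
    # asymmetric genes so each class mixes left and right genes
    shuffled = rng.permutation(asym_idx)
    n_m, n_b, n_mi = cfg.n_meth_only, cfg.n_both, cfg.n_mirna_only
    coupling[shuffled[:n_m]] = "methylation"
    coupling[shuffled[n_m:n_m + n_b]] = "both"
    coupling[shuffled[n_m + n_b:n_m + n_b + n_mi]] = "mirna"
    return pd.DataFrame({
        "gene_id": gene_ids,
        "true_direction": direction,
        "coupling_class": coupling,
    })


def _gene_models(cfg: SyntheticConfig, gene_ids: list[str],
                 rng: np.random.Generator) -> pd.DataFrame:
    """Tile one toy chromosome; gaps exceed the promoter window so
    upstream windows never collide with a neighbouring gene."""
    pitch = cfg.gene_length + cfg.intergenic_gap
    starts = cfg.intergenic_gap + pitch * np.arange(len(gene_ids))
    return pd.DataFrame({
        "gene_id": gene_ids,
        "chrom": "chrS",
        "start": starts,
        "end": starts + cfg.gene_length,
        "strand": rng.choice(["+", "-"], size=len(gene_ids)),
    })


def _expression_table(cfg: SyntheticConfig, truth_genes: pd.DataFrame,
                      samples: dict[str, list[str]],
                      rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    direction = truth_genes["true_direction"].to_numpy()
    is_asym = direction != "none"
    # null genes span the abundance threshold; planted genes sit well above
    # it so their low side stays abundant at the planted fold change
    base = np.exp(rng.normal(np.log(3.0), 1.2, size=n))
    base[is_asym] = np.exp(rng.normal(np.log(20.0), 0.5, size=int(is_asym.sum())))
    half = np.sqrt(2.0) ** cfg.planted_lfc  # 2**(lfc/2)
    rows = []
    for stage, ids in samples.items():
        right_mean = base.copy()
        left_mean = base.copy()
        if stage == cfg.focal_stage:
            right_mean = np.where(direction == "right", base * half, right_mean)
            left_mean = np.where(direction == "right", base / half, left_mean)
            left_mean = np.where(direction == "left", base * half, left_mean)
            right_mean = np.where(direction == "left", base / half, right_mean)
        for sample in ids:
            for side, mean in (("left", left_mean), ("right", right_mean)):
                noise = np.exp(rng.normal(0.0, cfg.expr_noise_sd, size=n))
                rows.append(pd.DataFrame({
                    "feature_id": truth_genes["gene_id"],
                    "sample_id": sample,
                    "stage": stage,
                    "side": side,
                    "fpkm": mean * noise,
                }))
    return pd.concat(rows, ignore_index=True)


def _plant_mirnas(cfg: SyntheticConfig, truth_genes: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Plant asymmetric miRNAs, guaranteeing a miRNA of the repressive
    (opposite) direction for every miRNA-coupled gene direction."""
    width = len(str(cfg.n_mirnas))
    mirna_ids = [f"mir{i:0{width}d}" for i in range(cfg.n_mirnas)]
    direction = np.array(["none"] * cfg.n_mirnas, dtype=object)
    coupled = truth_genes[truth_genes["coupling_class"].isin(["mirna", "both"])]
    need_left = bool((coupled["true_direction"] == "right").any())
    need_right = bool((coupled["true_direction"] == "left").any())
    n_asym = cfg.n_asym_mirnas
    if n_asym == 0 and (need_left or need_right):
        raise ConfigError("miRNA coupling requested but n_asym_mirnas is 0")
    if n_asym:
        n_right = int(round_half_up(cfg.mirna_right_bias * n_asym))
        if need_right and n_right == 0:
            n_right = 1
        if need_left and n_right == n_asym:
            n_right = n_asym - 1
        if (need_left and need_right) and n_asym < 2:
            raise ConfigError("need at least 2 asymmetric miRNAs to cover both directions")
        asym_idx = rng.choice(cfg.n_mirnas, size=n_asym, replace=False)
        direction[asym_idx[:n_right]] = "right"
        direction[asym_idx[n_right:]] = "left"
    return pd.DataFrame({"mirna_id": mirna_ids, "true_direction": direction})


def _mirna_table(cfg: SyntheticConfig, truth_mirnas: pd.DataFrame,
                 samples: dict[str, list[str]],
                 rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_mirnas
    direction = truth_mirnas["true_direction"].to_numpy()
    is_asym = direction != "none"
    lengths = rng.integers(20, 25, size=n)
    base = np.exp(rng.normal(np.log(200.0), 1.0, size=n))
    base[is_asym] = np.exp(rng.normal(np.log(500.0), 0.5, size=int(is_asym.sum())))
    half = np.sqrt(2.0) ** cfg.planted_lfc
    disp = cfg.mirna_dispersion
    nb_n = 1.0 / disp
    rows = []
    for stage, ids in samples.items():
        mu_right = base.copy()
        mu_left = base.copy()
        if stage == cfg.focal_stage:
            mu_right = np.where(direction == "right", base * half, mu_right)
            mu_left = np.where(direction == "right", base / half, mu_left)
            mu_left = np.where(direction == "left", base * half, mu_left)
            mu_right = np.where(direction == "left", base / half, mu_right)
        for sample in ids:
            for side, mu in (("left", mu_left), ("right", mu_right)):
                lib = int(rng.integers(int(0.9 * cfg.library_size),
                                       int(1.1 * cfg.library_size)))
                p = nb_n / (nb_n + mu)
                counts = rng.negative_binomial(nb_n, p)
                rows.append(pd.DataFrame({
                    "mirna_id": truth_mirnas["mirna_id"],
                    "sample_id": sample,
                    "stage": stage,
                    "side": side,
                    "read_count": np.minimum(counts, lib),
                    "transcript_length": lengths,
                    "library_size": lib,
                }))
    return pd.concat(rows, ignore_index=True)


def _cpg_tables(cfg: SyntheticConfig, truth_genes: pd.DataFrame,
                gene_models: pd.DataFrame, samples: dict[str, list[str]],
                rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-CpG calls for every sample/side plus the truth proportions.

    CpGs are placed in the gene body and its 1500-nt strand-aware
    promoter.  Methylation-coupled genes get side proportions differing
    by ``meth_delta`` at the focal stage, hyper-methylated on the side
    *opposite* their expression direction; all other gene/stage
    combinations share one proportion on both sides.
    """
    promoter = 1500
    per = cfg.cpgs_per_gene
    direction = truth_genes["true_direction"].to_numpy()
    coupling = truth_genes["coupling_class"].to_numpy()
    meth_coupled = np.isin(coupling, ["methylation", "both"])

    pos_list, gene_col = [], []
    for i, g in enumerate(gene_models.itertuples(index=False)):
        if g.strand == "+":
            lo, hi = g.start - promoter, g.end
        else:
            lo, hi = g.start, g.end + promoter
        span = np.sort(rng.choice(np.arange(max(lo, 0), hi), size=per, replace=False))
        pos_list.append(span + 1)  # 1-based cytosine positions
        gene_col.extend([g.gene_id] * per)
    positions = np.concatenate(pos_list)
    n_cpg = len(positions)

    # focal-stage per-CpG side proportions
    p_flat = rng.uniform(0.1, 0.9, size=n_cpg)
    gene_idx = np.repeat(np.arange(cfg.n_genes), per)
    p_left = p_flat.copy()
    p_right = p_flat.copy()
    hyper_left = meth_coupled[gene_idx] & (direction[gene_idx] == "right")
    hyper_right = meth_coupled[gene_idx] & (direction[gene_idx] == "left")
    p_left[hyper_left] = cfg.base_meth + cfg.meth_delta
    p_right[hyper_left] = cfg.base_meth
    p_right[hyper_right] = cfg.base_meth + cfg.meth_delta
    p_left[hyper_right] = cfg.base_meth

    truth_cpgs = pd.DataFrame({
        "chrom": "chrS", "pos": positions, "strand": "+",
        "gene_id": gene_col, "p_left": p_left, "p_right": p_right,
    })

    rows = []
    for stage, ids in samples.items():
        focal = stage == cfg.focal_stage
        for sample in ids:
            for side, p_focal in (("left", p_left), ("right", p_right)):
                p = p_focal if focal else p_flat
                cov = np.maximum(rng.poisson(cfg.cpg_coverage_mean, size=n_cpg), 1)
                met = rng.binomial(cov, p)
                rows.append(pd.DataFrame({
                    "chrom": "chrS", "pos": positions, "strand": "+",
                    "sample_id": sample, "stage": stage, "side": side,
                    "coverage": cov, "methylated": met,
                }))
    return pd.concat(rows, ignore_index=True), truth_cpgs


def _target_map(cfg: SyntheticConfig, truth_genes: pd.DataFrame,
                truth_mirnas: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    """Planted high-probability pairs for coupled genes plus background.

    Each miRNA-coupled gene is targeted (p in (0.85, 0.99)) by an
    asymmetric miRNA of the direction opposite its expression, i.e. the
    side where a repressive miRNA would push it down.  Background pairs
    involving asymmetric miRNAs stay at or below the 0.8 probability
    gate so only planted couplings can explain a gene.
    """
    mirna_dir = truth_mirnas.set_index("mirna_id")["true_direction"]
    left_mirnas = list(mirna_dir[mirna_dir == "left"].index)
    right_mirnas = list(mirna_dir[mirna_dir == "right"].index)
    coupled = truth_genes[truth_genes["coupling_class"].isin(["mirna", "both"])]
    rows = []
    for g in coupled.itertuples(index=False):
        pool = left_mirnas if g.true_direction == "right" else right_mirnas
        mirna_id = pool[int(rng.integers(len(pool)))]
        rows.append((mirna_id, g.gene_id, float(rng.uniform(0.85, 0.99))))
    # background interactions
    n_background = 5 * cfg.n_mirnas
    mirna_pick = truth_mirnas["mirna_id"].to_numpy()[
        rng.integers(cfg.n_mirnas, size=n_background)]
    gene_pick = truth_genes["gene_id"].to_numpy()[
        rng.integers(cfg.n_genes, size=n_background)]
    probs = rng.uniform(0.0, 1.0, size=n_background)
    asym_set = set(left_mirnas) | set(right_mirnas)
    for m, g, p in zip(mirna_pick, gene_pick, probs):
        if m in asym_set:
            p = min(p, 0.8)  # never trips the strict > 0.8 gate
        rows.append((m, g, float(p)))
    df = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "probability"])
    df = df.drop_duplicates(subset=["mirna_id", "gene_id"], keep="first")
    return df.sort_values(["mirna_id", "gene_id"], kind="mergesort").reset_index(drop=True)


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Generate one full paired left/right bundle; deterministic per seed."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    samples = _sample_ids(cfg)
    truth_genes = _plant_genes(cfg, rng)
    gene_models = _gene_models(cfg, list(truth_genes["gene_id"]), rng)
    expression = _expression_table(cfg, truth_genes, samples, rng)
    truth_mirnas = _plant_mirnas(cfg, truth_genes, rng)
    mirna = _mirna_table(cfg, truth_mirnas, samples, rng)
    cpg, truth_cpgs = _cpg_tables(cfg, truth_genes, gene_models, samples, rng)
    targets = _target_map(cfg, truth_genes, truth_mirnas, rng)
    truth = GroundTruth(genes=truth_genes, mirnas=truth_mirnas, cpgs=truth_cpgs)
    return SyntheticBundle(expression=expression, mirna=mirna, cpg=cpg,
                           genes=gene_models, targets=targets, truth=truth,
                           config=cfg)


def generate_week8_like(config: SyntheticConfig | None = None,
                        **overrides) -> SyntheticBundle:
    """Preset with the strong rightward bias of the earliest stage.

    ``right_bias`` is forced to 1651/1690 unless explicitly overridden.
    """
    base = (config or SyntheticConfig()).model_dump()
    base["right_bias"] = WEEK8_RIGHT_BIAS
    base["focal_stage"] = "wk8"
    base.update(overrides)
    return generate_dataset(SyntheticConfig(**base))
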