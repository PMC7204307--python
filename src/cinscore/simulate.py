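"""Synthetic multi-cohort generator with a latent chromosomal-instability driver.

Each sample carries a latent CIN level ``c`` that jointly drives (i) the
per-arm probability of a broad copy-number event, (ii) a log2 expression
shift on a planted signature gene set, and (iii) the nonsynonymous mutation
and fusion event counts.  Stage classes mirror a metastatic prostate-cancer
biopsy cohort: M0-NM (localized, never metastasized), M0-oligo / M0-poly
(localized at diagnosis, later oligo-/polymetastatic), and M1-oligo /
M1-poly (de novo metastatic).  M1 latent CIN is a two-component normal
mixture so that a tunable fraction of M1 samples sits in a low-CIN mode,
reproducing the bimodal CIN distribution seen in de novo metastatic cases.

Counts are negative-binomial (mean/dispersion parameterization), the
standard overdispersed model for bulk RNA-seq libraries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeArmModel

STAGE_CLASSES: Tuple[str, ...] = (
    "M0-NM",
    "M0-oligo",
    "M0-poly",
    "M1-oligo",
    "M1-poly",
)

SEG_COLUMNS = ["sample", "chrom", "start", "end", "value"]


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


def _default_group_sizes() -> Dict[str, int]:
    # 99-case biopsy cohort: 63 de novo metastatic, 13 M0 with eventual
    # metastatic progression, 23 localized without progression.
    return {
        "M0-NM": 23,
        "M0-oligo": 6,
        "M0-poly": 7,
        "M1-oligo": 25,
        "M1-poly": 38,
    }


def _default_cin_means() -> Dict[str, float]:
    return {
        "M0-NM": 0.2,
        "M0-oligo": 0.45,
        "M0-poly": 0.6,
        "M1-oligo": 0.9,
        "M1-poly": 1.0,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``cin_effect`` is the log2 expression shift on signature genes per unit
    latent CIN; ``broad_rate_slope`` is the per-arm broad-event probability
    per unit latent CIN (clipped to [0, 1]); ``m1_bimodal_weight`` is the
    fraction of M1 samples drawn from the low-CIN mixture component.
    """

    n_samples_per_group: Mapping[str, int] = field(default_factory=_default_group_sizes)
    n_genes: int = 2000
    n_signature_genes: int = 70
    cin_effect: float = 1.0
    group_cin_means: Mapping[str, float] = field(default_factory=_default_cin_means)
    m1_bimodal_weight: float = 1.0 / 3.0
    m1_low_mode_mean: float = 0.2
    cin_sd: float = 0.15
    arms: int = 46
    arm_length_bp: int = 5_000_000
    broad_rate_slope: float = 0.35
    focal_rate: float = 4.0
    dispersion: float = 0.3
    fusion_types_total: int = 6
    signature_gene_symbols: Optional[Tuple[str, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arms <= 0 or self.arms % 2:
            raise ConfigError("arms must be a positive even integer")
        if self.arm_length_bp <= 0:
            raise ConfigError("arm_length_bp must be positive")
        if self.n_genes <= 0 or self.n_signature_genes <= 0:
            raise ConfigError("gene counts must be positive")
        if self.n_signature_genes > self.n_genes:
            raise ConfigError("n_signature_genes cannot exceed n_genes")
        if not 0.0 <= self.m1_bimodal_weight <= 1.0:
            raise ConfigError("m1_bimodal_weight must be in [0, 1]")
        if self.cin_effect < 0 or self.focal_rate < 0:
            raise ConfigError("cin_effect and focal_rate must be >= 0")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if self.fusion_types_total <= 0:
            raise ConfigError("fusion_types_total must be > 0")
        for grp in self.n_samples_per_group:
            if grp not in STAGE_CLASSES:
                raise ConfigError(f"unknown stage class {grp!r}")
            if grp not in self.group_cin_means:
                raise ConfigError(f"no latent CIN mean for stage class {grp!r}")
        for grp, n in self.n_samples_per_group.items():
            if n <= 0:
                raise ConfigError(f"non-positive sample count for {grp!r}")
        if self.signature_gene_symbols is not None:
            syms = tuple(self.signature_gene_symbols)
            if len(syms) != self.n_signature_genes:
                raise ConfigError(
                    "signature_gene_symbols must have length n_signature_genes"
                )
            if len(set(syms)) != len(syms):
                raise ConfigError("signature_gene_symbols must be unique")
            object.__setattr__(self, "signature_gene_symbols", syms)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: expression, segments, annotations, and the truth.

    ``truth`` records the planted signature genes and the per-group latent
    CIN means so that recovery tests can compare against ground truth.
    """

    expression: pd.DataFrame  # genes x samples, integer counts
    segments: pd.DataFrame  # SEG-style table
    annotations: pd.DataFrame  # per-sample metadata incl. latent_cin
    arm_model: GenomeArmModel
    truth: pd.DataFrame  # planted signature genes with effect sizes
    config: SimulationConfig

    @property
    def samples(self) -> list:
        return list(self.expression.columns)

    @property
    def signature_genes(self) -> list:
        return list(self.truth["gene"])


def generate_arm_model(config: SimulationConfig) -> GenomeArmModel:
    """Build a toy genome of ``arms/2`` chromosomes, each with p and q arms.

    Gene intervals (10 kb) are placed uniformly, each fully inside one arm;
    placement is deterministic given the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n_chrom = config.arms // 2
    L = config.arm_length_bp
    arm_rows = []
    for i in range(n_chrom):
        chrom = f"chr{i + 1}"
        arm_rows.append((chrom, "p", 0, L))
        arm_rows.append((chrom, "q", L, 2 * L))
    arms = pd.DataFrame(arm_rows, columns=["chrom", "arm", "start", "end"])

    gene_len = min(10_000, max(1, L // 100))
    arm_idx = rng.integers(0, len(arms), size=config.n_genes)
    starts = np.empty(config.n_genes, dtype=np.int64)
    for j, ai in enumerate(arm_idx):
        a = arms.iloc[ai]
        starts[j] = rng.integers(a["start"], a["end"] - gene_len)
    width = len(str(config.n_genes))
    genes = pd.DataFrame(
        {
            "gene": [f"G{j + 1:0{width}d}" for j in range(config.n_genes)],
            "chrom": arms["chrom"].to_numpy()[arm_idx],
            "start": starts,
            "end": starts + gene_len,
        }
    )
    return GenomeArmModel(arms, genes)


def _draw_latent_cin(rng: np.random.Generator, config: SimulationConfig, group: str) -> float:
    mean = config.group_cin_means[group]
    if group.startswith("M1") and rng.random() < config.m1_bimodal_weight:
        mean = config.m1_low_mode_mean
    return float(max(0.0, rng.normal(mean, config.cin_sd)))


def _sample_segments(
    rng: np.random.Generator,
    config: SimulationConfig,
    model: GenomeArmModel,
    sample: str,
    c: float,
) -> list:
    """Emit SEG rows for one sample: broad events (99% of arm, |value|>0.3),
    focal events (<=8% of arm), and neutral filler segments (|value|<0.3).

    Focal/neutral segments on an arm are placed in disjoint tenth-of-arm
    blocks so the per-chromosome non-overlap invariant holds by construction.
    """
    rows = []
    arms = model.arms
    p_broad = float(np.clip(config.broad_rate_slope * c, 0.0, 1.0))
    broad_hit = rng.random(len(arms)) < p_broad

    # focal events across the genome, assigned to arms without a broad event
    n_focal = rng.poisson(config.focal_rate)
    free_arms = np.flatnonzero(~broad_hit)
    focal_per_arm = np.zeros(len(arms), dtype=int)
    if len(free_arms):
        for ai in rng.choice(free_arms, size=n_focal, replace=True):
            if focal_per_arm[ai] < 8:  # at most 8 of the 10 blocks
                focal_per_arm[ai] += 1

    for ai, arm in arms.iterrows():
        alen = arm["end"] - arm["start"]
        if broad_hit[ai]:
            margin = int(alen * 0.005)  # covers 99% of the arm
            value = rng.uniform(0.35, 1.0) * rng.choice([-1.0, 1.0])
            rows.append(
                (sample, arm["chrom"], arm["start"] + margin, arm["end"] - margin,
                 round(float(value), 4))
            )
            continue
        k = focal_per_arm[ai]
        n_neutral = rng.integers(0, 2)
        if k + n_neutral == 0:
            continue
        blocks = rng.choice(10, size=k + n_neutral, replace=False)
        block_len = alen // 10
        for bi, block in enumerate(blocks):
            b0 = arm["start"] + block * block_len
            seg_len = int(rng.uniform(0.1, 0.8) * block_len)
            start = int(rng.integers(b0, b0 + block_len - seg_len))
            if bi < k:  # focal alteration, <= 8% of arm
                value = rng.uniform(0.35, 1.0) * rng.choice([-1.0, 1.0])
            else:  # neutral filler below threshold
                value = rng.uniform(-0.2, 0.2)
            rows.append((sample, arm["chrom"], start, start + seg_len,
                         round(float(value), 4)))
    return rows


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort, reproducible from ``config.seed``.

    A single seed sequence drives the cohort; per-sample child streams are
    spawned deterministically so samples are independent given the seed.
    """
    model = generate_arm_model(config)
    root = np.random.SeedSequence([config.seed, 7])
    rng = np.random.default_rng(root)

    # per-gene baseline log2 means and signature membership
    base_log2 = rng.uniform(3.0, 9.0, size=config.n_genes)
    sig_idx = rng.choice(config.n_genes, size=config.n_signature_genes, replace=False)
    gene_ids = model.genes["gene"].to_numpy().copy()
    if config.signature_gene_symbols is not None:
        # planted signature genes carry real symbols so shipped signatures
        # (e.g. CIN70) can be scored directly on the synthetic matrix
        gene_ids[sig_idx] = np.asarray(config.signature_gene_symbols, dtype=object)
        genes_renamed = model.genes.copy()
        genes_renamed["gene"] = gene_ids
        model = GenomeArmModel(model.arms, genes_renamed)

    samples = []
    for grp in STAGE_CLASSES:
        n = config.n_samples_per_group.get(grp, 0)
        samples += [(f"S{len(samples) + i + 1:03d}", grp) for i in range(n)]

    child_seeds = root.spawn(len(samples))
    ann_rows = []
    seg_rows = []
    counts = np.empty((config.n_genes, len(samples)), dtype=np.int64)
    inv_disp = 1.0 / config.dispersion

    for j, ((sample, grp), seed_j) in enumerate(zip(samples, child_seeds)):
        srng = np.random.default_rng(seed_j)
        c = _draw_latent_cin(srng, config, grp)

        mu = base_log2.copy()
        mu[sig_idx] += config.cin_effect * c
        mean = 2.0 ** mu
        # NB with var = m + dispersion * m^2
        counts[:, j] = srng.negative_binomial(inv_disp, inv_disp / (inv_disp + mean))

        seg_rows += _sample_segments(srng, config, model, sample, c)

        nonsyn = int(srng.poisson(200 + 300 * c))
        fusions = int(srng.poisson(1 + 3 * c))
        p_out = 1.0 / (1.0 + np.exp(-(c - 0.6) * 3.0))
        ann_rows.append(
            {
                "sample": sample,
                "stage": grp,
                "latent_cin": c,
                "nonsyn_mutations": nonsyn,
                "fusion_events": fusions,
                "fusion_types_total": config.fusion_types_total,
                "msi_score": float(srng.beta(1.2, 8.0)),
                "bcr": int(srng.random() < p_out),
                "crpc": int(srng.random() < p_out * 0.8),
                "death": int(srng.random() < p_out * 0.6),
            }
        )

    expression = pd.DataFrame(counts, index=gene_ids, columns=[s for s, _ in samples])
    expression.index.name = "gene"
    segments = pd.DataFrame(seg_rows, columns=SEG_COLUMNS)
    annotations = pd.DataFrame(ann_rows)
    truth = pd.DataFrame(
        {
            "gene": gene_ids[sig_idx],
            "log2_effect_per_unit_cin": config.cin_effect,
        }
    )
    return SyntheticCohort(expression, segments, annotations, model, truth, config)


def write_cohort(cohort: SyntheticCohort, outdir) -> Dict[str, Path]:
    """Write the cohort as plain-text tables; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "segments": outdir / "segments.seg",
        "annotations": outdir / "annotations.tsv",
        "arms": outdir / "arms.bed",
        "genes": outdir / "genes.tsv",
        "truth": outdir / "truth.tsv",
    }
    cohort.expression.to_csv(paths["expression"], sep="\t")
    cohort.segments.to_csv(paths["segments"], sep="\t", index=False)
    cohort.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    cohort.arm_model.to_bed(paths["arms"])
    cohort.arm_model.genes_to_tsv(paths["genes"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
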