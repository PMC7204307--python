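"""Chromosome-arm model and gene catalog.

Arm-level copy-number scoring needs two denominators: the number of
chromosomal arms (for the broad-CNA score) and the number of genes in the
catalog (for the focal-CNA score).  :class:`GenomeArmModel` bundles both,
with arm intervals in 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ARM_COLUMNS = ["chrom", "arm", "start", "end"]
GENE_COLUMNS = ["gene", "chrom", "start", "end"]


class GenomeModelError(ValueError):
    """Raised when an arm model or gene catalog violates its invariants."""


@dataclass(frozen=True)
class GenomeArmModel:
    """Chromosome arms plus a gene catalog.

    Parameters
    ----------
    arms
        One row per arm with columns ``chrom``, ``arm`` (``"p"``/``"q"``),
        ``start``, ``end`` (0-based half-open, non-overlapping per chromosome).
    genes
        One row per gene with columns ``gene``, ``chrom``, ``start``, ``end``.
        Every gene must lie entirely within exactly one arm.
    """

    arms: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        arms = self.arms.reset_index(drop=True)
        genes = self.genes.reset_index(drop=True)
        for col in ARM_COLUMNS:
            if col not in arms.columns:
                raise GenomeModelError(f"arm table missing column {col!r}")
        for col in GENE_COLUMNS:
            if col not in genes.columns:
                raise GenomeModelError(f"gene table missing column {col!r}")
        if len(arms) == 0:
            raise GenomeModelError("arm table is empty")
        if (arms["end"] <= arms["start"]).any():
            raise GenomeModelError("every arm needs end > start")
        if len(genes) and (genes["end"] <= genes["start"]).any():
            raise GenomeModelError("every gene needs end > start")
        if genes["gene"].duplicated().any():
            raise GenomeModelError("duplicate gene ids in catalog")
        # arms non-overlapping within each chromosome
        for chrom, grp in arms.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise GenomeModelError(f"overlapping arms on chromosome {chrom}")
        # every gene inside exactly one arm (arms are disjoint, so containment
        # in the arm found by binary search on starts is containment in one)
        arm_by_chrom = {
            chrom: grp.sort_values("start")
            for chrom, grp in arms.groupby("chrom", sort=False)
        }
        for chrom, ggrp in genes.groupby("chrom", sort=False):
            if chrom not in arm_by_chrom:
                raise GenomeModelError(f"gene chromosome {chrom} not in arm model")
            agrp = arm_by_chrom[chrom]
            astart = agrp["start"].to_numpy()
            aend = agrp["end"].to_numpy()
            idx = np.searchsorted(astart, ggrp["start"].to_numpy(), side="right") - 1
            safe = idx.clip(0)
            ok = (
                (idx >= 0)
                & (ggrp["start"].to_numpy() >= astart[safe])
                & (ggrp["end"].to_numpy() <= aend[safe])
            )
            if not ok.all():
                bad = ggrp.loc[~ok, "gene"].iloc[0]
                raise GenomeModelError(f"gene {bad} not contained in exactly one arm")
        object.__setattr__(self, "arms", arms)
        object.__setattr__(self, "genes", genes)

    @property
    def total_arms(self) -> int:
        return len(self.arms)

    @property
    def total_genes(self) -> int:
        return len(self.genes)

    def arm_length(self, chrom: str, arm: str) -> int:
        row = self.arms[(self.arms["chrom"] == chrom) & (self.arms["arm"] == arm)]
        if len(row) != 1:
            raise GenomeModelError(f"unknown arm {chrom}{arm}")
        return int(row["end"].iloc[0] - row["start"].iloc[0])

    def to_bed(self, path) -> None:
        """Write arms as BED-like TSV: chrom, start, end, arm name."""
        out = self.arms.assign(name=self.arms["chrom"] + self.arms["arm"])
        out[["chrom", "start", "end", "name"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def genes_to_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_files(cls, arms_bed, genes_tsv) -> "GenomeArmModel":
        """Read an arm model from BED-like TSV plus a gene-catalog TSV."""
        arms = pd.read_csv(
            arms_bed, sep="\t", header=None, names=["chrom", "start", "end", "name"]
        )
        arms["arm"] = arms["name"].str[-1]
        genes = pd.read_csv(genes_tsv, sep="\t")
        return cls(arms[ARM_COLUMNS], genes[GENE_COLUMNS])
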