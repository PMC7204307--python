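"""Gene signatures for chromosomal instability and GMT gene-set I/O.

Two signatures ship with the package:

* ``CIN70`` — the published 70-gene chromosomal-instability expression
  signature (Carter et al., Nat Genet 2006), whose activation correlates
  with total chromosomal imbalance across tumor types.  Symbols are given
  in modern HGNC nomenclature where the original publication used legacy
  aliases (e.g. TOPK→PBK, CDC2→CDK1, STK6→AURKA).
* ``PC_CIN`` — the seven-gene prostate-specific distillation (PBK, CEP55,
  UBE2C, MELK, TPX2, PTTG1, CDCA3), mitotic regulators drawn from the top
  of the CIN70 leading edge in metastatic-versus-localized comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set, optionally with expected per-gene directions.

    ``directions`` maps a member gene to +1 (expected up in the condition
    of interest) or -1; members absent from the map default to +1.
    """

    name: str
    genes: Tuple[str, ...]
    directions: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate members")
        if self.directions:
            bad = set(self.directions) - set(self.genes)
            if bad:
                raise ValueError(f"directions for non-members: {sorted(bad)}")
            if any(v not in (-1, 1) for v in self.directions.values()):
                raise ValueError("directions must be +1 or -1")

    def direction(self, gene: str) -> int:
        if self.directions and gene in self.directions:
            return self.directions[gene]
        return 1

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


PC_CIN_GENES: Tuple[str, ...] = (
    "PBK",
    "CEP55",
    "UBE2C",
    "MELK",
    "TPX2",
    "PTTG1",
    "CDCA3",
)
PC_CIN = GeneSignature("PC-CIN", PC_CIN_GENES)

CIN70_GENES: Tuple[str, ...] = (
    "TPX2", "PRC1", "FOXM1", "CDK1", "TGIF2", "MCM2", "H2AFZ", "TOP2A",
    "PCNA", "UBE2C", "MELK", "TRIP13", "NCAPD2", "MCM7", "RNASEH2A",
    "RAD51AP1", "KIF20A", "CDC45", "MAD2L1", "ESPL1", "CCNB2", "FEN1",
    "TTK", "CCT5", "RFC4", "ATAD2", "CKAP5", "NUP205", "CDC20", "CKS2",
    "RRM2", "ELAVL1", "CCNB1", "RRM1", "AURKB", "MSH6", "EZH2", "CTPS1",
    "DKC1", "OIP5", "CDCA8", "PTTG1", "CEP55", "H2AFX", "CMAS", "NCAPH",
    "MCM10", "LSM4", "ZNF639", "ASF1B", "ZWINT", "PBK", "CENPM", "CDCA3",
    "ECT2", "CDC6", "UNG", "MTCH2", "RAD21", "ACTL6A", "SRSF2", "HDGF",
    "NXT1", "NEK2", "DHCR7", "AURKA", "NDUFAB1", "KIF4A", "PLK1", "FANCI",
)
CIN70 = GeneSignature("CIN70", CIN70_GENES)

#: Synthetic stand-in for a top-19 leading-edge gene list from a GSEA of the
#: CIN70 signature in polymetastatic versus non-metastatic primary tumors.
#: The seven mitotic regulators are the published PC-CIN members placed in
#: leading-edge rank order; the twelve interleaved context genes are CIN70
#: members drawn as a synthetic reconstruction (the full ordered list is not
#: public).
TOP19_LEADING_EDGE_SYNTHETIC: Tuple[str, ...] = (
    "PBK", "KIF20A", "CEP55", "TOP2A", "UBE2C", "RRM2", "MELK", "FOXM1",
    "TPX2", "PRC1", "ZWINT", "PTTG1", "MCM2", "ATAD2", "CDCA3", "RAD51AP1",
    "FEN1", "MSH6", "DKC1",
)

#: Synthetic curated mask of mitosis regulators (centrosome function,
#: chromosome segregation, mitotic spindle assembly).  Membership for the
#: seven PC-CIN genes follows the published annotation; the extra entries
#: are canonical mitotic kinases/checkpoint genes included so that the mask
#: is a proper superset of no single leading edge.
MITOSIS_REGULATORS_SYNTHETIC: frozenset = frozenset(
    PC_CIN_GENES
    + ("AURKA", "AURKB", "PLK1", "BUB1", "BUB1B", "MAD2L1", "NEK2",
       "ESPL1", "NDC80", "INCENP")
)


def read_gmt(path) -> Dict[str, GeneSignature]:
    """Read gene sets from a GMT file (name, description, members...)."""
    out: Dict[str, GeneSignature] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name, _desc, *members = fields
            members = [m for m in members if m]
            out[name] = GeneSignature(name, tuple(members))
    return out


def write_gmt(signatures: Iterable[GeneSignature], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, description, *sig.genes]) + "\n")


BUILTIN_SIGNATURES: Dict[str, GeneSignature] = {
    "CIN70": CIN70,
    "PC-CIN": PC_CIN,
}
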