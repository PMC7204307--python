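"""Gene set enrichment: Signal2Noise ranking, KS running-sum enrichment
score, random-gene-set permutation p-values, leading-edge extraction, and
annotation-guided distillation to a compact signature.

The enrichment score walks the ranked list accumulating a hit increment
(equal-weight by default, i.e. the classical Kolmogorov-Smirnov form) and a
miss decrement 1/(N-k); ES is the signed maximum deviation of the running
sum.  Significance comes from random gene sets of the same size, with a +1
correction so the p-value is never zero.  The leading edge is the subset of
set members at or before the running-sum extremum, the genes that carry the
enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .degs import GroupContrast
from .signatures import GeneSignature


class EnrichmentError(ValueError):
    pass


def signal2noise_ranking(
    expr: pd.DataFrame, contrast: GroupContrast, sd_floor_frac: float = 0.2
) -> pd.DataFrame:
    """Rank genes by the Signal2Noise metric, descending.

    metric = (meanA - meanB) / (sdA + sdB) with each sd floored at
    ``sd_floor_frac * |mean|`` (and at ``sd_floor_frac`` when the mean is
    zero), the canonical definition.  Ties break by gene id.
    """
    missing = (set(contrast.group_a) | set(contrast.group_b)) - set(expr.columns)
    if missing:
        raise EnrichmentError(f"samples not in matrix: {sorted(missing)}")
    a = expr[list(contrast.group_a)].to_numpy(dtype=float)
    b = expr[list(contrast.group_b)].to_numpy(dtype=float)

    def floored_sd(x: np.ndarray) -> np.ndarray:
        sd = x.std(axis=1, ddof=1)
        mean = x.mean(axis=1)
        floor = np.where(mean == 0, sd_floor_frac, sd_floor_frac * np.abs(mean))
        return np.maximum(sd, floor)

    metric = (a.mean(axis=1) - b.mean(axis=1)) / (floored_sd(a) + floored_sd(b))
    ranked = pd.DataFrame({"gene": expr.index, "metric": metric})
    ranked = ranked.sort_values(
        ["metric", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return ranked


def enrichment_score(
    ranked: pd.DataFrame, geneset: GeneSignature, weight: float = 0.0
) -> Tuple[float, np.ndarray]:
    """KS running-sum enrichment score of a gene set on a ranked list.

    Returns ``(ES, running_sum)``.  ``weight=0`` is the classical
    equal-weight KS statistic; ``weight=1`` weights hits by |metric|.
    """
    genes = ranked["gene"].to_numpy()
    metric = ranked["metric"].to_numpy(dtype=float)
    members = set(geneset.genes)
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    k = int(hit.sum())
    n = len(genes)
    if k == 0:
        raise EnrichmentError(f"no members of {geneset.name} in the ranked list")
    if k == n:
        raise EnrichmentError("gene set covers the whole ranked list")

    if weight == 0:
        hit_w = hit.astype(float) / k
    else:
        w = np.abs(metric) ** weight
        tot = w[hit].sum()
        if tot == 0:
            hit_w = hit.astype(float) / k
        else:
            hit_w = np.where(hit, w, 0.0) / tot
    miss_w = (~hit).astype(float) / (n - k)
    running = np.cumsum(hit_w - miss_w)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


@dataclass(frozen=True)
class EnrichmentResult:
    """ES, permutation p, running sum, and the ordered leading edge."""

    geneset: str
    es: float
    pvalue: float
    n_perm: int
    running: np.ndarray
    leading_edge: Tuple[str, ...]
    seed: Optional[int] = None


def leading_edge(
    es: float, running: np.ndarray, ranked: pd.DataFrame, geneset: GeneSignature
) -> Tuple[str, ...]:
    """Members at or before the running-sum maximum (positive ES) or at or
    after the minimum (negative ES), in rank order."""
    if es == 0:
        warnings.warn("ES is 0; leading edge is empty")
        return ()
    genes = ranked["gene"].to_numpy()
    members = set(geneset.genes)
    peak = int(np.argmax(np.abs(running) * np.sign(running) * np.sign(es)))
    if es > 0:
        idx = range(0, peak + 1)
    else:
        idx = range(peak, len(genes))
    return tuple(g for g in genes[list(idx)] if g in members)


def random_geneset_pvalue(
    ranked: pd.DataFrame,
    geneset: GeneSignature,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 0.0,
) -> EnrichmentResult:
    """Permutation p-value against random gene sets of the same size.

    p = (1 + #{|ES_null| >= |ES_obs|}) / (n_perm + 1); deterministic given
    ``seed``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives poorly resolved p-values")
    es, running = enrichment_score(ranked, geneset, weight)
    genes = ranked["gene"].to_numpy()
    members = set(geneset.genes)
    k = int(sum(g in members for g in genes))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        null_genes = rng.choice(genes, size=k, replace=False)
        null_set = GeneSignature("_null", tuple(null_genes))
        es_null, _ = enrichment_score(ranked, null_set, weight)
        if abs(es_null) >= abs(es):
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    le = leading_edge(es, running, ranked, geneset)
    return EnrichmentResult(geneset.name, es, p, n_perm, running, le, seed)


def distill_signature(
    leading: Sequence[str],
    annotation_mask: Set[str],
    k_max: int,
    name: str = "distilled",
) -> GeneSignature:
    """Intersect the top ``k_max`` leading-edge genes with a curated
    annotation mask, preserving rank order.

    The mask encodes externally curated biology (e.g. mitosis regulators);
    it is an input, never computed here.
    """
    if k_max <= 0:
        raise EnrichmentError("k_max must be positive")
    top = list(leading)[:k_max]
    kept = tuple(g for g in top if g in annotation_mask)
    if not kept:
        raise EnrichmentError(
            "no leading-edge gene matches the annotation mask; try a larger k_max"
        )
    return GeneSignature(name, kept)
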