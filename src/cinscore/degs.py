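"""Permutation-based differential expression and cross-cohort intersection.

The two-group test combines two per-gene statistics — a Welch t-statistic
and a log2 median-ratio — each referred to an empirical null built from
random label permutations pooled across genes.  The two one-sided empirical
p-values are combined by Stouffer's method and Benjamini-Hochberg adjusted;
a gene is called differentially expressed at q < 0.05 and linear fold
change >= 1.5.

Cross-cohort machinery: Venn-region counts over several DEG sets, the
"shared" list (focal-cohort DEGs overlapping at least one external set),
directional concordance of fold-change signs, and fold-change correlation
between cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FDR_THRESHOLD = 0.05
FC_THRESHOLD = 1.5


class ContrastError(ValueError):
    pass


@dataclass(frozen=True)
class GroupContrast:
    """Two disjoint sample groups to compare (A over B)."""

    group_a: Tuple[str, ...]
    group_b: Tuple[str, ...]
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ContrastError("groups must be disjoint")
        if len(self.group_a) < 3 or len(self.group_b) < 3:
            raise ContrastError("each group needs at least 3 samples")

    @classmethod
    def from_annotations(
        cls, annotations: pd.DataFrame, label_a: str, label_b: str,
        stage_column: str = "stage", sample_column: str = "sample",
    ) -> "GroupContrast":
        """Build a contrast from an annotation table.

        ``label_a``/``label_b`` may be a stage-class name or a prefix
        (e.g. ``"M1"`` collects M1-oligo and M1-poly).
        """
        stages = annotations[stage_column].astype(str)
        a = annotations.loc[
            (stages == label_a) | stages.str.startswith(label_a + "-"), sample_column
        ]
        b = annotations.loc[
            (stages == label_b) | stages.str.startswith(label_b + "-"), sample_column
        ]
        return cls(tuple(a), tuple(b), label_a, label_b)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or not np.isfinite(p).all()):
        raise ValueError("p-values must be finite and in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Welch t per row; zero where both groups are constant."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(denom == 0, 0.0, t)


def _median_ratio(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Log2 median ratio per row (data already on the log2 scale)."""
    return np.median(a, axis=1) - np.median(b, axis=1)


def _pooled_empirical_p(obs: np.ndarray, null_pool: np.ndarray) -> np.ndarray:
    """Two-sided empirical p of each observed statistic against the pooled
    null, comparing magnitudes, with a +1 correction so p is never 0."""
    null_sorted = np.sort(np.abs(null_pool))
    n = null_sorted.size
    ge = n - np.searchsorted(null_sorted, np.abs(obs), side="left")
    return (ge + 1.0) / (n + 1.0)


def integrative_deg_test(
    expr: pd.DataFrame,
    contrast: GroupContrast,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_threshold: float = FDR_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
) -> pd.DataFrame:
    """Two-statistic permutation test for differential expression.

    ``expr`` must be normalized log2 expression.  Returns one row per gene
    with log2 fold change, both statistics, the combined p, BH q, direction,
    and the ``is_deg`` flag at the given thresholds.  Deterministic given
    ``seed``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives poorly resolved empirical p-values")
    missing = (set(contrast.group_a) | set(contrast.group_b)) - set(expr.columns)
    if missing:
        raise ContrastError(f"samples not in matrix: {sorted(missing)}")

    a = expr[list(contrast.group_a)].to_numpy(dtype=float)
    b = expr[list(contrast.group_b)].to_numpy(dtype=float)

    t_obs = _welch_t(a, b)
    m_obs = _median_ratio(a, b)
    lfc = a.mean(axis=1) - b.mean(axis=1)

    # The empirical null depends only on the unordered sample partition:
    # pooled columns in sorted sample-id order, the smaller group size
    # assigned first, and magnitudes compared two-sided.  Swapping the two
    # groups therefore preserves every p-value exactly.
    ordered = sorted(contrast.group_a) + sorted(contrast.group_b)
    pooled = expr[sorted(ordered)].to_numpy(dtype=float)
    n_tot = pooled.shape[1]
    n_small = min(len(contrast.group_a), len(contrast.group_b))

    rng = np.random.default_rng(seed)
    t_null = np.empty((n_perm, expr.shape[0]))
    m_null = np.empty((n_perm, expr.shape[0]))
    for i in range(n_perm):
        idx = rng.permutation(n_tot)
        pa, pb = pooled[:, idx[:n_small]], pooled[:, idx[n_small:]]
        t_null[i] = _welch_t(pa, pb)
        m_null[i] = _median_ratio(pa, pb)

    # Two-sided empirical p's against the pooled null, combined by signed
    # Stouffer z.  The two statistics are positively correlated, so the
    # combined z is referred to its own permutation null rather than to the
    # normal, which keeps the test calibrated.
    t_pool, m_pool = t_null.ravel(), m_null.ravel()

    def signed_z(t_vals, m_vals):
        p_t = _pooled_empirical_p(t_vals, t_pool)
        p_m = _pooled_empirical_p(m_vals, m_pool)
        z_t = np.sign(t_vals) * stats.norm.isf(p_t / 2.0)
        z_m = np.sign(m_vals) * stats.norm.isf(p_m / 2.0)
        return (z_t + z_m) / np.sqrt(2.0)

    z_obs = signed_z(t_obs, m_obs)
    z_null = signed_z(t_null.ravel(), m_null.ravel())
    p_combined = _pooled_empirical_p(z_obs, z_null)
    q = bh_fdr(p_combined)

    direction = np.where(lfc >= 0, "+", "-")
    is_deg = (q < fdr_threshold) & (np.abs(lfc) >= np.log2(fc_threshold))
    out = pd.DataFrame(
        {
            "log2_fc": lfc,
            "t_stat": t_obs,
            "median_ratio": m_obs,
            "p_combined": p_combined,
            "q": q,
            "direction": direction,
            "is_deg": is_deg,
        },
        index=expr.index,
    )
    out.attrs["fdr_threshold"] = fdr_threshold
    out.attrs["fc_threshold"] = fc_threshold
    out.attrs["contrast"] = f"{contrast.label_a} vs {contrast.label_b}"
    return out


@dataclass(frozen=True)
class IntersectionResult:
    """Cross-cohort DEG overlap: Venn regions and the shared gene list.

    ``shared`` holds genes in the focal cohort's DEG set that appear in at
    least one other cohort's set.  ``regions`` maps a frozenset of cohort
    names to the number of genes exclusive to exactly that combination.
    """

    deg_sets: Dict[str, frozenset]
    focal: str
    shared: Tuple[str, ...]
    regions: Dict[frozenset, int]


def intersect_degs(
    deg_tables: Mapping[str, pd.DataFrame], focal: Optional[str] = None
) -> IntersectionResult:
    """Venn-region counts and the focal-cohort shared DEG list.

    ``deg_tables`` maps cohort name to a DEG table (``is_deg`` column) or
    directly to an iterable of DEG gene ids.  The focal cohort defaults to
    the first key.
    """
    if len(deg_tables) < 2:
        raise ValueError("need at least 2 DEG tables to intersect")
    sets: Dict[str, frozenset] = {}
    for name, table in deg_tables.items():
        if isinstance(table, pd.DataFrame):
            sets[name] = frozenset(table.index[table["is_deg"]])
        else:
            sets[name] = frozenset(table)
    names = list(sets)
    focal = focal or names[0]
    if focal not in sets:
        raise ValueError(f"unknown focal cohort {focal!r}")

    union = frozenset().union(*sets.values())
    regions: Dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = frozenset(combo)
            outside = [sets[n] for n in names if n not in inside]
            region = frozenset.intersection(*[sets[n] for n in combo])
            for o in outside:
                region -= o
            regions[inside] = len(region)

    others = frozenset().union(*(sets[n] for n in names if n != focal))
    shared = tuple(sorted(sets[focal] & others))
    return IntersectionResult(sets, focal, shared, regions)


def directional_concordance(
    result: IntersectionResult, deg_tables: Mapping[str, pd.DataFrame]
) -> Tuple[Optional[float], pd.Series]:
    """Fraction of shared DEGs whose fold-change sign agrees in every cohort
    where the gene is a DEG.  Undefined (None) when no genes are shared."""
    flags = {}
    for gene in result.shared:
        signs = set()
        for name, table in deg_tables.items():
            if gene in result.deg_sets[name]:
                if gene not in table.index or "direction" not in table.columns:
                    raise ValueError(f"missing direction for {gene} in {name}")
                signs.add(table.loc[gene, "direction"])
        flags[gene] = len(signs) == 1
    series = pd.Series(flags, dtype=bool, name="concordant")
    if len(series) == 0:
        return None, series
    return float(series.mean()), series


def deg_fc_correlation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    gene_subset: Optional[Sequence[str]] = None,
) -> Optional[float]:
    """Pearson r of log2 fold changes over common (or specified) genes.

    Returns None when fewer than 3 common genes or a constant vector makes
    the correlation undefined.
    """
    common = table_a.index.intersection(table_b.index)
    if gene_subset is not None:
        common = common.intersection(pd.Index(gene_subset))
    if len(common) < 3:
        raise ValueError("need at least 3 common genes")
    x = table_a.loc[common, "log2_fc"].to_numpy(dtype=float)
    y = table_b.loc[common, "log2_fc"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.pearsonr(x, y)[0])
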