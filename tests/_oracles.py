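"""Independent brute-force oracles for cross-checking the implementation.

Every function here recomputes a quantity from first principles (elementary
interval pieces, all-pairs counting, explicit re-accumulation) without
reusing the package's merging or scanning shortcuts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def interval_union_runs(intervals):
    """Maximal covered runs of a set of half-open intervals.

    Splits the axis at every endpoint and tests each elementary piece by
    midpoint membership against every interval.
    """
    pts = sorted({p for iv in intervals for p in iv})
    runs = []
    cur = None
    for a, b in zip(pts[:-1], pts[1:]):
        mid = (a + b) / 2.0
        covered = any(s <= mid < e for s, e in intervals)
        if covered:
            if cur is None:
                cur = [a, b]
            else:
                cur[1] = b
        elif cur is not None:
            runs.append((cur[0], cur[1]))
            cur = None
    if cur is not None:
        runs.append((cur[0], cur[1]))
    return runs


def brute_force_cna(
    segments: pd.DataFrame,
    model,
    gain_thr: float = 0.3,
    loss_thr: float = -0.3,
    broad_frac: float = 0.98,
    samples=None,
):
    """Per-sample (broad, focal) event counts by direct interval arithmetic.

    Returns ``{sample: (n_broad, n_focal)}`` plus a detail dict keyed by
    (sample, chrom, arm, direction) -> (total altered bp, runs).
    """
    counts = {}
    detail = {}
    if samples is None:
        samples = segments["sample"].unique()
    by_key = {}
    for row in segments.itertuples(index=False):
        by_key.setdefault((row.sample, row.chrom), []).append(
            (row.start, row.end, row.value)
        )
    arm_list = [
        (r["chrom"], r["arm"], r["start"], r["end"])
        for _, r in model.arms.iterrows()
    ]
    for sample in samples:
        nb = nf = 0
        for chrom, arm, a0, a1 in arm_list:
            for direction in ("gain", "loss"):
                ivs = []
                for s, e, v in by_key.get((sample, chrom), ()):
                    if direction == "gain" and not v > gain_thr:
                        continue
                    if direction == "loss" and not v < loss_thr:
                        continue
                    s2, e2 = max(s, a0), min(e, a1)
                    if s2 < e2:
                        ivs.append((s2, e2))
                if not ivs:
                    continue
                runs = interval_union_runs(ivs)
                total = sum(e - s for s, e in runs)
                detail[(sample, chrom, arm, direction)] = (total, runs)
                if total / (a1 - a0) > broad_frac:
                    nb += 1
                else:
                    nf += len(runs)
        counts[sample] = (nb, nf)
    return counts, detail


def random_segment_table(rng: np.random.Generator, model, samples):
    """Random SEG table respecting per-sample/chromosome non-overlap.

    Each chromosome is cut at random breakpoints; pieces are kept with
    probability 1/2.  Values mix clear gains/losses, neutral values, and
    exact-boundary values (+-0.3).  Occasionally a near-whole-chromosome
    segment (spanning the centromere) or an exact-98%-of-arm segment is
    emitted to exercise the broad/focal boundary.
    """
    rows = []
    chroms = model.arms.groupby("chrom", sort=False).agg(
        start=("start", "min"), end=("end", "max")
    )
    for sample in samples:
        for chrom, row in chroms.iterrows():
            c0, c1 = int(row["start"]), int(row["end"])
            u = rng.random()
            if u < 0.15:
                # near-whole-chromosome event: broad on both arms
                margin = int((c1 - c0) * 0.004)
                rows.append(
                    (sample, chrom, c0 + margin, c1 - margin,
                     float(rng.choice([-1, 1])) * rng.uniform(0.31, 1.0))
                )
                continue
            if u < 0.25:
                # exactly 98% of the p arm: must be called focal
                arm = model.arms[
                    (model.arms["chrom"] == chrom) & (model.arms["arm"] == "p")
                ].iloc[0]
                span = int(round((arm["end"] - arm["start"]) * 0.98))
                rows.append(
                    (sample, chrom, int(arm["start"]), int(arm["start"]) + span,
                     float(rng.choice([-1, 1])) * rng.uniform(0.31, 1.0))
                )
                continue
            n_break = int(rng.integers(0, 8))
            pts = np.sort(rng.integers(c0 + 1, c1, size=n_break))
            edges = np.r_[c0, pts, c1]
            for s, e in zip(edges[:-1], edges[1:]):
                if e <= s or rng.random() < 0.5:
                    continue
                r = rng.random()
                if r < 0.1:
                    value = float(rng.choice([-0.3, 0.3]))  # boundary: not altered
                else:
                    value = float(rng.uniform(-1.0, 1.0))
                rows.append((sample, chrom, int(s), int(e), value))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "value"])


def brute_force_es(genes, members, metric=None, weight: float = 0.0) -> float:
    """Enrichment score by explicit O(N^2) re-accumulation and max scan."""
    genes = list(genes)
    n = len(genes)
    hits = [g in members for g in genes]
    k = sum(hits)
    if weight == 0:
        hit_w = [1.0 / k if h else 0.0 for h in hits]
    else:
        w = [abs(m) ** weight for m in metric]
        tot = sum(wi for wi, h in zip(w, hits) if h)
        hit_w = [wi / tot if h else 0.0 for wi, h in zip(w, hits)]
    best = 0.0
    for i in range(n):
        run = 0.0
        for j in range(i + 1):
            run += hit_w[j] if hits[j] else -1.0 / (n - k)
        if abs(run) > abs(best):
            best = run
    return best


def pair_counting_auc(scores, labels) -> float:
    """AUC as (concordant + half ties) over all positive-negative pairs."""
    scores = list(scores)
    labels = list(labels)
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_bh(pvalues):
    """Benjamini-Hochberg step-up q-values by the textbook recursion."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q
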