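"""Copy-number segment classification and genomic alteration scores.

The pipeline mirrors the standard arm-level workflow on GISTIC-style
segment values: threshold segments into gains (> 0.3) and losses (< -0.3),
split them at centromeres so every piece lies in one arm, merge altered
regions per (sample, arm, direction), and classify the merged extent as
*broad* when it covers more than 98% of the arm, otherwise as *focal*
events (one per maximal altered run).  The per-sample scores are then

* broad-CNA score = broad events / total chromosomal arms,
* focal-CNA score = focal events / total genes in the catalog,
* TMB = nonsynonymous mutations / exome size in Mb (default 299.029409),
* fusion score = fusion events / total fusion types.

All thresholds use strict inequalities: a value of exactly +/-0.3 is not
altered and a merged extent of exactly 98% is not broad.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeArmModel

GAIN_THRESHOLD = 0.3
LOSS_THRESHOLD = -0.3
BROAD_FRACTION = 0.98
EXOME_SIZE_MB = 299.029409

EVENT_COLUMNS = [
    "sample", "chrom", "arm", "direction", "breadth", "span", "arm_fraction",
]


class SegmentError(ValueError):
    """Raised for malformed segment records."""


def validate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "chrom", "start", "end", "value"}
    missing = required - set(segments.columns)
    if missing:
        raise SegmentError(f"segment table missing columns {sorted(missing)}")
    bad = segments[segments["end"] <= segments["start"]]
    if len(bad):
        rec = bad.iloc[0]
        raise SegmentError(
            f"segment with end <= start: sample={rec['sample']} "
            f"{rec['chrom']}:{rec['start']}-{rec['end']}"
        )
    return segments


def threshold_segments(
    segments: pd.DataFrame,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
) -> pd.DataFrame:
    """Keep altered segments only, labelling each gain or loss.

    value > gain_threshold -> gain; value < loss_threshold -> loss; values
    between the thresholds (boundaries included) are dropped.
    """
    if not loss_threshold < gain_threshold:
        raise SegmentError("loss_threshold must be below gain_threshold")
    validate_segments(segments)
    value = segments["value"].to_numpy(dtype=float)
    direction = np.where(
        value > gain_threshold, "gain", np.where(value < loss_threshold, "loss", "")
    )
    out = segments.copy()
    out["direction"] = direction
    return out[out["direction"] != ""].reset_index(drop=True)


def split_segments_by_arm(
    segments: pd.DataFrame, model: GenomeArmModel
) -> pd.DataFrame:
    """Clip every segment to the arms it overlaps (split at the centromere).

    The value is copied to both parts; total altered base pairs are
    conserved.  A segment overlapping no arm raises.
    """
    validate_segments(segments)
    known = set(model.arms["chrom"])
    unknown = set(segments["chrom"]) - known
    if unknown:
        raise SegmentError(f"chromosomes not in arm model: {sorted(unknown)}")

    pieces = []
    for chrom, seg_grp in segments.groupby("chrom", sort=False):
        arms = model.arms[model.arms["chrom"] == chrom]
        s = seg_grp["start"].to_numpy()
        e = seg_grp["end"].to_numpy()
        covered = np.zeros(len(seg_grp), dtype=np.int64)
        for _, arm in arms.iterrows():
            lo = np.maximum(s, arm["start"])
            hi = np.minimum(e, arm["end"])
            keep = lo < hi
            if keep.any():
                part = seg_grp.loc[keep].copy()
                part["start"] = lo[keep]
                part["end"] = hi[keep]
                part["arm"] = arm["arm"]
                pieces.append(part)
                covered[keep] += hi[keep] - lo[keep]
        if (covered < e - s).any():
            rec = seg_grp.iloc[int(np.argmax(covered < e - s))]
            raise SegmentError(
                f"segment outside arm intervals: sample={rec['sample']} "
                f"{chrom}:{rec['start']}-{rec['end']}"
            )
    if not pieces:
        out = segments.iloc[0:0].copy()
        out["arm"] = pd.Series(dtype=object)
        return out
    return pd.concat(pieces, ignore_index=True)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> list:
    order = np.argsort(starts, kind="stable")
    merged = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([int(s), int(e)])
    return merged


def call_events(
    altered: pd.DataFrame,
    model: GenomeArmModel,
    broad_fraction: float = BROAD_FRACTION,
) -> pd.DataFrame:
    """Classify thresholded, arm-split segments into broad/focal events.

    Per (sample, arm, direction) the altered regions are merged; when the
    merged extent exceeds ``broad_fraction`` of the arm one broad event is
    emitted, otherwise one focal event per maximal altered run.
    """
    if not 0.0 < broad_fraction < 1.0:
        raise SegmentError("broad_fraction must be in (0, 1)")
    if "direction" not in altered.columns or "arm" not in altered.columns:
        raise SegmentError("call_events needs thresholded, arm-split segments")

    arm_len = {
        (r["chrom"], r["arm"]): r["end"] - r["start"]
        for _, r in model.arms.iterrows()
    }
    rows = []
    keys = ["sample", "chrom", "arm", "direction"]
    for (sample, chrom, arm, direction), grp in altered.groupby(keys, sort=False):
        alen = arm_len[(chrom, arm)]
        merged = _merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
        total = sum(e - s for s, e in merged)
        frac = total / alen
        if frac > broad_fraction:
            rows.append((sample, chrom, arm, direction, "broad", total, frac))
        else:
            for s, e in merged:
                rows.append(
                    (sample, chrom, arm, direction, "focal", e - s, (e - s) / alen)
                )
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return events.sort_values(["sample", "chrom", "arm", "direction"]).reset_index(
        drop=True
    )


def _per_sample_count(
    events: pd.DataFrame, breadth: str, samples: Optional[Sequence[str]]
) -> pd.Series:
    sub = events[events["breadth"] == breadth]
    counts = sub.groupby("sample").size()
    if samples is not None:
        counts = counts.reindex(samples, fill_value=0)
    return counts.astype(float)


def broad_cna_score(
    events: pd.DataFrame,
    model: GenomeArmModel,
    samples: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Broad events per sample over the total number of chromosomal arms."""
    score = _per_sample_count(events, "broad", samples) / model.total_arms
    score.name = "broad_cna_score"
    return score


def focal_cna_score(
    events: pd.DataFrame,
    model: GenomeArmModel,
    samples: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Focal events per sample over the total number of catalog genes."""
    if model.total_genes == 0:
        raise SegmentError("gene catalog is empty; focal score undefined")
    score = _per_sample_count(events, "focal", samples) / model.total_genes
    score.name = "focal_cna_score"
    return score


def tmb_score(nonsyn_count, exome_size_mb: float = EXOME_SIZE_MB):
    """Tumor mutational burden: nonsynonymous mutations per Mb of exome."""
    if exome_size_mb <= 0:
        raise ValueError("exome_size_mb must be positive")
    arr = np.asarray(nonsyn_count, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative mutation count")
    out = arr / exome_size_mb
    return float(out) if np.isscalar(nonsyn_count) else out


def fusion_score(n_events, n_fusion_types):
    """Fusion events over the total number of fusion types."""
    types = np.asarray(n_fusion_types, dtype=float)
    if (types <= 0).any():
        raise ValueError("n_fusion_types must be positive")
    events = np.asarray(n_events, dtype=float)
    if (events < 0).any():
        raise ValueError("negative fusion event count")
    out = events / types
    return float(out) if np.isscalar(n_events) else out


def cna_frequency_profile(
    altered: pd.DataFrame, model: GenomeArmModel, bin_bp: int
) -> pd.DataFrame:
    """Cohort gain/loss frequency along the genome in fixed bins.

    For each bin the gain (loss) frequency is the fraction of samples with
    any gain (loss) segment overlapping it.
    """
    if bin_bp <= 0:
        raise SegmentError("bin_bp must be positive")
    samples = altered["sample"].unique()
    if len(samples) == 0:
        raise SegmentError("empty cohort: no samples in segment table")
    n = len(samples)
    rows = []
    for chrom, cgrp in model.arms.groupby("chrom", sort=False):
        cstart, cend = int(cgrp["start"].min()), int(cgrp["end"].max())
        edges = np.append(np.arange(cstart, cend, bin_bp), cend)
        segs = altered[altered["chrom"] == chrom]
        for b0, b1 in zip(edges[:-1], edges[1:]):
            if b1 <= b0:
                continue
            hit = segs[(segs["start"] < b1) & (segs["end"] > b0)]
            gain = hit.loc[hit["direction"] == "gain", "sample"].nunique()
            loss = hit.loc[hit["direction"] == "loss", "sample"].nunique()
            rows.append((chrom, int(b0), int(b1), gain / n, loss / n))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gain_freq", "loss_freq"]
    )


def score_correlation_matrix(panel: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between per-sample score columns.

    Constant columns yield undefined (NaN) correlations rather than 0.
    """
    numeric = panel.select_dtypes(include=[np.number])
    if len(numeric) < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    corr = numeric.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    const = numeric.std(ddof=0) == 0
    for col in numeric.columns[const]:
        corr.loc[col, :] = np.nan
        corr.loc[:, col] = np.nan
    return corr


def score_segments(
    segments: pd.DataFrame,
    model: GenomeArmModel,
    samples: Optional[Sequence[str]] = None,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
    broad_fraction: float = BROAD_FRACTION,
) -> pd.DataFrame:
    """Threshold -> arm-split -> call events -> per-sample CNA scores."""
    altered = threshold_segments(segments, gain_threshold, loss_threshold)
    split = split_segments_by_arm(altered, model)
    events = call_events(split, model, broad_fraction)
    if samples is None:
        samples = sorted(segments["sample"].unique())
    return pd.DataFrame(
        {
            "broad_cna_score": broad_cna_score(events, model, samples),
            "focal_cna_score": focal_cna_score(events, model, samples),
        }
    )
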