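"""Count-matrix preprocessing and single-sample signature activation.

Preprocessing follows the standard bulk RNA-seq path: drop genes whose
summed raw count across libraries falls below a floor, then normalize
library composition with the trimmed mean of M-values (TMM) and work on
log2 counts-per-million.

Signature activation is a single-sample Z-score: each signature gene is
standardized across the cohort and a sample's score is the direction-signed
sum of its member z-values divided by sqrt(k) (Stouffer combination), so a
random gene set on null data scores approximately standard normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .signatures import GeneSignature

TMM_TRIM_LOGRATIO = 0.30
TMM_TRIM_ABS = 0.05
LOG_PSEUDOCOUNT = 0.5


class ExpressionError(ValueError):
    pass


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ExpressionError("empty expression matrix")
    if matrix.index.duplicated().any():
        raise ExpressionError("duplicate gene ids")
    if matrix.columns.duplicated().any():
        raise ExpressionError("duplicate sample ids")


def filter_low_counts(
    raw: pd.DataFrame, min_total: int = 2, per_library: bool = False
) -> pd.DataFrame:
    """Drop genes with insufficient raw counts across all libraries.

    With ``per_library=False`` (default) a gene is kept when its counts
    summed over all libraries reach ``min_total``; with ``per_library=True``
    every single library must reach ``min_total``.
    """
    _check_matrix(raw)
    if (raw.to_numpy() < 0).any():
        raise ExpressionError("raw counts must be non-negative")
    if per_library:
        keep = (raw >= min_total).all(axis=1)
    else:
        keep = raw.sum(axis=1) >= min_total
    return raw.loc[keep]


def _tmm_factor_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_logratio: float,
    trim_abs: float,
) -> float:
    """TMM scaling factor of one library against the reference library.

    Doubly trimmed (by log-ratio and by absolute expression) precision-
    weighted mean of M-values, as in the original TMM description.
    """
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    if len(o) == 0:
        return 1.0
    p_o, p_r = o / lib_obs, r / lib_ref
    M = np.log2(p_o / p_r)
    A = 0.5 * np.log2(p_o * p_r)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    lo_m = np.floor(n * trim_logratio) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_abs) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(M).rank().to_numpy()
    rank_a = pd.Series(A).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any() or w[keep2].sum() == 0:
        return 1.0
    f = np.sum(M[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


@dataclass(frozen=True)
class TmmResult:
    """Normalization factors, effective library sizes, and log2-CPM matrix."""

    factors: pd.Series
    lib_sizes: pd.Series
    log2_cpm: pd.DataFrame
    ref_sample: str

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


def tmm_normalize(
    raw: pd.DataFrame,
    trim_logratio: float = TMM_TRIM_LOGRATIO,
    trim_abs: float = TMM_TRIM_ABS,
    ref_sample: Optional[str] = None,
) -> TmmResult:
    """TMM library-composition normalization on a filtered count matrix.

    The reference library defaults to the one whose 75th-percentile count
    fraction is closest to the cohort mean.  Factors are rescaled so their
    geometric mean is 1; the normalized matrix is log2 CPM over effective
    library sizes with a 0.5 pseudocount.
    """
    _check_matrix(raw)
    counts = raw.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = raw.columns[lib <= 0].tolist()
        raise ExpressionError(f"libraries with zero total counts: {bad}")

    if ref_sample is None:
        f75 = np.quantile(counts, 0.75, axis=0) / lib
        ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
        ref_sample = raw.columns[ref_j]
    else:
        if ref_sample not in raw.columns:
            raise ExpressionError(f"unknown reference sample {ref_sample!r}")
        ref_j = raw.columns.get_loc(ref_sample)

    factors = np.array(
        [
            _tmm_factor_pair(
                counts[:, j], counts[:, ref_j], lib[j], lib[ref_j],
                trim_logratio, trim_abs,
            )
            for j in range(counts.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    eff = lib * factors
    log2_cpm = pd.DataFrame(
        np.log2((counts + LOG_PSEUDOCOUNT) / eff[np.newaxis, :] * 1e6),
        index=raw.index,
        columns=raw.columns,
    )
    return TmmResult(
        factors=pd.Series(factors, index=raw.columns, name="tmm_factor"),
        lib_sizes=pd.Series(lib, index=raw.columns, name="lib_size"),
        log2_cpm=log2_cpm,
        ref_sample=str(ref_sample),
    )


@dataclass(frozen=True)
class ActivationScores:
    """Per-sample activation of one signature plus the scoring parameters."""

    scores: pd.Series
    signature: str
    n_members_used: int
    combine: str
    missing: Tuple[str, ...] = ()


def signature_zscore(
    expr: pd.DataFrame,
    signature: GeneSignature,
    combine: str = "stouffer",
) -> ActivationScores:
    """Single-sample signature activation by the Z-score method.

    Each present member gene is standardized to zero mean / unit variance
    across samples; a sample's score is the direction-signed sum of member
    z-values divided by sqrt(k) (``combine="stouffer"``) or the plain mean
    (``combine="mean"``).  Missing and zero-variance members are skipped
    with a warning.
    """
    _check_matrix(expr)
    if expr.shape[1] < 2:
        raise ExpressionError("need at least 2 samples to standardize")
    if combine not in ("stouffer", "mean"):
        raise ExpressionError(f"unknown combination rule {combine!r}")

    present = [g for g in signature.genes if g in expr.index]
    missing = tuple(g for g in signature.genes if g not in expr.index)
    if missing:
        warnings.warn(
            f"{signature.name}: {len(missing)} member(s) absent from matrix"
        )
    sub = expr.loc[present]
    sd = sub.std(axis=1, ddof=0)
    flat = sd[sd == 0].index.tolist()
    if flat:
        warnings.warn(f"{signature.name}: zero-variance member(s) {flat} excluded")
        sub = sub.drop(index=flat)
        sd = sd.drop(index=flat)
    if sub.shape[0] == 0:
        raise ExpressionError(f"no usable members of {signature.name} in matrix")

    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    signs = np.array([signature.direction(g) for g in sub.index], dtype=float)
    signed_sum = (z.to_numpy() * signs[:, None]).sum(axis=0)
    k = sub.shape[0]
    values = signed_sum / np.sqrt(k) if combine == "stouffer" else signed_sum / k
    scores = pd.Series(values, index=expr.columns, name=f"{signature.name}_score")
    return ActivationScores(
        scores=scores,
        signature=signature.name,
        n_members_used=k,
        combine=combine,
        missing=missing,
    )


def stratify_cin(scores: pd.Series, method: str = "median") -> pd.DataFrame:
    """Label samples CIN-high/low (median split) or by empirical tertiles.

    Median method: score strictly above the cohort median -> ``high``,
    otherwise ``low``.  Tertile method: ``lowest`` / ``middle`` / ``highest``.
    """
    if len(scores) < 2:
        raise ExpressionError("need at least 2 samples to stratify")
    if scores.nunique() == 1:
        raise ExpressionError("constant scores cannot be stratified")
    if method == "median":
        thr = float(scores.median())
        labels = np.where(scores > thr, "high", "low")
        thresholds = [thr]
    elif method == "tertile":
        q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
        labels = np.where(
            scores <= q1, "lowest", np.where(scores <= q2, "middle", "highest")
        )
        thresholds = [float(q1), float(q2)]
    else:
        raise ExpressionError(f"unknown stratification method {method!r}")
    return pd.DataFrame(
        {
            "sample": scores.index,
            "score": scores.to_numpy(),
            "cin_status": labels,
            "method": method,
            "threshold": ", ".join(f"{t:.6g}" for t in thresholds),
        }
    ).set_index("sample")
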