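"""Assembly of the per-sample genomic score panel.

Combines the copy-number, mutation, fusion, and MSI scores with the
expression-based signature activation scores into one table, the input for
the score correlation matrix.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from . import cna, expression
from .genome import GenomeArmModel
from .signatures import CIN70, PC_CIN


def build_score_panel(
    segments: pd.DataFrame,
    model: GenomeArmModel,
    annotations: pd.DataFrame,
    log2_expr: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-sample panel: broad/focal CNA, TMB, fusion, MSI passthrough, and
    (when expression is given) CIN70 and PC-CIN activation scores.

    ``annotations`` needs columns sample, nonsyn_mutations, fusion_events,
    fusion_types_total, and optionally msi_score (passthrough from MANTIS).
    """
    samples = list(annotations["sample"])
    panel = cna.score_segments(segments, model, samples=samples)
    ann = annotations.set_index("sample")
    panel["tmb"] = cna.tmb_score(ann["nonsyn_mutations"].to_numpy())
    panel["fusion_score"] = cna.fusion_score(
        ann["fusion_events"].to_numpy(), ann["fusion_types_total"].to_numpy()
    )
    if "msi_score" in ann.columns:
        panel["msi_score"] = ann["msi_score"]

    if log2_expr is not None:
        for sig in (CIN70, PC_CIN):
            present = [g for g in sig.genes if g in log2_expr.index]
            if present:
                scores = expression.signature_zscore(log2_expr, sig).scores
                col = "cin70_score" if sig.name == "CIN70" else "pccin_score"
                panel[col] = scores.reindex(panel.index)
    return panel
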