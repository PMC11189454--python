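"""Nearest-centroid molecular subtyping with an "undefined" class.

Each ROI's log2 expression over genes shared with the centroid matrix is
Pearson-correlated with every subtype centroid; the ROI takes the best
centroid's label when that correlation reaches ``min_corr``, otherwise it is
called undefined. The best-minus-second-best separation is reported for
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import CentroidMatrix, ExpressionMatrix, ValidationError
from .crosstalk import pearson

UNDEFINED = "undefined"

DEFAULT_SUBTYPES = ("LumP", "LumNS", "LumU", "Basal", "Stroma-rich", "NE-like")


@dataclass
class SubtypeCall:
    roi_id: str
    correlations: dict  # subtype label -> Pearson r
    label: str  # centroid label or "undefined"
    separation: float  # best minus second-best correlation
    tied: bool


def classify(
    expr: ExpressionMatrix, centroids: CentroidMatrix, min_corr: float = 0.2
) -> list[SubtypeCall]:
    """Pearson nearest-centroid calls over shared genes (>= 20 required)."""
    if expr.scale != "log2":
        raise ValidationError("classify expects log2-scale expression")
    shared = [g for g in expr.gene_ids if g in set(centroids.gene_ids)]
    if len(shared) < 20:
        raise ValidationError(
            f"only {len(shared)} gene(s) shared with centroids; need at least 20"
        )
    X = expr.data.loc[shared]
    C = centroids.data.loc[shared]

    calls = []
    for rid in expr.roi_ids:
        x = X[rid].to_numpy(dtype=float)
        corr = {lab: pearson(x, C[lab].to_numpy(dtype=float)) for lab in centroids.labels}
        finite = {k: v for k, v in corr.items() if not np.isnan(v)}
        if not finite:
            calls.append(SubtypeCall(rid, corr, UNDEFINED, np.nan, False))
            continue
        best_r = max(finite.values())
        winners = sorted(k for k, v in finite.items() if v == best_r)
        label = winners[0] if best_r >= min_corr else UNDEFINED
        rest = sorted(finite.values(), reverse=True)
        separation = best_r - rest[1] if len(rest) > 1 else np.nan
        calls.append(SubtypeCall(rid, corr, label, separation, len(winners) > 1))
    return calls


def calls_table(calls: list[SubtypeCall]) -> pd.DataFrame:
    labels = sorted({k for c in calls for k in c.correlations})
    rows = []
    for c in calls:
        row = {"roi_id": c.roi_id, "label": c.label, "separation": c.separation, "tied": c.tied}
        for lab in labels:
            row[f"r_{lab}"] = c.correlations.get(lab, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
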