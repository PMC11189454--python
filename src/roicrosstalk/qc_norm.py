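"""ROI/gene QC filters and third-quartile (Q3) normalization.

ROI retention rules (defaults): raw reads >= 1000, sequencing saturation
strictly > 50%, aligned/trimmed/stitched percentages strictly > 80%, and at
least 10% of panel genes detected (count > 0). Genes are then kept only if
detected in strictly more than 10% of the retained ROIs. Q3 normalization
scales each ROI by its 75th percentile of counts, anchored to the geometric
mean of the per-ROI 75th percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    CountMatrix,
    ExpressionMatrix,
    RoiAnnotation,
    ValidationError,
    check_roi_agreement,
)


@dataclass
class QcThresholds:
    min_raw_reads: int = 1000  # kept if >=
    min_saturation: float = 50.0  # kept if strictly >
    min_pct_aligned: float = 80.0  # strictly >
    min_pct_trimmed: float = 80.0  # strictly >
    min_pct_stitched: float = 80.0  # strictly >
    min_genes_detected_frac: float = 0.10  # ROI kept if fraction detected >=
    gene_detection_frac: float = 0.10  # gene kept if detected in strictly > this fraction
    detection_min_count: int = 1  # detected means count >= this

    def __post_init__(self) -> None:
        for name in ("min_genes_detected_frac", "gene_detection_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("min_saturation", "min_pct_aligned", "min_pct_trimmed", "min_pct_stitched"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} must lie in [0, 100], got {v}")


@dataclass
class QcReport:
    """Per-item pass/fail accounting for a filtering step."""

    kept_roi_ids: list = field(default_factory=list)
    removed_roi_ids: list = field(default_factory=list)
    kept_gene_ids: list = field(default_factory=list)
    removed_gene_ids: list = field(default_factory=list)
    failed_rules: dict = field(default_factory=dict)  # id -> list of rule names

    @property
    def n_removed_rois(self) -> int:
        return len(self.removed_roi_ids)

    @property
    def n_removed_genes(self) -> int:
        return len(self.removed_gene_ids)

    def roi_table(self) -> pd.DataFrame:
        rows = []
        for rid in self.kept_roi_ids:
            rows.append({"roi_id": rid, "kept": True, "failed_rules": ""})
        for rid in self.removed_roi_ids:
            rows.append(
                {"roi_id": rid, "kept": False, "failed_rules": ";".join(self.failed_rules[rid])}
            )
        return pd.DataFrame(rows)


def roi_failures(counts: CountMatrix, annot: RoiAnnotation, th: QcThresholds) -> dict:
    """Evaluate every ROI rule; return {roi_id: [failed rule names]} (empty list = pass)."""
    check_roi_agreement(counts.roi_ids, annot.roi_ids)
    arr = counts.counts
    n_genes = arr.shape[0]
    detected_frac = (arr >= th.detection_min_count).sum(axis=0) / n_genes
    frac_by_roi = dict(zip(counts.roi_ids, detected_frac))

    out: dict = {}
    for rid in counts.roi_ids:
        row = annot.data.loc[rid]
        failed = []
        if row["raw_reads"] < th.min_raw_reads:
            failed.append("min_raw_reads")
        if not row["saturation"] > th.min_saturation:
            failed.append("min_saturation")
        if not row["pct_aligned"] > th.min_pct_aligned:
            failed.append("min_pct_aligned")
        if not row["pct_trimmed"] > th.min_pct_trimmed:
            failed.append("min_pct_trimmed")
        if not row["pct_stitched"] > th.min_pct_stitched:
            failed.append("min_pct_stitched")
        if frac_by_roi[rid] < th.min_genes_detected_frac:
            failed.append("min_genes_detected_frac")
        out[rid] = failed
    return out


def filter_rois(
    counts: CountMatrix, annot: RoiAnnotation, th: QcThresholds | None = None
) -> tuple[CountMatrix, QcReport]:
    """Drop ROIs failing any QC rule; the report names every failed rule per ROI."""
    th = th or QcThresholds()
    failures = roi_failures(counts, annot, th)
    kept = [rid for rid in counts.roi_ids if not failures[rid]]
    removed = [rid for rid in counts.roi_ids if failures[rid]]
    if not kept:
        raise ValidationError("all ROIs failed QC; refusing to return an empty matrix")
    report = QcReport(
        kept_roi_ids=kept,
        removed_roi_ids=removed,
        failed_rules={rid: failures[rid] for rid in removed},
    )
    return counts.subset(rois=kept), report


def filter_genes(
    counts: CountMatrix, frac: float = 0.10, detection_min_count: int = 1
) -> tuple[CountMatrix, QcReport]:
    """Keep genes detected in strictly more than ``frac`` of the ROIs."""
    if not 0.0 <= frac <= 1.0:
        raise ValidationError(f"gene detection fraction must lie in [0, 1], got {frac}")
    arr = counts.counts
    n_rois = arr.shape[1]
    detected_frac = (arr >= detection_min_count).sum(axis=1) / n_rois
    keep_mask = detected_frac > frac
    kept = [g for g, k in zip(counts.gene_ids, keep_mask) if k]
    removed = [g for g, k in zip(counts.gene_ids, keep_mask) if not k]
    report = QcReport(
        kept_gene_ids=kept,
        removed_gene_ids=removed,
        failed_rules={g: ["gene_detection_frac"] for g in removed},
    )
    return counts.subset(genes=kept), report


def q3_scale_factors(counts: CountMatrix) -> pd.Series:
    """Per-ROI 75th percentile of counts (linear-interpolation percentile)."""
    q3 = np.percentile(counts.counts, 75, axis=0, method="linear")
    return pd.Series(q3, index=counts.roi_ids)


def q3_normalize(counts: CountMatrix) -> ExpressionMatrix:
    """Q3-normalize: value = count * geomean(Q3_j over ROIs) / Q3_j.

    After normalization every ROI's 75th percentile equals the common
    geometric mean of the raw per-ROI third quartiles.
    """
    q3 = q3_scale_factors(counts)
    zero = q3[q3 <= 0]
    if len(zero):
        raise ValidationError(
            f"ROI(s) with non-positive third quartile (should have been removed by QC): "
            f"{list(zero.index)}"
        )
    anchor = float(np.exp(np.mean(np.log(q3.to_numpy()))))
    scaled = counts.data.astype(float) * (anchor / q3)
    return ExpressionMatrix(scaled, "normalized")


def log2_transform(expr: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(normalized + offset); requires a normalized-scale input."""
    if expr.scale != "normalized":
        raise ValidationError(f"log2_transform expects scale 'normalized', got {expr.scale!r}")
    if offset <= 0:
        raise ValidationError(f"offset must be positive, got {offset}")
    if np.any(expr.values < 0):
        raise ValidationError("negative values in normalized matrix")
    return ExpressionMatrix(np.log2(expr.data + offset), "log2")
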