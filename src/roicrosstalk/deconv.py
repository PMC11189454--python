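"""Signature-matrix cell-type deconvolution by non-negative least squares.

Each ROI's linear-scale expression vector is regressed on the cell-profile
matrix over shared (optionally signature-restricted) genes; the non-negative
coefficients are renormalized to proportions summing to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core_model import CellProfileMatrix, ExpressionMatrix, ValidationError


@dataclass
class CellProportions:
    data: pd.DataFrame  # index = ROI ids, columns = cell types, rows sum to 1
    residuals: pd.Series  # per-ROI residual 2-norm of the NNLS fit

    @property
    def roi_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


def select_signature_genes(profiles: CellProfileMatrix, top_n: int = 50) -> list[str]:
    """Top ``top_n`` genes per cell type by fold difference over the mean of other types."""
    df = profiles.data
    eps = 1e-9
    chosen: set[str] = set()
    n_types = df.shape[1]
    for ct in df.columns:
        others = (df.sum(axis=1) - df[ct]) / (n_types - 1)
        fold = (df[ct] + eps) / (others + eps)
        chosen.update(fold.sort_values(ascending=False).head(top_n).index)
    return sorted(chosen)


def estimate_proportions(
    expr: ExpressionMatrix,
    profiles: CellProfileMatrix,
    signature_genes=None,
    use_signature_selection: bool = False,
    signature_top_n: int = 50,
) -> CellProportions:
    """Per-ROI NNLS deconvolution against the cell-profile matrix.

    Proportions are scale-invariant in the ROI expression and exact on
    noiseless mixtures of linearly independent profiles.
    """
    if expr.scale != "normalized":
        raise ValidationError("estimate_proportions expects linear normalized expression")
    if signature_genes is None and use_signature_selection:
        signature_genes = select_signature_genes(profiles, signature_top_n)

    shared = [g for g in expr.gene_ids if g in set(profiles.gene_ids)]
    if signature_genes is not None:
        sig = set(signature_genes)
        shared = [g for g in shared if g in sig]
    n_types = len(profiles.cell_types)
    if len(shared) < n_types:
        raise ValidationError(
            f"only {len(shared)} shared gene(s) for {n_types} cell types; need at least {n_types}"
        )

    P = profiles.data.loc[shared].to_numpy(dtype=float)
    Y = expr.data.loc[shared].to_numpy(dtype=float)

    props = np.zeros((len(expr.roi_ids), n_types))
    resid = np.zeros(len(expr.roi_ids))
    for j, rid in enumerate(expr.roi_ids):
        beta, rnorm = nnls(P, Y[:, j])
        total = beta.sum()
        if total <= 0:
            raise ValidationError(f"ROI {rid!r} is non-decomposable (all NNLS coefficients zero)")
        props[j] = beta / total
        resid[j] = rnorm

    return CellProportions(
        data=pd.DataFrame(props, index=expr.roi_ids, columns=profiles.cell_types),
        residuals=pd.Series(resid, index=expr.roi_ids, name="residual"),
    )
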