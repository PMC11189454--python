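"""Paired sender->receiver ligand-activity scoring.

Cores pair a sender-compartment profile with a receiver-compartment profile.
For each ligand, its expression across sender profiles is correlated
(Pearson) with each prior target's expression across the paired receiver
profiles; the mean of those per-target correlations is the ligand's activity,
and a ligand is called active when activity >= 0.2. A companion routine
correlates ligand expression with deconvolved cell-type proportions to
attribute ligand origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    COMPARTMENTS,
    ExpressionMatrix,
    LigandTargetPrior,
    RoiAnnotation,
    ValidationError,
)
from .deconv import CellProportions


@dataclass
class CrosstalkConfig:
    activity_threshold: float = 0.2  # active iff activity >=
    top_k_targets_per_ligand: int | None = 200  # None keeps every surviving pair
    min_targets_present: int = 5
    min_pairs: int = 3

    def __post_init__(self) -> None:
        if not -1.0 < self.activity_threshold < 1.0:
            raise ValidationError("activity_threshold must lie in (-1, 1)")
        if self.min_targets_present < 2:
            raise ValidationError("min_targets_present must be >= 2")
        if (
            self.top_k_targets_per_ligand is not None
            and self.top_k_targets_per_ligand < self.min_targets_present
        ):
            raise ValidationError("top_k_targets_per_ligand must be >= min_targets_present")
        if self.min_pairs < 3:
            raise ValidationError("min_pairs must be >= 3")


@dataclass
class RoiPairing:
    """One sender/receiver profile pair per core, gene x core matrices."""

    sender_compartment: str
    receiver_compartment: str
    core_ids: list
    sender: pd.DataFrame  # genes x cores, mean log2 expression of sender ROIs
    receiver: pd.DataFrame  # genes x cores
    skipped_cores: list = field(default_factory=list)  # cores lacking a compartment

    @property
    def n_pairs(self) -> int:
        return len(self.core_ids)


@dataclass
class LigandActivity:
    ligand: str
    sender_compartment: str
    receiver_compartment: str
    target_r: dict  # target -> Pearson r over pairs
    n_targets_used: int
    n_targets_skipped: int  # targets with zero receiver variance
    activity: float | None  # None when the ligand is not evaluable
    n_pairs: int
    active: bool
    evaluable: bool


def pearson(x, y) -> float:
    """Plain Pearson correlation of two 1-D vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def build_pairs(
    annot: RoiAnnotation,
    expr: ExpressionMatrix,
    sender: str,
    receiver: str,
    min_pairs: int = 3,
) -> RoiPairing:
    """Per-core sender/receiver profiles; compartment profiles are arithmetic
    means over the core's ROIs of that compartment. Cores lacking either
    compartment are skipped and recorded."""
    for c in (sender, receiver):
        if c not in COMPARTMENTS:
            raise ValidationError(f"compartment {c!r} outside the closed set {COMPARTMENTS}")
    if expr.scale != "log2":
        raise ValidationError("build_pairs expects log2-scale expression")
    rois = [r for r in annot.roi_ids if r in set(expr.roi_ids)]

    by_core: dict = {}
    for rid in rois:
        row = annot.data.loc[rid]
        by_core.setdefault(row["core_id"], {}).setdefault(row["compartment"], []).append(rid)

    core_ids, sender_cols, receiver_cols, skipped = [], [], [], []
    for core in sorted(by_core):
        comps = by_core[core]
        if sender in comps and receiver in comps:
            core_ids.append(core)
            sender_cols.append(expr.data[comps[sender]].mean(axis=1))
            receiver_cols.append(expr.data[comps[receiver]].mean(axis=1))
        else:
            skipped.append(core)

    if len(core_ids) < min_pairs:
        raise ValidationError(
            f"only {len(core_ids)} core(s) have both {sender!r} and {receiver!r} ROIs; "
            f"need at least {min_pairs}"
        )
    return RoiPairing(
        sender_compartment=sender,
        receiver_compartment=receiver,
        core_ids=core_ids,
        sender=pd.concat(sender_cols, axis=1, keys=core_ids),
        receiver=pd.concat(receiver_cols, axis=1, keys=core_ids),
        skipped_cores=skipped,
    )


def restrict_prior(
    prior: LigandTargetPrior, genes_present, cfg: CrosstalkConfig | None = None
) -> LigandTargetPrior:
    """Keep pairs whose ligand and target are both measured; per ligand retain
    the top-K pairs by weight (ties by target symbol) and drop ligands with
    fewer than ``min_targets_present`` surviving targets."""
    cfg = cfg or CrosstalkConfig()
    present = set(genes_present)
    df = prior.data
    df = df[df["ligand"].isin(present) & df["target"].isin(present)]

    kept = []
    for ligand, grp in df.groupby("ligand", sort=True):
        grp = grp.sort_values(["weight", "target"], ascending=[False, True], kind="stable")
        if cfg.top_k_targets_per_ligand is not None:
            grp = grp.head(cfg.top_k_targets_per_ligand)
        if len(grp) >= cfg.min_targets_present:
            kept.append(grp)
    if not kept:
        raise ValidationError("no ligand survives prior restriction")
    return LigandTargetPrior(pd.concat(kept, ignore_index=True))


def ligand_activity(
    pairs: RoiPairing, prior: LigandTargetPrior, cfg: CrosstalkConfig | None = None
) -> list[LigandActivity]:
    """Mean per-target Pearson correlation between sender ligand expression and
    receiver target expression, one score per ligand."""
    cfg = cfg or CrosstalkConfig()
    if pairs.n_pairs < cfg.min_pairs:
        raise ValidationError(f"{pairs.n_pairs} pair(s) < min_pairs = {cfg.min_pairs}")
    sender_genes = set(pairs.sender.index)
    receiver_genes = set(pairs.receiver.index)

    results = []
    for ligand in prior.ligands:
        if ligand not in sender_genes:
            continue
        x = pairs.sender.loc[ligand].to_numpy(dtype=float)
        targets = prior.targets_of(ligand)
        if np.ptp(x) == 0:
            results.append(
                LigandActivity(
                    ligand=ligand,
                    sender_compartment=pairs.sender_compartment,
                    receiver_compartment=pairs.receiver_compartment,
                    target_r={},
                    n_targets_used=0,
                    n_targets_skipped=0,
                    activity=None,
                    n_pairs=pairs.n_pairs,
                    active=False,
                    evaluable=False,
                )
            )
            continue
        target_r: dict = {}
        skipped = 0
        for t in targets["target"]:
            if t not in receiver_genes:
                continue
            y = pairs.receiver.loc[t].to_numpy(dtype=float)
            r = pearson(x, y)
            if np.isnan(r):
                skipped += 1
                continue
            target_r[t] = r
        if not target_r:
            activity = None
            active = False
            evaluable = False
        else:
            activity = float(np.mean(list(target_r.values())))
            active = activity >= cfg.activity_threshold
            evaluable = True
        results.append(
            LigandActivity(
                ligand=ligand,
                sender_compartment=pairs.sender_compartment,
                receiver_compartment=pairs.receiver_compartment,
                target_r=target_r,
                n_targets_used=len(target_r),
                n_targets_skipped=skipped,
                activity=activity,
                n_pairs=pairs.n_pairs,
                active=active,
                evaluable=evaluable,
            )
        )
    return results


def activity_table(results: list[LigandActivity]) -> pd.DataFrame:
    rows = [
        {
            "ligand": r.ligand,
            "sender": r.sender_compartment,
            "receiver": r.receiver_compartment,
            "activity": r.activity,
            "n_targets_used": r.n_targets_used,
            "n_targets_skipped": r.n_targets_skipped,
            "n_pairs": r.n_pairs,
            "active": r.active,
            "evaluable": r.evaluable,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("activity", ascending=False, na_position="last").reset_index(drop=True)
    return df


def target_edge_table(results: list[LigandActivity]) -> pd.DataFrame:
    """Ligand-target correlation edge list (for circos-style plotting)."""
    rows = []
    for r in results:
        for t, rr in sorted(r.target_r.items()):
            rows.append(
                {
                    "ligand": r.ligand,
                    "target": t,
                    "r": rr,
                    "sender": r.sender_compartment,
                    "receiver": r.receiver_compartment,
                }
            )
    return pd.DataFrame(rows, columns=["ligand", "target", "r", "sender", "receiver"])


def permutation_null(
    pairs: RoiPairing,
    prior: LigandTargetPrior,
    cfg: CrosstalkConfig | None = None,
    n_reps: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Calibration utility (off by default in the pipeline): per replicate,
    shuffle receiver profiles across pairs and recompute activity; returns the
    fraction of evaluable ligands called active in each replicate."""
    cfg = cfg or CrosstalkConfig()
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_reps)
    for i in range(n_reps):
        perm = rng.permutation(pairs.n_pairs)
        shuffled = RoiPairing(
            sender_compartment=pairs.sender_compartment,
            receiver_compartment=pairs.receiver_compartment,
            core_ids=pairs.core_ids,
            sender=pairs.sender,
            receiver=pairs.receiver.iloc[:, perm].set_axis(pairs.core_ids, axis=1),
            skipped_cores=pairs.skipped_cores,
        )
        results = ligand_activity(shuffled, prior, cfg)
        evaluable = [r for r in results if r.evaluable]
        fractions[i] = (
            sum(r.active for r in evaluable) / len(evaluable) if evaluable else 0.0
        )
    return fractions


def correlate_ligands_with_cells(
    expr: ExpressionMatrix,
    proportions: CellProportions,
    ligands,
    r_threshold: float = 0.2,
) -> pd.DataFrame:
    """Pearson r between ligand expression and cell-type proportion across
    shared ROIs; edges emitted for r strictly above the threshold."""
    if expr.scale != "log2":
        raise ValidationError("correlate_ligands_with_cells expects log2-scale expression")
    shared = [r for r in expr.roi_ids if r in set(proportions.roi_ids)]
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared ROI(s); need at least 3")
    rows = []
    gene_set = set(expr.gene_ids)
    for ligand in sorted(set(ligands)):
        if ligand not in gene_set:
            continue
        x = expr.data.loc[ligand, shared].to_numpy(dtype=float)
        for ct in proportions.cell_types:
            y = proportions.data.loc[shared, ct].to_numpy(dtype=float)
            r = pearson(x, y)
            if not np.isnan(r) and r > r_threshold:
                rows.append({"cell_type": ct, "ligand": ligand, "r": r})
    return pd.DataFrame(rows, columns=["cell_type", "ligand", "r"])
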