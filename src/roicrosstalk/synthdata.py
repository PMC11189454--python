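"""Synthetic compartment-labelled ROI datasets with full ground truth.

The generator emits every input the pipeline consumes — counts, annotations,
cell profiles, ligand-target prior, signalling network, subtype centroids —
plus a GroundTruth record of everything that was planted: per-ROI cell
proportions, active/null ligands with their couplings, differential genes,
subtype labels and designated QC failures.

Construction, in order: (i) log-normal cell profiles; (ii) per-ROI expected
expression as profiles x compartment-specific Dirichlet proportions;
(iii) multiplicative (log-linear) ligand coupling — receiver-side target
means scaled by 2^(coupling * eta_core) where eta_core also drives the
sender-side ligand level, so the realized Pearson r on log2 data tracks the
configured coupling; (iv) negative-binomial counts under log-normal library
sizes; (v) QC metadata drawn passing, then dedicated extra ROIs corrupted to
fail exactly one named rule each; (vi) mean-zero signature centroids whose
planted tumour ROIs correlate at a configurable level. All randomness flows
from the single seed through one numpy Generator (PCG64), so identical
configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    CellProfileMatrix,
    CentroidMatrix,
    CountMatrix,
    LigandTargetPrior,
    RoiAnnotation,
    SignallingNetwork,
    ValidationError,
)

CELL_TYPE_NAMES = (
    "malignant",
    "urothelial",
    "myocaf",
    "matrixcaf",
    "bcell",
    "tcell",
    "macrophage",
    "endothelial",
)

QC_FAIL_RULES = (
    "min_raw_reads",
    "min_saturation",
    "min_pct_aligned",
    "min_pct_trimmed",
    "min_pct_stitched",
    "min_genes_detected_frac",
)


@dataclass
class PlantedLigand:
    sender: str  # compartment
    receiver: str  # compartment
    coupling: float  # log2-linear coupling of target means to the sender signal
    n_targets: int = 8
    ligand: str | None = None  # autonamed when None
    targets: list = field(default_factory=list)


@dataclass
class SimConfig:
    seed: int
    n_cores: int = 15
    compartment_presence: dict = field(
        default_factory=lambda: {"tumour": 1.0, "stroma": 0.9, "immune": 0.5}
    )
    n_genes: int = 300
    n_cell_types: int = 6
    library_log_mean: float = math.log(5e4)
    library_log_sd: float = 0.25
    nb_dispersion: float = 0.1  # var = mu + dispersion * mu^2; 0 means Poisson
    profile_log_sd: float = 1.0
    ligand_amp: float = 1.0  # sender-side log2 sd of the per-core ligand signal
    active_ligands: list = field(default_factory=list)  # list[PlantedLigand]
    n_null_ligands: int = 0
    null_targets_per_ligand: int = 8
    qc_failures: dict = field(default_factory=dict)  # rule name -> count of extra bad ROIs
    n_de_genes: int = 10  # tumour-vs-stroma planted genes
    de_log2fc: float = 2.0
    n_subtypes: int = 3
    subtype_amp: float = 1.0
    n_signature_genes: int = 60
    donors_per_core: int = 1  # cores per donor actually: ceil grouping of 2 when 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for c, p in self.compartment_presence.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"presence probability for {c!r} outside [0, 1]")
        if self.n_cell_types < 2 or self.n_cell_types > len(CELL_TYPE_NAMES):
            raise ValidationError(f"n_cell_types must be in [2, {len(CELL_TYPE_NAMES)}]")
        bad = set(self.qc_failures) - set(QC_FAIL_RULES)
        if bad:
            raise ValidationError(f"unknown QC failure rule(s): {sorted(bad)}")


@dataclass
class GroundTruth:
    proportions: pd.DataFrame  # ROI x cell type Dirichlet truths
    active_ligands: list  # PlantedLigand records with resolved names/targets
    null_ligands: dict  # ligand -> list of (uncoupled) prior targets
    de_genes: list  # genes shifted in tumour vs stroma
    subtype_labels: dict  # tumour roi_id -> planted subtype
    qc_failures: dict  # roi_id -> rule it was built to fail
    mean_expression: pd.DataFrame  # expected relative expression, gene x ROI
    core_signals: dict  # ligand -> per-core eta (the latent coupling driver)


# compartment -> dominant cell-type indices (echoes typical compositions:
# tumour malignant/urothelial, stroma CAF-dominated, immune B-cell/macrophage)
_DOMINANT = {"tumour": (0, 1), "stroma": (2, 3), "immune": (4, 6)}


def _dirichlet_alpha(compartment: str, n_types: int) -> np.ndarray:
    alpha = np.full(n_types, 0.3)
    for idx in _DOMINANT[compartment]:
        if idx < n_types:
            alpha[idx] = 8.0
    return alpha


def generate_dataset(cfg: SimConfig):
    """Build the full synthetic bundle; returns (counts, annot, profiles,
    prior, network, centroids, truth)."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    cell_types = list(CELL_TYPE_NAMES[: cfg.n_cell_types])

    # (i) cell profiles, log-normal linear-scale means
    profile_vals = np.exp(rng.normal(0.0, cfg.profile_log_sd, size=(cfg.n_genes, cfg.n_cell_types)))
    profiles = CellProfileMatrix(pd.DataFrame(profile_vals, index=genes, columns=cell_types))

    # ROI layout: one ROI per present compartment per core
    roi_rows = []
    for c in range(cfg.n_cores):
        core = f"core{c:03d}"
        donor = f"donor{c // 2:03d}"
        for comp in ("tumour", "stroma", "immune"):
            p = cfg.compartment_presence.get(comp, 0.0)
            if rng.random() < p:
                roi_rows.append({"roi_id": f"{core}_{comp}", "core_id": core,
                                 "donor_id": donor, "compartment": comp})
    if not roi_rows:
        raise ValidationError("no ROIs generated; raise presence probabilities")

    # (ii) per-ROI Dirichlet proportions and expected expression
    prop_rows = {}
    mean_cols = {}
    for row in roi_rows:
        alpha = _dirichlet_alpha(row["compartment"], cfg.n_cell_types)
        props = rng.dirichlet(alpha)
        prop_rows[row["roi_id"]] = props
        mean_cols[row["roi_id"]] = profile_vals @ props
    mean_expr = pd.DataFrame(mean_cols, index=genes)

    # reserve non-overlapping gene blocks for the plants
    cursor = 0

    def take(n):
        nonlocal cursor
        if cursor + n > cfg.n_genes:
            raise ValidationError("n_genes too small for the requested plants")
        block = genes[cursor : cursor + n]
        cursor += n
        return block

    # (iii) planted ligand couplings
    active = []
    core_signals: dict = {}
    cores = sorted({r["core_id"] for r in roi_rows})
    comp_of = {r["roi_id"]: r["compartment"] for r in roi_rows}
    core_of = {r["roi_id"]: r["core_id"] for r in roi_rows}
    prior_rows = []

    for i, spec_l in enumerate(cfg.active_ligands):
        ligand = spec_l.ligand or take(1)[0]
        targets = list(spec_l.targets) or take(spec_l.n_targets)
        eta = rng.normal(0.0, 1.0, size=len(cores))
        eta_by_core = dict(zip(cores, eta))
        core_signals[ligand] = eta_by_core
        for rid in mean_expr.columns:
            e = eta_by_core[core_of[rid]]
            if comp_of[rid] == spec_l.sender:
                mean_expr.loc[ligand, rid] *= 2.0 ** (cfg.ligand_amp * e)
            if comp_of[rid] == spec_l.receiver:
                mean_expr.loc[targets, rid] *= 2.0 ** (spec_l.coupling * e)
        for t in targets:
            prior_rows.append({"ligand": ligand, "target": t,
                               "weight": float(rng.uniform(0.5, 1.0))})
        active.append(
            PlantedLigand(sender=spec_l.sender, receiver=spec_l.receiver,
                          coupling=spec_l.coupling, n_targets=len(targets),
                          ligand=ligand, targets=targets)
        )

    # null ligands: own per-core signal (so they are evaluable) but targets
    # drawn from unrelated genes, hence zero population coupling
    null_ligands: dict = {}
    for i in range(cfg.n_null_ligands):
        ligand = take(1)[0]
        eta = rng.normal(0.0, 1.0, size=len(cores))
        eta_by_core = dict(zip(cores, eta))
        core_signals[ligand] = eta_by_core
        for rid in mean_expr.columns:
            mean_expr.loc[ligand, rid] *= 2.0 ** (
                cfg.ligand_amp * eta_by_core[core_of[rid]]
            )
        targets = list(rng.choice(genes[cursor:], size=cfg.null_targets_per_ligand,
                                  replace=False))
        for t in sorted(targets):
            prior_rows.append({"ligand": ligand, "target": t,
                               "weight": float(rng.uniform(0.0, 1.0))})
        null_ligands[ligand] = sorted(targets)

    # planted tumour-vs-stroma differential genes
    de_genes = take(cfg.n_de_genes) if cfg.n_de_genes else []
    for rid in mean_expr.columns:
        if comp_of[rid] == "tumour" and de_genes:
            mean_expr.loc[de_genes, rid] *= 2.0**cfg.de_log2fc

    # (vi) subtype signatures on a dedicated gene block
    subtype_names = [f"ST{i + 1}" for i in range(cfg.n_subtypes)]
    sig_genes = take(cfg.n_signature_genes)
    signatures = rng.normal(0.0, 1.0, size=(len(sig_genes), cfg.n_subtypes))
    centroids = CentroidMatrix(
        pd.DataFrame(cfg.subtype_amp * signatures, index=sig_genes, columns=subtype_names)
    )
    subtype_labels: dict = {}
    tumour_rois = [r["roi_id"] for r in roi_rows if r["compartment"] == "tumour"]
    for rid in tumour_rois:
        s = int(rng.integers(cfg.n_subtypes))
        subtype_labels[rid] = subtype_names[s]
        mean_expr.loc[sig_genes, rid] *= 2.0 ** (cfg.subtype_amp * signatures[:, s])

    # normalize each ROI's expected expression to relative abundance
    mean_expr = mean_expr / mean_expr.sum(axis=0)

    # (v) extra ROIs designed to fail exactly one QC rule each
    qc_fail_assign: dict = {}
    fail_rows = []
    n_fail = sum(cfg.qc_failures.values())
    for rule, count in sorted(cfg.qc_failures.items()):
        for k in range(count):
            rid = f"fail_{rule}_{k}"
            core = f"failcore_{rule}_{k}"
            fail_rows.append({"roi_id": rid, "core_id": core,
                              "donor_id": core, "compartment": "tumour"})
            qc_fail_assign[rid] = rule
            alpha = _dirichlet_alpha("tumour", cfg.n_cell_types)
            props = rng.dirichlet(alpha)
            prop_rows[rid] = props
            mu = profile_vals @ props
            mean_expr[rid] = mu / mu.sum()
    roi_rows = roi_rows + fail_rows
    roi_ids = [r["roi_id"] for r in roi_rows]
    mean_expr = mean_expr[roi_ids]

    # (iv) negative-binomial counts under log-normal library sizes
    libs = np.exp(rng.normal(cfg.library_log_mean, cfg.library_log_sd, size=len(roi_ids)))
    counts = np.zeros((cfg.n_genes, len(roi_ids)), dtype=np.int64)
    for j, rid in enumerate(roi_ids):
        mu = libs[j] * mean_expr[rid].to_numpy()
        if cfg.nb_dispersion > 0:
            theta = 1.0 / cfg.nb_dispersion
            counts[:, j] = rng.negative_binomial(theta, theta / (theta + mu))
        else:
            counts[:, j] = rng.poisson(mu)

    # QC metadata: passing draws, then corrupt the designated ROIs
    annot_rows = []
    for j, row in enumerate(roi_rows):
        rid = row["roi_id"]
        rec = dict(row)
        rec["raw_reads"] = int(libs[j])
        rec["saturation"] = float(rng.uniform(60, 95))
        rec["pct_aligned"] = float(rng.uniform(85, 99))
        rec["pct_trimmed"] = float(rng.uniform(85, 99))
        rec["pct_stitched"] = float(rng.uniform(85, 99))
        rule = qc_fail_assign.get(rid)
        if rule == "min_raw_reads":
            rec["raw_reads"] = 500
        elif rule == "min_saturation":
            rec["saturation"] = 40.0
        elif rule == "min_pct_aligned":
            rec["pct_aligned"] = 70.0
        elif rule == "min_pct_trimmed":
            rec["pct_trimmed"] = 70.0
        elif rule == "min_pct_stitched":
            rec["pct_stitched"] = 70.0
        elif rule == "min_genes_detected_frac":
            # silence all but ~5% of genes so detection falls below 10%
            keep = rng.choice(cfg.n_genes, size=max(1, cfg.n_genes // 20), replace=False)
            mask = np.ones(cfg.n_genes, dtype=bool)
            mask[keep] = False
            counts[mask, j] = 0
        annot_rows.append(rec)

    count_matrix = CountMatrix(pd.DataFrame(counts, index=genes, columns=roi_ids))
    annot = RoiAnnotation(pd.DataFrame(annot_rows))
    prior = LigandTargetPrior(pd.DataFrame(prior_rows, columns=["ligand", "target", "weight"]))
    network = _build_network(active, rng)
    truth = GroundTruth(
        proportions=pd.DataFrame.from_dict(prop_rows, orient="index", columns=cell_types),
        active_ligands=active,
        null_ligands=null_ligands,
        de_genes=de_genes,
        subtype_labels=subtype_labels,
        qc_failures=qc_fail_assign,
        mean_expression=mean_expr,
        core_signals=core_signals,
    )
    return count_matrix, annot, profiles, prior, network, centroids, truth


def _build_network(active: list, rng) -> SignallingNetwork:
    """Layered ligand->receptor->kinase->target chains for each planted ligand,
    plus a few decoy edges."""
    rows = []
    for i, pl in enumerate(active):
        rec = f"REC{i:02d}"
        kin = f"KIN{i:02d}"
        rows.append({"source": pl.ligand, "target": rec,
                     "weight": float(rng.uniform(0.6, 1.0)), "layer": "ligand_receptor"})
        rows.append({"source": rec, "target": kin,
                     "weight": float(rng.uniform(0.6, 1.0)), "layer": "signalling"})
        for t in pl.targets[:3]:
            rows.append({"source": kin, "target": t,
                         "weight": float(rng.uniform(0.4, 1.0)), "layer": "gene_regulatory"})
        # weaker decoy shortcut
        if pl.targets:
            rows.append({"source": rec, "target": pl.targets[0],
                         "weight": float(rng.uniform(0.05, 0.2)), "layer": "signalling"})
    if not rows:
        rows = [
            {"source": "L0", "target": "R0", "weight": 0.9, "layer": "ligand_receptor"},
            {"source": "R0", "target": "T0", "weight": 0.8, "layer": "signalling"},
        ]
    df = pd.DataFrame(rows).drop_duplicates(subset=["source", "target", "layer"])
    return SignallingNetwork(df.reset_index(drop=True))


def default_config(seed: int, **overrides) -> SimConfig:
    """A moderately sized scenario exercising every pipeline stage."""
    params = dict(
        seed=seed,
        n_cores=15,
        n_genes=300,
        n_cell_types=6,
        active_ligands=[
            PlantedLigand(sender="stroma", receiver="tumour", coupling=0.8, n_targets=6),
            PlantedLigand(sender="stroma", receiver="stroma", coupling=0.8, n_targets=6),
        ],
        n_null_ligands=5,
        qc_failures={"min_raw_reads": 1, "min_saturation": 1, "min_genes_detected_frac": 1},
    )
    params.update(overrides)
    return SimConfig(**params)


def small_fixture(seed: int = 20240101):
    """Deterministic miniature dataset (<= 50 genes, <= 12 ROIs incl. planted
    failures) used by doc examples and fast tests: 3 ROIs each failing one QC
    rule and a single strongly coupled stroma->tumour ligand."""
    cfg = SimConfig(
        seed=seed,
        n_cores=4,
        compartment_presence={"tumour": 1.0, "stroma": 1.0, "immune": 0.0},
        n_genes=50,
        n_cell_types=3,
        library_log_mean=math.log(2e4),
        nb_dispersion=0.05,
        active_ligands=[PlantedLigand(sender="stroma", receiver="tumour",
                                      coupling=1.2, n_targets=4)],
        n_null_ligands=1,
        null_targets_per_ligand=4,
        qc_failures={"min_raw_reads": 1, "min_saturation": 1,
                     "min_genes_detected_frac": 1},
        n_de_genes=4,
        n_subtypes=2,
        n_signature_genes=20,
    )
    return generate_dataset(cfg)
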