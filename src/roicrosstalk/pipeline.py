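"""End-to-end orchestration: qc -> normalize -> log2 -> DE -> deconvolution ->
ligand activity per compartment pair -> origin correlation -> subtyping ->
path inference, with a JSON run manifest accounting for every stage."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import core_model as cm
from . import crosstalk, deconv, diffexp, netpath, qc_norm, subtype

log = logging.getLogger("roicrosstalk")

DEFAULT_PAIRS = (
    ("stroma", "tumour"),
    ("stroma", "stroma"),
    ("tumour", "stroma"),
    ("tumour", "tumour"),
    ("immune", "tumour"),
)


@dataclass
class RunConfig:
    counts_path: str
    annot_path: str
    prior_path: str
    out_dir: str
    profiles_path: str | None = None
    network_path: str | None = None
    centroids_path: str | None = None
    qc: qc_norm.QcThresholds = field(default_factory=qc_norm.QcThresholds)
    crosstalk: crosstalk.CrosstalkConfig = field(default_factory=crosstalk.CrosstalkConfig)
    compartment_pairs: tuple = DEFAULT_PAIRS
    de_contrasts: tuple = (("tumour", "stroma"),)
    subtype_min_corr: float = 0.2
    path_max_len: int = 6
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        qc = qc_norm.QcThresholds(**raw.pop("qc", {}))
        ct = crosstalk.CrosstalkConfig(**raw.pop("crosstalk", {}))
        pairs = tuple(tuple(p) for p in raw.pop("compartment_pairs", DEFAULT_PAIRS))
        contrasts = tuple(tuple(c) for c in raw.pop("de_contrasts", (("tumour", "stroma"),)))
        return cls(qc=qc, crosstalk=ct, compartment_pairs=pairs, de_contrasts=contrasts, **raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(cfg: RunConfig) -> dict:
    """Execute every configured stage, writing TSVs under ``out_dir`` and
    returning (and writing) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": {"seed": cfg.seed}, "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                manifest["stages"][name] = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                (out / "FAILED").write_text(f"{name}: {exc}\n")
                raise StageError(name, exc) from exc

        return deco

    counts = cm.read_count_matrix(cfg.counts_path)
    annot = cm.read_annotation(cfg.annot_path)
    prior = cm.read_prior(cfg.prior_path)

    state: dict = {}

    @stage("qc_rois")
    def _():
        kept, report = qc_norm.filter_rois(counts, annot, cfg.qc)
        state["counts"] = kept
        state["annot"] = annot.subset(kept.roi_ids)
        report.roi_table().to_csv(out / "qc_rois.tsv", sep="\t", index=False)
        for rid in report.removed_roi_ids:
            log.info("ROI excluded: %s (%s)", rid, ";".join(report.failed_rules[rid]))
        return {"rois_kept": len(report.kept_roi_ids), "rois_removed": report.n_removed_rois}

    @stage("qc_genes")
    def _():
        kept, report = qc_norm.filter_genes(
            state["counts"], cfg.qc.gene_detection_frac, cfg.qc.detection_min_count
        )
        state["counts"] = kept
        cm.write_count_matrix(kept, out / "counts_filtered.tsv")
        for g in report.removed_gene_ids:
            log.info("gene excluded: %s", g)
        return {"genes_kept": len(report.kept_gene_ids), "genes_removed": report.n_removed_genes}

    @stage("normalize")
    def _():
        norm = qc_norm.q3_normalize(state["counts"])
        state["norm"] = norm
        state["log2"] = qc_norm.log2_transform(norm)
        cm.write_expression_matrix(norm, out / "normalized.tsv")
        cm.write_expression_matrix(state["log2"], out / "log2.tsv")
        return {"genes": len(norm.gene_ids), "rois": len(norm.roi_ids)}

    @stage("diffexp")
    def _():
        info = {}
        for a, b in cfg.de_contrasts:
            ga = state["annot"].rois_in(a)
            gb = state["annot"].rois_in(b)
            if len(ga) < 2 or len(gb) < 2:
                log.info("contrast %s vs %s skipped (too few ROIs)", a, b)
                info[f"{a}_vs_{b}"] = None
                continue
            res = diffexp.moderated_t(state["log2"], ga, gb)
            res.table.to_csv(out / f"de_{a}_vs_{b}.tsv", sep="\t")
            info[f"{a}_vs_{b}"] = {
                "n_genes": len(res.table),
                "n_significant": int((res.table["adj_pvalue"] < 0.05).sum()),
            }
        return info

    if cfg.profiles_path:

        @stage("deconv")
        def _():
            profiles = cm.read_profiles(cfg.profiles_path)
            props = deconv.estimate_proportions(state["norm"], profiles)
            state["proportions"] = props
            tbl = props.data.copy()
            tbl.index.name = "roi_id"
            tbl.to_csv(out / "proportions.tsv", sep="\t")
            return {"rois": len(props.roi_ids), "cell_types": len(props.cell_types)}

    @stage("activity")
    def _():
        info = {}
        active_ligands: set = set()
        restricted = crosstalk.restrict_prior(
            prior, set(state["log2"].gene_ids), cfg.crosstalk
        )
        for sender, receiver in cfg.compartment_pairs:
            key = f"{sender}->{receiver}"
            try:
                pairs = crosstalk.build_pairs(
                    state["annot"], state["log2"], sender, receiver, cfg.crosstalk.min_pairs
                )
            except cm.ValidationError as exc:
                log.info("pairing %s skipped: %s", key, exc)
                info[key] = None
                continue
            for core in pairs.skipped_cores:
                log.info("core skipped for %s: %s", key, core)
            results = crosstalk.ligand_activity(pairs, restricted, cfg.crosstalk)
            tag = f"{sender}_to_{receiver}"
            crosstalk.activity_table(results).to_csv(
                out / f"activity_{tag}.tsv", sep="\t", index=False
            )
            crosstalk.target_edge_table(results).to_csv(
                out / f"activity_edges_{tag}.tsv", sep="\t", index=False
            )
            for r in results:
                if not r.evaluable:
                    log.info("ligand not evaluable for %s: %s", key, r.ligand)
                elif r.active:
                    active_ligands.add(r.ligand)
            info[key] = {
                "n_pairs": pairs.n_pairs,
                "n_ligands": len(results),
                "n_active": sum(r.active for r in results),
            }
        state["active_ligands"] = sorted(active_ligands)
        return info

    if cfg.profiles_path:

        @stage("origin_correlation")
        def _():
            edges = crosstalk.correlate_ligands_with_cells(
                state["log2"], state["proportions"], state["active_ligands"]
            )
            edges.to_csv(out / "ligand_cell_edges.tsv", sep="\t", index=False)
            return {"n_edges": len(edges)}

    if cfg.centroids_path:

        @stage("subtype")
        def _():
            centroids = cm.read_centroids(cfg.centroids_path)
            calls = subtype.classify(state["log2"], centroids, cfg.subtype_min_corr)
            subtype.calls_table(calls).to_csv(out / "subtype_calls.tsv", sep="\t", index=False)
            from collections import Counter

            return dict(Counter(c.label for c in calls))

    if cfg.network_path:

        @stage("netpath")
        def _():
            network = cm.read_network(cfg.network_path)
            lig_with_lr = set(
                network.data.loc[network.data["layer"] == "ligand_receptor", "source"]
            )
            rows = []
            for ligand in state.get("active_ligands", []):
                if ligand not in lig_with_lr:
                    continue
                for target in sorted(network.nodes):
                    if target == ligand:
                        continue
                    res = netpath.infer_path(network, ligand, target, cfg.path_max_len)
                    if isinstance(res, netpath.SignallingPath):
                        rows.append(
                            {
                                "ligand": ligand,
                                "target": target,
                                "path": "->".join(res.nodes),
                                "score": res.score,
                            }
                        )
            pd.DataFrame(rows, columns=["ligand", "target", "path", "score"]).to_csv(
                out / "paths.tsv", sep="\t", index=False
            )
            return {"n_paths": len(rows)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
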