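"""Domain types, validation and TSV/MTX readers/writers.

All tabular artifacts are tab-separated UTF-8 with a mandatory header row;
the first column carries gene/ROI identifiers. Gene identifiers are
case-sensitive symbols and joins across tables are exact-string by
identifier, never positional.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

COMPARTMENTS = ("tumour", "stroma", "immune")
NETWORK_LAYERS = ("ligand_receptor", "signalling", "gene_regulatory")

ANNOTATION_COLUMNS = (
    "roi_id",
    "core_id",
    "donor_id",
    "compartment",
    "raw_reads",
    "saturation",
    "pct_aligned",
    "pct_trimmed",
    "pct_stitched",
)

PERCENT_COLUMNS = ("saturation", "pct_aligned", "pct_trimmed", "pct_stitched")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _find_duplicates(values) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for v in values:
        if v in seen and v not in dups:
            dups.append(v)
        seen.add(v)
    return dups


def _check_unique(values, what: str) -> None:
    dups = _find_duplicates(values)
    if dups:
        raise ValidationError(f"duplicate {what} identifier(s): {', '.join(map(str, dups))}")


@dataclass
class CountMatrix:
    """Gene x ROI matrix of non-negative integer counts."""

    data: pd.DataFrame  # index = gene symbols, columns = ROI ids

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "ROI")
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("count matrix contains non-numeric entries")
        bad = np.argwhere(arr != np.floor(arr))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"non-integer count at gene {self.data.index[i]!r}, ROI {self.data.columns[j]!r}"
            )
        neg = np.argwhere(arr < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative count at gene {self.data.index[i]!r}, ROI {self.data.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def roi_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(self, genes=None, rois=None) -> "CountMatrix":
        df = self.data
        if genes is not None:
            df = df.loc[list(genes)]
        if rois is not None:
            df = df[list(rois)]
        return CountMatrix(df.copy())


@dataclass
class ExpressionMatrix:
    """Gene x ROI matrix on a declared scale: 'normalized' (linear, >=0) or 'log2'."""

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in ("normalized", "log2"):
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "ROI")
        arr = self.data.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression matrix contains non-finite values")
        if self.scale == "normalized" and np.any(arr < 0):
            raise ValidationError("normalized expression must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def roi_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class RoiAnnotation:
    """Per-ROI metadata: compartment, core/donor membership and sequencing QC metrics."""

    data: pd.DataFrame  # one row per ROI, columns ANNOTATION_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"annotation missing column(s): {', '.join(missing)}")
        _check_unique(self.data["roi_id"], "ROI")
        bad = set(self.data["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValidationError(
                f"compartment value(s) {sorted(bad)} outside the closed set {COMPARTMENTS}"
            )
        for col in PERCENT_COLUMNS:
            vals = self.data[col].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 100)):
                raise ValidationError(f"{col} outside [0, 100]")
        if np.any(self.data["raw_reads"].to_numpy(dtype=float) < 0):
            raise ValidationError("raw_reads must be non-negative")
        self.data = self.data.set_index("roi_id", drop=False)

    @property
    def roi_ids(self) -> list[str]:
        return list(self.data["roi_id"])

    def compartment_of(self, roi_id: str) -> str:
        return self.data.at[roi_id, "compartment"]

    def rois_in(self, compartment: str) -> list[str]:
        if compartment not in COMPARTMENTS:
            raise ValidationError(f"unknown compartment {compartment!r}")
        sel = self.data["compartment"] == compartment
        return list(self.data.loc[sel, "roi_id"])

    def subset(self, roi_ids) -> "RoiAnnotation":
        df = self.data.loc[list(roi_ids)].reset_index(drop=True)
        return RoiAnnotation(df)


def check_roi_agreement(counts_rois, annot_rois) -> None:
    """Reject matrix/annotation pairs whose ROI sets differ, reporting the difference."""
    a, b = set(counts_rois), set(annot_rois)
    if a != b:
        only_counts = sorted(a - b)
        only_annot = sorted(b - a)
        raise ValidationError(
            "ROI sets differ between count matrix and annotation; "
            f"only in matrix: {only_counts}; only in annotation: {only_annot}"
        )


@dataclass
class LigandTargetPrior:
    """Weighted ligand->target records (regulatory potential)."""

    data: pd.DataFrame  # columns: ligand, target, weight

    def __post_init__(self) -> None:
        missing = [c for c in ("ligand", "target", "weight") if c not in self.data.columns]
        if missing:
            raise ValidationError(f"prior missing column(s): {', '.join(missing)}")
        pairs = list(zip(self.data["ligand"], self.data["target"]))
        dups = _find_duplicates(pairs)
        if dups:
            raise ValidationError(f"duplicate (ligand, target) pair(s): {dups[:5]}")
        if np.any(self.data["weight"].to_numpy(dtype=float) < 0):
            raise ValidationError("prior weights must be non-negative")

    @property
    def ligands(self) -> list[str]:
        return sorted(self.data["ligand"].unique())

    def targets_of(self, ligand: str) -> pd.DataFrame:
        return self.data[self.data["ligand"] == ligand]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class SignallingNetwork:
    """Directed, layered, weighted gene network; weights in (0, 1]."""

    data: pd.DataFrame  # columns: source, target, weight, layer

    def __post_init__(self) -> None:
        missing = [c for c in ("source", "target", "weight", "layer") if c not in self.data.columns]
        if missing:
            raise ValidationError(f"network missing column(s): {', '.join(missing)}")
        w = self.data["weight"].to_numpy(dtype=float)
        if np.any((w <= 0) | (w > 1)):
            raise ValidationError("network weights must lie in (0, 1]")
        bad_layers = set(self.data["layer"]) - set(NETWORK_LAYERS)
        if bad_layers:
            raise ValidationError(f"unknown network layer(s): {sorted(bad_layers)}")
        loops = self.data[self.data["source"] == self.data["target"]]
        if len(loops):
            raise ValidationError(f"self-loop(s) on: {sorted(loops['source'].unique())[:5]}")

    @property
    def nodes(self) -> set[str]:
        return set(self.data["source"]) | set(self.data["target"])


@dataclass
class CellProfileMatrix:
    """Gene x cell-type matrix of mean linear-scale expression."""

    data: pd.DataFrame  # index = genes, columns = cell types

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "cell type")
        if self.data.shape[1] < 2:
            raise ValidationError("cell profile matrix needs at least 2 cell types")
        if np.any(self.data.to_numpy() < 0):
            raise ValidationError("cell profiles must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class CentroidMatrix:
    """Gene x subtype centroid expression used by the nearest-centroid classifier."""

    data: pd.DataFrame  # index = genes, columns = subtype labels

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "subtype")
        if self.data.shape[1] < 2:
            raise ValidationError("centroid matrix needs at least 2 subtypes")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def labels(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={0: str})


def read_count_matrix(path, format: str = "tsv") -> CountMatrix:
    """Read a gene x ROI count matrix from TSV or MatrixMarket.

    For ``format='mtx'`` the matrix file must sit next to ``<stem>.rows.txt``
    and ``<stem>.cols.txt`` holding gene and ROI identifiers, one per line.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return CountMatrix(df)
    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        stem = path.with_suffix("")
        genes = Path(f"{stem}.rows.txt").read_text().split()
        rois = Path(f"{stem}.cols.txt").read_text().split()
        if mat.shape != (len(genes), len(rois)):
            raise ValidationError(
                f"MTX shape {mat.shape} does not match {len(genes)} row / {len(rois)} col names"
            )
        return CountMatrix(pd.DataFrame(np.asarray(mat), index=genes, columns=rois))
    raise ValidationError(f"unknown count-matrix format {format!r}")


def write_count_matrix(cm: CountMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = cm.data.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts))
        stem = path.with_suffix("")
        Path(f"{stem}.rows.txt").write_text("\n".join(cm.gene_ids) + "\n")
        Path(f"{stem}.cols.txt").write_text("\n".join(cm.roi_ids) + "\n")
    else:
        raise ValidationError(f"unknown count-matrix format {format!r}")


def read_expression_matrix(path, scale: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, scale)


def write_expression_matrix(em: ExpressionMatrix, path) -> None:
    out = em.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_annotation(path) -> RoiAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"roi_id": str, "core_id": str, "donor_id": str})
    return RoiAnnotation(df)


def write_annotation(annot: RoiAnnotation, path) -> None:
    annot.data.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def read_prior(path) -> LigandTargetPrior:
    return LigandTargetPrior(pd.read_csv(path, sep="\t", dtype={"ligand": str, "target": str}))


def write_prior(prior: LigandTargetPrior, path) -> None:
    prior.data.to_csv(path, sep="\t", index=False)


def read_network(path) -> SignallingNetwork:
    return SignallingNetwork(pd.read_csv(path, sep="\t", dtype={"source": str, "target": str}))


def write_network(net: SignallingNetwork, path) -> None:
    net.data.to_csv(path, sep="\t", index=False)


def read_profiles(path) -> CellProfileMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CellProfileMatrix(df)


def write_profiles(profiles: CellProfileMatrix, path) -> None:
    out = profiles.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_centroids(path) -> CentroidMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CentroidMatrix(df)


def write_centroids(centroids: CentroidMatrix, path) -> None:
    out = centroids.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
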