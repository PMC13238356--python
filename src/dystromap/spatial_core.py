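"""Core spatial containers, 10x-style I/O, QC and lattice geometry.

Visium places capture spots on a hexagonal lattice: ``array_col`` advances in
half-steps of the 100 um center-to-center pitch (so only every second column
exists within a row) and ``array_row`` advances by ``100 * sqrt(3)/2`` um.
Under that embedding every spot has up to six equidistant neighbours at
exactly 100 um. All geometry in this package derives from that convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

#: um travelled per unit of array_col (half the 100 um pitch).
UM_PER_COL = 50.0
#: um travelled per unit of array_row (row pitch of the hex lattice).
UM_PER_ROW = 100.0 * math.sqrt(3.0) / 2.0

#: Offsets to the six hex neighbours in (array_row, array_col) units.
HEX_OFFSETS = ((0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1))

MITO_RIBO_PREFIXES = ("MT-", "MRPS", "MRPL", "RPS", "RPL")


class FormatError(ValueError):
    """Malformed input file or table."""


class EmptyTissueError(ValueError):
    """QC removed every spot (or every gene)."""


@dataclass
class SpotGrid:
    """Spot positions on the Visium hex lattice.

    Out-of-tissue spots are retained but flagged via ``in_tissue``.
    """

    barcodes: np.ndarray          # str array
    in_tissue: np.ndarray         # bool
    array_row: np.ndarray         # int
    array_col: np.ndarray         # int
    pxl_x: np.ndarray             # float, full-res pixels
    pxl_y: np.ndarray

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes in spot grid")
        parity = (np.asarray(self.array_row) + np.asarray(self.array_col)) % 2
        bad = np.nonzero(parity != 0)[0]
        if bad.size:
            raise FormatError(
                f"row {bad[0]} (barcode {self.barcodes[bad[0]]}): "
                "array_row + array_col must be even on the Visium lattice"
            )

    @property
    def x_um(self) -> np.ndarray:
        return np.asarray(self.array_col, dtype=float) * UM_PER_COL

    @property
    def y_um(self) -> np.ndarray:
        return np.asarray(self.array_row, dtype=float) * UM_PER_ROW

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    def index_of(self, barcodes) -> np.ndarray:
        lut = {b: i for i, b in enumerate(self.barcodes)}
        return np.array([lut[b] for b in barcodes], dtype=int)

    def subset(self, barcodes) -> "SpotGrid":
        idx = self.index_of(barcodes)
        return SpotGrid(
            self.barcodes[idx],
            np.asarray(self.in_tissue)[idx],
            np.asarray(self.array_row)[idx],
            np.asarray(self.array_col)[idx],
            np.asarray(self.pxl_x)[idx],
            np.asarray(self.pxl_y)[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "in_tissue": np.asarray(self.in_tissue, dtype=int),
                "array_row": self.array_row,
                "array_col": self.array_col,
                "pxl_row_in_fullres": self.pxl_y,
                "pxl_col_in_fullres": self.pxl_x,
            }
        )


@dataclass
class CountMatrix:
    """gene x spot raw counts (sparse, non-negative integers)."""

    genes: np.ndarray
    barcodes: np.ndarray
    X: sp.csr_matrix  # shape (n_genes, n_spots)

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.X = sp.csr_matrix(self.X)
        if self.X.shape != (len(self.genes), len(self.barcodes)):
            raise FormatError(
                f"count matrix shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("gene names are not unique")
        if self.X.nnz and self.X.data.min() < 0:
            raise FormatError("negative entry in count matrix")

    @property
    def spot_totals(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=0)).ravel()

    def dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())

    def subset(self, genes=None, barcodes=None) -> "CountMatrix":
        gi = np.arange(len(self.genes)) if genes is None else _index(self.genes, genes)
        bi = (
            np.arange(len(self.barcodes))
            if barcodes is None
            else _index(self.barcodes, barcodes)
        )
        return CountMatrix(self.genes[gi], self.barcodes[bi], self.X[gi][:, bi])


@dataclass
class NormalizedMatrix:
    """gene x spot log-normalized expression: ln(1 + scale * c / spot_total)."""

    genes: np.ndarray
    barcodes: np.ndarray
    X: sp.csr_matrix
    scale: float = 10_000.0

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.X = sp.csr_matrix(self.X)

    def dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())

    def gene_vector(self, gene: str) -> np.ndarray:
        i = int(np.nonzero(self.genes == gene)[0][0])
        return np.asarray(self.X[i].todense()).ravel()


#: Region labels use plain dicts barcode -> {"fat","fold","gap","none"}.
RegionLabels = dict

#: Mask precedence: tissue artefacts must never be analysed, so folds and
#: gaps shadow fat wherever polygons overlap.
MASK_PRECEDENCE = ("fold", "gap", "fat")


def _index(haystack: np.ndarray, needles) -> np.ndarray:
    lut = {g: i for i, g in enumerate(haystack)}
    return np.array([lut[n] for n in needles], dtype=int)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def read_spot_positions(path) -> SpotGrid:
    """Read a 10x ``tissue_positions.csv`` (headered or headerless dialect)."""
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = str(first.iloc[0, 0]).strip().lower() == "barcode"
    if hasattr(path, "seek"):
        path.seek(0)
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] != 6:
        raise FormatError(f"expected 6 columns in {path}, found {df.shape[1]}")
    df.columns = _POSITION_COLUMNS
    try:
        in_tissue = df["in_tissue"].astype(int).to_numpy().astype(bool)
        rows = df["array_row"].astype(int).to_numpy()
        cols = df["array_col"].astype(int).to_numpy()
        py = df["pxl_row_in_fullres"].astype(float).to_numpy()
        px = df["pxl_col_in_fullres"].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"malformed row in {path}: {exc}") from exc
    return SpotGrid(df["barcode"].to_numpy(dtype=object), in_tissue, rows, cols, px, py)


def write_spot_positions(grid: SpotGrid, path, header: bool = True) -> None:
    grid.to_frame().to_csv(path, index=False, header=header)


def read_counts(mtx_path, features_path, barcodes_path) -> CountMatrix:
    """Read MatrixMarket counts with feature/barcode TSVs (genes x spots)."""
    X = sp.csr_matrix(mmread(mtx_path))
    genes = pd.read_csv(features_path, sep="\t", header=None)[0].to_numpy(dtype=object)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].to_numpy(dtype=object)
    if X.shape[0] != len(genes):
        raise FormatError(
            f"{mtx_path}: {X.shape[0]} rows but {len(genes)} features"
        )
    if X.shape[1] != len(barcodes):
        raise FormatError(
            f"{mtx_path}: {X.shape[1]} columns but {len(barcodes)} barcodes"
        )
    return CountMatrix(genes, barcodes, X)


def write_counts(counts: CountMatrix, mtx_path, features_path, barcodes_path) -> None:
    mmwrite(str(mtx_path), sp.coo_matrix(counts.X), field="integer")
    pd.Series(counts.genes).to_csv(features_path, sep="\t", header=False, index=False)
    pd.Series(counts.barcodes).to_csv(barcodes_path, sep="\t", header=False, index=False)


def read_region_labels(path) -> RegionLabels:
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "label"])
    return dict(zip(df["barcode"], df["label"]))


def write_region_labels(labels: RegionLabels, path) -> None:
    pd.DataFrame(sorted(labels.items()), columns=["barcode", "label"]).to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def apply_masks(grid: SpotGrid, masks) -> RegionLabels:
    """Label spots by histology masks drawn in pixel space.

    ``masks`` is a sequence of ``(label, polygon)`` where polygon is a
    shapely Polygon or a coordinate list. A spot takes the label of the
    first covering polygon after sorting by precedence fold > gap > fat
    (document order within a class); polygon boundaries count as inside.
    """
    from shapely.geometry import Point, Polygon

    prepared = []
    for label, poly in masks:
        if label not in MASK_PRECEDENCE:
            raise ValueError(f"unknown mask label {label!r}")
        if not isinstance(poly, Polygon):
            poly = Polygon(poly)
        if not poly.is_valid:
            raise ValueError(f"self-intersecting or invalid polygon for {label!r}")
        prepared.append((MASK_PRECEDENCE.index(label), label, poly))
    prepared.sort(key=lambda t: t[0])

    out: RegionLabels = {}
    for b, x, y in zip(grid.barcodes, grid.pxl_x, grid.pxl_y):
        pt = Point(float(x), float(y))
        out[b] = next((lab for _, lab, poly in prepared if poly.covers(pt)), "none")
    return out


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


def is_mito_or_ribo(gene: str) -> bool:
    return gene.upper().startswith(MITO_RIBO_PREFIXES)


def qc_filter(
    counts: CountMatrix,
    labels: RegionLabels,
    min_counts: int = 30,
) -> tuple[CountMatrix, list, pd.DataFrame]:
    """Spot and gene QC.

    Drops fold/gap spots, drops spots with total counts below ``min_counts``
    unless they are fat-masked (adipocytes are transcriptionally sparse, so
    low counts there are biology, not failure), and removes mitochondrial
    and ribosomal genes by name prefix. Returns the filtered matrix, the
    kept barcodes, and a per-dropped-spot log with reasons.
    """
    missing = [b for b in counts.barcodes if b not in labels]
    if missing:
        raise ValueError(f"labels missing for {len(missing)} barcodes, e.g. {missing[0]}")

    totals = counts.spot_totals
    keep, dropped = [], []
    for j, b in enumerate(counts.barcodes):
        lab = labels[b]
        if lab in ("fold", "gap"):
            dropped.append((b, lab))
        elif totals[j] < min_counts and lab != "fat":
            dropped.append((b, "low_count"))
        else:
            keep.append(b)
    if not keep:
        raise EmptyTissueError("no spots survive QC")

    kept_genes = [g for g in counts.genes if not is_mito_or_ribo(g)]
    if not kept_genes:
        raise EmptyTissueError("no genes survive QC")
    out = counts.subset(genes=kept_genes, barcodes=keep)
    log = pd.DataFrame(dropped, columns=["barcode", "reason"])
    return out, keep, log


def log_normalize(counts: CountMatrix, scale: float = 10_000.0) -> NormalizedMatrix:
    """Per-spot library-size log normalization: v = ln(1 + scale*c/total)."""
    totals = counts.spot_totals
    if (totals <= 0).any():
        bad = counts.barcodes[np.nonzero(totals <= 0)[0][0]]
        raise ValueError(f"spot {bad} has zero total counts; run qc_filter first")
    X = counts.X.tocsc(copy=True).astype(float)
    X.data *= scale / np.repeat(totals, np.diff(X.indptr))
    X.data = np.log1p(X.data)
    return NormalizedMatrix(counts.genes, counts.barcodes, X.tocsr(), scale)


# ---------------------------------------------------------------------------
# lattice geometry
# ---------------------------------------------------------------------------


def hex_neighbors(grid: SpotGrid) -> dict:
    """Adjacency (barcode -> set of barcodes) over in-tissue spots."""
    pos = {}
    for b, it, r, c in zip(grid.barcodes, grid.in_tissue, grid.array_row, grid.array_col):
        if it:
            pos[(int(r), int(c))] = b
    adj = {b: set() for b in pos.values()}
    for (r, c), b in pos.items():
        for dr, dc in HEX_OFFSETS:
            nb = pos.get((r + dr, c + dc))
            if nb is not None:
                adj[b].add(nb)
    return adj


def adjacency_matrix(adj: dict, barcodes) -> sp.csr_matrix:
    """Symmetric 0/1 adjacency restricted and ordered to ``barcodes``."""
    barcodes = list(barcodes)
    lut = {b: i for i, b in enumerate(barcodes)}
    rows, cols = [], []
    for b, nbrs in adj.items():
        i = lut.get(b)
        if i is None:
            continue
        for nb in nbrs:
            j = lut.get(nb)
            if j is not None:
                rows.append(i)
                cols.append(j)
    n = len(barcodes)
    return sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )


# ---------------------------------------------------------------------------
# sequencing metadata
# ---------------------------------------------------------------------------


def round_half_away(x) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def summarize_sequencing(meta: pd.DataFrame) -> dict:
    """Per-sample and cohort sequencing summaries.

    ``meta`` columns: cohort, sample, reads_site_a, reads_site_b (NaN when
    a sample was sequenced at one site only), spots_under_tissue. Returns
    ``{"samples": DataFrame, "cohorts": DataFrame}`` where the cohort table
    includes an "all" rollup row. Mean reads per spot are rounded half away
    from zero; the cohort mean is the rounded mean of the rounded
    per-sample means.
    """
    if len(meta) == 0:
        raise ValueError("no samples in metadata table")
    if (meta["spots_under_tissue"] <= 0).any():
        raise ValueError("spots_under_tissue must be >= 1")

    reads = meta[["reads_site_a", "reads_site_b"]].fillna(0.0)
    if (reads.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    total_reads = reads.sum(axis=1).astype("int64")
    spots = meta["spots_under_tissue"].astype("int64")
    mean_rps = np.array(
        [round_half_away(t / s) for t, s in zip(total_reads, spots)], dtype="int64"
    )
    samples = meta.copy()
    samples["total_reads"] = total_reads.to_numpy()
    samples["mean_reads_per_spot"] = mean_rps

    rows = []
    groups = [(c, g) for c, g in samples.groupby("cohort", sort=False)]
    groups.append(("all", samples))
    for name, g in groups:
        rows.append(
            {
                "cohort": name,
                "n_samples": len(g),
                "total_reads": int(g["total_reads"].sum()),
                "total_spots": int(g["spots_under_tissue"].sum()),
                "mean_reads_per_spot": round_half_away(
                    g["mean_reads_per_spot"].mean()
                ),
            }
        )
    return {"samples": samples, "cohorts": pd.DataFrame(rows)}
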