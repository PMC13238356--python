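"""Reference-based spot deconvolution with spatial smoothing.

Marker genes are selected one-vs-rest from a labeled single-nucleus
reference (Wilcoxon rank-sum, expressing-fraction and fold-change
thresholds, Bonferroni, top 50 per type), averaged into per-type profiles,
and per-spot cell-type weights are estimated by non-negative least squares
with a graph-Laplacian penalty that pulls neighbouring spots on the hex
lattice toward similar compositions:

    min_{W >= 0}  ||Y - W B||_F^2  +  lambda * sum_{i~j} ||w_i - w_j||^2

solved by cyclic per-type projected-gradient descent (exact coordinate
minimization when lambda = 0). Rows are normalized to the simplex; the
largest entry gives the spot's dominant cell type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .spatial_core import NormalizedMatrix, adjacency_matrix


@dataclass
class MarkerSelectionParams:
    min_pct: float = 0.1
    log2fc_threshold: float = 2.5
    positive_only: bool = True
    alpha: float = 0.05           # Bonferroni-adjusted cutoff
    top_k: int = 50
    fc_log_base: float = 2.0      # 2.0 or np.e; threshold applies on this base

    def __post_init__(self) -> None:
        if not 0 <= self.min_pct <= 1:
            raise ValueError("min_pct must be in [0,1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class ReferenceProfiles:
    cell_types: list
    genes: np.ndarray            # marker union
    B: np.ndarray                # types x genes, mean expression over the union
    scale: str = "counts"        # "counts" (relative counts) or "log"


@dataclass
class CellTypeProportions:
    V: pd.DataFrame              # barcode x type, rows on the simplex
    lam: float
    dominant: pd.Series          # per-barcode label ("ambiguous" when flagged)
    ambiguous: np.ndarray        # bool per spot (all-zero weight rows)
    objective: list              # per-sweep objective values
    n_sweeps: int


def _log_normalize_cells(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    return np.log1p(scale * counts / totals)


def select_markers(
    counts: np.ndarray,
    cell_labels: np.ndarray,
    genes: np.ndarray,
    params: MarkerSelectionParams | None = None,
    exclude_types: tuple = ("B/T cells",),
) -> dict:
    """Ranked marker lists per cell type (one-vs-rest Wilcoxon).

    ``counts`` is cells x genes. Types in ``exclude_types`` are removed
    before testing (cell populations too small for reliable estimates).
    Genes pass when their in-type expressing fraction is at least
    ``min_pct``, their average fold-change on the configured log base is at
    least the threshold, and the Bonferroni-adjusted rank-sum p is below
    ``alpha``; the top ``top_k`` per type are kept, ranked by adjusted p
    then fold-change.
    """
    params = params or MarkerSelectionParams()
    keep_cells = ~np.isin(cell_labels, exclude_types)
    counts = np.asarray(counts)[keep_cells]
    cell_labels = np.asarray(cell_labels)[keep_cells]
    X = _log_normalize_cells(counts)
    n_genes = X.shape[1]
    types = [t for t in pd.unique(cell_labels)]
    for t in types:
        if (cell_labels == t).sum() < 2:
            raise ValueError(f"cell type {t!r} has fewer than 2 cells")

    out = {}
    for t in types:
        sel = cell_labels == t
        xin, xout = X[sel], X[~sel]
        pct_in = (xin > 0).mean(axis=0)
        mean_in = np.expm1(xin).mean(axis=0)
        mean_out = np.expm1(xout).mean(axis=0)
        ratio = (mean_in + 1.0) / (mean_out + 1.0)
        lfc = np.log(ratio) / np.log(params.fc_log_base)
        p = stats.mannwhitneyu(
            xin, xout, axis=0, alternative="two-sided", method="asymptotic"
        ).pvalue
        padj = np.minimum(p * n_genes, 1.0)
        ok = (pct_in >= params.min_pct) & (lfc >= params.log2fc_threshold) & (
            padj < params.alpha
        )
        if params.positive_only:
            ok &= lfc > 0
        df = pd.DataFrame(
            {"gene": genes[ok], "log2fc": lfc[ok], "padj": padj[ok]}
        ).sort_values(["padj", "log2fc"], ascending=[True, False], kind="mergesort")
        out[t] = df.head(params.top_k).reset_index(drop=True)
    return out


def build_profiles(
    counts: np.ndarray,
    cell_labels: np.ndarray,
    genes: np.ndarray,
    markers: dict,
    scale: str = "counts",
) -> ReferenceProfiles:
    """Per-type mean expression over the marker union.

    ``scale="counts"`` (default) averages each cell's relative counts,
    matching the linear mixing model of the deconvolution; ``scale="log"``
    averages log-normalized expression instead.
    """
    union: list = []
    for df in markers.values():
        for g in df["gene"]:
            if g not in union:
                union.append(g)
    if not union:
        raise ValueError("empty marker union")
    gidx = {g: i for i, g in enumerate(genes)}
    cols = [gidx[g] for g in union]
    counts = np.asarray(counts)
    if scale == "counts":
        totals = counts.sum(axis=1, keepdims=True).astype(float)
        totals[totals == 0] = 1.0
        X = (counts / totals)[:, cols]
    elif scale == "log":
        X = _log_normalize_cells(counts)[:, cols]
    else:
        raise ValueError(f"unknown scale {scale!r}")
    types = list(markers)
    B = np.vstack([X[np.asarray(cell_labels) == t].mean(axis=0) for t in types])
    return ReferenceProfiles(types, np.array(union, dtype=object), B, scale)


def deconvolve(
    norm: NormalizedMatrix,
    profiles: ReferenceProfiles,
    adjacency: dict | sp.spmatrix | None,
    lam: float = 0.1,
    tol: float = 1e-10,
    max_sweeps: int = 2000,
    min_overlap: int = 10,
) -> CellTypeProportions:
    """Estimate per-spot cell-type proportions.

    ``adjacency`` is a barcode adjacency dict (or precomputed sparse
    matrix aligned to ``norm.barcodes``); with ``lam=0`` the problem
    separates into independent per-spot NNLS fits. ``lam`` is expressed in
    units of the mean marker-profile energy (trace(B B^T)/K), so its
    meaning does not depend on the expression scale.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    present = set(norm.genes)
    shared = [g for g in profiles.genes if g in present]
    if len(shared) < min_overlap:
        raise ValueError(
            f"only {len(shared)} marker genes overlap the matrix (< {min_overlap})"
        )
    gsel = {g: i for i, g in enumerate(profiles.genes)}
    B = profiles.B[:, [gsel[g] for g in shared]]
    gidx = {g: i for i, g in enumerate(norm.genes)}
    Y = norm.dense()[[gidx[g] for g in shared], :].T  # spots x genes
    if profiles.scale == "counts":
        # undo the log transform so spots mix linearly in count space
        Y = np.expm1(Y) / norm.scale

    n, K = Y.shape[0], B.shape[0]
    if adjacency is None:
        A = sp.csr_matrix((n, n))
    elif isinstance(adjacency, dict):
        A = adjacency_matrix(adjacency, norm.barcodes)
    else:
        A = sp.csr_matrix(adjacency)
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = sp.diags(deg) - A
    dmax = deg.max() if n else 0.0

    G = B @ B.T
    C = Y @ B.T
    # Scale-free smoothing weight: lam is the ratio of spatial to data
    # curvature per spot (trace(G)/K per type vs ~degree Laplacian rows).
    lam = lam * float(np.trace(G)) / (K * max(deg.mean(), 1.0))
    W = np.full((n, K), 1.0 / K)

    def objective(W):
        data = float(((W @ B - Y) ** 2).sum())
        spatial = float(lam * (W * (L @ W)).sum()) if lam > 0 else 0.0
        return data + spatial

    obj = [objective(W)]
    for sweep in range(max_sweeps):
        for k in range(K):
            denom = G[k, k] + 2.0 * lam * dmax
            if denom <= 0:
                continue
            grad = W @ G[:, k] - C[:, k]
            if lam > 0:
                # refresh the Laplacian term for this column only
                grad = grad + lam * (L @ W[:, k])
            W[:, k] = np.maximum(0.0, W[:, k] - grad / denom)
        obj.append(objective(W))
        if abs(obj[-2] - obj[-1]) < tol * (abs(obj[-2]) + 1e-12):
            break

    rowsum = W.sum(axis=1)
    ambiguous = rowsum <= 1e-12
    V = np.where(ambiguous[:, None], 1.0 / K, W / np.maximum(rowsum, 1e-300)[:, None])
    Vdf = pd.DataFrame(V, index=norm.barcodes, columns=profiles.cell_types)
    dom = dominant_cell_type(Vdf, ambiguous)
    return CellTypeProportions(Vdf, lam, dom, ambiguous, obj, sweep + 1)


def dominant_cell_type(V: pd.DataFrame, ambiguous: np.ndarray | None = None) -> pd.Series:
    """Row argmax of the proportion matrix; ties break by column order."""
    labels = V.columns.to_numpy()[np.argmax(V.to_numpy(), axis=1)]
    out = pd.Series(labels, index=V.index, name="dominant", dtype=object)
    if ambiguous is not None:
        out[np.asarray(ambiguous)] = "ambiguous"
    return out
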