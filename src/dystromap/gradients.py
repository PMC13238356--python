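"""Fat-distance gradient screening.

Genes whose expression tracks the distance to annotated intramuscular fat
are candidate markers of muscle committed to fibro-fatty replacement. The
screen has three steps: (1) a spatial-variability prefilter (Moran's I with
an analytic z-test and BH correction), (2) binning each gene's expression
along normalized distance-to-fat, and (3) matching the min-max-rescaled bin
profile against a registry of descending / ascending / peak templates by
RMSE, accepting genes with adjusted p < 0.05 and RMSE < 0.25.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import norm as norm_dist

from .pseudode import bh_adjust
from .spatial_core import NormalizedMatrix, SpotGrid, adjacency_matrix, hex_neighbors

# Template curves on t in [0,1]; all are min-max rescaled on the evaluated
# grid before comparison, so only the shape matters.
TEMPLATES = {
    "linear_descending": lambda t: 1.0 - t,
    "early_descending": lambda t: (1.0 - t) ** 3,
    "instant_descending": lambda t: np.exp(-10.0 * t),
    "gradual_peak": lambda t: np.exp(-((t - 0.5) ** 2) / (2 * 0.20**2)),
    "medium_peak": lambda t: np.exp(-((t - 0.5) ** 2) / (2 * 0.125**2)),
    "small_peak": lambda t: np.exp(-((t - 0.5) ** 2) / (2 * 0.05**2)),
    "linear_ascending": lambda t: t,
    "early_ascending": lambda t: t**3,
    "instant_ascending": lambda t: np.exp(-10.0 * (1.0 - t)),
}


def _rescale(v: np.ndarray) -> np.ndarray | None:
    rng = v.max() - v.min()
    if rng <= 0:
        return None
    return (v - v.min()) / rng


def distance_to_annotation(grid: SpotGrid, fat_labels: dict) -> dict:
    """Euclidean um distance from each spot center to the nearest fat spot."""
    fat_idx = [i for i, b in enumerate(grid.barcodes) if fat_labels.get(b) == "fat"]
    if not fat_idx:
        raise ValueError("no fat-labeled spots; distance field undefined")
    xy = np.column_stack([grid.x_um, grid.y_um])
    d = cdist(xy, xy[fat_idx]).min(axis=1)
    d[fat_idx] = 0.0
    return dict(zip(grid.barcodes, d))


def spatial_variability_filter(
    norm: NormalizedMatrix, grid: SpotGrid, alpha: float = 0.05
) -> pd.DataFrame:
    """Moran's I screen for spatially autocorrelated genes.

    Uses row-normalized hex-neighbour weights and the z-test against
    E[I] = -1/(n-1) with the normality-assumption variance; one-sided
    (positive autocorrelation), BH-adjusted. Genes with zero total or zero
    variance are dropped up front.
    """
    sub = grid.subset(norm.barcodes)
    n = len(norm.barcodes)
    if n < 30:
        raise ValueError(f"need >= 30 spots for the spatial screen, have {n}")
    W = adjacency_matrix(hex_neighbors(sub), norm.barcodes).astype(float)
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    inv = np.where(rowsum > 0, 1.0 / np.maximum(rowsum, 1e-300), 0.0)
    W = W.multiply(inv[:, None]).tocsr()

    S0 = W.sum()
    WT = W.T.tocsr()
    S1 = 0.5 * ((W + WT).power(2)).sum()
    rs = np.asarray(W.sum(axis=1)).ravel() + np.asarray(W.sum(axis=0)).ravel()
    S2 = float((rs**2).sum())

    X = norm.dense()
    total = X.sum(axis=1)
    var = X.var(axis=1)
    testable = (total > 0) & (var > 0)

    Z = X - X.mean(axis=1, keepdims=True)
    num = (Z * (W @ Z.T).T).sum(axis=1)  # sum_ij w_ij z_i z_j per gene
    den = (Z**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        I = (n / S0) * num / den

    EI = -1.0 / (n - 1)
    varI = (n**2 * S1 - n * S2 + 3 * S0**2) / ((n**2 - 1) * S0**2) - EI**2
    z = (I - EI) / np.sqrt(varI)
    p = norm_dist.sf(z)

    df = pd.DataFrame({"gene": norm.genes, "moran_i": I, "p": p})
    df = df[testable].reset_index(drop=True)
    df["padj"] = bh_adjust(df["p"].to_numpy())
    df["keep"] = df["padj"] < alpha
    return df


def fit_gradient_templates(
    norm: NormalizedMatrix,
    field: dict,
    templates: dict | None = None,
    n_bins: int = 20,
    rmse_max: float = 0.25,
    adjusted_p: dict | None = None,
    alpha: float = 0.05,
    genes=None,
) -> pd.DataFrame:
    """Fit each gene's distance-binned profile against the template registry.

    Fat spots (distance 0) are excluded; the remaining distances are scaled
    to t in [0,1] and cut into ``n_bins`` equal-width bins. Per gene the bin
    means are min-max rescaled and compared by RMSE against every template
    evaluated (and likewise rescaled) at the occupied bin centers. A gene is
    selected when its spatial-variability adjusted p is below ``alpha`` and
    its best RMSE is below ``rmse_max``. Constant profiles are skipped.
    """
    templates = templates or TEMPLATES
    d = np.array([field[b] for b in norm.barcodes])
    keep = d > 0
    if keep.sum() < n_bins:
        raise ValueError("fewer non-fat spots than distance bins")
    t = d[keep] / d[keep].max()
    bins = np.minimum((t * n_bins).astype(int), n_bins - 1)

    X = norm.dense()[:, keep]
    gene_list = list(norm.genes) if genes is None else list(genes)
    gidx = {g: i for i, g in enumerate(norm.genes)}

    counts = np.bincount(bins, minlength=n_bins)
    occupied = counts > 0
    # evaluate templates at each occupied bin's mean t: unbiased for any
    # curve that is locally linear, and exact for linear profiles
    eval_t = np.bincount(bins, weights=t, minlength=n_bins)[occupied] / counts[occupied]
    tmpl_curves = {}
    for name, f in templates.items():
        c = _rescale(np.asarray(f(eval_t), dtype=float))
        if c is not None:
            tmpl_curves[name] = c

    rows = []
    for g in gene_list:
        v = X[gidx[g]]
        means = np.bincount(bins, weights=v, minlength=n_bins)[occupied] / counts[occupied]
        if occupied.sum() < 2:
            continue
        prof = _rescale(means)
        if prof is None:
            continue  # flat profile: nothing to fit
        best_name, best_rmse = None, np.inf
        for name, curve in tmpl_curves.items():
            rmse = float(np.sqrt(np.mean((prof - curve) ** 2)))
            if rmse < best_rmse:
                best_name, best_rmse = name, rmse
        padj = np.nan if adjusted_p is None else float(adjusted_p.get(g, np.nan))
        selected = bool(best_rmse < rmse_max) and bool(
            adjusted_p is not None and padj < alpha
        )
        rows.append(
            {"gene": g, "template": best_name, "rmse": best_rmse,
             "padj": padj, "selected": selected}
        )
    return pd.DataFrame(rows, columns=["gene", "template", "rmse", "padj", "selected"])


def screen_gradients(
    norm: NormalizedMatrix,
    grid: SpotGrid,
    fat_labels: dict,
    alpha: float = 0.05,
    n_bins: int = 20,
    rmse_max: float = 0.25,
) -> pd.DataFrame:
    """Full screen: Moran prefilter, then template fits on retained genes."""
    sv = spatial_variability_filter(norm, grid, alpha=alpha)
    retained = sv[sv["keep"]]
    field = distance_to_annotation(grid.subset(norm.barcodes), fat_labels)
    padj = dict(zip(sv["gene"], sv["padj"]))
    return fit_gradient_templates(
        norm, field, n_bins=n_bins, rmse_max=rmse_max,
        adjusted_p=padj, alpha=alpha, genes=retained["gene"].tolist(),
    )
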