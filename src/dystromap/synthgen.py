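"""Synthetic Visium-like tissue and reference generator with ground truth.

Emulates the statistical structure of dystrophic skeletal muscle sections:
a hex spot lattice at 100 um pitch, per-spot cell-type mixtures on the
simplex, contiguous intramuscular fat patches ringed by a fibrotic
(FAP-rich) halo, negative-binomial counts, planted group fold-changes,
niche-restricted ligand-receptor expression around fat, and genes whose
expectation decays with distance from fat following a named template.

Every artifact carries a ground-truth record so downstream stages can be
tested as parameter-recovery problems rather than smoke tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .spatial_core import (
    CountMatrix,
    RegionLabels,
    SpotGrid,
    hex_neighbors,
)

DEFAULT_CELL_TYPES = (
    "fast_fibers",
    "slow_fibers",
    "regenerative_fibers",
    "adipocytes",
    "faps",
    "endothelial_cells",
    "satellite_cells",
    "smooth_muscle_cells",
    "monocytic_cells",
)

# Named marker genes seeded into each type's marker slots so that module
# definitions, myosin typing, and L-R planting use field-standard symbols.
CURATED_MARKERS = {
    "fast_fibers": ["MYH1", "MYH2", "ACTA1", "TNNT3", "MYBPC2", "ATP2A1"],
    "slow_fibers": ["MYH7", "TNNT1", "MYL3", "TPM3", "ATP2A2"],
    "regenerative_fibers": ["MYH8", "MYH3", "NCAM1"],
    "adipocytes": ["ADIPOQ", "PLIN1", "LPL", "FABP4", "PLIN4", "SCD"],
    "faps": ["COL1A1", "COL1A2", "THBS4", "COL3A1", "LRP1", "DCN", "PDGFRA"],
    "endothelial_cells": ["PECAM1", "VWF", "FLT1"],
    "satellite_cells": ["PAX7", "MYF5"],
    "smooth_muscle_cells": ["MYH11", "ACTA2", "TAGLN"],
    "monocytic_cells": ["CD68", "PTPRC", "LYZ"],
}

# Non-marker named genes kept at baseline (handy for DE / gradient plants).
CURATED_BASELINE = [
    "SPARC", "CA3", "ART3", "PGM1", "ENO3", "MYL9", "FTL", "ADIRF",
    "EEF1A1", "VIM", "CD44", "APP", "VLDLR", "APOE", "MIF", "CD74",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


def derive_seed(master_seed: int, tag: str) -> int:
    """Stable per-stage/per-sample seed below 2**31."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


@dataclass
class ReferenceConfig:
    cell_types: tuple = DEFAULT_CELL_TYPES
    n_genes: int = 2000
    markers_per_type: int = 20
    marker_log2fc: float = 4.0
    baseline_mean: float = 2.0
    dispersion: float = 0.3
    cells_per_type: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ConfigurationError("cell_types must be unique")
        if self.markers_per_type * len(self.cell_types) > self.n_genes:
            raise ConfigurationError(
                "marker budget exceeds n_genes: "
                f"{self.markers_per_type} x {len(self.cell_types)} > {self.n_genes}"
            )
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")


@dataclass
class ReferenceData:
    """Cell x gene counts with labels plus the true type-mean matrix."""

    counts: np.ndarray            # cells x genes, int
    cell_labels: np.ndarray      # str per cell
    genes: np.ndarray
    cell_types: tuple
    type_means: np.ndarray       # types x genes expectation used to sample


def _gene_names(cfg: ReferenceConfig) -> tuple[np.ndarray, dict]:
    """Gene list and per-type marker slots (curated symbols first)."""
    markers: dict[str, list] = {}
    names: list = []
    for t in cfg.cell_types:
        slots = list(CURATED_MARKERS.get(t, []))[: cfg.markers_per_type]
        while len(slots) < cfg.markers_per_type:
            slots.append(f"MRK-{t.upper()}-{len(slots):02d}")
        markers[t] = slots
        names.extend(slots)
    for g in CURATED_BASELINE:
        if len(names) < cfg.n_genes and g not in names:
            names.append(g)
    i = 0
    while len(names) < cfg.n_genes:
        names.append(f"SYNG{i:04d}")
        i += 1
    return np.array(names[: cfg.n_genes], dtype=object), markers


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via Gamma-Poisson; dispersion 0 degrades to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def make_reference(cfg: ReferenceConfig) -> tuple[ReferenceData, pd.DataFrame]:
    """Sample a labeled cell x gene reference with planted markers.

    Each marker gene's expected expression in its own type is
    ``2**marker_log2fc`` times its expectation elsewhere.
    """
    rng = np.random.default_rng(cfg.seed)
    genes, marker_slots = _gene_names(cfg)
    gene_idx = {g: i for i, g in enumerate(genes)}
    K = len(cfg.cell_types)

    type_means = np.full((K, cfg.n_genes), cfg.baseline_mean, dtype=float)
    rows = []
    for k, t in enumerate(cfg.cell_types):
        for g in marker_slots[t]:
            type_means[k, gene_idx[g]] = cfg.baseline_mean * 2.0**cfg.marker_log2fc
            rows.append({"gene": g, "cell_type": t, "log2fc": cfg.marker_log2fc})
    marker_table = pd.DataFrame(rows)

    labels = np.repeat(list(cfg.cell_types), cfg.cells_per_type)
    means = np.repeat(type_means, cfg.cells_per_type, axis=0)
    counts = _nb_sample(rng, means, cfg.dispersion)
    ref = ReferenceData(counts, np.array(labels, dtype=object), genes,
                        tuple(cfg.cell_types), type_means)
    return ref, marker_table


# ---------------------------------------------------------------------------
# tissue
# ---------------------------------------------------------------------------


def default_mixture_priors(cell_types=DEFAULT_CELL_TYPES) -> dict:
    """Dirichlet concentrations per zone.

    Fat patches are adipocyte-dominated, the surrounding ring is FAP-rich
    (fibrotic halo), and bulk tissue is fast/slow fiber muscle.
    """
    def prior(**kw):
        a = np.full(len(cell_types), 0.2)
        for t, v in kw.items():
            a[list(cell_types).index(t)] = v
        return a

    return {
        "fat": prior(adipocytes=30.0, faps=1.5),
        "ring": prior(faps=30.0, adipocytes=1.0, endothelial_cells=0.5),
        "bulk": prior(fast_fibers=10.0, slow_fibers=10.0,
                      endothelial_cells=0.5, monocytic_cells=0.3),
    }


@dataclass
class NichePlant:
    ligand: str
    receptor: str
    sender_type: str
    receiver_type: str
    factor: float = 8.0


@dataclass
class GradientPlant:
    gene: str
    template: str
    length_scale_um: float | None = None  # None -> the sample's max distance
    amplitude: float = 8.0


@dataclass
class TissueConfig:
    n_rows: int = 20
    n_cols: int = 40                    # array_col units (half-pitch steps)
    fat_patches: tuple = ()             # (array_row, array_col, radius_rings)
    ct_patches: tuple = ()              # fibrotic patches independent of fat
    ring_width: int = 3
    mixture_prior: dict | None = None   # zone -> Dirichlet concentrations
    library_size_mean: float = 10_000.0
    lr_niche_pairs: tuple = ()          # NichePlant
    gradient_genes: tuple = ()          # GradientPlant
    group: str = "HC"
    de_genes: tuple = ()                # (gene, log2fc), applied when DYS
    n_folds: int = 0
    n_gaps: int = 0
    mixture_smoothing: int = 1          # rounds of within-zone neighbour averaging
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("HC", "DYS"):
            raise ConfigurationError(f"group must be HC or DYS, got {self.group!r}")
        for r, c, k in tuple(self.fat_patches) + tuple(self.ct_patches):
            if (r + c) % 2 != 0:
                raise ConfigurationError(f"fat patch center ({r},{c}) violates parity")
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ConfigurationError(f"fat patch center ({r},{c}) outside lattice")
            if r - k < 0 or r + k >= self.n_rows or c - 2 * k < 0 or c + 2 * k >= self.n_cols:
                raise ConfigurationError(
                    f"fat patch ({r},{c},{k}) does not fit inside the lattice"
                )
        if self.mixture_prior is not None:
            for z, a in self.mixture_prior.items():
                if np.any(np.asarray(a) <= 0):
                    raise ConfigurationError(f"Dirichlet concentrations for {z} must be > 0")


@dataclass
class GroundTruth:
    proportions: pd.DataFrame        # barcode x cell type, rows sum to 1
    zone: dict                       # barcode -> fat|ring|bulk
    de_table: pd.DataFrame           # gene, log2fc (empty for HC)
    marker_table: pd.DataFrame
    gradient_table: pd.DataFrame     # gene, template, length_scale_um, amplitude
    niche_table: pd.DataFrame        # ligand, receptor, sender, receiver, factor


def full_lattice(n_rows: int, n_cols: int) -> SpotGrid:
    """All valid (row+col even) positions, all in-tissue; 2 px per um."""
    rows, cols = [], []
    for r in range(n_rows):
        for c in range(r % 2, n_cols, 2):
            rows.append(r)
            cols.append(c)
    rows = np.array(rows)
    cols = np.array(cols)
    barcodes = np.array([f"BC{r:03d}x{c:03d}" for r, c in zip(rows, cols)], dtype=object)
    grid = SpotGrid(barcodes, np.ones(len(rows), bool), rows, cols,
                    cols * 50.0 * 2.0, rows * 86.60254037844386 * 2.0)
    return grid


def hex_ball(grid: SpotGrid, center: tuple, radius: int) -> set:
    """Barcodes within ``radius`` hex rings of ``center`` (BFS on the lattice)."""
    adj = hex_neighbors(grid)
    pos = {(int(r), int(c)): b for b, r, c in zip(grid.barcodes, grid.array_row, grid.array_col)}
    start = pos.get((int(center[0]), int(center[1])))
    if start is None:
        raise ConfigurationError(f"no spot at patch center {center}")
    frontier, ball = {start}, {start}
    for _ in range(radius):
        frontier = {nb for b in frontier for nb in adj[b]} - ball
        ball |= frontier
    return ball


def _zones(grid: SpotGrid, cfg: TissueConfig) -> dict:
    fat: set = set()
    for patch in cfg.fat_patches:
        fat |= hex_ball(grid, patch[:2], patch[2])
    adj = hex_neighbors(grid)
    ring: set = set()
    frontier = set(fat)
    seen = set(fat)
    for _ in range(cfg.ring_width):
        frontier = {nb for b in frontier for nb in adj[b]} - seen
        ring |= frontier
        seen |= frontier
    for patch in cfg.ct_patches:
        ring |= hex_ball(grid, patch[:2], patch[2]) - fat
    return {
        b: ("fat" if b in fat else "ring" if b in ring else "bulk")
        for b in grid.barcodes
    }


def make_tissue(
    cfg: TissueConfig, reference: ReferenceData, marker_table: pd.DataFrame | None = None
) -> tuple[CountMatrix, SpotGrid, RegionLabels, GroundTruth]:
    """Sample one Visium-like section from the reference's type profiles."""
    rng = np.random.default_rng(cfg.seed)
    grid = full_lattice(cfg.n_rows, cfg.n_cols)
    genes = reference.genes
    _gene_idx = {g: i for i, g in enumerate(genes)}

    def gene_idx(g):
        if g not in _gene_idx:
            raise ConfigurationError(f"gene {g!r} not present in the reference")
        return _gene_idx[g]
    types = reference.cell_types
    zone = _zones(grid, cfg)
    priors = cfg.mixture_prior or default_mixture_priors(types)

    n = grid.n_spots
    W = np.empty((n, len(types)))
    for i, b in enumerate(grid.barcodes):
        W[i] = rng.dirichlet(priors[zone[b]])
    if cfg.mixture_smoothing:
        # Neighbouring spots share tissue context: average each spot's
        # mixture with its same-zone hex neighbours (stays on the simplex).
        adj = hex_neighbors(grid)
        bidx = {b: i for i, b in enumerate(grid.barcodes)}
        for _ in range(cfg.mixture_smoothing):
            W_new = W.copy()
            for i, b in enumerate(grid.barcodes):
                nbrs = [bidx[nb] for nb in adj[b] if zone[nb] == zone[b]]
                if nbrs:
                    W_new[i] = (W[i] + W[nbrs].sum(axis=0)) / (1 + len(nbrs))
            W = W_new

    # Relative expression profile per type; spot expectation is the
    # proportion-weighted mixture scaled to the library size.
    profiles = reference.type_means / reference.type_means.sum(axis=1, keepdims=True)
    mean = cfg.library_size_mean * (W @ profiles)

    de_rows = []
    if cfg.group == "DYS":
        for g, lfc in cfg.de_genes:
            mean[:, gene_idx(g)] *= 2.0**lfc
            de_rows.append({"gene": g, "log2fc": lfc})

    fat_ring = np.array([zone[b] in ("fat", "ring") for b in grid.barcodes])
    ring_only = np.array([zone[b] == "ring" for b in grid.barcodes])
    niche_rows = []
    for plant in cfg.lr_niche_pairs:
        mean[fat_ring, gene_idx(plant.ligand)] *= plant.factor
        mean[ring_only, gene_idx(plant.receptor)] *= plant.factor
        niche_rows.append(
            {"ligand": plant.ligand, "receptor": plant.receptor,
             "sender": plant.sender_type, "receiver": plant.receiver_type,
             "factor": plant.factor}
        )

    grad_rows = []
    if cfg.gradient_genes:
        from .gradients import TEMPLATES, distance_to_annotation

        fat_labels = {b: ("fat" if zone[b] == "fat" else "none") for b in grid.barcodes}
        dist = distance_to_annotation(grid, fat_labels)
        d = np.array([dist[b] for b in grid.barcodes])
        for plant in cfg.gradient_genes:
            L = plant.length_scale_um or max(d.max(), 1.0)
            t = np.clip(d / L, 0.0, 1.0)
            f = TEMPLATES[plant.template](t)
            mean[:, gene_idx(plant.gene)] *= 1.0 + plant.amplitude * f
            grad_rows.append(
                {"gene": plant.gene, "template": plant.template,
                 "length_scale_um": L, "amplitude": plant.amplitude}
            )

    counts = _nb_sample(rng, mean, 0.3).astype(np.int64)
    cm = CountMatrix(genes, grid.barcodes, sp.csr_matrix(counts.T))

    labels: RegionLabels = {
        b: ("fat" if zone[b] == "fat" else "none") for b in grid.barcodes
    }
    artefact_pool = [b for b in grid.barcodes if zone[b] == "bulk"]
    n_art = cfg.n_folds + cfg.n_gaps
    if n_art:
        picked = rng.choice(artefact_pool, size=n_art, replace=False)
        for b in picked[: cfg.n_folds]:
            labels[b] = "fold"
        for b in picked[cfg.n_folds:]:
            labels[b] = "gap"

    props = pd.DataFrame(W, index=grid.barcodes, columns=list(types))
    truth = GroundTruth(
        proportions=props,
        zone=zone,
        de_table=pd.DataFrame(de_rows, columns=["gene", "log2fc"]),
        marker_table=marker_table if marker_table is not None else pd.DataFrame(),
        gradient_table=pd.DataFrame(
            grad_rows, columns=["gene", "template", "length_scale_um", "amplitude"]
        ),
        niche_table=pd.DataFrame(
            niche_rows, columns=["ligand", "receptor", "sender", "receiver", "factor"]
        ),
    )
    return cm, grid, labels, truth


def fat_polygons(grid: SpotGrid, labels: RegionLabels, pad_px: float = 90.0):
    """Emit pixel-space square mask polygons around fat spots.

    Convenience emitter so mask-reading code paths can be exercised against
    tissues whose fat zones were defined on the lattice.
    """
    from shapely.geometry import box
    from shapely.ops import unary_union

    boxes = [
        box(x - pad_px, y - pad_px, x + pad_px, y + pad_px)
        for b, x, y in zip(grid.barcodes, grid.pxl_x, grid.pxl_y)
        if labels.get(b) == "fat"
    ]
    if not boxes:
        return []
    merged = unary_union(boxes)
    geoms = getattr(merged, "geoms", [merged])
    return [("fat", g) for g in geoms]


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class Sample:
    name: str
    group: str
    counts: CountMatrix
    grid: SpotGrid
    labels: RegionLabels
    truth: GroundTruth


def make_cohort(
    configs: list, reference: ReferenceData, master_seed: int = 0,
    marker_table: pd.DataFrame | None = None,
) -> tuple[list, pd.DataFrame]:
    """Generate named samples plus a sequencing-metadata table.

    ``configs`` is a list of ``(name, TissueConfig)``. Each sample's seed is
    derived from the master seed and its name, so the cohort is reproducible
    as a whole. Reads per site emulate the two-site study layout: a target
    of ~50,000 read pairs per spot with log-normal sample-to-sample spread,
    split across one or two sequencing sites.
    """
    names = [n for n, _ in configs]
    if not names:
        raise ConfigurationError("empty cohort config")
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate sample names in cohort config")

    rng = np.random.default_rng(derive_seed(master_seed, "cohort-meta"))
    samples, meta_rows = [], []
    for name, cfg in configs:
        from dataclasses import replace

        cfg = replace(cfg, seed=derive_seed(master_seed, f"sample:{name}"))
        cm, grid, labels, truth = make_tissue(cfg, reference, marker_table)
        samples.append(Sample(name, cfg.group, cm, grid, labels, truth))

        n_spots = grid.n_spots
        total = int(n_spots * 50_000 * rng.lognormal(0.0, 0.25))
        if rng.random() < 0.5:
            a = int(total * rng.uniform(0.5, 0.9))
            row = {"reads_site_a": a, "reads_site_b": total - a}
        elif rng.random() < 0.5:
            row = {"reads_site_a": total, "reads_site_b": np.nan}
        else:
            row = {"reads_site_a": np.nan, "reads_site_b": total}
        meta_rows.append(
            {"cohort": cfg.group, "sample": name, **row, "spots_under_tissue": n_spots}
        )
    return samples, pd.DataFrame(meta_rows)


def demo_cohort_configs(
    n_rows: int = 16, n_cols: int = 32, de_genes: tuple = (("SPARC", 2.0), ("CA3", -2.0)),
) -> list:
    """Desk-scale analogue of the study design: 4 HC + 8 DYS, 7 DYS with fat.

    HC tissue is nearly pure muscle; DYS tissue carries one fat patch (except
    the last sample, mirroring the one biopsy without adipose infiltration),
    a fibrotic ring, planted group fold-changes, the LPL->LRP1 niche pair,
    and fat-distance gradient genes.
    """
    # centers on the lattice diagonal, where (row + col) is always even
    center = (n_rows // 2, n_rows // 2)
    niche = (NichePlant("LPL", "LRP1", "adipocytes", "faps"),)
    grads = (
        GradientPlant("FTL", "instant_descending"),
        GradientPlant("ADIRF", "early_descending"),
    )
    configs = []
    ct = ((n_rows // 4, n_rows // 4, 1),)
    for i in range(1, 5):
        configs.append(
            (f"HC{i}", TissueConfig(n_rows=n_rows, n_cols=n_cols, group="HC", ct_patches=ct))
        )
    for i in range(1, 8):
        configs.append(
            (
                f"DYS{i}",
                TissueConfig(
                    n_rows=n_rows, n_cols=n_cols, group="DYS",
                    fat_patches=((center[0], center[1], 2),), ct_patches=ct,
                    lr_niche_pairs=niche, gradient_genes=grads,
                    de_genes=de_genes, n_folds=2, n_gaps=2,
                ),
            )
        )
    configs.append(
        (
            "DYS8",
            TissueConfig(n_rows=n_rows, n_cols=n_cols, group="DYS",
                         ct_patches=ct, de_genes=de_genes),
        )
    )
    return configs
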