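"""Pseudo-bulk differential expression between HC and DYS cohorts.

Spots are summed into per-sample (optionally per annotated cluster)
profiles, profiles with fewer than 10 spots are excluded, lowly expressed
genes are filtered, libraries are TMM-normalized, and each gene is tested
with a negative-binomial log-linear model: per-gene dispersions are
estimated by Cox-Reid adjusted profile likelihood shrunk toward the common
value, and group contrasts use a likelihood-ratio chi-square test with
Benjamini-Hochberg correction. A gene is called differentially expressed
when |log2 fold-change| > 0.5 and adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .spatial_core import CountMatrix


@dataclass
class PseudoBulk:
    genes: np.ndarray
    Y: np.ndarray              # profiles x genes, integer sums
    meta: pd.DataFrame         # profile_id, sample, cluster, group, n_spots

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.Y.sum(axis=1).astype(float)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# aggregation and filtering
# ---------------------------------------------------------------------------


def aggregate_pseudobulk(
    samples, level: str = "sample", min_spots: int = 10
) -> tuple[PseudoBulk, pd.DataFrame]:
    """Sum spot counts into pseudo-bulk profiles.

    ``samples`` is an iterable of ``(name, group, CountMatrix, annotation)``
    where ``annotation`` maps barcode -> cluster label (ignored at
    ``level="sample"``). Profiles with fewer than ``min_spots`` member spots
    are dropped; the second return value logs them.
    """
    genes = None
    rows, metas, dropped = [], [], []
    for name, group, cm, ann in samples:
        if genes is None:
            genes = cm.genes
        elif list(genes) != list(cm.genes):
            raise ValueError(f"gene list of sample {name} differs from the first sample")
        if level == "sample":
            members = {"all": list(cm.barcodes)}
        else:
            members = {}
            for b in cm.barcodes:
                members.setdefault(ann[b], []).append(b)
        for cluster, bcs in sorted(members.items()):
            if len(bcs) < min_spots:
                dropped.append(
                    {"sample": name, "cluster": cluster, "n_spots": len(bcs)}
                )
                continue
            idx = [i for i, b in enumerate(cm.barcodes) if b in set(bcs)]
            rows.append(np.asarray(cm.X[:, idx].sum(axis=1)).ravel())
            metas.append(
                {"profile_id": f"{name}:{cluster}", "sample": name,
                 "cluster": cluster, "group": group, "n_spots": len(bcs)}
            )
    if not rows:
        raise ValueError("no pseudo-bulk profile survives the minimum-spot rule")
    pb = PseudoBulk(np.asarray(genes), np.vstack(rows).astype(np.int64),
                    pd.DataFrame(metas))
    return pb, pd.DataFrame(dropped, columns=["sample", "cluster", "n_spots"])


def filter_low_expressed(pb: PseudoBulk, min_count: float = 10.0,
                         min_total: float = 15.0) -> np.ndarray:
    """Boolean mask of genes passing the expression filter.

    Keep a gene when its CPM exceeds ``min_count`` re-expressed on the
    median library size in at least as many profiles as the smallest group,
    and its total count is at least ``min_total``.
    """
    if len(pb.meta) < 2:
        raise ValueError("need at least two profiles")
    lib = pb.lib_sizes
    cpm = pb.Y / lib[:, None] * 1e6
    cutoff = min_count / (np.median(lib) / 1e6)
    n_min = int(pb.meta.groupby("group").size().min())
    return ((cpm >= cutoff).sum(axis=0) >= n_min) & (pb.Y.sum(axis=0) >= min_total)


def tmm_factors(pb: PseudoBulk, m_trim: float = 0.3, a_trim: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    Reference profile = the one whose 75th CPM percentile is closest to the
    mean across profiles; M and A values are doubly trimmed and averaged
    with inverse asymptotic-variance weights.
    """
    Y = pb.Y.astype(float)
    lib = Y.sum(axis=1)
    if (lib <= 0).any():
        raise ValueError("profile with zero total counts")
    f75 = np.array([np.quantile(y / l, 0.75) for y, l in zip(Y, lib)])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(len(Y))
    yr, lr = Y[ref], lib[ref]
    for i in range(len(Y)):
        if i == ref:
            continue
        y, l = Y[i], lib[i]
        ok = (y > 0) & (yr > 0)
        if not ok.any():
            continue
        M = np.log2((y[ok] / l) / (yr[ok] / lr))
        A = 0.5 * np.log2((y[ok] / l) * (yr[ok] / lr))
        w = (l - y[ok]) / (l * y[ok]) + (lr - yr[ok]) / (lr * yr[ok])
        keep = (
            (M >= np.quantile(M, m_trim)) & (M <= np.quantile(M, 1 - m_trim))
            & (A >= np.quantile(A, a_trim)) & (A <= np.quantile(A, 1 - a_trim))
        )
        if keep.any() and w[keep].sum() > 0:
            factors[i] = 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# NB likelihood machinery
# ---------------------------------------------------------------------------


def _fit_means(Y: np.ndarray, offsets: np.ndarray, phi: float, n_iter: int = 12):
    """Per-gene intercept MLE for NB with log link and fixed offsets.

    Y is profiles x genes; returns (beta per gene, mu profiles x genes,
    Fisher information per gene). Vectorized Fisher scoring.
    """
    tot = Y.sum(axis=0)
    beta = np.log(np.maximum(tot, 0.5) / np.exp(offsets).sum())
    eo = np.exp(offsets)[:, None]
    for _ in range(n_iter):
        mu = np.exp(beta)[None, :] * eo
        denom = 1.0 + phi * mu
        score = ((Y - mu) / denom).sum(axis=0)
        info = (mu / denom).sum(axis=0)
        step = np.where(info > 0, score / np.maximum(info, 1e-12), 0.0)
        beta = np.clip(beta + np.clip(step, -5, 5), -30.0, 30.0)
    mu = np.exp(beta)[None, :] * eo
    info = (mu / (1.0 + phi * mu)).sum(axis=0)
    return beta, mu, info


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-gene NB log-likelihood summed over profiles."""
    mu = np.maximum(mu, 1e-300)
    if phi <= 1e-8:
        return (Y * np.log(mu) - mu - gammaln(Y + 1.0)).sum(axis=0)
    r = 1.0 / phi
    return (
        gammaln(Y + r) - gammaln(r) - gammaln(Y + 1.0)
        + Y * np.log(phi * mu / (1.0 + phi * mu))
        - r * np.log1p(phi * mu)
    ).sum(axis=0)


def _adjusted_profile_ll(Y, offsets, groups, phi) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at dispersion phi."""
    ll = np.zeros(Y.shape[1])
    adj = np.zeros(Y.shape[1])
    for g in np.unique(groups):
        sel = groups == g
        _, mu, info = _fit_means(Y[sel], offsets[sel], phi)
        ll += _nb_loglik(Y[sel], mu, phi)
        adj += 0.5 * np.log(np.maximum(info, 1e-12))
    return ll - adj


def estimate_dispersion(
    pb: PseudoBulk,
    groups: np.ndarray | None = None,
    factors: np.ndarray | None = None,
    prior_weight: float = 10.0,
    grid: np.ndarray | None = None,
) -> dict:
    """Common and per-gene (shrunk) NB dispersions.

    The common dispersion maximizes the summed Cox-Reid adjusted profile
    likelihood over a log-spaced grid; per-gene dispersions maximize the
    gene's own adjusted likelihood plus ``prior_weight`` times the
    gene-averaged likelihood, which shrinks noisy estimates toward the
    common value.
    """
    groups = pb.meta["group"].to_numpy() if groups is None else np.asarray(groups)
    factors = np.ones(len(pb.meta)) if factors is None else factors
    offsets = np.log(pb.lib_sizes * factors)
    grid = np.logspace(-4, 0.9, 45) if grid is None else grid

    L = np.column_stack(
        [_adjusted_profile_ll(pb.Y, offsets, groups, phi) for phi in grid]
    )
    common = float(grid[int(np.argmax(L.sum(axis=0)))])
    Lbar = L.mean(axis=0)
    per_gene = grid[np.argmax(L + prior_weight * Lbar[None, :], axis=1)]
    per_gene = np.where(pb.Y.sum(axis=0) == 0, common, per_gene)
    return {"common": common, "per_gene": per_gene, "grid": grid}


def de_test(
    pb: PseudoBulk,
    factors: np.ndarray,
    dispersions: np.ndarray,
    contrast: tuple = ("DYS", "HC"),
    lfc_cutoff: float = 0.5,
    alpha: float = 0.05,
    genes_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio NB test of ``contrast[0]`` versus ``contrast[1]``.

    Full model: one intercept per group; null: pooled intercept; offsets
    log(library size x TMM factor); chi-square(1) p-values, BH adjustment,
    and the DEG flag |log2FC| > ``lfc_cutoff`` and adjusted p < ``alpha``.
    """
    groups = pb.meta["group"].to_numpy()
    use = np.isin(groups, contrast)
    Y = pb.Y[use]
    grp = groups[use]
    offsets = np.log(pb.lib_sizes[use] * np.asarray(factors)[use])
    if genes_mask is None:
        genes_mask = np.ones(len(pb.genes), bool)
    Yf = Y[:, genes_mask]
    phi = np.asarray(dispersions)[genes_mask]

    # Dispersions vary per gene: group genes by phi value (grid-valued) so
    # each fit stays vectorized.
    n_genes = Yf.shape[1]
    beta = {c: np.zeros(n_genes) for c in contrast}
    ll_full = np.zeros(n_genes)
    ll_null = np.zeros(n_genes)
    for ph in np.unique(phi):
        cols = phi == ph
        for c in contrast:
            sel = grp == c
            b, mu, _ = _fit_means(Yf[np.ix_(sel, cols)], offsets[sel], ph)
            beta[c][cols] = b
            ll_full[cols] += _nb_loglik(Yf[np.ix_(sel, cols)], mu, ph)
        _, mu0, _ = _fit_means(Yf[:, cols], offsets, ph)
        ll_null[cols] = _nb_loglik(Yf[:, cols], mu0, ph)

    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = chi2.sf(lrt, df=1)
    bad = ~np.isfinite(p)
    p[bad] = 1.0
    padj = bh_adjust(p)
    log2fc = (beta[contrast[0]] - beta[contrast[1]]) / np.log(2.0)
    df = pd.DataFrame(
        {
            "gene": pb.genes[genes_mask],
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "deg": (np.abs(log2fc) > lfc_cutoff) & (padj < alpha),
            "converged": ~bad,
        }
    )
    return df


def deg_overlap(deg_sets: dict) -> pd.DataFrame:
    """Exact exclusive/shared counts over every combination of DEG sets."""
    if len(deg_sets) < 2:
        raise ValueError("need at least two DEG sets")
    names = list(deg_sets)
    rows = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(set(deg_sets[n]) for n in combo))
            outside = set.union(
                set(), *(set(deg_sets[n]) for n in names if n not in combo)
            )
            rows.append(
                {"modules": "+".join(combo), "degree": k,
                 "exclusive": len(inside - outside), "intersection": len(inside)}
            )
    return pd.DataFrame(rows)
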