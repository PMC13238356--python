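"""Spot annotation by module scores and mixture-model thresholding.

Each QC-passing spot is assigned one label. Fat comes straight from the
histology masks; the rest are scored against a connective-tissue and a
muscle-fibers gene module (signature mean minus expression-matched control
mean), split into high/low by majority vote over repeated two-component
Gaussian-mixture EM fits, and assigned hierarchically: Fat > Connective
Tissue > Muscle > Not assigned. Muscle spots are then typed by the myosin
with the highest log-normalized expression (MYH7 -> Type I, MYH2 -> Type
IIa, MYH1 -> Type IIx).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spatial_core import NormalizedMatrix, RegionLabels

LABELS = (
    "Fat",
    "ConnectiveTissue",
    "TypeI",
    "TypeIIa",
    "TypeIIx",
    "MuscleUntyped",
    "NotAssigned",
)

MYOSIN_TYPES = (("MYH7", "TypeI"), ("MYH2", "TypeIIa"), ("MYH1", "TypeIIx"))

DEFAULT_MODULES = {
    "connective_tissue": ["COL1A1", "COL1A2", "THBS4"],
    "muscle_fibers": ["MYH1", "MYH2", "MYH7", "ACTA1", "TNNT3", "TNNT1", "MYL3"],
}


class UnimodalityError(ValueError):
    """Score distribution has no stable two-component structure."""


@dataclass
class ModuleDefinition:
    name: str
    genes: list


@dataclass
class BimodalSplit:
    high: np.ndarray             # bool per spot
    vote_fraction: np.ndarray    # share of runs calling the spot high
    n_runs: int
    threshold: float             # midpoint between flip-adjacent scores
    component_means: np.ndarray  # n_runs x 2


def module_score(
    norm: NormalizedMatrix,
    module: ModuleDefinition,
    nbin: int = 24,
    nctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Signature score per spot: module mean minus matched-control mean.

    Genes are ranked by their mean expression across spots and cut into
    ``nbin`` equal-size bins; each module gene contributes the difference
    between its expression and the mean of ``nctrl`` control genes drawn
    from its own bin, so the score is centered on zero under the null of
    no enrichment.
    """
    genes = list(norm.genes)
    if nbin > len(genes):
        raise ValueError(f"nbin={nbin} exceeds the {len(genes)} available genes")
    present = [g for g in module.genes if g in set(genes)]
    missing = set(module.genes) - set(present)
    if missing:
        warnings.warn(f"module {module.name}: dropping absent genes {sorted(missing)}")
    if not present:
        raise ValueError(f"module {module.name} has no genes in the matrix")

    rng = np.random.default_rng(seed)
    X = norm.dense()
    means = X.mean(axis=1)
    order = np.argsort(means, kind="mergesort")
    bin_of = np.empty(len(genes), dtype=int)
    for b, chunk in enumerate(np.array_split(order, nbin)):
        bin_of[chunk] = b
    gidx = {g: i for i, g in enumerate(genes)}

    score = np.zeros(X.shape[1])
    for g in present:
        i = gidx[g]
        pool = np.nonzero(bin_of == bin_of[i])[0]
        ctrl = rng.choice(pool, size=nctrl, replace=len(pool) < nctrl)
        score += X[i] - X[ctrl].mean(axis=0)
    return score / len(present)


# ---------------------------------------------------------------------------
# repeated-EM bimodal threshold
# ---------------------------------------------------------------------------


def _em_runs(x, mu, var, w, tol, max_steps):
    """Vectorized EM for R simultaneous 2-component 1D Gaussian mixtures.

    Returns (mu, resp_high, degenerate, ll) where resp_high is the
    posterior of the larger-mean component per run and spot and ll the
    final log-likelihood per run.
    """
    R, n = mu.shape[0], x.size
    ll_old = np.full(R, -np.inf)
    active = np.ones(R, bool)
    xx = x[None, :, None]
    for _ in range(max_steps):
        if not active.any():
            break
        m, v, p = mu[active], var[active], w[active]
        v = np.maximum(v, 1e-300)
        logd = (
            np.log(np.maximum(p, 1e-300))[:, None, :]
            - 0.5 * np.log(2 * np.pi * v)[:, None, :]
            - (xx - m[:, None, :]) ** 2 / (2 * v[:, None, :])
        )
        top = logd.max(axis=2, keepdims=True)
        norm = top[..., 0] + np.log(np.exp(logd - top).sum(axis=2))
        ll = norm.sum(axis=1)
        resp = np.exp(logd - norm[..., None])
        Nk = resp.sum(axis=1)
        p_new = Nk / n
        mu_new = (resp * xx).sum(axis=1) / np.maximum(Nk, 1e-300)
        var_new = (resp * (xx - mu_new[:, None, :]) ** 2).sum(axis=1) / np.maximum(
            Nk, 1e-300
        )
        mu[active], var[active], w[active] = mu_new, var_new, p_new
        conv = np.abs(ll - ll_old[active]) < tol * (np.abs(ll_old[active]) + 1e-12)
        ll_old[active] = ll
        idx = np.nonzero(active)[0]
        active[idx[conv]] = False
    degenerate = (var.min(axis=1) < 1e-12) | (w.min(axis=1) < 0.01)
    # runs stuck on the symmetric saddle (components collapsed onto each
    # other) carry no split information either
    degenerate |= np.abs(mu[:, 0] - mu[:, 1]) < 1e-9 * max(x.std(), 1e-300)
    # posterior of the larger-mean component, for all runs at final params
    hi = np.argmax(mu, axis=1)
    v = np.maximum(var, 1e-300)
    logd = (
        np.log(np.maximum(w, 1e-300))[:, None, :]
        - 0.5 * np.log(2 * np.pi * v)[:, None, :]
        - (x[None, :, None] - mu[:, None, :]) ** 2 / (2 * v[:, None, :])
    )
    top = logd.max(axis=2, keepdims=True)
    norm = top[..., 0] + np.log(np.exp(logd - top).sum(axis=2))
    resp = np.exp(logd - norm[..., None])
    resp_high = resp[np.arange(len(mu)), :, hi]
    return mu, resp_high, degenerate, norm.sum(axis=1)


def bimodal_threshold(
    scores: np.ndarray,
    n_iter: int = 500,
    seed: int = 0,
    tol: float = 1e-8,
    max_em_steps: int = 300,
) -> BimodalSplit:
    """High/low split by majority vote over repeated mixture-EM fits.

    Each run initializes the two means at random data quantiles, both
    variances at the data variance and weights at 1/2, runs EM to a
    relative log-likelihood change below ``tol``, and MAP-classifies each
    spot against the larger-mean component. Runs that collapse (a variance
    below 1e-12, a weight below 0.01, or both means coincident) are
    discarded and redrawn, up to five times ``n_iter`` attempts; if every
    attempt collapses the scores are deemed unimodal and an
    :class:`UnimodalityError` is raised. Runs stuck in clearly inferior
    local optima (final log-likelihood more than ``ll_margin`` nats below
    the best run) do not vote, so the vote reflects the consensus of the
    best-likelihood solution family.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 spots to fit a mixture")
    if np.var(x) <= 0:
        raise UnimodalityError("scores are constant")
    ll_margin = 2.0

    rng = np.random.default_rng(seed)
    all_high, all_mu, all_ll = [], [], []
    n_valid, attempts = 0, 0
    while n_valid < n_iter and attempts < 5 * n_iter:
        batch = min(n_iter - n_valid, 5 * n_iter - attempts)
        attempts += batch
        q = rng.random((batch, 2))
        mu = np.stack([np.quantile(x, q[:, 0]), np.quantile(x, q[:, 1])], axis=1)
        var = np.full((batch, 2), np.var(x))
        w = np.full((batch, 2), 0.5)
        mu, resp_high, degen, ll = _em_runs(x, mu, var, w, tol, max_em_steps)
        good = ~degen
        if good.any():
            all_high.append(resp_high[good] > 0.5)
            all_mu.append(mu[good])
            all_ll.append(ll[good])
            n_valid += int(good.sum())
    if n_valid == 0:
        raise UnimodalityError("all mixture fits collapsed; scores look unimodal")

    high_runs = np.vstack(all_high)
    ll = np.concatenate(all_ll)
    comp_means = [np.vstack(all_mu)]
    voters = ll >= ll.max() - ll_margin
    vote_fraction = high_runs[voters].mean(axis=0)
    high = vote_fraction > 0.5
    if high.any() and (~high).any():
        threshold = 0.5 * (x[~high].max() + x[high].min())
    else:
        threshold = float("nan")
    return BimodalSplit(high, vote_fraction, n_valid, threshold,
                        np.vstack(comp_means))


# ---------------------------------------------------------------------------
# hierarchical assignment
# ---------------------------------------------------------------------------


def assign_modules(
    barcodes,
    fat_labels: RegionLabels,
    ct_high: dict,
    muscle_high: dict,
) -> dict:
    """Hierarchical label per spot: Fat > ConnectiveTissue > Muscle > NA.

    ``ct_high`` / ``muscle_high`` map non-fat barcodes to their high/low
    split; "Muscle" is an interim label refined by
    :func:`assign_fiber_types`.
    """
    out = {}
    for b in barcodes:
        if fat_labels.get(b) == "fat":
            out[b] = "Fat"
            continue
        if b not in ct_high or b not in muscle_high:
            raise ValueError(f"missing module split for spot {b}")
        if ct_high[b]:
            out[b] = "ConnectiveTissue"
        elif muscle_high[b]:
            out[b] = "Muscle"
        else:
            out[b] = "NotAssigned"
    return out


def assign_fiber_types(norm: NormalizedMatrix, annotation: dict) -> dict:
    """Type interim Muscle spots by the highest myosin expression.

    Ties break by priority Type I > Type IIa > Type IIx; spots with all
    three myosins at zero become MuscleUntyped. A missing myosin gene makes
    its fiber type unreachable (warned, treated as zero).
    """
    expr = {}
    for gene, _ in MYOSIN_TYPES:
        if gene in set(norm.genes):
            expr[gene] = norm.gene_vector(gene)
        else:
            warnings.warn(f"myosin {gene} absent; its fiber type is unreachable")
            expr[gene] = np.zeros(len(norm.barcodes))
    bidx = {b: i for i, b in enumerate(norm.barcodes)}
    out = dict(annotation)
    for b, lab in annotation.items():
        if lab != "Muscle":
            continue
        i = bidx[b]
        vals = [expr[g][i] for g, _ in MYOSIN_TYPES]
        if max(vals) <= 0:
            out[b] = "MuscleUntyped"
        else:
            out[b] = MYOSIN_TYPES[int(np.argmax(vals))][1]  # argmax = first max
    return out


def annotate_sample(
    norm: NormalizedMatrix,
    region_labels: RegionLabels,
    modules: dict | None = None,
    nbin: int = 24,
    nctrl: int = 100,
    n_iter: int = 500,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Full annotation of one QC-passed sample.

    Returns (annotation, details) where details holds per-module scores and
    splits. Module thresholds are fitted on non-fat spots only; a module
    whose scores are unimodal sends every spot to its low group.
    """
    modules = modules or DEFAULT_MODULES
    nonfat = [b for b in norm.barcodes if region_labels.get(b) != "fat"]
    nf_mask = np.array([region_labels.get(b) != "fat" for b in norm.barcodes])
    details = {}
    highs = {}
    for i, (name, genes) in enumerate(modules.items()):
        score = module_score(
            norm, ModuleDefinition(name, list(genes)), nbin, nctrl,
            seed=seed + 7919 * i,
        )
        try:
            split = bimodal_threshold(score[nf_mask], n_iter=n_iter, seed=seed + i)
            high = dict(zip(nonfat, split.high))
        except UnimodalityError:
            split = None
            high = {b: False for b in nonfat}
        details[name] = {"score": dict(zip(norm.barcodes, score)), "split": split}
        highs[name] = high
    ct_name, muscle_name = list(modules)[0], list(modules)[1]
    ann = assign_modules(norm.barcodes, region_labels, highs[ct_name], highs[muscle_name])
    ann = assign_fiber_types(norm, ann)
    return ann, details


def composition(annotations: dict, groups: dict) -> pd.DataFrame:
    """Per-sample label percentages (rows sum to 100).

    ``annotations`` maps sample -> {barcode: label}; ``groups`` maps
    sample -> cohort label.
    """
    rows = []
    for sample, ann in annotations.items():
        if not ann:
            raise ValueError(f"sample {sample} has no annotated spots")
        n = len(ann)
        counts = pd.Series(list(ann.values())).value_counts()
        row = {"sample": sample, "group": groups[sample]}
        for lab in LABELS:
            row[lab] = 100.0 * counts.get(lab, 0) / n
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    values: np.ndarray,
    groups: np.ndarray,
    group_pair: tuple = ("HC", "DYS"),
    sides: str = "two",
) -> tuple[float, float]:
    """Pooled-variance t-test on arcsine-square-root transformed percentages.

    ``values`` are percentages in [0, 100]; the transform
    y = arcsin(sqrt(pct/100)) stabilizes the variance of proportions. With
    ``sides="one"`` the alternative is mean(first group) > mean(second).
    """
    values = np.asarray(values, dtype=float)
    if ((values < 0) | (values > 100)).any():
        raise ValueError("percentages must lie in [0, 100]")
    groups = np.asarray(groups)
    a = values[groups == group_pair[0]]
    b = values[groups == group_pair[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two samples per group")
    ya, yb = np.arcsin(np.sqrt(a / 100.0)), np.arcsin(np.sqrt(b / 100.0))
    if ya.var(ddof=1) + yb.var(ddof=1) == 0:
        # degenerate pooled variance: identical-group convention
        if ya.mean() == yb.mean():
            return 0.0, 1.0
        t = math.copysign(math.inf, ya.mean() - yb.mean())
        return t, 0.0 if (sides == "two" or t > 0) else 1.0
    alternative = "two-sided" if sides == "two" else "greater"
    res = stats.ttest_ind(ya, yb, equal_var=True, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
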