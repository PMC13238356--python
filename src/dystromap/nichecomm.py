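"""Fat-adjacent niche layering, ligand-receptor scoring, tensor factorization.

Fat-annotated spots form layer L0; successive hex-lattice rings form L1-L3
and everything farther is unassigned. Within each context (sample x
adjacent layer pair: L0-L1, L1-L2, L2-L3) communication between dominant
cell types is scored per ligand-receptor pair as the mean of the sender-side
ligand and receiver-side receptor expression (multi-subunit genes enter via
the minimum subunit value). Two filters mirror the niche logic: both
ligand and receptor must be expressed in at least 60% of their spots, and
the pair's mean expression over the fat-adjacent layers must be at least
two-fold that over the unassigned tissue. Retained scores fill a
contexts x pairs x senders x receivers tensor which a masked non-negative
CP (canonical polyadic) alternating-least-squares decomposition reduces to
interpretable communication programs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.linalg import cholesky, solve
from scipy.optimize import nnls

from .spatial_core import NormalizedMatrix

LAYER_PAIRS = (("L0", "L1"), ("L1", "L2"), ("L2", "L3"))


@dataclass
class LRPair:
    ligand_subunits: list
    receptor_subunits: list

    def __post_init__(self) -> None:
        if not self.ligand_subunits or not self.receptor_subunits:
            raise ValueError("L-R pair needs at least one subunit on each side")

    @property
    def pair_id(self) -> str:
        return "_".join(self.ligand_subunits) + "^" + "_".join(self.receptor_subunits)


def read_lr_table(path) -> list:
    """TSV with columns ligand, receptor; subunits joined by '_'."""
    df = pd.read_csv(path, sep="\t")
    return [
        LRPair(str(l).split("_"), str(r).split("_"))
        for l, r in zip(df["ligand"], df["receptor"])
    ]


@dataclass
class CCCTensor:
    values: np.ndarray           # contexts x pairs x senders x receivers
    mask: np.ndarray             # True where a score is defined
    contexts: list
    pairs: list
    senders: list
    receivers: list


@dataclass
class CPFactors:
    rank: int
    factors: list                # four non-negative matrices
    rel_error: float
    loss_history: list


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def build_layers(adjacency: dict, fat_labels: dict, n_layers: int = 3) -> dict:
    """Breadth-first rings from the fat set on the spot adjacency graph."""
    layers = {b: "unassigned" for b in adjacency}
    fat = {b for b in adjacency if fat_labels.get(b) == "fat"}
    if not fat:
        warnings.warn("no fat spots; all spots left unassigned")
        return layers
    for b in fat:
        layers[b] = "L0"
    frontier, seen = set(fat), set(fat)
    for k in range(1, n_layers + 1):
        frontier = {nb for b in frontier for nb in adjacency[b]} - seen
        for b in frontier:
            layers[b] = f"L{k}"
        seen |= frontier
    return layers


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _subunit_min(norm: NormalizedMatrix, subunits: list) -> np.ndarray | None:
    present = set(norm.genes)
    if any(g not in present for g in subunits):
        return None
    return np.min([norm.gene_vector(g) for g in subunits], axis=0)


def ccc_scores(
    norm: NormalizedMatrix,
    layers: dict,
    dominant,
    pairs: list,
    sample: str,
    layer_pairs: tuple = LAYER_PAIRS,
    min_spots: int = 3,
) -> pd.DataFrame:
    """Communication records for one sample across adjacent-layer contexts.

    For every (sender, receiver) dominant-type combination with at least
    ``min_spots`` spots each inside the context's two layers:
    score = (mean ligand over sender spots + mean receptor over receiver
    spots) / 2. Pair-level niche enrichment columns (mean over L1-L3 spots
    vs unassigned spots) are attached for :func:`filter_lr`. Pairs with an
    absent subunit gene are skipped (logged in ``df.attrs["skipped"]``).
    """
    dom = dict(dominant) if not isinstance(dominant, dict) else dominant
    barcodes = list(norm.barcodes)
    lay = np.array([layers.get(b, "unassigned") for b in barcodes])
    types = np.array([dom.get(b, "ambiguous") for b in barcodes], dtype=object)
    niche_mask = np.isin(lay, ["L1", "L2", "L3"])
    ref_mask = lay == "unassigned"

    rows, skipped = [], []
    for pair in pairs:
        el = _subunit_min(norm, pair.ligand_subunits)
        er = _subunit_min(norm, pair.receptor_subunits)
        if el is None or er is None:
            skipped.append(pair.pair_id)
            continue
        combined = 0.5 * (el + er)
        niche_mean = float(combined[niche_mask].mean()) if niche_mask.any() else 0.0
        ref_mean = float(combined[ref_mask].mean()) if ref_mask.any() else 0.0
        for la, lb in layer_pairs:
            in_ctx = (lay == la) | (lay == lb)
            if not in_ctx.any():
                continue
            ctx_types = types[in_ctx]
            counts = pd.Series(ctx_types).value_counts()
            eligible = [t for t, c in counts.items() if c >= min_spots and t != "ambiguous"]
            for s in eligible:
                s_mask = in_ctx & (types == s)
                mu_l = float(el[s_mask].mean())
                frac_l = float((el[s_mask] > 0).mean())
                for r in eligible:
                    r_mask = in_ctx & (types == r)
                    mu_r = float(er[r_mask].mean())
                    frac_r = float((er[r_mask] > 0).mean())
                    rows.append(
                        {
                            "sample": sample,
                            "layer_pair": f"{la}-{lb}",
                            "pair_id": pair.pair_id,
                            "sender": s,
                            "receiver": r,
                            "score": 0.5 * (mu_l + mu_r),
                            "ligand_frac": frac_l,
                            "receptor_frac": frac_r,
                            "niche_mean": niche_mean,
                            "ref_mean": ref_mean,
                        }
                    )
    df = pd.DataFrame(
        rows,
        columns=[
            "sample", "layer_pair", "pair_id", "sender", "receiver",
            "score", "ligand_frac", "receptor_frac", "niche_mean", "ref_mean",
        ],
    )
    df.attrs["skipped"] = skipped
    return df


def filter_lr(
    records: pd.DataFrame, prop_min: float = 0.6, fold_min: float = 2.0
) -> pd.DataFrame:
    """Apply the expression-fraction and niche-enrichment filters.

    Both thresholds are inclusive. A zero reference mean with a nonzero
    niche mean counts as infinite enrichment and passes.
    """
    frac_ok = (records["ligand_frac"] >= prop_min) & (
        records["receptor_frac"] >= prop_min
    )
    ref = records["ref_mean"].to_numpy()
    niche = records["niche_mean"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(ref > 0, niche / np.maximum(ref, 1e-300), np.inf)
    fold_ok = np.where(ref > 0, fold >= fold_min, niche > 0)
    out = records[frac_ok & fold_ok].copy()
    out["niche_fold"] = fold[frac_ok & fold_ok]
    return out


def build_tensor(records: pd.DataFrame) -> CCCTensor:
    """Assemble retained records into the 4-way communication tensor."""
    if len(records) == 0:
        raise ValueError("no records to build a tensor from")
    contexts = sorted(set(zip(records["sample"], records["layer_pair"])))
    contexts = [f"{s}|{lp}" for s, lp in contexts]
    pairs = sorted(records["pair_id"].unique())
    senders = sorted(records["sender"].unique())
    receivers = sorted(records["receiver"].unique())
    shape = (len(contexts), len(pairs), len(senders), len(receivers))
    values = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    ci = {c: i for i, c in enumerate(contexts)}
    pi = {p: i for i, p in enumerate(pairs)}
    si = {s: i for i, s in enumerate(senders)}
    ri = {r: i for i, r in enumerate(receivers)}
    for rec in records.itertuples():
        idx = (ci[f"{rec.sample}|{rec.layer_pair}"], pi[rec.pair_id],
               si[rec.sender], ri[rec.receiver])
        values[idx] = rec.score
        mask[idx] = True
    return CCCTensor(values, mask, contexts, pairs, senders, receivers)


# ---------------------------------------------------------------------------
# masked non-negative CP decomposition
# ---------------------------------------------------------------------------


def _unfold(X: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def _khatri_rao(mats: list) -> np.ndarray:
    """Column-wise Kronecker product, first matrix varying slowest."""
    out = mats[0]
    for M in mats[1:]:
        out = (out[:, None, :] * M[None, :, :]).reshape(-1, M.shape[1])
    return out


def _reconstruct(factors: list) -> np.ndarray:
    A, B, C, D = factors
    return np.einsum("ir,jr,kr,lr->ijkl", A, B, C, D)


def cp_decompose(
    tensor: CCCTensor | np.ndarray,
    rank: int = 15,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    mask: np.ndarray | None = None,
) -> CPFactors:
    """Masked non-negative CP via alternating non-negative least squares.

    Undefined entries are imputed with the current reconstruction at the
    start of each iteration (EM-style), after which each factor matrix is
    refit exactly by per-row NNLS on the completed tensor; the loss on the
    defined entries is therefore non-increasing. Random uniform
    initialization from ``seed``; stops when the relative loss change
    drops below ``tol``.
    """
    if isinstance(tensor, CCCTensor):
        X, mask = tensor.values, tensor.mask
    else:
        X = np.asarray(tensor, dtype=float)
        mask = np.ones(X.shape, dtype=bool) if mask is None else mask
    if rank < 1:
        raise ValueError("rank must be >= 1")
    for m, dim in enumerate(X.shape):
        other = int(np.prod(X.shape) // dim)
        if rank > other:
            raise ValueError(
                f"rank {rank} exceeds the mode-{m} least-squares bound {other}"
            )

    rng = np.random.default_rng(seed)
    factors = [rng.uniform(0.1, 1.0, size=(dim, rank)) for dim in X.shape]
    norm_def = float(np.sqrt((X[mask] ** 2).sum()))
    norm_def = norm_def if norm_def > 0 else 1.0

    def defined_loss(recon):
        return float(np.sqrt(((X - recon)[mask] ** 2).sum()))

    recon = _reconstruct(factors)
    loss_history = [defined_loss(recon)]
    for _ in range(max_iter):
        Xc = np.where(mask, X, recon)
        for m in range(4):
            others = [factors[j] for j in range(4) if j != m]
            Z = _khatri_rao(others)
            G = np.ones((rank, rank))
            for A in others:
                G *= A.T @ A
            P = _unfold(Xc, m) @ Z
            M = cholesky(G + 1e-12 * np.eye(rank)).T  # upper triangular
            rhs = solve(M.T, P.T)                      # rank x I_m
            factors[m] = np.vstack(
                [nnls(M, rhs[:, i])[0] for i in range(P.shape[0])]
            )
        recon = _reconstruct(factors)
        loss_history.append(defined_loss(recon))
        if abs(loss_history[-2] - loss_history[-1]) < tol * (loss_history[-2] + 1e-12):
            break
    return CPFactors(rank, factors, loss_history[-1] / norm_def, loss_history)
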