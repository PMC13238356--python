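from collections import deque

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from dystromap import nichecomm as nc
from dystromap import spatial_core as sc
from dystromap import synthgen as sg


def layers_oracle(grid, fat_barcodes, n_layers=3):
    """Independent BFS over the 100-um distance graph."""
    xy = np.column_stack([grid.x_um, grid.y_um])
    bidx = {b: i for i, b in enumerate(grid.barcodes)}
    dist = {b: 0 for b in fat_barcodes}
    q = deque(fat_barcodes)
    while q:
        b = q.popleft()
        if dist[b] == n_layers:
            continue
        d = np.sqrt(((xy - xy[bidx[b]]) ** 2).sum(1))
        for j in np.nonzero(np.abs(d - 100.0) < 1e-6)[0]:
            nb = grid.barcodes[j]
            if nb not in dist:
                dist[nb] = dist[b] + 1
                q.append(nb)
    return {b: (f"L{dist[b]}" if b in dist else "unassigned") for b in grid.barcodes}


class TestBuildLayers:
    def test_single_fat_spot_ring_sizes(self):
        grid = sg.full_lattice(9, 18)
        adj = sc.hex_neighbors(grid)
        center = [b for b, r, c in zip(grid.barcodes, grid.array_row, grid.array_col)
                  if (r, c) == (4, 8)][0]
        layers = nc.build_layers(adj, {center: "fat"})
        sizes = pd.Series(list(layers.values())).value_counts()
        assert sizes["L0"] == 1 and sizes["L1"] == 6
        assert sizes["L2"] == 12 and sizes["L3"] == 18

    def test_two_adjacent_fat_spots(self):
        grid = sg.full_lattice(9, 18)
        adj = sc.hex_neighbors(grid)
        pos = {(int(r), int(c)): b for b, r, c in
               zip(grid.barcodes, grid.array_row, grid.array_col)}
        fat = {pos[(4, 8)]: "fat", pos[(4, 10)]: "fat"}
        layers = nc.build_layers(adj, fat)
        l1 = {b for b, l in layers.items() if l == "L1"}
        expected = (adj[pos[(4, 8)]] | adj[pos[(4, 10)]]) - set(fat)
        assert l1 == expected

    def test_fat_free_sample_unassigned(self):
        grid = sg.full_lattice(5, 10)
        with pytest.warns(UserWarning, match="no fat"):
            layers = nc.build_layers(sc.hex_neighbors(grid), {})
        assert set(layers.values()) == {"unassigned"}

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_and_distance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        full = sg.full_lattice(14, 28)
        pick = np.sort(rng.choice(full.n_spots, size=120, replace=False))
        grid = full.subset(full.barcodes[pick])
        fat = list(rng.choice(grid.barcodes, size=3, replace=False))
        layers = nc.build_layers(sc.hex_neighbors(grid), dict.fromkeys(fat, "fat"))
        assert set(layers) == set(grid.barcodes)  # partition covers all spots
        assert layers == layers_oracle(grid, fat)


def norm_of(X, genes, barcodes):
    return sc.NormalizedMatrix(genes, barcodes, sp.csr_matrix(np.asarray(X, float)))


class TestCCCScores:
    def setup_method(self):
        # 12 spots: 4 in L0, 4 in L1, 4 unassigned
        self.barcodes = [f"s{i}" for i in range(12)]
        self.layers = {b: ("L0" if i < 4 else "L1" if i < 8 else "unassigned")
                       for i, b in enumerate(self.barcodes)}
        self.dom = {b: ("adipocytes" if i < 4 else "faps")
                    for i, b in enumerate(self.barcodes)}

    def test_constant_expression_score(self):
        X = np.zeros((2, 12))
        X[0] = 2.0  # ligand everywhere
        X[1] = 4.0  # receptor everywhere
        norm = norm_of(X, ["LG", "RC"], self.barcodes)
        recs = nc.ccc_scores(norm, self.layers, self.dom, [nc.LRPair(["LG"], ["RC"])], "s")
        row = recs[(recs.sender == "adipocytes") & (recs.receiver == "faps")
                   & (recs.layer_pair == "L0-L1")].iloc[0]
        assert row["score"] == pytest.approx((2.0 + 4.0) / 2)
        assert row["ligand_frac"] == 1.0 and row["receptor_frac"] == 1.0

    def test_receptor_subunit_minimum(self):
        X = np.zeros((3, 12))
        X[0] = 2.0
        X[1] = 1.0  # subunit a
        X[2] = 3.0  # subunit b -> complex expression is min = 1.0
        norm = norm_of(X, ["LG", "RCA", "RCB"], self.barcodes)
        recs = nc.ccc_scores(norm, self.layers, self.dom,
                             [nc.LRPair(["LG"], ["RCA", "RCB"])], "s")
        row = recs[(recs.sender == "adipocytes") & (recs.receiver == "faps")].iloc[0]
        assert row["score"] == pytest.approx((2.0 + 1.0) / 2)

    def test_min_spot_rule(self):
        dom = dict(self.dom)
        dom["s0"] = dom["s1"] = "rare"  # only 2 rare spots -> no records for it
        norm = norm_of(np.ones((2, 12)), ["LG", "RC"], self.barcodes)
        recs = nc.ccc_scores(norm, self.layers, dom, [nc.LRPair(["LG"], ["RC"])], "s")
        assert "rare" not in set(recs["sender"]) | set(recs["receiver"])

    def test_absent_gene_pair_skipped(self):
        norm = norm_of(np.ones((1, 12)), ["LG"], self.barcodes)
        recs = nc.ccc_scores(norm, self.layers, self.dom,
                             [nc.LRPair(["LG"], ["MISSING"])], "s")
        assert len(recs) == 0
        assert recs.attrs["skipped"] == ["LG^MISSING"]


class TestFilterLR:
    def base_record(self, **kw):
        rec = {"sample": "s", "layer_pair": "L0-L1", "pair_id": "p", "sender": "a",
               "receiver": "b", "score": 1.0, "ligand_frac": 0.8,
               "receptor_frac": 0.8, "niche_mean": 2.0, "ref_mean": 1.0}
        rec.update(kw)
        return rec

    @pytest.mark.parametrize(
        "kw,kept",
        [
            (dict(ligand_frac=0.60, receptor_frac=0.75, niche_mean=2.0, ref_mean=1.0), True),
            (dict(ligand_frac=0.59), False),
            (dict(receptor_frac=0.59), False),
            (dict(niche_mean=1.9, ref_mean=1.0), False),
            (dict(niche_mean=2.0, ref_mean=1.0), True),       # exactly two-fold
            (dict(niche_mean=0.5, ref_mean=0.0), True),       # infinite enrichment
            (dict(niche_mean=0.0, ref_mean=0.0), False),
        ],
    )
    def test_boundaries_inclusive(self, kw, kept):
        records = pd.DataFrame([self.base_record(**kw)])
        out = nc.filter_lr(records)
        assert (len(out) == 1) is kept


class TestBuildTensor:
    def test_seven_samples_three_layerpairs_give_21_contexts(self):
        rows = []
        for s in range(7):
            for lp in ("L0-L1", "L1-L2", "L2-L3"):
                rows.append({"sample": f"d{s}", "layer_pair": lp, "pair_id": "p",
                             "sender": "a", "receiver": "b", "score": 1.0})
        tensor = nc.build_tensor(pd.DataFrame(rows))
        assert len(tensor.contexts) == 21
        assert tensor.values.shape == (21, 1, 1, 1)

    def test_single_record_single_defined_entry(self):
        df = pd.DataFrame([{"sample": "s", "layer_pair": "L0-L1", "pair_id": "p",
                            "sender": "a", "receiver": "b", "score": 2.5}])
        tensor = nc.build_tensor(df)
        assert tensor.mask.sum() == 1
        assert tensor.values[tensor.mask][0] == 2.5

    def test_axis_labels_sorted_unique(self):
        rows = [
            {"sample": "s", "layer_pair": "L1-L2", "pair_id": "q", "sender": "b",
             "receiver": "a", "score": 1.0},
            {"sample": "s", "layer_pair": "L0-L1", "pair_id": "p", "sender": "a",
             "receiver": "b", "score": 2.0},
        ]
        tensor = nc.build_tensor(pd.DataFrame(rows))
        assert tensor.contexts == ["s|L0-L1", "s|L1-L2"]
        assert tensor.pairs == ["p", "q"]
        assert tensor.senders == ["a", "b"]


class TestCPDecompose:
    def test_rank_one_recovery(self):
        rng = np.random.default_rng(0)
        a, b, c, d = (rng.uniform(0.2, 1.0, s) for s in (6, 10, 4, 4))
        X = np.einsum("i,j,k,l->ijkl", a, b, c, d)
        fac = nc.cp_decompose(X, rank=1, seed=0)
        assert fac.rel_error < 1e-4

    def test_loss_non_increasing(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (5, 8, 3, 3))
        mask = rng.random(X.shape) > 0.3
        fac = nc.cp_decompose(X, rank=3, seed=2, mask=mask, max_iter=60)
        assert (np.diff(fac.loss_history) <= 1e-9 * (1 + fac.loss_history[0])).all()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (4, 6, 3, 3))
        f1 = nc.cp_decompose(X, rank=2, seed=7, max_iter=20)
        f2 = nc.cp_decompose(X, rank=2, seed=7, max_iter=20)
        for A, B in zip(f1.factors, f2.factors):
            np.testing.assert_array_equal(A, B)

    def test_rank_bound_rejected(self):
        X = np.ones((2, 2, 2, 2))
        with pytest.raises(ValueError, match="rank"):
            nc.cp_decompose(X, rank=9)

    def test_masked_low_rank_recovery_near_noise_floor(self):
        rng = np.random.default_rng(4)
        A = [rng.uniform(0, 1, (s, 3)) for s in (8, 20, 5, 5)]
        X = np.einsum("ir,jr,kr,lr->ijkl", *A)
        noise = 0.05 * X.std() * rng.standard_normal(X.shape)
        mask = rng.random(X.shape) > 0.2
        fac = nc.cp_decompose(X + noise, rank=3, seed=5, mask=mask)
        floor = np.sqrt((noise[mask] ** 2).sum()) / np.sqrt(((X + noise)[mask] ** 2).sum())
        assert fac.rel_error <= 2 * floor


class TestNicheRecovery:
    def test_planted_pair_survives_and_ranks_top5(self, reference, profiles):
        """An 8x over-expressed fat-niche L-R pair is found in >= 9/10 tissues."""
        ref, mt = reference
        _, prof = profiles
        pairs = [nc.LRPair(["LPL"], ["LRP1"])] + [
            nc.LRPair([l], [r]) for l, r in
            [("VIM", "CD44"), ("APP", "VLDLR"), ("APOE", "VLDLR"), ("MIF", "CD74")]
        ]
        from dystromap import deconv as dc

        hits = 0
        for seed in range(10):
            cfg = sg.TissueConfig(
                n_rows=14, n_cols=28, fat_patches=((7, 7, 2),), group="DYS",
                seed=100 + seed,
                lr_niche_pairs=(sg.NichePlant("LPL", "LRP1", "adipocytes", "faps"),),
            )
            cm, grid, labels, truth = sg.make_tissue(cfg, ref, mt)
            filtered, _, _ = sc.qc_filter(cm, labels)
            norm = sc.log_normalize(filtered)
            adj = sc.hex_neighbors(grid.subset(norm.barcodes))
            layers = nc.build_layers(adj, labels)
            res = dc.deconvolve(norm, prof, adj, lam=0.1)
            recs = nc.ccc_scores(norm, layers, res.dominant.to_dict(), pairs, "t")
            kept = nc.filter_lr(recs)
            planted = kept[(kept.pair_id == "LPL^LRP1")
                           & (kept.sender == "adipocytes") & (kept.receiver == "faps")]
            if len(planted) == 0:
                continue
            ctx = planted.iloc[0]["layer_pair"]
            in_ctx = kept[kept.layer_pair == ctx].sort_values("score", ascending=False)
            if planted.index[0] in in_ctx.index[:5]:
                hits += 1
        assert hits >= 9
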