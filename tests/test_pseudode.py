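from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from dystromap import pseudode as pdm
from dystromap import spatial_core as sc


def bh_bruteforce(p):
    """Independent step-up implementation straight from the definition."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_stepup_example(self):
        # every raw p adjusts up to the largest downstream p*n/rank = 0.04
        np.testing.assert_allclose(
            pdm.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_exactly(self, p):
        got = pdm.bh_adjust(np.array(p))
        np.testing.assert_array_equal(got, np.array(bh_bruteforce(p)))


def make_sample(name, group, X, labels=None):
    genes = [f"g{i}" for i in range(X.shape[0])]
    barcodes = [f"{name}-b{i}" for i in range(X.shape[1])]
    cm = sc.CountMatrix(genes, barcodes, sp.csr_matrix(X))
    ann = None if labels is None else dict(zip(barcodes, labels))
    return (name, group, cm, ann)


class TestAggregate:
    def test_sums_and_small_cluster_exclusion(self):
        X = np.array([[1, 3] + [0] * 10, [2, 4] + [1] * 10])
        labels = ["big"] * 11 + ["small"]
        pb, dropped = pdm.aggregate_pseudobulk(
            [make_sample("s1", "HC", X, labels)], level="module"
        )
        assert list(pb.meta["cluster"]) == ["big"]
        assert dropped.iloc[0]["cluster"] == "small"
        assert dropped.iloc[0]["n_spots"] == 1

    def test_two_spot_sum(self):
        X = np.array([[1, 3], [2, 4]])
        pb, _ = pdm.aggregate_pseudobulk(
            [make_sample("s1", "HC", X)], level="sample", min_spots=1
        )
        np.testing.assert_array_equal(pb.Y[0], [4, 6])

    def test_count_conservation(self, dys_tissue):
        cm = dys_tissue["filtered"]
        labels = {b: ("A" if i % 3 else "B") for i, b in enumerate(cm.barcodes)}
        pb, dropped = pdm.aggregate_pseudobulk(
            [("s", "DYS", cm, labels)], level="module", min_spots=1
        )
        assert pb.Y.sum() == cm.X.sum()

    def test_all_dropped_rejected(self):
        X = np.ones((2, 3), dtype=int)
        with pytest.raises(ValueError, match="profile"):
            pdm.aggregate_pseudobulk([make_sample("s1", "HC", X)], level="sample",
                                     min_spots=10)


def random_pseudobulk(rng, n=6, G=50, groups=("HC",) * 3 + ("DYS",) * 3):
    Y = rng.poisson(rng.uniform(0, 60, size=(n, G))).astype(np.int64)
    Y[:, 0] += 1  # avoid all-zero libraries
    meta = pd.DataFrame({
        "profile_id": [f"p{i}" for i in range(n)], "sample": [f"s{i}" for i in range(n)],
        "cluster": "all", "group": list(groups), "n_spots": 50,
    })
    return pdm.PseudoBulk(np.array([f"g{i}" for i in range(G)], dtype=object), Y, meta)


class TestFilterLowExpressed:
    def test_zero_gene_dropped(self):
        rng = np.random.default_rng(0)
        pb = random_pseudobulk(rng)
        pb.Y[:, 5] = 0
        assert not pdm.filter_low_expressed(pb)[5]

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            pb = random_pseudobulk(rng)
            got = pdm.filter_low_expressed(pb)
            lib = pb.Y.sum(1)
            cutoff = 10.0 / (np.median(lib) / 1e6)
            cpm = pb.Y / lib[:, None] * 1e6
            n_min = 3
            want = ((cpm >= cutoff).sum(0) >= n_min) & (pb.Y.sum(0) >= 15)
            np.testing.assert_array_equal(got, want)

    def test_boundary_gene_kept(self):
        # gene exactly at the CPM cutoff in exactly n_min profiles, total >= 15
        Y = np.zeros((4, 3), dtype=np.int64)
        Y[:, 0] = 1_000_000  # library anchor
        Y[:2, 0] -= 10       # keep every library at exactly 1e6
        Y[:2, 1] = 10        # CPM exactly 10 = cutoff for median lib 1e6
        meta = pd.DataFrame({"profile_id": list("abcd"), "sample": list("abcd"),
                             "cluster": "all", "group": ["HC", "HC", "DYS", "DYS"],
                             "n_spots": 50})
        pb = pdm.PseudoBulk(np.array(["anchor", "edge", "zero"], dtype=object), Y, meta)
        keep = pdm.filter_low_expressed(pb)
        assert keep[1] and not keep[2]


class TestTMM:
    def test_identical_profiles_unit_factors(self):
        Y = np.tile(np.arange(1, 51), (4, 1))
        meta = pd.DataFrame({"profile_id": list("abcd"), "sample": list("abcd"),
                             "cluster": "all", "group": ["HC"] * 4, "n_spots": 10})
        pb = pdm.PseudoBulk(np.array([f"g{i}" for i in range(50)], dtype=object), Y, meta)
        np.testing.assert_allclose(pdm.tmm_factors(pb), 1.0, atol=1e-12)

    def test_depth_absorbed_by_library_size(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(40, 60) + 1
        Y = np.vstack([base, 2 * base, base])
        meta = pd.DataFrame({"profile_id": list("abc"), "sample": list("abc"),
                             "cluster": "all", "group": ["HC"] * 3, "n_spots": 10})
        pb = pdm.PseudoBulk(np.array([f"g{i}" for i in range(60)], dtype=object), Y, meta)
        f = pdm.tmm_factors(pb)
        np.testing.assert_allclose(f, f[0], atol=1e-9)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(1)
        pb = random_pseudobulk(rng, n=8, G=200, groups=("HC",) * 4 + ("DYS",) * 4)
        f = pdm.tmm_factors(pb)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_zero_library_rejected(self):
        rng = np.random.default_rng(2)
        pb = random_pseudobulk(rng)
        pb.Y[0] = 0
        with pytest.raises(ValueError, match="zero"):
            pdm.tmm_factors(pb)


def simulate_pb(rng, phi, n=12, G=2000, lfc_genes=(), lfc=0.0,
                groups=None):
    groups = groups or ["HC"] * (n // 2) + ["DYS"] * (n // 2)
    lib = rng.uniform(5e4, 2e5, n)
    base = np.maximum(rng.lognormal(np.log(40), 0.8, G), 2)
    mu = np.outer(lib / lib.mean(), base)
    fc = np.ones(G)
    fc[list(lfc_genes)] = 2.0 ** lfc
    mu[np.array(groups) == "DYS"] *= fc
    lam = mu if phi <= 0 else rng.gamma(1 / phi, phi * mu)
    Y = rng.poisson(lam).astype(np.int64)
    meta = pd.DataFrame({"profile_id": [f"p{i}" for i in range(n)],
                         "sample": [f"s{i}" for i in range(n)],
                         "cluster": "all", "group": groups, "n_spots": 100})
    return pdm.PseudoBulk(np.array([f"g{i}" for i in range(G)], dtype=object), Y, meta)


class TestDispersion:
    def test_poisson_common_near_zero(self):
        rng = np.random.default_rng(0)
        pb = simulate_pb(rng, phi=0.0)
        assert pdm.estimate_dispersion(pb)["common"] < 0.05

    def test_nb_common_recovered(self):
        rng = np.random.default_rng(1)
        pb = simulate_pb(rng, phi=0.4)
        assert pdm.estimate_dispersion(pb)["common"] == pytest.approx(0.4, abs=0.1)

    def test_all_zero_gene_gets_common(self):
        rng = np.random.default_rng(2)
        pb = simulate_pb(rng, phi=0.2, G=300)
        pb.Y[:, 7] = 0
        d = pdm.estimate_dispersion(pb)
        assert d["per_gene"][7] == d["common"]


class TestDETest:
    def test_planted_fold_changes_detected(self):
        rng = np.random.default_rng(3)
        hits = list(range(40))
        pb = simulate_pb(rng, phi=0.05, n=8, G=1000, lfc_genes=hits, lfc=2.0)
        keep = pdm.filter_low_expressed(pb)
        f = pdm.tmm_factors(pb)
        d = pdm.estimate_dispersion(pb, factors=f)
        res = pdm.de_test(pb, f, d["per_gene"], genes_mask=keep).set_index("gene")
        planted = [f"g{i}" for i in hits if f"g{i}" in res.index]
        assert res.loc[planted, "deg"].mean() >= 0.9
        assert res.loc[planted, "log2fc"].median() == pytest.approx(2.0, abs=0.3)

    def test_null_type_one_error_controlled(self):
        rejections, tested = 0, 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            pb = simulate_pb(rng, phi=0.1, n=8, G=800)
            keep = pdm.filter_low_expressed(pb)
            f = pdm.tmm_factors(pb)
            d = pdm.estimate_dispersion(pb, factors=f)
            res = pdm.de_test(pb, f, d["per_gene"], genes_mask=keep)
            rejections += (res["p"] < 0.05).sum()
            tested += len(res)
        rate = rejections / tested
        se = np.sqrt(0.05 * 0.95 / tested)
        assert rate <= 0.05 + 2 * se

    def test_flag_consistency(self):
        rng = np.random.default_rng(4)
        pb = simulate_pb(rng, phi=0.1, n=8, G=500, lfc_genes=range(20), lfc=1.5)
        keep = pdm.filter_low_expressed(pb)
        f = pdm.tmm_factors(pb)
        d = pdm.estimate_dispersion(pb, factors=f)
        res = pdm.de_test(pb, f, d["per_gene"], genes_mask=keep)
        assert (res["padj"] >= res["p"] - 1e-12).all()
        want = (res["log2fc"].abs() > 0.5) & (res["padj"] < 0.05)
        assert (res["deg"] == want).all()


class TestDegOverlap:
    def test_pairwise_example(self):
        out = pdm.deg_overlap({"m1": {"A", "B"}, "m2": {"B", "C"}}).set_index("modules")
        assert out.loc["m1", "exclusive"] == 1
        assert out.loc["m2", "exclusive"] == 1
        assert out.loc["m1+m2", "intersection"] == 1

    def test_identical_sets_all_shared(self):
        out = pdm.deg_overlap({"a": {"x", "y"}, "b": {"x", "y"}}).set_index("modules")
        assert out.loc["a", "exclusive"] == 0
        assert out.loc["a+b", "intersection"] == 2

    def test_matches_powerset_enumeration(self):
        rng = np.random.default_rng(0)
        universe = list("abcdefghij")
        sets = {f"m{k}": set(rng.choice(universe, rng.integers(1, 8), replace=False))
                for k in range(3)}
        out = pdm.deg_overlap(sets).set_index("modules")
        names = list(sets)
        for k in range(1, 4):
            for combo in combinations(names, k):
                inside = set.intersection(*(sets[c] for c in combo))
                outside = set().union(*(sets[c] for c in names if c not in combo))
                assert out.loc["+".join(combo), "exclusive"] == len(inside - outside)
                assert out.loc["+".join(combo), "intersection"] == len(inside)
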