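import numpy as np
import pytest
from scipy.spatial.distance import cdist

from alcatrack import routes as rt
from alcatrack import simulate as sim


def brute_force_nna(a, b):
    d = cdist(a, b)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def _straight(n=20, x0=0.0):
    s = np.linspace(0, 19_000, n)
    return np.column_stack([np.full(n, x0), s])


class TestNnaDistance:
    def test_identical_paths_zero(self):
        p = _straight()
        assert rt.nna_distance(p, p) == 0.0

    def test_parallel_offset_paths(self):
        assert rt.nna_distance(_straight(), _straight(x0=5000.0)) == pytest.approx(5000.0)

    def test_symmetric_by_construction(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1000, (15, 2))
            b = rng.normal(500, 1000, (18, 2))
            assert rt.nna_distance(a, b) == pytest.approx(rt.nna_distance(b, a))

    def test_short_path_rejected(self):
        with pytest.raises(ValueError):
            rt.nna_distance(_straight(n=9), _straight())

    def test_matches_brute_force_scan(self, rng):
        # k-d tree fast path must equal the all-pairs scan to 1e-9 relative
        for _ in range(50):
            a = rng.normal(0, 5000, (rng.integers(10, 200), 2))
            b = rng.normal(2000, 5000, (rng.integers(10, 200), 2))
            assert rt.nna_distance(a, b) == pytest.approx(brute_force_nna(a, b), rel=1e-9)


class TestNnaMatrix:
    def test_identical_paths_zero_matrix(self):
        _, D = rt.nna_matrix([_straight()] * 4)
        assert np.allclose(D, 0.0)

    def test_agrees_with_elementwise_calls(self, rng):
        paths = [rng.normal(i * 500, 1000, (12, 2)) for i in range(5)]
        _, D = rt.nna_matrix(paths)
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else rt.nna_distance(paths[i], paths[j])
                assert D[i, j] == pytest.approx(expected)

    def test_families_separate(self, route_families):
        paths, labels = route_families
        _, D = rt.nna_matrix(paths)
        within = D[np.ix_(labels == 0, labels == 0)]
        between = D[np.ix_(labels == 0, labels == 1)]
        assert between.min() > within.max()


class TestClusterTree:
    def test_root_split_recovers_families(self, route_families):
        paths, labels = route_families
        _, D = rt.nna_matrix(paths)
        tree = rt.cluster_tree(D)
        cut = tree.cut(2)
        # the 2-cluster cut must coincide with the family partition
        assert len(np.unique(cut[labels == 0])) == 1
        assert len(np.unique(cut[labels == 1])) == 1
        assert cut[labels == 0][0] != cut[labels == 1][0]

    def test_heights_monotone(self, route_families):
        paths, _ = route_families
        _, D = rt.nna_matrix(paths)
        tree = rt.cluster_tree(D)
        assert (np.diff(tree.Z[:, 2]) >= -1e-9).all()

    def test_partition_invariant_to_input_order(self, rng, route_families):
        paths, labels = route_families
        _, D = rt.nna_matrix(paths)
        perm = rng.permutation(len(paths))
        t1 = rt.cluster_tree(D)
        t2 = rt.cluster_tree(D[np.ix_(perm, perm)])
        for k in (2, 3, 4):
            p1 = {frozenset(np.flatnonzero(t1.cut(k) == c)) for c in np.unique(t1.cut(k))}
            c2 = t2.cut(k)
            p2 = {frozenset(perm[np.flatnonzero(c2 == c)]) for c in np.unique(c2)}
            assert p1 == p2


class TestAuSupport:
    def test_separated_families_high_support(self, route_families):
        paths, labels = route_families
        _, D = rt.nna_matrix(paths)
        tree = rt.cluster_tree(D)
        au = rt.au_support(D, n_boot=300, seed=0, tree=tree)
        fam1 = frozenset(np.flatnonzero(labels == 1))
        nid = next(n for n, s in tree.nodes.items() if s == fam1)
        assert au[nid] >= 95.0

    def test_bounded_zero_hundred(self, rng):
        for s in range(5):
            X = np.random.default_rng(s).normal(size=(10, 10))
            au = rt.au_support(X, n_boot=100, seed=s)
            assert all(0.0 <= v <= 100.0 for v in au.values())

    def test_support_monotone_in_separation(self):
        vals = []
        for sep in (600.0, 1500.0, 6000.0):
            paths, labels = sim.gen_route_families(2, [10, 10], jitter_m=1000.0,
                                                   seed=7, separation_m=sep)
            _, D = rt.nna_matrix(paths)
            tree = rt.cluster_tree(D)
            au = rt.au_support(D, n_boot=300, seed=7, tree=tree)
            fam = frozenset(np.flatnonzero(labels == 0))
            vals.append(next((au[n] for n, s in tree.nodes.items() if s == fam), 0.0))
        assert vals[0] <= vals[1] <= vals[2]

    def test_scales_must_straddle_one(self, rng):
        with pytest.raises(ValueError):
            rt.au_support(rng.normal(size=(8, 8)), n_boot=50,
                          scale_factors=[0.5, 0.7, 0.9])


class TestGroupRecovery:
    def test_perfect_families(self, route_families):
        paths, labels = route_families
        _, D = rt.nna_matrix(paths)
        rec = rt.group_recovery(rt.cluster_tree(D), labels, k=2)
        assert rec[0] == 1.0 and rec[1] == 1.0

    def test_one_planted_mislabel(self, rng):
        # 12 'a' at feature 0, 36 'b' at 10, one 'b' planted with the a's
        X = np.concatenate([rng.normal(0, 0.1, (12, 3)),
                            rng.normal(0, 0.1, (1, 3)),
                            rng.normal(10, 0.1, (36, 3))])
        labels = np.array(["a"] * 12 + ["b"] * 37)
        from scipy.spatial.distance import squareform, pdist
        D = squareform(pdist(X))
        rec = rt.group_recovery(rt.cluster_tree(D), labels, k=2)
        assert rec["b"] == pytest.approx(36 / 37)
        assert rec["a"] == 1.0

    def test_fractions_bounded(self, rng):
        X = rng.normal(size=(20, 5))
        from scipy.spatial.distance import squareform, pdist
        D = squareform(pdist(X))
        labels = np.array(["a", "b"] * 10)
        rec = rt.group_recovery(rt.cluster_tree(D), labels, k=2)
        assert all(0.5 <= v <= 1.0 for v in rec.values())


def test_newick_export_roundtrips_labels(route_families):
    paths, labels = route_families
    lbl, D = rt.nna_matrix(paths)
    tree = rt.cluster_tree(D, labels=[f"trip{i}" for i in range(len(paths))])
    rt.au_support(D, n_boot=50, seed=0, tree=tree)
    nwk = rt.to_newick(tree)
    assert nwk.endswith(";") and "trip0" in nwk and "AU=" in nwk
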