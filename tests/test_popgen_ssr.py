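"""SSR statistics against hand counts and brute-force oracles; NJ against
additivity and an independent library implementation."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selfsig.popgen_ssr import (
    DistanceMatrix,
    SSRGenotypeTable,
    allele_frequencies,
    allelic_richness,
    bootstrap_support,
    da_distance_matrix,
    inbreeding_coefficient,
    locus_diversity,
    nei_da,
    neighbor_joining,
    private_alleles,
)


def _table(genos, pops=None, loci=None):
    genos = np.asarray(genos)
    n, L, _ = genos.shape
    pops = pops or ["p"] * n
    return SSRGenotypeTable(
        samples=[f"s{i}" for i in range(n)],
        population=np.array(pops, dtype=object),
        species=np.array(["x"] * n, dtype=object),
        loci=loci or [f"L{j}" for j in range(L)],
        alleles=genos,
    )


class TestAlleleFrequencies:
    def test_hand_counts(self):
        t = _table([[[1, 1]], [[1, 2]]])
        f = allele_frequencies(t)["L0"]
        assert f == {1: 0.75, 2: 0.25}

    def test_missing_copies_excluded_from_denominator(self):
        t = _table([[[1, 1]], [[0, 0]], [[1, 2]]])
        f = allele_frequencies(t)["L0"]
        assert f == {1: 0.75, 2: 0.25}

    def test_all_missing_locus_flagged_empty(self):
        t = _table([[[0, 0], [1, 1]], [[0, 0], [1, 1]]])
        assert allele_frequencies(t)["L0"] == {}

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        t = _table(rng.integers(1, 5, size=(12, 3, 2)))
        for f in allele_frequencies(t).values():
            assert sum(f.values()) == pytest.approx(1.0)


class TestLocusDiversity:
    @pytest.mark.parametrize(
        "genos,a,ho,he",
        [
            ([[[1, 1]], [[1, 1]]], 1, 0.0, 0.0),
            ([[[1, 2]], [[1, 2]]], 2, 1.0, 0.5),
            ([[[1, 1]], [[1, 2]], [[2, 2]], [[1, 2]]], 2, 0.5, 0.5),
        ],
    )
    def test_hand_examples(self, genos, a, ho, he):
        div = locus_diversity(_table(genos))
        assert div.loc["L0", "A"] == a
        assert div.loc["L0", "H_O"] == pytest.approx(ho)
        assert div.loc["L0", "H_E"] == pytest.approx(he)

    def test_he_upper_bound(self):
        rng = np.random.default_rng(1)
        t = _table(rng.integers(1, 6, size=(20, 4, 2)))
        div = locus_diversity(t)
        assert np.all(div["H_E"] <= 1 - 1 / div["A"] + 1e-12)

    def test_unbiased_correction_scales(self):
        t = _table([[[1, 2]], [[1, 2]]])
        he = locus_diversity(t)["H_E"].iloc[0]
        heu = locus_diversity(t, unbiased=True)["H_E"].iloc[0]
        assert heu == pytest.approx(he * 4 / 3)


def _brute_force_richness(copies: list[int], g: int) -> float:
    """Mean allele count over all C(N, g) subsamples of the gene copies."""
    subs = list(itertools.combinations(range(len(copies)), g))
    return float(
        np.mean([len({copies[i] for i in sub}) for sub in subs])
    )


class TestAllelicRichness:
    def test_monomorphic_is_one(self):
        t = _table([[[1, 1]], [[1, 1]]])
        assert allelic_richness(t, g=2)["L0"] == pytest.approx(1.0)

    def test_full_sample_equals_allele_count(self):
        t = _table([[[1, 2]], [[3, 3]]])
        assert allelic_richness(t, g=4)["L0"] == pytest.approx(3.0)

    def test_aabc_at_g2_hand_value(self):
        t = _table([[[1, 1]], [[2, 3]]])
        assert allelic_richness(t, g=2)["L0"] == pytest.approx(11 / 6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        copies=st.lists(st.integers(1, 4), min_size=2, max_size=8).filter(
            lambda c: len(c) % 2 == 0
        ),
        data=st.data(),
    )
    def test_matches_brute_force_enumeration(self, copies, data):
        g = data.draw(st.integers(1, len(copies)))
        genos = np.array(copies).reshape(-1, 1, 2)
        rs = allelic_richness(_table(genos), g=g)["L0"]
        assert rs == pytest.approx(_brute_force_richness(copies, g))

    def test_monotone_in_g_and_exceeding_g_rejected(self):
        t = _table([[[1, 2]], [[3, 1]], [[1, 1]]])
        vals = [allelic_richness(t, g=g)["L0"] for g in range(1, 7)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        with pytest.raises(ValueError):
            allelic_richness(t, g=7)


class TestInbreedingCoefficient:
    def test_all_homozygous_polymorphic_is_one(self):
        t = _table([[[1, 1]], [[2, 2]]])
        fis, mean = inbreeding_coefficient(t)
        assert fis["L0"] == pytest.approx(1.0)
        assert mean == pytest.approx(1.0)

    def test_ho_equals_he_gives_zero(self):
        t = _table([[[1, 1]], [[1, 2]], [[2, 2]], [[1, 2]]])
        fis, _ = inbreeding_coefficient(t)
        assert fis["L0"] == pytest.approx(0.0)

    def test_monomorphic_loci_excluded_as_nan(self):
        t = _table([[[1, 1], [1, 1]], [[2, 2], [1, 1]]])
        fis, mean = inbreeding_coefficient(t)
        assert np.isnan(fis["L1"])
        assert mean == pytest.approx(1.0)


class TestPrivateAlleles:
    def test_identical_allele_sets_have_none(self):
        t = _table([[[1, 2]], [[1, 2]]], pops=["p1", "p2"])
        assert private_alleles(t) == {"p1": 0, "p2": 0}

    def test_hand_example(self):
        t = _table([[[1, 2]], [[2, 3]]], pops=["p1", "p2"])
        assert private_alleles(t) == {"p1": 1, "p2": 1}

    def test_allele_in_two_of_three_pops_is_private_nowhere(self):
        t = _table(
            [[[1, 1]], [[1, 2]], [[3, 3]]], pops=["p1", "p2", "p3"]
        )
        counts = private_alleles(t)
        assert counts == {"p1": 0, "p2": 1, "p3": 1}  # allele 1 shared p1/p2


class TestNeiDa:
    def test_identical_frequencies_zero(self):
        f = {"L0": {1: 0.5, 2: 0.5}}
        assert nei_da(f, f) == pytest.approx(0.0)

    def test_disjoint_alleles_one(self):
        assert nei_da({"L0": {1: 1.0}}, {"L0": {2: 1.0}}) == pytest.approx(1.0)

    def test_hand_value(self):
        assert nei_da(
            {"L0": {1: 1.0, 2: 0.0}}, {"L0": {1: 0.25, 2: 0.75}}
        ) == pytest.approx(0.5)

    def test_locus_without_data_excluded_with_warning(self):
        fx = {"L0": {1: 1.0}, "L1": {1: 1.0}}
        fy = {"L0": {1: 1.0}, "L1": {}}
        with pytest.warns(UserWarning, match="excluded"):
            assert nei_da(fx, fy) == pytest.approx(0.0)

    def test_matrix_properties(self, hand_ssr_table):
        dm = da_distance_matrix(hand_ssr_table, by="population")
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        assert np.all((dm.values >= 0) & (dm.values <= 1))


def _random_additive_tree(rng, n):
    """Random unrooted binary tree built edge-by-edge with plain dicts (kept
    independent of the package's tree code); returns labels and the exact
    tip path-length matrix the tree induces."""
    hub = 0  # internal nodes are ints, tips are 't<k>' strings
    adj = {hub: {}, "t0": {}, "t1": {}, "t2": {}}
    for k in range(3):
        w = rng.uniform(0.1, 2.0)
        adj[f"t{k}"][hub] = adj[hub][f"t{k}"] = w
    next_internal = 1
    for k in range(3, n):
        edges = [(a, b) for a in adj for b in adj[a] if str(a) < str(b)]
        a, b = edges[rng.randrange(len(edges))]
        mid = next_internal
        next_internal += 1
        w = adj[a].pop(b)
        adj[b].pop(a)
        cut = rng.uniform(0.05, w - 0.05) if w > 0.1 else w / 2
        adj[mid] = {}
        adj[a][mid] = adj[mid][a] = cut
        adj[b][mid] = adj[mid][b] = w - cut
        tip = f"t{k}"
        adj[tip] = {}
        wl = rng.uniform(0.1, 2.0)
        adj[tip][mid] = adj[mid][tip] = wl
    labels = [f"t{i}" for i in range(n)]
    d = np.zeros((n, n))
    for i, s in enumerate(labels):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, t2 in enumerate(labels):
            d[i, j] = dist[t2]
    return labels, d


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float))
        tree = neighbor_joining(d)
        assert np.allclose(tree.path_length_matrix(["A", "B", "C"]), d.values)

    def test_four_point_fixture_recovers_ab_cd(self):
        d = DistanceMatrix(
            list("ABCD"),
            np.array(
                [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
            ),
        )
        tree = neighbor_joining(d)
        bps = tree.bipartitions()
        assert frozenset({"A", "B"}) in bps
        assert bps[frozenset({"A", "B"})] == pytest.approx(1.0)
        assert np.allclose(tree.path_length_matrix(list("ABCD")), d.values)

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_reconstructs_random_additive_metrics_exactly(self, n):
        import random

        rng = random.Random(123 + n)
        for _ in range(20):
            labels, d = _random_additive_tree(rng, n)
            tree = neighbor_joining(DistanceMatrix(labels, d))
            assert np.allclose(tree.path_length_matrix(labels), d, atol=1e-9)

    def test_agrees_with_scikit_bio_on_random_matrix(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj

        labels, d = _random_additive_tree(__import__("random").Random(9), 6)
        d = (d + d.T) / 2  # exact symmetry for skbio's validator
        sk_tree = nj(SkbioDM(d, ids=labels))
        ours = neighbor_joining(DistanceMatrix(labels, d))
        sk_d = np.array(
            [[sk_tree.find(a).distance(sk_tree.find(b)) for b in labels] for a in labels]
        )
        assert np.allclose(ours.path_length_matrix(labels), sk_d, atol=1e-9)

    def test_rejects_tiny_or_invalid_matrices(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B", "C"], np.arange(9.0).reshape(3, 3))


class TestBootstrapSupport:
    def _strong_table(self):
        # Two pairs of populations, every locus separating them identically.
        genos = np.array(
            [
                [[1, 1]] * 6,
                [[1, 1]] * 6,
                [[9, 9]] * 6,
                [[9, 9]] * 6,
            ]
        )
        return _table(genos, pops=["p1", "p2", "p3", "p4"])

    def test_unanimous_bipartition_gets_full_support(self):
        tree, support = bootstrap_support(self._strong_table(), n_reps=50, seed=1)
        assert support
        assert all(v == 1.0 for v in support.values())

    def test_fixed_seed_reproduces_support(self):
        t = self._strong_table()
        _, s1 = bootstrap_support(t, n_reps=30, seed=4)
        _, s2 = bootstrap_support(t, n_reps=30, seed=4)
        assert s1 == s2

    def test_single_locus_rejected(self):
        t = _table([[[1, 1]], [[2, 2]], [[3, 3]]], pops=["a", "b", "c"])
        with pytest.raises(ValueError):
            bootstrap_support(t, n_reps=10)
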