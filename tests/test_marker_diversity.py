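"""PIC, Jaccard similarity, UPGMA clustering and Newick export."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ssrmine import (
    GenotypeMatrix,
    jaccard_similarity,
    mean_alleles_per_marker,
    pic,
    score_alleles,
    to_newick,
    upgma,
    write_newick,
)
from ssrmine.marker_diversity import DendrogramNode, SimilarityMatrix
from ssrmine.synthetic_data import generate_genotypes


class TestPic:
    @pytest.mark.parametrize(
        "freqs,expected",
        [((1.0,), 0.0), ((0.5, 0.5), 0.5), ((0.5, 0.3, 0.2), 0.62)],
    )
    def test_known_values(self, freqs, expected):
        assert pic(freqs) == pytest.approx(expected)

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_equal_frequencies_maximize(self, k, rng):
        bound = 1 - 1 / k
        assert pic([1 / k] * k) == pytest.approx(bound)
        for _ in range(200):
            w = rng.dirichlet(np.ones(k))
            w = w / w.sum()
            if np.any(w <= 0):
                continue
            assert pic(w) <= bound + 1e-12

    def test_permutation_invariant(self):
        freqs = (0.5, 0.3, 0.2)
        vals = {round(pic(p), 12) for p in itertools.permutations(freqs)}
        assert vals == {round(pic(freqs), 12)}

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            pic([0.5, 0.4])
        with pytest.raises(ValueError):
            pic([0.5, 0.5, 0.0])


class TestScoreAlleles:
    def test_monomorphic_marker(self):
        bands = {("m1", a): frozenset({200}) for a in ("a1", "a2", "a3")}
        m = GenotypeMatrix(["a1", "a2", "a3"], ["m1"], bands)
        (poly,) = score_alleles(m)
        assert poly.n_alleles == 1 and poly.pic == 0.0

    def test_two_allele_even_split(self):
        bands = {("m1", "a1"): frozenset({200}), ("m1", "a2"): frozenset({200}),
                 ("m1", "a3"): frozenset({210}), ("m1", "a4"): frozenset({210})}
        m = GenotypeMatrix(["a1", "a2", "a3", "a4"], ["m1"], bands)
        (poly,) = score_alleles(m)
        assert poly.n_alleles == 2 and poly.allele_freqs == (0.5, 0.5)
        assert poly.pic == pytest.approx(0.5)

    def test_non_amplifying_marker_excluded_with_warning(self):
        bands = {("m1", "a1"): frozenset({200}), ("m1", "a2"): frozenset({210})}
        m = GenotypeMatrix(["a1", "a2"], ["m1", "m2"], bands)
        with pytest.warns(UserWarning, match="m2"):
            polys = score_alleles(m)
        assert [p.marker for p in polys] == ["m1"]

    def test_pic_recovery_from_large_sample(self):
        m, truth = generate_genotypes(5000, [(0.5, 0.3, 0.2)], seed=7)
        (poly,) = score_alleles(m)
        assert abs(poly.pic - 0.62) <= 0.01

    def test_estimated_pic_converges_for_many_markers(self, rng):
        freq_sets = []
        for _ in range(20):
            k = int(rng.integers(2, 5))
            w = rng.dirichlet(np.ones(k) * 2)
            freq_sets.append(tuple(w / w.sum()))
        m, truth = generate_genotypes(400, freq_sets, seed=13)
        for poly, (_, row) in zip(score_alleles(m), truth.iterrows()):
            # binomial sampling error at n=400 accessions
            assert abs(poly.pic - row["true_pic"]) < 0.08


class TestJaccard:
    def _matrix(self, profiles):
        accs = list(profiles)
        markers = sorted({m for p in profiles.values() for m, _ in p})
        bands = {}
        for a, items in profiles.items():
            for m, size in items:
                key = (m, a)
                bands[key] = bands.get(key, frozenset()) | {size}
        return GenotypeMatrix(accs, markers, bands)

    def test_identical_profiles(self):
        m = self._matrix({"x": [("m1", 200), ("m2", 150)], "y": [("m1", 200), ("m2", 150)]})
        assert jaccard_similarity(m).get("x", "y") == 1.0

    def test_disjoint_profiles(self):
        m = self._matrix({"x": [("m1", 200)], "y": [("m1", 210)]})
        assert jaccard_similarity(m).get("x", "y") == 0.0

    def test_half_shared(self):
        m = self._matrix(
            {"x": [("m1", 200), ("m2", 150), ("m3", 300)],
             "y": [("m1", 200), ("m2", 150), ("m4", 400)]}
        )
        assert jaccard_similarity(m).get("x", "y") == pytest.approx(0.5)

    def test_adding_shared_band_never_decreases(self, rng):
        base = {"x": [("m1", 200), ("m2", 150)], "y": [("m1", 200), ("m3", 120)]}
        s0 = jaccard_similarity(self._matrix(base)).get("x", "y")
        base["x"].append(("m9", 500))
        base["y"].append(("m9", 500))
        s1 = jaccard_similarity(self._matrix(base)).get("x", "y")
        assert s1 >= s0


class TestUpgma:
    def test_two_accessions(self):
        sim = SimilarityMatrix(["A", "B"], np.array([[1.0, 0.8], [0.8, 1.0]]))
        root = upgma(sim)
        assert root.height == pytest.approx(0.8)
        assert sorted(root.leaves()) == ["A", "B"]

    def test_three_taxa_hand_computed(self):
        sim = SimilarityMatrix(
            ["A", "B", "C"],
            np.array([[1.0, 0.9, 0.5], [0.9, 1.0, 0.7], [0.5, 0.7, 1.0]]),
        )
        root = upgma(sim)
        assert root.height == pytest.approx(0.6)  # (0.5 + 0.7) / 2
        ab = [c for c in root.children if not c.is_leaf][0]
        assert ab.height == pytest.approx(0.9) and sorted(ab.leaves()) == ["A", "B"]

    def test_heights_non_increasing_toward_root(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            d = squareform(rng.uniform(0.05, 0.95, size=n * (n - 1) // 2))
            sim = SimilarityMatrix([f"a{i}" for i in range(n)], 1 - d)
            def check(node, parent_h):
                assert node.height >= parent_h - 1e-12
                if not node.is_leaf:
                    for c in node.children:
                        check(c, node.height)
            check(upgma(sim), 0.0)

    def test_merge_heights_match_scipy_average_linkage(self, rng):
        """Independent cross-check: our merge similarities equal
        1 - (scipy 'average' linkage distances)."""
        for _ in range(10):
            n = int(rng.integers(4, 10))
            condensed = rng.uniform(0.05, 0.95, size=n * (n - 1) // 2)
            sim = SimilarityMatrix(
                [f"a{i}" for i in range(n)], 1 - squareform(condensed)
            )
            root = upgma(sim)
            mine = []
            def collect(node):
                if not node.is_leaf:
                    mine.append(node.height)
                    for c in node.children:
                        collect(c)
            collect(root)
            scipy_heights = sorted(1 - linkage(condensed, "average")[:, 2])
            assert np.allclose(sorted(mine), scipy_heights)

    def test_recovers_planted_ultrametric_topology(self):
        # clades planted at decreasing similarity: ((A,B), (C,(D,E)))
        ids = ["A", "B", "C", "D", "E"]
        merge_sim = {
            frozenset("AB"): 0.9, frozenset("DE"): 0.85,
            frozenset("CDE"): 0.7, frozenset("ABCDE"): 0.4,
        }
        vals = np.eye(5)
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i < j:
                    s = next(
                        merge_sim[g]
                        for g in sorted(merge_sim, key=len)
                        if {x, y} <= set(g)
                    )
                    vals[i, j] = vals[j, i] = s
        root = upgma(SimilarityMatrix(ids, vals))
        clades = set()
        def collect(node):
            if not node.is_leaf:
                clades.add(frozenset(node.leaves()))
                for c in node.children:
                    collect(c)
        collect(root)
        assert clades == {
            frozenset("AB"), frozenset("DE"), frozenset("CDE"), frozenset("ABCDE")
        }

    def test_single_accession_rejected(self):
        sim = SimilarityMatrix(["A"], np.array([[1.0]]))
        with pytest.raises(ValueError):
            upgma(sim)


class TestNewick:
    def test_two_leaf_branch_lengths(self):
        sim = SimilarityMatrix(["A", "B"], np.array([[1.0, 0.8], [0.8, 1.0]]))
        assert to_newick(upgma(sim)) == "(A:0.1,B:0.1);"

    def test_leaf_only_input_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            to_newick(DendrogramNode(height=1.0, name="A"))

    def test_round_trip_topology_and_heights(self, rng, tmp_path):
        n = 8
        condensed = rng.uniform(0.1, 0.9, size=n * (n - 1) // 2)
        sim = SimilarityMatrix(
            [f"a{i}" for i in range(n)], 1 - squareform(condensed)
        )
        root = upgma(sim)
        path = tmp_path / "tree.nwk"
        write_newick(root, path)
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == sim.ids
        # ultrametric on the distance scale: root-to-leaf depth = (1 - S_root)/2
        expected = (1 - root.height) / 2
        for leaf in tree.leaf_node_iter():
            depth, node = 0.0, leaf
            while node.parent_node is not None:
                depth += node.edge.length or 0.0
                node = node.parent_node
            assert depth == pytest.approx(expected, abs=1e-5)


def test_mean_alleles_74_over_32():
    # 23 markers with 2 alleles, 8 with 3, 1 with 4 -> 74 alleles total
    counts = [2] * 23 + [3] * 8 + [4]
    bands = {}
    accs = [f"a{i}" for i in range(24)]
    for mi, k in enumerate(counts):
        for ai, a in enumerate(accs):
            bands[(f"m{mi}", a)] = frozenset({100 + 10 * (ai % k)})
    m = GenotypeMatrix(accs, [f"m{i}" for i in range(32)], bands)
    polys = score_alleles(m)
    assert sum(p.n_alleles for p in polys) == 74
    assert mean_alleles_per_marker(polys) == 2.31
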