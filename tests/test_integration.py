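import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from anchorprio.integration import (
    anchor_correlation, assemble_candidates, cluster_heatmap,
    disease_enrichment, export_network, hypergeom_overlap, reorder_matrix,
)


def enumerate_overlap_p(n_universe, set_a, size_b, k_obs):
    """Exhaustive enumeration of P(|A ∩ B| >= k) over all size-|B| draws."""
    universe = list(range(n_universe))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, size_b):
        total += 1
        if len(set_a & set(draw)) >= k_obs:
            hits += 1
    return hits / total


class TestAssembly:
    def test_neighborhood_union_bookkeeping(self):
        """26 meta-significant + 42 heart-significant with 13 shared
        gives the 55-gene source union."""
        shared = {f"s{i}" for i in range(13)}
        meta = shared | {f"m{i}" for i in range(13)}          # 26
        heart = shared | {f"h{i}" for i in range(29)}         # 42
        source = meta | heart | {f"n{i}" for i in range(40)}
        table, counts = assemble_candidates({"neighborhood": source},
                                            meta, heart)
        c = counts["neighborhood"]
        assert (c["meta_significant"], c["heart_significant"],
                c["overlap"], c["union"]) == (26, 42, 13, 55)
        assert len(table) == 55

    def test_module_union_bookkeeping(self):
        """43 and 46 with 19 shared give the 70-gene module union."""
        shared = {f"s{i}" for i in range(19)}
        meta = shared | {f"m{i}" for i in range(24)}          # 43
        heart = shared | {f"h{i}" for i in range(27)}         # 46
        source = meta | heart
        _, counts = assemble_candidates({"module": source}, meta, heart)
        assert counts["module"]["union"] == 70

    def test_empty_inputs_give_empty_table(self):
        table, counts = assemble_candidates({"neighborhood": set()},
                                            set(), set())
        assert table.empty

    def test_candidates_need_source_and_significance(self):
        table, _ = assemble_candidates({"src": {"a", "b"}}, {"b", "z"}, set())
        assert list(table["gene"]) == ["b"]

    def test_partial_flag_set_for_single_universe_genes(self):
        table, _ = assemble_candidates({"src": {"a", "b"}}, {"a", "b"}, set(),
                                       meta_universe={"a", "b"},
                                       heart_universe={"a"})
        flags = dict(zip(table["gene"], table["partial"]))
        assert flags == {"a": False, "b": True}


class TestHypergeom:
    def test_worked_example(self):
        universe = set(range(10))
        a = set(range(4))
        b = set(range(4)) | {9}
        res = hypergeom_overlap(a, b, universe)
        assert res.n_overlap == 4
        assert res.p == pytest.approx(6 / 252)

    def test_empty_set_gives_p_one(self):
        res = hypergeom_overlap(set(), {1, 2}, set(range(10)))
        assert res.p == pytest.approx(1.0)

    def test_universe_must_contain_sets(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_overlap({"x"}, set(), {"y"})

    def test_matches_enumeration_for_small_universes(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            size_a = int(rng.integers(0, n + 1))
            size_b = int(rng.integers(0, n + 1))
            a = set(rng.choice(n, size=size_a, replace=False).tolist())
            b = set(rng.choice(n, size=size_b, replace=False).tolist())
            res = hypergeom_overlap(a, b, set(range(n)))
            ref = enumerate_overlap_p(n, a, size_b, len(a & b))
            assert res.p == pytest.approx(ref, rel=1e-12)

    def test_odds_ratio_infinite_when_cell_empty(self):
        res = hypergeom_overlap({0, 1}, {0, 1}, set(range(6)))
        assert math.isinf(res.odds_ratio)


class TestDiseaseEnrichment:
    def test_published_percentages(self):
        """34 of 52 disease genes evaluated is 65%; 16 of those 34
        significant is 47%."""
        disease = [f"d{i}" for i in range(52)]
        evaluated = set(disease[:34]) | {f"e{i}" for i in range(100)}
        significant = set(disease[:16]) | {f"e{i}" for i in range(20)}
        stats = disease_enrichment(evaluated, significant, disease)
        assert stats["pct_evaluated"] == 65
        assert stats["pct_significant"] == 47

    def test_disjoint_disease_list(self):
        stats = disease_enrichment({"a", "b"}, {"a"}, ["x", "y"])
        assert stats["pct_evaluated"] == 0
        assert stats["enrichment_p"] == pytest.approx(1.0)


class TestAnchorCorrelation:
    def make_inputs(self, profiles):
        heart = pd.DataFrame(profiles,
                             columns=[f"s{j}" for j in
                                      range(len(next(iter(profiles.values()))))]
                             ).T if isinstance(profiles, dict) else profiles
        return heart

    def test_proportional_profiles_correlate_perfectly(self):
        heart = pd.DataFrame({"FBN1": [1.0, 2.0, 3.0, 4.0],
                              "q": [2.0, 4.0, 6.0, 8.0]}).T
        meta = pd.DataFrame({"FBN1": [0.1, 0.2, 0.3],
                             "q": [0.3, 0.1, 0.2]}).T
        out = anchor_correlation(heart, meta, "FBN1", ["q"])
        assert out.iloc[0]["r_heart"] == pytest.approx(1.0)

    def test_reversed_profile_anticorrelates(self):
        heart = pd.DataFrame({"FBN1": [1.0, 2.0, 3.0],
                              "q": [3.0, 2.0, 1.0]}).T
        meta = pd.DataFrame({"FBN1": [1.0, 2.0, 3.0],
                             "q": [1.0, 2.0, 3.0]}).T
        out = anchor_correlation(heart, meta, "FBN1", ["q"])
        assert out.iloc[0]["r_heart"] == pytest.approx(-1.0)
        assert not out.iloc[0]["concordant"]

    def test_worked_r_example(self):
        heart = pd.DataFrame({"FBN1": [1.0, 2.0, 3.0, 4.0],
                              "q": [1.0, 3.0, 2.0, 4.0]}).T
        meta = pd.DataFrame({"FBN1": [1.0, 2.0, 3.0, 4.0],
                             "q": [1.0, 3.0, 2.0, 4.0]}).T
        out = anchor_correlation(heart, meta, "FBN1", ["q"])
        assert out.iloc[0]["r_heart"] == pytest.approx(0.8)
        assert out.iloc[0]["concordant"]

    def test_zero_variance_reported_missing(self):
        heart = pd.DataFrame({"FBN1": [1.0, 2.0, 3.0],
                              "q": [5.0, 5.0, 5.0]}).T
        meta = pd.DataFrame({"FBN1": [1.0, 2.0, 3.0],
                             "q": [1.0, 2.0, 3.0]}).T
        out = anchor_correlation(heart, meta, "FBN1", ["q"])
        assert np.isnan(out.iloc[0]["r_heart"])
        assert not out.iloc[0]["concordant"]


class TestClustering:
    def test_canberra_worked_example(self):
        from scipy.spatial.distance import canberra
        assert canberra([1, 2, 3], [2, 2, 0]) == pytest.approx(1 / 3 + 0 + 1)

    def test_canberra_identity(self, rng):
        from scipy.spatial.distance import canberra
        x = rng.normal(size=10)
        assert canberra(x, x) == 0.0

    def test_complete_linkage_hand_example(self):
        # three points with pairwise distances 1, 2, 3
        d = squareform(np.array([[0.0, 1.0, 2.0],
                                 [1.0, 0.0, 3.0],
                                 [2.0, 3.0, 0.0]]), checks=False)
        link = hierarchy.linkage(d, method="complete")
        assert link[0, 2] == pytest.approx(1.0)
        assert link[1, 2] == pytest.approx(3.0)

    def test_merge_heights_non_decreasing(self, rng):
        m = pd.DataFrame(rng.normal(size=(12, 6)) + 3,
                         index=[f"g{i}" for i in range(12)],
                         columns=[f"s{j}" for j in range(6)])
        res = cluster_heatmap(m)
        assert np.all(np.diff(res.gene_linkage[:, 2]) >= -1e-12)
        assert np.all(np.diff(res.sample_linkage[:, 2]) >= -1e-12)

    def test_row_permutation_changes_nothing_but_labels(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 5)) + 2,
                         index=[f"g{i}" for i in range(10)],
                         columns=[f"s{j}" for j in range(5)])
        res1 = cluster_heatmap(m)
        perm = m.sample(frac=1, random_state=1)
        res2 = cluster_heatmap(perm)
        coph1 = dict(zip(itertools.combinations(m.index, 2),
                         hierarchy.cophenet(res1.gene_linkage)))
        # map cophenetic distances back to label pairs for comparison
        labels2 = list(perm.index)
        coph2_raw = hierarchy.cophenet(res2.gene_linkage)
        coph2 = {}
        for (i, j), dist in zip(itertools.combinations(range(len(labels2)), 2),
                                coph2_raw):
            coph2[tuple(sorted((labels2[i], labels2[j])))] = dist
        for pair, dist in coph1.items():
            assert coph2[tuple(sorted(pair))] == pytest.approx(dist)

    def test_newick_export_parses(self, rng, tmp_path):
        m = pd.DataFrame(rng.normal(size=(6, 4)) + 1,
                         index=[f"g{i}" for i in range(6)],
                         columns=[f"s{j}" for j in range(4)])
        res = cluster_heatmap(m)
        assert res.gene_newick.endswith(";")
        assert res.gene_newick.count("(") == 5        # n-1 internal nodes
        reordered = reorder_matrix(m, res)
        assert sorted(reordered.index) == sorted(m.index)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cluster_heatmap(pd.DataFrame([[1.0, 2.0]]))


class TestNetworkExport:
    def test_edge_and_isolated_node(self, tmp_path):
        net = nx.Graph([("A", "B"), ("B", "C")])
        attrs = export_network({"A", "B", "Z"}, net,
                               tmp_path / "n.sif", tmp_path / "n_attrs.tsv")
        sif = (tmp_path / "n.sif").read_text().strip().splitlines()
        assert sif == ["A\tpp\tB"]
        assert set(attrs["gene"]) == {"A", "B", "Z"}
        assert len(attrs) == 3
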