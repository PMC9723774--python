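"""VT merging, monophyletic identity clustering and guild filtering."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from mycodiv import CommunityTable, cluster_unassigned, merge_by_vt
from mycodiv.core import TaxonAnnotation
from mycodiv.taxa import filter_guild, name_clusters

from conftest import random_bifurcating_tree


def table_of(columns, samples=None, guild="AMF"):
    samples = samples or [f"s{i}" for i in range(len(next(iter(columns.values()))))]
    df = pd.DataFrame(columns, index=samples)
    return CommunityTable(df, {c: guild for c in columns})


def ann(asv, vt=None, guild="AMF", conf=None, genus=None):
    return TaxonAnnotation(asv, vt, genus, guild, conf)


class TestMergeByVt:
    def test_counts_summed_under_shared_vt(self):
        raw = table_of({"a1": [5, 0], "a2": [7, 1], "a3": [2, 2]})
        merged, mm = merge_by_vt(
            raw, [ann("a1", "VTX00001"), ann("a2", "VTX00001"), ann("a3")]
        )
        assert merged.counts.loc["s0", "VTX00001"] == 12
        assert merged.counts.loc["s1", "VTX00001"] == 1
        assert mm.asv_to_taxon == {
            "a1": "VTX00001", "a2": "VTX00001", "a3": "a3"
        }
        assert mm.provenance == {
            "VTX00001": "vt_assigned", "a3": "singleton"
        }

    def test_all_distinct_vt_is_renaming(self):
        raw = table_of({"a1": [1, 2], "a2": [3, 4]})
        merged, _ = merge_by_vt(
            raw, [ann("a1", "VTX00001"), ann("a2", "VTX00002")]
        )
        assert merged.taxa == ["VTX00001", "VTX00002"]
        assert merged.counts.to_numpy().tolist() == [[1, 3], [2, 4]]

    def test_per_sample_totals_conserved_random(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_asv = int(rng.integers(2, 9))
            raw = table_of(
                {
                    f"a{j}": rng.integers(0, 30, size=4).tolist()
                    for j in range(n_asv)
                }
            )
            vts = [
                f"VTX{rng.integers(3):05d}" if rng.random() < 0.7 else None
                for _ in range(n_asv)
            ]
            merged, mm = merge_by_vt(
                raw, [ann(f"a{j}", vts[j]) for j in range(n_asv)]
            )
            assert (
                merged.counts.sum(axis=1) == raw.counts.sum(axis=1)
            ).all()
            # brute-force per-sample group sums
            for vt in {v for v in vts if v}:
                members = [f"a{j}" for j in range(n_asv) if vts[j] == vt]
                assert (
                    merged.counts[vt] == raw.counts[members].sum(axis=1)
                ).all()

    def test_missing_annotation_named(self):
        raw = table_of({"a1": [1], "a2": [1]})
        with pytest.raises(ValueError, match="a2"):
            merge_by_vt(raw, [ann("a1", "VTX00001")])

    def test_idempotent_on_merged_output(self):
        raw = table_of({"a1": [5, 0], "a2": [7, 1], "a3": [2, 2]})
        anns = [ann("a1", "VTX00001"), ann("a2", "VTX00001"), ann("a3")]
        merged, _ = merge_by_vt(raw, anns)
        again, _ = merge_by_vt(
            merged,
            [ann("VTX00001", "VTX00001"), ann("a3")],
        )
        assert again == merged


def brute_force_clusters(tree, identities, threshold):
    """Oracle: enumerate all clades, keep maximal all-pairs-qualifying ones."""
    qualifying = []
    for node in tree.traverse(include_self=True):
        if node.is_tip():
            continue
        tips = sorted(t.name for t in node.tips())
        ok = all(
            identities.loc[a, b] > threshold
            for a, b in itertools.combinations(tips, 2)
        )
        if ok:
            qualifying.append(set(tips))
    # maximality: drop any qualifying clade nested in another
    maximal = [
        c
        for c in qualifying
        if not any(c < other for other in qualifying)
    ]
    return sorted(frozenset(c) for c in maximal)


def identity_from_values(tips, values):
    m = pd.DataFrame(values, index=tips, columns=tips, dtype=float)
    return m


class TestClusterUnassigned:
    def test_sister_pair_above_threshold_merges(self):
        tree = TreeNode.read(io.StringIO("(a:0.1,b:0.1):0;"))
        ident = identity_from_values(
            ["a", "b"], [[1.0, 0.99], [0.99, 1.0]]
        )
        raw = table_of({"a": [3, 1], "b": [2, 0]})
        merged, mm = cluster_unassigned(raw, tree, ident, 0.97)
        assert merged.taxa == ["add_cluster1"]
        assert merged.counts["add_cluster1"].tolist() == [5, 1]

    def test_sister_pair_below_threshold_kept_separate(self):
        tree = TreeNode.read(io.StringIO("(a:0.1,b:0.1):0;"))
        ident = identity_from_values(
            ["a", "b"], [[1.0, 0.95], [0.95, 1.0]]
        )
        raw = table_of({"a": [3], "b": [2]})
        merged, _ = cluster_unassigned(raw, tree, ident, 0.97)
        assert sorted(merged.taxa) == ["a", "b"]

    def test_threshold_is_strict(self):
        tree = TreeNode.read(io.StringIO("(a:0.1,b:0.1):0;"))
        ident = identity_from_values(
            ["a", "b"], [[1.0, 0.97], [0.97, 1.0]]
        )
        raw = table_of({"a": [3], "b": [2]})
        merged, _ = cluster_unassigned(raw, tree, ident, 0.97)
        assert sorted(merged.taxa) == ["a", "b"]  # exactly 0.97 not merged

    def test_six_tip_example_matches_oracle(self):
        nwk = "(((a:.01,b:.01):.01,c:.01):.2,((d:.01,e:.01):.2,f:.3):.1):0;"
        tree = TreeNode.read(io.StringIO(nwk))
        tips = ["a", "b", "c", "d", "e", "f"]
        vals = np.full((6, 6), 0.90)
        np.fill_diagonal(vals, 1.0)
        ident = identity_from_values(tips, vals)
        for x, y in [("a", "b"), ("a", "c"), ("b", "c")]:
            ident.loc[x, y] = ident.loc[y, x] = 0.99
        ident.loc["d", "e"] = ident.loc["e", "d"] = 0.96
        raw = table_of({t: [1, 2] for t in tips})
        merged, mm = cluster_unassigned(raw, tree, ident, 0.97)
        clusters = [
            frozenset(mm.members(t))
            for t, tag in mm.provenance.items()
            if tag == "clustered"
        ]
        assert clusters == [frozenset({"a", "b", "c"})]
        assert brute_force_clusters(tree, ident, 0.97) == sorted(clusters)

    def test_missing_tip_errors(self):
        tree = TreeNode.read(io.StringIO("(a:0.1,b:0.1):0;"))
        ident = identity_from_values(
            ["a", "b"], [[1.0, 0.99], [0.99, 1.0]]
        )
        raw = table_of({"a": [3]})
        with pytest.raises(ValueError, match="absent from count table"):
            cluster_unassigned(raw, tree, ident, 0.97)

    @pytest.mark.parametrize("threshold", [0.95, 0.97, 0.99])
    def test_random_trees_match_brute_force(self, threshold):
        rng = np.random.default_rng(int(threshold * 1000))
        for _ in range(30):
            n = int(rng.integers(3, 13))
            tips = [f"t{j}" for j in range(n)]
            tree = random_bifurcating_tree(rng, tips)
            vals = rng.uniform(0.9, 1.0, size=(n, n))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 1.0)
            ident = identity_from_values(tips, vals)
            raw = table_of({t: rng.integers(0, 50, size=3).tolist() for t in tips})
            merged, mm = cluster_unassigned(raw, tree, ident, threshold)
            got = sorted(
                frozenset(mm.members(t))
                for t, tag in mm.provenance.items()
                if tag == "clustered"
            )
            assert got == brute_force_clusters(tree, ident, threshold)
            assert (
                merged.counts.sum(axis=1) == raw.counts.sum(axis=1)
            ).all()


class TestNameClusters:
    def _cluster_two(self, counts_a, counts_b):
        nwk = "((a:.01,b:.01):.5,(c:.01,d:.01):.5):0;"
        tree = TreeNode.read(io.StringIO(nwk))
        tips = ["a", "b", "c", "d"]
        vals = np.full((4, 4), 0.90)
        np.fill_diagonal(vals, 1.0)
        ident = identity_from_values(tips, vals)
        for x, y in [("a", "b"), ("c", "d")]:
            ident.loc[x, y] = ident.loc[y, x] = 0.99
        raw = table_of(
            {
                "a": [counts_a[0]],
                "b": [counts_a[1]],
                "c": [counts_b[0]],
                "d": [counts_b[1]],
            }
        )
        return cluster_unassigned(raw, tree, ident, 0.97)

    def test_highest_abundance_is_cluster1(self):
        merged, mm = self._cluster_two((60, 40), (30, 10))
        assert merged.counts["add_cluster1"].tolist() == [100]
        assert merged.counts["add_cluster2"].tolist() == [40]
        assert mm.members("add_cluster1") == ["a", "b"]

    def test_tie_broken_lexicographically_by_members(self):
        merged, mm = self._cluster_two((25, 25), (40, 10))
        # equal totals: {a,b} sorts before {c,d}
        assert mm.members("add_cluster1") == ["a", "b"]
        assert mm.members("add_cluster2") == ["c", "d"]

    def test_single_cluster_named_cluster1(self):
        tree = TreeNode.read(io.StringIO("(a:0.1,b:0.1):0;"))
        ident = identity_from_values(["a", "b"], [[1.0, 0.99], [0.99, 1.0]])
        raw = table_of({"a": [3], "b": [2]})
        merged, _ = cluster_unassigned(raw, tree, ident, 0.97)
        assert merged.taxa == ["add_cluster1"]


class TestFilterGuild:
    def test_confidence_vocabulary(self):
        raw = table_of(
            {"e1": [1], "e2": [2], "e3": [3], "s1": [4]}, guild="EMF"
        )
        anns = [
            ann("e1", guild="EMF", conf="probable"),
            ann("e2", guild="EMF", conf="Highly Probable"),
            ann("e3", guild="EMF", conf="uncertain"),
            ann("s1", guild="saprotroph", conf="probable"),
        ]
        out = filter_guild(raw, anns, "EMF")
        assert sorted(out.taxa) == ["e1", "e2"]

    def test_allow_all_confidences_reduces_to_guild_match(self):
        raw = table_of({"e1": [1], "e3": [3], "s1": [4]}, guild="EMF")
        anns = [
            ann("e1", guild="EMF", conf="probable"),
            ann("e3", guild="EMF", conf="uncertain"),
            ann("s1", guild="saprotroph", conf="probable"),
        ]
        out = filter_guild(
            raw, anns, "EMF", {"probable", "uncertain", "possible"}
        )
        assert sorted(out.taxa) == ["e1", "e3"]

    def test_no_matching_guild_warns_not_errors(self):
        raw = table_of({"s1": [4]}, guild="EMF")
        anns = [ann("s1", guild="saprotroph", conf="probable")]
        with pytest.warns(UserWarning, match="retained no taxa"):
            out = filter_guild(raw, anns, "EMF")
        assert out.taxa == []

    def test_emptied_samples_flagged(self):
        raw = table_of({"e1": [1, 0], "x": [0, 5]}, guild="EMF")
        anns = [
            ann("e1", guild="EMF", conf="probable"),
            ann("x", guild="saprotroph"),
        ]
        with pytest.warns(UserWarning, match="no reads"):
            out = filter_guild(raw, anns, "EMF")
        assert out.all_zero_samples() == ["s1"]
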