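"""Sørensen similarity, pair extraction and per-stratum comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mycodiv import (
    CommunityTable,
    compare_pair_groups,
    extract_pairs,
    soerensen,
)
from mycodiv.core import AM_SPECIES, EM_SPECIES

from conftest import make_records


class TestSoerensen:
    def test_identical_sets(self):
        assert soerensen({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert soerensen({"a"}, {"b"}) == 0.0

    def test_worked_example(self):
        assert soerensen({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(
            2 * 2 / 6
        )

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        universe = [f"x{i}" for i in range(12)]
        for _ in range(200):
            a = set(rng.choice(universe, rng.integers(1, 10), replace=False))
            b = set(rng.choice(universe, rng.integers(1, 10), replace=False))
            s = soerensen(a, b)
            assert 0.0 <= s <= 1.0
            assert s == soerensen(b, a)
            assert soerensen(a, a) == 1.0

    def test_both_empty_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(soerensen(set(), set()))


def build_dataset(meta_spec, communities):
    meta = make_records(meta_spec)
    taxa = sorted(set().union(*communities.values()))
    counts = pd.DataFrame(
        [
            [1 if t in communities[r.sample_id] else 0 for t in taxa]
            for r in meta
        ],
        index=[r.sample_id for r in meta],
        columns=taxa,
    )
    return CommunityTable(counts, {t: "AMF" for t in taxa}), meta


class TestExtractPairs:
    def test_single_mixture_plot_enumeration(self):
        # one 2-species AM plot plus both same-block monocultures:
        # 2 monoculture pairs + 1 neighbour pair
        meta_spec = [
            ("m0", "B1", AM_SPECIES[0], 1, "AM", "m0_s"),
            ("m1", "B1", AM_SPECIES[1], 1, "AM", "m1_s"),
            ("mix", "B1", AM_SPECIES[0], 2, "AM", "mix_a"),
            ("mix", "B1", AM_SPECIES[1], 2, "AM", "mix_b"),
        ]
        communities = {
            "m0_s": {"t1", "t2"},
            "m1_s": {"t2", "t3"},
            "mix_a": {"t1"},
            "mix_b": {"t3", "t4"},
        }
        table, meta = build_dataset(meta_spec, communities)
        pairs, counters = extract_pairs(table, meta, "AMF")
        cats = sorted(p.category for p in pairs)
        assert cats == [
            "mixture_vs_monoculture",
            "mixture_vs_monoculture",
            "target_vs_neighbour",
        ]
        assert all(p.stratum == "AM-2" for p in pairs)
        assert counters["monoculture_partner_missing"] == 0
        by = {(p.focal_sample_id, p.partner_sample_id): p for p in pairs}
        assert by[("mix_a", "m0_s")].similarity == pytest.approx(2 / 3)
        assert by[("mix_b", "m1_s")].similarity == pytest.approx(0.5)

    def test_missing_monoculture_skipped_and_counted(self):
        meta_spec = [
            ("m0", "B2", AM_SPECIES[0], 1, "AM", "m0_s"),  # wrong block
            ("mix", "B1", AM_SPECIES[0], 2, "AM", "mix_a"),
            ("mix", "B1", AM_SPECIES[1], 2, "AM", "mix_b"),
        ]
        communities = {
            "m0_s": {"t1"},
            "mix_a": {"t1"},
            "mix_b": {"t2"},
        }
        table, meta = build_dataset(meta_spec, communities)
        pairs, counters = extract_pairs(table, meta, "AMF")
        assert counters["monoculture_partner_missing"] == 2
        assert all(p.category == "target_vs_neighbour" for p in pairs)

    def test_empty_community_pairs_dropped(self):
        meta_spec = [
            ("m0", "B1", AM_SPECIES[0], 1, "AM", "m0_s"),
            ("mix", "B1", AM_SPECIES[0], 2, "AM", "mix_a"),
            ("mix", "B1", AM_SPECIES[1], 2, "AM", "mix_b"),
        ]
        communities = {
            "m0_s": {"t1"},
            "mix_a": {"t1", "t2"},
            "mix_b": set(),
        }
        table, meta = build_dataset(meta_spec, communities)
        pairs, counters = extract_pairs(table, meta, "AMF")
        assert counters["pairs_dropped_empty"] == 1
        assert len(pairs) == 1  # only the monoculture pair survives

    def test_full_design_counts_match_enumeration_oracle(self):
        """On a dropout-free design, pair counts equal the closed-form
        enumeration from plot compositions."""
        from mycodiv import (
            CommunitySimParams,
            DesignParams,
            generate_design,
            simulate_communities,
        )

        meta = generate_design(DesignParams(sample_dropout=0.0), seed=8)
        params = CommunitySimParams(
            n_amf_taxa=15, n_emf_taxa=0, generalist_occupancy=1.0,
            amf_specialist_fraction=0.0, seed=8,
        )
        table, _ = simulate_communities(meta, params)
        pairs, counters = extract_pairs(table, meta, "AMF")
        # oracle: brute-force enumeration over the metadata alone
        mono = {
            (r.tree_species, r.block) for r in meta if r.plot_richness == 1
        }
        exp_mono = sum(
            1
            for r in meta
            if r.plot_richness > 1
            and r.host_myc_type == "AM"
            and (r.tree_species, r.block) in mono
        )
        by_plot = {}
        for r in meta:
            if r.plot_richness > 1:
                by_plot.setdefault(r.plot_id, []).append(r)
        exp_neigh = sum(
            1
            for recs in by_plot.values()
            for a, b in itertools.combinations(recs, 2)
            if a.tree_species != b.tree_species
            and "AM" in (a.host_myc_type, b.host_myc_type)
        )
        got_mono = sum(
            1 for p in pairs if p.category == "mixture_vs_monoculture"
        )
        got_neigh = sum(
            1 for p in pairs if p.category == "target_vs_neighbour"
        )
        assert got_mono == exp_mono
        assert got_neigh == exp_neigh
        assert counters["pairs_dropped_empty"] == 0  # occupancy 1 everywhere

    def test_invariant_to_sample_order(self):
        from mycodiv import (
            CommunitySimParams,
            DesignParams,
            generate_design,
            simulate_communities,
        )

        meta = generate_design(DesignParams(), seed=9)
        table, _ = simulate_communities(
            meta, CommunitySimParams(n_amf_taxa=10, n_emf_taxa=0), seed=9
        )
        pairs_a, _ = extract_pairs(table, meta, "AMF")
        pairs_b, _ = extract_pairs(table, list(reversed(meta)), "AMF")
        key = lambda p: (p.focal_sample_id, p.partner_sample_id, p.category)
        assert sorted(map(key, pairs_a)) == sorted(map(key, pairs_b))


class TestComparePairGroups:
    @staticmethod
    def pairs(mono_sims, neigh_sims, stratum="AM-2"):
        from mycodiv.beta import PairSimilarity

        out = []
        for i, s in enumerate(mono_sims):
            out.append(
                PairSimilarity(f"f{i}", f"m{i}", "mixture_vs_monoculture",
                               stratum, s)
            )
        for i, s in enumerate(neigh_sims):
            out.append(
                PairSimilarity(f"f{i}", f"n{i}", "target_vs_neighbour",
                               stratum, s)
            )
        return out

    def test_identical_distributions_p_one(self):
        res = compare_pair_groups(
            self.pairs([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        ).iloc[0]
        assert res["p_value"] == 1.0

    def test_extreme_separation_minimal_p(self):
        mono = [0.90, 0.91, 0.92, 0.93, 0.94]
        neigh = [0.10, 0.11, 0.12, 0.13, 0.14]
        res = compare_pair_groups(self.pairs(mono, neigh)).iloc[0]
        # exact two-sided rank-sum floor for 5 vs 5: 2 / C(10,5)
        assert res["p_value"] == pytest.approx(2 / 252, rel=1e-6)
        assert res["median_monoculture"] > res["median_neighbour"]

    def test_missing_category_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="missing a pair category"):
            df = compare_pair_groups(self.pairs([0.5], []))
        assert df.empty


class TestDirectionRecovery:
    @staticmethod
    def run_regime(affinity_level, seed):
        """Host-species-specific vs plot-driven community regimes."""
        from mycodiv import (
            CommunitySimParams,
            DesignParams,
            generate_design,
            simulate_communities,
        )

        meta = generate_design(DesignParams(sample_dropout=0.0), seed=seed)
        if affinity_level == "species":
            params = CommunitySimParams(
                n_amf_taxa=40, n_emf_taxa=0,
                amf_specialist_fraction=1.0,
                affinity_level="species",
                in_group_occupancy=0.9, out_group_occupancy=0.05,
                seed=seed,
            )
            table, _ = simulate_communities(meta, params)
        else:
            # plot-driven: communities depend only on the plot
            rng = np.random.default_rng(seed)
            taxa = [f"t{i}" for i in range(40)]
            plot_comms = {}
            rows = {}
            for r in meta:
                if r.plot_id not in plot_comms:
                    plot_comms[r.plot_id] = set(
                        rng.choice(taxa, size=12, replace=False)
                    )
                rows[r.sample_id] = plot_comms[r.plot_id]
            counts = pd.DataFrame(
                [
                    [1 if t in rows[r.sample_id] else 0 for t in taxa]
                    for r in meta
                ],
                index=[r.sample_id for r in meta],
                columns=taxa,
            )
            table = CommunityTable(counts, {t: "AMF" for t in taxa})
        pairs, _ = extract_pairs(table, meta, "AMF")
        mono = [
            p.similarity for p in pairs
            if p.category == "mixture_vs_monoculture"
        ]
        neigh = [
            p.similarity for p in pairs if p.category == "target_vs_neighbour"
        ]
        return float(np.mean(mono) - np.mean(neigh))

    def test_host_specific_regime_favours_monoculture_pairs(self):
        wins = sum(
            self.run_regime("species", seed) > 0 for seed in range(10)
        )
        assert wins >= 9

    def test_plot_driven_regime_reverses(self):
        wins = sum(
            self.run_regime("plot", seed) < 0 for seed in range(10)
        )
        assert wins >= 9
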