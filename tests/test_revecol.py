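"""revecol: network construction, seed sets, interaction indices."""

import math

import networkx as nx
import numpy as np
import pytest

from minigut import revecol, synthgen
from minigut.iokit import KOProfile, Reaction, ReactionUniverse, ValidationError
from minigut.revecol import (
    MetabolicNetwork,
    SeedSet,
    build_network,
    competition_index,
    complementarity_index,
    expressed_kos,
    pairwise_matrix,
    seed_set,
)

from .conftest import brute_force_seeds, random_digraph


def net_from_edges(edges, organism_id="org"):
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return MetabolicNetwork(organism_id=organism_id, graph=g, source_kos=frozenset())


class TestBuildNetwork:
    def test_single_reaction(self):
        universe = ReactionUniverse(
            (Reaction("r1", {"K00001"}, {"a"}, {"b"}, False),)
        )
        net = build_network(KOProfile.from_set("o", {"K00001"}), universe)
        assert net.compounds == {"a", "b"}
        assert net.edges == {("a", "b")}

    def test_reversible_adds_both_edges(self):
        universe = ReactionUniverse(
            (Reaction("r1", {"K00001"}, {"a"}, {"b"}, True),)
        )
        net = build_network(KOProfile.from_set("o", {"K00001"}), universe)
        assert net.edges == {("a", "b"), ("b", "a")}

    def test_or_semantics_over_kos(self):
        universe = ReactionUniverse(
            (Reaction("r1", {"K00001", "K00002"}, {"a"}, {"b"}, False),)
        )
        net = build_network(KOProfile.from_set("o", {"K00002"}), universe)
        assert net.edges == {("a", "b")}

    def test_empty_network_flagged_not_raised(self):
        universe = ReactionUniverse(
            (Reaction("r1", {"K00001"}, {"a"}, {"b"}, False),)
        )
        net = build_network(KOProfile.from_set("o", {"K00099"}), universe)
        assert net.is_empty

    def test_blacklist_removes_compounds(self):
        universe = ReactionUniverse(
            (Reaction("r1", {"K00001"}, {"a", "h2o"}, {"b"}, False),)
        )
        net = build_network(
            KOProfile.from_set("o", {"K00001"}), universe, exclude_compounds={"h2o"}
        )
        assert net.compounds == {"a", "b"}

    def test_matches_triple_loop_oracle(self, rng):
        for seed in range(10):
            universe = synthgen.gen_reaction_universe(12, 18, seed=seed)
            all_kos = sorted(universe.kos)
            picked = {
                all_kos[i]
                for i in rng.choice(len(all_kos), size=len(all_kos) // 3, replace=False)
            }
            net = build_network(KOProfile.from_set("o", picked), universe)
            expected = set()
            for reaction in universe.reactions:
                if picked & reaction.ko_ids:
                    for s in reaction.substrates:
                        for p in reaction.products:
                            expected.add((s, p))
                            if reaction.reversible:
                                expected.add((p, s))
            assert net.edges == expected


class TestSeedSet:
    def test_chain(self):
        ss = seed_set(net_from_edges([("a", "b"), ("b", "c")]))
        assert ss.seeds == {"a": 1.0}
        assert ss.nonseeds == {"b", "c"}

    def test_cycle_plus_sources(self):
        ss = seed_set(
            net_from_edges([("a", "b"), ("b", "a"), ("b", "c"), ("d", "c")])
        )
        assert ss.seeds == {"a": 0.5, "b": 0.5, "d": 1.0}
        assert ss.nonseeds == {"c"}

    def test_fully_cyclic(self):
        edges = [("a", "b"), ("b", "c"), ("c", "a")]
        ss = seed_set(net_from_edges(edges))
        assert ss.seeds == {c: pytest.approx(1 / 3) for c in "abc"}
        assert not ss.nonseeds

    def test_empty_network(self):
        ss = seed_set(
            MetabolicNetwork("o", nx.DiGraph(), frozenset())
        )
        assert not ss.seeds and not ss.nonseeds

    @pytest.mark.parametrize("chunk", range(4))
    def test_matches_brute_force_on_random_digraphs(self, chunk):
        # 4 x 50 draws here; the 1000-draw sweep runs in the acceptance suite
        rng = np.random.default_rng(1000 + chunk)
        for _ in range(50):
            edges, nodes = random_digraph(rng)
            ss = seed_set(net_from_edges(edges))
            seeds, nonseeds = brute_force_seeds(edges, nodes)
            assert set(ss.seeds) == set(seeds)
            for c, conf in seeds.items():
                assert ss.seeds[c] == pytest.approx(conf)
            assert ss.nonseeds == nonseeds

    def test_confidence_normalization(self, rng):
        for _ in range(20):
            edges, nodes = random_digraph(rng)
            ss = seed_set(net_from_edges(edges))
            g = nx.DiGraph()
            g.add_edges_from(edges)
            cond = nx.condensation(g)
            sources = [c for c in cond.nodes if cond.in_degree(c) == 0]
            # per-component confidences sum to 1; total = number of sources
            for comp in sources:
                members = cond.nodes[comp]["members"]
                assert sum(ss.seeds[c] for c in members) == pytest.approx(1.0)
            assert sum(ss.seeds.values()) == pytest.approx(len(sources))


class TestIndices:
    def make_seedset(self, seeds, nonseeds=(), organism_id="o"):
        if not isinstance(seeds, dict):
            seeds = {c: 1.0 for c in seeds}
        return SeedSet(
            organism_id=organism_id, seeds=seeds, nonseeds=frozenset(nonseeds)
        )

    def test_identical_seed_sets_compete_fully(self):
        a = self.make_seedset({"x", "y"})
        b = self.make_seedset({"x", "y"}, organism_id="p")
        assert competition_index(a, b) == 1.0

    def test_disjoint_seed_sets(self):
        a = self.make_seedset({"x"})
        b = self.make_seedset({"y"})
        assert competition_index(a, b) == 0.0

    def test_half_overlap(self):
        a = self.make_seedset({"a", "b"})
        b = self.make_seedset({"b", "c"})
        assert competition_index(a, b) == pytest.approx(0.5)

    def test_weighted_competition(self):
        a = self.make_seedset({"a": 0.25, "b": 0.75})
        b = self.make_seedset({"b"})
        assert competition_index(a, b, weighted=True) == pytest.approx(0.75)

    def test_self_complementarity_zero(self):
        a = self.make_seedset({"x"}, nonseeds={"y"})
        assert complementarity_index(a, a) == 0.0

    def test_full_complementarity(self):
        a = self.make_seedset({"x"})
        b = self.make_seedset({"z"}, nonseeds={"x"})
        assert complementarity_index(a, b) == 1.0

    def test_empty_focal_flagged_undefined(self):
        a = self.make_seedset(set())
        b = self.make_seedset({"x"})
        assert math.isnan(competition_index(a, b))
        assert math.isnan(complementarity_index(a, b))

    def test_planted_crossfeeding_certificate(self):
        universe = synthgen.gen_reaction_universe(16, 30, seed=7)
        prof_a, prof_b, cert = synthgen.gen_crossfeeding_pair(universe, seed=8)
        sa = seed_set(build_network(prof_a, universe))
        sb = seed_set(build_network(prof_b, universe))
        assert cert["compound"] in sa.seeds
        assert cert["compound"] in sb.nonseeds
        assert complementarity_index(sa, sb) > 0

    def test_bounds_on_random_instances(self):
        for seed in range(30):
            universe = synthgen.gen_reaction_universe(14, 22, seed=seed)
            rng = np.random.default_rng(seed)
            kos = sorted(universe.kos)
            pick = lambda: {kos[i] for i in rng.choice(len(kos), 6, replace=False)}
            sa = seed_set(build_network(KOProfile.from_set("a", pick()), universe))
            sb = seed_set(build_network(KOProfile.from_set("b", pick()), universe))
            for weighted in (False, True):
                for f in (competition_index, complementarity_index):
                    v = f(sa, sb, weighted=weighted)
                    if not math.isnan(v):
                        assert 0.0 <= v <= 1.0
            if sa.seeds:
                assert competition_index(sa, sa) == 1.0
                assert complementarity_index(sa, sa) == 0.0

    def test_complementarity_monotone_under_feeding_reaction(self):
        # giving B a reaction that internalizes one of A's seeds (from a
        # fresh substrate) can only raise or preserve complementarity(A->B)
        for seed in range(15):
            universe = synthgen.gen_reaction_universe(12, 18, seed=seed)
            rng = np.random.default_rng(seed + 99)
            kos = sorted(universe.kos)
            pick = lambda n: {kos[i] for i in rng.choice(len(kos), n, replace=False)}
            prof_a = KOProfile.from_set("a", pick(5))
            kos_b = pick(5)
            sa = seed_set(build_network(prof_a, universe))
            if not sa.seeds:
                continue
            sb = seed_set(build_network(KOProfile.from_set("b", kos_b), universe))
            before = complementarity_index(sa, sb)
            target = sorted(sa.seeds)[0]
            feeding = Reaction(
                "R_FEED", {"K99999"}, {"C_FRESH_SUBSTRATE"}, {target}, False
            )
            bigger = ReactionUniverse(universe.reactions + (feeding,))
            sb_after = seed_set(
                build_network(
                    KOProfile.from_set("b", kos_b | {"K99999"}), bigger
                )
            )
            after = complementarity_index(sa, sb_after)
            assert after >= before - 1e-12


class TestExpressedKOs:
    def test_min_count_one_gives_support(self):
        p = KOProfile("u", {"K00001": 3.0, "K00002": 0.0}, mode="counts")
        assert expressed_kos(p).support() == {"K00001"}

    def test_threshold_above_max_empty(self):
        p = KOProfile("u", {"K00001": 3.0}, mode="counts")
        assert expressed_kos(p, min_count=10).support() == set()

    def test_matches_loop_filter(self, rng):
        counts = {f"K{i:05d}": float(rng.integers(0, 10)) for i in range(1, 40)}
        p = KOProfile("u", counts, mode="counts")
        got = expressed_kos(p, min_count=3).support()
        assert got == {k for k, v in counts.items() if v >= 3}

    def test_rejects_set_mode(self):
        with pytest.raises(ValidationError):
            expressed_kos(KOProfile.from_set("u", {"K00001"}))


class TestPairwiseMatrix:
    def test_identical_organisms(self):
        universe = synthgen.gen_reaction_universe(12, 20, seed=3)
        kos = sorted(universe.kos)[:8]
        orgs = [KOProfile.from_set("a", kos), KOProfile.from_set("b", kos)]
        indices = pairwise_matrix(orgs, universe)
        for x in indices:
            assert x.competition == 1.0
            assert x.complementarity == 0.0

    def test_expressed_full_expression_equals_genome(self):
        universe = synthgen.gen_reaction_universe(14, 25, seed=4)
        genomes = []
        rng = np.random.default_rng(4)
        kos = sorted(universe.kos)
        for name in ("a", "b", "c"):
            picked = sorted(
                {kos[i] for i in rng.choice(len(kos), 8, replace=False)}
            )
            genomes.append(KOProfile.from_set(name, picked))
        expressed = [
            synthgen.gen_expression_subset(g, 1.0, seed=i)
            for i, g in enumerate(genomes)
        ]
        gen = pairwise_matrix(genomes, universe, basis="genome")
        exp = pairwise_matrix(expressed, universe, basis="expressed")
        for g, e in zip(gen, exp):
            assert (g.focal, g.partner) == (e.focal, e.partner)
            assert g.competition == pytest.approx(e.competition, nan_ok=True)
            assert g.complementarity == pytest.approx(e.complementarity, nan_ok=True)

    def test_matrix_matches_elementwise_brute_force(self):
        universe = synthgen.gen_reaction_universe(12, 20, seed=9)
        rng = np.random.default_rng(9)
        kos = sorted(universe.kos)
        orgs = [
            KOProfile.from_set(
                f"org{i}", {kos[j] for j in rng.choice(len(kos), 5, replace=False)}
            )
            for i in range(10)
        ]
        indices = {
            (x.focal, x.partner): x for x in pairwise_matrix(orgs, universe)
        }
        for fa in orgs:
            for fb in orgs:
                net_a = build_network(fa, universe)
                seeds_a, nons_a = brute_force_seeds(
                    set(net_a.edges), set(net_a.compounds)
                )
                net_b = build_network(fb, universe)
                seeds_b, nons_b = brute_force_seeds(
                    set(net_b.edges), set(net_b.compounds)
                )
                x = indices[(fa.unit_id, fb.unit_id)]
                if not seeds_a:
                    assert math.isnan(x.competition)
                    continue
                comp = len(set(seeds_a) & set(seeds_b)) / len(seeds_a)
                compl = len(set(seeds_a) & nons_b) / len(seeds_a)
                assert x.competition == pytest.approx(comp)
                assert x.complementarity == pytest.approx(compl)

    def test_needs_two_organisms(self):
        universe = synthgen.gen_reaction_universe(8, 10, seed=1)
        with pytest.raises(ValidationError):
            pairwise_matrix([KOProfile.from_set("a", {"K00001"})], universe)
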