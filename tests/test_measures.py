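import itertools

import networkx as nx
import numpy as np
import pytest

from duonet.measures import (
    UndefinedMeasureError,
    alter_density,
    burt_constraint,
    composition_and_overlap,
    count_components,
    criterion_profile,
    nominee_subgroup_density,
)
from duonet.merge import classify_roles, match_alters, merge_to_duocentric
from duonet.synthetic import DEFAULT_ARCHETYPES, generate_couple

from .conftest import make_net
from .oracles import components_oracle, constraint_oracle, density_oracle


def _random_net(rng, max_alters=13):
    """Random weighted duocentric-shaped network, incl. ego-alter edges."""
    n = int(rng.integers(3, max_alters + 1))
    alter_edges, ego_edges = {}, {}
    for i, j in itertools.combinations(range(n), 2):
        alter_edges[(i, j)] = int(rng.integers(0, 4)) if rng.random() < 0.5 else 0
    for i in range(n):
        for role in ("wife", "husband"):
            if rng.random() < 0.6:
                ego_edges[(role, i)] = int(rng.integers(1, 4))
    return make_net(alter_edges, n_alters=n, ego_edges=ego_edges), n, alter_edges, ego_edges


class TestDensity:
    def test_hand_enumerated_example(self):
        net = make_net({(0, 1): 3, (1, 2): 2, (2, 3): 1}, n_alters=4)
        assert alter_density(net) == pytest.approx(2 / 6)

    def test_complete_and_empty(self):
        full = make_net({(i, j): 3 for i, j in itertools.combinations(range(6), 2)})
        assert alter_density(full) == 1.0
        weak = make_net({(0, 1): 1}, n_alters=5)
        assert alter_density(weak) == 0.0

    def test_ego_edges_do_not_count(self):
        net = make_net({(0, 1): 3}, n_alters=3,
                       ego_edges={("wife", 0): 3, ("husband", 2): 3})
        assert alter_density(net) == pytest.approx(1 / 3)

    def test_undefined_below_two_alters(self):
        with pytest.raises(UndefinedMeasureError):
            alter_density(make_net({}, n_alters=1))


class TestComponents:
    def test_all_isolates(self):
        assert count_components(make_net({}, n_alters=24)) == 24

    def test_spanning_path(self):
        net = make_net({(i, i + 1): 2 for i in range(23)}, n_alters=24)
        assert count_components(net) == 1

    def test_two_cliques_plus_isolates(self):
        edges = {(i, j): 3 for i, j in itertools.combinations(range(5), 2)}
        edges.update({(i, j): 2 for i, j in itertools.combinations(range(5, 10), 2)})
        assert count_components(make_net(edges, n_alters=13)) == 5

    def test_undefined_without_alters(self):
        with pytest.raises(UndefinedMeasureError):
            count_components(make_net({}, n_alters=0))


def test_density_and_components_match_oracle_on_random_graphs():
    rng = np.random.default_rng(42)
    for _ in range(100):
        net, n, alter_edges, _ = _random_net(rng)
        for threshold in (1, 2, 3):
            edges = {frozenset((f"a{i}", f"a{j}"))
                     for (i, j), w in alter_edges.items() if w >= threshold}
            nodes = [f"a{i}" for i in range(n)]
            assert alter_density(net, threshold) == pytest.approx(
                density_oracle(nodes, edges))
            assert count_components(net, threshold) == components_oracle(nodes, edges)


def test_threshold_monotonicity():
    rng = np.random.default_rng(7)
    for _ in range(25):
        net, *_ = _random_net(rng)
        d = [alter_density(net, t) for t in (1, 2, 3)]
        c = [count_components(net, t) for t in (1, 2, 3)]
        assert d[0] >= d[1] >= d[2]
        assert c[0] <= c[1] <= c[2]


class TestCompositionOverlap:
    def test_proportions_use_full_size(self):
        roles = {i: {"husband_family"} for i in range(6)}
        net = make_net({}, n_alters=24, roles=roles)
        comp = composition_and_overlap(net)
        assert comp["husband_family"] == pytest.approx(6 / 26)
        assert comp["both_nominated"] == 0.0

    def test_generator_planted_counts(self, couple_seed7):
        rec, truth = couple_seed7
        m = match_alters(rec.wife, rec.husband)
        net = classify_roles(merge_to_duocentric(rec.wife, rec.husband, m),
                             rec.wife, rec.husband, m)
        comp = composition_and_overlap(net)
        assert comp["both_nominated"] == pytest.approx(len(truth.shared_pairs) / net.size)
        # recount husband-family from the planted blocks
        blocks = truth.blocks
        hf = sum(1 for b in blocks["husband"].values() if b in ("family", "shared_family_h"))
        assert comp["husband_family"] == pytest.approx(hf / net.size)
        assert all(0 <= v <= 1 for v in comp.values())


class TestNomineeDensity:
    def test_clique_among_nominees(self):
        prov = {i: "husband_only" for i in range(24)}
        edges = {(i, j): 3 for i, j in itertools.combinations(range(5), 2)}
        net = make_net(edges, n_alters=24, provenance=prov)
        assert nominee_subgroup_density(net, "husband") == pytest.approx(10 / 276)
        with pytest.raises(UndefinedMeasureError):
            nominee_subgroup_density(net, "wife")  # no wife nominees

    def test_saturated_subgroup(self):
        prov = {0: "wife_only", 1: "both", 2: "husband_only"}
        net = make_net({(0, 1): 2, (0, 2): 1, (1, 2): 1}, n_alters=3, provenance=prov)
        assert nominee_subgroup_density(net, "wife") == 1.0

    def test_husband_family_archetype_has_denser_husband_side(self):
        rec, _ = generate_couple(DEFAULT_ARCHETYPES["husband_family"], "c", 11)
        m = match_alters(rec.wife, rec.husband)
        net = merge_to_duocentric(rec.wife, rec.husband, m)
        assert nominee_subgroup_density(net, "husband") > nominee_subgroup_density(net, "wife")


class TestConstraint:
    def test_closed_triad(self):
        net = make_net({(0, 1): 3}, n_alters=2,
                       ego_edges={("wife", 0): 3, ("wife", 1): 3})
        # spouse edge makes the husband a third contact; isolate him instead
        net.graph.remove_edge(net.WIFE_EGO, net.HUSBAND_EGO)
        assert burt_constraint(net, "wife") == pytest.approx(1.125)

    @pytest.mark.parametrize("d", [1, 2, 5, 10])
    def test_star_closed_form(self, d):
        net = make_net({}, n_alters=d, ego_edges={("wife", i): 3 for i in range(d)})
        net.graph.remove_edge(net.WIFE_EGO, net.HUSBAND_EGO)
        assert burt_constraint(net, "wife") == pytest.approx(1 / d)

    def test_single_neighbor_is_fully_constrained(self):
        net = make_net({}, n_alters=3)
        # only the forced spouse edge is strong: a dyad
        assert burt_constraint(net, "wife") == pytest.approx(1.0)

    def test_isolated_ego_undefined(self):
        net = make_net({}, n_alters=3)
        net.graph.remove_edge(net.WIFE_EGO, net.HUSBAND_EGO)
        with pytest.raises(UndefinedMeasureError):
            burt_constraint(net, "wife")

    def test_matches_triple_sum_oracle_and_networkx(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            net, n, alter_edges, ego_edges = _random_net(rng, max_alters=8)
            edges = {frozenset((f"a{i}", f"a{j}"))
                     for (i, j), w in alter_edges.items() if w >= 3}
            edges |= {
                frozenset((net.ego_node(r), f"a{i}"))
                for (r, i), w in ego_edges.items() if w >= 3
            }
            edges.add(frozenset((net.WIFE_EGO, net.HUSBAND_EGO)))
            nodes = [f"a{i}" for i in range(n)] + [net.WIFE_EGO, net.HUSBAND_EGO]
            for role in ("wife", "husband"):
                ours = burt_constraint(net, role)
                assert ours == pytest.approx(constraint_oracle(net.ego_node(role), nodes, edges))
                g = nx.Graph(list(tuple(e) for e in edges))
                assert ours == pytest.approx(nx.constraint(g, [net.ego_node(role)])[net.ego_node(role)])


class TestCriterionProfile:
    def test_profile_equals_component_measures(self, couple_seed7):
        rec, _ = couple_seed7
        m = match_alters(rec.wife, rec.husband)
        net = classify_roles(merge_to_duocentric(rec.wife, rec.husband, m),
                             rec.wife, rec.husband, m)
        p = criterion_profile(net)
        assert p.density == pytest.approx(alter_density(net))
        assert p.components == count_components(net)
        assert p.husband_constraint == pytest.approx(burt_constraint(net, "husband"))
        assert p.wife_nominee_density == pytest.approx(nominee_subgroup_density(net, "wife"))
        comp = composition_and_overlap(net)
        for key, value in comp.items():
            assert getattr(p, key) == pytest.approx(value)
        assert p.network_size == net.size
        for key in ("density", "husband_family", "wife_family", "husband_friend",
                    "wife_friend", "shared_friends", "both_nominated",
                    "husband_nominee_density", "wife_nominee_density"):
            assert 0 <= getattr(p, key) <= 1

    def test_undefined_measures_become_nan(self):
        net = make_net({}, n_alters=2, provenance={0: "wife_only", 1: "wife_only"})
        net.graph.remove_edge(net.WIFE_EGO, net.HUSBAND_EGO)
        p = criterion_profile(net)
        assert np.isnan(p.husband_nominee_density)
        assert np.isnan(p.wife_constraint)
        assert p.components == 2
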