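import itertools

import numpy as np
import pytest

from duonet.merge import (
    MatchingConsistencyError,
    classify_roles,
    export_graphml,
    match_alters,
    merge_to_duocentric,
    read_graphml,
)
from duonet.synthetic import DEFAULT_ARCHETYPES, generate_couple

from .conftest import make_interview


def _names(prefix, n):
    return [f"{prefix}{i:02d} person" for i in range(n)]


def test_kin_reciprocity_confirms_name_match():
    wife = make_interview("c1", "wife", "hank smith", ["maria lopez"] + _names("w", 23),
                          flags={"maria lopez": {"own_family"}})
    husband = make_interview("c1", "husband", "wilma smith", ["maria lopez"] + _names("h", 23),
                             flags={"maria lopez": {"spouse_family"}})
    m = match_alters(wife, husband)
    assert m.pairs == [(2, 2)]
    assert "kin_reciprocity" in m.evidence[0].criteria


def test_disjoint_names_match_nothing():
    wife = make_interview("c1", "wife", "hank smith", _names("w", 24))
    husband = make_interview("c1", "husband", "wilma smith", _names("h", 24))
    m = match_alters(wife, husband)
    assert m.n_matched == 0
    assert len(m.unmatched_wife) == 24
    assert len(m.unmatched_husband) == 24


def test_spouse_entries_never_match_third_parties():
    # the husband names an alter whose name equals the wife's spouse entry
    wife = make_interview("c1", "wife", "hank smith", _names("w", 24))
    husband = make_interview("c1", "husband", "wilma smith",
                             ["hank smith"] + _names("h", 23))
    m = match_alters(wife, husband)
    assert m.n_matched == 0


def test_duplicate_names_resolved_deterministically_and_flagged():
    dup = ["ana ruiz", "ana ruiz"]
    wife = make_interview("c1", "wife", "h s", dup + _names("w", 22))
    husband = make_interview("c1", "husband", "w s", dup + _names("h", 22))
    m = match_alters(wife, husband)
    assert m.pairs == [(2, 2), (3, 3)]
    assert all(ev.ambiguous for ev in m.evidence)


def test_generator_overlap_recovered_exactly(couple_seed7):
    rec, truth = couple_seed7
    m = match_alters(rec.wife, rec.husband)
    assert sorted(m.pairs) == truth.shared_pairs


def test_max_rule_takes_the_higher_spouse_rating():
    shared = ["ana ruiz", "beto cruz"]
    wife = make_interview("c1", "wife", "hank s", shared + _names("w", 22),
                          ties={("ana ruiz", "beto cruz"): 3})
    husband = make_interview("c1", "husband", "wilma s", shared + _names("h", 22),
                             ties={("ana ruiz", "beto cruz"): 2})
    m = match_alters(wife, husband)
    net = merge_to_duocentric(wife, husband, m, combine="max")
    a, b = "b02_02", "b03_03"
    assert net.weight(a, b) == 3
    assert merge_to_duocentric(wife, husband, m, combine="min").weight(a, b) == 2
    assert merge_to_duocentric(wife, husband, m, combine="mean").weight(a, b) == 2.5


def test_node_count_bounds():
    shared = _names("s", 24)
    wife = make_interview("c1", "wife", "hank s", shared)
    husband = make_interview("c1", "husband", "wilma s", shared)
    net = merge_to_duocentric(wife, husband, match_alters(wife, husband))
    assert net.size == 26  # identical lists: 2 egos + 24 unique alters

    wife = make_interview("c1", "wife", "hank s", _names("w", 24))
    husband = make_interview("c1", "husband", "wilma s", _names("h", 24))
    net = merge_to_duocentric(wife, husband, match_alters(wife, husband))
    assert net.size == 50  # fully disjoint lists: the theoretical maximum


@pytest.mark.parametrize("seed", [1, 5, 9])
@pytest.mark.parametrize("archetype", ["wife_friend", "shared_friends"])
def test_node_count_equals_fifty_minus_matches(archetype, seed):
    rec, truth = generate_couple(DEFAULT_ARCHETYPES[archetype], "cx", seed)
    m = match_alters(rec.wife, rec.husband)
    net = merge_to_duocentric(rec.wife, rec.husband, m)
    assert net.size == 50 - m.n_matched
    assert 26 <= net.size <= 50
    assert net.weight(net.WIFE_EGO, net.HUSBAND_EGO) == 3


def test_combine_rule_monotonicity(couple_seed7):
    rec, _ = couple_seed7
    m = match_alters(rec.wife, rec.husband)
    nets = {c: merge_to_duocentric(rec.wife, rec.husband, m, combine=c)
            for c in ("max", "min", "mean")}
    for u, v, w in nets["max"].graph.edges(data="weight"):
        if {u, v} == {nets["max"].WIFE_EGO, nets["max"].HUSBAND_EGO}:
            continue
        assert nets["min"].weight(u, v) <= nets["mean"].weight(u, v) <= w


def test_merge_symmetric_in_spouse_order(couple_seed7):
    rec, _ = couple_seed7
    m = match_alters(rec.wife, rec.husband)
    net = merge_to_duocentric(rec.wife, rec.husband, m)

    swapped_m = match_alters(rec.husband, rec.wife)
    assert sorted((h, w) for w, h in m.pairs) == sorted(swapped_m.pairs)
    # swap roles so the "wife" argument is the husband's interview
    import copy
    w2, h2 = copy.deepcopy(rec.husband), copy.deepcopy(rec.wife)
    w2.ego_role, h2.ego_role = "wife", "husband"
    net2 = merge_to_duocentric(w2, h2, swapped_m)
    assert net.size == net2.size
    weights1 = sorted(w for _, _, w in net.graph.edges(data="weight"))
    weights2 = sorted(w for _, _, w in net2.graph.edges(data="weight"))
    assert weights1 == weights2


def test_inconsistent_matching_rejected(couple_seed7):
    rec, _ = couple_seed7
    m = match_alters(rec.wife, rec.husband)
    m.pairs.append((99, 98))
    with pytest.raises(MatchingConsistencyError):
        merge_to_duocentric(rec.wife, rec.husband, m)
    m.pairs.pop()


def test_role_classification_rules():
    wife = make_interview(
        "c1", "wife", "hank s",
        ["ana ruiz", "beto cruz", "cleo diaz"] + _names("w", 21),
        flags={"ana ruiz": {"own_friend"}, "cleo diaz": {"coworker"}},
    )
    husband = make_interview(
        "c1", "husband", "wilma s",
        ["ana ruiz", "dora ponce"] + _names("h", 22),
        flags={"ana ruiz": {"own_friend"}, "dora ponce": {"own_family"}},
    )
    m = match_alters(wife, husband)
    net = classify_roles(merge_to_duocentric(wife, husband, m), wife, husband, m)
    roles = {n: net.graph.nodes[n]["roles"] for n in net.alter_nodes()}
    shared = "b02_02"
    # named own friend by both spouses: shared friend, and a friend of each
    assert roles[shared] == {"shared_friend", "wife_friend", "husband_friend"}
    # flagged own_family by the husband only
    assert roles["h03"] == {"husband_family"}
    # coworker only: contributes to size but to no composition numerator
    assert roles["w04"] == set()


def test_one_spouse_double_friend_flag_makes_shared_friend():
    wife = make_interview("c1", "wife", "h s", ["eva luna"] + _names("w", 23),
                          flags={"eva luna": {"own_friend", "spouse_friend"}})
    husband = make_interview("c1", "husband", "w s", _names("h", 24))
    m = match_alters(wife, husband)
    net = classify_roles(merge_to_duocentric(wife, husband, m), wife, husband, m)
    assert "shared_friend" in net.graph.nodes["w02"]["roles"]


def test_graphml_round_trip_and_spouse_exclusion(tmp_path, couple_seed7):
    rec, truth = couple_seed7
    m = match_alters(rec.wife, rec.husband)
    net = classify_roles(merge_to_duocentric(rec.wife, rec.husband, m),
                         rec.wife, rec.husband, m)
    p_full = tmp_path / "full.graphml"
    p_bare = tmp_path / "bare.graphml"
    export_graphml(net, p_full, include_spouses=True)
    export_graphml(net, p_bare, include_spouses=False)

    g = read_graphml(p_full)
    assert g.number_of_nodes() == net.size
    assert read_graphml(p_bare).number_of_nodes() == net.size - 2
    for n in net.alter_nodes():
        assert g.nodes[n]["roles"] == net.graph.nodes[n]["roles"]
        assert g.edges == net.graph.edges
    # provenance counts in the file equal the matching statistics
    prov = [d["provenance"] for _, d in g.nodes(data=True) if d["kind"] == "alter"]
    assert prov.count("both") == m.n_matched == len(truth.shared_pairs)
    assert prov.count("wife_only") == len(m.unmatched_wife)
    assert prov.count("husband_only") == len(m.unmatched_husband)
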