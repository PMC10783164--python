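import networkx as nx
import numpy as np
import pytest

from duonet.merge import DuocentricNetwork
from duonet.records import AlterRecord, CoupleRecord, EgoInterview
from duonet.synthetic import DEFAULT_ARCHETYPES, generate_cohort, generate_couple


def make_interview(couple_id, role, spouse_name, alter_names, ties=None, flags=None,
                   knowing=None, satisfaction=40.0, **alter_kwargs):
    """Build a small interview by hand: spouse first, then the named alters.

    ``ties`` maps (name_a, name_b) -> rating over the non-spouse alters;
    ``flags``/``knowing`` map name -> relation-flag set / knowing rating.
    """
    flags = flags or {}
    knowing = knowing or {}
    alters = [AlterRecord(alter_index=1, name_key=spouse_name, is_spouse=True, knowing=3)]
    for i, name in enumerate(alter_names, start=2):
        alters.append(
            AlterRecord(alter_index=i, name_key=name, is_spouse=False,
                        relation_flags=flags.get(name, set()),
                        knowing=knowing.get(name, 2), **alter_kwargs)
        )
    n = len(alters)
    mat = np.zeros((n, n), dtype=int)
    pos = {a.name_key: a.alter_index - 1 for a in alters}
    for (a, b), r in (ties or {}).items():
        mat[pos[a], pos[b]] = mat[pos[b], pos[a]] = r
    return EgoInterview(couple_id=couple_id, ego_role=role, alters=alters,
                        alter_ties=mat, satisfaction=satisfaction)


def make_net(alter_edges, n_alters=None, provenance=None, roles=None,
             ego_edges=None, couple_id="t1"):
    """Build a DuocentricNetwork directly from weighted alter-alter edges.

    ``alter_edges``: {(i, j): weight} over integer alter ids 0..n-1;
    ``ego_edges``: {("wife"|"husband", i): weight} ego-alter ties.
    """
    if n_alters is None:
        n_alters = 1 + max((max(i, j) for i, j in alter_edges), default=-1)
    g = nx.Graph()
    g.add_node(DuocentricNetwork.WIFE_EGO, kind="ego", ego_role="wife",
               provenance="ego", both_nominated=False, roles=set())
    g.add_node(DuocentricNetwork.HUSBAND_EGO, kind="ego", ego_role="husband",
               provenance="ego", both_nominated=False, roles=set())
    g.add_edge(DuocentricNetwork.WIFE_EGO, DuocentricNetwork.HUSBAND_EGO, weight=3)
    provenance = provenance or {}
    roles = roles or {}
    for i in range(n_alters):
        prov = provenance.get(i, "wife_only")
        g.add_node(f"a{i}", kind="alter", provenance=prov, name=f"a{i}",
                   both_nominated=prov == "both", roles=set(roles.get(i, set())))
    for (i, j), w in alter_edges.items():
        if w > 0:
            g.add_edge(f"a{i}", f"a{j}", weight=w)
    for (role, i), w in (ego_edges or {}).items():
        node = DuocentricNetwork.WIFE_EGO if role == "wife" else DuocentricNetwork.HUSBAND_EGO
        if w > 0:
            g.add_edge(node, f"a{i}", weight=w)
    return DuocentricNetwork(g, couple_id)


@pytest.fixture(scope="session")
def couple_seed7():
    """One wife_friend-archetype couple with its ground truth (seed 7)."""
    return generate_couple(DEFAULT_ARCHETYPES["wife_friend"], "c7", 7)


@pytest.fixture(scope="session")
def small_cohort():
    """40 synthetic couples with ground truth, shared across tests."""
    return generate_cohort(40, seed=11)


@pytest.fixture(scope="session")
def cohort_tables(tmp_path_factory, small_cohort):
    from duonet.synthetic import write_cohort

    records, truths = small_cohort
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(records, truths, out)
    return out
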