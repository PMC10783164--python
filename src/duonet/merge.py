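"""Merge two spouses' egocentric networks into one duocentric network.

Construction follows the consensus ("cognitive social structure") approach:
alters named by both spouses are identified by normalized name comparison,
corroborated by relation-flag reciprocity (a husband's "my family" alter
matching a wife's "spouse's family" alter) and alter demographics; matched
alters become a single node. Where both spouses rated the same pair, the
ratings are combined — by maximum by default, so a tie exists whenever either
spouse perceives it. Both egos are nodes: each ego's knowing ratings of their
own alters are edges, each ego's ratings of (spouse, alter) pairs inform the
partner's ego-alter edges, and the spouse-spouse edge is fixed at the maximum
strength (spouses were not asked to rate each other).

With two complete 25-alter interviews the merged network has between 26 nodes
(identical alter lists) and 50 (fully disjoint lists).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import networkx as nx

from .records import AlterRecord, EgoInterview

#: maximum ordinal tie strength; the forced spouse-spouse edge weight
MAX_TIE = 3

COMBINE_RULES = {
    "max": max,
    "min": min,
    "mean": lambda vals: statistics.fmean(vals),
}

ROLE_LABELS = ("husband_family", "wife_family", "husband_friend", "wife_friend", "shared_friend")


@dataclass
class MatchEvidence:
    wife_index: int
    husband_index: int
    criteria: list = field(default_factory=list)  # subset of {"name","unique","kin_reciprocity","demographics"}
    ambiguous: bool = False


@dataclass
class AlterMatching:
    """Cross-spouse identity map over non-spouse alters."""

    pairs: list  # (wife_alter_index, husband_alter_index)
    unmatched_wife: list
    unmatched_husband: list
    evidence: list  # MatchEvidence, parallel to pairs

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def _flags_reciprocal(w: AlterRecord, h: AlterRecord) -> bool:
    """Relation flags corroborate identity across the two interviews."""
    wf, hf = w.relation_flags, h.relation_flags
    return bool(
        ("own_family" in wf and "spouse_family" in hf)
        or ("spouse_family" in wf and "own_family" in hf)
        or ("own_friend" in wf and "spouse_friend" in hf)
        or ("spouse_friend" in wf and "own_friend" in hf)
        or ("own_friend" in wf and "own_friend" in hf)
    )


def _demographics_match(w: AlterRecord, h: AlterRecord) -> bool:
    shared = set(w.demographics) & set(h.demographics)
    return bool(shared) and all(w.demographics[k] == h.demographics[k] for k in shared)


def match_alters(wife: EgoInterview, husband: EgoInterview) -> AlterMatching:
    """Identify alters named by both spouses.

    Exact normalized-name equality proposes a pair; the pair is confirmed when
    the name is unique on both sides, or when relation-flag reciprocity or
    matching demographics corroborate it. Duplicate names are paired
    deterministically (corroborated pairs first, then lowest indices) and
    flagged ambiguous. Spouse-as-alter entries are never matched to a third
    party — they fold into the partner's ego node at merge time.
    """
    w_alters = [a for a in wife.alters if not a.is_spouse]
    h_alters = [a for a in husband.alters if not a.is_spouse]
    by_key_w: dict[str, list[AlterRecord]] = {}
    by_key_h: dict[str, list[AlterRecord]] = {}
    for a in w_alters:
        by_key_w.setdefault(a.name_key, []).append(a)
    for a in h_alters:
        by_key_h.setdefault(a.name_key, []).append(a)

    pairs, evidence = [], []
    matched_w, matched_h = set(), set()
    for key in sorted(set(by_key_w) & set(by_key_h)):
        ws = sorted(by_key_w[key], key=lambda a: a.alter_index)
        hs = sorted(by_key_h[key], key=lambda a: a.alter_index)
        unique = len(ws) == 1 and len(hs) == 1
        if unique:
            w, h = ws[0], hs[0]
            ev = MatchEvidence(w.alter_index, h.alter_index, ["name", "unique"])
            if _flags_reciprocal(w, h):
                ev.criteria.append("kin_reciprocity")
            if _demographics_match(w, h):
                ev.criteria.append("demographics")
            pairs.append((w.alter_index, h.alter_index))
            evidence.append(ev)
            continue
        # duplicate names: corroborated pairings first, then lowest-index fill
        used_w, used_h = set(), set()
        proposals = []
        for w in ws:
            for h in hs:
                if _flags_reciprocal(w, h) or _demographics_match(w, h):
                    proposals.append((w, h))
        for w, h in proposals:
            if w.alter_index in used_w or h.alter_index in used_h:
                continue
            ev = MatchEvidence(w.alter_index, h.alter_index, ["name"], ambiguous=True)
            if _flags_reciprocal(w, h):
                ev.criteria.append("kin_reciprocity")
            if _demographics_match(w, h):
                ev.criteria.append("demographics")
            pairs.append((w.alter_index, h.alter_index))
            evidence.append(ev)
            used_w.add(w.alter_index)
            used_h.add(h.alter_index)
        for w, h in zip(
            [a for a in ws if a.alter_index not in used_w],
            [a for a in hs if a.alter_index not in used_h],
        ):
            pairs.append((w.alter_index, h.alter_index))
            evidence.append(MatchEvidence(w.alter_index, h.alter_index, ["name"], ambiguous=True))
    for w_idx, _ in pairs:
        matched_w.add(w_idx)
    for _, h_idx in pairs:
        matched_h.add(h_idx)
    order = sorted(range(len(pairs)), key=lambda k: pairs[k])
    return AlterMatching(
        pairs=[pairs[k] for k in order],
        unmatched_wife=sorted(a.alter_index for a in w_alters if a.alter_index not in matched_w),
        unmatched_husband=sorted(a.alter_index for a in h_alters if a.alter_index not in matched_h),
        evidence=[evidence[k] for k in order],
    )


class DuocentricNetwork:
    """The merged couple network: two ego nodes plus unique alters.

    Wraps a weighted undirected :class:`networkx.Graph`. Node attributes:
    ``kind`` ("ego"/"alter"), ``provenance`` ("wife_only"/"husband_only"/
    "both"), ``name``, ``both_nominated``, ``roles`` (set of role labels,
    filled by :func:`classify_roles`). Edge attribute ``weight`` in 1..3;
    weight-0 (no contact) pairs carry no edge.
    """

    WIFE_EGO = "wife_ego"
    HUSBAND_EGO = "husband_ego"

    def __init__(self, graph: nx.Graph, couple_id: str):
        self.graph = graph
        self.couple_id = couple_id

    @property
    def size(self) -> int:
        """Network size: unique alters plus the two ego nodes."""
        return self.graph.number_of_nodes()

    def alter_nodes(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "alter"]

    def ego_node(self, role: str) -> str:
        return self.WIFE_EGO if role == "wife" else self.HUSBAND_EGO

    def nominees(self, role: str) -> list:
        """Alter nodes nominated by the given ego (solely or by both spouses)."""
        keep = {"both", f"{role}_only"}
        return [n for n in self.alter_nodes() if self.graph.nodes[n]["provenance"] in keep]

    def weight(self, u, v) -> float:
        data = self.graph.get_edge_data(u, v)
        return data["weight"] if data else 0


class MatchingConsistencyError(ValueError):
    """The matching references alter indices absent from the interviews."""


def merge_to_duocentric(
    wife: EgoInterview,
    husband: EgoInterview,
    matching: AlterMatching,
    combine: str = "max",
) -> DuocentricNetwork:
    """Build the duocentric network under the given combine rule.

    For every node pair the edge weight combines all available evidence: each
    spouse's alter-alter rating of the (mapped) pair, the ego's knowing rating
    for ego-alter pairs, and — because each ego's nomination of their spouse
    folds into the partner's ego node — the ego's rating of (spouse, alter)
    pairs for the partner's ego-alter edges. ``combine`` is one of
    ``max`` (default), ``min``, ``mean``.
    """
    if combine not in COMBINE_RULES:
        raise ValueError(f"combine must be one of {sorted(COMBINE_RULES)}")
    combine_fn = COMBINE_RULES[combine]

    valid_w = {a.alter_index for a in wife.alters if not a.is_spouse}
    valid_h = {a.alter_index for a in husband.alters if not a.is_spouse}
    for w_idx, h_idx in matching.pairs:
        if w_idx not in valid_w or h_idx not in valid_h:
            raise MatchingConsistencyError(
                f"matching pair ({w_idx},{h_idx}) references an unknown or spouse alter"
            )

    g = nx.Graph()
    g.add_node(DuocentricNetwork.WIFE_EGO, kind="ego", ego_role="wife",
               provenance="ego", both_nominated=False, roles=set())
    g.add_node(DuocentricNetwork.HUSBAND_EGO, kind="ego", ego_role="husband",
               provenance="ego", both_nominated=False, roles=set())

    # map (ego_role, alter_index) -> node id; spouse-as-alter folds into partner ego
    matched_w = {w: h for w, h in matching.pairs}
    matched_h = {h: w for w, h in matching.pairs}
    node_of: dict[tuple, str] = {}
    for a in wife.alters:
        if a.is_spouse:
            node_of[("wife", a.alter_index)] = DuocentricNetwork.HUSBAND_EGO
        elif a.alter_index in matched_w:
            node_of[("wife", a.alter_index)] = f"b{a.alter_index:02d}_{matched_w[a.alter_index]:02d}"
        else:
            node_of[("wife", a.alter_index)] = f"w{a.alter_index:02d}"
    for a in husband.alters:
        if a.is_spouse:
            node_of[("husband", a.alter_index)] = DuocentricNetwork.WIFE_EGO
        elif a.alter_index in matched_h:
            node_of[("husband", a.alter_index)] = f"b{matched_h[a.alter_index]:02d}_{a.alter_index:02d}"
        else:
            node_of[("husband", a.alter_index)] = f"h{a.alter_index:02d}"

    for role, iv in (("wife", wife), ("husband", husband)):
        for a in iv.alters:
            if a.is_spouse:
                continue
            node = node_of[(role, a.alter_index)]
            if node not in g:
                g.add_node(node, kind="alter", provenance=f"{role}_only", name=a.name_key,
                           both_nominated=False, roles=set())
            elif g.nodes[node]["provenance"] != f"{role}_only":
                g.nodes[node]["provenance"] = "both"
                g.nodes[node]["both_nominated"] = True

    evidence: dict[frozenset, list] = {}

    def add_evidence(u, v, value):
        if u == v:
            return
        evidence.setdefault(frozenset((u, v)), []).append(value)

    for role, iv in (("wife", wife), ("husband", husband)):
        idx = [a.alter_index for a in iv.alters]
        # ego-alter knowing ratings
        ego_node = DuocentricNetwork.WIFE_EGO if role == "wife" else DuocentricNetwork.HUSBAND_EGO
        for a in iv.alters:
            if a.is_spouse:
                continue
            add_evidence(ego_node, node_of[(role, a.alter_index)], a.knowing)
        # alter-alter ratings (spouse-as-alter pairs map onto partner ego-alter edges)
        n = len(idx)
        for i in range(n):
            for j in range(i + 1, n):
                add_evidence(
                    node_of[(role, idx[i])],
                    node_of[(role, idx[j])],
                    int(iv.alter_ties[i, j]),
                )

    for pair, values in evidence.items():
        u, v = tuple(pair)
        w = combine_fn(values)
        if w > 0:
            g.add_edge(u, v, weight=w)

    # spouses were not asked to rate each other: forced to maximum strength
    g.add_edge(DuocentricNetwork.WIFE_EGO, DuocentricNetwork.HUSBAND_EGO, weight=MAX_TIE)

    return DuocentricNetwork(g, wife.couple_id)


def classify_roles(
    net: DuocentricNetwork,
    wife: EgoInterview,
    husband: EgoInterview,
    matching: AlterMatching,
) -> DuocentricNetwork:
    """Fill per-alter role labels from both spouses' relation flags.

    An alter belongs to the husband's family if the husband flagged them as
    his own family and/or the wife flagged them as her spouse's family
    (symmetrically for the wife's family); friend roles follow the same
    either-spouse rule. A shared friend is named by both spouses as their own
    friend, or by one spouse as both their own and their spouse's friend.
    Ego nodes carry no role labels.
    """
    matched_w = dict(matching.pairs)

    flags_at: dict[str, dict[str, set]] = {}
    for role, iv in (("wife", wife), ("husband", husband)):
        for a in iv.alters:
            if a.is_spouse:
                continue
            node = None
            if role == "wife":
                node = (f"b{a.alter_index:02d}_{matched_w[a.alter_index]:02d}"
                        if a.alter_index in matched_w else f"w{a.alter_index:02d}")
            else:
                rev = {h: w for w, h in matching.pairs}
                node = (f"b{rev[a.alter_index]:02d}_{a.alter_index:02d}"
                        if a.alter_index in rev else f"h{a.alter_index:02d}")
            flags_at.setdefault(node, {})[role] = a.relation_flags

    for node in net.alter_nodes():
        wf = flags_at.get(node, {}).get("wife", set())
        hf = flags_at.get(node, {}).get("husband", set())
        roles = set()
        if "own_family" in hf or "spouse_family" in wf:
            roles.add("husband_family")
        if "own_family" in wf or "spouse_family" in hf:
            roles.add("wife_family")
        if "own_friend" in hf or "spouse_friend" in wf:
            roles.add("husband_friend")
        if "own_friend" in wf or "spouse_friend" in hf:
            roles.add("wife_friend")
        if (
            ("own_friend" in wf and "own_friend" in hf)
            or {"own_friend", "spouse_friend"} <= wf
            or {"own_friend", "spouse_friend"} <= hf
        ):
            roles.add("shared_friend")
        net.graph.nodes[node]["roles"] = roles
    return net


def export_graphml(net: DuocentricNetwork, path, include_spouses: bool = True):
    """Write the network as GraphML with provenance/role node attributes."""
    g = net.graph.copy()
    if not include_spouses:
        g.remove_nodes_from([DuocentricNetwork.WIFE_EGO, DuocentricNetwork.HUSBAND_EGO])
    for _, data in g.nodes(data=True):
        data["roles"] = ";".join(sorted(data.get("roles", set())))
        data["both_nominated"] = int(data.get("both_nominated", False))
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    """Read a network written by :func:`export_graphml` (roles back to sets)."""
    g = nx.read_graphml(path)
    for _, data in g.nodes(data=True):
        data["roles"] = {r for r in str(data.get("roles", "")).split(";") if r}
        data["both_nominated"] = bool(int(data.get("both_nominated", 0)))
    return g


def export_edgelist_csv(net: DuocentricNetwork, path):
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_a", "node_b", "weight"])
        for u, v, w in sorted(net.graph.edges(data="weight")):
            writer.writerow([u, v, w])
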