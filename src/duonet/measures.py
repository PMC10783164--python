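"""Structural and compositional measures of a duocentric network.

Ten criterion measures feed the couple typology: two structural (alter-alter
density and component count, both on ties rated "Pretty Well" or better, ego
nodes excluded), four compositional (proportions of husband/wife family and
friends), two overlap (shared friends, both-nominated), and two subgroup
(density among each spouse's nominees). Burt's constraint for each spouse —
computed on strongest ties only, with both egos and the forced spouse edge in
the graph — summarizes each spouse's access to structural holes (bridging
capital): low constraint means many non-redundant contacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import networkx as nx
import numpy as np

from .merge import DuocentricNetwork

log = logging.getLogger(__name__)

#: default tie thresholds: density/components use "Pretty Well"+ (>=2),
#: constraint uses "Very Well" only (>=3)
DENSITY_THRESHOLD = 2
CONSTRAINT_THRESHOLD = 3

#: the 10 clustering criterion variables, in reporting order
CRITERION_VARS = [
    "density",
    "components",
    "husband_family",
    "wife_family",
    "husband_friend",
    "wife_friend",
    "shared_friends",
    "both_nominated",
    "husband_nominee_density",
    "wife_nominee_density",
]


class UndefinedMeasureError(ValueError):
    """The measure is undefined on this network (e.g. too few nodes)."""


@dataclass
class CriterionProfile:
    """Per-couple measure vector: the 10 criterion variables plus auxiliaries."""

    couple_id: str
    density: float
    components: float
    husband_family: float
    wife_family: float
    husband_friend: float
    wife_friend: float
    shared_friends: float
    both_nominated: float
    husband_nominee_density: float
    wife_nominee_density: float
    network_size: int
    husband_constraint: float
    wife_constraint: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _thresholded_alter_graph(net: DuocentricNetwork, threshold: int, nodes=None) -> nx.Graph:
    keep = net.alter_nodes() if nodes is None else list(nodes)
    g = nx.Graph()
    g.add_nodes_from(keep)
    keep_set = set(keep)
    for u, v, w in net.graph.edges(data="weight"):
        if u in keep_set and v in keep_set and w >= threshold:
            g.add_edge(u, v)
    return g


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        raise UndefinedMeasureError(f"density undefined on {n} node(s)")
    return g.number_of_edges() / (n * (n - 1) / 2)


def alter_density(net: DuocentricNetwork, threshold: int = DENSITY_THRESHOLD) -> float:
    """Density of the alter-only graph at the given tie threshold.

    Ego nodes and ego-incident edges are excluded: every alter is connected
    through the egos by construction, so including them would flatten the
    measure to near-constant.
    """
    return _density(_thresholded_alter_graph(net, threshold))


def count_components(net: DuocentricNetwork, threshold: int = DENSITY_THRESHOLD) -> int:
    """Connected components of the thresholded alter-only graph.

    Isolated alters count as single-node components: each disconnected group,
    however small, is a set the couple alone bridges.
    """
    g = _thresholded_alter_graph(net, threshold)
    if g.number_of_nodes() == 0:
        raise UndefinedMeasureError("components undefined on an alterless network")
    return nx.number_connected_components(g)


def composition_and_overlap(net: DuocentricNetwork) -> dict:
    """Role and overlap proportions of network size.

    Each proportion counts alters carrying the role label (or the
    both-nominated flag) divided by the full network size *including both ego
    nodes*; egos never enter numerators.
    """
    size = net.size
    counts = dict.fromkeys(
        ["husband_family", "wife_family", "husband_friend", "wife_friend", "shared_friends",
         "both_nominated"],
        0,
    )
    for n in net.alter_nodes():
        data = net.graph.nodes[n]
        roles = data.get("roles", set())
        for role in ("husband_family", "wife_family", "husband_friend", "wife_friend"):
            if role in roles:
                counts[role] += 1
        if "shared_friend" in roles:
            counts["shared_friends"] += 1
        if data.get("both_nominated"):
            counts["both_nominated"] += 1
    return {k: v / size for k, v in counts.items()}


def nominee_subgroup_density(
    net: DuocentricNetwork,
    ego_role: str,
    threshold: int = DENSITY_THRESHOLD,
    include_shared: bool = True,
) -> float:
    """Density among the alters nominated by one spouse.

    ``include_shared`` keeps alters nominated by both spouses in the
    subgroup (default): a shared nominee is still one of "those nominated by
    the husband". Ego nodes are excluded as in :func:`alter_density`.
    """
    if ego_role not in ("wife", "husband"):
        raise ValueError(f"unknown ego role: {ego_role!r}")
    keep = {f"{ego_role}_only", "both"} if include_shared else {f"{ego_role}_only"}
    nodes = [n for n in net.alter_nodes() if net.graph.nodes[n]["provenance"] in keep]
    if len(nodes) < 2:
        raise UndefinedMeasureError(
            f"{ego_role}-nominee subgroup has {len(nodes)} member(s); density undefined"
        )
    return _density(_thresholded_alter_graph(net, threshold, nodes=nodes))


def burt_constraint(
    net: DuocentricNetwork,
    ego_role: str,
    threshold: int = CONSTRAINT_THRESHOLD,
) -> float:
    """Burt's constraint of one spouse on the strongest-tie graph.

    On the binary graph of ties with weight >= ``threshold`` (the full
    duocentric network, both egos and the forced spouse edge included), with
    p_ij = a_ij / degree(i):

        C_i = sum_{j in N(i)} ( p_ij + sum_{q != i,j} p_iq * p_qj )^2

    A spouse whose contacts all know each other is fully constrained
    (closed triad: 1.125); a spouse at the center of a star of d mutually
    unconnected contacts has constraint 1/d.
    """
    ego = net.ego_node(ego_role)
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, w in net.graph.edges(data="weight"):
        if w >= threshold:
            g.add_edge(u, v)
    neighbors = list(g.neighbors(ego))
    if not neighbors:
        raise UndefinedMeasureError(f"{ego_role} ego is isolated at threshold {threshold}")
    deg = dict(g.degree())

    def p(a, b):
        return (1.0 / deg[a]) if g.has_edge(a, b) else 0.0

    total = 0.0
    for j in neighbors:
        indirect = sum(p(ego, q) * p(q, j) for q in neighbors if q != j)
        total += (p(ego, j) + indirect) ** 2
    return total


def criterion_profile(
    net: DuocentricNetwork,
    density_threshold: int = DENSITY_THRESHOLD,
    constraint_threshold: int = CONSTRAINT_THRESHOLD,
) -> CriterionProfile:
    """Assemble the full measure vector for one couple.

    Undefined sub-measures propagate as NaN with a logged reason; the
    typology stage excludes incomplete rows listwise.
    """
    values: dict = {"couple_id": net.couple_id, "network_size": net.size}

    def guarded(name, fn):
        try:
            values[name] = fn()
        except UndefinedMeasureError as err:
            log.warning("couple %s: %s", net.couple_id, err)
            values[name] = np.nan

    guarded("density", lambda: alter_density(net, density_threshold))
    guarded("components", lambda: count_components(net, density_threshold))
    values.update(composition_and_overlap(net))
    guarded("husband_nominee_density",
            lambda: nominee_subgroup_density(net, "husband", density_threshold))
    guarded("wife_nominee_density",
            lambda: nominee_subgroup_density(net, "wife", density_threshold))
    guarded("husband_constraint", lambda: burt_constraint(net, "husband", constraint_threshold))
    guarded("wife_constraint", lambda: burt_constraint(net, "wife", constraint_threshold))
    return CriterionProfile(**values)
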