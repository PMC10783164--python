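"""Independent brute-force oracles for the structural measures.

Deliberately naive: pair enumeration for density, flood-fill for components,
literal triple-summation for constraint. They never call the package's
measure code.
"""

import itertools


def density_oracle(nodes, edges):
    """Edge share over all unordered node pairs (edges: set of frozensets)."""
    nodes = list(nodes)
    pairs = list(itertools.combinations(nodes, 2))
    present = sum(1 for a, b in pairs if frozenset((a, b)) in edges)
    return present / len(pairs)


def components_oracle(nodes, edges):
    """Connected components by flood fill; isolates count."""
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for e in edges:
        a, b = tuple(e)
        if a in adj and b in adj:
            adj[a].add(b)
            adj[b].add(a)
    seen, count = set(), 0
    for start in nodes:
        if start in seen:
            continue
        count += 1
        stack = [start]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            stack.extend(adj[n] - seen)
    return count


def constraint_oracle(focal, nodes, edges):
    """Burt constraint by literal evaluation of the defining sums."""
    adj = {n: set() for n in nodes}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)

    def p(i, j):
        return (1.0 / len(adj[i])) if j in adj[i] else 0.0

    total = 0.0
    for j in adj[focal]:
        indirect = 0.0
        for q in nodes:
            if q not in (focal, j):
                indirect += p(focal, q) * p(q, j)
        total += (p(focal, j) + indirect) ** 2
    return total
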