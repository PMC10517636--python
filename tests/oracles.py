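"""Brute-force reference implementations used only by the test suite.

These deliberately avoid the package's ESU enumeration and canonical
labelling: subsets come from exhaustive combination filtering, and motif
equality from an all-permutations color-preserving isomorphism search.
"""

from itertools import combinations, permutations, product

import networkx as nx


def connected_subsets(net, k):
    """All k-node subsets with a connected induced subgraph, by filtering."""
    g = net.graph
    out = set()
    for combo in combinations(sorted(g.nodes), k):
        if nx.is_connected(g.subgraph(combo)):
            out.add(frozenset(combo))
    return out


def color_isomorphic(adj1, states1, adj2, states2):
    """Is there a color-preserving isomorphism between two labeled graphs?"""
    k = len(states1)
    if len(states2) != k:
        return False
    for p in permutations(range(k)):
        if all(states2[i] == states1[p[i]] for i in range(k)) and all(
            adj2[i][j] == adj1[p[i]][p[j]] for i in range(k) for j in range(k)
        ):
            return True
    return False


def _labeled_subgraph(net, subset):
    nodes = sorted(subset)
    k = len(nodes)
    adj = [[0] * k for _ in range(k)]
    g = net.graph
    for i in range(k):
        for j in range(i + 1, k):
            if g.has_edge(nodes[i], nodes[j]):
                adj[i][j] = adj[j][i] = 1
    states = tuple(net.state_of(n) for n in nodes)
    return adj, states


def brute_force_census(net, k):
    """Colored-motif classes and counts by pairwise isomorphism grouping.

    Returns a list of ((adjacency, states) representative, count) pairs.
    Classes are bucketed by cheap invariants first to keep the pairwise
    search tractable.
    """
    buckets = {}
    for subset in connected_subsets(net, k):
        adj, states = _labeled_subgraph(net, subset)
        n_edges = sum(sum(row) for row in adj)
        key = (n_edges, tuple(sorted(states)))
        classes = buckets.setdefault(key, [])
        for entry in classes:
            (radj, rstates), _ = entry
            if color_isomorphic(adj, states, radj, rstates):
                entry[1] += 1
                break
        else:
            classes.append([(adj, states), 1])
    return [
        (rep, count) for classes in buckets.values() for rep, count in classes
    ]


def orbit_count(adjacency, n_states):
    """Exhaustive orbit enumeration of state assignments under automorphisms."""
    k = len(adjacency)
    autos = [
        p
        for p in permutations(range(k))
        if all(
            adjacency[i][j] == adjacency[p[i]][p[j]]
            for i in range(k)
            for j in range(k)
        )
    ]
    seen = set()
    n_orbits = 0
    for assignment in product(range(n_states), repeat=k):
        if assignment in seen:
            continue
        n_orbits += 1
        for p in autos:
            seen.add(tuple(assignment[p[i]] for i in range(k)))
    return n_orbits
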