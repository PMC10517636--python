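"""Synthetic chromatin-state networks for testing and demonstration.

The generator emulates the input edge-list format: a uniform random simple
graph (fixed node and edge counts) whose nodes draw a chromatin state
independently from a small alphabet — by default the four canonical states
active, repressed, poised and weak, uniformly.  Planted-motif fixtures add
vertex-disjoint copies of a chosen colored motif on fresh nodes, so the
planted colored count is a guaranteed lower bound in the census.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .motifs import MotifType
from .network_io import StateNetwork

DEFAULT_STATES = ("active", "repressed", "poised", "weak")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic background network."""

    n_nodes: int
    n_edges: int
    state_alphabet: tuple[str, ...] = DEFAULT_STATES
    state_probs: Optional[tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self):
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if not 0 <= self.n_edges <= max_edges:
            raise ValueError(
                f"n_edges={self.n_edges} infeasible for {self.n_nodes} nodes "
                f"(max {max_edges})"
            )
        if self.state_probs is not None:
            p = np.asarray(self.state_probs, dtype=float)
            if len(p) != len(self.state_alphabet):
                raise ValueError("state_probs length must match state_alphabet")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("state_probs must be non-negative and sum to 1")


def random_state_network(spec: FixtureSpec) -> StateNetwork:
    """Uniform random simple graph with states drawn i.i.d. per node."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    width = max(len(str(n - 1)), 1)
    nodes = [f"n{i:0{width}d}" for i in range(n)]
    all_pairs = list(combinations(range(n), 2))
    chosen = rng.choice(len(all_pairs), size=spec.n_edges, replace=False)
    edges = [(nodes[all_pairs[i][0]], nodes[all_pairs[i][1]]) for i in sorted(chosen)]
    probs = spec.state_probs
    if probs is None:
        probs = [1.0 / len(spec.state_alphabet)] * len(spec.state_alphabet)
    draws = rng.choice(len(spec.state_alphabet), size=n, p=probs)
    states = {nodes[i]: spec.state_alphabet[draws[i]] for i in range(n)}
    return StateNetwork.from_edges(edges, states, extra_nodes=nodes)


def plant_motifs(
    net: StateNetwork,
    motif_type: MotifType,
    states: Sequence[str],
    copies: int,
    seed: int = 0,
) -> StateNetwork:
    """Add vertex-disjoint instances of a colored motif on fresh nodes.

    Each copy occupies ``motif_type.size`` brand-new nodes wired with the
    motif's canonical edges and labeled with ``states`` (canonical position
    order); the original network is untouched, so the census count of the
    planted colored motif is at least ``copies``.
    """
    if copies < 0:
        raise ValueError("copies must be >= 0")
    k = motif_type.size
    if len(states) != k:
        raise ValueError(f"expected {k} states, got {len(states)}")
    existing = set(net.nodes())
    all_states = dict(net.states)
    edges = list(net.edges())
    for c in range(copies):
        new_nodes = []
        for pos in range(k):
            name = f"planted{c:03d}_{pos}"
            if name in existing:
                raise ValueError(f"node name collision: {name}")
            existing.add(name)
            new_nodes.append(name)
            all_states[name] = states[pos]
        for i, j in motif_type.edge_list():
            edges.append((new_nodes[i], new_nodes[j]))
    return StateNetwork.from_edges(edges, all_states, extra_nodes=existing)
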