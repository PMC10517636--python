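"""Null-model network randomization.

Two nulls are provided.  Method I (``edge_swap``) rewires the topology with
degree-preserving double-edge swaps — delete edges a-b and x-y, create
a-x and b-y — keeping the state map fixed; the swap budget defaults to five
times the edge count.  Method II (``state_shuffle``) keeps the topology
fixed and permutes the chromatin states across nodes.  Replicate censuses
are generated with per-replicate counter-based seeds so results are
bit-identical regardless of how many workers run the batch.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from joblib import Parallel, delayed

from .motifs import MotifCensus, motif_census
from .network_io import StateNetwork

#: attempts allowed per requested successful swap before giving up
MAX_TRIES_PER_SWAP = 100


@dataclass(frozen=True)
class RandomizationConfig:
    """How to build the random-network ensemble.

    ``n_random`` defaults to 500 replicates and ``swaps_per_edge`` to 5
    (method I applies ``round(swaps_per_edge * |E|)`` successful swaps).
    """

    method: str = "edge_swap"
    n_random: int = 500
    swaps_per_edge: float = 5.0
    base_seed: int = 0
    n_workers: int = 1

    def __post_init__(self):
        if self.method not in {"edge_swap", "state_shuffle"}:
            raise ValueError(f"unknown randomization method {self.method!r}")
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.swaps_per_edge <= 0:
            raise ValueError("swaps_per_edge must be > 0")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")


def double_edge_swap_randomize(
    net: StateNetwork, n_swaps: int, seed
) -> StateNetwork:
    """Degree-preserving randomization by repeated double-edge swaps.

    Each proposal draws two distinct edges uniformly without replacement;
    with the stored orientations (a, b) and (x, y) the rewiring is always
    a-x / b-y.  Proposals that would create a self-loop or a duplicate edge
    are rejected and do not count toward the budget; exactly ``n_swaps``
    successful swaps are applied.  Raises ``RuntimeError`` if the budget
    cannot be met within ``MAX_TRIES_PER_SWAP * n_swaps`` attempts (e.g. on
    a complete graph, where every proposal is rejected).
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    edges = net.edges()  # sorted pairs, deterministic order and orientation
    if n_swaps > 0 and len(edges) < 2:
        raise ValueError("need at least 2 edges to swap")
    edge_set = set(edges)
    rng = np.random.default_rng(seed)
    successes = 0
    attempts = 0
    cap = max(MAX_TRIES_PER_SWAP * n_swaps, MAX_TRIES_PER_SWAP)
    while successes < n_swaps:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                f"double-edge swap stalled: {successes}/{n_swaps} swaps after "
                f"{attempts - 1} attempts (network too dense or too small?)"
            )
        i, j = rng.choice(len(edges), size=2, replace=False)
        a, b = edges[i]
        x, y = edges[j]
        if a == x or b == y:
            continue
        e1 = (a, x) if a < x else (x, a)
        e2 = (b, y) if b < y else (y, b)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
        successes += 1
    return StateNetwork.from_edges(
        edge_set, net.states, extra_nodes=net.nodes()
    )


def shuffle_states(net: StateNetwork, seed) -> StateNetwork:
    """Permute chromatin states uniformly at random across nodes.

    The edge set is untouched; the multiset of states is preserved exactly.
    """
    nodes = net.nodes()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(nodes))
    old = net.states
    new_states = {nodes[i]: old[nodes[perm[i]]] for i in range(len(nodes))}
    return StateNetwork.from_edges(net.edges(), new_states, extra_nodes=nodes)


def randomize(net: StateNetwork, method: str, replicate_seed, n_swaps: int = 0):
    if method == "edge_swap":
        return double_edge_swap_randomize(net, n_swaps, replicate_seed)
    if method == "state_shuffle":
        return shuffle_states(net, replicate_seed)
    raise ValueError(f"unknown randomization method {method!r}")


def _replicate_census(
    net: StateNetwork, k: int, method: str, n_swaps: int, base_seed: int, i: int
) -> MotifCensus:
    # counter-based seed: independent of worker scheduling
    rnet = randomize(net, method, [base_seed, i], n_swaps=n_swaps)
    return motif_census(rnet, k, record_instances=False)


def generate_random_censuses(
    net: StateNetwork, k: int, config: RandomizationConfig
) -> list[MotifCensus]:
    """Census of each of ``config.n_random`` randomized networks.

    Replicate ``i`` uses the seed ``[base_seed, i]``, so the returned list is
    identical for any ``n_workers``; batches only change where the work runs.
    """
    n_swaps = (
        int(round(config.swaps_per_edge * net.n_edges))
        if config.method == "edge_swap"
        else 0
    )
    args = [
        (net, k, config.method, n_swaps, config.base_seed, i)
        for i in range(config.n_random)
    ]
    if config.n_workers == 1:
        return [_replicate_census(*a) for a in args]
    return Parallel(n_jobs=config.n_workers)(
        delayed(_replicate_census)(*a) for a in args
    )
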