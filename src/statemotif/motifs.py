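"""Colored motif census for size-3 and size-4 connected subgraphs.

Every connected induced subgraph on k ∈ {3, 4} nodes is enumerated once
(ESU-style extension) and classified twice: by topology alone (its
*motif type*, via a canonical adjacency form) and by topology plus the
chromatin states of its nodes (its *chromatin state-marked motif*, the
state sequence canonicalized under the motif's automorphisms).  At these
sizes exhaustive permutation (k! ≤ 24) is an exact and cheap canonical
labelling, so no external isomorphism machinery is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Iterator, Optional, Sequence

import numpy as np

from .network_io import StateNetwork

SUPPORTED_SIZES = (3, 4)

_PAIRS = {k: list(combinations(range(k), 2)) for k in SUPPORTED_SIZES}
_PERMS = {k: list(permutations(range(k))) for k in SUPPORTED_SIZES}


def _as_matrix(adjacency) -> np.ndarray:
    a = np.asarray(adjacency, dtype=int)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    k = a.shape[0]
    if k not in SUPPORTED_SIZES:
        raise ValueError(f"motif size must be one of {SUPPORTED_SIZES}, got {k}")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if a.diagonal().any():
        raise ValueError("adjacency must have a zero diagonal")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency must be 0/1")
    return a


def _is_connected(a: np.ndarray) -> bool:
    k = a.shape[0]
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in range(k):
            if a[u, v] and v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == k


def _perm_bits(a: np.ndarray, perm: Sequence[int], pairs) -> tuple[int, ...]:
    return tuple(int(a[perm[i], perm[j]]) for i, j in pairs)


def _canonical_bits(a: np.ndarray) -> tuple[int, ...]:
    """Maximum upper-triangle bit string over all node permutations."""
    k = a.shape[0]
    pairs = _PAIRS[k]
    return max(_perm_bits(a, p, pairs) for p in _PERMS[k])


@dataclass(frozen=True)
class MotifType:
    """An isomorphism class of connected graphs on 3 or 4 nodes.

    ``canonical_adjacency`` encodes the upper triangle of the canonical
    adjacency matrix, row by row, under the maximum-bit-string convention.
    """

    size: int
    canonical_adjacency: tuple[int, ...]
    label: str

    @property
    def n_edges(self) -> int:
        return sum(self.canonical_adjacency)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.size, self.size), dtype=int)
        for bit, (i, j) in zip(self.canonical_adjacency, _PAIRS[self.size]):
            a[i, j] = a[j, i] = bit
        return a

    def edge_list(self) -> list[tuple[int, int]]:
        return [
            (i, j)
            for bit, (i, j) in zip(self.canonical_adjacency, _PAIRS[self.size])
            if bit
        ]

    def automorphisms(self) -> list[tuple[int, ...]]:
        a = self.adjacency()
        pairs = _PAIRS[self.size]
        return [
            p
            for p in _PERMS[self.size]
            if _perm_bits(a, p, pairs) == self.canonical_adjacency
        ]

    def __str__(self) -> str:
        return f"size-{self.size} type {self.label}"


def _build_registry() -> dict[tuple[int, tuple[int, ...]], MotifType]:
    """Enumerate all connected graphs on 3/4 labeled nodes; group by canonical form.

    Size-3 labels follow the field's convention for chromatin networks
    (type I = triangle, type II = linear path); size-4 types are ordered by
    ascending edge count with ties broken by the canonical bit string, giving
    path, star, cycle, triangle-plus-pendant, diamond, complete = I..VI.
    """
    registry: dict[tuple[int, tuple[int, ...]], MotifType] = {}
    romans = ["I", "II", "III", "IV", "V", "VI"]
    for k in SUPPORTED_SIZES:
        pairs = _PAIRS[k]
        canon: set[tuple[int, ...]] = set()
        for mask in range(2 ** len(pairs)):
            a = np.zeros((k, k), dtype=int)
            for b, (i, j) in enumerate(pairs):
                if mask >> b & 1:
                    a[i, j] = a[j, i] = 1
            if _is_connected(a):
                canon.add(_canonical_bits(a))
        if k == 3:
            ordered = sorted(canon, key=lambda bits: -sum(bits))  # triangle first
        else:
            ordered = sorted(canon, key=lambda bits: (sum(bits), bits))
        for label, bits in zip(romans, ordered):
            registry[(k, bits)] = MotifType(k, bits, label)
    return registry


_REGISTRY = _build_registry()


_ROMAN_ORDER = {r: i for i, r in enumerate(["I", "II", "III", "IV", "V", "VI"], 1)}


def motif_types(size: int) -> list[MotifType]:
    """All motif types of a given size, in label order."""
    if size not in SUPPORTED_SIZES:
        raise ValueError(f"motif size must be one of {SUPPORTED_SIZES}, got {size}")
    return sorted(
        (t for (k, _), t in _REGISTRY.items() if k == size),
        key=lambda t: _ROMAN_ORDER[t.label],
    )


def canonical_uncolored(adjacency) -> MotifType:
    """Classify a connected k-node adjacency matrix into its motif type."""
    a = _as_matrix(adjacency)
    if not _is_connected(a):
        raise ValueError("adjacency is not connected")
    return _REGISTRY[(a.shape[0], _canonical_bits(a))]


@dataclass(frozen=True)
class ColoredMotif:
    """A motif type with a canonical chromatin-state assignment to its positions.

    ``position_states`` is the lexicographically least state sequence over
    all isomorphisms of the input onto the canonical graph, so two labeled
    subgraphs share a ``colored_motif_id`` iff they are related by a
    color-preserving isomorphism.
    """

    motif_type: MotifType
    position_states: tuple[str, ...]

    @property
    def colored_motif_id(self) -> str:
        bits = "".join(map(str, self.motif_type.canonical_adjacency))
        return f"{self.motif_type.size}:{bits}:{';'.join(self.position_states)}"


def canonical_colored(adjacency, states: Sequence[str]) -> ColoredMotif:
    """Canonical form of a state-labeled connected subgraph."""
    a = _as_matrix(adjacency)
    k = a.shape[0]
    if len(states) != k:
        raise ValueError(f"expected {k} states, got {len(states)}")
    if any(not s for s in states):
        raise ValueError("empty state label")
    if not _is_connected(a):
        raise ValueError("adjacency is not connected")
    cm, _ = _canonical_colored_with_perm(a, tuple(states))
    return cm


def _canonical_colored_with_perm(
    a: np.ndarray, states: tuple[str, ...]
) -> tuple[ColoredMotif, tuple[int, ...]]:
    """Canonical colored motif plus the permutation that realises it.

    The returned permutation ``p`` maps canonical positions to input indices
    (position i holds input node ``p[i]``); among the permutations achieving
    the minimal state sequence, the lexicographically least index sequence is
    chosen so instance node ordering is deterministic.
    """
    k = a.shape[0]
    pairs = _PAIRS[k]
    target = _canonical_bits(a)
    best: Optional[tuple[tuple[str, ...], tuple[int, ...]]] = None
    for p in _PERMS[k]:
        if _perm_bits(a, p, pairs) != target:
            continue
        key = (tuple(states[i] for i in p), p)
        if best is None or key < best:
            best = key
    assert best is not None
    mtype = _REGISTRY[(k, target)]
    return ColoredMotif(mtype, best[0]), best[1]


@dataclass
class MotifCensus:
    """Frequencies of every colored motif observed in one network at one size."""

    size: int
    colored_counts: dict[str, int] = field(default_factory=dict)
    type_counts: dict[str, int] = field(default_factory=dict)
    colored_motifs: dict[str, ColoredMotif] = field(default_factory=dict)
    instances: Optional[dict[str, list[tuple[str, ...]]]] = None

    def count(self, colored_motif_id: str) -> int:
        return self.colored_counts.get(colored_motif_id, 0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotifCensus):
            return NotImplemented
        return (
            self.size == other.size
            and self.colored_counts == other.colored_counts
            and self.type_counts == other.type_counts
        )


def enumerate_connected_subgraphs(
    net: StateNetwork, k: int
) -> Iterator[frozenset[str]]:
    """Yield every k-node subset inducing a connected subgraph, exactly once.

    ESU-style enumeration: each subgraph is grown from its least node (in
    sorted node order) by extension nodes restricted to exclusive
    neighborhoods, which guarantees uniqueness without storing seen sets.
    Order is deterministic for a fixed node set.
    """
    if k not in SUPPORTED_SIZES:
        raise ValueError(f"motif size must be one of {SUPPORTED_SIZES}, got {k}")
    nodes = net.nodes()
    index = {v: i for i, v in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    for u, v in net.edges():
        adj[index[u]].append(index[v])
        adj[index[v]].append(index[u])
    adj = [sorted(a) for a in adj]
    adjset = [set(a) for a in adj]

    def extend(sub: list[int], ext: list[int], root: int, closed: set[int]):
        if len(sub) == k - 1:
            for w in ext:
                yield (*sub, w)
            return
        for i, w in enumerate(ext):
            excl = [u for u in adj[w] if u > root and u not in closed]
            new_ext = ext[i + 1 :] + excl
            yield from extend(sub + [w], new_ext, root, closed | {w} | adjset[w])

    for v in range(len(nodes)):
        ext0 = [u for u in adj[v] if u > v]
        for tup in extend([v], ext0, v, {v} | adjset[v]):
            yield frozenset(nodes[i] for i in tup)


def motif_census(
    net: StateNetwork, k: int, record_instances: bool = False
) -> MotifCensus:
    """Count every connected induced k-subgraph under its canonical colored form.

    Induced-occurrence semantics: each k-subset contributes one count to
    exactly one motif type — the type of its full induced subgraph — so a
    triangle is never also counted as a path.  When ``record_instances`` is
    set, each instance's nodes are stored in canonical position order.
    """
    census = MotifCensus(size=k, instances={} if record_instances else None)
    state_map = net.states
    gadj = net.graph.adj
    # cache keyed by (edge bitmask over the sorted subset, state tuple)
    cache: dict[tuple[int, tuple[str, ...]], tuple[ColoredMotif, tuple[int, ...]]] = {}
    pairs = _PAIRS[k]
    for subset in enumerate_connected_subgraphs(net, k):
        nodes = sorted(subset)
        states = tuple(state_map[n] for n in nodes)
        mask = 0
        for b, (i, j) in enumerate(pairs):
            if nodes[j] in gadj[nodes[i]]:
                mask |= 1 << b
        key = (mask, states)
        hit = cache.get(key)
        if hit is None:
            a = np.zeros((k, k), dtype=int)
            for b, (i, j) in enumerate(pairs):
                if mask >> b & 1:
                    a[i, j] = a[j, i] = 1
            hit = _canonical_colored_with_perm(a, states)
            cache[key] = hit
        cm, perm = hit
        cid = cm.colored_motif_id
        census.colored_counts[cid] = census.colored_counts.get(cid, 0) + 1
        census.colored_motifs.setdefault(cid, cm)
        label = cm.motif_type.label
        census.type_counts[label] = census.type_counts.get(label, 0) + 1
        if record_instances:
            census.instances.setdefault(cid, []).append(
                tuple(nodes[i] for i in perm)
            )
    return census


def count_possible_colored_motifs(motif_type: MotifType, n_states: int) -> int:
    """Number of distinct state assignments to a motif, up to its symmetries.

    Counts orbits of the N^k state assignments under the motif's
    automorphism group by Burnside's lemma: the average over automorphisms
    of N raised to the number of cycles of the permutation.  For the
    size-3 triangle with N = 4 this gives 20, the number of 3-multisets
    from 4 states.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    autos = motif_type.automorphisms()
    total = 0
    for p in autos:
        seen = set()
        n_cycles = 0
        for i in range(motif_type.size):
            if i in seen:
                continue
            n_cycles += 1
            j = i
            while j not in seen:
                seen.add(j)
                j = p[j]
        total += n_states**n_cycles
    assert total % len(autos) == 0
    return total // len(autos)
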