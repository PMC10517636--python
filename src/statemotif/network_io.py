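"""Reading and writing chromatin-state network files.

The input format is a headered CSV with at least four columns: the first
two name the interacting chromatin regions (nodes), the third and fourth
give the chromatin state of each region.  Header names are ignored; only
column order matters.  Columns beyond the fourth are ignored.  The network
is undirected, unweighted and simple: duplicate edges are collapsed and
self-loops dropped.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

_REGION_RE = re.compile(r"^\s*([^:]+?)\s*:\s*(\d+)\s*-\s*(\d+)\s*$")

SUMMARY_COLUMNS = [
    "motif_size",
    "motif_type_label",
    "colored_motif_id",
    "position_states",
    "freq_real",
    "mean_freq_random",
    "sd_freq_random",
    "p_value",
    "log2_fold_change",
]


@dataclass(frozen=True)
class ChromatinRegion:
    """A network node: an opaque region identifier plus best-effort coordinates.

    ``chrom``/``start``/``end`` are populated only when ``node_id`` looks like
    ``chromosome:start-end`` (1-based inclusive display coordinates); they are
    metadata and play no role in any computation.
    """

    node_id: str
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None

    @classmethod
    def from_string(cls, node_id: str) -> "ChromatinRegion":
        if not node_id:
            raise ValueError("empty node identifier")
        m = _REGION_RE.match(node_id)
        if m:
            start, end = int(m.group(2)), int(m.group(3))
            if start < end:
                return cls(node_id, m.group(1), start, end)
        return cls(node_id)


class StateNetwork:
    """An undirected simple graph of chromatin regions, each with one state.

    Thin wrapper around :class:`networkx.Graph`; every node carries a
    ``state`` attribute and a ``region`` attribute (:class:`ChromatinRegion`).
    """

    def __init__(self, graph: nx.Graph):
        for u in graph:
            if graph.nodes[u].get("state") in (None, ""):
                raise ValueError(f"node {u!r} has no chromatin state")
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")
        self.graph = graph

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        states: Mapping[str, str],
        extra_nodes: Iterable[str] = (),
    ) -> "StateNetwork":
        g = nx.Graph()
        for n in list(states):
            g.add_node(n)
        for n in extra_nodes:
            g.add_node(n)
        g.add_edges_from(edges)
        for n in g:
            if n not in states:
                raise ValueError(f"node {n!r} referenced by an edge has no state")
            g.nodes[n]["state"] = states[n]
            g.nodes[n]["region"] = ChromatinRegion.from_string(str(n))
        return cls(g)

    # -- views -----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str]]:
        """Edges as sorted pairs in a deterministic global order."""
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def state_of(self, node: str) -> str:
        return self.graph.nodes[node]["state"]

    @property
    def states(self) -> dict[str, str]:
        return {n: d["state"] for n, d in self.graph.nodes(data=True)}

    def state_alphabet(self) -> list[str]:
        return sorted(set(self.states.values()))

    def region_of(self, node: str) -> ChromatinRegion:
        return self.graph.nodes[node]["region"]

    def copy(self) -> "StateNetwork":
        return StateNetwork(self.graph.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StateNetwork):
            return NotImplemented
        return (
            set(self.graph.nodes) == set(other.graph.nodes)
            and self.edges() == other.edges()
            and self.states == other.states
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"StateNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


def parse_network_csv(path, state_conflict_policy: str = "error") -> StateNetwork:
    """Read a 4-column chromatin-state network CSV into a :class:`StateNetwork`.

    Parameters
    ----------
    path
        CSV file with a header line (content ignored) and rows
        ``node1,node2,state1,state2[,...]``.
    state_conflict_policy
        What to do when a node appears with different states in different
        rows: ``"error"`` (default) raises, ``"first"`` keeps the first
        observed state, ``"majority"`` keeps the most frequent one (ties
        resolved in favour of the first state to reach the winning count).
    """
    if state_conflict_policy not in {"error", "first", "majority"}:
        raise ValueError(f"unknown state_conflict_policy {state_conflict_policy!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    observed: dict[str, Counter] = {}
    first_seen: dict[str, str] = {}
    edges: set[tuple[str, str]] = set()
    n_rows = n_self_loops = n_duplicates = 0

    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            next(reader)  # header: content irrelevant, order of columns fixed
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected a header line")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 4 comma-separated "
                    f"fields, got {len(row)}"
                )
            u, v, su, sv = (f.strip() for f in row[:4])
            if not u or not v:
                raise ValueError(f"{path}:{lineno}: empty node identifier")
            if not su or not sv:
                raise ValueError(f"{path}:{lineno}: empty chromatin state")
            n_rows += 1
            for node, state in ((u, su), (v, sv)):
                observed.setdefault(node, Counter())[state] += 1
                first_seen.setdefault(node, state)
            if u == v:
                n_self_loops += 1
                continue
            edge = tuple(sorted((u, v)))
            if edge in edges:
                n_duplicates += 1
            edges.add(edge)

    states: dict[str, str] = {}
    for node, counts in observed.items():
        if len(counts) == 1:
            states[node] = next(iter(counts))
        elif state_conflict_policy == "error":
            raise ValueError(
                f"{path}: node {node!r} observed with conflicting states "
                f"{sorted(counts)}; rerun with state_conflict_policy='first' "
                f"or 'majority' to coerce"
            )
        elif state_conflict_policy == "first":
            states[node] = first_seen[node]
        else:  # majority
            top = max(counts.values())
            winners = [s for s, c in counts.items() if c == top]
            states[node] = winners[0]  # Counter preserves insertion order

    if n_self_loops:
        logger.warning("%s: dropped %d self-loop row(s)", path, n_self_loops)
    if n_duplicates:
        logger.info("%s: collapsed %d duplicate edge row(s)", path, n_duplicates)

    return StateNetwork.from_edges(edges, states)


def write_network_csv(net: StateNetwork, path) -> None:
    """Write a network back out in the 4-column input format."""
    rows = [
        (u, v, net.state_of(u), net.state_of(v)) for u, v in net.edges()
    ]
    df = pd.DataFrame(rows, columns=["from_node", "to_node", "from_state", "to_state"])
    df.to_csv(path, index=False)


def write_bed(net: StateNetwork, path) -> int:
    """Export regions with parseable coordinates as BED (0-based half-open).

    Returns the number of regions written; regions whose identifier is not
    of the form ``chrom:start-end`` are skipped.
    """
    n = 0
    with open(path, "w") as fh:
        for node in net.nodes():
            r = net.region_of(node)
            if r.chrom is not None:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{net.state_of(node)}\n")
                n += 1
    return n


def _roman_value(label: str) -> int:
    vals = {"I": 1, "V": 5, "X": 10}
    total = 0
    for a, b in zip(label, label[1:] + " "):
        v = vals[a]
        total += -v if b in vals and vals[b] > v else v
    return total


def summary_frame(records: Sequence) -> pd.DataFrame:
    """Tabulate enrichment records into the summary-file layout."""
    rows = []
    for r in records:
        cm = r.colored_motif
        rows.append(
            {
                "motif_size": cm.motif_type.size,
                "motif_type_label": cm.motif_type.label,
                "colored_motif_id": cm.colored_motif_id,
                "position_states": ";".join(cm.position_states),
                "freq_real": r.freq_real,
                "mean_freq_random": r.mean_freq_random,
                "sd_freq_random": r.sd_freq_random,
                "p_value": r.p_value,
                "log2_fold_change": r.log2_fold_change,
            }
        )
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if len(df):
        df["_type_ord"] = df["motif_type_label"].map(_roman_value)
        df = df.sort_values(
            ["motif_size", "_type_ord", "log2_fold_change", "colored_motif_id"],
            ascending=[True, True, False, True],
            kind="mergesort",
        ).drop(columns="_type_ord")
        df = df.reset_index(drop=True)
    return df


def write_summary(records: Sequence, path) -> None:
    """Write the enrichment summary CSV.

    One row per chromatin state-marked motif: its real-network frequency,
    the mean and SD of its frequency across randomized networks, the
    empirical P-value and the log2 fold change.  Rows are ordered by motif
    size, motif type, then descending fold change.
    """
    summary_frame(records).to_csv(path, index=False)


def write_occurrences(census, enriched_ids: Iterable[str], path) -> None:
    """Write every real-network instance of each enriched colored motif.

    Requires the census to have been built with instance recording enabled.
    Each row lists the original node identifiers and their states in the
    instance's canonical position order.
    """
    if census.instances is None:
        raise ValueError("census was built without instance recording")
    enriched_ids = set(enriched_ids)
    unknown = enriched_ids - set(census.colored_counts)
    if unknown:
        raise KeyError(f"unknown colored motif id(s): {sorted(unknown)[:5]}")
    k = census.size
    cols = (
        ["colored_motif_id", "motif_type_label"]
        + [f"node_{i}" for i in range(1, k + 1)]
        + [f"state_{i}" for i in range(1, k + 1)]
    )
    rows = []
    for cid in sorted(enriched_ids):
        cm = census.colored_motifs[cid]
        for inst in census.instances.get(cid, []):
            rows.append(
                [cid, cm.motif_type.label, *inst, *cm.position_states]
            )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
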