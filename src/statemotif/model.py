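"""Model/Results interface for colored-motif enrichment analysis.

``ColoredMotifEnrichment`` holds a chromatin-state network and a motif
size; ``fit`` runs the full procedure — real census with instances, the
random ensemble, empirical P-values and fold changes — and returns a
``MotifEnrichmentResults`` carrying the estimates, the filtered record
set, and writers for the summary, occurrence and heatmap output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import pandas as pd

from . import enrichment as _enrich
from . import network_io as nio
from . import randomize as _rand
from . import visualize as _viz
from .motifs import MotifCensus, motif_census, motif_types
from .network_io import StateNetwork

logger = logging.getLogger(__name__)


class ColoredMotifEnrichment:
    """Enrichment model for chromatin state-marked motifs of one size.

    Parameters
    ----------
    network
        The chromatin-state interaction network.
    motif_size
        3 or 4; one size is analysed per model, mirroring per-size analyses
        of chromatin interaction data.

    Examples
    --------
    >>> from statemotif import ColoredMotifEnrichment
    >>> model = ColoredMotifEnrichment.from_csv("network.csv", motif_size=3)
    >>> res = model.fit(method="state_shuffle", n_random=100, seed=7)
    >>> res.summary().head()                               # doctest: +SKIP
    """

    def __init__(self, network: StateNetwork, motif_size: int = 3):
        if motif_size not in (3, 4):
            raise ValueError(f"motif_size must be 3 or 4, got {motif_size}")
        self.network = network
        self.motif_size = motif_size

    @classmethod
    def from_csv(
        cls, path, motif_size: int = 3, state_conflict_policy: str = "error"
    ) -> "ColoredMotifEnrichment":
        net = nio.parse_network_csv(path, state_conflict_policy=state_conflict_policy)
        return cls(net, motif_size=motif_size)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, motif_size: int = 3
    ) -> "ColoredMotifEnrichment":
        """Build from a 4-column frame: node1, node2, state1, state2."""
        if df.shape[1] < 4:
            raise ValueError("expected at least 4 columns")
        edges = []
        states: dict[str, str] = {}
        for u, v, su, sv in df.iloc[:, :4].astype(str).itertuples(index=False):
            for node, s in ((u, su), (v, sv)):
                if node in states and states[node] != s:
                    raise ValueError(f"conflicting states for node {node!r}")
                states[node] = s
            if u != v:
                edges.append(tuple(sorted((u, v))))
        return cls(StateNetwork.from_edges(set(edges), states), motif_size=motif_size)

    def fit(
        self,
        method: str = "edge_swap",
        n_random: int = 500,
        swaps_per_edge: float = 5.0,
        p_threshold: float = 0.05,
        min_freq: int = 1,
        pseudocount: float = 1.0,
        pvalue_floor: bool = False,
        seed: int = 0,
        n_workers: int = 1,
    ) -> "MotifEnrichmentResults":
        """Run census + randomization + enrichment.

        ``method`` selects the null: ``"edge_swap"`` (degree-preserving
        topology rewiring, ``round(swaps_per_edge * |E|)`` swaps per
        replicate) or ``"state_shuffle"`` (states permuted, topology kept).
        """
        net, k = self.network, self.motif_size
        logger.info(
            "network: %d nodes, %d edges, %d states",
            net.n_nodes, net.n_edges, len(net.state_alphabet()),
        )
        real = motif_census(net, k, record_instances=True)
        logger.info(
            "real census (size %d): %d connected subgraphs, %d colored motifs",
            k, sum(real.type_counts.values()), len(real.colored_counts),
        )
        config = _rand.RandomizationConfig(
            method=method,
            n_random=n_random,
            swaps_per_edge=swaps_per_edge,
            base_seed=seed,
            n_workers=n_workers,
        )
        randoms = _rand.generate_random_censuses(net, k, config)
        all_records = _enrich.compute_records(
            real, randoms, pseudocount=pseudocount, pvalue_floor=pvalue_floor
        )
        records = [
            r
            for r in all_records
            if r.p_value < p_threshold and r.freq_real >= min_freq
        ]
        logger.info(
            "%d of %d colored motifs pass p < %g and freq >= %d",
            len(records), len(all_records), p_threshold, min_freq,
        )
        return MotifEnrichmentResults(
            model=self,
            real_census=real,
            records=records,
            all_records=all_records,
            config=config,
            p_threshold=p_threshold,
            min_freq=min_freq,
            pseudocount=pseudocount,
        )


@dataclass
class MotifEnrichmentResults:
    """Fitted enrichment results for one network and motif size."""

    model: ColoredMotifEnrichment
    real_census: MotifCensus
    records: list  # filtered, ranked EnrichmentRecords
    all_records: list  # every motif seen in the real network
    config: _rand.RandomizationConfig
    p_threshold: float
    min_freq: int
    pseudocount: float

    @property
    def motif_size(self) -> int:
        return self.model.motif_size

    @property
    def enriched_ids(self) -> list[str]:
        return [r.colored_motif.colored_motif_id for r in self.records]

    def summary(self, enriched_only: bool = True) -> pd.DataFrame:
        """Summary table: frequencies, random means/SDs, P-values, fold changes."""
        return nio.summary_frame(self.records if enriched_only else self.all_records)

    def write_summary(self, path) -> None:
        nio.write_summary(self.records, path)

    def write_occurrences(self, path) -> None:
        nio.write_occurrences(self.real_census, self.enriched_ids, path)

    def plot_heatmaps(self, outdir, fmt: str = "png") -> list[Path]:
        """One heatmap (+ TSV sidecar) per motif type with enriched motifs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        palette = _viz.make_palette(
            [s for r in self.records for s in r.colored_motif.position_states]
        )
        written: list[Path] = []
        for mtype in motif_types(self.motif_size):
            matrix = _viz.build_heatmap_matrix(self.records, mtype, palette=palette)
            name = f"motifs_size{self.motif_size}_type{mtype.label}.{fmt}"
            written.extend(_viz.render_heatmap(matrix, outdir / name))
        return written

    def __str__(self) -> str:
        df = self.summary()
        head = (
            f"Colored motif enrichment (size {self.motif_size}, "
            f"method {self.config.method}, {self.config.n_random} replicates)\n"
            f"{len(self.records)} enriched of {len(self.all_records)} observed "
            f"colored motifs (p < {self.p_threshold}, freq >= {self.min_freq})\n"
        )
        return head + df.to_string(index=False)
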