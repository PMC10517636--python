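"""Heatmap visualization of enriched chromatin state-marked motifs.

One heatmap per motif type: rows are enriched colored motifs (descending
fold change), columns are the canonical node positions of the motif, and
cell colors encode chromatin states.  Because a heatmap cannot show edges,
the motif's topology is drawn as a small schematic next to the heatmap.
Every image gets a TSV sidecar with the same cells as plain text, so
results stay inspectable without an image viewer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
from matplotlib.colors import ListedColormap
from matplotlib.patches import Patch

from .enrichment import EnrichmentRecord
from .motifs import MotifType

logger = logging.getLogger(__name__)

#: documented default colors for the four canonical chromatin states
DEFAULT_STATE_COLORS = {
    "active": "#e41a1c",     # red: transcriptionally active
    "poised": "#984ea3",     # purple: bivalent/poised
    "repressed": "#377eb8",  # blue: polycomb/heterochromatin repressed
    "weak": "#bdbdbd",       # grey: weakly marked
}

_COLOR_CYCLE = [
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
    "#a65628", "#f781bf", "#999999", "#66c2a5", "#ffd92f",
]


def make_palette(states: Sequence[str]) -> dict[str, str]:
    """Deterministic state -> color map.

    States are sorted lexicographically and assigned colors from a fixed
    cycle; the four canonical chromatin states override their cycle slot
    with their documented colors.
    """
    palette = {}
    for i, s in enumerate(sorted(set(states))):
        palette[s] = DEFAULT_STATE_COLORS.get(s, _COLOR_CYCLE[i % len(_COLOR_CYCLE)])
    return palette


@dataclass
class HeatmapMatrix:
    """Rows of canonical position states for one motif type's enriched motifs."""

    motif_type: MotifType
    row_ids: list[str]
    cells: list[tuple[str, ...]]
    state_palette: dict[str, str]

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)


def build_heatmap_matrix(
    records: Sequence[EnrichmentRecord],
    motif_type: MotifType,
    palette: dict[str, str] | None = None,
) -> HeatmapMatrix:
    """Assemble the heatmap for one motif type from enrichment records.

    Rows are the records of that type ordered by descending fold change;
    an empty matrix is legal (nothing enriched for this type).
    """
    rows = sorted(
        (r for r in records if r.colored_motif.motif_type == motif_type),
        key=lambda r: (-r.log2_fold_change, r.colored_motif.colored_motif_id),
    )
    if palette is None:
        palette = make_palette(
            [s for r in rows for s in r.colored_motif.position_states]
        )
    return HeatmapMatrix(
        motif_type=motif_type,
        row_ids=[r.colored_motif.colored_motif_id for r in rows],
        cells=[r.colored_motif.position_states for r in rows],
        state_palette=palette,
    )


def write_heatmap_tsv(matrix: HeatmapMatrix, path) -> None:
    k = matrix.motif_type.size
    df = pd.DataFrame(
        matrix.cells,
        index=pd.Index(matrix.row_ids, name="colored_motif_id"),
        columns=[f"position_{i}" for i in range(1, k + 1)],
    )
    df.to_csv(path, sep="\t")


def read_heatmap_tsv(path) -> tuple[list[str], list[tuple[str, ...]]]:
    """Round-trip helper: (row_ids, cells) from a sidecar TSV."""
    df = pd.read_csv(path, sep="\t", index_col="colored_motif_id", dtype=str)
    return list(df.index), [tuple(row) for row in df.itertuples(index=False)]


def _draw_motif_schematic(ax, motif_type: MotifType) -> None:
    """Tiny node-and-edge drawing of the motif's canonical topology."""
    import numpy as np

    k = motif_type.size
    theta = np.linspace(0.5 * np.pi, 2.5 * np.pi, k, endpoint=False)
    xs, ys = np.cos(theta), np.sin(theta)
    for i, j in motif_type.edge_list():
        ax.plot([xs[i], xs[j]], [ys[i], ys[j]], color="black", lw=1.5, zorder=1)
    ax.scatter(xs, ys, s=250, facecolor="white", edgecolor="black", zorder=2)
    for i in range(k):
        ax.text(xs[i], ys[i], str(i + 1), ha="center", va="center", fontsize=8)
    ax.set_xlim(-1.6, 1.6)
    ax.set_ylim(-1.6, 1.6)
    ax.set_aspect("equal")
    ax.axis("off")


def render_heatmap(matrix: HeatmapMatrix, path) -> list[Path]:
    """Write the heatmap image and its TSV sidecar; returns written paths.

    An empty matrix writes nothing (a warning is logged).  The image format
    follows the file extension (png, svg, pdf, ...).
    """
    path = Path(path)
    if matrix.n_rows == 0:
        logger.warning(
            "no enriched motifs for %s; skipping %s", matrix.motif_type, path
        )
        return []
    k = matrix.motif_type.size
    states = sorted({s for row in matrix.cells for s in row})
    level = {s: i for i, s in enumerate(states)}
    grid = [[level[s] for s in row] for row in matrix.cells]
    cmap = ListedColormap([matrix.state_palette[s] for s in states])

    fig_h = max(2.2, 0.45 * matrix.n_rows + 1.6)
    fig, (ax_schema, ax) = plt.subplots(
        1, 2, figsize=(2.2 + 1.0 * k, fig_h), width_ratios=[1, 1.4 * k]
    )
    _draw_motif_schematic(ax_schema, matrix.motif_type)
    ax_schema.set_title(f"{matrix.motif_type}", fontsize=9)
    ax.imshow(grid, cmap=cmap, vmin=0, vmax=max(len(states) - 1, 1), aspect="auto")
    ax.set_xticks(range(k), [f"position {i}" for i in range(1, k + 1)], fontsize=8)
    ax.set_yticks(range(matrix.n_rows), matrix.row_ids, fontsize=7)
    ax.set_title(
        f"enriched chromatin state-marked motifs ({matrix.n_rows})", fontsize=9
    )
    handles = [
        Patch(facecolor=matrix.state_palette[s], edgecolor="black", label=s)
        for s in states
    ]
    ax.legend(
        handles=handles, loc="upper left", bbox_to_anchor=(1.02, 1),
        fontsize=8, title="state", title_fontsize=8,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)

    tsv_path = path.with_suffix(".tsv")
    write_heatmap_tsv(matrix, tsv_path)
    return [path, tsv_path]
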