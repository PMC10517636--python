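"""Empirical enrichment of colored motifs against a random-network ensemble.

The P-value of a chromatin state-marked motif is the fraction of random
replicates whose count of that motif is at least its count in the real
network.  Fold change is computed as log2((real + eps) / (mean_random +
eps)) with a pseudocount eps (default 1) guarding motifs that never occur
in the random ensemble.  No multiple-testing correction is applied: the
filter operates on the raw empirical P-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .motifs import ColoredMotif, MotifCensus

_ROMAN_ORDER = {r: i for i, r in enumerate(["I", "II", "III", "IV", "V", "VI"], 1)}


@dataclass(frozen=True)
class EnrichmentRecord:
    """One colored motif's real frequency versus the random ensemble."""

    colored_motif: ColoredMotif
    freq_real: int
    mean_freq_random: float
    sd_freq_random: float
    p_value: float
    log2_fold_change: float


def empirical_pvalue(freq_real: int, random_counts: Sequence[int]) -> float:
    """Fraction of random replicates with count >= the real count."""
    if len(random_counts) == 0:
        raise ValueError("random_counts must be non-empty")
    if freq_real < 0:
        raise ValueError("freq_real must be >= 0")
    n_ge = sum(1 for c in random_counts if c >= freq_real)
    return n_ge / len(random_counts)


def log_fold_change(
    freq_real: int, mean_random: float, pseudocount: float = 1.0
) -> float:
    """log2 fold change of real vs mean random frequency, pseudocounted."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return math.log2((freq_real + pseudocount) / (mean_random + pseudocount))


def compute_records(
    real_census: MotifCensus,
    random_censuses: Sequence[MotifCensus],
    pseudocount: float = 1.0,
    pvalue_floor: bool = False,
) -> list[EnrichmentRecord]:
    """Enrichment record for every colored motif present in the real network.

    Motifs absent from a random replicate count as 0 there; motifs that
    occur only in random networks are skipped (they cannot be
    over-represented in the real network).  With ``pvalue_floor`` the
    conventional floor 1/(n_random + 1) replaces exact zeros; off by
    default, matching the plain ratio definition.
    """
    if not random_censuses:
        raise ValueError("random_censuses must be non-empty")
    sizes = {c.size for c in random_censuses} | {real_census.size}
    if len(sizes) != 1:
        raise ValueError(f"mixed census sizes: {sorted(sizes)}")
    n_random = len(random_censuses)
    records = []
    for cid, freq_real in real_census.colored_counts.items():
        if freq_real < 1:
            continue
        counts = np.array([c.count(cid) for c in random_censuses])
        p = empirical_pvalue(freq_real, counts)
        if pvalue_floor and p == 0.0:
            p = 1.0 / (n_random + 1)
        mean = float(counts.mean())
        sd = float(counts.std(ddof=0))
        records.append(
            EnrichmentRecord(
                colored_motif=real_census.colored_motifs[cid],
                freq_real=freq_real,
                mean_freq_random=mean,
                sd_freq_random=sd,
                p_value=p,
                log2_fold_change=log_fold_change(freq_real, mean, pseudocount),
            )
        )
    return _sorted_records(records)


def _sorted_records(records: list[EnrichmentRecord]) -> list[EnrichmentRecord]:
    return sorted(
        records,
        key=lambda r: (
            r.colored_motif.motif_type.size,
            _ROMAN_ORDER[r.colored_motif.motif_type.label],
            -r.log2_fold_change,
            r.colored_motif.colored_motif_id,
        ),
    )


def enrich(
    real_census: MotifCensus,
    random_censuses: Sequence[MotifCensus],
    p_threshold: float = 0.05,
    min_freq: int = 1,
    pseudocount: float = 1.0,
    pvalue_floor: bool = False,
) -> list[EnrichmentRecord]:
    """Filtered, ranked enrichment records.

    Keeps records with ``p_value < p_threshold`` and ``freq_real >=
    min_freq``, sorted by descending log2 fold change within each motif
    type.  ``min_freq`` defaults to 1; raising it (e.g. to 50) screens out
    rare motifs whose enrichment rests on a handful of instances.
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    records = compute_records(
        real_census, random_censuses, pseudocount=pseudocount, pvalue_floor=pvalue_floor
    )
    return [
        r for r in records if r.p_value < p_threshold and r.freq_real >= min_freq
    ]
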