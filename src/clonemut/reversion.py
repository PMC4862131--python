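"""Reversion-probability model for treatment-induced genetic reversal.

A back-of-envelope uniform-placement model: a frameshift in a tumour
suppressor (e.g. BRCA2) can be reverted by a second frameshift landing
within a short window (default 20 bp) of the original lesion, and a
premature stop codon by an SNV hitting any of its three bases. With
mutations placed uniformly on a genome of G bases, one event reverts with
probability w/G, N independent events with probability 1 - (1 - w/G)^N,
and a cell carrying a burden of B mutations reverts with
p_cell = 1 - (1 - w/G)^B. The number of events (or surviving cells) needed
for a 50 % chance of at least one reversion is ln(1/2) / ln(1 - p).

The uniform-placement assumption is deliberate: measured spectra are
non-uniform, but the model mirrors the order-of-magnitude framing of the
clinical question. Genome size defaults to 3.1e9 bp (human).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import ReversionParams


def p_hit(genome_size_bp: float, window_bp: float) -> float:
    """Probability that one uniformly placed mutation lands in a window."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    if window_bp <= 0:
        raise ValueError("window must be positive")
    if window_bp >= genome_size_bp:
        raise ValueError("window must be smaller than the genome")
    return window_bp / genome_size_bp


def events_for_half_chance(p: float) -> float:
    """Number of events N with 1 - (1-p)^N = 1/2; ~ ln2/p for small p."""
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    return math.log(0.5) / math.log1p(-p)


def cells_for_half_chance(burden_per_genome: float, p_event: float) -> float:
    """Surviving cells needed for a 50 % chance that some cell reverted.

    Each cell carries ``burden_per_genome`` independent uniformly placed
    mutations, each reverting with probability ``p_event``.
    """
    if burden_per_genome <= 0:
        raise ValueError("burden must be positive")
    if not (0 < p_event < 1):
        raise ValueError("p_event must be in (0, 1)")
    log_miss = burden_per_genome * math.log1p(-p_event)
    p_cell = -math.expm1(log_miss)
    if p_cell >= 1.0:
        return 1.0
    return max(1.0, math.log(0.5) / math.log1p(-p_cell))


def per_cell_hit_probability(burden_per_genome: float, p_event: float) -> float:
    """p_cell = 1 - (1 - p_event)^burden."""
    return -math.expm1(burden_per_genome * math.log1p(-p_event))


@dataclass(frozen=True)
class ReversionSummary:
    """Event and cell counts for a 50 % reversion chance, per mutation type."""

    p_indel: float
    p_snv: float
    indel_events: float
    snv_events: float
    indel_burden: float
    snv_burden: float
    cells_indel: float
    cells_snv: float
    cells_combined: float


def reversion_summary(params: ReversionParams | None = None) -> ReversionSummary:
    """Evaluate the model for the treatment-measured burdens.

    Indel reversion uses the frameshift window; SNV reversion the stop
    codon. Burdens per genome are the per-Gb loads scaled by genome size.
    ``cells_combined`` lets either mutation type produce the reversion.
    """
    params = params or ReversionParams()
    g = params.genome_size_bp
    p_ind = p_hit(g, params.indel_window_bp)
    p_snv = p_hit(g, params.stop_codon_bp)
    b_ind = params.indel_per_gb * g / 1e9
    b_snv = params.snv_per_gb * g / 1e9
    p_cell_ind = per_cell_hit_probability(b_ind, p_ind)
    p_cell_snv = per_cell_hit_probability(b_snv, p_snv)
    p_cell_any = 1 - (1 - p_cell_ind) * (1 - p_cell_snv)
    return ReversionSummary(
        p_indel=p_ind,
        p_snv=p_snv,
        indel_events=events_for_half_chance(p_ind),
        snv_events=events_for_half_chance(p_snv),
        indel_burden=b_ind,
        snv_burden=b_snv,
        cells_indel=cells_for_half_chance(b_ind, p_ind),
        cells_snv=cells_for_half_chance(b_snv, p_snv),
        cells_combined=math.log(0.5) / math.log1p(-p_cell_any),
    )


def monte_carlo_cell_hit_fraction(
    genome_size_bp: float,
    window_bp: int,
    burden_per_genome: int,
    n_replicates: int,
    rng: np.random.Generator,
) -> float:
    """Simulation oracle for the per-cell reversion probability.

    Places ``burden_per_genome`` mutations uniformly on a discrete genome
    per replicate cell and reports the fraction of cells with at least one
    mutation inside a fixed window of ``window_bp`` sites.
    """
    g = int(genome_size_bp)
    hits = 0
    target_lo = g // 2  # arbitrary fixed window; placement is uniform
    target_hi = target_lo + int(window_bp)
    batch = max(1, 10_000_000 // max(burden_per_genome, 1))
    done = 0
    while done < n_replicates:
        n = min(batch, n_replicates - done)
        draws = rng.integers(0, g, size=(n, burden_per_genome))
        hits += int((((draws >= target_lo) & (draws < target_hi)).any(axis=1)).sum())
        done += n
    return hits / n_replicates
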