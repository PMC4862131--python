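"""Mutation spectra: 96-channel classification, triplet normalisation,
cross-species adjustment, signature comparison, and rate arithmetic.

Rates here follow the study's conventions: the spontaneous rate divides the
mean per-clone mutation count by the diploid genome size and the number of
cell divisions of the regimen; mutation density divides by the haploid
genome size in Mb. Spectra are pooled across same-treatment clones before
comparison with reference signatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .channels import (
    BASES,
    CHANNELS,
    TRIPLETS32,
    channel_context,
    channel_of,
    fold_triplet,
)
from .types import Mutation, SignatureMatrix, Spectrum96, TripletFrequencyTable


def classify_snv(reference: dict[str, str], mutation: Mutation) -> int | None:
    """Channel index of an SNV in its triplet context, or None if unassignable.

    Purine-reference substitutions are folded to the pyrimidine-centred
    representation. Chromosome-end SNVs lacking a flank, or flanks
    containing non-ACGT bases, are unassignable.
    """
    if mutation.mut_class != "SNV":
        raise ValueError(f"not an SNV: {mutation.mut_class}")
    seq = reference[mutation.chrom]
    pos = mutation.pos
    if seq[pos - 1] != mutation.ref_allele:
        raise ValueError(
            f"{mutation.chrom}:{pos}: reference base {seq[pos - 1]!r} != "
            f"mutation ref {mutation.ref_allele!r}"
        )
    if pos < 2 or pos > len(seq) - 1:
        return None
    return channel_of(seq[pos - 2], mutation.ref_allele, mutation.alt_allele, seq[pos])


@dataclass
class SpectrumResult:
    """Counts over the 96 channels plus the 6-class marginal."""

    spectrum: Spectrum96
    six_class: np.ndarray
    n_unassignable: int

    def six_class_fractions(self) -> np.ndarray:
        total = self.six_class.sum()
        return self.six_class / total if total else self.six_class


def count_spectrum(mutations: list[Mutation], reference: dict[str, str]) -> SpectrumResult:
    """Tally SNVs into the 96 channels; channel sums equal assignable SNVs."""
    values = np.zeros(96)
    unassignable = 0
    for mut in mutations:
        ch = classify_snv(reference, mut)
        if ch is None:
            unassignable += 1
        else:
            values[ch] += 1
    spectrum = Spectrum96(values)
    return SpectrumResult(spectrum, spectrum.six_class(), unassignable)


def triplet_occurrences(reference: dict[str, str]) -> TripletFrequencyTable:
    """Count overlapping triplets, strand-folded to the 32 pyrimidine keys.

    Windows containing non-ACGT bases are skipped. Raises for genomes with
    no countable window.
    """
    if not reference or all(len(s) < 3 for s in reference.values()):
        raise ValueError("genome has no triplet window")
    code = {b: i for i, b in enumerate(BASES)}
    counts64 = np.zeros(64, dtype=np.int64)
    for seq in reference.values():
        if len(seq) < 3:
            continue
        arr = np.array([code.get(b, -1) for b in seq], dtype=np.int64)
        valid = (arr[:-2] >= 0) & (arr[1:-1] >= 0) & (arr[2:] >= 0)
        idx = arr[:-2] * 16 + arr[1:-1] * 4 + arr[2:]
        counts64 += np.bincount(idx[valid], minlength=64)
    counts32: dict[str, float] = {t: 0.0 for t in TRIPLETS32}
    for i in range(64):
        t = BASES[i // 16] + BASES[(i % 16) // 4] + BASES[i % 4]
        counts32[fold_triplet(t)] += int(counts64[i])
    if sum(counts32.values()) == 0:
        raise ValueError("degenerate genome: no valid ACGT triplet window")
    return TripletFrequencyTable(counts32)


def normalize_rates(counts: Spectrum96, occurrences: TripletFrequencyTable) -> Spectrum96:
    """Per-channel mutation rate: count divided by context-triplet occurrence."""
    rates = np.zeros(96)
    for i in range(96):
        occ = occurrences[channel_context(i)]
        if occ <= 0:
            if counts.values[i] > 0:
                raise ValueError(
                    f"zero occurrence for context {channel_context(i)} with non-zero count")
            continue
        rates[i] = counts.values[i] / occ
    return Spectrum96(rates)


def fold_enrichment(rates: Spectrum96, channel_subset: list[str]) -> float:
    """Mean rate over a channel subset divided by the mean over all channels."""
    overall = rates.values.mean()
    if overall == 0:
        raise ValueError("overall mean rate is zero")
    idx = [CHANNELS.index(c) for c in channel_subset]
    if not idx:
        raise ValueError("empty channel subset")
    return float(rates.values[idx].mean() / overall)


def adjust_to_species(
    spectrum: Spectrum96,
    source: TripletFrequencyTable,
    target: TripletFrequencyTable,
) -> Spectrum96:
    """Rescale a spectrum from the source genome's triplet composition to the
    target's: each channel is multiplied by the target/source frequency ratio
    of its context triplet, then the spectrum is renormalised to sum to 1.

    Pearson correlation against signature catalogues is unaffected by the
    final renormalisation (scale-invariant); it is applied for presentation.
    """
    src = source.frequencies()
    tgt = target.frequencies()
    values = spectrum.values.copy()
    for i in range(96):
        t = channel_context(i)
        if src[t] == 0:
            if values[i] > 0:
                raise ValueError(f"source table has zero frequency for context {t}")
            continue
        values[i] *= tgt[t] / src[t]
    return Spectrum96(values).normalized()


@dataclass
class SignatureComparison:
    """Per-signature Pearson r and cosine similarity against one spectrum."""

    table: pd.DataFrame  # index: signature name; columns: pearson_r, cosine

    def best(self, by: str = "pearson_r") -> str:
        return self.table[by].idxmax()


def compare_signatures(spectrum: Spectrum96, signatures: SignatureMatrix) -> SignatureComparison:
    """Pearson r and cosine similarity of a spectrum against each signature.

    A zero-variance vector leaves Pearson undefined (NaN); cosine of a zero
    vector is likewise NaN.
    """
    v = spectrum.values
    rows = []
    for name, sig in zip(signatures.names, signatures.matrix):
        if np.ptp(v) == 0 or np.ptp(sig) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(v, sig).statistic)
        nv, ns = np.linalg.norm(v), np.linalg.norm(sig)
        cos = float(v @ sig / (nv * ns)) if nv > 0 and ns > 0 else float("nan")
        rows.append((name, r, cos))
    table = pd.DataFrame(rows, columns=["signature", "pearson_r", "cosine"]).set_index("signature")
    return SignatureComparison(table)


# ---------------------------------------------------------------------------
# Rates, densities, group tests

@dataclass(frozen=True)
class RateResult:
    """A per-base per-cell-division mutation rate and its inputs."""

    per_base_per_division: float
    n_mutations: float
    diploid_genome_bp: float
    generations: float

    def rounded(self, sig_figs: int = 2) -> float:
        if self.per_base_per_division == 0:
            return 0.0
        from math import floor, log10

        exp = floor(log10(abs(self.per_base_per_division)))
        return round(self.per_base_per_division, -exp + sig_figs - 1)


def mutation_rate(n_mutations: float, diploid_genome_bp: float, generations: float) -> RateResult:
    """Mutations per base per cell division over a treatment regimen."""
    if diploid_genome_bp <= 0 or generations <= 0:
        raise ValueError("genome size and generations must be positive")
    if n_mutations < 0:
        raise ValueError("mutation count must be non-negative")
    return RateResult(
        per_base_per_division=n_mutations / (diploid_genome_bp * generations),
        n_mutations=n_mutations,
        diploid_genome_bp=diploid_genome_bp,
        generations=generations,
    )


def per_mb_density(n_mutations: float, haploid_genome_bp: float) -> float:
    """Mutations per megabase of the haploid genome."""
    if haploid_genome_bp <= 0:
        raise ValueError("genome size must be positive")
    return n_mutations / (haploid_genome_bp / 1e6)


@dataclass
class GroupTestResult:
    """One-way ANOVA across treatments plus pairwise t-tests vs the mock group."""

    anova_f: float
    anova_p: float
    ttest_p: dict[str, float]


def group_tests(counts_by_treatment: dict[str, list], mock: str = "mock") -> GroupTestResult:
    """Per-clone mutation-count comparison across treatment groups.

    One-way ANOVA over all groups, and unpaired two-sided Student t-tests of
    each non-mock group against the mock group.
    """
    if len(counts_by_treatment) < 2:
        raise ValueError("need at least two treatment groups")
    for name, counts in counts_by_treatment.items():
        if len(counts) < 2:
            raise ValueError(f"group {name!r} needs at least two replicates")
    groups = [np.asarray(v, float) for v in counts_by_treatment.values()]
    if all(np.ptp(g) == 0 for g in groups) and len({g.mean() for g in groups}) == 1:
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*groups)
    ttests: dict[str, float] = {}
    if mock in counts_by_treatment:
        base = np.asarray(counts_by_treatment[mock], float)
        for name, counts in counts_by_treatment.items():
            if name == mock:
                continue
            ttests[name] = float(stats.ttest_ind(np.asarray(counts, float), base).pvalue)
    return GroupTestResult(anova_f=float(f), anova_p=float(p), ttest_p=ttests)
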