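"""Mutation density with respect to gene annotation and transcription.

Three analyses: genic/intergenic mutation-density comparison against the
genome-fraction expectation; expression-stratified distribution of mutated
genes (transcription-coupled repair depletes mutations from highly
expressed genes); and transcriptional strand bias of a substitution class
within genes. "Genic" means the union of annotated primary-transcript
intervals, introns included, with overlapping transcripts merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .channels import complement
from .types import GenomeAnnotation, Mutation


@dataclass
class RegionTally:
    """Genic vs intergenic mutation counts against genome-fraction expectation."""

    genic_fraction_genome: float
    intergenic_fraction_genome: float
    n_genic: int
    n_intergenic: int
    n_excluded: int
    chi2: float
    p_value: float

    @property
    def n_assigned(self) -> int:
        return self.n_genic + self.n_intergenic

    @property
    def genic_fraction_mutations(self) -> float:
        return self.n_genic / self.n_assigned

    @property
    def intergenic_enrichment(self) -> float:
        """Intergenic mutation density relative to uniform placement."""
        return (1 - self.genic_fraction_mutations) / self.intergenic_fraction_genome

    @property
    def genic_depletion(self) -> float:
        """Genic mutation density relative to uniform placement (< 1 = depleted)."""
        return self.genic_fraction_mutations / self.genic_fraction_genome


def enrichment_from_fractions(genic_fraction_genome: float,
                              genic_fraction_mutations: float) -> tuple[float, float]:
    """(intergenic enrichment, genic density ratio) from the two fractions.

    Both ratios come from the same 2x2 table, so intergenic enrichment and
    genic depletion are two views of a single comparison.
    """
    inter = (1 - genic_fraction_mutations) / (1 - genic_fraction_genome)
    genic = genic_fraction_mutations / genic_fraction_genome
    return inter, genic


def assign_regions(mutations: list[Mutation], annotation: GenomeAnnotation) -> RegionTally:
    """Assign each mutation genic/intergenic and test against genome fractions.

    A mutation is genic iff its position lies inside any merged gene
    interval. Mutations on unannotated chromosomes are excluded (counted).
    The chi-square test (1 df) compares observed genic/intergenic counts
    with the expectation from the genome's genic fraction.
    """
    genic_frac = annotation.genic_fraction()
    n_genic = n_intergenic = n_excluded = 0
    for m in mutations:
        if m.chrom not in annotation.chrom_lengths:
            n_excluded += 1
            continue
        if annotation.genes_at(m.chrom, m.pos):
            n_genic += 1
        else:
            n_intergenic += 1
    n = n_genic + n_intergenic
    if n == 0:
        raise ValueError("no mutations on annotated chromosomes")
    expected = np.array([n * genic_frac, n * (1 - genic_frac)])
    chi2, p = stats.chisquare([n_genic, n_intergenic], f_exp=expected)
    return RegionTally(
        genic_fraction_genome=genic_frac,
        intergenic_fraction_genome=1 - genic_frac,
        n_genic=n_genic,
        n_intergenic=n_intergenic,
        n_excluded=n_excluded,
        chi2=float(chi2),
        p_value=float(p),
    )


@dataclass
class ExpressionDistribution:
    """log10 FPKM distributions of all genes vs mutated genes."""

    all_genes_log10: np.ndarray
    mutated_log10: np.ndarray
    n_missing: int
    mannwhitney_u: float
    p_value: float  # one-sided: mutated genes skewed toward low expression


def expression_distribution(
    mutated_gene_ids: list[str],
    fpkm: pd.Series,
    pseudo_fpkm: float = 1e-3,
) -> ExpressionDistribution:
    """Compare expression of mutated genes with all genes.

    Expression is shown as log10(FPKM); zero-FPKM genes get a pseudo-count
    of ``pseudo_fpkm`` for display. The one-sided Mann-Whitney test (rank
    based, unaffected by the pseudo-count) asks whether mutated genes sit
    at lower expression than the full gene set. Mutated genes absent from
    the table are excluded and counted.
    """
    if len(mutated_gene_ids) == 0:
        raise ValueError("empty mutated gene set")
    present = [g for g in mutated_gene_ids if g in fpkm.index]
    n_missing = len(mutated_gene_ids) - len(present)
    if not present:
        raise ValueError("no mutated gene is present in the FPKM table")
    all_vals = fpkm.to_numpy(dtype=float)
    mut_vals = fpkm.loc[present].to_numpy(dtype=float)
    u, p = stats.mannwhitneyu(mut_vals, all_vals, alternative="less")
    return ExpressionDistribution(
        all_genes_log10=np.log10(all_vals + pseudo_fpkm),
        mutated_log10=np.log10(mut_vals + pseudo_fpkm),
        n_missing=n_missing,
        mannwhitney_u=float(u),
        p_value=float(p),
    )


@dataclass
class StrandBiasResult:
    """Counts of a substitution class on the transcribed vs non-transcribed
    strand of the genes containing them, with a 1-df chi-square against 50:50."""

    mutation_class: str
    n_transcribed: int
    n_non_transcribed: int
    n_excluded: int
    chi2: float
    p_value: float

    @property
    def ratio(self) -> float:
        if self.n_transcribed == 0:
            return float("inf") if self.n_non_transcribed else float("nan")
        return self.n_non_transcribed / self.n_transcribed


def strand_bias(
    snvs: list[Mutation],
    annotation: GenomeAnnotation,
    mutation_class: str,
) -> StrandBiasResult:
    """Transcriptional strand bias of one substitution class in genic SNVs.

    ``mutation_class`` is given in pyrimidine notation (e.g. ``C>A``). The
    strand carrying the mutated pyrimidine is compared with the gene's
    template (transcribed) strand; SNVs falling in overlapping genes of
    opposite strand are excluded rather than double-counted.
    """
    ref_base, alt_base = mutation_class.split(">")
    if ref_base not in "CT":
        raise ValueError("mutation_class must be pyrimidine notation, e.g. 'C>A'")
    n_t = n_nt = n_excluded = 0
    for m in snvs:
        if m.mut_class != "SNV":
            continue
        if m.ref_allele == ref_base and m.alt_allele == alt_base:
            pyr_strand = "+"
        elif m.ref_allele == complement(ref_base) and m.alt_allele == complement(alt_base):
            pyr_strand = "-"
        else:
            continue
        genes = annotation.genes_at(m.chrom, m.pos)
        if not genes:
            continue
        strands = {g.strand for g in genes}
        if len(strands) > 1:
            n_excluded += 1
            continue
        gene_strand = strands.pop()
        # template (transcribed) strand is the opposite of the gene strand
        if pyr_strand != gene_strand:
            n_t += 1
        else:
            n_nt += 1
    if n_t + n_nt == 0:
        raise ValueError(f"no genic SNVs of class {mutation_class}")
    chi2, p = stats.chisquare([n_t, n_nt])
    return StrandBiasResult(
        mutation_class=mutation_class,
        n_transcribed=n_t,
        n_non_transcribed=n_nt,
        n_excluded=n_excluded,
        chi2=float(chi2),
        p_value=float(p),
    )
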