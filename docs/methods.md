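# Methods

## The assay the package models

`clonemut` analyses whole-genome sequencing of *isogenic clone cohorts*: all
samples descend from one ancestral cell, so they share every germline
variant, and a variant confined to exactly one clone must have arisen after
the clones diverged — during the treatment window of a mutagenesis assay.
The package covers the full chain from per-position pileups to summary
statistics: unique-mutation calling, triplet-spectrum characterisation,
dinucleotide and indel context analysis, transcription-related mutation
density, and a closed-form reversion-probability model. A synthetic cohort
generator stands in for sequencing data and defines the statistical
structure every downstream stage assumes.

## Unique-mutation caller

At each genomic position, with per-sample quality-filtered read counts, a
candidate allele in sample *s* is accepted iff

1. allele fraction in *s* ≥ `min_mut_af` (default **0.33**),
2. coverage of *s* ≥ `min_cov_mutated` (default **10**),
3. reference-allele fraction in **every** other sample ≥ `min_other_ref_af`
   (default **0.9**).

A Phred ≥ 30 base-quality cut (default) is applied when the pileup is
built (the bundled `samtools mpileup` text converter performs it during
conversion). The defaults are the published optimised thresholds for this
cohort design. The three filters apply identically to SNVs, insertions and
deletions, with allele fraction = supporting reads / spanning coverage.
Heterozygous mutations sit near allele fraction 0.5, so filter (1) accepts
them with margin, while shared germline variants fail filter (3) in every
sample; uniqueness is not tested separately — it follows from (3).

Decisions where the design was open:

- If two alternate alleles pass in one sample, the higher-fraction allele is
  reported; ties break alphabetically. Multiple inserted sequences at one
  anchor are tracked separately and only the most frequent is evaluated.
- A zero-coverage "other" sample fails filter (3): absence of evidence of
  the reference state suppresses the call (conservative).
- The indel reference-allele fraction in other samples is the fraction of
  spanning reads supporting no indel at the anchor, matching the SNV
  convention.
- At least 2 samples are required; specificity grows with cohort size.

Emitted indels are canonicalised to their **leftmost** equivalent
representation (unit shifts through homopolymer/repeat context; idempotent).
A right-alignment is used internally before strand-folding indel contexts,
because the left-aligned form on one strand is the right-aligned form on the
other. Both operations are tested against exhaustive enumeration of
equivalent edit representations.

The caller has two code paths with identical output (tested): a stream path
over `PileupColumn` records, and a vectorised path over the array-backed
`PileupMatrix` the simulator produces, which handles a 5-clone × 2-Mb cohort
in ~2 s.

## Spectra

SNVs are classified into 96 channels: six pyrimidine-reference classes
(C>A, C>G, C>T, T>A, T>C, T>G) × 16 single-base 5′/3′ contexts, channel
order class-major then alphabetical flanks (the COSMIC table layout).
Purine-reference substitutions are folded to their reverse complement, so
no assumption is made about which strand carried the lesion. SNVs lacking
an ACGT flank are reported as unassignable rather than guessed.

Rates divide channel counts by the strand-folded genomic occurrence of the
context triplet. Cross-genome adjustment multiplies each channel by the
target/source triplet-frequency ratio and renormalises to unit sum; the
renormalisation is presentational — Pearson correlation against signature
catalogues is scale-invariant. Adjacent SNV pairs (dinucleotide events)
remain in SNV totals and triplet spectra and are *additionally* reported as
dinucleotide mutations; the clone-level bookkeeping is most consistent with
that convention, and the DNV detector exposes the isolated/merged split for
callers who want them excluded.

Rate conventions: the spontaneous per-base per-division rate divides the
mean per-clone mutation count by the *diploid* genome size and the number
of cell divisions (default 100 for a four-week regimen, configurable);
mutation density per Mb divides by the *haploid* genome size. Treatment
comparisons use one-way ANOVA across groups plus unpaired two-sided
Student t-tests against the mock group.

## Dinucleotide and indel contexts

Maximal runs of adjacent substituted positions within one sample are merged:
length-2 runs become dinucleotide mutations; runs ≥ 3 are reported
separately as multi-nucleotide events (none are implied by a 2-base table,
and conflating them would distort DNV tallies). The conservation identity
`isolated + 2·DNV + Σ(run lengths ≥ 3) = total SNVs` is enforced by test.
DNVs are folded so complementary events share one label, choosing the
representation whose reference dinucleotide carries fewer purines (ties
lexicographic): GG>TT → CC>AA, as in the standard presentation. The
purine-rich reference orientation is kept alongside, since the putative
lesions (GG/AG intrastrand crosslinks) live on the purine strand.

One-base insertions are classified by (preceding 2 bases, inserted base,
following 2 bases) and deletions by (preceding, deleted, following), both
after folding A/G events to T/C on the opposite strand. The two-base
deletion motif test requires the deleted pair to coincide *exactly* with AG
or GG on either strand (CT/CC on the forward read), not merely overlap it.
A generic context catalogue tallies flanking windows around any
pyrimidine-notation SNV class — e.g. the "TC>AC" breakdown is a T>A class
with 3′ C, catalogued with a window of the mutated base plus two downstream
bases. Cross-clone clustering counts inter-clone mutation pairs within a
window against the uniform-placement expectation `n_a·n_b·2w/L`.

## Genomic context

"Genic" means the union of annotated primary-transcript intervals, introns
included, with overlapping transcripts merged before computing the genome
fraction. Genic/intergenic mutation counts are tested against that fraction
with a 1-df χ². The intergenic enrichment and genic depletion ratios are
two views of the same 2×2 table and are reported as computed, not rounded
to a headline figure. Expression stratification takes a gene → FPKM table;
zero-FPKM genes receive a 10⁻³ pseudo-count for log-display only — the
one-sided Mann–Whitney location test is rank-based and unaffected. Strand
bias compares the strand carrying the mutated pyrimidine with the gene's
template strand (1-df χ² against 50:50); SNVs inside overlapping genes of
opposite strand are excluded rather than double-counted.

## Reversion model

A uniform-placement model: one mutation reverts a frameshift if it lands
within `w = 20` bp of the original lesion (probability `w/G`), or a
nonsense codon if it hits any of the 3 stop-codon bases (`3/G`).
`N = ln(1/2)/ln(1−p)` events — `ln 2/p` for small p, with relative
difference < 10⁻⁶ below p = 10⁻⁴ — or `N` cells each carrying burden `B`
(per-cell hit probability `1−(1−p)^B`) give a 50 % chance. `G` defaults to
3.1 × 10⁹ bp; the headline magnitudes (10⁸ indels, 7 × 10⁸ SNVs, < 10⁶
cells at 130 indels and 800 SNVs per Gb) are insensitive to `G` across
3.0–3.2 × 10⁹. The uniformity assumption is deliberate: measured spectra
are strongly non-uniform, and the model mirrors the order-of-magnitude
framing of the clinical question, not a sequence-specific likelihood. A
Monte-Carlo placement oracle validates the closed form in the tests.

## Synthetic cohorts

The generator emulates what downstream stages assume, not raw reads:

- **Reference** — i.i.d. bases at a target GC content (default 0.42,
  vertebrate-like), or an order-2 Markov chain matched to a triplet table.
- **Truth** — `germline_het_count` shared heterozygous SNVs; per clone,
  Poisson-distributed unique SNVs placed channel-by-channel from a
  96-channel probability vector at uniformly chosen sites carrying the
  required triplet context on either strand; insertions/deletions placed by
  weighted context patterns on either strand; a configurable fraction of
  SNV draws emits adjacent dinucleotide pairs. Implanted positions are
  pairwise disjoint across clones and from germline sites.
- **Pileup** — coverage ~ Poisson(mean 20 by default; the assay's depth is
  a configuration choice, exposed in `SimConfig`); heterozygous sites draw
  Binomial(coverage, 0.5) alternate reads (every sample at germline sites,
  the carrier only at unique sites); elsewhere non-reference reads appear
  at the base-error rate (default 0.3 %) split uniformly over the three
  other bases. Deletion-supporting reads span the anchor but contribute no
  base call at deleted positions. Indel sequencing noise is off by default
  (alignment-induced indel artefacts are out of scope); an optional
  homopolymer deletion-noise rate exists for caller stress tests.

All randomness flows from one seeded `numpy` generator: identical configs
give byte-identical references, truth sets and pileups (tested, and
recorded as SHA-256 digests in the pipeline manifest).

The preset spectra (`mock`: C>T/C>A dominated with a strong C>T excess at
CpG; `cisplatin`: 57 % C>A with 3′-C/T context enrichment, adjacent-pair
events, GG-preceded T insertions followed by T, deletions at AG/GG motifs;
`cyclophosphamide`: T>A and C>T dominated with 3′-T preference) are
figure-level approximations of the published proportions, constructed as
class weight × independent 5′/3′ flank weights. They make the generator
*qualitatively* faithful; passing tests therefore demonstrate that the
pipeline recovers what the generator implants under realistic noise — they
do not certify performance on real alignments, where mapping artefacts,
coverage biases and correlated errors (all out of scope here) dominate the
false-positive budget.

## Problem sizes and numerical choices

The validation cohort is 5 clones on a 2-Mb genome (two chromosomes) at
coverage 20 with 0.3 % errors, 200 unique SNVs per clone and 1000 germline
variants — large enough that the binomial/Poisson filter statistics are
well resolved (expected SNV sensitivity ≈ 93 % from the allele-fraction
filter at Poisson coverage, inside the 90–95 % published operating band)
while a full run stays under a minute. Signature rows must sum to 1 within
10⁻⁶; Pearson r of a zero-variance vector is reported as NaN, never
silently zero; χ² tests are 1-df with expected counts from the model, via
scipy. Chromosome-order sorting is natural (chr2 < chr10). Coordinates are
1-based inclusive internally; BED is converted at the boundary; VCF output
uses anchored indel representation.

## Known limitations

- No read-level simulation (FASTQ/alignment), duplicate marking, mapping
  artefacts, copy-number variation or structural-variant calling.
- The caller is a threshold filter, not a genotyper: no base-quality
  recalibration, no joint likelihoods, no matched-normal mode.
- Preset spectra are reconstructions at figure precision; clone-level
  published counts are not reproducible from them and are not targets.
- The reversion model ignores sequence specificity and selection; it
  estimates opportunity, not fixation.
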