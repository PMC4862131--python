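"""Dinucleotide mutations, rainfall distances, indel sequence contexts and
lesion-motif cataloguing.

Dinucleotide mutations (DNVs) are maximal runs of exactly two adjacent
substituted positions in one sample; longer runs are reported separately as
multi-nucleotide events. DNVs are folded so that complementary events on
the two strands share one label (GG>TT is shown as CC>AA); the purine-rich
orientation is also kept, since the putative mutagenic lesions (GG/AG
intrastrand crosslinks) live on the purine strand.

Insertion and deletion contexts are read after orientation folding: A/G
insertions (deletions) are represented as T/C events on the opposite
strand, with the indel right-aligned first so that the folded
representation is the left-aligned one on its own strand.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from .caller import left_align_indel, realign_right
from .channels import BASES, PURINES, complement, revcomp
from .types import Mutation

_DNA = set(BASES)


# ---------------------------------------------------------------------------
# Rainfall / intermutation distances

def intermutation_distances(snvs: list[Mutation]) -> list[tuple[Mutation, int]]:
    """Distance of each SNV to the previous SNV on the same chromosome.

    The first SNV of each chromosome has no distance and is omitted.
    Unsorted input is sorted internally with a warning. An intermutation
    distance of 1 flags dinucleotide-mutation candidacy.
    """
    keys = [m.sort_key() for m in snvs]
    if keys != sorted(keys):
        warnings.warn("SNVs were not sorted; sorting internally", stacklevel=2)
        snvs = sorted(snvs, key=Mutation.sort_key)
    out: list[tuple[Mutation, int]] = []
    prev: Mutation | None = None
    for mut in snvs:
        if prev is not None and prev.chrom == mut.chrom:
            out.append((mut, mut.pos - prev.pos))
        prev = mut
    return out


# ---------------------------------------------------------------------------
# Dinucleotide mutations

@dataclass(frozen=True)
class DinucMutation:
    """Two adjacent substituted bases in one sample.

    ``pos`` is the 1-based position of the 5' base. ``folded_ref/alt`` give
    the strand-folded table representation (fewest purines in the reference
    dinucleotide, ties broken lexicographically: GG>TT folds to CC>AA);
    ``purine_ref`` is the reference dinucleotide read on its purine-rich
    strand, the orientation of the putative crosslinked lesion.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_dinuc: str
    alt_dinuc: str

    @property
    def folded(self) -> tuple[str, str]:
        fwd = (self.ref_dinuc, self.alt_dinuc)
        rev = (revcomp(self.ref_dinuc), revcomp(self.alt_dinuc))
        n_fwd = sum(b in PURINES for b in fwd[0])
        n_rev = sum(b in PURINES for b in rev[0])
        if n_fwd != n_rev:
            return fwd if n_fwd < n_rev else rev
        return min(fwd, rev)

    @property
    def purine_ref(self) -> str:
        fwd = self.ref_dinuc
        rev = revcomp(self.ref_dinuc)
        n_fwd = sum(b in PURINES for b in fwd)
        n_rev = sum(b in PURINES for b in rev)
        if n_fwd != n_rev:
            return fwd if n_fwd > n_rev else rev
        return min(fwd, rev)

    @property
    def folded_label(self) -> str:
        ref, alt = self.folded
        return f"{ref}>{alt}"


@dataclass
class DinucResult:
    """DNVs, longer multi-nucleotide runs, and the remaining isolated SNVs."""

    dnvs: list[DinucMutation]
    multi_runs: list[list[Mutation]]  # runs of >= 3 adjacent substitutions
    isolated: list[Mutation]


def detect_dinucleotides(snvs: list[Mutation]) -> DinucResult:
    """Merge maximal runs of adjacent substituted positions per sample.

    Runs of length 2 become DNVs; runs of length >= 3 are reported as
    multi-nucleotide events and excluded from the DNV tally.
    """
    by_group: dict[tuple[str, str], list[Mutation]] = {}
    for m in snvs:
        if m.mut_class != "SNV":
            raise ValueError("detect_dinucleotides expects SNVs")
        by_group.setdefault((m.sample_id, m.chrom), []).append(m)
    dnvs: list[DinucMutation] = []
    multi: list[list[Mutation]] = []
    isolated: list[Mutation] = []
    for (_, _), muts in sorted(by_group.items()):
        muts = sorted(muts, key=lambda m: m.pos)
        run: list[Mutation] = []
        for m in muts + [None]:  # sentinel flushes the last run
            if run and m is not None and m.pos == run[-1].pos + 1:
                run.append(m)
                continue
            if len(run) == 1:
                isolated.append(run[0])
            elif len(run) == 2:
                a, b = run
                dnvs.append(DinucMutation(
                    a.sample_id, a.chrom, a.pos,
                    a.ref_allele + b.ref_allele, a.alt_allele + b.alt_allele,
                ))
            elif len(run) >= 3:
                multi.append(run)
            run = [m] if m is not None else []
    return DinucResult(dnvs=dnvs, multi_runs=multi, isolated=isolated)


# ---------------------------------------------------------------------------
# Indel contexts

@dataclass(frozen=True)
class InsertionContext:
    """Context of a one-base insertion: two bases either side, folded so the
    inserted base is a pyrimidine (T or C)."""

    preceding_2: str
    inserted_base: str
    following_2: str
    strand_folded: bool


@dataclass(frozen=True)
class DeletionContext:
    """Context of a one-base deletion: one base either side, folded so the
    deleted base is a pyrimidine (T or C)."""

    preceding_base: str
    deleted_base: str
    following_base: str
    strand_folded: bool


def classify_insertion(reference: dict[str, str], mutation: Mutation) -> InsertionContext | None:
    """Classify a 1-base insertion by its flanking bases after folding.

    A and G insertions are represented on the opposite strand (as T and C
    insertions); the event is right-aligned first so the folded
    representation is left-aligned on the reading strand. Returns None when
    a flank runs off the contig or contains non-ACGT bases.
    """
    if mutation.mut_class != "INS" or len(mutation.alt_allele) != 1:
        raise ValueError("classify_insertion expects a 1-base insertion")
    seq = reference[mutation.chrom]
    base = mutation.alt_allele
    if base in PURINES:
        m = realign_right(seq, mutation)
        pos = m.pos  # anchor base 5' of insertion (on +); on - it is 3'
        pre = revcomp(seq[pos: pos + 2])          # bases 3' of anchor on +
        fol = revcomp(seq[pos - 2: pos])          # anchor and the base before
        base = complement(base)
        folded = True
        if pos < 2 or pos + 2 > len(seq):
            return None
    else:
        m = left_align_indel(seq, mutation)
        pos = m.pos
        if pos < 2 or pos + 2 > len(seq):
            return None
        pre = seq[pos - 2: pos]
        fol = seq[pos: pos + 2]
        folded = False
    if not (set(pre) <= _DNA and set(fol) <= _DNA):
        return None
    return InsertionContext(pre, base, fol, folded)


def classify_deletion(reference: dict[str, str], mutation: Mutation) -> DeletionContext | None:
    """Classify a 1-base deletion by its neighbouring bases after folding."""
    if mutation.mut_class != "DEL" or len(mutation.ref_allele) != 1:
        raise ValueError("classify_deletion expects a 1-base deletion")
    seq = reference[mutation.chrom]
    base = mutation.ref_allele
    if base in PURINES:
        m = realign_right(seq, mutation)
        pos = m.pos
        if pos < 2 or pos + 1 > len(seq):
            return None
        pre = revcomp(seq[pos])       # base 3' on + is 5' on -
        fol = revcomp(seq[pos - 2])
        base = complement(base)
        folded = True
    else:
        m = left_align_indel(seq, mutation)
        pos = m.pos
        if pos < 2 or pos + 1 > len(seq):
            return None
        pre = seq[pos - 2]
        fol = seq[pos]
        folded = False
    if pre not in _DNA or fol not in _DNA:
        return None
    return DeletionContext(pre, base, fol, folded)


def insertion_context_table(reference, insertions: list[Mutation]) -> Counter:
    """Tally of (preceding_2, inserted, following_2) classes; 1-base only."""
    tally: Counter = Counter()
    for m in insertions:
        if m.mut_class != "INS" or len(m.alt_allele) != 1:
            continue
        ctx = classify_insertion(reference, m)
        if ctx is not None:
            tally[(ctx.preceding_2, ctx.inserted_base, ctx.following_2)] += 1
    return tally


def deletion_context_table(reference, deletions: list[Mutation]) -> Counter:
    """Tally of (preceding, deleted, following) classes; 1-base only."""
    tally: Counter = Counter()
    for m in deletions:
        if m.mut_class != "DEL" or len(m.ref_allele) != 1:
            continue
        ctx = classify_deletion(reference, m)
        if ctx is not None:
            tally[(ctx.preceding_base, ctx.deleted_base, ctx.following_base)] += 1
    return tally


_CROSSLINK_DINUCS = {"AG", "GG", "CT", "CC"}  # AG/GG on either strand


def motif_overlap_two_base_deletions(reference, deletions: list[Mutation]) -> tuple[int, int, float]:
    """Fraction of 2-base deletions removing exactly an AG or GG dinucleotide
    (read on either strand) — the putative intrastrand-crosslink motifs.

    Returns (n_at_motif, n_total, fraction). Requires exact coincidence of
    the deleted pair with the motif, not mere overlap.
    """
    total = 0
    hit = 0
    for m in deletions:
        if m.mut_class != "DEL" or len(m.ref_allele) != 2:
            continue
        total += 1
        if m.ref_allele in _CROSSLINK_DINUCS:
            hit += 1
    return hit, total, (hit / total if total else 0.0)


def context_catalogue(
    reference: dict[str, str],
    snvs: list[Mutation],
    mut_class: str,
    five: str | None = None,
    three: str | None = None,
    flank5: int = 1,
    flank3: int = 1,
) -> Counter:
    """Tally flanking windows around SNVs of one pyrimidine class.

    ``mut_class`` is e.g. ``"C>A"``; optional ``five``/``three`` constrain
    the immediate flanks (on the pyrimidine strand). The returned Counter
    maps the window string ``5'-flanks + ref + 3'-flanks`` (read on the
    pyrimidine strand) to its count. SNVs whose window runs off the contig
    are skipped and tallied under the key ``None``.
    """
    ref_base, alt_base = mut_class.split(">")
    if ref_base not in "CT":
        raise ValueError("mut_class must be in pyrimidine notation, e.g. 'C>A'")
    if five is not None and flank5 < 1:
        raise ValueError("a 5' constraint needs flank5 >= 1")
    if three is not None and flank3 < 1:
        raise ValueError("a 3' constraint needs flank3 >= 1")
    tally: Counter = Counter()
    for m in snvs:
        if m.mut_class != "SNV":
            continue
        seq = reference[m.chrom]
        if m.ref_allele == ref_base and m.alt_allele == alt_base:
            strand = "+"
        elif m.ref_allele == complement(ref_base) and m.alt_allele == complement(alt_base):
            strand = "-"
        else:
            continue
        if strand == "+":
            lo, hi = m.pos - 1 - flank5, m.pos + flank3
            if lo < 0 or hi > len(seq):
                tally[None] += 1
                continue
            window = seq[lo:hi]
        else:
            lo, hi = m.pos - 1 - flank3, m.pos + flank5
            if lo < 0 or hi > len(seq):
                tally[None] += 1
                continue
            window = revcomp(seq[lo:hi])
        if five is not None and window[flank5 - 1] != five:
            continue
        if three is not None and window[flank5 + 1] != three:
            continue
        if not set(window) <= _DNA:
            tally[None] += 1
            continue
        tally[window] += 1
    return tally


# ---------------------------------------------------------------------------
# Cross-clone clustering

@dataclass(frozen=True)
class ClonePairClustering:
    clone_a: str
    clone_b: str
    observed_pairs: int
    expected_pairs: float


def cross_clone_clustering(
    positions_by_clone: dict[str, list[tuple[str, int]]],
    window_bp: int,
    genome_length: int,
) -> list[ClonePairClustering]:
    """Count inter-clone mutation pairs within a window, per clone pair.

    For each ordered pair of mutations (one from each clone on the same
    chromosome) with |distance| <= window, one pair is counted. Under
    uniform placement the expectation is approximately
    ``n_a * n_b * 2 * window / L``; hotspot-free cohorts should match it.
    """
    if len(positions_by_clone) < 2:
        raise ValueError("need at least two clones")
    import bisect

    names = sorted(positions_by_clone)
    sorted_pos = {
        name: sorted(positions_by_clone[name]) for name in names
    }
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            count = 0
            by_chrom: dict[str, list[int]] = {}
            for chrom, pos in sorted_pos[b]:
                by_chrom.setdefault(chrom, []).append(pos)
            for chrom, pos in sorted_pos[a]:
                arr = by_chrom.get(chrom)
                if not arr:
                    continue
                lo = bisect.bisect_left(arr, pos - window_bp)
                hi = bisect.bisect_right(arr, pos + window_bp)
                count += hi - lo
            expected = len(sorted_pos[a]) * len(sorted_pos[b]) * 2 * window_bp / genome_length
            out.append(ClonePairClustering(a, b, count, expected))
    return out
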