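"""Unique-mutation calling across isogenic clone cohorts.

A variant is accepted only when it is present in exactly one sample of the
cohort: in that sample the candidate allele fraction must reach
``min_mut_af`` at coverage ``min_cov_mutated`` or better, while every other
sample must show the reference allele at a fraction of at least
``min_other_ref_af``. The same three filters apply to SNVs, insertions and
deletions (allele fraction = supporting reads / coverage). Emitted indels
are canonicalised to their leftmost equivalent representation.

Since all samples derive from a single ancestral cell, shared germline
heterozygous variants sit near allele fraction 0.5 in *every* sample and
are rejected by the other-sample reference-allele filter; specificity
therefore grows with cohort size. At least two samples are required.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .channels import BASES
from .types import CallerParams, Mutation, PileupColumn

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class CandidateCall:
    """A mutation candidate with the evidence the filters were applied to."""

    mutation: Mutation
    mut_af: float
    cov: int
    other_ref_afs: tuple[float, ...]


# ---------------------------------------------------------------------------
# Indel canonicalisation

def _shift_indel(reference: str, pos: int, allele: str, is_del: bool, left: bool) -> tuple[int, str]:
    """Shift an indel to its 5'-most (left=True) or 3'-most equivalent spot.

    ``pos`` is 1-based: first deleted base for deletions, the base 5' of the
    insertion for insertions. Works on the 0-based string internally.
    """
    k = len(allele)
    if is_del:
        i = pos - 1  # 0-based index of first deleted base
        if reference[i: i + k] != allele:
            raise ValueError(f"deletion allele {allele!r} does not match reference at {pos}")
        if left:
            while i > 0 and reference[i - 1] == reference[i + k - 1]:
                i -= 1
        else:
            while i + k < len(reference) and reference[i] == reference[i + k]:
                i += 1
        return i + 1, reference[i: i + k]
    # insertion after 0-based index j
    j = pos - 1
    seq = allele
    if left:
        while j >= 1 and reference[j] == seq[-1]:
            seq = reference[j] + seq[:-1]
            j -= 1
    else:
        while j + 1 < len(reference) and reference[j + 1] == seq[0]:
            seq = seq[1:] + reference[j + 1]
            j += 1
    return j + 1, seq


def left_align_indel(reference: dict[str, str] | str, mutation: Mutation) -> Mutation:
    """Return the 5'-most equivalent representation of an indel.

    Idempotent; raises for non-indel input. Insertions never shift past
    position 1 (an anchor base is kept for VCF representation).
    """
    return _realign(reference, mutation, left=True)


def realign_right(reference: dict[str, str] | str, mutation: Mutation) -> Mutation:
    """Return the 3'-most equivalent representation of an indel.

    Used before strand-folding indel contexts: the left-aligned form on the
    forward strand corresponds to the right-aligned form on the reverse.
    """
    return _realign(reference, mutation, left=False)


def _realign(reference, mutation: Mutation, left: bool) -> Mutation:
    if not mutation.is_indel:
        raise ValueError(f"not an indel: {mutation.mut_class} at {mutation.chrom}:{mutation.pos}")
    seq = reference[mutation.chrom] if isinstance(reference, dict) else reference
    if mutation.mut_class == "DEL":
        pos, allele = _shift_indel(seq, mutation.pos, mutation.ref_allele, True, left)
        return Mutation(mutation.sample_id, mutation.chrom, pos, allele, "")
    pos, allele = _shift_indel(seq, mutation.pos, mutation.alt_allele, False, left)
    return Mutation(mutation.sample_id, mutation.chrom, pos, "", allele)


# ---------------------------------------------------------------------------
# Filtering

def _ref_af_snv(sc, ref_base: str) -> float | None:
    """Reference allele fraction for the SNV filters; None when uncovered."""
    if sc.coverage <= 0:
        return None
    return sc.base_count(ref_base) / sc.coverage


def _ref_af_indel(sc) -> float | None:
    """Fraction of spanning reads supporting no indel at this anchor."""
    if sc.coverage <= 0:
        return None
    supported = sum(sc.ins.values()) + sum(sc.dels.values())
    return max(0, sc.coverage - supported) / sc.coverage


def call_unique_mutations(
    pileup,
    reference: dict[str, str],
    params: CallerParams | None = None,
    samples: list[str] | None = None,
) -> list[Mutation]:
    """Call mutations unique to one sample from a pileup.

    ``pileup`` is either an iterable of :class:`PileupColumn` or a
    :class:`~clonemut.simulate.PileupMatrix` (vectorised fast path; both
    paths produce identical call sets). Positions with a non-ACGT reference
    base are skipped. Returns left-aligned, sorted mutations.
    """
    params = params or CallerParams()
    from .simulate import PileupMatrix  # local import to avoid a cycle

    if isinstance(pileup, PileupMatrix):
        calls = _call_matrix(pileup, reference, params, samples)
    else:
        calls = _call_stream(pileup, reference, params, samples)
    calls = [
        left_align_indel(reference, m) if m.is_indel else m for m in calls
    ]
    return sorted(calls, key=lambda m: (m.sort_key(), m.sample_id))


def _call_stream(columns: Iterable[PileupColumn], reference, params, samples) -> list[Mutation]:
    calls: list[Mutation] = []
    declared = list(samples) if samples is not None else None
    for col in columns:
        if declared is None:
            declared = sorted(col.samples)
        unknown = set(col.samples) - set(declared)
        if unknown:
            raise ValueError(f"pileup sample(s) {sorted(unknown)} not declared in cohort")
        if len(declared) < 2:
            raise ValueError("cohort must contain at least two samples")
        if col.ref_base not in BASES:
            continue
        calls.extend(_call_column(col, declared, reference, params))
    return calls


def _call_column(col: PileupColumn, cohort: list[str], reference, params) -> list[Mutation]:
    out: list[Mutation] = []
    counts = {sid: col.samples.get(sid) for sid in cohort}
    snv_ref_afs = {
        sid: (_ref_af_snv(sc, col.ref_base) if sc is not None else None)
        for sid, sc in counts.items()
    }
    indel_ref_afs = {
        sid: (_ref_af_indel(sc) if sc is not None else None)
        for sid, sc in counts.items()
    }

    def others_ok(sid: str, afs: dict) -> bool:
        return all(
            afs[o] is not None and afs[o] >= params.min_other_ref_af
            for o in cohort if o != sid
        )

    for sid in cohort:
        sc = counts[sid]
        if sc is None or sc.coverage < params.min_cov_mutated:
            continue
        # --- SNV candidates: best-passing alternate allele, ties alphabetical
        best: tuple[float, str] | None = None
        for base in BASES:
            if base == col.ref_base:
                continue
            af = sc.base_count(base) / sc.coverage
            if af >= params.min_mut_af and (best is None or af > best[0]):
                best = (af, base)
        if best is not None and others_ok(sid, snv_ref_afs):
            out.append(Mutation(sid, col.chrom, col.pos, col.ref_base, best[1]))
        # --- insertion candidate: the most frequent inserted sequence
        if sc.ins:
            # most frequent inserted sequence; ties broken alphabetically
            seq = min(sc.ins, key=lambda s: (-sc.ins[s], s))
            if sc.ins[seq] / sc.coverage >= params.min_mut_af and others_ok(sid, indel_ref_afs):
                out.append(Mutation(sid, col.chrom, col.pos, "", seq))
        # --- deletion candidate: the most frequent deletion length
        if sc.dels:
            length = max(sc.dels, key=lambda k: (sc.dels[k], -k))
            if sc.dels[length] / sc.coverage >= params.min_mut_af:
                seq = reference[col.chrom][col.pos: col.pos + length]
                if len(seq) == length and others_ok(sid, indel_ref_afs):
                    out.append(Mutation(sid, col.chrom, col.pos + 1, seq, ""))
    return out


def _call_matrix(pm, reference, params, samples) -> list[Mutation]:
    """Vectorised filter over a PileupMatrix; mirrors the stream path."""
    cohort = list(samples) if samples is not None else list(pm.samples)
    if set(cohort) != set(pm.samples):
        raise ValueError("declared cohort does not match pileup samples")
    if len(cohort) < 2:
        raise ValueError("cohort must contain at least two samples")
    order = [pm.samples.index(sid) for sid in cohort]
    calls: list[Mutation] = []
    for chrom, data in pm.chroms.items():
        cov = data["cov"][order]            # (S, L)
        counts = data["counts"][:, order]   # (4, S, L)
        ref_code = data["ref_code"]         # (L,)
        S, L = cov.shape
        covered = cov > 0
        cov_safe = np.where(covered, cov, 1)
        ref_count = np.take_along_axis(
            counts, ref_code[None, None, :].repeat(S, axis=1), axis=0
        )[0]
        # indel support per sample/pos (sparse dicts -> dense corrections)
        indel_support = np.zeros((S, L), dtype=np.int32)
        for pos, per_sample in data["ins"].items():
            for sid, seqs in per_sample.items():
                indel_support[cohort.index(sid), pos - 1] += sum(seqs.values())
        for pos, per_sample in data["dels"].items():
            for sid, lens in per_sample.items():
                indel_support[cohort.index(sid), pos - 1] += sum(lens.values())

        ref_ok_snv = covered & (ref_count / cov_safe >= params.min_other_ref_af)
        n_ok_snv = ref_ok_snv.sum(axis=0)
        valid_ref = ref_code >= 0

        for alt_code in range(4):
            alt_count = counts[alt_code]
            pass_mut = (
                (cov >= params.min_cov_mutated)
                & covered
                & (alt_count / cov_safe >= params.min_mut_af)
                & (ref_code[None, :] != alt_code)
                & valid_ref[None, :]
            )
            others_all_ok = (n_ok_snv - ref_ok_snv.astype(np.int64)) == S - 1
            hit_s, hit_p = np.nonzero(pass_mut & others_all_ok)
            for s, p in zip(hit_s.tolist(), hit_p.tolist()):
                calls.append((chrom, int(p), s, alt_code))

        # resolve multi-allele passes per (sample, pos): keep best af, tie alpha
        calls_here = {}
        snv_calls = []
        for chrom_, p, s, alt_code in calls:
            if chrom_ != chrom:
                snv_calls.append((chrom_, p, s, alt_code))
                continue
            key = (p, s)
            af = counts[alt_code, s, p] / cov[s, p]
            prev = calls_here.get(key)
            if prev is None or af > prev[0] or (af == prev[0] and alt_code < prev[1]):
                calls_here[key] = (af, alt_code)
        calls = snv_calls
        for (p, s), (_, alt_code) in calls_here.items():
            calls.append((chrom, p, s, alt_code))

        # --- indels at the sparse positions
        ref_ok_indel = covered & ((cov - indel_support) / cov_safe >= params.min_other_ref_af)
        seq = reference[chrom]
        for pos, per_sample in data["ins"].items():
            p = pos - 1
            for sid, seqs in per_sample.items():
                s = cohort.index(sid)
                if cov[s, p] < params.min_cov_mutated or cov[s, p] == 0:
                    continue
                best = min(seqs, key=lambda q: (-seqs[q], q))
                if seqs[best] / cov[s, p] < params.min_mut_af:
                    continue
                mask = ref_ok_indel[:, p].copy()
                mask[s] = True
                if mask.all():
                    calls.append((chrom, p, s, ("INS", best)))
        for pos, per_sample in data["dels"].items():
            p = pos - 1
            for sid, lens in per_sample.items():
                s = cohort.index(sid)
                if cov[s, p] < params.min_cov_mutated or cov[s, p] == 0:
                    continue
                best = max(lens, key=lambda k: (lens[k], -k))
                if lens[best] / cov[s, p] < params.min_mut_af:
                    continue
                dseq = seq[pos: pos + best]
                if len(dseq) != best:
                    continue
                mask = ref_ok_indel[:, p].copy()
                mask[s] = True
                if mask.all():
                    calls.append((chrom, p, s, ("DEL", dseq)))

    out: list[Mutation] = []
    for chrom, p, s, what in calls:
        sid = cohort[s]
        if isinstance(what, int):
            ref_b = pm.chroms[chrom]["ref_code"][p]
            out.append(Mutation(sid, chrom, p + 1, BASES[ref_b], BASES[what]))
        elif what[0] == "INS":
            out.append(Mutation(sid, chrom, p + 1, "", what[1]))
        else:
            out.append(Mutation(sid, chrom, p + 2, what[1], ""))
    return out
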