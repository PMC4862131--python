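"""Unique-mutation caller: hand-worked filter cases, a brute-force oracle,
and indel canonicalisation checked against exhaustive equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonemut.caller import call_unique_mutations, left_align_indel, realign_right
from clonemut.types import CallerParams, Mutation, PileupColumn, SampleCounts


def col(ref="C", **samples):
    return PileupColumn("chr1", 5, ref, samples)


def sc(cov, **bases):
    kw = {f"n_{b}": n for b, n in bases.items()}
    return SampleCounts(coverage=cov, **kw)


REF = {"chr1": "AAAACGTACGTACG"}
PARAMS = CallerParams()


class TestFilterByHand:
    def test_clean_unique_snv_called(self):
        calls = call_unique_mutations(
            [col(s1=sc(20, C=10, A=10), s2=sc(20, C=20), s3=sc(20, C=20))],
            REF, PARAMS, ["s1", "s2", "s3"])
        assert calls == [Mutation("s1", "chr1", 5, "C", "A")]

    def test_other_sample_ref_af_below_09_blocks_call(self):
        calls = call_unique_mutations(
            [col(s1=sc(20, C=10, A=10), s2=sc(20, C=17, A=3), s3=sc(20, C=20))],
            REF, PARAMS, ["s1", "s2", "s3"])
        assert calls == []

    def test_coverage_filter_blocks_low_coverage(self):
        calls = call_unique_mutations(
            [col(s1=sc(9, C=4, A=5), s2=sc(20, C=20), s3=sc(20, C=20))],
            REF, PARAMS, ["s1", "s2", "s3"])
        assert calls == []

    def test_af_filter_blocks_low_fraction(self):
        calls = call_unique_mutations(
            [col(s1=sc(20, C=14, A=6), s2=sc(20, C=20), s3=sc(20, C=20))],
            REF, PARAMS, ["s1", "s2", "s3"])
        assert calls == []

    def test_all_reference_no_call(self):
        calls = call_unique_mutations(
            [col(s1=sc(20, C=20), s2=sc(20, C=20), s3=sc(20, C=20))],
            REF, PARAMS, ["s1", "s2", "s3"])
        assert calls == []

    def test_shared_variant_not_unique(self):
        """A variant at ~0.5 AF in two samples suppresses both calls."""
        calls = call_unique_mutations(
            [col(s1=sc(20, C=10, A=10), s2=sc(20, C=10, A=10), s3=sc(20, C=20))],
            REF, PARAMS, ["s1", "s2", "s3"])
        assert calls == []

    def test_zero_coverage_other_sample_suppresses(self):
        calls = call_unique_mutations(
            [col(s1=sc(20, C=10, A=10), s2=sc(0), s3=sc(20, C=20))],
            REF, PARAMS, ["s1", "s2", "s3"])
        assert calls == []

    def test_undeclared_sample_rejected(self):
        with pytest.raises(ValueError, match="not declared"):
            call_unique_mutations(
                [col(s1=sc(20, C=20), s9=sc(20, C=20))], REF, PARAMS, ["s1", "s2"])

    def test_higher_fraction_allele_wins(self):
        calls = call_unique_mutations(
            [col(s1=SampleCounts(coverage=30, n_C=6, n_A=10, n_T=14),
                 s2=sc(20, C=20), s3=sc(20, C=20))],
            REF, PARAMS, ["s1", "s2", "s3"])
        assert calls == [Mutation("s1", "chr1", 5, "C", "T")]

    def test_insertion_called_with_same_filters(self):
        c = col(s1=SampleCounts(coverage=20, n_C=20, ins={"T": 9}),
                s2=sc(20, C=20), s3=sc(20, C=20))
        calls = call_unique_mutations([c], REF, PARAMS, ["s1", "s2", "s3"])
        assert [m.mut_class for m in calls] == ["INS"]

    def test_deletion_called_and_left_aligned(self):
        # deletion of G at pos 6 within ref AAAACGTACGTACG
        c = PileupColumn("chr1", 5, "C", {
            "s1": SampleCounts(coverage=20, n_C=10, dels={1: 9}),
            "s2": sc(20, C=20), "s3": sc(20, C=20)})
        calls = call_unique_mutations([c], REF, PARAMS, ["s1", "s2", "s3"])
        assert calls == [Mutation("s1", "chr1", 6, "G", "")]


# ---------------------------------------------------------------------------
# Brute-force oracle

def oracle_unique_calls(columns, reference, params, cohort):
    """Direct transcription of the acceptance rule: a candidate allele is
    accepted iff its fraction >= min_mut_af at coverage >= min_cov in exactly
    that sample while every other sample shows the reference allele at
    >= min_other_ref_af."""
    accepted = []
    for c in columns:
        if c.ref_base not in "ACGT":
            continue
        for sid in cohort:
            s = c.samples.get(sid, SampleCounts())
            if s.coverage < params.min_cov_mutated or s.coverage == 0:
                continue
            others = [c.samples.get(o, SampleCounts()) for o in cohort if o != sid]

            def ref_ok(osc, indel):
                if osc.coverage == 0:
                    return False
                if indel:
                    supp = sum(osc.ins.values()) + sum(osc.dels.values())
                    return (osc.coverage - supp) / osc.coverage >= params.min_other_ref_af
                return osc.base_count(c.ref_base) / osc.coverage >= params.min_other_ref_af

            passing = [
                b for b in "ACGT"
                if b != c.ref_base and s.base_count(b) / s.coverage >= params.min_mut_af
            ]
            if passing and all(ref_ok(o, False) for o in others):
                best = sorted(passing, key=lambda b: (-s.base_count(b), b))[0]
                accepted.append(Mutation(sid, c.chrom, c.pos, c.ref_base, best))
            if s.ins:
                seq = sorted(s.ins, key=lambda q: (-s.ins[q], q))[0]
                if s.ins[seq] / s.coverage >= params.min_mut_af and all(
                        ref_ok(o, True) for o in others):
                    accepted.append(Mutation(sid, c.chrom, c.pos, "", seq))
            if s.dels:
                ln = sorted(s.dels, key=lambda k: (-s.dels[k], k))[0]
                dseq = reference[c.chrom][c.pos: c.pos + ln]
                if len(dseq) == ln and s.dels[ln] / s.coverage >= params.min_mut_af and all(
                        ref_ok(o, True) for o in others):
                    accepted.append(Mutation(sid, c.chrom, c.pos + 1, dseq, ""))
    return sorted(
        (left_align_indel(reference, m) if m.is_indel else m for m in accepted),
        key=lambda m: (m.sort_key(), m.sample_id))


def _random_columns(rng, reference, cohort, n):
    chrom = "chr1"
    seq = reference[chrom]
    cols = []
    for _ in range(n):
        pos = int(rng.integers(2, len(seq) - 2))
        ref = seq[pos - 1]
        samples = {}
        for sid in cohort:
            cov = int(rng.poisson(12))
            s = SampleCounts(coverage=cov)
            if cov:
                alt_n = int(rng.binomial(cov, rng.choice([0.0, 0.05, 0.5], p=[0.5, 0.3, 0.2])))
                alt_b = "ACGT"[int(rng.integers(4))]
                n_ref = cov - alt_n
                setattr(s, f"n_{ref}", getattr(s, f"n_{ref}") + n_ref)
                if alt_b != ref:
                    setattr(s, f"n_{alt_b}", getattr(s, f"n_{alt_b}") + alt_n)
                else:
                    setattr(s, f"n_{ref}", cov)
                if rng.random() < 0.15:
                    s.ins["ACGT"[int(rng.integers(4))]] = int(rng.integers(1, cov + 1))
                if rng.random() < 0.15:
                    s.dels[int(rng.integers(1, 3))] = int(rng.integers(1, cov + 1))
            samples[sid] = s
        cols.append(PileupColumn(chrom, pos, ref, samples))
    return cols


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_cohorts(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        reference = {"chr1": seq}
        cohort = [f"s{i}" for i in range(int(rng.integers(2, 6)))]
        cols = _random_columns(rng, reference, cohort, 300)
        ours = call_unique_mutations(cols, reference, PARAMS, cohort)
        assert ours == oracle_unique_calls(cols, reference, PARAMS, cohort)

    def test_matrix_and_stream_paths_identical(self, small_cohort):
        cfg, reference, truth, pileup = small_cohort
        fast = call_unique_mutations(pileup, reference, PARAMS, pileup.samples)
        slow = call_unique_mutations(pileup.iter_columns(), reference, PARAMS, pileup.samples)
        assert fast == slow

    def test_uniqueness_of_emitted_calls(self, small_cohort):
        cfg, reference, truth, pileup = small_cohort
        calls = call_unique_mutations(pileup, reference, PARAMS, pileup.samples)
        seen = {}
        for m in calls:
            key = (m.chrom, m.pos, m.ref_allele, m.alt_allele)
            assert key not in seen or seen[key] == m.sample_id
            seen[key] = m.sample_id

    def test_germline_immunity(self, small_cohort):
        cfg, reference, truth, pileup = small_cohort
        calls = call_unique_mutations(pileup, reference, PARAMS, pileup.samples)
        germ = {(m.chrom, m.pos) for m in truth.germline}
        assert sum((m.chrom, m.pos) in germ for m in calls) == 0

    @pytest.mark.parametrize("tweak", [
        {"min_mut_af": 0.5}, {"min_cov_mutated": 15}, {"min_other_ref_af": 0.95},
    ])
    def test_raising_any_threshold_never_adds_calls(self, small_cohort, tweak):
        cfg, reference, truth, pileup = small_cohort
        base = set(call_unique_mutations(pileup, reference, PARAMS, pileup.samples))
        stricter = set(call_unique_mutations(
            pileup, reference, CallerParams(**tweak), pileup.samples))
        assert stricter <= base


# ---------------------------------------------------------------------------
# Indel canonicalisation

def _apply(seq, pos, allele, is_del):
    if is_del:
        return seq[: pos - 1] + seq[pos - 1 + len(allele):]
    return seq[:pos] + allele + seq[pos:]


def _equivalents(seq, mut):
    """All representations of an indel producing the same edited sequence."""
    is_del = mut.mut_class == "DEL"
    allele = mut.ref_allele if is_del else mut.alt_allele
    target = _apply(seq, mut.pos, allele, is_del)
    out = []
    k = len(allele)
    for p in range(1, len(seq) + 1):
        if is_del:
            cand = seq[p - 1: p - 1 + k]
            if len(cand) == k and _apply(seq, p, cand, True) == target:
                out.append((p, cand))
        else:
            # insertion allele at p is determined by the target string
            cand = target[p: p + k]
            if _apply(seq, p, cand, False) == target:
                out.append((p, cand))
    return out


class TestIndelAlignment:
    SEQ = {"chr1": "CAAAT"}

    def test_homopolymer_deletion_shifts_left(self):
        m = Mutation("s", "chr1", 4, "A", "")
        assert left_align_indel(self.SEQ, m) == Mutation("s", "chr1", 2, "A", "")

    def test_homopolymer_deletion_shifts_right(self):
        m = Mutation("s", "chr1", 2, "A", "")
        assert realign_right(self.SEQ, m) == Mutation("s", "chr1", 4, "A", "")

    def test_no_repeat_context_is_fixed_point(self):
        ref = {"chr1": "ACGTGCA"}
        m = Mutation("s", "chr1", 3, "G", "")
        assert left_align_indel(ref, m) == m
        assert realign_right(ref, m) == m

    def test_dimer_insertion_shifts_to_leftmost_repeat(self):
        ref = {"chr1": "TTAGAGCC"}
        # AG inserted after the second AG unit is equivalent to insertion
        # after position 2 (before the first AG)
        m = Mutation("s", "chr1", 6, "", "AG")
        assert left_align_indel(ref, m).pos == 2

    def test_non_indel_rejected(self):
        with pytest.raises(ValueError):
            left_align_indel(self.SEQ, Mutation("s", "chr1", 2, "A", "C"))

    @given(st.data())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_alignment_matches_exhaustive_equivalence(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=30))
        is_del = bool(rng.integers(2))
        if is_del:
            pos = int(rng.integers(1, 29))
            k = int(rng.integers(1, min(3, 30 - pos) + 1))
            mut = Mutation("s", "chr1", pos, seq[pos - 1: pos - 1 + k], "")
        else:
            pos = int(rng.integers(1, 30))
            allele = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 3))))
            mut = Mutation("s", "chr1", pos, "", allele)
        equivs = _equivalents(seq, mut)
        allele_attr = "ref_allele" if is_del else "alt_allele"
        left = left_align_indel({"chr1": seq}, mut)
        right = realign_right({"chr1": seq}, mut)
        valid = [e for e in equivs if e[0] >= 1]
        assert (left.pos, getattr(left, allele_attr)) == min(valid)
        assert (right.pos, getattr(right, allele_attr)) == max(valid)
        # idempotence and composition
        assert left_align_indel({"chr1": seq}, left) == left
        assert left_align_indel({"chr1": seq}, right) == left
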