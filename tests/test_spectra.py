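"""Spectrum classification, normalisation, species adjustment, signature
similarity and rate arithmetic."""

import numpy as np
import pytest
from scipy import stats

from clonemut.channels import CHANNELS, CHANNEL_INDEX, TRIPLETS32, channel_context
from clonemut.spectra import (
    adjust_to_species,
    classify_snv,
    compare_signatures,
    count_spectrum,
    fold_enrichment,
    group_tests,
    mutation_rate,
    normalize_rates,
    per_mb_density,
    triplet_occurrences,
)
from clonemut.types import Mutation, SignatureMatrix, Spectrum96, TripletFrequencyTable


class TestClassifySnv:
    def test_pyrimidine_reference_direct(self):
        ref = {"chr1": "TACAG"}
        ch = classify_snv(ref, Mutation("s", "chr1", 3, "C", "T"))
        assert CHANNELS[ch] == "A[C>T]A"

    def test_purine_reference_folded(self):
        ref = {"chr1": "ATGAG"}
        ch = classify_snv(ref, Mutation("s", "chr1", 3, "G", "T"))
        assert CHANNELS[ch] == "T[C>A]A"

    def test_chromosome_end_unassignable(self):
        ref = {"chr1": "CAG"}
        assert classify_snv(ref, Mutation("s", "chr1", 1, "C", "T")) is None
        assert classify_snv(ref, Mutation("s", "chr1", 3, "G", "T")) is None

    def test_n_flank_unassignable(self):
        ref = {"chr1": "ANCTG"}
        assert classify_snv(ref, Mutation("s", "chr1", 3, "C", "T")) is None

    def test_reference_mismatch_rejected(self):
        ref = {"chr1": "AACTG"}
        with pytest.raises(ValueError):
            classify_snv(ref, Mutation("s", "chr1", 3, "G", "T"))


class TestCountSpectrum:
    def test_empty_input_all_zero(self):
        result = count_spectrum([], {"chr1": "ACGT"})
        assert result.spectrum.total() == 0

    def test_single_snv_one_hot(self):
        ref = {"chr1": "TACAG"}
        result = count_spectrum([Mutation("s", "chr1", 3, "C", "G")], ref)
        assert result.spectrum["A[C>G]A"] == 1
        assert result.spectrum.total() == 1

    def test_matches_exhaustive_tally_on_random_snvs(self, rng):
        """Channel tally equals a brute-force 96-way enumeration."""
        seq = "".join(rng.choice(list("ACGT"), 5_000))
        ref = {"chr1": seq}
        muts = []
        for _ in range(400):
            pos = int(rng.integers(2, len(seq)))
            r = seq[pos - 1]
            alt = "ACGT"[(("ACGT".index(r)) + int(rng.integers(1, 4))) % 4]
            muts.append(Mutation("s", "chr1", pos, r, alt))
        result = count_spectrum(muts, ref)
        # brute force: enumerate all 96 (class, context) combinations
        from clonemut.channels import revcomp

        brute = np.zeros(96)
        for i, label in enumerate(CHANNELS):
            five, ref_b, alt_b, three = label[0], label[2], label[4], label[6]
            for m in muts:
                if m.pos < 2 or m.pos >= len(seq):
                    continue
                trip = seq[m.pos - 2: m.pos + 1]
                fwd = (trip == five + ref_b + three
                       and (m.ref_allele, m.alt_allele) == (ref_b, alt_b))
                rc_trip = revcomp(trip)
                rev = (rc_trip == five + ref_b + three
                       and (revcomp(m.ref_allele), revcomp(m.alt_allele)) == (ref_b, alt_b))
                if fwd or rev:
                    brute[i] += 1
        assert (result.spectrum.values == brute).all()
        assert result.six_class.sum() + result.n_unassignable == len(muts)

    def test_six_class_is_channel_marginal(self):
        values = np.arange(96, dtype=float)
        s = Spectrum96(values)
        assert (s.six_class() == values.reshape(6, 16).sum(axis=1)).all()


class TestTripletOccurrences:
    def test_hand_enumeration_with_folding(self):
        table = triplet_occurrences({"chr1": "ACGT"})
        assert table["ACG"] == 2  # ACG plus CGT (folds to ACG)
        assert sum(table.values()) == 2

    def test_poly_a_folds_to_ttt(self):
        table = triplet_occurrences({"chr1": "A" * 10})
        assert table["TTT"] == 8

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            triplet_occurrences({})
        with pytest.raises(ValueError):
            triplet_occurrences({"chr1": "NNNNN"})

    def test_uniform_genome_near_flat(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300_000))
        freqs = triplet_occurrences({"chr1": seq}).frequencies()
        for t in TRIPLETS32:
            expected = 2 / 64 if t != (t[1] + t[1] + t[1]) else None
            # every folded key aggregates 2 of the 64 raw triplets except
            # self-complementary ones... none of the 32 keys is; check 1/32
            assert abs(freqs[t] - 1 / 32) < 0.003

    def test_n_windows_skipped(self):
        with_n = triplet_occurrences({"chr1": "ACGTNACGT"})
        without = triplet_occurrences({"chr1": "ACGT"})
        assert with_n["ACG"] == 2 * without["ACG"]


class TestNormalizeRates:
    def test_direct_division(self):
        counts = Spectrum96.zeros()
        counts.values[CHANNEL_INDEX["A[C>T]G"]] = 10
        occ = dict.fromkeys(TRIPLETS32, 500.0)
        occ["ACG"] = 1000.0
        rates = normalize_rates(Spectrum96(counts.values), TripletFrequencyTable(occ))
        assert rates["A[C>T]G"] == pytest.approx(0.01)

    def test_equal_occurrences_keep_proportions(self, rng):
        counts = Spectrum96(rng.integers(0, 50, 96).astype(float))
        rates = normalize_rates(counts, TripletFrequencyTable.flat())
        assert np.allclose(rates.values, counts.values)

    def test_conservation_rates_times_occurrences(self, rng):
        counts = Spectrum96(rng.integers(0, 50, 96).astype(float))
        occ = TripletFrequencyTable(
            {t: float(rng.integers(100, 1000)) for t in TRIPLETS32})
        rates = normalize_rates(counts, occ)
        back = sum(rates.values[i] * occ[channel_context(i)] for i in range(96))
        assert back == pytest.approx(counts.total())

    def test_zero_occurrence_with_count_rejected(self):
        counts = Spectrum96.zeros()
        counts.values[CHANNEL_INDEX["A[C>T]G"]] = 1
        occ = dict.fromkeys(TRIPLETS32, 1.0)
        occ["ACG"] = 0.0
        with pytest.raises(ValueError):
            normalize_rates(Spectrum96(counts.values), TripletFrequencyTable(occ))

    def test_all_zero_counts_all_zero_rates(self):
        rates = normalize_rates(Spectrum96.zeros(), TripletFrequencyTable.flat())
        assert rates.total() == 0


class TestFoldEnrichment:
    def test_full_subset_is_identity(self, rng):
        rates = Spectrum96(rng.random(96) + 0.1)
        assert fold_enrichment(rates, list(CHANNELS)) == pytest.approx(1.0)

    def test_constructed_twofold_channel(self):
        x = 1.0
        values = np.full(96, x * 96 / 95 - 2 * x / 95)  # 95 channels
        values[0] = 2 * x
        values[1:] = (96 * x - 2 * x) / 95
        rates = Spectrum96(values)
        assert rates.values.mean() == pytest.approx(x)
        assert fold_enrichment(rates, [CHANNELS[0]]) == pytest.approx(2.0)

    def test_zero_rate_subset(self):
        values = np.ones(96)
        values[3] = 0
        assert fold_enrichment(Spectrum96(values), [CHANNELS[3]]) == 0

    def test_ncg_ntg_style_subset(self):
        """A CpG-focused enrichment: boost all N[C>T]G channels 15x."""
        values = np.ones(96)
        idx = [CHANNEL_INDEX[f"{f}[C>T]G"] for f in "ACGT"]
        values[idx] = 15 * np.mean(values)
        rates = Spectrum96(values)
        ratio = fold_enrichment(rates, [CHANNELS[i] for i in idx])
        assert ratio == pytest.approx(15 * 96 / (92 + 4 * 15))


class TestSpeciesAdjustment:
    def test_identical_tables_identity(self, rng):
        s = Spectrum96(rng.random(96)).normalized()
        occ = TripletFrequencyTable({t: float(rng.integers(10, 100)) for t in TRIPLETS32})
        out = adjust_to_species(s, occ, occ)
        assert np.allclose(out.values, s.values)

    def test_flat_tables_identity(self, rng):
        s = Spectrum96(rng.random(96)).normalized()
        out = adjust_to_species(s, TripletFrequencyTable.flat(), TripletFrequencyTable.flat())
        assert np.allclose(out.values, s.values)

    def test_doubling_target_frequency_doubles_weight(self):
        s = Spectrum96(np.ones(96)).normalized()
        src = TripletFrequencyTable.flat()
        tgt = dict(TripletFrequencyTable.flat())
        tgt["ACA"] = 2.0
        out = adjust_to_species(s, src, TripletFrequencyTable(tgt))
        i = CHANNEL_INDEX["A[C>A]A"]
        j = CHANNEL_INDEX["A[C>A]G"]  # untouched context ACG
        # pre-normalisation weight of ACA channels doubled relative to others
        # (up to the common renormalisation of the target table itself)
        assert out.values[i] / out.values[j] == pytest.approx(2.0)

    def test_one_hot_stays_one_hot(self):
        values = np.zeros(96)
        values[5] = 1.0
        occ = TripletFrequencyTable({t: float(i + 1) for i, t in enumerate(TRIPLETS32)})
        out = adjust_to_species(Spectrum96(values), occ, TripletFrequencyTable.flat())
        assert out.values[5] == pytest.approx(1.0)
        assert out.total() == pytest.approx(1.0)


class TestCompareSignatures:
    def _sig(self, rows, names=None):
        rows = np.asarray(rows, float)
        rows = rows / rows.sum(axis=1, keepdims=True)
        return SignatureMatrix(names or [f"S{i}" for i in range(len(rows))], rows)

    def test_identical_vector_gives_unity(self, rng):
        v = rng.random(96) + 0.01
        sig = self._sig([v])
        comp = compare_signatures(Spectrum96(v).normalized(), sig)
        assert comp.table.loc["S0", "pearson_r"] == pytest.approx(1.0)
        assert comp.table.loc["S0", "cosine"] == pytest.approx(1.0)

    def test_orthogonal_one_hots_cosine_zero(self):
        a = np.zeros(96); a[0] = 1
        b = np.zeros(96); b[1] = 1
        comp = compare_signatures(Spectrum96(a), self._sig([b]))
        assert comp.table.loc["S0", "cosine"] == pytest.approx(0.0)

    def test_affine_decreasing_vector_gives_minus_one(self, rng):
        v = rng.random(96) + 0.1
        w = v.max() + v.min() - v  # exact affine reversal: r must be -1
        comp = compare_signatures(Spectrum96(v).normalized(), self._sig([w]))
        assert comp.table.loc["S0", "pearson_r"] == pytest.approx(-1.0)

    def test_pearson_affine_and_cosine_scale_invariance(self, rng):
        v = rng.random(96) + 0.1
        w = rng.random(96) + 0.1
        base = compare_signatures(Spectrum96(v), self._sig([w]))
        scaled = compare_signatures(Spectrum96(3.7 * v), self._sig([w]))
        assert scaled.table.loc["S0", "pearson_r"] == pytest.approx(
            base.table.loc["S0", "pearson_r"])
        assert scaled.table.loc["S0", "cosine"] == pytest.approx(
            base.table.loc["S0", "cosine"])

    def test_zero_variance_reported_as_nan(self):
        flat = np.full(96, 1 / 96)
        comp = compare_signatures(Spectrum96(flat), self._sig([np.ones(96)]))
        assert np.isnan(comp.table.loc["S0", "pearson_r"])
        assert comp.table.loc["S0", "cosine"] == pytest.approx(1.0)


class TestRatesAndDensities:
    def test_spontaneous_rate_arithmetic(self):
        r = mutation_rate(47, 2.06e9, 100)
        assert r.per_base_per_division == pytest.approx(47 / 2.06e11)
        assert r.rounded(2) == pytest.approx(2.3e-10)

    def test_zero_mutations_zero_rate(self):
        assert mutation_rate(0, 1e9, 10).per_base_per_division == 0

    def test_direct_rate_example(self):
        assert mutation_rate(100, 1e9, 10).per_base_per_division == pytest.approx(1e-8)

    def test_zero_generations_rejected(self):
        with pytest.raises(ValueError):
            mutation_rate(10, 1e9, 0)

    def test_density_examples(self):
        assert per_mb_density(812, 1.03e9) == pytest.approx(0.788, abs=0.001)
        assert per_mb_density(0, 1e9) == 0
        assert per_mb_density(1000, 1e9) == pytest.approx(1.0)


class TestGroupTests:
    def test_identical_groups_f_zero(self):
        res = group_tests({"mock": [47, 47, 47], "drugA": [47, 47, 47]})
        assert res.anova_f == 0.0
        assert res.anova_p == 1.0

    def test_clear_difference_matches_textbook_t(self):
        a = [47.0, 47.1, 46.9, 47.0]
        b = [95.0, 95.2, 94.8]
        res = group_tests({"mock": a, "cisplatin": b})
        # textbook pooled-variance t statistic
        na, nb = len(a), len(b)
        va = np.var(a, ddof=1); vb = np.var(b, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (np.mean(b) - np.mean(a)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p_hand = 2 * stats.t.sf(abs(t), na + nb - 2)
        assert res.ttest_p["cisplatin"] == pytest.approx(p_hand, rel=1e-9)
        assert res.ttest_p["cisplatin"] < 1e-6

    def test_equal_mean_groups_f_near_zero(self, rng):
        g = {k: list(100 + rng.normal(0, 1e-9, 3)) for k in ("a", "b", "c")}
        res = group_tests(g, mock="a")
        assert res.anova_p > 0.5

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            group_tests({"mock": [1, 2], "x": [5]})
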