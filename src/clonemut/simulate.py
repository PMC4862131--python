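"""Synthetic isogenic-cohort generator.

Emulates the statistical structure the downstream analyses assume: a random
reference genome, N diploid clones sharing heterozygous germline variants,
each clone additionally carrying unique implanted SNVs / insertions /
deletions drawn from treatment-like spectra and context models, observed
through per-position pileups with Poisson coverage, binomial heterozygous
allele counts (VAF 0.5) and a uniform base-error rate.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from ``SimConfig.seed``; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .channels import BASES, channel_context, channel_class, complement, revcomp
from .types import Mutation, PileupColumn, SampleCounts

_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic clone/pileup generator.

    Per-clone event counts are Poisson means. ``spectrum_weights`` is a
    96-channel probability vector in canonical channel order;
    ``insertion_model`` / ``deletion_model`` map flanking-context patterns
    (with N wildcards) to weights. Defaults reproduce the scaled-down
    cohort used throughout the test-bench: 5 clones on a 2-Mb genome at
    mean coverage 20 with 0.3 % base errors.
    """

    genome_length: int = 2_000_000
    chrom_count: int = 2
    gc_content: float = 0.42
    triplet_target: dict | None = None
    n_clones: int = 5
    germline_het_count: int = 1000
    n_snv: float = 200.0
    n_ins: float = 12.0
    n_del: float = 20.0
    spectrum_weights: np.ndarray | None = None
    insertion_model: dict = field(default_factory=lambda: {("NN", "T", "NN"): 1.0})
    deletion_model: dict = field(default_factory=lambda: {("N", "T", "N"): 1.0})
    dnv_fraction: float = 0.0
    coverage_mean: float = 20.0
    base_error_rate: float = 0.003
    homopolymer_indel_noise: float = 0.0
    include_starting_clone: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if self.chrom_count < 1 or self.chrom_count > self.genome_length:
            raise ValueError("bad chrom_count")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_clones < 2:
            raise ValueError("need at least two clones for uniqueness filtering")
        if self.spectrum_weights is not None:
            w = np.asarray(self.spectrum_weights, float)
            if w.shape != (96,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("spectrum_weights must be a 96-vector summing to 1")
            self.spectrum_weights = w
        if not (0 <= self.dnv_fraction <= 1):
            raise ValueError("dnv_fraction must be in [0, 1]")
        if not (0 <= self.base_error_rate <= 0.05):
            raise ValueError("base_error_rate must be in [0, 0.05]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")

    @property
    def sample_ids(self) -> list[str]:
        clones = [f"clone{i}" for i in range(1, self.n_clones + 1)]
        return (["start"] + clones) if self.include_starting_clone else clones

    def spectrum(self) -> np.ndarray:
        if self.spectrum_weights is not None:
            return self.spectrum_weights
        from .presets import preset_spectrum

        return preset_spectrum("mock").values


@dataclass
class TruthSet:
    """Implanted unique mutations per clone plus shared germline variants."""

    clones: dict[str, list[Mutation]]
    germline: list[Mutation]

    def all_unique(self) -> list[Mutation]:
        return [m for muts in self.clones.values() for m in muts]


# ---------------------------------------------------------------------------
# Reference generation

def generate_reference(config: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Generate random chromosome sequences.

    Either i.i.d. bases at the requested GC content, or — when
    ``triplet_target`` is given — an order-2 Markov chain whose stationary
    triplet composition approximates the (strand-folded) target table.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lengths = _chrom_lengths(config)
    if config.triplet_target is not None:
        return {
            name: _markov_sequence(config.triplet_target, L, rng)
            for name, L in lengths.items()
        }
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = {}
    for name, L in lengths.items():
        codes = rng.choice(4, size=L, p=p)
        out[name] = "".join(BASES[c] for c in codes)
    return out


def _chrom_lengths(config: SimConfig) -> dict[str, int]:
    base = config.genome_length // config.chrom_count
    rem = config.genome_length - base * config.chrom_count
    if base == 0:
        raise ValueError("genome_length too small for chrom_count")
    return {
        f"chr{i + 1}": base + (1 if i < rem else 0)
        for i in range(config.chrom_count)
    }


def _markov_sequence(triplet_target: dict, length: int, rng) -> str:
    """Order-2 chain with P(c | ab) proportional to unfolded triplet counts."""
    counts64 = np.zeros((4, 4, 4))
    for t, n in triplet_target.items():
        if n <= 0:
            raise ValueError(f"non-positive target count for triplet {t}")
        for tt in (t, revcomp(t)):
            counts64[_CODE[tt[0]], _CODE[tt[1]], _CODE[tt[2]]] += n / 2
    cond = counts64.reshape(16, 4)
    rowsum = cond.sum(axis=1, keepdims=True)
    if (rowsum == 0).any():
        raise ValueError("triplet target is not normalisable: some contexts have no continuation")
    cum = np.cumsum(cond / rowsum, axis=1)
    marg2 = counts64.sum(axis=2).ravel()
    start = rng.choice(16, p=marg2 / marg2.sum())
    seq = [start // 4, start % 4]
    u = rng.random(max(length - 2, 0))
    for i in range(length - 2):
        ctx = seq[-2] * 4 + seq[-1]
        seq.append(int(np.searchsorted(cum[ctx], u[i], side="right")))
    return "".join(BASES[c] for c in seq[:length])


# ---------------------------------------------------------------------------
# Mutation implantation

def _pattern_regex(parts: tuple[str, ...]) -> str:
    return "".join("." if ch == "N" else ch for ch in "".join(parts))


class _SiteIndex:
    """Cached genomic site lookup for triplet contexts and indel patterns."""

    def __init__(self, reference: dict[str, str]) -> None:
        self.reference = reference
        self.chroms = list(reference)
        self.lengths = np.array([len(reference[c]) for c in self.chroms], float)
        self._triplet_cache: dict[str, list] = {}
        self._pattern_cache: dict[str, list] = {}

    def triplet_sites(self, triplet: str) -> list[tuple[str, int]]:
        """All 1-based centre positions whose forward triplet equals ``triplet``."""
        if triplet not in self._triplet_cache:
            sites = []
            pat = re.compile(f"(?={re.escape(triplet)})")
            for chrom in self.chroms:
                for m in pat.finditer(self.reference[chrom]):
                    sites.append((chrom, m.start() + 2))
            self._triplet_cache[triplet] = sites
        return self._triplet_cache[triplet]

    def pattern_sites(self, pattern: str) -> list[tuple[str, int]]:
        """1-based start positions of regex-style pattern matches."""
        if pattern not in self._pattern_cache:
            sites = []
            pat = re.compile(f"(?={pattern})")
            for chrom in self.chroms:
                for m in pat.finditer(self.reference[chrom]):
                    sites.append((chrom, m.start() + 1))
            self._pattern_cache[pattern] = sites
        return self._pattern_cache[pattern]


def implant_mutations(
    reference: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Draw germline and per-clone unique mutations onto the reference.

    SNVs are drawn channel-by-channel from the spectrum and placed at a
    uniformly chosen site carrying the required triplet context on either
    strand; indels are placed per the context pattern models. Unique
    mutations of different clones never share (or neighbour) a position,
    and germline sites are disjoint from all implanted sites.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    index = _SiteIndex(reference)
    occupied: set[tuple[str, int]] = set()
    spectrum = config.spectrum()

    def reserve(chrom: str, lo: int, hi: int) -> bool:
        span = [(chrom, p) for p in range(lo, hi + 1)]
        if any(s in occupied for s in span):
            return False
        occupied.update(span)
        return True

    # germline heterozygous SNVs, shared by every sample
    germline: list[Mutation] = []
    probs = index.lengths / index.lengths.sum()
    attempts = 0
    while len(germline) < config.germline_het_count:
        attempts += 1
        if attempts > 50 * max(config.germline_het_count, 1):
            raise RuntimeError("could not place germline variants; genome too small")
        chrom = index.chroms[rng.choice(len(index.chroms), p=probs)]
        L = len(reference[chrom])
        if L < 3:
            continue
        pos = int(rng.integers(2, L))  # keep a flank on both sides
        ref = reference[chrom][pos - 1]
        if ref not in BASES or not reserve(chrom, pos, pos):
            continue
        alt = BASES[(_CODE[ref] + int(rng.integers(1, 4))) % 4]
        germline.append(Mutation("germline", chrom, pos, ref, alt))

    clones: dict[str, list[Mutation]] = {}
    for sid in config.sample_ids:
        muts: list[Mutation] = []
        if sid != "start":
            muts += _implant_snvs(sid, index, spectrum, config, rng, reserve)
            muts += _implant_indels(sid, index, config, rng, reserve)
        clones[sid] = sorted(muts, key=Mutation.sort_key)
    return TruthSet(clones=clones, germline=sorted(germline, key=Mutation.sort_key))


def _implant_snvs(sid, index, spectrum, config, rng, reserve) -> list[Mutation]:
    n_draws = int(rng.poisson(config.n_snv / (1 + config.dnv_fraction)))
    muts: list[Mutation] = []
    channels = rng.choice(96, size=n_draws, p=spectrum)
    for ch in channels:
        as_dnv = bool(rng.random() < config.dnv_fraction)
        triplet = channel_context(int(ch))
        alt_pyr = channel_class(int(ch))[2]
        fwd = index.triplet_sites(triplet)
        rc = revcomp(triplet)
        rev = index.triplet_sites(rc) if rc != triplet else []
        sites = fwd + rev
        if not sites:
            raise RuntimeError(f"no eligible genomic site for channel {triplet} "
                               f"({channel_class(int(ch))})")
        placed = False
        for _ in range(200):
            i = int(rng.integers(len(sites)))
            chrom, pos = sites[i]
            span = (pos - 1, pos + (2 if as_dnv else 1))
            if not reserve(chrom, *span):
                continue
            on_forward = i < len(fwd)
            ref = index.reference[chrom][pos - 1]
            alt = alt_pyr if on_forward else complement(alt_pyr)
            muts.append(Mutation(sid, chrom, pos, ref, alt))
            if as_dnv and pos < len(index.reference[chrom]):
                ref2 = index.reference[chrom][pos]
                if ref2 in BASES:
                    alt2 = BASES[(_CODE[ref2] + int(rng.integers(1, 4))) % 4]
                    muts.append(Mutation(sid, chrom, pos + 1, ref2, alt2))
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place SNV for context {triplet}; genome too crowded")
    return muts


def _sample_pattern(model: dict, rng) -> tuple[str, ...]:
    patterns = sorted(model)
    weights = np.array([model[p] for p in patterns], float)
    return patterns[rng.choice(len(patterns), p=weights / weights.sum())]


def _implant_indels(sid, index, config, rng, reserve) -> list[Mutation]:
    muts: list[Mutation] = []
    for kind, mean, model in (
        ("INS", config.n_ins, config.insertion_model),
        ("DEL", config.n_del, config.deletion_model),
    ):
        n = int(rng.poisson(mean))
        for _ in range(n):
            placed = False
            for _ in range(200):
                pre, core, fol = _sample_pattern(model, rng)
                minus = bool(rng.random() < 0.5)
                if minus:
                    pattern = _minus_pattern(pre, core, fol, kind)
                elif kind == "INS":
                    pattern = _pattern_regex((pre, fol))
                else:
                    pattern = _pattern_regex((pre, core, fol))
                sites = index.pattern_sites(pattern)
                if not sites:
                    continue
                chrom, start = sites[int(rng.integers(len(sites)))]
                mut = _indel_at(sid, chrom, start, pre, core, fol, kind, minus, index)
                if mut is None:
                    continue
                lo = mut.pos - 1
                hi = mut.pos + (len(mut.ref_allele) if kind == "DEL" else 1)
                if not reserve(chrom, lo, hi):
                    continue
                muts.append(mut)
                placed = True
                break
            if not placed:
                raise RuntimeError(f"could not place {kind} for model {model}")
    return muts


def _minus_pattern(pre: str, core: str, fol: str, kind: str) -> str:
    if kind == "INS":
        return _pattern_regex((revcomp(fol), revcomp(pre)))
    return _pattern_regex((revcomp(fol), revcomp(core), revcomp(pre)))


def _indel_at(sid, chrom, start, pre, core, fol, kind, minus, index) -> Mutation | None:
    """Build the Mutation for a pattern match at 1-based ``start``."""
    if kind == "INS":
        # forward: match is pre+fol, insertion goes between them
        if not minus:
            pos = start + len(pre) - 1
            seq = core
        else:
            # match is revcomp(fol)+revcomp(pre); minus-strand insertion sits
            # between them, i.e. after forward base at the end of revcomp(fol)
            pos = start + len(fol) - 1
            seq = revcomp(core)
        if pos < 1:
            return None
        return Mutation(sid, chrom, pos, "", seq)
    # deletion: forward match is pre+core+fol
    if not minus:
        pos = start + len(pre)
        seq = core
    else:
        pos = start + len(fol)
        seq = revcomp(core)
    if pos < 2:  # keep an anchor base for VCF/pileup representation
        return None
    if index.reference[chrom][pos - 1: pos - 1 + len(seq)] != seq:
        return None
    return Mutation(sid, chrom, pos, seq, "")


# ---------------------------------------------------------------------------
# Pileup simulation

class PileupMatrix:
    """Array-backed multi-sample pileup over a genome.

    Per chromosome: ``cov`` (S x L) spanning-read coverage, ``counts``
    (4 x S x L) base calls, ``ref_code`` (L,) with -1 for non-ACGT, and
    sparse ``ins`` / ``dels`` dicts keyed by 1-based anchor position.
    """

    def __init__(self, samples: list[str], reference: dict[str, str]) -> None:
        self.samples = list(samples)
        self.reference = reference
        self.chroms: dict[str, dict] = {}

    def iter_columns(self) -> Iterator[PileupColumn]:
        """Stream PileupColumn records (intended for small genomes/tests)."""
        for chrom, data in self.chroms.items():
            cov, counts = data["cov"], data["counts"]
            ref = self.reference[chrom]
            for p in range(cov.shape[1]):
                pos = p + 1
                samples = {}
                for s, sid in enumerate(self.samples):
                    samples[sid] = SampleCounts(
                        coverage=int(cov[s, p]),
                        n_A=int(counts[0, s, p]), n_C=int(counts[1, s, p]),
                        n_G=int(counts[2, s, p]), n_T=int(counts[3, s, p]),
                        ins=dict(data["ins"].get(pos, {}).get(sid, {})),
                        dels=dict(data["dels"].get(pos, {}).get(sid, {})),
                    )
                yield PileupColumn(chrom=chrom, pos=pos, ref_base=ref[p], samples=samples)

    def write_tsv(self, path) -> None:
        from .io import write_pileup_tsv

        write_pileup_tsv(self.iter_columns(), self.samples, path)


def simulate_pileup(
    reference: dict[str, str],
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> PileupMatrix:
    """Simulate per-position, per-sample read counts for the cohort.

    Coverage is Poisson(``coverage_mean``); heterozygous variant sites get
    Binomial(coverage, 0.5) alternate reads (germline sites in every
    sample, unique sites in the carrying clone only); elsewhere non-reference
    reads arise at ``base_error_rate`` spread uniformly over the three other
    bases.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    samples = config.sample_ids
    pm = PileupMatrix(samples, reference)
    S = len(samples)
    for chrom, seq in reference.items():
        L = len(seq)
        ref_code = np.array([_CODE.get(b, -1) for b in seq], dtype=np.int64)
        cov = rng.poisson(config.coverage_mean, size=(S, L)).astype(np.int32)
        counts = np.zeros((4, S, L), dtype=np.int32)
        err = rng.binomial(cov, config.base_error_rate)
        e1 = rng.binomial(err, 1.0 / 3.0)
        e2 = rng.binomial(err - e1, 0.5)
        e3 = err - e1 - e2
        esplit = (e1, e2, e3)
        for b in range(4):
            mask = ref_code == b
            if not mask.any():
                continue
            counts[b][:, mask] = (cov - err)[:, mask]
            others = [x for x in range(4) if x != b]
            for k, x in enumerate(others):
                counts[x][:, mask] += esplit[k][:, mask]
        # non-ACGT reference positions: all reads uninformative
        bad = ref_code < 0
        if bad.any():
            for b in range(4):
                counts[b][:, bad] = 0
        pm.chroms[chrom] = {
            "cov": cov, "counts": counts, "ref_code": ref_code,
            "ins": {}, "dels": {},
        }

    def set_het(chrom: str, pos: int, ref: str, alt: str, sample_idx: list[int]) -> None:
        data = pm.chroms[chrom]
        p = pos - 1
        for s in sample_idx:
            c = int(data["cov"][s, p])
            a = int(rng.binomial(c, 0.5))
            data["counts"][:, s, p] = 0
            data["counts"][_CODE[ref], s, p] = c - a
            data["counts"][_CODE[alt], s, p] = a

    all_idx = list(range(S))
    for mut in truth.germline:
        set_het(mut.chrom, mut.pos, mut.ref_allele, mut.alt_allele, all_idx)
    for sid, muts in truth.clones.items():
        s = samples.index(sid)
        for mut in muts:
            data = pm.chroms[mut.chrom]
            if mut.mut_class == "SNV":
                set_het(mut.chrom, mut.pos, mut.ref_allele, mut.alt_allele, [s])
            elif mut.mut_class == "INS":
                p = mut.pos - 1
                n = int(rng.binomial(int(data["cov"][s, p]), 0.5))
                if n:
                    data["ins"].setdefault(mut.pos, {}).setdefault(sid, {})
                    data["ins"][mut.pos][sid][mut.alt_allele] = n
            elif mut.mut_class == "DEL":
                anchor = mut.pos - 1
                p = anchor - 1
                n = int(rng.binomial(int(data["cov"][s, p]), 0.5))
                if n:
                    data["dels"].setdefault(anchor, {}).setdefault(sid, {})
                    data["dels"][anchor][sid][len(mut.ref_allele)] = n
                for q in range(mut.pos, mut.pos + len(mut.ref_allele)):
                    c = int(data["cov"][s, q - 1])
                    d = int(rng.binomial(c, 0.5))
                    ref_b = pm.reference[mut.chrom][q - 1]
                    if ref_b in BASES:
                        data["counts"][:, s, q - 1] = 0
                        data["counts"][_CODE[ref_b], s, q - 1] = c - d

    if config.homopolymer_indel_noise > 0:
        _add_homopolymer_noise(pm, config, rng)
    return pm


def _add_homopolymer_noise(pm: PileupMatrix, config: SimConfig, rng) -> None:
    """Low-level 1-bp deletion evidence at homopolymer runs (stress testing)."""
    runs = []
    for chrom, seq in pm.reference.items():
        for m in re.finditer(r"(A{4,}|C{4,}|G{4,}|T{4,})", seq):
            if m.start() >= 1:
                runs.append((chrom, m.start()))  # 1-based anchor before the run
    if not runs:
        return
    n_events = int(rng.poisson(config.homopolymer_indel_noise * len(runs) * len(pm.samples)))
    for _ in range(n_events):
        chrom, anchor = runs[int(rng.integers(len(runs)))]
        sid = pm.samples[int(rng.integers(len(pm.samples)))]
        data = pm.chroms[chrom]
        data["dels"].setdefault(anchor, {}).setdefault(sid, {})
        data["dels"][anchor][sid][1] = data["dels"][anchor][sid].get(1, 0) + int(rng.integers(1, 3))


def simulate_cohort(config: SimConfig) -> tuple[dict[str, str], TruthSet, PileupMatrix]:
    """Generate reference, truth set and pileup in one deterministic run."""
    rng = np.random.default_rng(config.seed)
    reference = generate_reference(config, rng)
    truth = implant_mutations(reference, config, rng)
    pileup = simulate_pileup(reference, truth, config, rng)
    return reference, truth, pileup
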