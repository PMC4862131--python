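"""Shared domain types: mutations, pileup columns, parameters, spectra.

Coordinates are 1-based inclusive throughout the package; half-open 0-based
inputs (BED) are converted at the I/O boundary. An insertion is anchored at
the base immediately 5' of the inserted sequence (empty reference allele);
a deletion is anchored at its first deleted base (empty alternate allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import BASES, CHANNELS, TRIPLETS32

_DNA = set(BASES)


@dataclass(frozen=True)
class Mutation:
    """A single called or implanted variant in one sample.

    ``pos`` is 1-based: for insertions the base immediately 5' of the
    insertion, for deletions the first deleted base.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        ref, alt = self.ref_allele, self.alt_allele
        if ref == alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if not ref and not alt:
            raise ValueError("both alleles empty")
        for allele in (ref, alt):
            if not set(allele) <= _DNA:
                raise ValueError(f"non-ACGT allele {allele!r} at {self.chrom}:{self.pos}")
        if ref and alt and len(ref) != len(alt):
            raise ValueError(
                f"length-changing substitution at {self.chrom}:{self.pos}; "
                "use empty ref (INS) or empty alt (DEL)"
            )
        if ref and alt and len(ref) > 2:
            raise ValueError("substitutions longer than 2 bases are not modelled")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def mut_class(self) -> str:
        """One of SNV / DNV / INS / DEL."""
        if not self.ref_allele:
            return "INS"
        if not self.alt_allele:
            return "DEL"
        return "SNV" if len(self.ref_allele) == 1 else "DNV"

    @property
    def is_indel(self) -> bool:
        return not self.ref_allele or not self.alt_allele

    def sort_key(self) -> tuple:
        return (_natural_key(self.chrom), self.pos, self.ref_allele, self.alt_allele)


def _natural_key(name: str) -> tuple:
    """Sort chr2 before chr10."""
    out: list = []
    num = ""
    for ch in name:
        if ch.isdigit():
            num += ch
        else:
            if num:
                out.append((1, int(num)))
                num = ""
            out.append((0, ch))
    if num:
        out.append((1, int(num)))
    return tuple(out)


@dataclass
class SampleCounts:
    """Quality-filtered read support for one sample at one position."""

    coverage: int = 0
    n_A: int = 0
    n_C: int = 0
    n_G: int = 0
    n_T: int = 0
    #: reads supporting an insertion immediately after this position, by sequence
    ins: dict[str, int] = field(default_factory=dict)
    #: reads supporting a deletion starting at pos+1, by deleted length
    dels: dict[int, int] = field(default_factory=dict)

    def base_count(self, base: str) -> int:
        return getattr(self, f"n_{base}")

    @property
    def base_total(self) -> int:
        return self.n_A + self.n_C + self.n_G + self.n_T

    def validate(self) -> None:
        counts = [self.coverage, self.n_A, self.n_C, self.n_G, self.n_T,
                  *self.ins.values(), *self.dels.values()]
        if any(c < 0 for c in counts):
            raise ValueError("negative read count")
        if self.base_total > self.coverage:
            raise ValueError("base counts exceed coverage")


@dataclass
class PileupColumn:
    """Per-position, per-sample filtered allele counts for the whole cohort."""

    chrom: str
    pos: int
    ref_base: str
    samples: dict[str, SampleCounts]

    def validate(self) -> None:
        for counts in self.samples.values():
            counts.validate()


@dataclass(frozen=True)
class CallerParams:
    """The published unique-mutation filter thresholds.

    Defaults are the optimised values used for the clone cohorts:
    mutated-sample allele fraction >= 0.33, mutated-sample coverage >= 10,
    reference allele fraction >= 0.9 in every other sample, and a Phred 30
    base-quality cut applied when the pileup is built.
    """

    min_mut_af: float = 0.33
    min_cov_mutated: int = 10
    min_other_ref_af: float = 0.9
    min_base_quality: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.min_mut_af <= 1):
            raise ValueError("min_mut_af must be in (0, 1]")
        if not (0 < self.min_other_ref_af <= 1):
            raise ValueError("min_other_ref_af must be in (0, 1]")
        if self.min_cov_mutated < 1:
            raise ValueError("min_cov_mutated must be >= 1")


class Spectrum96:
    """Counts or rates over the 96 pyrimidine-centred substitution channels."""

    __slots__ = ("values",)

    def __init__(self, values) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.shape != (96,):
            raise ValueError(f"expected 96 channels, got shape {arr.shape}")
        if (arr < 0).any():
            raise ValueError("spectrum values must be non-negative")
        self.values = arr

    @classmethod
    def zeros(cls) -> "Spectrum96":
        return cls(np.zeros(96))

    def total(self) -> float:
        return float(self.values.sum())

    def normalized(self) -> "Spectrum96":
        """Return the spectrum rescaled to sum to 1."""
        s = self.total()
        if s == 0:
            raise ValueError("cannot normalise an all-zero spectrum")
        return Spectrum96(self.values / s)

    def six_class(self) -> np.ndarray:
        """Channel-wise marginal over the six substitution classes."""
        return self.values.reshape(6, 16).sum(axis=1)

    def to_dict(self) -> dict[str, float]:
        return dict(zip(CHANNELS, self.values))

    def __getitem__(self, label: str) -> float:
        from .channels import CHANNEL_INDEX

        return float(self.values[CHANNEL_INDEX[label]])

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, Spectrum96) and np.array_equal(self.values, other.values)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Spectrum96(total={self.total():g})"


class TripletFrequencyTable(dict):
    """Occurrence counts (or frequencies) of the 32 strand-folded triplets.

    Zero entries are permitted (a context may be absent from a small
    genome); operations that divide by an occurrence raise at the point of
    use when the relevant entry is zero.
    """

    def __init__(self, data) -> None:
        super().__init__(data)
        missing = set(TRIPLETS32) - set(self)
        extra = set(self) - set(TRIPLETS32)
        if missing or extra:
            raise ValueError(f"bad triplet keys; missing={sorted(missing)} extra={sorted(extra)}")
        if any(v < 0 for v in self.values()):
            raise ValueError("triplet occurrences must be non-negative")

    def frequencies(self) -> dict[str, float]:
        total = sum(self.values())
        if total == 0:
            raise ValueError("all triplet occurrences are zero")
        return {k: v / total for k, v in self.items()}

    @classmethod
    def flat(cls) -> "TripletFrequencyTable":
        return cls({t: 1.0 for t in TRIPLETS32})


class SignatureMatrix:
    """K reference signatures over the 96 channels (rows sum to 1)."""

    def __init__(self, names, matrix) -> None:
        mat = np.asarray(matrix, dtype=float)
        names = list(names)
        if mat.ndim != 2 or mat.shape != (len(names), 96):
            raise ValueError(f"expected (K, 96) matrix matching {len(names)} names")
        if (mat < 0).any():
            raise ValueError("signature entries must be non-negative")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each signature row must sum to 1")
        self.names = names
        self.matrix = mat

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class GeneInterval:
    """One annotated gene: 1-based inclusive interval with strand."""

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad interval {self.start}-{self.end} for {self.gene_id}")


class GenomeAnnotation:
    """Per-chromosome gene intervals plus chromosome lengths."""

    def __init__(self, genes, chrom_lengths: dict[str, int]) -> None:
        self.genes: list[GeneInterval] = list(genes)
        self.chrom_lengths = dict(chrom_lengths)
        for g in self.genes:
            length = self.chrom_lengths.get(g.chrom)
            if length is None:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > length:
                raise ValueError(f"gene {g.gene_id} extends past end of {g.chrom}")
        self._trees: dict | None = None

    def _build_trees(self):
        from intervaltree import IntervalTree

        trees: dict = {}
        for g in self.genes:
            trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
        self._trees = trees
        return trees

    def genes_at(self, chrom: str, pos: int) -> list[GeneInterval]:
        trees = self._trees if self._trees is not None else self._build_trees()
        tree = trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda g: (g.start, g.gene_id))

    def merged_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Union of gene intervals on one chromosome (1-based inclusive)."""
        spans = sorted((g.start, g.end) for g in self.genes if g.chrom == chrom)
        merged: list[tuple[int, int]] = []
        for start, end in spans:
            if merged and start <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        return merged

    def genic_fraction(self) -> float:
        """Fraction of the genome covered by the merged gene intervals."""
        total = sum(self.chrom_lengths.values())
        if total == 0:
            raise ValueError("empty genome")
        genic = sum(
            end - start + 1
            for chrom in self.chrom_lengths
            for start, end in self.merged_intervals(chrom)
        )
        return genic / total


@dataclass(frozen=True)
class ReversionParams:
    """Inputs of the uniform-placement reversion-probability model.

    A reverting frameshift must fall within ``indel_window_bp`` of the
    original lesion; a reverting SNV must hit any of the ``stop_codon_bp``
    bases of a premature stop codon. Burdens are treatment-induced mutation
    loads per Gb per surviving cell.
    """

    genome_size_bp: float = 3.1e9
    indel_window_bp: float = 20.0
    stop_codon_bp: float = 3.0
    snv_per_gb: float = 800.0
    indel_per_gb: float = 130.0

    def __post_init__(self) -> None:
        if not (0 < self.indel_window_bp < self.genome_size_bp):
            raise ValueError("indel window must be in (0, G)")
        if not (0 < self.stop_codon_bp < self.genome_size_bp):
            raise ValueError("stop-codon window must be in (0, G)")
        if self.snv_per_gb < 0 or self.indel_per_gb < 0:
            raise ValueError("burdens must be non-negative")
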