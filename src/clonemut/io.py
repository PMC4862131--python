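"""Readers and writers for the external formats.

Formats handled here: FASTA (reference genomes), a documented pileup TSV
dialect, VCF 4.2 (calls out / truth in), GFF3 and BED gene annotation,
gene-expression TSV (gene_id -> FPKM), COSMIC-layout 96-row signature
tables, and 32-row triplet-occurrence tables.

Pileup TSV dialect: one row per genomic position. Fixed columns
``chrom  pos  ref`` followed by a seven-column block per sample:
``{sid}.cov {sid}.nA {sid}.nC {sid}.nG {sid}.nT {sid}.ins {sid}.del``
where the last two are JSON objects mapping inserted sequence -> reads and
deleted length -> reads (``{}`` when empty).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .channels import BASES, CHANNELS, TRIPLETS32
from .types import (
    GeneInterval,
    GenomeAnnotation,
    Mutation,
    PileupColumn,
    SampleCounts,
    SignatureMatrix,
    Spectrum96,
    TripletFrequencyTable,
    _natural_key,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line/position."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a chrom -> upper-case sequence mapping.

    Ambiguity codes are preserved but counted and logged as a warning.
    """
    path = Path(path)
    text_head = path.read_text()[:1].strip() if path.stat().st_size else ""
    if text_head and text_head != ">":
        raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        warnings.warn(f"{path}: empty FASTA, no sequences read", stacklevel=2)
    n_ambig = sum(len(s) - sum(s.count(b) for b in BASES) for s in seqs.values())
    if n_ambig:
        log.warning("%s: %d non-ACGT (ambiguity) bases present", path, n_ambig)
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Pileup TSV

def _pileup_header(sample_ids: list[str]) -> list[str]:
    cols = ["#chrom", "pos", "ref"]
    for sid in sample_ids:
        cols += [f"{sid}.cov", f"{sid}.nA", f"{sid}.nC", f"{sid}.nG", f"{sid}.nT",
                 f"{sid}.ins", f"{sid}.del"]
    return cols


def write_pileup_tsv(columns: Iterable[PileupColumn], sample_ids: list[str], path) -> None:
    """Write pileup columns in the documented TSV dialect."""
    with open(path, "w") as fh:
        fh.write("\t".join(_pileup_header(sample_ids)) + "\n")
        for col in columns:
            fields = [col.chrom, str(col.pos), col.ref_base]
            for sid in sample_ids:
                sc = col.samples.get(sid, SampleCounts())
                fields += [
                    str(sc.coverage), str(sc.n_A), str(sc.n_C), str(sc.n_G), str(sc.n_T),
                    json.dumps(sc.ins, sort_keys=True, separators=(",", ":")),
                    json.dumps(sc.dels, sort_keys=True, separators=(",", ":")),
                ]
            fh.write("\t".join(fields) + "\n")


def read_pileup_tsv(path, sample_ids: list[str] | None = None) -> Iterator[PileupColumn]:
    """Stream PileupColumn records from the TSV dialect.

    If ``sample_ids`` is given it must match the header's declared samples.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "#chrom":
            raise ParseError(f"{path}: line 1: missing '#chrom' pileup header")
        declared = [c[:-4] for c in header[3:] if c.endswith(".cov")]
        expected = _pileup_header(declared)
        if header != expected:
            raise ParseError(f"{path}: line 1: malformed per-sample column block")
        if sample_ids is not None and list(sample_ids) != declared:
            raise ParseError(
                f"{path}: declared samples {declared} do not match expected {list(sample_ids)}"
            )
        n_cols = len(expected)
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_cols} columns, got {len(fields)}"
                )
            chrom, pos, ref = fields[0], int(fields[1]), fields[2]
            samples: dict[str, SampleCounts] = {}
            for i, sid in enumerate(declared):
                block = fields[3 + 7 * i: 10 + 7 * i]
                sc = SampleCounts(
                    coverage=int(block[0]), n_A=int(block[1]), n_C=int(block[2]),
                    n_G=int(block[3]), n_T=int(block[4]),
                    ins=dict(json.loads(block[5])),
                    dels={int(k): v for k, v in json.loads(block[6]).items()},
                )
                try:
                    sc.validate()
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno} ({chrom}:{pos}): {exc}") from exc
                samples[sid] = sc
            yield PileupColumn(chrom=chrom, pos=pos, ref_base=ref, samples=samples)


def read_mpileup(path, sample_ids: list[str], min_base_quality: int = 30) -> Iterator[PileupColumn]:
    """Convert samtools mpileup text output into PileupColumn records.

    Base calls below ``min_base_quality`` (Phred, offset 33) are dropped from
    the base counts; indel observations attached to a read are counted
    regardless of the neighbouring base quality, matching how the pileup was
    quality-filtered upstream of the published caller. Expects one
    ``depth / bases / quals`` column triple per sample.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 + 3 * len(sample_ids):
                raise ParseError(
                    f"{path}: line {lineno}: expected {3 + 3 * len(sample_ids)} columns "
                    f"for {len(sample_ids)} samples, got {len(fields)}"
                )
            chrom, pos, ref = fields[0], int(fields[1]), fields[2].upper()
            samples: dict[str, SampleCounts] = {}
            for i, sid in enumerate(sample_ids):
                _, bases, quals = fields[3 + 3 * i: 6 + 3 * i]
                samples[sid] = _parse_mpileup_bases(bases, quals, ref, min_base_quality)
            yield PileupColumn(chrom=chrom, pos=pos, ref_base=ref, samples=samples)


def _parse_mpileup_bases(bases: str, quals: str, ref: str, min_q: int) -> SampleCounts:
    sc = SampleCounts()
    if bases == "*":
        return sc
    i = 0
    qi = 0
    while i < len(bases):
        ch = bases[i]
        if ch == "^":
            i += 2  # mapping-quality byte follows
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            j = i + 1
            while j < len(bases) and bases[j].isdigit():
                j += 1
            length = int(bases[i + 1: j])
            seq = bases[j: j + length].upper()
            if ch == "+":
                sc.ins[seq] = sc.ins.get(seq, 0) + 1
            else:
                sc.dels[length] = sc.dels.get(length, 0) + 1
            i = j + length
            continue
        # a quality-bearing base column
        q = ord(quals[qi]) - 33 if qi < len(quals) else 0
        qi += 1
        sc.coverage += 1
        if q >= min_q:
            base = ref if ch in ".," else ch.upper()
            if base in BASES:
                setattr(sc, f"n_{base}", sc.base_count(base) + 1)
        i += 1
    return sc


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample carrying the unique mutation">
##INFO=<ID=CLASS,Number=1,Type=String,Description="Mutation class (SNV/DNV/INS/DEL)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(mutations: list[Mutation], reference: dict[str, str], path) -> None:
    """Write mutations as VCF 4.2 with anchored indel representation.

    Insertions/deletions are emitted with the preceding reference base as
    anchor; the carrying sample goes into the SAMPLE INFO field. Input must
    be sorted by chromosome and position.
    """
    keys = [m.sort_key() for m in mutations]
    if keys != sorted(keys):
        raise ValueError("mutations must be sorted by chromosome and position")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for mut in mutations:
            seq = reference.get(mut.chrom)
            if seq is None:
                raise ValueError(f"chromosome {mut.chrom} absent from reference")
            if mut.mut_class in ("SNV", "DNV"):
                found = seq[mut.pos - 1: mut.pos - 1 + len(mut.ref_allele)]
                if found != mut.ref_allele:
                    raise ValueError(
                        f"{mut.chrom}:{mut.pos}: reference is {found!r}, "
                        f"mutation claims {mut.ref_allele!r}"
                    )
                pos, ref, alt = mut.pos, mut.ref_allele, mut.alt_allele
            elif mut.mut_class == "INS":
                anchor = seq[mut.pos - 1]
                pos, ref, alt = mut.pos, anchor, anchor + mut.alt_allele
            else:  # DEL
                if mut.pos < 2:
                    raise ValueError(f"{mut.chrom}:{mut.pos}: deletion at contig start")
                found = seq[mut.pos - 1: mut.pos - 1 + len(mut.ref_allele)]
                if found != mut.ref_allele:
                    raise ValueError(
                        f"{mut.chrom}:{mut.pos}: reference is {found!r}, "
                        f"deletion claims {mut.ref_allele!r}"
                    )
                anchor = seq[mut.pos - 2]
                pos, ref, alt = mut.pos - 1, anchor + mut.ref_allele, anchor
            info = f"SAMPLE={mut.sample_id};CLASS={mut.mut_class}"
            fh.write(f"{mut.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


def read_vcf(path) -> list[Mutation]:
    """Read a VCF written by :func:`write_vcf` back into Mutation records."""
    muts: list[Mutation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path}: line {lineno}: fewer than 8 VCF columns")
            chrom, pos, _, ref, alt, _, _, info = fields[:8]
            pos = int(pos)
            tags = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            sample = tags.get("SAMPLE", "unknown")
            if len(ref) == len(alt):
                mut = Mutation(sample, chrom, pos, ref, alt)
            elif len(ref) < len(alt):
                if not alt.startswith(ref):
                    raise ParseError(f"{path}: line {lineno}: non-anchored insertion")
                mut = Mutation(sample, chrom, pos + len(ref) - 1, "", alt[len(ref):])
            else:
                if not ref.startswith(alt):
                    raise ParseError(f"{path}: line {lineno}: non-anchored deletion")
                mut = Mutation(sample, chrom, pos + len(alt), ref[len(alt):], "")
            muts.append(mut)
    return muts


# ---------------------------------------------------------------------------
# Annotation (GFF3 / BED)

def read_gff3(path, chrom_lengths: dict[str, int] | None = None,
              feature_types: tuple[str, ...] = ("gene",)) -> GenomeAnnotation:
    """Read gene intervals from a GFF3 file (1-based inclusive coordinates).

    Chromosome lengths are taken from ``##sequence-region`` pragmas unless
    supplied explicitly.
    """
    pragma_lengths: dict[str, int] = {}
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    pragma_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype not in feature_types:
                continue
            gene_id = None
            for kv in attrs.split(";"):
                key, _, val = kv.partition("=")
                if key.strip() in ("ID", "gene_id"):
                    gene_id = val.strip()
                    break
            if gene_id is None:
                gene_id = f"{chrom}:{start}-{end}"
            genes.append(GeneInterval(chrom, int(start), int(end), gene_id, strand))
    lengths = chrom_lengths if chrom_lengths is not None else pragma_lengths
    if not lengths:
        raise ParseError(f"{path}: no chromosome lengths (need ##sequence-region pragmas)")
    return GenomeAnnotation(genes, lengths)


def read_bed(path, chrom_lengths: dict[str, int]) -> GenomeAnnotation:
    """Read gene intervals from BED (0-based half-open, converted here)."""
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 else "+"
            genes.append(GeneInterval(chrom, start + 1, end, name, strand))
    return GenomeAnnotation(genes, chrom_lengths)


# ---------------------------------------------------------------------------
# Tables

def read_fpkm_tsv(path) -> pd.Series:
    """Read a two-column gene_id / FPKM table into a pandas Series."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_id", "fpkm"], dtype={"gene_id": str})
    if df["fpkm"].isna().any() or (df["fpkm"] < 0).any():
        raise ParseError(f"{path}: FPKM values must be non-negative numbers")
    return df.set_index("gene_id")["fpkm"]


def read_signature_matrix(path) -> SignatureMatrix:
    """Read a COSMIC-layout signature TSV: 96 rows, first column the channel
    label (``A[C>A]A`` style), one column per signature."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS) - set(df.index)
    if missing:
        raise ParseError(f"{path}: missing channels, e.g. {sorted(missing)[:3]}")
    df = df.loc[list(CHANNELS)]
    return SignatureMatrix(list(df.columns), df.to_numpy().T)


def write_signature_matrix(sig: SignatureMatrix, path) -> None:
    df = pd.DataFrame(sig.matrix.T, index=list(CHANNELS), columns=sig.names)
    df.to_csv(path, sep="\t", index_label="channel")


def read_triplet_table(path) -> TripletFrequencyTable:
    """Read a 32-row triplet / occurrence TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["triplet", "count"], dtype={"triplet": str})
    return TripletFrequencyTable(dict(zip(df["triplet"], df["count"].astype(float))))


def write_triplet_table(table: TripletFrequencyTable, path) -> None:
    with open(path, "w") as fh:
        for t in TRIPLETS32:
            fh.write(f"{t}\t{table[t]:g}\n")


def write_spectrum_tsv(spectrum: Spectrum96, path, value_name: str = "value") -> None:
    with open(path, "w") as fh:
        fh.write(f"channel\t{value_name}\n")
        for label, v in zip(CHANNELS, spectrum.values):
            fh.write(f"{label}\t{v:g}\n")


def read_spectrum_tsv(path) -> Spectrum96:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS) - set(df.index)
    if missing:
        raise ParseError(f"{path}: missing channels, e.g. {sorted(missing)[:3]}")
    return Spectrum96(df.loc[list(CHANNELS)].iloc[:, 0].to_numpy())


def sort_mutations(mutations: Iterable[Mutation]) -> list[Mutation]:
    """Sort by chromosome (natural order), position, then alleles."""
    return sorted(mutations, key=Mutation.sort_key)
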