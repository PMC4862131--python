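"""Channel and triplet conventions for pyrimidine-centred mutation spectra.

The 96 substitution channels cover the six pyrimidine-reference classes
(C>A, C>G, C>T, T>A, T>C, T>G), each in the 16 possible single-base 5'/3'
flanking contexts. Substitutions observed with a purine reference base are
represented by their reverse complement, so complementary events on the two
strands share one channel. Channel order is class-major, then 5' base, then
3' base, both alphabetical -- the layout used by the public COSMIC signature
tables (``A[C>A]A`` ... ``T[T>G]T``).
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = "CT"
PURINES = "AG"

CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{cls}]{three}" for cls in CLASSES for five in BASES for three in BASES
)
CHANNEL_INDEX: dict[str, int] = {label: i for i, label in enumerate(CHANNELS)}

#: The 32 strand-folded triplet keys (central C then central T, flanks alphabetical).
TRIPLETS32: tuple[str, ...] = tuple(
    f"{five}{mid}{three}" for mid in PYRIMIDINES for five in BASES for three in BASES
)
TRIPLET_INDEX: dict[str, int] = {t: i for i, t in enumerate(TRIPLETS32)}

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(seq: str) -> str:
    """Base-wise complement (keeps orientation)."""
    return seq.translate(_COMP)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    return seq.translate(_COMP)[::-1]


def fold_triplet(triplet: str) -> str:
    """Fold a triplet onto its pyrimidine-centred representative."""
    if len(triplet) != 3:
        raise ValueError(f"not a triplet: {triplet!r}")
    return triplet if triplet[1] in PYRIMIDINES else revcomp(triplet)


def channel_of(five: str, ref: str, alt: str, three: str) -> int | None:
    """Return the channel index of a substitution in context, or None.

    Purine-reference substitutions are folded to the reverse complement
    first. Returns None (unassignable) when any involved base is not ACGT.
    """
    for b in (five, ref, alt, three):
        if b not in BASES:
            return None
    if ref in PURINES:
        five, ref, alt, three = (
            complement(three), complement(ref), complement(alt), complement(five),
        )
    return CHANNEL_INDEX[f"{five}[{ref}>{alt}]{three}"]


def channel_class(index: int) -> str:
    """The six-class label (e.g. ``C>A``) of a channel index."""
    return CLASSES[index // 16]


def channel_context(index: int) -> str:
    """The pyrimidine-centred context triplet of a channel index."""
    cls = CLASSES[index // 16]
    five = BASES[(index % 16) // 4]
    three = BASES[index % 4]
    return f"{five}{cls[0]}{three}"
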