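"""Canonical 96-channel single-base-substitution (SBS) channel ordering.

Channels are pyrimidine-centered: the six substitution classes are
C>A, C>G, C>T, T>A, T>C, T>G; within each class the 16 trinucleotide
contexts are ordered A, C, G, T by 5' flank, then 3' flank.  This is the
standard COSMIC ordering, so catalogs published in that layout load
without reindexing.
"""

from __future__ import annotations

BASES = "ACGT"
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def channel_labels() -> list[str]:
    """Return the 96 channel labels, e.g. ``A[C>A]A``, in canonical order."""
    labels = []
    for sub in SUBSTITUTION_CLASSES:
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return labels


CHANNELS: tuple[str, ...] = tuple(channel_labels())
_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def channel_index(ref: str, alt: str, trinucleotide: str) -> int:
    """Map an SNV to its pyrimidine-centered channel index.

    Purine-reference SNVs are reverse-complemented onto the pyrimidine
    strand, so (G, T, "TGT") and (C, A, "ACA") land on the same channel.

    Raises
    ------
    ValueError
        If bases are invalid, ref == alt, or the middle base of the
        trinucleotide does not match ``ref``.
    """
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"invalid bases ref={ref!r} alt={alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref!r}")
    if len(trinucleotide) != 3 or any(b not in BASES for b in trinucleotide):
        raise ValueError(f"invalid trinucleotide {trinucleotide!r}")
    if trinucleotide[1] != ref:
        raise ValueError(
            f"trinucleotide middle base {trinucleotide[1]!r} != ref {ref!r}"
        )
    if ref in "AG":  # purine reference: flip to the pyrimidine strand
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
        trinucleotide = reverse_complement(trinucleotide)
    label = f"{trinucleotide[0]}[{ref}>{alt}]{trinucleotide[2]}"
    return _CHANNEL_INDEX[label]


def channel_to_mutation(index: int) -> tuple[str, str, str]:
    """Inverse of :func:`channel_index` on the pyrimidine strand.

    Returns ``(ref, alt, trinucleotide)`` for a channel index.
    """
    label = CHANNELS[index]
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    return ref, alt, five + ref + three
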