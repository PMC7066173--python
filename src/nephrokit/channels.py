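"""Canonical 96-channel single-base-substitution catalog conventions.

A mutation catalog counts single-base substitutions in their trinucleotide
context. With the substituted base expressed on the pyrimidine strand there
are six substitution classes (C>A, C>G, C>T, T>A, T>C, T>G), each observed in
4 x 4 flanking contexts, giving 96 channels. The canonical order used
throughout this package is the COSMIC convention: substitution classes in the
order above, contexts within each class sorted alphabetically by (5' flank,
3' flank). Labels use the bracket form ``A[C>A]A``; the arrow form
``ACA>AAA`` is accepted on input and normalized, including purine-strand
spellings which are reverse-complemented.
"""

from __future__ import annotations

import re

from .errors import FormatError

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

#: The 96 channel labels in canonical (COSMIC) order.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BRACKET_RE = re.compile(r"^([ACGT])\[([ACGT])>([ACGT])\]([ACGT])$")
_ARROW_RE = re.compile(r"^([ACGT]{3})>([ACGT]{3})$")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_channel(label: str) -> str:
    """Normalize a channel label to the canonical bracket form.

    Accepts ``A[C>A]A`` directly and the trinucleotide arrow form
    ``ACA>AAA`` (flanks must agree, middle base must change). Purine
    reference bases are mapped to the pyrimidine strand by reverse
    complementation.

    Raises
    ------
    FormatError
        If the label matches neither form or is internally inconsistent.
    """
    label = label.strip().upper()
    m = _BRACKET_RE.match(label)
    if m:
        five, ref, alt, three = m.groups()
    else:
        m = _ARROW_RE.match(label)
        if not m:
            raise FormatError(f"unrecognized channel label: {label!r}")
        src, dst = m.groups()
        if src[0] != dst[0] or src[2] != dst[2]:
            raise FormatError(f"flanking bases disagree in channel label {label!r}")
        if src[1] == dst[1]:
            raise FormatError(f"reference and alternate base identical in {label!r}")
        five, ref, alt, three = src[0], src[1], dst[1], src[2]
    if ref not in "CT":
        five, three = _revcomp(three), _revcomp(five)
        ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
    canonical = f"{five}[{ref}>{alt}]{three}"
    if canonical not in CHANNEL_INDEX:
        raise FormatError(f"invalid substitution channel: {label!r}")
    return canonical


def channel_order(labels: list[str]) -> list[int]:
    """Map *labels* (any accepted spelling, any order) onto canonical indices.

    Every canonical channel must appear exactly once.

    Raises
    ------
    FormatError
        Naming the first missing channel, or any duplicated channel.
    """
    seen: dict[str, int] = {}
    for row, label in enumerate(labels):
        canon = normalize_channel(label)
        if canon in seen:
            raise FormatError(f"duplicate channel label: {canon}")
        seen[canon] = row
    for canon in CHANNELS:
        if canon not in seen:
            raise FormatError(f"missing channel label: {canon}")
    return [seen[c] for c in CHANNELS]
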