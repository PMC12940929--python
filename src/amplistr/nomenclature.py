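"""Forensic STR nomenclature: bracketed repeat motifs and length-based designations.

Sequence-based STR alleles are written as bracketed motifs, e.g.
``[TAGA]9 [CAGA]3 N48 [TAGA]13 [CAGA]6``: bracketed blocks are a repeat unit
with a count, bare blocks are singleton units, and ``Nk`` denotes a k-base
non-repeat spacer.  The length-based (CE-compatible) designation of an allele
is the number of whole repeat units it contains, with leftover bases rendered
as a microvariant suffix (``15.1`` = 15 units plus one base).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional


class MotifParseError(ValueError):
    """Raised when a bracketed-motif string cannot be parsed."""


class MotifExpansionError(ValueError):
    """Raised when a motif cannot be expanded to a nucleotide sequence."""


_UNIT_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class MotifBlock:
    """One block of a bracketed motif: a repeated unit, a singleton, or a spacer."""

    unit: str = ""
    count: int = 1
    bracketed: bool = True
    spacer: bool = False
    spacer_length: int = 0
    # Actual spacer bases when known (from a sequenced record). Not part of
    # the printed nomenclature, hence excluded from equality.
    spacer_sequence: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.spacer:
            if self.spacer_length <= 0:
                raise ValueError("spacer block requires spacer_length > 0")
            if self.spacer_sequence is not None and len(self.spacer_sequence) != self.spacer_length:
                raise ValueError("spacer_sequence length disagrees with spacer_length")
        else:
            if not self.unit:
                raise ValueError("non-spacer block requires a non-empty unit")
            if set(self.unit) - _UNIT_ALPHABET:
                raise ValueError(f"unit {self.unit!r} contains non-ACGT characters")
            if self.count < 1:
                raise ValueError("count must be >= 1 for non-spacer blocks")

    @property
    def length(self) -> int:
        """Number of bases this block contributes to the repeat sequence."""
        return self.spacer_length if self.spacer else len(self.unit) * self.count

    def serialize(self) -> str:
        if self.spacer:
            return f"N{self.spacer_length}"
        if self.bracketed:
            return f"[{self.unit}]{self.count}"
        return self.unit


@dataclass(frozen=True)
class BracketedMotif:
    """Ordered blocks making up one sequence-based allele motif."""

    blocks: tuple[MotifBlock, ...]

    def __post_init__(self) -> None:
        if not any(not b.spacer for b in self.blocks):
            raise ValueError("motif requires at least one non-spacer block")

    @property
    def length(self) -> int:
        return sum(b.length for b in self.blocks)

    @property
    def has_spacer(self) -> bool:
        return any(b.spacer for b in self.blocks)

    def serialize(self) -> str:
        return " ".join(b.serialize() for b in self.blocks)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


@dataclass(frozen=True)
class AlleleDesignation:
    """Length-based allele name: whole repeat-unit count plus leftover bases."""

    whole: int
    partial: int = 0

    def __post_init__(self) -> None:
        if self.whole < 0 or self.partial < 0:
            raise ValueError("designation components must be non-negative")

    def render(self) -> str:
        if self.partial == 0:
            return str(self.whole)
        return f"{self.whole}.{self.partial}"

    def __str__(self) -> str:
        return self.render()

    @classmethod
    def from_string(cls, text: str) -> "AlleleDesignation":
        text = text.strip()
        if "." in text:
            whole, partial = text.split(".", 1)
            return cls(int(whole), int(partial))
        return cls(int(text))


_BRACKETED_RE = re.compile(r"\[([A-Za-z]+)\](\d+)$")
_SPACER_RE = re.compile(r"N(\d+)$")
_SINGLETON_RE = re.compile(r"[A-Za-z]+$")


def parse_bracketed_motif(text: str) -> BracketedMotif:
    """Parse a whitespace-separated bracketed-motif string.

    Tokens are ``[UNIT]count``, a bare ``UNIT`` (singleton, count 1), or
    ``Nk`` (a k-base spacer).

    Raises
    ------
    MotifParseError
        On empty input or any malformed token; the message names the token.
    """
    if not text or not text.strip():
        raise MotifParseError("empty motif string")
    blocks: list[MotifBlock] = []
    for token in text.split():
        m = _BRACKETED_RE.fullmatch(token)
        if m:
            unit, count = m.group(1).upper(), int(m.group(2))
            if count < 1:
                raise MotifParseError(f"non-positive repeat count in token {token!r}")
            if set(unit) - _UNIT_ALPHABET:
                raise MotifParseError(f"non-ACGT unit in token {token!r}")
            blocks.append(MotifBlock(unit=unit, count=count, bracketed=True))
            continue
        m = _SPACER_RE.fullmatch(token)
        if m:
            length = int(m.group(1))
            if length <= 0:
                raise MotifParseError(f"non-positive spacer length in token {token!r}")
            blocks.append(MotifBlock(spacer=True, spacer_length=length))
            continue
        if _SINGLETON_RE.fullmatch(token):
            unit = token.upper()
            if set(unit) - _UNIT_ALPHABET:
                raise MotifParseError(f"non-ACGT unit in token {token!r}")
            blocks.append(MotifBlock(unit=unit, count=1, bracketed=False))
            continue
        raise MotifParseError(f"malformed motif token {token!r}")
    return BracketedMotif(tuple(blocks))


def expand_motif(motif: BracketedMotif) -> str:
    """Concatenate each unit ``count`` times (spacers need explicit sequence).

    Raises
    ------
    MotifExpansionError
        If the motif contains a spacer without an explicit spacer_sequence.
    """
    parts: list[str] = []
    for block in motif.blocks:
        if block.spacer:
            if block.spacer_sequence is None:
                raise MotifExpansionError(
                    f"cannot expand spacer N{block.spacer_length} without explicit sequence"
                )
            parts.append(block.spacer_sequence)
        else:
            parts.append(block.unit * block.count)
    return "".join(parts)


def designation_from_motif(motif: BracketedMotif, unit_length: int) -> AlleleDesignation:
    """Length-based designation of a motif at a locus with the given unit length.

    Blocks whose unit length equals ``unit_length`` contribute their repeat
    counts; off-length blocks are pooled by total base length, contributing
    whole units plus a microvariant remainder; spacers contribute nothing.
    """
    if unit_length < 2:
        raise ValueError("unit_length must be >= 2")
    whole = 0
    off_length_bases = 0
    for block in motif.blocks:
        if block.spacer:
            continue
        if len(block.unit) == unit_length:
            whole += block.count
        else:
            off_length_bases += block.length
    whole += off_length_bases // unit_length
    partial = off_length_bases % unit_length
    return AlleleDesignation(whole=whole, partial=partial)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (case-insensitive)."""
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")
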