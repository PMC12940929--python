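"""Read-to-allele assignment by semi-global edit distance.

Each locus-binned read is scored against every catalog allele of its locus.
The score is the minimum unit-cost edit distance of the best placement of the
shorter sequence anywhere within the longer one (overhangs of the longer
sequence are free), computed with Myers' bit-parallel algorithm over
arbitrary-width Python integers.  Both read orientations are scored and the
better one kept, so counting is strand-invariant.

A read is assigned to the unique lowest-cost allele provided its identity
clears the divergence ceiling; ties and too-divergent reads are left
unassigned (inflating either tied allele would bias normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .catalog import CatalogEntry
from .intake import LocusReadSet
from .nomenclature import reverse_complement

DEFAULT_MAX_DIVERGENCE = 0.30


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleScore:
    """Cost of the best semi-global placement of a read against one allele."""

    accession: str
    cost: int
    identity: float


def _pattern_masks(pattern: str) -> dict[str, int]:
    """Per-character position bitmasks. N has no mask: it matches nothing."""
    masks: dict[str, int] = {}
    for i, ch in enumerate(pattern):
        if ch in "ACGT":
            masks[ch] = masks.get(ch, 0) | (1 << i)
    return masks


def _myers_search(masks: Mapping[str, int], m: int, text: str) -> int:
    """Minimum edit distance of the pattern against any substring of text.

    Bit-parallel Myers/Hyyrö approximate-matching recurrence; the text prefix
    and suffix are free (boundary D[0][j] = 0, answer = min over end columns).
    """
    all_ones = (1 << m) - 1
    high_bit = 1 << (m - 1)
    vp = all_ones
    vn = 0
    dist = m
    best = m
    get = masks.get
    for ch in text:
        eq = get(ch, 0)
        xv = eq | vn
        xh = ((((eq & vp) + vp) & all_ones) ^ vp) | eq
        ph = vn | (all_ones & ~(xh | vp))
        mh = vp & xh
        if ph & high_bit:
            dist += 1
        elif mh & high_bit:
            dist -= 1
        ph = (ph << 1) & all_ones
        mh = (mh << 1) & all_ones
        vp = mh | (all_ones & ~(xv | ph))
        vn = ph & xv
        if dist < best:
            best = dist
    return best


def semiglobal_cost(seq_a: str, seq_b: str) -> int:
    """Edit distance of the best placement of the shorter sequence in the longer."""
    if not seq_a or not seq_b:
        raise ScoringError("cannot score empty sequences")
    pattern, text = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    return _myers_search(_pattern_masks(pattern), len(pattern), text)


def score_read(read_sequence: str, allele_sequence: str, accession: str = "") -> AlleleScore:
    """Score a read against one allele reference, best of both orientations.

    Identity is 1 - cost / len(shorter sequence); cost 0 iff the shorter
    sequence is contained exactly in the longer.
    """
    if not read_sequence or not allele_sequence:
        raise ScoringError("cannot score empty sequences")
    read_sequence = read_sequence.upper()
    allele_sequence = allele_sequence.upper()
    cost = min(
        semiglobal_cost(read_sequence, allele_sequence),
        semiglobal_cost(reverse_complement(read_sequence), allele_sequence),
    )
    shorter = min(len(read_sequence), len(allele_sequence))
    return AlleleScore(accession=accession, cost=cost, identity=1.0 - cost / shorter)


def _score_against_entries(
    read_sequence: str, entries: Sequence[CatalogEntry]
) -> list[AlleleScore]:
    """Score one read against all candidates, reusing per-orientation masks."""
    read_sequence = read_sequence.upper()
    rc = reverse_complement(read_sequence)
    scores: list[AlleleScore] = []
    fwd_masks = rc_masks = None
    for entry in entries:
        ref = entry.reference_sequence
        if len(read_sequence) <= len(ref):
            if fwd_masks is None:
                fwd_masks = _pattern_masks(read_sequence)
                rc_masks = _pattern_masks(rc)
            m = len(read_sequence)
            cost = min(
                _myers_search(fwd_masks, m, ref),
                _myers_search(rc_masks, m, ref),
            )
            shorter = m
        else:
            cost = min(
                semiglobal_cost(read_sequence, ref),
                semiglobal_cost(rc, ref),
            )
            shorter = len(ref)
        scores.append(
            AlleleScore(
                accession=entry.allele.accession,
                cost=cost,
                identity=1.0 - cost / shorter,
            )
        )
    return scores


def assign_read(
    read_sequence: str,
    entries: Sequence[CatalogEntry],
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
) -> Optional[str]:
    """Assign a read to the unique lowest-cost candidate allele.

    Returns None (unassigned) on a tie for lowest cost or when the best
    identity falls below 1 - max_divergence.
    """
    if not entries:
        raise ScoringError("assign_read requires at least one candidate allele")
    scores = _score_against_entries(read_sequence, entries)
    best = min(scores, key=lambda s: s.cost)
    if sum(1 for s in scores if s.cost == best.cost) > 1:
        return None
    if best.identity < 1.0 - max_divergence:
        return None
    return best.accession


@dataclass
class CountRow:
    """Raw per-allele read tallies for one locus."""

    counts: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0

    @property
    def assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def total(self) -> int:
        return self.assigned + self.unassigned


@dataclass
class AlleleCountTable:
    """Per-locus mapping allele accession -> raw assigned-read count."""

    rows: dict[str, CountRow] = field(default_factory=dict)

    def row(self, locus: str) -> CountRow:
        return self.rows.setdefault(locus, CountRow())


def count_alleles(
    read_set: LocusReadSet,
    entries: Sequence[CatalogEntry],
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
) -> CountRow:
    """Tally assigned reads per allele for one locus read set."""
    if not entries:
        raise ScoringError(
            f"locus {read_set.locus.name} has no catalog entries"
        )
    row = CountRow(counts={e.allele.accession: 0 for e in entries})
    for read in read_set.reads:
        if not read.sequence:
            row.unassigned += 1
            continue
        accession = assign_read(read.sequence, entries, max_divergence)
        if accession is None:
            row.unassigned += 1
        else:
            row.counts[accession] += 1
    return row
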