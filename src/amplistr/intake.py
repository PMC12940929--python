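"""Alignment intake: load SAM/BAM, keep primary alignments, bin reads by locus.

Reads are binned to a target STR locus only when their primary alignment
fully spans the locus repeat interval plus a small margin on each side
(``min_span_flank``, default 10 bp), guarding against alignment end-trimming
artifacts.  Secondary and supplementary alignments are excluded.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pysam

from .catalog import LocusDefinition

PRIMARY = "primary"
SECONDARY = "secondary"
SUPPLEMENTARY = "supplementary"
UNMAPPED = "unmapped"


class ConfigurationError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class MappedRead:
    """One alignment record, flags decoded into a category."""

    name: str
    sequence: Optional[str]
    qualities: Optional[str]
    reference_name: Optional[str]
    reference_start: Optional[int]  # 0-based
    reference_end: Optional[int]  # half-open
    category: str
    mapping_quality: int = 0

    @property
    def is_mapped(self) -> bool:
        return self.category != UNMAPPED


@dataclass
class LocusReadSet:
    locus: LocusDefinition
    reads: list[MappedRead] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class MappingStats:
    """On-target / off-target / unmapped read partition."""

    on_target: int
    off_target: int
    unmapped: int
    empty: bool = False

    @property
    def total(self) -> int:
        return self.on_target + self.off_target + self.unmapped

    @property
    def proportions(self) -> Optional[tuple[float, float, float]]:
        if self.empty:
            return None
        total = self.total
        return (self.on_target / total, self.off_target / total, self.unmapped / total)


def load_alignments(source: Union[str, Path]) -> list[MappedRead]:
    """Read every record of a SAM/BAM file into MappedReads (streaming, no index).

    Raises AlignmentError naming the record number on a malformed record.
    """
    reads: list[MappedRead] = []
    with pysam.AlignmentFile(str(source), check_sq=False) as fh:
        iterator = fh.fetch(until_eof=True)
        n = 0
        while True:
            try:
                rec = next(iterator)
            except StopIteration:
                break
            except Exception as exc:  # pysam raises ValueError/OSError variants
                raise AlignmentError(f"malformed alignment record #{n + 1}: {exc}") from exc
            n += 1
            if rec.is_unmapped:
                category = UNMAPPED
            elif rec.is_supplementary:
                category = SUPPLEMENTARY
            elif rec.is_secondary:
                category = SECONDARY
            else:
                category = PRIMARY
            reads.append(
                MappedRead(
                    name=rec.query_name,
                    sequence=rec.query_sequence,
                    qualities=rec.qual if rec.query_qualities is not None else None,
                    reference_name=rec.reference_name if category != UNMAPPED else None,
                    reference_start=rec.reference_start if category != UNMAPPED else None,
                    reference_end=rec.reference_end if category != UNMAPPED else None,
                    category=category,
                    mapping_quality=rec.mapping_quality,
                )
            )
    return reads


def _check_non_overlapping(loci: Sequence[LocusDefinition]) -> None:
    by_chrom: dict[str, list[LocusDefinition]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda l: l.reference_interval)
        for a, b in zip(group, group[1:]):
            if a.reference_interval[1] > b.reference_interval[0]:
                raise ConfigurationError(
                    f"overlapping loci {a.name} and {b.name} on {chrom}"
                )


def _spans(read: MappedRead, locus: LocusDefinition, margin: int) -> bool:
    if read.reference_name != locus.chromosome:
        return False
    start, end = locus.reference_interval
    return read.reference_start <= start - margin and read.reference_end >= end + margin


def extract_locus_reads(
    reads: Iterable[MappedRead],
    loci: Sequence[LocusDefinition],
    min_span_flank: int = 10,
    min_mapping_quality: Optional[int] = None,
) -> dict[str, LocusReadSet]:
    """Bin primary alignments to the (at most one) locus they fully span."""
    _check_non_overlapping(loci)
    read_sets = {locus.name: LocusReadSet(locus=locus) for locus in loci}
    for read in reads:
        if read.category != PRIMARY:
            continue
        if min_mapping_quality is not None and read.mapping_quality < min_mapping_quality:
            continue
        for locus in loci:
            if _spans(read, locus, min_span_flank):
                read_sets[locus.name].reads.append(read)
                break  # non-overlapping loci: at most one bin
    return read_sets


def compute_mapping_stats(
    reads: Iterable[MappedRead],
    loci: Sequence[LocusDefinition],
    min_span_flank: int = 10,
) -> MappingStats:
    """Partition reads into on-target (primary, spanning a locus), off-target, unmapped."""
    _check_non_overlapping(loci)
    on_target = off_target = unmapped = 0
    for read in reads:
        if read.category == UNMAPPED:
            unmapped += 1
        elif read.category == PRIMARY and any(
            _spans(read, locus, min_span_flank) for locus in loci
        ):
            on_target += 1
        else:
            off_target += 1
    total = on_target + off_target + unmapped
    return MappingStats(
        on_target=on_target,
        off_target=off_target,
        unmapped=unmapped,
        empty=total == 0,
    )


DEFAULT_ALIGNER_TEMPLATE = "minimap2 -a -x map-ont --secondary=no {reference} {reads}"


def align_fastq(
    fastq: Union[str, Path],
    reference: Union[str, Path],
    command_template: str = DEFAULT_ALIGNER_TEMPLATE,
    out_sam: Optional[Union[str, Path]] = None,
) -> Path:
    """Shell out to an external aligner and return the path to the SAM output.

    The template must contain ``{reference}`` and ``{reads}`` placeholders;
    the aligner must write SAM to stdout.
    """
    if out_sam is None:
        out_sam = Path(tempfile.mkstemp(suffix=".sam")[1])
    command = command_template.format(reference=str(reference), reads=str(fastq))
    with open(out_sam, "w") as fh:
        result = subprocess.run(
            shlex.split(command), stdout=fh, stderr=subprocess.PIPE, text=True
        )
    if result.returncode != 0:
        raise AlignmentError(
            f"aligner failed (exit {result.returncode}): {result.stderr[-2000:]}"
        )
    return Path(out_sam)
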