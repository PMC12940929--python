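"""Genotype calling from normalized read counts.

Raw per-allele counts at a locus are normalized to the allele with the
highest coverage (top allele -> 1.0).  Autosomal loci report the top allele,
plus the second-ranked allele when its normalized value exceeds the
heterozygote threshold (default 0.4, strict comparison on full precision).
Non-merged Y loci report only the top allele; the merged DYS385ab locus
reports the top two alleles exceeding the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .catalog import AUTOSOMAL, Y, Y_MERGED, CatalogEntry, LocusDefinition
from .intake import LocusReadSet

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
HAPLOTYPE = "haplotype"
MERGED = "merged"
NO_CALL = "no-call"

FLAG_LOW_COVERAGE = "low_coverage"
FLAG_TIE = "tie"
FLAG_DROPOUT = "dropout"


@dataclass(frozen=True)
class CallerConfig:
    threshold: float = 0.4
    min_coverage: int = 10
    inclusive_threshold: bool = False
    display_decimals: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be non-negative")

    def exceeds(self, value: float) -> bool:
        if self.inclusive_threshold:
            return value >= self.threshold
        return value > self.threshold


@dataclass(frozen=True)
class NormalizedCounts:
    """Per-allele (raw, normalized) pairs; normalized = raw / max raw."""

    values: Mapping[str, tuple[int, float]]
    dropout: bool = False

    def ranked(self) -> list[tuple[str, int, float]]:
        """(accession, raw, norm) sorted by descending raw then accession."""
        return sorted(
            ((acc, raw, norm) for acc, (raw, norm) in self.values.items()),
            key=lambda item: (-item[1], item[0]),
        )


def normalize_counts(raw_counts: Mapping[str, int]) -> NormalizedCounts:
    """Normalize raw counts to the allele with the highest coverage.

    All-zero (or empty) input yields a dropout marker with no values.
    Full precision is retained; rounding happens only at report time.
    """
    positive = {acc: count for acc, count in raw_counts.items() if count > 0}
    if not positive:
        return NormalizedCounts(values={}, dropout=True)
    top = max(positive.values())
    return NormalizedCounts(
        values={acc: (count, count / top) for acc, count in positive.items()}
    )


@dataclass(frozen=True)
class AlleleCall:
    accession: str
    designation: str
    motif: str
    raw: int
    normalized: float


@dataclass(frozen=True)
class LocusCall:
    locus: str
    locus_class: str
    zygosity: str
    alleles: tuple[AlleleCall, ...] = ()
    flags: tuple[str, ...] = ()

    @property
    def designations(self) -> tuple[str, ...]:
        return tuple(a.designation for a in self.alleles)


@dataclass
class Profile:
    """A sample's called profile: at most one LocusCall per locus."""

    sample: str
    calls: dict[str, LocusCall] = field(default_factory=dict)

    def add(self, call: LocusCall) -> None:
        if call.locus in self.calls:
            raise ValueError(f"duplicate call for locus {call.locus}")
        self.calls[call.locus] = call

    def __eq__(self, other) -> bool:
        if not isinstance(other, Profile):
            return NotImplemented
        return self.sample == other.sample and self.calls == other.calls


AlleleMeta = Mapping[str, tuple[str, str]]  # accession -> (designation, motif)


def meta_from_entries(entries: Sequence[CatalogEntry]) -> dict[str, tuple[str, str]]:
    return {
        e.allele.accession: (e.allele.designation.render(), e.allele.motif.serialize())
        for e in entries
    }


def _allele_call(acc: str, raw: int, norm: float, meta: AlleleMeta) -> AlleleCall:
    designation, motif = meta.get(acc, (acc, ""))
    return AlleleCall(
        accession=acc, designation=designation, motif=motif, raw=raw, normalized=norm
    )


def _dropout(locus: str, locus_class: str, extra_flags: tuple[str, ...] = ()) -> LocusCall:
    return LocusCall(
        locus=locus,
        locus_class=locus_class,
        zygosity=NO_CALL,
        alleles=(),
        flags=(FLAG_DROPOUT,) + extra_flags,
    )


def call_autosomal(
    locus: str,
    normalized: NormalizedCounts,
    meta: AlleleMeta,
    config: CallerConfig = CallerConfig(),
) -> LocusCall:
    """Call an autosomal locus as homozygous (top allele) or heterozygous (top two)."""
    if normalized.dropout:
        return _dropout(locus, AUTOSOMAL)
    ranked = normalized.ranked()
    top_acc, top_raw, top_norm = ranked[0]
    alleles = [_allele_call(top_acc, top_raw, top_norm, meta)]
    flags: tuple[str, ...] = ()
    if len(ranked) > 1:
        second_acc, second_raw, second_norm = ranked[1]
        if second_raw == top_raw:
            flags = (FLAG_TIE,)
            alleles.append(_allele_call(second_acc, second_raw, second_norm, meta))
            zygosity = HETEROZYGOUS
        elif config.exceeds(second_norm):
            alleles.append(_allele_call(second_acc, second_raw, second_norm, meta))
            zygosity = HETEROZYGOUS
        else:
            zygosity = HOMOZYGOUS
    else:
        zygosity = HOMOZYGOUS
    return LocusCall(
        locus=locus,
        locus_class=AUTOSOMAL,
        zygosity=zygosity,
        alleles=tuple(alleles),
        flags=flags,
    )


def call_y(
    locus: str,
    normalized: NormalizedCounts,
    meta: AlleleMeta,
    config: CallerConfig = CallerConfig(),
    merged: bool = False,
) -> LocusCall:
    """Call a Y locus: top allele only, or top two over threshold when merged (DYS385ab)."""
    locus_class = Y_MERGED if merged else Y
    if normalized.dropout:
        return _dropout(locus, locus_class)
    ranked = normalized.ranked()
    top_acc, top_raw, top_norm = ranked[0]
    rank1_tied = len(ranked) > 1 and ranked[1][1] == top_raw
    if merged:
        alleles = [_allele_call(top_acc, top_raw, top_norm, meta)]
        flags: tuple[str, ...] = (FLAG_TIE,) if rank1_tied else ()
        if len(ranked) > 1:
            second_acc, second_raw, second_norm = ranked[1]
            if rank1_tied or config.exceeds(second_norm):
                alleles.append(_allele_call(second_acc, second_raw, second_norm, meta))
        return LocusCall(
            locus=locus,
            locus_class=locus_class,
            zygosity=MERGED,
            alleles=tuple(alleles),
            flags=flags,
        )
    if rank1_tied:
        return LocusCall(
            locus=locus,
            locus_class=locus_class,
            zygosity=NO_CALL,
            alleles=(),
            flags=(FLAG_TIE,),
        )
    return LocusCall(
        locus=locus,
        locus_class=locus_class,
        zygosity=HAPLOTYPE,
        alleles=(_allele_call(top_acc, top_raw, top_norm, meta),),
    )


def merge_dys385(read_set_a: LocusReadSet, read_set_b: LocusReadSet, merged_name: str = "DYS385ab") -> LocusReadSet:
    """Pool the reads of the two DYS385 duplication loci into one merged set.

    The merged set is treated downstream as a single Y-merged locus.
    """
    a, b = read_set_a.locus, read_set_b.locus
    if a.chromosome != b.chromosome:
        raise ValueError("DYS385 pair must share a chromosome")
    start = min(a.reference_interval[0], b.reference_interval[0])
    end = max(a.reference_interval[1], b.reference_interval[1])
    merged_locus = LocusDefinition(
        name=merged_name,
        chromosome=a.chromosome,
        reference_interval=(start, end),
        locus_class=Y_MERGED,
        unit_length=a.unit_length,
    )
    return LocusReadSet(locus=merged_locus, reads=list(read_set_a.reads) + list(read_set_b.reads))


def call_locus(
    locus: LocusDefinition,
    raw_counts: Mapping[str, int],
    meta: AlleleMeta,
    config: CallerConfig = CallerConfig(),
    total_reads: Optional[int] = None,
) -> LocusCall:
    """Dispatch on locus class, with dropout / low-coverage bookkeeping."""
    coverage = total_reads if total_reads is not None else sum(raw_counts.values())
    normalized = normalize_counts(raw_counts)
    if normalized.dropout:
        return _dropout(locus.name, locus.locus_class)
    if coverage < config.min_coverage:
        # Below the coverage floor no genotype is asserted: a homozygote must
        # remain distinguishable from allele dropout.
        return LocusCall(
            locus=locus.name,
            locus_class=locus.locus_class,
            zygosity=NO_CALL,
            alleles=(),
            flags=(FLAG_LOW_COVERAGE,),
        )
    if locus.locus_class == AUTOSOMAL:
        return call_autosomal(locus.name, normalized, meta, config)
    return call_y(
        locus.name, normalized, meta, config, merged=locus.locus_class == Y_MERGED
    )
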