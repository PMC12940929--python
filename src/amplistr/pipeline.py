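"""End-to-end profiling: alignments in, called profile + count table out."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import yaml

from .caller import CallerConfig, Profile, call_locus, merge_dys385, meta_from_entries
from .catalog import Catalog
from .intake import (
    DEFAULT_ALIGNER_TEMPLATE,
    LocusReadSet,
    MappingStats,
    align_fastq,
    compute_mapping_stats,
    extract_locus_reads,
    load_alignments,
)
from .matcher import DEFAULT_MAX_DIVERGENCE, AlleleCountTable, ScoringError, count_alleles


@dataclass(frozen=True)
class PipelineConfig:
    min_span_flank: int = 10
    max_divergence: float = DEFAULT_MAX_DIVERGENCE
    min_mapping_quality: Optional[int] = None
    caller: CallerConfig = field(default_factory=CallerConfig)
    dys385_pair: tuple[str, str] = ("DYS385a", "DYS385b")
    dys385_merged_name: str = "DYS385ab"
    aligner_template: str = DEFAULT_ALIGNER_TEMPLATE

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        caller_data = data.pop("caller", {})
        if "dys385_pair" in data:
            data["dys385_pair"] = tuple(data["dys385_pair"])
        return cls(caller=CallerConfig(**caller_data), **data)


@dataclass
class ProfileResult:
    profile: Profile
    count_table: AlleleCountTable
    mapping_stats: MappingStats
    read_sets: dict[str, LocusReadSet]


def profile_alignments(
    alignments: Union[str, Path],
    catalog: Catalog,
    sample: str,
    config: PipelineConfig = PipelineConfig(),
) -> ProfileResult:
    """Profile one sample from a SAM/BAM of genome-aligned reads."""
    reads = load_alignments(alignments)
    stats = compute_mapping_stats(reads, catalog.loci, config.min_span_flank)
    read_sets = extract_locus_reads(
        reads,
        catalog.loci,
        min_span_flank=config.min_span_flank,
        min_mapping_quality=config.min_mapping_quality,
    )

    # Fold the DYS385 duplication into one merged locus before counting.
    ordered: list[LocusReadSet] = []
    pair = [name for name in config.dys385_pair if name in read_sets]
    merged_inserted = False
    for locus in catalog.loci:
        if locus.name in config.dys385_pair:
            if len(pair) == 2 and not merged_inserted:
                ordered.append(
                    merge_dys385(
                        read_sets[pair[0]],
                        read_sets[pair[1]],
                        merged_name=config.dys385_merged_name,
                    )
                )
                merged_inserted = True
            elif len(pair) == 1 and not merged_inserted:
                # lone half of the duplication: counted under the merged name
                only = read_sets[pair[0]]
                ordered.append(
                    LocusReadSet(
                        locus=replace(only.locus, name=config.dys385_merged_name),
                        reads=only.reads,
                    )
                )
                merged_inserted = True
            continue
        ordered.append(read_sets[locus.name])

    table = AlleleCountTable()
    profile = Profile(sample=sample)
    for read_set in ordered:
        name = read_set.locus.name
        entries = catalog.entries_for(name)
        if not entries:
            raise ScoringError(f"locus {name} has no catalog entries")
        row = count_alleles(read_set, entries, config.max_divergence)
        table.rows[name] = row
        profile.add(
            call_locus(
                read_set.locus,
                row.counts,
                meta_from_entries(entries),
                config.caller,
                total_reads=row.total,
            )
        )
    return ProfileResult(
        profile=profile, count_table=table, mapping_stats=stats, read_sets=read_sets
    )


def profile_fastq(
    fastq: Union[str, Path],
    reference: Union[str, Path],
    catalog: Catalog,
    sample: str,
    config: PipelineConfig = PipelineConfig(),
    out_sam: Optional[Union[str, Path]] = None,
) -> ProfileResult:
    """Profile from FASTQ by shelling out to the configured genome aligner."""
    sam = align_fastq(
        fastq, reference, command_template=config.aligner_template, out_sam=out_sam
    )
    return profile_alignments(sam, catalog, sample, config)
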