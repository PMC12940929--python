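"""STR allele catalog: GenBank record parsing, redundancy collapse, flank assembly.

The catalog is the allele reference used for read assignment.  Each allele is
parsed from a GenBank flat-file record carrying a repeat-region feature, the
set of same-locus records is collapsed to unique (repeat sequence, flanking
variants) combinations, and reference-genome flanks are attached to produce
the per-allele reference sequences written to FASTA.

Coordinates are 0-based half-open internally; GenBank's 1-based inclusive
intervals and BED's 0-based half-open intervals are converted at the boundary.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO

from .nomenclature import (
    AlleleDesignation,
    BracketedMotif,
    MotifExpansionError,
    designation_from_motif,
    expand_motif,
    parse_bracketed_motif,
)

logger = logging.getLogger(__name__)

AUTOSOMAL = "autosomal"
Y = "Y"
Y_MERGED = "Y-merged"
LOCUS_CLASSES = (AUTOSOMAL, Y, Y_MERGED)


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class FlankingVariant:
    """A variant in the flanking sequence of an allele.

    ``offset`` is relative to the repeat start (0 = first repeat base);
    negative offsets are upstream, offsets >= repeat length are downstream.
    ``ref``/``alt`` follow VCF-like semantics with ``-`` for the empty allele
    (``ref='-'`` insertion, ``alt='-'`` deletion).
    """

    offset: int
    ref: str
    alt: str

    def render(self) -> str:
        return f"{self.offset}:{self.ref}>{self.alt}"

    @classmethod
    def from_string(cls, text: str) -> "FlankingVariant":
        m = re.fullmatch(r"(-?\d+):([ACGTN-]+)>([ACGTN-]+)", text.strip())
        if not m:
            raise CatalogError(f"malformed flanking variant {text!r}")
        return cls(int(m.group(1)), m.group(2), m.group(3))


@dataclass(frozen=True)
class AlleleRecord:
    """One sequence-based STR allele extracted from a GenBank record."""

    accession: str
    locus: str
    chromosome: str
    repeat_interval: tuple[int, int]  # 0-based half-open, reference coords
    repeat_sequence: str
    flanking_variants: frozenset[FlankingVariant]
    motif: BracketedMotif
    designation: AlleleDesignation
    unit_length: int
    locus_class: str = AUTOSOMAL

    def duplicate_key(self) -> tuple:
        return (self.locus, self.repeat_sequence, self.flanking_variants)


@dataclass(frozen=True)
class LocusDefinition:
    """A target STR locus on the reference genome."""

    name: str
    chromosome: str
    reference_interval: tuple[int, int]  # 0-based half-open
    locus_class: str
    unit_length: int

    def __post_init__(self) -> None:
        if self.locus_class not in LOCUS_CLASSES:
            raise ValueError(f"unknown locus class {self.locus_class!r}")
        if self.unit_length < 2:
            raise ValueError("unit_length must be >= 2")
        start, end = self.reference_interval
        if end <= start:
            raise ValueError(f"empty interval for locus {self.name}")


@dataclass(frozen=True)
class CatalogEntry:
    """An allele plus its flanked reference sequence used for read alignment."""

    allele: AlleleRecord
    reference_sequence: str
    flank_length: int
    upstream_used: int
    downstream_used: int
    truncated: bool = False


# ---------------------------------------------------------------------------
# GenBank parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenBankDialect:
    """Qualifier keys used to pull allele metadata out of GenBank features."""

    feature_type: str = "repeat_region"
    locus_keys: tuple[str, ...] = ("locus", "standard_name", "gene")
    chromosome_key: str = "chromosome"
    interval_key: str = "genomic_interval"  # "start..end", 1-based inclusive
    motif_key: str = "bracketed_motif"
    variants_key: str = "flanking_variants"
    unit_length_key: str = "repeat_unit_length"
    class_key: str = "locus_class"


@dataclass(frozen=True)
class RecordError:
    record_id: str
    reason: str


def _qualifier(feature, key: str) -> Optional[str]:
    values = feature.qualifiers.get(key)
    return values[0] if values else None


def parse_genbank_records(
    source: Union[str, Path, io.TextIOBase],
    dialect: GenBankDialect = GenBankDialect(),
) -> tuple[list[AlleleRecord], list[RecordError]]:
    """Parse a (possibly multi-record) GenBank flat file into allele records.

    Records lacking the repeat feature, a locus name, or self-consistent
    annotation are skipped; each skip is logged and collected, never fatal
    to the batch.
    """
    records: list[AlleleRecord] = []
    errors: list[RecordError] = []
    for rec in SeqIO.parse(_as_handle(source), "genbank"):
        try:
            records.append(_allele_from_record(rec, dialect))
        except CatalogError as exc:
            logger.warning("skipping record %s: %s", rec.id, exc)
            errors.append(RecordError(record_id=rec.id, reason=str(exc)))
    return records, errors


def _as_handle(source):
    if isinstance(source, (str, Path)):
        return str(source)
    return source


def _allele_from_record(rec, dialect: GenBankDialect) -> AlleleRecord:
    feature = next(
        (f for f in rec.features if f.type == dialect.feature_type), None
    )
    if feature is None:
        raise CatalogError(f"no {dialect.feature_type} feature")
    locus = next(
        (v for k in dialect.locus_keys if (v := _qualifier(feature, k))), None
    )
    if locus is None:
        raise CatalogError("repeat feature lacks a locus qualifier")

    chromosome = _qualifier(feature, dialect.chromosome_key)
    if chromosome is None:
        source = next((f for f in rec.features if f.type == "source"), None)
        chromosome = _qualifier(source, dialect.chromosome_key) if source else None
    if chromosome is None:
        raise CatalogError("no chromosome qualifier on repeat or source feature")

    interval_text = _qualifier(feature, dialect.interval_key)
    if interval_text is None:
        raise CatalogError(f"no {dialect.interval_key} qualifier")
    m = re.fullmatch(r"(\d+)\.\.(\d+)", interval_text.strip())
    if not m:
        raise CatalogError(f"malformed genomic interval {interval_text!r}")
    start_1based, end_inclusive = int(m.group(1)), int(m.group(2))
    if start_1based < 1 or end_inclusive < start_1based:
        raise CatalogError(f"invalid genomic interval {interval_text!r}")
    repeat_interval = (start_1based - 1, end_inclusive)  # to 0-based half-open

    repeat_sequence = str(feature.extract(rec.seq)).upper()
    if not repeat_sequence:
        raise CatalogError("empty repeat sequence")

    motif_text = _qualifier(feature, dialect.motif_key)
    if motif_text is None:
        raise CatalogError(f"no {dialect.motif_key} qualifier")
    try:
        motif = parse_bracketed_motif(motif_text)
    except ValueError as exc:
        raise CatalogError(f"bad motif: {exc}") from exc
    # Spacer blocks in the annotation get their actual bases from the record
    # sequence so the motif is expandable and validatable.
    motif = _fill_spacer_sequences(motif, repeat_sequence)
    if motif.length != len(repeat_sequence):
        raise CatalogError(
            f"motif length {motif.length} != repeat sequence length {len(repeat_sequence)}"
        )
    if not motif.has_spacer and expand_motif(motif) != repeat_sequence:
        raise CatalogError("motif does not expand to the annotated repeat sequence")

    unit_length_text = _qualifier(feature, dialect.unit_length_key)
    if unit_length_text is None:
        raise CatalogError(f"no {dialect.unit_length_key} qualifier")
    unit_length = int(unit_length_text)

    variants_text = _qualifier(feature, dialect.variants_key) or ""
    variants = frozenset(
        FlankingVariant.from_string(tok)
        for tok in variants_text.split(";")
        if tok.strip()
    )

    locus_class = _qualifier(feature, dialect.class_key) or AUTOSOMAL
    if locus_class not in LOCUS_CLASSES:
        raise CatalogError(f"unknown locus class {locus_class!r}")

    return AlleleRecord(
        accession=rec.name or rec.id,
        locus=locus,
        chromosome=chromosome,
        repeat_interval=repeat_interval,
        repeat_sequence=repeat_sequence,
        flanking_variants=variants,
        motif=motif,
        designation=designation_from_motif(motif, unit_length),
        unit_length=unit_length,
        locus_class=locus_class,
    )


def _fill_spacer_sequences(motif: BracketedMotif, repeat_sequence: str) -> BracketedMotif:
    if not motif.has_spacer:
        return motif
    blocks = []
    pos = 0
    for block in motif.blocks:
        if block.spacer:
            blocks.append(
                replace(block, spacer_sequence=repeat_sequence[pos : pos + block.spacer_length])
            )
        else:
            blocks.append(block)
        pos += block.length
    return BracketedMotif(tuple(blocks))


# ---------------------------------------------------------------------------
# Redundancy collapse
# ---------------------------------------------------------------------------

def collapse_redundant(records: Sequence[AlleleRecord]) -> list[AlleleRecord]:
    """Collapse duplicate alleles (same locus, repeat sequence and variants).

    Keeps the lexicographically smallest accession for each duplicate group;
    output preserves first-occurrence order. Idempotent.
    """
    best: dict[tuple, AlleleRecord] = {}
    order: list[tuple] = []
    for rec in records:
        key = rec.duplicate_key()
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec.accession < best[key].accession:
            best[key] = rec
    return [best[key] for key in order]


# ---------------------------------------------------------------------------
# Reference genome access and flank assembly
# ---------------------------------------------------------------------------

class ReferenceGenome:
    """Reference FASTA wrapper accepting both 'chr1' and '1' style names."""

    def __init__(self, source: Union[str, Path, Mapping[str, str]]):
        if isinstance(source, Mapping):
            self._seqs = {name: str(seq).upper() for name, seq in source.items()}
            self._fasta = None
        else:
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source))
            self._seqs = None

    def _resolve(self, name: str) -> str:
        names = self._seqs.keys() if self._seqs is not None else self._fasta.keys()
        if name in names:
            return name
        alias = name[3:] if name.startswith("chr") else "chr" + name
        if alias in names:
            return alias
        raise CatalogError(f"chromosome {name!r} absent from reference")

    def length(self, name: str) -> int:
        name = self._resolve(name)
        if self._seqs is not None:
            return len(self._seqs[name])
        return len(self._fasta[name])

    def fetch(self, name: str, start: int, end: int) -> str:
        """0-based half-open slice, clamped to the contig."""
        name = self._resolve(name)
        start = max(0, start)
        if self._seqs is not None:
            return self._seqs[name][start:end]
        return str(self._fasta[name][start:end]).upper()


def apply_flanking_variants(
    upstream: str, downstream: str, repeat_length: int, variants: Iterable[FlankingVariant]
) -> tuple[str, str]:
    """Apply offset-addressed variants to flank sequences.

    Offsets are relative to the repeat start; negative offsets index the
    upstream flank from its right edge, offsets >= repeat_length index the
    downstream flank. Variants inside the repeat are rejected (the repeat
    sequence is already allele-specific).
    """
    up = list(upstream)
    down = list(downstream)
    for var in sorted(variants, key=lambda v: -v.offset):
        if 0 <= var.offset < repeat_length:
            raise CatalogError(f"variant {var.render()} falls inside the repeat")
        if var.offset < 0:
            target, pos = up, len(up) + var.offset
        else:
            target, pos = down, var.offset - repeat_length
        if pos < 0 or pos > len(target):
            raise CatalogError(f"variant {var.render()} outside available flank")
        if var.ref == "-":  # insertion before pos
            target[pos:pos] = list(var.alt)
        elif var.alt == "-":  # deletion of ref bases at pos
            if "".join(target[pos : pos + len(var.ref)]) != var.ref:
                raise CatalogError(f"reference mismatch for variant {var.render()}")
            del target[pos : pos + len(var.ref)]
        else:  # substitution
            if "".join(target[pos : pos + len(var.ref)]) != var.ref:
                raise CatalogError(f"reference mismatch for variant {var.render()}")
            target[pos : pos + len(var.ref)] = list(var.alt)
    return "".join(up), "".join(down)


def build_catalog(
    records: Sequence[AlleleRecord],
    reference: Union[str, Path, Mapping[str, str], ReferenceGenome],
    flank_length: int = 500,
) -> list[CatalogEntry]:
    """Attach reference flanks to each allele record.

    Entries are ordered by (locus, accession) so downstream FASTA output is
    deterministic. Repeats closer than ``flank_length`` to a contig end get a
    truncated flank and are flagged.
    """
    if flank_length <= 0:
        raise ValueError("flank_length must be positive")
    genome = reference if isinstance(reference, ReferenceGenome) else ReferenceGenome(reference)
    entries = []
    for rec in sorted(records, key=lambda r: (r.locus, r.accession)):
        start, end = rec.repeat_interval
        contig_len = genome.length(rec.chromosome)
        up_start = max(0, start - flank_length)
        down_end = min(contig_len, end + flank_length)
        upstream = genome.fetch(rec.chromosome, up_start, start)
        downstream = genome.fetch(rec.chromosome, end, down_end)
        truncated = len(upstream) < flank_length or len(downstream) < flank_length
        upstream, downstream = apply_flanking_variants(
            upstream, downstream, len(rec.repeat_sequence), rec.flanking_variants
        )
        entries.append(
            CatalogEntry(
                allele=rec,
                reference_sequence=upstream + rec.repeat_sequence + downstream,
                flank_length=flank_length,
                upstream_used=len(upstream),
                downstream_used=len(downstream),
                truncated=truncated,
            )
        )
    return entries


def locus_definitions_from_records(records: Sequence[AlleleRecord]) -> list[LocusDefinition]:
    """Derive one LocusDefinition per locus (interval = union over alleles)."""
    by_locus: dict[str, list[AlleleRecord]] = {}
    for rec in records:
        by_locus.setdefault(rec.locus, []).append(rec)
    loci = []
    for name in sorted(by_locus):
        group = by_locus[name]
        chroms = {r.chromosome for r in group}
        if len(chroms) != 1:
            raise CatalogError(f"locus {name} spans multiple chromosomes: {sorted(chroms)}")
        classes = {r.locus_class for r in group}
        if len(classes) != 1:
            raise CatalogError(f"locus {name} has inconsistent classes: {sorted(classes)}")
        units = {r.unit_length for r in group}
        if len(units) != 1:
            raise CatalogError(f"locus {name} has inconsistent unit lengths: {sorted(units)}")
        start = min(r.repeat_interval[0] for r in group)
        end = max(r.repeat_interval[1] for r in group)
        loci.append(
            LocusDefinition(
                name=name,
                chromosome=chroms.pop(),
                reference_interval=(start, end),
                locus_class=classes.pop(),
                unit_length=units.pop(),
            )
        )
    return loci


# ---------------------------------------------------------------------------
# Catalog serialization: FASTA headers, TSV table, loci BED
# ---------------------------------------------------------------------------

MOTIF_SPACE_SUBSTITUTE = "_"


def format_catalog_header(entry: CatalogEntry) -> str:
    """Single-token FASTA header: accession then pipe-delimited key=value fields.

    Motif spaces are replaced by underscores so the header survives
    whitespace-splitting FASTA readers.
    """
    rec = entry.allele
    motif = rec.motif.serialize().replace(" ", MOTIF_SPACE_SUBSTITUTE)
    return (
        f"{rec.accession}|locus={rec.locus}|class={rec.locus_class}"
        f"|motif={motif}|designation={rec.designation.render()}"
        f"|unit={rec.unit_length}|up={entry.upstream_used}|truncated={int(entry.truncated)}"
    )


def parse_catalog_header(header: str) -> dict:
    """Inverse of :func:`format_catalog_header`."""
    token = header.split()[0].lstrip(">")
    accession, *fields = token.split("|")
    info: dict = {"accession": accession}
    for f in fields:
        if "=" not in f:
            raise CatalogError(f"malformed header field {f!r}")
        key, value = f.split("=", 1)
        info[key] = value
    info["motif"] = parse_bracketed_motif(
        info["motif"].replace(MOTIF_SPACE_SUBSTITUTE, " ")
    )
    info["designation"] = AlleleDesignation.from_string(info["designation"])
    info["unit"] = int(info.get("unit", 0))
    info["truncated"] = bool(int(info.get("truncated", 0)))
    return info


def write_catalog_fasta(entries: Sequence[CatalogEntry], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for entry in entries:
            fh.write(f">{format_catalog_header(entry)}\n")
            seq = entry.reference_sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_catalog_table(entries: Sequence[CatalogEntry], path: Union[str, Path]) -> None:
    columns = [
        "accession", "locus", "chrom", "start", "end",
        "repeat_seq", "variants", "motif", "designation",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for entry in entries:
            rec = entry.allele
            variants = ";".join(sorted(v.render() for v in rec.flanking_variants)) or "."
            fh.write(
                "\t".join(
                    [
                        rec.accession, rec.locus, rec.chromosome,
                        str(rec.repeat_interval[0]), str(rec.repeat_interval[1]),
                        rec.repeat_sequence, variants,
                        rec.motif.serialize(), rec.designation.render(),
                    ]
                )
                + "\n"
            )


def write_loci_bed(loci: Sequence[LocusDefinition], path: Union[str, Path]) -> None:
    """BED6-style: chrom, start, end, name, unit_length, locus_class."""
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                "\t".join(
                    [
                        locus.chromosome,
                        str(locus.reference_interval[0]),
                        str(locus.reference_interval[1]),
                        locus.name,
                        str(locus.unit_length),
                        locus.locus_class,
                    ]
                )
                + "\n"
            )


def read_loci_bed(path: Union[str, Path]) -> list[LocusDefinition]:
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise CatalogError(f"loci BED requires 6 columns, got {len(fields)}")
            loci.append(
                LocusDefinition(
                    name=fields[3],
                    chromosome=fields[0],
                    reference_interval=(int(fields[1]), int(fields[2])),
                    locus_class=fields[5],
                    unit_length=int(fields[4]),
                )
            )
    return loci


@dataclass
class Catalog:
    """Loaded allele reference: entries plus target locus definitions."""

    entries: list[CatalogEntry]
    loci: list[LocusDefinition]

    def __post_init__(self) -> None:
        self._by_locus: dict[str, list[CatalogEntry]] = {}
        for entry in self.entries:
            self._by_locus.setdefault(entry.allele.locus, []).append(entry)

    def entries_for(self, locus: str) -> list[CatalogEntry]:
        return self._by_locus.get(locus, [])

    def locus(self, name: str) -> LocusDefinition:
        for locus in self.loci:
            if locus.name == name:
                return locus
        raise KeyError(name)

    @classmethod
    def from_entries(cls, entries: Sequence[CatalogEntry], loci: Sequence[LocusDefinition]) -> "Catalog":
        return cls(entries=list(entries), loci=list(loci))

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "Catalog":
        """Load a catalog written by :func:`write_catalog`."""
        directory = Path(directory)
        loci = read_loci_bed(directory / "loci.bed")
        table: dict[str, dict] = {}
        with open(directory / "catalog.tsv") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                table[row["accession"]] = row
        locus_by_name = {l.name: l for l in loci}
        entries = []
        for rec in SeqIO.parse(str(directory / "alleles.fasta"), "fasta"):
            info = parse_catalog_header(rec.description)
            row = table[info["accession"]]
            # merged loci (e.g. DYS385ab) carry entries without their own BED row
            locus_def = locus_by_name.get(info["locus"])
            variants = frozenset(
                FlankingVariant.from_string(tok)
                for tok in row["variants"].split(";")
                if tok.strip() and tok.strip() != "."
            )
            repeat_seq = row["repeat_seq"]
            allele = AlleleRecord(
                accession=info["accession"],
                locus=info["locus"],
                chromosome=row["chrom"],
                repeat_interval=(int(row["start"]), int(row["end"])),
                repeat_sequence=repeat_seq,
                flanking_variants=variants,
                motif=info["motif"],
                designation=info["designation"],
                unit_length=info["unit"] or (locus_def.unit_length if locus_def else 4),
                locus_class=info.get(
                    "class", locus_def.locus_class if locus_def else AUTOSOMAL
                ),
            )
            sequence = str(rec.seq).upper()
            upstream_used = int(info.get("up", 0))
            entries.append(
                CatalogEntry(
                    allele=allele,
                    reference_sequence=sequence,
                    flank_length=max(upstream_used, len(sequence) - upstream_used - len(repeat_seq)),
                    upstream_used=upstream_used,
                    downstream_used=len(sequence) - upstream_used - len(repeat_seq),
                    truncated=info["truncated"],
                )
            )
        return cls(entries=entries, loci=loci)


def write_catalog(
    entries: Sequence[CatalogEntry],
    loci: Sequence[LocusDefinition],
    directory: Union[str, Path],
) -> None:
    """Write alleles.fasta, catalog.tsv and loci.bed to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_catalog_fasta(entries, directory / "alleles.fasta")
    write_catalog_table(entries, directory / "catalog.tsv")
    write_loci_bed(loci, directory / "loci.bed")
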