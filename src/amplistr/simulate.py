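"""Seeded synthetic data: toy allele catalogs and nanopore-like amplicon reads.

The fixture generator builds a miniature GenBank allele set plus a matching
reference genome so the whole pipeline is testable offline; it always
includes an isoallele pair (same length, different sequence), a microvariant
allele, a compound motif with a spacer, and a DYS385-like duplicated Y locus
pair.  The read simulator draws full-length amplicon reads from a specified
diploid/haploid truth profile with configurable substitution, insertion and
deletion rates plus optional minus-one-repeat PCR stutter, and emits FASTQ,
a pre-aligned SAM, and the matching ground-truth profile.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .catalog import (
    AUTOSOMAL,
    Y,
    Y_MERGED,
    AlleleRecord,
    Catalog,
    CatalogEntry,
    LocusDefinition,
    build_catalog,
    parse_genbank_records,
)
from .nomenclature import reverse_complement
from .report import GroundTruthProfile, TruthLocus

DYS385_A = "DYS385a"
DYS385_B = "DYS385b"
DYS385_MERGED = "DYS385ab"

_BASES = "ACGT"


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Error / stutter models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorModel:
    """Per-base error rates; deletions inside homopolymer runs >= 4 are boosted."""

    substitution: float = 0.0
    insertion: float = 0.0
    deletion: float = 0.0
    homopolymer_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in ("substitution", "insertion", "deletion"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.2:
                raise ValueError(f"{name} rate must lie in [0, 0.2], got {rate}")
        if self.homopolymer_multiplier < 1.0:
            raise ValueError("homopolymer_multiplier must be >= 1")


@dataclass(frozen=True)
class StutterModel:
    """PCR stutter: proportion of reads carrying one fewer whole repeat unit."""

    minus_one: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.minus_one < 0.5:
            raise ValueError("minus_one must lie in [0, 0.5)")


@dataclass(frozen=True)
class SimSampleSpec:
    """Truth profile for one simulated sample."""

    sample: str
    sex: str  # 'female' | 'male'
    truth: Mapping[str, tuple[str, ...]]  # locus -> 1-2 allele accessions
    depth: int = 100

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.depth < 1:
            raise ValueError("depth must be positive")


# ---------------------------------------------------------------------------
# Fixture catalog generation
# ---------------------------------------------------------------------------

@dataclass
class FixtureCatalog:
    """Toy GenBank allele set + mini reference + derived catalog and truth."""

    genbank_text: str
    reference: dict[str, str]
    records: list[AlleleRecord]
    loci: list[LocusDefinition]
    catalog: Catalog
    # locus -> accession -> length designation (the generator's truth table)
    truth_designations: dict[str, dict[str, str]]

    def write(self, directory: Union[str, Path]) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        gb = directory / "alleles.gb"
        gb.write_text(self.genbank_text)
        fasta = directory / "reference.fasta"
        with open(fasta, "w") as fh:
            for name, seq in self.reference.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        return {"genbank": gb, "reference": fasta}


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _random_unit(rng: random.Random, length: int) -> str:
    while True:
        unit = _random_seq(rng, length)
        if len(set(unit)) > 1:  # avoid homopolymer units
            return unit


def _variant_unit(rng: random.Random, unit: str) -> str:
    """One-substitution variant of a repeat unit."""
    pos = rng.randrange(len(unit))
    alt = rng.choice([b for b in _BASES if b != unit[pos]])
    return unit[:pos] + alt + unit[pos + 1 :]


def _genbank_record(
    accession: str,
    locus: str,
    chromosome: str,
    anchor_interval: tuple[int, int],
    repeat_sequence: str,
    motif_text: str,
    unit_length: int,
    locus_class: str,
    context_up: str,
    context_down: str,
    variants: str = "",
) -> SeqRecord:
    rec = SeqRecord(
        Seq(context_up + repeat_sequence + context_down),
        id=accession,
        name=accession,
        description=f"{locus} allele",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["date"] = "01-JAN-2026"
    qualifiers = {
        "locus": [locus],
        "chromosome": [chromosome],
        "genomic_interval": [f"{anchor_interval[0] + 1}..{anchor_interval[1]}"],
        "bracketed_motif": [motif_text],
        "repeat_unit_length": [str(unit_length)],
        "locus_class": [locus_class],
    }
    if variants:
        qualifiers["flanking_variants"] = [variants]
    rec.features.append(SeqFeature(FeatureLocation(0, len(rec.seq)), type="source",
                                   qualifiers={"organism": ["synthetic construct"]}))
    rec.features.append(
        SeqFeature(
            FeatureLocation(len(context_up), len(context_up) + len(repeat_sequence)),
            type="repeat_region",
            qualifiers=qualifiers,
        )
    )
    return rec


def make_fixture_catalog(
    n_loci: int = 5,
    alleles_per_locus: int = 4,
    unit_lengths: Sequence[int] = (4, 4, 5, 3, 4),
    seed: int = 0,
    flank_length: int = 150,
    locus_spacing: int = 900,
    context: int = 60,
) -> FixtureCatalog:
    """Build a deterministic toy catalog.

    ``n_loci`` autosomal loci are generated, then one plain Y locus with a
    compound (spacer-containing) motif and a DYS385-like duplicated pair are
    appended.  The first autosomal locus carries an isoallele pair, the
    second (when present) a microvariant allele.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = random.Random(seed)
    reference: dict[str, str] = {}
    loci: list[LocusDefinition] = []
    gb_records: list[SeqRecord] = []
    truth: dict[str, dict[str, str]] = {}
    acc_counter = 0

    def next_acc() -> str:
        nonlocal acc_counter
        acc_counter += 1
        return f"SIM{acc_counter:04d}"

    def add_locus(
        chrom_parts: list[str],
        chrom_name: str,
        name: str,
        unit_length: int,
        locus_class: str,
        allele_motifs: list[tuple[str, str]],  # (motif text, repeat sequence)
        extra_variant_allele: bool = False,
    ) -> LocusDefinition:
        upstream = _random_seq(rng, locus_spacing // 2)
        downstream = _random_seq(rng, locus_spacing // 2)
        ref_repeat = allele_motifs[0][1]
        start = sum(len(p) for p in chrom_parts) + len(upstream)
        chrom_parts.extend([upstream, ref_repeat, downstream])
        anchor = (start, start + len(ref_repeat))
        truth[name] = {}
        for i, (motif_text, repeat_seq) in enumerate(allele_motifs):
            acc = next_acc()
            variants = ""
            if extra_variant_allele and i == len(allele_motifs) - 1:
                # duplicate of allele 0's repeat distinguished only by a
                # flanking SNP five bases upstream of the repeat
                ref_base = upstream[-5]
                alt_base = rng.choice([b for b in _BASES if b != ref_base])
                variants = f"-5:{ref_base}>{alt_base}"
            gb_records.append(
                _genbank_record(
                    accession=acc,
                    locus=name,
                    chromosome=chrom_name,
                    anchor_interval=anchor,
                    repeat_sequence=repeat_seq,
                    motif_text=motif_text,
                    unit_length=unit_length,
                    locus_class=locus_class,
                    context_up=upstream[-context:],
                    context_down=downstream[:context],
                    variants=variants,
                )
            )
            spacer_bases = sum(
                int(tok[1:]) for tok in motif_text.split() if tok.startswith("N") and tok[1:].isdigit()
            )
            whole, rem = divmod(len(repeat_seq) - spacer_bases, unit_length)
            truth[name][acc] = f"{whole}.{rem}" if rem else str(whole)
        return LocusDefinition(
            name=name,
            chromosome=chrom_name,
            reference_interval=anchor,
            locus_class=locus_class,
            unit_length=unit_length,
        )

    # --- autosomal loci -----------------------------------------------------
    chromA_parts: list[str] = [_random_seq(rng, 300)]
    for idx in range(n_loci):
        unit_length = unit_lengths[idx % len(unit_lengths)]
        unit = _random_unit(rng, unit_length)
        base = rng.randint(8, 12)
        motifs: list[tuple[str, str]] = []
        for j in range(alleles_per_locus):
            count = base + j
            motifs.append((f"[{unit}]{count}", unit * count))
        if idx == 0 and alleles_per_locus >= 2:
            # isoallele of allele 0: same length, different sequence
            var = _variant_unit(rng, unit)
            motif_text = f"[{unit}]{base - 2} {var} {unit}"
            motifs.append((motif_text, unit * (base - 2) + var + unit))
            # duplicate of allele 0's repeat kept apart only by a flanking SNP
            motifs.append((f"[{unit}]{base}", unit * base))
        if idx == 1:
            # microvariant: trailing partial repeat of 2 bases (or 1 for dinucleotides)
            partial = unit[: 2 if unit_length > 2 else 1]
            motifs.append((f"[{unit}]{base + alleles_per_locus} {partial}",
                           unit * (base + alleles_per_locus) + partial))
        loci.append(
            add_locus(
                chromA_parts,
                "chrA",
                f"D{idx + 1}S{1000 + idx}",
                unit_length,
                AUTOSOMAL,
                motifs,
                extra_variant_allele=idx == 0 and alleles_per_locus >= 2,
            )
        )
    reference["chrA"] = "".join(chromA_parts) + _random_seq(rng, 300)

    # --- Y locus with a compound, spacer-containing motif -------------------
    chromY_parts: list[str] = [_random_seq(rng, 300)]
    unit = _random_unit(rng, 4)
    spacer = _random_seq(rng, 6)
    y_motifs = []
    for j in range(max(2, alleles_per_locus - 1)):
        a, b = 5 + j, 7
        motif_text = f"[{unit}]{a} N6 [{unit}]{b}"
        y_motifs.append((motif_text, unit * a + spacer + unit * b))
    loci.append(add_locus(chromY_parts, "chrY_sim", "DYSSIM1", 4, Y, y_motifs))

    # --- DYS385-like duplicated pair ----------------------------------------
    unit = _random_unit(rng, 4)
    pair_motifs = []
    for j in range(max(4, alleles_per_locus)):
        count = 11 + j
        pair_motifs.append((f"[{unit}]{count}", unit * count))
    # site A carries the records; site B shares its amplicon-scale flanks
    site_a_upstream = _random_seq(rng, locus_spacing // 2)
    site_a_downstream = _random_seq(rng, locus_spacing // 2)
    ref_repeat = pair_motifs[0][1]
    start_a = sum(len(p) for p in chromY_parts) + len(site_a_upstream)
    chromY_parts.extend([site_a_upstream, ref_repeat, site_a_downstream])
    anchor_a = (start_a, start_a + len(ref_repeat))
    start_b = sum(len(p) for p in chromY_parts) + len(site_a_upstream)
    chromY_parts.extend([site_a_upstream, ref_repeat, site_a_downstream])
    anchor_b = (start_b, start_b + len(ref_repeat))
    truth[DYS385_MERGED] = {}
    for motif_text, repeat_seq in pair_motifs:
        acc = next_acc()
        gb_records.append(
            _genbank_record(
                accession=acc,
                locus=DYS385_MERGED,
                chromosome="chrY_sim",
                anchor_interval=anchor_a,
                repeat_sequence=repeat_seq,
                motif_text=motif_text,
                unit_length=4,
                locus_class=Y_MERGED,
                context_up=site_a_upstream[-context:],
                context_down=site_a_downstream[:context],
            )
        )
        truth[DYS385_MERGED][acc] = str(len(repeat_seq) // 4)
    loci.append(
        LocusDefinition(
            name=DYS385_A, chromosome="chrY_sim", reference_interval=anchor_a,
            locus_class=Y_MERGED, unit_length=4,
        )
    )
    loci.append(
        LocusDefinition(
            name=DYS385_B, chromosome="chrY_sim", reference_interval=anchor_b,
            locus_class=Y_MERGED, unit_length=4,
        )
    )
    reference["chrY_sim"] = "".join(chromY_parts) + _random_seq(rng, 300)

    handle = io.StringIO()
    SeqIO.write(gb_records, handle, "genbank")
    genbank_text = handle.getvalue()

    records, errors = parse_genbank_records(io.StringIO(genbank_text))
    if errors:  # pragma: no cover - generator bug guard
        raise SimulationError(f"fixture records failed to parse: {errors}")
    entries = build_catalog(records, reference, flank_length=flank_length)
    catalog = Catalog.from_entries(entries, loci)
    return FixtureCatalog(
        genbank_text=genbank_text,
        reference=reference,
        records=records,
        loci=loci,
        catalog=catalog,
        truth_designations=truth,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _homopolymer_runs(seq: str) -> list[int]:
    """Length of the maximal homopolymer run containing each position."""
    runs = [1] * len(seq)
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        for k in range(i, j):
            runs[k] = j - i
        i = j
    return runs


def apply_errors(
    template: str, model: ErrorModel, rng: random.Random
) -> tuple[str, list[tuple[str, int]], int]:
    """Apply positional substitution/insertion/deletion errors to a template.

    Returns the read sequence, a condensed CIGAR (M/I/D ops) describing the
    read against the template, and the number of leading template bases lost
    to deletions (to be folded into the mapping position).
    """
    out: list[str] = []
    cigar: list[list] = []

    def add(op: str, length: int = 1) -> None:
        if cigar and cigar[-1][0] == op:
            cigar[-1][1] += length
        else:
            cigar.append([op, length])

    runs = _homopolymer_runs(template) if model.homopolymer_multiplier > 1 else None
    for i, base in enumerate(template):
        if model.insertion and rng.random() < model.insertion:
            out.append(rng.choice(_BASES))
            add("I")
        p_del = model.deletion
        if runs is not None and runs[i] >= 4:
            p_del = min(0.95, p_del * model.homopolymer_multiplier)
        if p_del and rng.random() < p_del:
            add("D")
            continue
        if model.substitution and rng.random() < model.substitution:
            out.append(rng.choice([b for b in _BASES if b != base]))
        else:
            out.append(base)
        add("M")
    # SAM forbids alignments without aligned bases and leading/trailing
    # deletions are meaningless: trim them into the position offset.
    lead = 0
    while cigar and cigar[0][0] == "D":
        lead += cigar.pop(0)[1]
    while cigar and cigar[-1][0] == "D":
        cigar.pop()
    return "".join(out), [tuple(c) for c in cigar], lead


def _stutter_template(repeat: str, unit_length: int) -> str:
    """Drop one whole repeat unit (the leading one) from the repeat sequence."""
    if len(repeat) < 2 * unit_length:
        return repeat
    return repeat[unit_length:]


@dataclass
class SimResult:
    fastq: str
    sam: str
    truth: GroundTruthProfile
    reads_per_locus: dict[str, int] = field(default_factory=dict)

    def write(self, directory: Union[str, Path], prefix: str = "sim") -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "fastq": directory / f"{prefix}.fastq",
            "sam": directory / f"{prefix}.sam",
        }
        paths["fastq"].write_text(self.fastq)
        paths["sam"].write_text(self.sam)
        return paths


def simulate_reads(
    spec: SimSampleSpec,
    catalog: Catalog,
    error: ErrorModel = ErrorModel(),
    stutter: StutterModel = StutterModel(),
    seed: int = 0,
    amplicon_flank: int = 80,
    second_allele_fraction: float = 0.5,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> SimResult:
    """Simulate amplicon reads for one sample; deterministic under a fixed seed.

    Heterozygous loci draw each read's template allele binomially
    (``second_allele_fraction`` for the second allele).  Reads are emitted in
    both orientations at random; the SAM records carry the true origin with a
    CIGAR consistent with the applied errors.
    """
    rng = random.Random(seed)
    entries_by_acc: dict[str, CatalogEntry] = {
        e.allele.accession: e for e in catalog.entries
    }
    loci_by_name = {l.name: l for l in catalog.loci}
    merged_sites = [
        loci_by_name[name] for name in (DYS385_A, DYS385_B) if name in loci_by_name
    ]

    fastq_lines: list[str] = []
    sam_lines: list[str] = []
    truth_profile = GroundTruthProfile(sample=spec.sample)
    reads_per_locus: dict[str, int] = {}

    # header
    lengths: dict[str, int] = {}
    for locus in catalog.loci:
        end = locus.reference_interval[1] + 5000
        lengths[locus.chromosome] = max(lengths.get(locus.chromosome, 0), end)
    if contig_lengths:
        lengths.update(contig_lengths)
    sam_lines.append("@HD\tVN:1.6\tSO:unknown")
    for chrom in sorted(lengths):
        sam_lines.append(f"@SQ\tSN:{chrom}\tLN:{lengths[chrom]}")

    for locus_name in spec.truth:
        accessions = tuple(spec.truth[locus_name])
        if not 1 <= len(accessions) <= 2:
            raise SimulationError(f"{locus_name}: specify 1 or 2 allele accessions")
        for acc in accessions:
            if acc not in entries_by_acc:
                raise SimulationError(f"allele {acc} absent from catalog")
        first = entries_by_acc[accessions[0]]
        locus_class = first.allele.locus_class
        if spec.sex == "female" and locus_class in (Y, Y_MERGED):
            raise SimulationError(
                f"female spec {spec.sample} lists Y-class locus {locus_name}"
            )
        is_merged = locus_class == Y_MERGED
        if locus_class == Y and len(accessions) != 1:
            raise SimulationError(f"non-merged Y locus {locus_name} takes one allele")

        truth_profile.loci[locus_name] = TruthLocus(
            alleles=tuple(
                entries_by_acc[a].allele.designation.render() for a in accessions
            ),
            motifs=tuple(
                entries_by_acc[a].allele.motif.serialize() for a in accessions
            ),
        )
        reads_per_locus[locus_name] = spec.depth

        for i in range(spec.depth):
            if len(accessions) == 2:
                allele_idx = 1 if rng.random() < second_allele_fraction else 0
            else:
                allele_idx = 0
            entry = entries_by_acc[accessions[allele_idx]]
            rec = entry.allele
            repeat = rec.repeat_sequence
            if stutter.minus_one and rng.random() < stutter.minus_one:
                repeat = _stutter_template(repeat, rec.unit_length)
            up_len = min(amplicon_flank, entry.upstream_used)
            down_len = min(amplicon_flank, entry.downstream_used)
            upstream = entry.reference_sequence[
                entry.upstream_used - up_len : entry.upstream_used
            ]
            down_start = entry.upstream_used + len(rec.repeat_sequence)
            downstream = entry.reference_sequence[down_start : down_start + down_len]
            template = upstream + repeat + downstream

            read_seq, cigar_ops, lead = apply_errors(template, error, rng)
            if not read_seq:
                continue  # vanishingly unlikely full deletion
            # genomic placement: merged pair alternates its two sites
            if is_merged and merged_sites:
                site = merged_sites[allele_idx % len(merged_sites)]
                chrom = site.chromosome
                pos = site.reference_interval[0] - up_len + lead
            else:
                chrom = rec.chromosome
                pos = rec.repeat_interval[0] - up_len + lead
            reverse = rng.random() < 0.5
            name = f"{spec.sample}:{locus_name}:{i}"
            cigar = "".join(f"{length}{op}" for op, length in cigar_ops)
            flag = 16 if reverse else 0
            sam_lines.append(
                "\t".join(
                    [
                        name, str(flag), chrom, str(pos + 1), "60", cigar,
                        "*", "0", "0", read_seq, "I" * len(read_seq),
                    ]
                )
            )
            fq_seq = reverse_complement(read_seq) if reverse else read_seq
            fastq_lines.extend([f"@{name}", fq_seq, "+", "I" * len(fq_seq)])

    return SimResult(
        fastq="\n".join(fastq_lines) + ("\n" if fastq_lines else ""),
        sam="\n".join(sam_lines) + "\n",
        truth=truth_profile,
        reads_per_locus=reads_per_locus,
    )
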