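"""Shared fixtures: deterministic toy catalog, GenBank builders, SAM text."""

from __future__ import annotations

import io
import textwrap

import pytest

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from amplistr.simulate import FixtureCatalog, make_fixture_catalog


@pytest.fixture(scope="session")
def fixture_catalog() -> FixtureCatalog:
    """Toy catalog: 5 autosomal + 1 Y + DYS385-like pair, seeded."""
    return make_fixture_catalog(seed=1)


@pytest.fixture(scope="session")
def panel_catalog() -> FixtureCatalog:
    """Larger panel (10 callable loci) used by end-to-end recovery tests."""
    return make_fixture_catalog(n_loci=8, seed=11)


def genbank_text(
    accession: str,
    locus: str = "D9S9000",
    chromosome: str = "chr9",
    genomic_interval: str = "101..140",
    repeat: str = "AGAT" * 10,
    motif: str = "[AGAT]10",
    unit_length: int = 4,
    locus_class: str = "autosomal",
    context_up: str = "C" * 30,
    context_down: str = "G" * 30,
    variants: str = "",
    omit_feature: bool = False,
    omit_locus: bool = False,
) -> str:
    """Render a single synthetic GenBank record as flat-file text."""
    rec = SeqRecord(
        Seq(context_up + repeat + context_down),
        id=accession,
        name=accession,
        description=f"{locus} test allele",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["date"] = "01-JAN-2026"
    if not omit_feature:
        qualifiers = {
            "chromosome": [chromosome],
            "genomic_interval": [genomic_interval],
            "bracketed_motif": [motif],
            "repeat_unit_length": [str(unit_length)],
            "locus_class": [locus_class],
        }
        if not omit_locus:
            qualifiers["locus"] = [locus]
        if variants:
            qualifiers["flanking_variants"] = [variants]
        rec.features.append(
            SeqFeature(
                FeatureLocation(len(context_up), len(context_up) + len(repeat)),
                type="repeat_region",
                qualifiers=qualifiers,
            )
        )
    handle = io.StringIO()
    SeqIO.write([rec], handle, "genbank")
    return handle.getvalue()


SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:chr1\tLN:100000\n@SQ\tSN:chr2\tLN:100000\n"


def sam_line(
    name: str,
    flag: int,
    rname: str = "chr1",
    pos_1based: int = 1,
    cigar: str = "50M",
    seq: str = "A" * 50,
    mapq: int = 60,
) -> str:
    if flag & 4:
        return f"{name}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n"
    return f"{name}\t{flag}\t{rname}\t{pos_1based}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*\n"


def dp_semiglobal(pattern: str, text: str) -> int:
    """Quadratic-DP oracle: best edit distance of pattern vs any text substring.

    Independent of the production scorer (plain nested loops, no bit tricks).
    """
    m, n = len(pattern), len(text)
    prev = [0] * (n + 1)  # free text prefix: D[0][j] = 0
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        pc = pattern[i - 1]
        for j in range(1, n + 1):
            cost = 0 if (pc == text[j - 1] and pc != "N") else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return min(prev)  # free text suffix
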