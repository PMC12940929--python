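import random

import pytest

from amplistr.caller import HOMOZYGOUS, call_locus, meta_from_entries
from amplistr.catalog import AUTOSOMAL, Y_MERGED, build_catalog
from amplistr.matcher import count_alleles
from amplistr.intake import LocusReadSet, MappedRead, PRIMARY
from amplistr.nomenclature import expand_motif
from amplistr.simulate import (
    DYS385_MERGED,
    ErrorModel,
    SimSampleSpec,
    SimulationError,
    StutterModel,
    apply_errors,
    make_fixture_catalog,
    simulate_reads,
)


class TestFixtureCatalog:
    def test_seed_determinism_byte_identical(self):
        a = make_fixture_catalog(n_loci=5, alleles_per_locus=4, seed=1)
        b = make_fixture_catalog(n_loci=5, alleles_per_locus=4, seed=1)
        assert a.genbank_text == b.genbank_text
        assert a.reference == b.reference
        c = make_fixture_catalog(n_loci=5, alleles_per_locus=4, seed=2)
        assert c.genbank_text != a.genbank_text

    def test_isoallele_pair_constructed(self, fixture_catalog):
        records = [r for r in fixture_catalog.records if r.locus == "D1S1000"]
        by_len = {}
        for rec in records:
            by_len.setdefault(len(rec.repeat_sequence), []).append(rec)
        iso_groups = [g for g in by_len.values() if len(g) >= 2]
        assert iso_groups
        group = iso_groups[0]
        sequences = {r.repeat_sequence for r in group}
        designations = {r.designation.render() for r in group}
        assert len(designations) == 1  # equal length -> equal designation
        assert len(sequences) >= 2 or any(r.flanking_variants for r in group)

    def test_microvariant_present(self, fixture_catalog):
        assert any(
            "." in d
            for locus in fixture_catalog.truth_designations.values()
            for d in locus.values()
        )

    def test_dys385_pair_present(self, fixture_catalog):
        names = {l.name for l in fixture_catalog.loci}
        assert {"DYS385a", "DYS385b"} <= names
        assert fixture_catalog.catalog.entries_for(DYS385_MERGED)

    def test_build_catalog_designations_match_truth_table(self, fixture_catalog):
        """The generator's recorded truth is the oracle for catalog output."""
        entries = build_catalog(fixture_catalog.records, fixture_catalog.reference, 100)
        for entry in entries:
            rec = entry.allele
            expected = fixture_catalog.truth_designations[rec.locus][rec.accession]
            assert rec.designation.render() == expected

    def test_repeats_embedded_at_recorded_coordinates(self, fixture_catalog):
        for locus in fixture_catalog.loci:
            start, end = locus.reference_interval
            embedded = fixture_catalog.reference[locus.chromosome][start:end]
            lookup = DYS385_MERGED if locus.locus_class == Y_MERGED else locus.name
            reference_alleles = [
                r.repeat_sequence
                for r in fixture_catalog.records
                if r.locus == lookup
            ]
            assert embedded in reference_alleles

    def test_motifs_expand(self, fixture_catalog):
        for rec in fixture_catalog.records:
            assert expand_motif(rec.motif) == rec.repeat_sequence


class TestApplyErrors:
    def test_no_error_is_identity(self):
        rng = random.Random(0)
        read, cigar, lead = apply_errors("ACGTACGT", ErrorModel(), rng)
        assert read == "ACGTACGT"
        assert cigar == [("M", 8)] and lead == 0

    def test_substitution_rate_matches_binomial_expectation(self):
        # empirical mismatch fraction within 3 sigma of the configured 0.05
        rng = random.Random(7)
        template = "".join(rng.choice("ACGT") for _ in range(250))
        model = ErrorModel(substitution=0.05)
        mismatches = bases = 0
        for _ in range(1000):
            read, _, _ = apply_errors(template, model, rng)
            assert len(read) == len(template)
            mismatches += sum(1 for a, b in zip(read, template) if a != b)
            bases += len(template)
        rate = mismatches / bases
        # substituted bases are drawn from the 3 alternatives, so every
        # substitution event is a visible mismatch
        sigma = (0.05 * 0.95 / bases) ** 0.5
        assert abs(rate - 0.05) < max(3 * sigma, 0.005)

    def test_deletion_shortens_and_cigar_consistent(self):
        rng = random.Random(3)
        template = "".join(rng.choice("ACGT") for _ in range(500))
        read, cigar, lead = apply_errors(template, ErrorModel(deletion=0.1), rng)
        assert len(read) < len(template)
        query = sum(n for op, n in cigar if op in "MI")
        ref = sum(n for op, n in cigar if op in "MD") + lead
        assert query == len(read)
        assert ref <= len(template)

    def test_homopolymer_multiplier_boosts_deletions(self):
        rng = random.Random(5)
        template = "A" * 2000
        model = ErrorModel(deletion=0.05, homopolymer_multiplier=3.0)
        deleted = 0
        for _ in range(50):
            read, _, _ = apply_errors(template, model, rng)
            deleted += len(template) - len(read)
        rate = deleted / (50 * len(template))
        assert rate > 0.10  # ~0.15 expected, far above the 0.05 base rate

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            ErrorModel(substitution=0.5)
        with pytest.raises(ValueError):
            ErrorModel(homopolymer_multiplier=0.5)
        with pytest.raises(ValueError):
            StutterModel(minus_one=0.5)


def _reads_from_fastq(fastq):
    lines = fastq.splitlines()
    return lines[1::4]


class TestSimulateReads:
    def test_seed_determinism_byte_identical(self, fixture_catalog):
        spec = SimSampleSpec(
            sample="s", sex="male", truth={"D3S1002": ("SIM0013",)}, depth=30
        )
        kwargs = dict(
            error=ErrorModel(substitution=0.05, insertion=0.02, deletion=0.03),
            stutter=StutterModel(minus_one=0.1),
        )
        a = simulate_reads(spec, fixture_catalog.catalog, seed=9, **kwargs)
        b = simulate_reads(spec, fixture_catalog.catalog, seed=9, **kwargs)
        assert a.fastq == b.fastq and a.sam == b.sam
        c = simulate_reads(spec, fixture_catalog.catalog, seed=10, **kwargs)
        assert c.fastq != a.fastq

    def test_noiseless_reads_are_exact_amplicon_substrings(self, fixture_catalog):
        catalog = fixture_catalog.catalog
        spec = SimSampleSpec(
            sample="s", sex="male", truth={"D3S1002": ("SIM0013",)}, depth=50
        )
        result = simulate_reads(spec, catalog, seed=1)
        (entry,) = [
            e for e in catalog.entries_for("D3S1002")
            if e.allele.accession == "SIM0013"
        ]
        from amplistr.nomenclature import reverse_complement

        hits = 0
        for seq in _reads_from_fastq(result.fastq):
            assert (
                seq in entry.reference_sequence
                or reverse_complement(seq) in entry.reference_sequence
            )
            hits += 1
        assert hits == 50

    def test_truth_profile_emitted(self, fixture_catalog):
        spec = SimSampleSpec(
            sample="s",
            sex="male",
            truth={"D1S1000": ("SIM0001", "SIM0003"), "DYSSIM1": ("SIM0024",)},
            depth=10,
        )
        result = simulate_reads(spec, fixture_catalog.catalog, seed=2)
        assert result.truth.loci["D1S1000"].alleles == ("11", "13")
        assert result.truth.loci["DYSSIM1"].alleles == ("12",)
        assert result.truth.loci["D1S1000"].motifs is not None

    def test_stutter_stays_below_threshold_at_15_percent(self, fixture_catalog):
        """15% minus-one stutter normalizes to ~0.18 of the top allele -> still hom."""
        catalog = fixture_catalog.catalog
        locus = catalog.locus("D5S1004")
        entries = catalog.entries_for("D5S1004")
        spec = SimSampleSpec(
            sample="s", sex="male", truth={"D5S1004": ("SIM0022",)}, depth=1000
        )
        result = simulate_reads(
            spec, catalog, stutter=StutterModel(minus_one=0.15), seed=13
        )
        reads = [
            MappedRead(
                name=f"r{i}", sequence=seq, qualities=None, reference_name="chrA",
                reference_start=0, reference_end=10**6, category=PRIMARY,
            )
            for i, seq in enumerate(_reads_from_fastq(result.fastq))
        ]
        row = count_alleles(LocusReadSet(locus=locus, reads=reads), entries)
        call = call_locus(locus, row.counts, meta_from_entries(entries))
        assert call.zygosity == HOMOZYGOUS
        assert call.designations == ("11",)
        minus_one = row.counts["SIM0021"]  # designation 10
        assert 0 < minus_one / row.counts["SIM0022"] < 0.4

    def test_female_with_y_locus_rejected(self, fixture_catalog):
        spec = SimSampleSpec(
            sample="s", sex="female", truth={"DYSSIM1": ("SIM0024",)}, depth=5
        )
        with pytest.raises(SimulationError):
            simulate_reads(spec, fixture_catalog.catalog, seed=1)

    def test_unknown_accession_rejected(self, fixture_catalog):
        spec = SimSampleSpec(
            sample="s", sex="male", truth={"D1S1000": ("NOPE",)}, depth=5
        )
        with pytest.raises(SimulationError):
            simulate_reads(spec, fixture_catalog.catalog, seed=1)

    def test_sam_parses_and_spans_locus(self, tmp_path, fixture_catalog):
        from amplistr.intake import extract_locus_reads, load_alignments

        spec = SimSampleSpec(
            sample="s", sex="male", truth={"D2S1001": ("SIM0008",)}, depth=20
        )
        result = simulate_reads(spec, fixture_catalog.catalog, seed=4)
        paths = result.write(tmp_path)
        reads = load_alignments(paths["sam"])
        assert len(reads) == 20
        sets = extract_locus_reads(reads, fixture_catalog.catalog.loci)
        assert len(sets["D2S1001"]) == 20
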