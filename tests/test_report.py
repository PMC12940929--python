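import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amplistr.caller import (
    AlleleCall,
    HETEROZYGOUS,
    HOMOZYGOUS,
    HAPLOTYPE,
    LocusCall,
    MERGED,
    Profile,
)
from amplistr.catalog import AUTOSOMAL, Y
from amplistr.report import (
    CONVENTIONAL,
    ConcordanceCounts,
    GroundTruthProfile,
    LENGTH,
    Metrics,
    PAPER,
    SEQUENCE,
    TruthLocus,
    compare_profiles,
    compute_metrics,
    format_percent,
    read_ground_truth,
    read_profile,
    write_ground_truth,
    write_profile,
)
from amplistr.matcher import AlleleCountTable, CountRow
from amplistr.pipeline import profile_alignments
from amplistr.simulate import SimSampleSpec, simulate_reads


def allele(designation, raw=100, norm=1.0, motif=""):
    return AlleleCall(
        accession=f"acc{designation}",
        designation=designation,
        motif=motif or f"[AGAT]{designation}",
        raw=raw,
        normalized=norm,
    )


def aut_call(locus, designations, zygosity=None):
    if zygosity is None:
        zygosity = HOMOZYGOUS if len(designations) == 1 else HETEROZYGOUS
    return LocusCall(
        locus=locus,
        locus_class=AUTOSOMAL,
        zygosity=zygosity,
        alleles=tuple(allele(d) for d in designations),
    )


def y_call(locus, designations, merged=False):
    from amplistr.catalog import Y_MERGED

    return LocusCall(
        locus=locus,
        locus_class=Y_MERGED if merged else Y,
        zygosity=MERGED if merged else HAPLOTYPE,
        alleles=tuple(allele(d) for d in designations),
    )


def profile_of(*calls, sample="s1"):
    profile = Profile(sample=sample)
    for call in calls:
        profile.add(call)
    return profile


def truth_of(sample="s1", **loci):
    return GroundTruthProfile(
        sample=sample,
        loci={name: TruthLocus(alleles=tuple(alleles)) for name, alleles in loci.items()},
    )


class TestCompareProfiles:
    def test_exact_het_match(self):
        tallies = compare_profiles(
            profile_of(aut_call("L", ("16", "17"))), truth_of(L=("16", "17"))
        )
        assert tallies[AUTOSOMAL] == ConcordanceCounts(tp=2, fp=0, fn=0)

    def test_concordant_homozygote_expands_to_two(self):
        tallies = compare_profiles(
            profile_of(aut_call("L", ("16",))), truth_of(L=("16",))
        )
        assert tallies[AUTOSOMAL] == ConcordanceCounts(tp=2, fp=0, fn=0)

    def test_spurious_second_allele_conventional(self):
        # predicted het {16,15} vs truth hom {16} -> {16,16}
        tallies = compare_profiles(
            profile_of(aut_call("L", ("16", "15"))),
            truth_of(L=("16",)),
            mode=CONVENTIONAL,
        )
        assert tallies[AUTOSOMAL] == ConcordanceCounts(tp=1, fp=1, fn=1)

    def test_spurious_second_allele_paper_mode(self):
        # the published tally dialect books the extra allele as FP only
        tallies = compare_profiles(
            profile_of(aut_call("L", ("16", "15"))), truth_of(L=("16",)), mode=PAPER
        )
        assert tallies[AUTOSOMAL] == ConcordanceCounts(tp=1, fp=1, fn=0)

    def test_missed_microvariant_paper_mode(self):
        # predicted hom {5} vs truth {5, 2.2}: TP 1, FN 1, no FP
        tallies = compare_profiles(
            profile_of(aut_call("L", ("5",))), truth_of(L=("5", "2.2")), mode=PAPER
        )
        assert tallies[AUTOSOMAL] == ConcordanceCounts(tp=1, fp=0, fn=1)

    def test_missed_second_allele_conventional_adds_fp(self):
        tallies = compare_profiles(
            profile_of(aut_call("L", ("5",))),
            truth_of(L=("5", "2.2")),
            mode=CONVENTIONAL,
        )
        assert tallies[AUTOSOMAL] == ConcordanceCounts(tp=1, fp=1, fn=1)

    def test_substituted_y_allele_is_fp_without_fn_in_paper_mode(self):
        # DYS390-style: truth 23, predicted 22
        tallies = compare_profiles(
            profile_of(y_call("DYS390", ("22",))), truth_of(DYS390=("23",)), mode=PAPER
        )
        assert tallies[Y] == ConcordanceCounts(tp=0, fp=1, fn=0)
        conventional = compare_profiles(
            profile_of(y_call("DYS390", ("22",))),
            truth_of(DYS390=("23",)),
            mode=CONVENTIONAL,
        )
        assert conventional[Y] == ConcordanceCounts(tp=0, fp=1, fn=1)

    def test_merged_y_two_spurious_alleles(self):
        # DYS385ab-style: truth {11}, predicted {12, 13} -> 2 FP, 0 FN (paper)
        tallies = compare_profiles(
            profile_of(y_call("DYS385ab", ("12", "13"), merged=True)),
            truth_of(DYS385ab=("11",)),
            mode=PAPER,
        )
        assert tallies[Y] == ConcordanceCounts(tp=0, fp=2, fn=0)

    def test_y_dropout_is_fn(self):
        tallies = compare_profiles(
            profile_of(
                LocusCall(locus="DYSX", locus_class=Y, zygosity="no-call", alleles=())
            ),
            truth_of(DYSX=("14",)),
            mode=PAPER,
        )
        assert tallies[Y] == ConcordanceCounts(tp=0, fp=0, fn=1)

    def test_predicted_locus_missing_from_truth_skipped(self):
        tallies = compare_profiles(
            profile_of(aut_call("L", ("16",)), aut_call("M", ("9",))),
            truth_of(L=("16",)),
        )
        assert tallies[AUTOSOMAL].tp == 2

    def test_sequence_level_stricter_than_length(self):
        predicted = profile_of(
            LocusCall(
                locus="L",
                locus_class=AUTOSOMAL,
                zygosity=HETEROZYGOUS,
                alleles=(
                    allele("11", motif="[TCTA]11"),
                    allele("11", motif="[TCTA]9 TCTG TCTA"),
                ),
            )
        )
        truth = GroundTruthProfile(
            sample="s1",
            loci={
                "L": TruthLocus(
                    alleles=("11", "11"), motifs=("[TCTA]11", "[TCTA]11")
                )
            },
        )
        length_tp = compare_profiles(predicted, truth, level=LENGTH)[AUTOSOMAL].tp
        seq_tp = compare_profiles(predicted, truth, level=SEQUENCE)[AUTOSOMAL].tp
        assert seq_tp <= length_tp
        assert (length_tp, seq_tp) == (2, 1)

    def test_sequence_level_requires_motifs(self):
        with pytest.raises(ValueError):
            compare_profiles(
                profile_of(aut_call("L", ("11",))),
                truth_of(L=("11",)),
                level=SEQUENCE,
            )


class TestComputeMetrics:
    def test_swab_y_row(self):
        metrics = compute_metrics(ConcordanceCounts(tp=154, fp=4, fn=0))
        assert metrics.recall == 1.0
        assert round(metrics.precision * 100, 1) == 97.5
        assert round(metrics.f1 * 100, 1) == 98.7

    def test_blood_autosomal_row(self):
        metrics = compute_metrics(ConcordanceCounts(tp=798, fp=0, fn=1))
        assert metrics.precision == 1.0
        assert round(metrics.recall * 100, 1) == 99.9
        assert round(metrics.f1 * 100, 1) == 99.9

    def test_perfect_profile(self):
        metrics = compute_metrics(ConcordanceCounts(tp=37, fp=0, fn=0))
        assert metrics.precision == metrics.recall == metrics.f1 == 1.0

    def test_zero_denominators_safe(self):
        empty = compute_metrics(ConcordanceCounts())
        assert empty.precision is None and empty.recall is None and empty.f1 is None
        no_calls = compute_metrics(ConcordanceCounts(tp=0, fp=0, fn=5))
        assert no_calls.precision is None and no_calls.recall == 0.0

    @given(
        st.integers(min_value=0, max_value=1000),
        st.integers(min_value=0, max_value=1000),
        st.integers(min_value=0, max_value=1000),
        st.integers(min_value=1, max_value=20),
    )
    @settings(deadline=None)
    def test_scale_free(self, tp, fp, fn, k):
        a = compute_metrics(ConcordanceCounts(tp, fp, fn))
        b = compute_metrics(ConcordanceCounts(tp * k, fp * k, fn * k))
        for x, y in ((a.precision, b.precision), (a.recall, b.recall), (a.f1, b.f1)):
            if x is None:
                assert y is None
            else:
                assert y == pytest.approx(x)

    def test_additivity_across_samples(self):
        per_sample = [
            ConcordanceCounts(tp=44, fp=0, fn=0),
            ConcordanceCounts(tp=40, fp=2, fn=1),
            ConcordanceCounts(tp=44, fp=1, fn=0),
        ]
        total = sum(per_sample, ConcordanceCounts())
        assert (total.tp, total.fp, total.fn) == (128, 3, 1)


def test_format_percent():
    assert format_percent(0.975, 1) == "97.5%"
    assert format_percent(0.9953, 2) == "99.53%"
    assert format_percent(1.0, 1) == "100.0%"
    assert format_percent(None) == "NA"


class TestProfileIO:
    def test_table2_style_rows(self, tmp_path, fixture_catalog):
        """DYS390-style fixture: uncalled 0.7 allele and called 1.0 allele rows."""
        catalog = fixture_catalog.catalog
        entries = catalog.entries_for("DYSSIM1")
        top, second = entries[0], entries[1]
        from amplistr.caller import call_locus, meta_from_entries

        locus = catalog.locus("DYSSIM1")
        raw = {top.allele.accession: 2865, second.allele.accession: 2112}
        call = call_locus(locus, raw, meta_from_entries(entries))
        profile = profile_of(call, sample="blood07")
        table = AlleleCountTable(rows={"DYSSIM1": CountRow(counts=raw)})
        out = tmp_path / "p.tsv"
        write_profile(profile, table, catalog, out)
        lines = out.read_text().splitlines()
        assert len(lines) == 3  # header + 2 detected alleles
        rows = [l.split("\t") for l in lines[1:]]
        called_row = [r for r in rows if r[8] == "called"][0]
        uncalled_row = [r for r in rows if r[8] == "uncalled"][0]
        assert called_row[6] == "2865" and called_row[7] == "1"
        assert uncalled_row[6] == "2112" and uncalled_row[7] == "0.7"

    def test_empty_profile_header_only(self, tmp_path, fixture_catalog):
        out = tmp_path / "empty.tsv"
        write_profile(
            Profile(sample="s"), AlleleCountTable(), fixture_catalog.catalog, out
        )
        assert len(out.read_text().splitlines()) == 1

    def test_round_trip(self, tmp_path, fixture_catalog):
        """Writer then reader reproduces the called Profile exactly."""
        catalog = fixture_catalog.catalog
        spec = SimSampleSpec(
            sample="s1",
            sex="male",
            truth={
                "D1S1000": ("SIM0001", "SIM0003"),
                "DYSSIM1": ("SIM0025",),
                "DYS385ab": ("SIM0028", "SIM0030"),
            },
            depth=40,
        )
        result = simulate_reads(spec, catalog, seed=5)
        paths = result.write(tmp_path)
        pr = profile_alignments(paths["sam"], catalog, "s1")
        # drop no-call loci: they carry no rows by design
        called = Profile(sample="s1")
        for name, call in pr.profile.calls.items():
            if call.alleles:
                called.add(call)
        out = tmp_path / "profile.tsv"
        write_profile(called, pr.count_table, catalog, out)
        assert read_profile(out) == called


class TestGroundTruthIO:
    def test_round_trip(self, tmp_path):
        profiles = [
            GroundTruthProfile(
                sample="s1",
                loci={
                    "L1": TruthLocus(alleles=("11", "13")),
                    "L2": TruthLocus(alleles=("9",), motifs=("[AGAT]9",)),
                },
            ),
            GroundTruthProfile(
                sample="s2", loci={"L1": TruthLocus(alleles=("12",))}
            ),
        ]
        path = tmp_path / "truth.tsv"
        write_ground_truth(profiles, path)
        loaded = read_ground_truth(path)
        assert set(loaded) == {"s1", "s2"}
        assert loaded["s1"].loci["L1"].alleles == ("11", "13")
        assert loaded["s1"].loci["L2"].motifs == ("[AGAT]9",)
        assert loaded["s2"].loci["L1"].alleles == ("12",)
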