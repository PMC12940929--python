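"""Profile reporting and concordance benchmarking.

Predicted profiles are written as a TSV with one row per detected allele
(raw and normalized counts, called flag, zygosity).  Benchmarking compares
predicted against ground-truth profiles at the length (designation) or
sequence (motif) level and tallies TP/FP/FN separately for autosomal and
Y-class loci, from which precision, recall and F1 are derived.

Two tally dialects are provided:

* ``paper`` (default): a reported allele that substitutes for a truth allele
  counts as a false positive only; a truth allele is a false negative only
  when the prediction reported fewer alleles than the truth holds.  This is
  the dialect needed to reproduce published forensic benchmarking tables in
  which substituted calls show FP without a matching FN.
* ``conventional``: symmetric multiset difference after homozygote
  expansion (every unmatched truth allele is an FN).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .caller import LocusCall, Profile
from .catalog import AUTOSOMAL, Y, Y_MERGED, Catalog
from .matcher import AlleleCountTable
from .caller import normalize_counts

logger = logging.getLogger(__name__)

PAPER = "paper"
CONVENTIONAL = "conventional"
LENGTH = "length"
SEQUENCE = "sequence"


@dataclass(frozen=True)
class TruthLocus:
    """Expected alleles at one locus: designations, optionally motifs."""

    alleles: tuple[str, ...]
    motifs: Optional[tuple[str, ...]] = None


@dataclass
class GroundTruthProfile:
    sample: str
    loci: dict[str, TruthLocus] = field(default_factory=dict)


@dataclass(frozen=True)
class ConcordanceCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConcordanceCounts") -> "ConcordanceCounts":
        return ConcordanceCounts(
            tp=self.tp + other.tp, fp=self.fp + other.fp, fn=self.fn + other.fn
        )


@dataclass(frozen=True)
class Metrics:
    """Precision, recall, F1 as fractions in [0,1]; None when undefined."""

    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]


def compute_metrics(counts: ConcordanceCounts) -> Metrics:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = harmonic mean.

    Zero denominators yield None markers rather than division failures.
    """
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(precision=precision, recall=recall, f1=f1)


def format_percent(fraction: Optional[float], decimals: int = 1) -> str:
    """Render a fraction as a percentage string (e.g. 0.9874 -> '98.7%')."""
    if fraction is None:
        return "NA"
    value = round(fraction * 100, decimals)
    return f"{value:.{decimals}f}%"


def _multiset_intersection_size(a: Sequence[str], b: Sequence[str]) -> int:
    return sum((Counter(a) & Counter(b)).values())


def _class_slots(locus_class: str) -> int:
    return 2 if locus_class == AUTOSOMAL else 1


def _expand(alleles: Sequence[str], locus_class: str) -> list[str]:
    """Expand a homozygote written once to two allele calls (autosomal only)."""
    alleles = list(alleles)
    if locus_class == AUTOSOMAL and len(alleles) == 1:
        return alleles * 2
    return alleles


def _predicted_alleles(call: LocusCall, level: str) -> list[str]:
    if level == SEQUENCE:
        return [" ".join(a.motif.split()) for a in call.alleles]
    return [a.designation for a in call.alleles]


def _truth_alleles(truth: TruthLocus, level: str, locus: str) -> list[str]:
    if level == SEQUENCE:
        if truth.motifs is None:
            raise ValueError(f"sequence-level comparison requires truth motifs at {locus}")
        return [" ".join(m.split()) for m in truth.motifs]
    return list(truth.alleles)


def _tally_locus(
    predicted: Sequence[str],
    truth: Sequence[str],
    locus_class: str,
    mode: str,
) -> ConcordanceCounts:
    truth_exp = _expand(truth, locus_class)
    pred_exp = _expand(predicted, locus_class)
    tp = _multiset_intersection_size(pred_exp, truth_exp)
    if mode == CONVENTIONAL:
        fp = len(pred_exp) - tp
        fn = len(truth_exp) - tp
        return ConcordanceCounts(tp=tp, fp=fp, fn=fn)
    # paper dialect: FP counts reported alleles whose value is absent from the
    # truth; FN counts truth alleles left uncovered because the prediction
    # reported fewer alleles than the truth holds (a substitution is FP only).
    truth_values = set(truth_exp)
    fp = sum(1 for a in predicted if a not in truth_values)
    unmatched_truth = len(truth_exp) - tp
    shortfall = max(0, len(truth_exp) - len(predicted))
    fn = min(unmatched_truth, shortfall)
    return ConcordanceCounts(tp=tp, fp=fp, fn=fn)


def compare_profiles(
    predicted: Profile,
    truth: GroundTruthProfile,
    level: str = LENGTH,
    mode: str = PAPER,
) -> dict[str, ConcordanceCounts]:
    """Tally TP/FP/FN over the loci shared by prediction and ground truth.

    Returns separate tallies keyed 'autosomal' and 'Y' (merged DYS385ab
    counts toward Y). Predicted loci absent from the truth are skipped with
    a warning, mirroring benchmarking limited to available ground truth.
    """
    if level not in (LENGTH, SEQUENCE):
        raise ValueError(f"unknown comparison level {level!r}")
    if mode not in (PAPER, CONVENTIONAL):
        raise ValueError(f"unknown comparison mode {mode!r}")
    tallies = {AUTOSOMAL: ConcordanceCounts(), Y: ConcordanceCounts()}
    for locus, call in predicted.calls.items():
        if locus not in truth.loci:
            logger.warning(
                "locus %s predicted for %s but absent from ground truth; skipped",
                locus,
                predicted.sample,
            )
            continue
        truth_locus = truth.loci[locus]
        counts = _tally_locus(
            _predicted_alleles(call, level),
            _truth_alleles(truth_locus, level, locus),
            call.locus_class,
            mode,
        )
        key = AUTOSOMAL if call.locus_class == AUTOSOMAL else Y
        tallies[key] = tallies[key] + counts
    return tallies


# ---------------------------------------------------------------------------
# Profile TSV I/O
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = [
    "sample", "locus", "class", "accession", "designation", "motif",
    "raw", "norm", "called", "zygosity", "flags",
]


def _format_norm(value: float, decimals: int) -> str:
    return f"{round(value, decimals):g}"


def write_profile(
    profile: Profile,
    count_table: AlleleCountTable,
    catalog: Catalog,
    path: Union[str, Path],
    display_decimals: int = 1,
) -> None:
    """One row per detected allele, ordered by locus panel then descending norm.

    Raw counts are written verbatim; normalized values are rounded for
    display only (full precision lives in the Profile object).
    """
    meta = {
        e.allele.accession: (e.allele.designation.render(), e.allele.motif.serialize())
        for e in catalog.entries
    }
    with open(path, "w") as fh:
        fh.write("\t".join(PROFILE_COLUMNS) + "\n")
        for locus_name, call in profile.calls.items():
            row = count_table.rows.get(locus_name)
            raw_counts = dict(row.counts) if row else {
                a.accession: a.raw for a in call.alleles
            }
            normalized = normalize_counts(raw_counts)
            called = {a.accession for a in call.alleles}
            for acc, raw, norm in normalized.ranked():
                designation, motif = meta.get(acc, (acc, ""))
                fh.write(
                    "\t".join(
                        [
                            profile.sample,
                            locus_name,
                            call.locus_class,
                            acc,
                            designation,
                            motif.replace(" ", "_") or ".",
                            str(raw),
                            _format_norm(norm, display_decimals),
                            "called" if acc in called else "uncalled",
                            call.zygosity,
                            ",".join(call.flags) or ".",
                        ]
                    )
                    + "\n"
                )


def read_profile(path: Union[str, Path]) -> Profile:
    """Rebuild a Profile from a report TSV (called rows only)."""
    from .caller import AlleleCall, LocusCall

    sample = ""
    per_locus: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            sample = row["sample"]
            locus = row["locus"]
            if locus not in per_locus:
                per_locus[locus] = {
                    "class": row["class"],
                    "zygosity": row["zygosity"],
                    "flags": tuple(row["flags"].split(",")) if row["flags"] != "." else (),
                    "alleles": [],
                    "raws": {},
                }
                order.append(locus)
            info = per_locus[locus]
            if row["called"] == "called":
                info["alleles"].append(
                    AlleleCall(
                        accession=row["accession"],
                        designation=row["designation"],
                        motif=row["motif"].replace("_", " ") if row["motif"] != "." else "",
                        raw=int(row["raw"]),
                        normalized=float(row["norm"]),
                    )
                )
            info["raws"][row["accession"]] = int(row["raw"])
    profile = Profile(sample=sample)
    for locus in order:
        info = per_locus[locus]
        # Recover full-precision normalized values from the raw counts.
        normalized = normalize_counts(info["raws"])
        alleles = tuple(
            AlleleCall(
                accession=a.accession,
                designation=a.designation,
                motif=a.motif,
                raw=a.raw,
                normalized=normalized.values[a.accession][1],
            )
            for a in info["alleles"]
        )
        profile.add(
            LocusCall(
                locus=locus,
                locus_class=info["class"],
                zygosity=info["zygosity"],
                alleles=alleles,
                flags=info["flags"],
            )
        )
    return profile


# ---------------------------------------------------------------------------
# Ground truth TSV I/O
# ---------------------------------------------------------------------------

def write_ground_truth(profiles: Sequence[GroundTruthProfile], path: Union[str, Path]) -> None:
    """TSV dialect: sample, locus, allele1[, allele2][, motif1, motif2]."""
    with open(path, "w") as fh:
        fh.write("sample\tlocus\tallele1\tallele2\tmotif1\tmotif2\n")
        for profile in profiles:
            for locus, tl in profile.loci.items():
                alleles = list(tl.alleles) + ["."] * (2 - len(tl.alleles))
                motifs = (
                    [m.replace(" ", "_") for m in tl.motifs] if tl.motifs else []
                )
                motifs += ["."] * (2 - len(motifs))
                fh.write(
                    "\t".join([profile.sample, locus] + alleles[:2] + motifs[:2]) + "\n"
                )


def read_ground_truth(path: Union[str, Path]) -> dict[str, GroundTruthProfile]:
    profiles: dict[str, GroundTruthProfile] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            sample = row["sample"]
            profile = profiles.setdefault(sample, GroundTruthProfile(sample=sample))
            alleles = tuple(
                row[k] for k in ("allele1", "allele2") if row.get(k, ".") not in (".", "")
            )
            motifs = tuple(
                row[k].replace("_", " ")
                for k in ("motif1", "motif2")
                if row.get(k, ".") not in (".", "")
            )
            profile.loci[row["locus"]] = TruthLocus(
                alleles=alleles, motifs=motifs or None
            )
    return profiles


# ---------------------------------------------------------------------------
# Benchmark summary
# ---------------------------------------------------------------------------

def write_benchmark_summary(
    tallies: Mapping[str, Mapping[str, ConcordanceCounts]],
    path: Union[str, Path],
    decimals: int = 1,
) -> None:
    """Per-dataset and overall TP/FP/FN + metrics, one row per (dataset, class)."""
    with open(path, "w") as fh:
        fh.write("dataset\tclass\tTP\tFP\tFN\trecall\tprecision\tF1\n")
        totals = {AUTOSOMAL: ConcordanceCounts(), Y: ConcordanceCounts()}
        for dataset in tallies:
            for cls in (AUTOSOMAL, Y):
                counts = tallies[dataset].get(cls, ConcordanceCounts())
                totals[cls] = totals[cls] + counts
                metrics = compute_metrics(counts)
                fh.write(
                    "\t".join(
                        [
                            dataset, cls,
                            str(counts.tp), str(counts.fp), str(counts.fn),
                            format_percent(metrics.recall, decimals),
                            format_percent(metrics.precision, decimals),
                            format_percent(metrics.f1, decimals),
                        ]
                    )
                    + "\n"
                )
        for cls in (AUTOSOMAL, Y):
            metrics = compute_metrics(totals[cls])
            fh.write(
                "\t".join(
                    [
                        "overall", cls,
                        str(totals[cls].tp), str(totals[cls].fp), str(totals[cls].fn),
                        format_percent(metrics.recall, decimals),
                        format_percent(metrics.precision, decimals),
                        format_percent(metrics.f1, decimals),
                    ]
                )
                + "\n"
            )
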