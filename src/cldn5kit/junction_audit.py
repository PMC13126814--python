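"""Five-step splice-junction validation from spliced alignments.

Audits candidate splice junctions the way a skeptical analyst would
before believing an unannotated event: (1) donor/acceptor motif
classification on the transcript strand, (2) emulation of aligner-style
junction filters (per-motif overhang and support thresholds), (3)
annotation context (intra-exonic / annotated-intron / exon-spanning /
intergenic), (4) alignment-level inspection (unique support, overhang,
MAPQ distribution), and (5) strand specificity inferred from
proper-pair SAM flags (99/147 = forward fragment, 83/163 = reverse)
under the library's strandedness protocol.

Coordinate convention: introns are reported 1-based with inclusive
ends — ``intron_start`` is the first intronic base and ``intron_end``
the last, matching the ``chr:start-end`` style of genome browsers.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SpliceJunction",
    "StrandCall",
    "MotifCall",
    "FilterVerdict",
    "FilterThresholds",
    "DEFAULT_THRESHOLDS",
    "extract_junctions",
    "junction_motif",
    "strand_from_flags",
    "annotation_context",
    "star_like_filter",
    "audit_report",
    "load_genome",
    "load_annotation",
    "junction_table",
]

logger = logging.getLogger(__name__)

REF_CONSUMING = {0, 2, 3, 7, 8}       # M, D, N, =, X
ALIGNED_OPS = {0, 7, 8}               # M, =, X
INFORMATIVE_FLAGS = {99, 147, 83, 163}
SEMI_CANONICAL = {"GT-AG", "GC-AG", "AT-AC"}


@dataclass
class SpliceJunction:
    """One junction's accumulated evidence across all supporting reads."""

    chrom: str
    intron_start: int    # 1-based, first intronic base
    intron_end: int      # 1-based, last intronic base
    read_support: int = 0
    unique_support: int = 0
    max_overhang: int = 0
    donor: str = ""
    acceptor: str = ""
    motif_class: str = "noncanonical"
    strand: str = "unknown"
    flag_counts: dict[int, int] = field(default_factory=dict)
    mapqs: list[int] = field(default_factory=list)
    supporting_reads: list[tuple[str, int]] = field(default_factory=list)  # (qname, flag)

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError("intron_start must not exceed intron_end")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)

    @property
    def intron_length(self) -> int:
        return self.intron_end - self.intron_start + 1


@dataclass(frozen=True)
class MotifCall:
    donor: str
    acceptor: str
    motif_class: str
    strand_used: str          # orientation the classification was read on
    ambiguous: bool = False   # both orientations looked (semi-)canonical


@dataclass(frozen=True)
class StrandCall:
    strand: str                       # '+', '-' or 'unknown'
    support_fraction: float           # majority fraction among informative pairs
    orientation_counts: dict[str, int]  # fragment-strand counts {'+': n, '-': n}
    flag_counts: dict[int, int]
    n_informative: int
    n_uninformative: int


@dataclass(frozen=True)
class FilterThresholds:
    """Aligner-style per-motif-class junction filter thresholds.

    These emulate the shape of a spliced aligner's default junction
    filters (stricter for noncanonical junctions); they do not claim
    bit-compatibility with any particular tool.
    """

    overhang_min: Mapping[str, int] = field(
        default_factory=lambda: {
            "GT-AG": 12, "GC-AG": 12, "AT-AC": 12, "noncanonical": 30,
        }
    )
    count_min: Mapping[str, int] = field(
        default_factory=lambda: {
            "GT-AG": 1, "GC-AG": 1, "AT-AC": 1, "noncanonical": 3,
        }
    )


DEFAULT_THRESHOLDS = FilterThresholds()


@dataclass(frozen=True)
class FilterVerdict:
    verdict: str                 # 'pass' or 'fail'
    reasons: tuple[str, ...]


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------

def load_genome(fasta_path: str | os.PathLike) -> dict[str, str]:
    """Reference sequences as a chrom -> uppercase string mapping."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def load_annotation(gff3_path: str | os.PathLike):
    """Load gene models from GFF3 into an in-memory gffutils database."""
    import gffutils

    return gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def _iter_alignments(alignments) -> Iterable[pysam.AlignedSegment]:
    if isinstance(alignments, (str, os.PathLike)):
        with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
            yield from fh
    else:
        yield from alignments


# ---------------------------------------------------------------------------
# Step 0: junction extraction from CIGAR reference-skips
# ---------------------------------------------------------------------------

def _read_junctions(read: pysam.AlignedSegment) -> list[tuple[int, int, int]]:
    """(intron_start, intron_end, overhang) for each N op of one read.

    The reference is walked op by op; M/=/X/D/N consume reference,
    I and soft clips do not, hard clips are ignored.  Overhang is the
    smaller of the aligned (M/=/X) base counts flanking the skip.
    """
    if read.is_unmapped or not read.cigartuples:
        return []
    # aligned bases between consecutive N ops
    segments: list[int] = [0]
    skips: list[tuple[int, int]] = []  # (ref_pos_before_skip, skip_len)
    pos = read.reference_start  # 0-based
    for op, length in read.cigartuples:
        if op == 3:  # N
            skips.append((pos, length))
            segments.append(0)
            pos += length
        else:
            if op in ALIGNED_OPS:
                segments[-1] += length
            if op in REF_CONSUMING:
                pos += length
    out = []
    for i, (ref_pos, skip_len) in enumerate(skips):
        # ref_pos is 0-based position of the first skipped base
        start = ref_pos + 1            # 1-based first intronic base
        end = ref_pos + skip_len       # 1-based last intronic base
        overhang = min(segments[i], segments[i + 1])
        out.append((start, end, overhang))
    return out


def _is_unique(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    if read.mapping_quality < min_mapq:
        return False
    try:
        if read.get_tag("NH") > 1:
            return False
    except KeyError:
        pass
    return True


def extract_junctions(
    alignments,
    min_overhang: int = 1,
    min_mapq: int = 0,
) -> dict[tuple[str, int, int], SpliceJunction]:
    """Collect splice junctions from reference-skip (N) CIGAR operations.

    ``alignments`` is a SAM path or an iterable of pysam records.
    Junctions are keyed by (chrom, intron_start, intron_end); a read
    contributes to ``read_support`` when its overhang at the junction
    meets ``min_overhang``, and additionally to ``unique_support`` when
    it maps uniquely (MAPQ >= ``min_mapq`` and NH tag <= 1).  Malformed
    records are counted, logged and skipped.
    """
    junctions: dict[tuple[str, int, int], SpliceJunction] = {}
    n_bad = 0
    it = iter(_iter_alignments(alignments))
    while True:
        try:
            read = next(it)
        except StopIteration:
            break
        except (ValueError, OSError) as exc:
            n_bad += 1
            logger.warning("skipping malformed alignment record: %s", exc)
            continue
        try:
            found = _read_junctions(read)
        except (ValueError, TypeError) as exc:
            n_bad += 1
            logger.warning("skipping record %s: %s", read.query_name, exc)
            continue
        if not found:
            continue
        chrom = read.reference_name
        for start, end, overhang in found:
            if overhang < min_overhang:
                continue
            key = (chrom, start, end)
            j = junctions.get(key)
            if j is None:
                j = junctions[key] = SpliceJunction(
                    chrom=chrom, intron_start=start, intron_end=end
                )
            j.read_support += 1
            if _is_unique(read, min_mapq):
                j.unique_support += 1
            j.max_overhang = max(j.max_overhang, overhang)
            j.flag_counts[read.flag] = j.flag_counts.get(read.flag, 0) + 1
            j.mapqs.append(read.mapping_quality)
            j.supporting_reads.append((read.query_name, read.flag))
    if n_bad:
        logger.warning("extract_junctions: %d malformed record(s) skipped", n_bad)
    return junctions


# ---------------------------------------------------------------------------
# Step 1: motif classification
# ---------------------------------------------------------------------------

def _classify(donor: str, acceptor: str) -> str:
    pair = f"{donor}-{acceptor}"
    return pair if pair in SEMI_CANONICAL else "noncanonical"


def junction_motif(
    j: SpliceJunction, genome: Mapping[str, str]
) -> MotifCall:
    """Donor/acceptor dinucleotides and motif class on the transcript strand.

    For minus-strand junctions the intron's plus-strand sequence is
    reverse-complemented, so the donor is read from the intron's 3' end
    on the reference.  Strand-unknown junctions are classified on the
    orientation (if exactly one) that yields a canonical or
    semi-canonical class; if both orientations do, the call is ambiguous
    and reported noncanonical with the ambiguity flag set.
    """
    seq = genome.get(j.chrom)
    if seq is None:
        raise ValueError(f"chromosome {j.chrom!r} not in reference")
    if j.intron_start < 1 or j.intron_end > len(seq):
        raise ValueError(
            f"junction {j.chrom}:{j.intron_start}-{j.intron_end} outside reference"
        )
    first2 = seq[j.intron_start - 1 : j.intron_start + 1]
    last2 = seq[j.intron_end - 2 : j.intron_end]

    def oriented(strand: str) -> tuple[str, str]:
        if strand == "+":
            return first2, last2
        return str(Seq(last2).reverse_complement()), str(Seq(first2).reverse_complement())

    if j.strand in ("+", "-"):
        donor, acceptor = oriented(j.strand)
        return MotifCall(donor, acceptor, _classify(donor, acceptor), j.strand)

    calls = {s: oriented(s) for s in ("+", "-")}
    hits = [s for s, (d, a) in calls.items() if _classify(d, a) != "noncanonical"]
    if len(hits) == 1:
        d, a = calls[hits[0]]
        return MotifCall(d, a, _classify(d, a), hits[0])
    d, a = calls["+"]
    return MotifCall(d, a, "noncanonical", "unknown", ambiguous=len(hits) == 2)


# ---------------------------------------------------------------------------
# Step 5: strand specificity from proper-pair flags
# ---------------------------------------------------------------------------

def _fragment_strand(flag: int) -> str | None:
    """Fragment reference strand from one proper-pair flag, or None."""
    if flag in (99, 147):
        return "+"
    if flag in (83, 163):
        return "-"
    return None


def strand_from_flags(
    records: Sequence[pysam.AlignedSegment] | Sequence[tuple[str, int]],
    library_type: str = "unstranded",
) -> StrandCall:
    """Infer the transcript strand of a junction from its supporting pairs.

    Fragment orientation per pair: flags (99, 147) place the fragment on
    the forward reference strand, (83, 163) on the reverse.  The mapping
    to transcript strand depends on the library protocol: ``FR`` reads
    the transcript strand directly from the fragment strand, ``RF``
    inverts it, and ``unstranded`` data carry no strand information
    (strand is reported unknown whatever the counts).  Pairs whose flags
    are not among the four proper-pair values are counted uninformative.
    """
    if library_type not in ("unstranded", "FR", "RF"):
        raise ValueError(f"unknown library_type {library_type!r}")
    flag_counts: dict[int, int] = {}
    per_fragment: dict[str, str] = {}
    n_uninformative_pairs: set[str] = set()
    for rec in records:
        if isinstance(rec, tuple):
            qname, flag = rec
        else:
            qname, flag = rec.query_name, rec.flag
        flag_counts[flag] = flag_counts.get(flag, 0) + 1
        strand = _fragment_strand(flag)
        if strand is None:
            n_uninformative_pairs.add(qname)
            logger.debug("uninformative flag %d on %s", flag, qname)
            continue
        prev = per_fragment.get(qname)
        if prev is not None and prev != strand:
            # contradictory mate flags: drop the pair
            del per_fragment[qname]
            n_uninformative_pairs.add(qname)
            continue
        per_fragment[qname] = strand
    counts = {"+": 0, "-": 0}
    for s in per_fragment.values():
        counts[s] += 1
    n_informative = counts["+"] + counts["-"]
    n_uninformative = len(n_uninformative_pairs - set(per_fragment))

    if library_type == "unstranded" or n_informative == 0:
        return StrandCall("unknown", 0.0, counts, flag_counts, n_informative, n_uninformative)

    frag_major = "+" if counts["+"] >= counts["-"] else "-"
    frac = counts[frag_major] / n_informative
    if library_type == "FR":
        transcript = frag_major
    else:  # RF
        transcript = "-" if frag_major == "+" else "+"
    return StrandCall(transcript, frac, counts, flag_counts, n_informative, n_uninformative)


# ---------------------------------------------------------------------------
# Step 3: annotation context
# ---------------------------------------------------------------------------

def annotation_context(j: SpliceJunction, annotation) -> str:
    """Place the intron relative to gene models.

    Returns ``"intra-exonic"`` when the intron lies entirely inside one
    annotated exon, ``"annotated-intron"`` when it exactly matches the
    gap between consecutive exons of a transcript, ``"exon-spanning"``
    when it overlaps exon boundaries otherwise, and ``"intergenic"``
    when no gene overlaps it.
    """
    start, end = j.intron_start, j.intron_end

    genes = list(annotation.region((j.chrom, start - 1, end), featuretype="gene"))
    if not genes:
        return "intergenic"

    exons = list(annotation.region((j.chrom, start - 1, end), featuretype="exon"))
    for exon in exons:
        if exon.start <= start and end <= exon.end:
            return "intra-exonic"

    # exact match against introns between consecutive exons of a transcript
    for ttype in ("mRNA", "transcript"):
        for tx in annotation.features_of_type(ttype):
            if tx.seqid != j.chrom:
                continue
            tx_exons = sorted(
                annotation.children(tx, featuretype="exon"), key=lambda e: e.start
            )
            for e1, e2 in zip(tx_exons, tx_exons[1:]):
                if e1.end + 1 == start and end == e2.start - 1:
                    return "annotated-intron"

    return "exon-spanning"


# ---------------------------------------------------------------------------
# Step 2: aligner-style filter emulation
# ---------------------------------------------------------------------------

def star_like_filter(
    j: SpliceJunction, thresholds: FilterThresholds = DEFAULT_THRESHOLDS
) -> FilterVerdict:
    """Would default aligner-style junction filters keep this junction?

    Fails when the overhang or unique support falls below the threshold
    for the junction's motif class (boundaries inclusive: meeting the
    threshold passes).  Every violated rule is listed as a reason.
    """
    cls = j.motif_class if j.motif_class in SEMI_CANONICAL else "noncanonical"
    reasons = []
    o_min = thresholds.overhang_min[cls]
    c_min = thresholds.count_min[cls]
    if j.max_overhang < o_min:
        reasons.append(f"overhang {j.max_overhang} below {o_min} for {cls}")
    if j.unique_support < c_min:
        reasons.append(f"unique support {j.unique_support} below {c_min} for {cls}")
    return FilterVerdict("fail" if reasons else "pass", tuple(reasons))


# ---------------------------------------------------------------------------
# Five-step report
# ---------------------------------------------------------------------------

def _gene_strand_at(annotation, chrom: str, start: int, end: int) -> str | None:
    genes = list(annotation.region((chrom, start - 1, end), featuretype="gene"))
    strands = {g.strand for g in genes}
    if len(strands) == 1:
        return strands.pop()
    return None


def audit_report(
    alignments,
    genome: Mapping[str, str] | str | os.PathLike,
    annotation,
    library_type: str = "unstranded",
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    min_mapq: int = 0,
) -> list[dict]:
    """Run the full five-step audit on every junction in the alignments.

    Returns one dict per junction with the five evidence sections and an
    overall verdict: ``"genuine-candidate"`` when the motif is at least
    semi-canonical, at least one uniquely mapped read supports the
    junction, and the inferred strand matches the overlapping gene (a
    strand call of unknown is accepted for unstranded libraries).
    """
    if isinstance(genome, (str, os.PathLike)):
        genome = load_genome(genome)
    if isinstance(annotation, (str, os.PathLike)):
        annotation = load_annotation(annotation)

    report = []
    junctions = extract_junctions(alignments, min_mapq=min_mapq)
    for key in sorted(junctions):
        j = junctions[key]
        entry: dict = {
            "chrom": j.chrom,
            "intron_start": j.intron_start,
            "intron_end": j.intron_end,
        }
        try:
            strand_call = strand_from_flags(j.supporting_reads, library_type)
            j.strand = strand_call.strand
            motif = junction_motif(j, genome)
            j.donor, j.acceptor = motif.donor, motif.acceptor
            j.motif_class = motif.motif_class
            verdict = star_like_filter(j, thresholds)
            context = annotation_context(j, annotation)
            mapqs = np.asarray(j.mapqs)
            entry.update(
                {
                    "motif": {
                        "donor": motif.donor,
                        "acceptor": motif.acceptor,
                        "motif_class": motif.motif_class,
                        "strand_used": motif.strand_used,
                        "ambiguous": motif.ambiguous,
                    },
                    "filter_emulation": {
                        "verdict": verdict.verdict,
                        "reasons": list(verdict.reasons),
                    },
                    "annotation_context": context,
                    "alignment_inspection": {
                        "read_support": j.read_support,
                        "unique_support": j.unique_support,
                        "max_overhang": j.max_overhang,
                        "mapq_min": int(mapqs.min()),
                        "mapq_median": float(np.median(mapqs)),
                        "mapq_max": int(mapqs.max()),
                    },
                    "strand_specificity": {
                        "strand": strand_call.strand,
                        "support_fraction": strand_call.support_fraction,
                        "orientation_counts": strand_call.orientation_counts,
                        "flag_counts": {str(k): v for k, v in sorted(strand_call.flag_counts.items())},
                        "n_informative": strand_call.n_informative,
                        "n_uninformative": strand_call.n_uninformative,
                    },
                }
            )
            gene_strand = _gene_strand_at(annotation, j.chrom, j.intron_start, j.intron_end)
            strand_ok = (
                strand_call.strand == "unknown"
                if library_type == "unstranded"
                else (gene_strand is not None and strand_call.strand == gene_strand)
            )
            genuine = (
                motif.motif_class in SEMI_CANONICAL
                and j.unique_support >= 1
                and strand_ok
            )
            entry["gene_strand"] = gene_strand
            entry["overall_verdict"] = "genuine-candidate" if genuine else "not-supported"
        except Exception as exc:  # junction-level isolation
            logger.warning("audit failed for %s: %s", key, exc)
            entry["error"] = str(exc)
        report.append(entry)
    return report


def junction_table(junctions: Mapping[tuple[str, int, int], SpliceJunction]):
    """Junctions as a BED-like DataFrame with both coordinate conventions.

    ``intron_start``/``intron_end`` are 1-based inclusive; ``bed_start``/
    ``bed_end`` are the 0-based half-open equivalents.
    """
    import pandas as pd

    rows = []
    for key in sorted(junctions):
        j = junctions[key]
        rows.append(
            {
                "chrom": j.chrom,
                "intron_start": j.intron_start,
                "intron_end": j.intron_end,
                "bed_start": j.intron_start - 1,
                "bed_end": j.intron_end,
                "read_support": j.read_support,
                "unique_support": j.unique_support,
                "max_overhang": j.max_overhang,
                "strand": j.strand,
                "motif_class": j.motif_class,
                "donor": j.donor,
                "acceptor": j.acceptor,
            }
        )
    return pd.DataFrame(rows)
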