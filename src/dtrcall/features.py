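"""Small exactly-specified sequence calculators.

Covers the annotation-side arithmetic that accompanies terminus mapping in
phage genome papers: intein splicing coordinates, tape-measure tail-length
prediction, tail-fiber length ranges, programmed -1 frameshift slippery
sites, codon/tRNA coverage, GC content, and a whole-genome DNA identity
statistic computed from tabular alignment segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .genome import GenomeInterval, gc_content, reverse_complement  # noqa: F401 (gc re-export)

__all__ = [
    "InteinSpan",
    "AlignmentSegment",
    "TRNASet",
    "splice_intein",
    "tape_measure_tail_length",
    "fiber_length_range",
    "find_slippery_sites",
    "codon_trna_coverage",
    "genome_identity",
    "pairwise_identity",
    "segments_from_blast6",
    "gc_content",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class InteinSpan:
    """Inclusive 1-based residue span of an intein within its precursor."""

    start_res: int
    end_res: int

    def __post_init__(self) -> None:
        if not 1 < self.start_res <= self.end_res:
            raise ValueError(
                f"intein span must satisfy 1 < start <= end, got {self}"
            )

    def __len__(self) -> int:
        return self.end_res - self.start_res + 1


def splice_intein(
    precursor_length: int,
    span: InteinSpan | Tuple[int, int],
    precursor_seq: Optional[str] = None,
) -> Tuple[int, int] | Tuple[int, int, str]:
    """Lengths of the excised intein and the spliced mature protein.

    Inteins are internal self-splicing elements: the span may touch neither
    residue 1 nor the precursor terminus.  When ``precursor_seq`` is given,
    the mature sequence (N-extein + C-extein concatenated) is returned too.

    >>> splice_intein(909, (131, 471))
    (341, 568)
    """
    if not isinstance(span, InteinSpan):
        span = InteinSpan(*span)
    if span.end_res >= precursor_length:
        raise ValueError(
            f"intein span {span} must end before the precursor terminus "
            f"({precursor_length} residues): inteins are internal"
        )
    intein_length = len(span)
    mature_length = precursor_length - intein_length
    if precursor_seq is None:
        return intein_length, mature_length
    if len(precursor_seq) != precursor_length:
        raise ValueError("precursor_seq length disagrees with precursor_length")
    mature_seq = precursor_seq[: span.start_res - 1] + precursor_seq[span.end_res:]
    return intein_length, mature_length, mature_seq


def tape_measure_tail_length(length_aa: int, rise_per_residue: float = 0.15) -> int:
    """Predicted tail length in nm from a tape measure protein.

    Tail tape measure proteins set tail length at ~0.15 nm per residue of
    alpha helix; a 1,964-residue protein predicts a 295 nm tail.
    """
    if length_aa <= 0:
        raise ValueError("protein length must be positive")
    return round(length_aa * rise_per_residue)


def fiber_length_range(
    length_aa: int, aa_per_nm: Tuple[float, float] = (12.0, 20.0)
) -> Tuple[int, int]:
    """Plausible tail-fiber length range in nm for a candidate fiber protein.

    Well-characterised phage tail fibers pack roughly 12-20 residues per nm
    of fiber, so an L-residue protein suggests a fiber between L/20 and
    L/12 nm (bounds rounded up to whole nm).
    """
    if length_aa <= 0:
        raise ValueError("protein length must be positive")
    lo_aa, hi_aa = min(aa_per_nm), max(aa_per_nm)
    return math.ceil(length_aa / hi_aa), math.ceil(length_aa / lo_aa)


def _is_slippery_heptamer(h: str) -> bool:
    """Canonical -1 frameshift heptamer X XXY YYZ: N1==N2==N3 and N4==N5==N6."""
    return len(h) == 7 and h[0] == h[1] == h[2] and h[3] == h[4] == h[5]


def find_slippery_sites(
    dna: str,
    motifs: Optional[Sequence[str]] = ("AAAAAAC",),
    region: Optional[GenomeInterval] = None,
) -> List[int]:
    """0-based positions of slippery heptamers enabling -1 frameshifting.

    With explicit ``motifs``, each must be a 7-mer of the X XXY YYZ form (or
    any literal 7-mer the caller vouches for by matching that form).  With
    ``motifs=None`` a generic scan reports every heptamer whose first and
    second base triplets are homogeneous.
    """
    dna = dna.upper()
    if region is not None:
        offset = region.start
        dna = dna[region.start: region.end]
    else:
        offset = 0
    positions: List[int] = []
    if motifs is None:
        for i in range(len(dna) - 6):
            if _is_slippery_heptamer(dna[i: i + 7]):
                positions.append(i + offset)
        return positions
    for motif in motifs:
        motif = motif.upper()
        if not _is_slippery_heptamer(motif):
            raise ValueError(
                f"motif {motif!r} is not an X XXY YYZ slippery heptamer"
            )
        start = dna.find(motif)
        while start >= 0:
            positions.append(start + offset)
            start = dna.find(motif, start + 1)
    return sorted(set(positions))


@dataclass
class TRNASet:
    """A phage's tRNA complement, keyed by anticodon.

    Decoding uses strict Watson-Crick reverse complement of the anticodon
    (no wobble rules); duplicate anticodons collapse, so the number of
    decoded codons equals the number of distinct anticodons.
    """

    anticodons: Sequence[str]

    def __post_init__(self) -> None:
        cleaned = []
        for ac in self.anticodons:
            ac = ac.upper().replace("U", "T")
            if len(ac) != 3 or set(ac) - set("ACGT"):
                raise ValueError(f"invalid anticodon {ac!r}")
            cleaned.append(ac)
        self.anticodons = tuple(cleaned)

    @property
    def decoded_codons(self) -> Set[str]:
        return {reverse_complement(ac) for ac in self.anticodons}


def codon_trna_coverage(
    cds_set: Iterable[str],
    trnas: TRNASet | Iterable[str],
) -> Tuple[int, float]:
    """Fraction of encoded residues whose codons have a phage tRNA.

    Counts codon *instances* over all CDS sequences (stop codons excluded),
    then reports ``(number of decoded codons, fraction of instances in the
    decoded set)``.  Invariant to CDS order; weighting is by instance, not
    by gene.
    """
    if not isinstance(trnas, TRNASet):
        trnas = TRNASet(list(trnas))
    decoded = trnas.decoded_codons
    total = 0
    covered = 0
    for cds in cds_set:
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length {len(cds)} not divisible by 3")
        for i in range(0, len(cds), 3):
            codon = cds[i: i + 3]
            bad = set(codon) - set("ACGTN")
            if bad:
                raise ValueError(f"invalid codon characters {sorted(bad)}")
            if "N" in codon or codon in STOP_CODONS:
                continue
            total += 1
            if codon in decoded:
                covered += 1
    if total == 0:
        return len(decoded) if decoded else 0, 0.0
    return len(decoded), covered / total


@dataclass(frozen=True)
class AlignmentSegment:
    """One matched segment from a pairwise nucleotide alignment."""

    query_interval: GenomeInterval
    subject_interval: GenomeInterval
    percent_identity: float
    aligned_length: int

    def __post_init__(self) -> None:
        if self.aligned_length <= 0:
            raise ValueError("aligned_length must be positive")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must be within [0, 100]")


def segments_from_blast6(df: pd.DataFrame) -> List[AlignmentSegment]:
    """Convert a BLAST outfmt-6 table into alignment segments.

    BLAST coordinates are 1-based inclusive and may be reversed on the
    subject for minus-strand hits; both are normalized here.
    """
    segments: List[AlignmentSegment] = []
    for row in df.itertuples(index=False):
        qs, qe = sorted((int(row.qstart), int(row.qend)))
        ss, se = sorted((int(row.sstart), int(row.send)))
        strand = "+" if row.sstart <= row.send else "-"
        segments.append(
            AlignmentSegment(
                query_interval=GenomeInterval(qs - 1, qe, "+"),
                subject_interval=GenomeInterval(ss - 1, se, strand),
                percent_identity=float(row.pident),
                aligned_length=int(row.length),
            )
        )
    return segments


def _merge_intervals(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for start, end in intervals[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(m) for m in merged]


def _clip_segments(
    segments: Sequence[AlignmentSegment],
    exclude: Optional[GenomeInterval],
    axis: str,
) -> List[AlignmentSegment]:
    if exclude is None:
        return list(segments)
    kept = []
    for seg in segments:
        iv = seg.subject_interval if axis == "subject" else seg.query_interval
        overlap = max(0, min(iv.end, exclude.end) - max(iv.start, exclude.start))
        if overlap == 0:
            kept.append(seg)
        # segments overlapping the excluded (terminal-repeat) region are
        # dropped whole: the repeat is duplicated sequence and inflates
        # identity symmetrically
    return kept


def genome_identity(
    segments: Sequence[AlignmentSegment],
    subject_length: int,
    axis: str = "subject",
    length_weighted: bool = True,
    exclude_interval: Optional[GenomeInterval] = None,
    min_aligned_length: int = 50,
) -> float:
    """Whole-genome DNA identity on a 0-100 scale.

    Defined as the mean percent identity of matched segments multiplied by
    the fraction of the genome covered by matches (after merging segment
    overlaps on the chosen axis).  The mean is aligned-length-weighted by
    default.  Short spurious segments below ``min_aligned_length`` are
    ignored; ``exclude_interval`` drops segments overlapping a region
    (terminal repeats are customarily excluded before this analysis).
    """
    if subject_length <= 0:
        raise ValueError("genome length must be positive")
    usable = [
        s for s in _clip_segments(segments, exclude_interval, axis)
        if s.aligned_length >= min_aligned_length
    ]
    if not usable:
        return 0.0
    if length_weighted:
        weight_sum = sum(s.aligned_length for s in usable)
        mean_identity = (
            sum(s.percent_identity * s.aligned_length for s in usable) / weight_sum
        )
    else:
        mean_identity = sum(s.percent_identity for s in usable) / len(usable)
    intervals = [
        (
            (s.subject_interval if axis == "subject" else s.query_interval).start,
            (s.subject_interval if axis == "subject" else s.query_interval).end,
        )
        for s in usable
    ]
    matched = sum(end - start for start, end in _merge_intervals(intervals))
    matched = min(matched, subject_length)
    return mean_identity * matched / subject_length


def pairwise_identity(
    segments: Sequence[AlignmentSegment],
    query_length: int,
    subject_length: int,
    asymmetry_flag_points: float = 2.0,
    **kwargs,
) -> Dict[str, float | bool]:
    """Identity statistic in both directions plus their average.

    The statistic is direction-dependent (merging happens on one genome's
    axis), so both directions are reported; an asymmetry beyond
    ``asymmetry_flag_points`` percentage points is flagged.
    """
    by_subject = genome_identity(segments, subject_length, axis="subject", **kwargs)
    by_query = genome_identity(segments, query_length, axis="query", **kwargs)
    return {
        "subject_direction": by_subject,
        "query_direction": by_query,
        "average": (by_subject + by_query) / 2.0,
        "asymmetric": abs(by_subject - by_query) > asymmetry_flag_points,
    }
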