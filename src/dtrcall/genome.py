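"""Coordinate-aware genome types shared by every pipeline stage.

Phage chromosomes come in two flavours here: the *circular assembly*, which
is what a de-novo assembler emits when a non-permuted terminal repeat
collapses onto itself, and the *physical linear* chromosome, which carries
one extra copy of the repeat at each end.  All internal coordinates are
0-based half-open; conversion to 1-based inclusive happens only at I/O
boundaries (GFF3, reports).

Wrap-around intervals on the circle are stored un-normalized (``start >
end``) and normalized lazily with :func:`normalize_wraparound`, because
terminal repeats frequently straddle the arbitrary assembly origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional

__all__ = [
    "Topology",
    "Packaging",
    "GenomeInterval",
    "PhageGenome",
    "GeneFeature",
    "OutOfFeatureError",
    "reverse_complement",
    "normalize_wraparound",
    "reading_frame_codon_at",
    "gc_content",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Topology(str, Enum):
    CIRCULAR_ASSEMBLY = "circular_assembly"
    LINEAR_PHYSICAL = "linear_physical"


class Packaging(str, Enum):
    """DNA packaging architecture of the virion chromosome.

    ``NONPERMUTED_REPEAT``
        Every molecule starts and ends at the same positions and carries the
        terminal repeat at both ends (T5/SPO1 style).
    ``NONPERMUTED_IMPRECISE``
        Fixed packaging initiation but an imprecise right-end cleavage, so
        the right terminus is spread over a few hundred bp.
    ``HEADFUL_PERMUTED``
        Circularly permuted headful packaging (T4/P22 style): starts uniform
        on the circle; no coverage discontinuity is expected.
    """

    NONPERMUTED_REPEAT = "nonpermuted_repeat"
    NONPERMUTED_IMPRECISE = "nonpermuted_imprecise"
    HEADFUL_PERMUTED = "headful_permuted"
    UNKNOWN = "unknown"


class OutOfFeatureError(ValueError):
    """A genomic position does not fall inside the queried feature."""


@dataclass(frozen=True)
class GenomeInterval:
    """Half-open interval ``[start, end)`` with optional strand.

    On a circular sequence an interval with ``start > end`` is interpreted
    as wrapping through the origin.  Linear contexts must have
    ``start < end``.
    """

    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError(f"negative coordinate in interval {self}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, unit_length: Optional[int] = None) -> int:
        if not self.wraps:
            return self.end - self.start
        if unit_length is None:
            raise ValueError("wrap-around interval needs unit_length to compute length")
        return (unit_length - self.start) + self.end

    def contains(self, pos: int, unit_length: Optional[int] = None) -> bool:
        if not self.wraps:
            return self.start <= pos < self.end
        if unit_length is None:
            raise ValueError("wrap-around interval needs unit_length")
        return pos >= self.start or pos < self.end


def normalize_wraparound(interval: GenomeInterval, unit_length: int) -> List[GenomeInterval]:
    """Split a (possibly wrapping) circular interval into linear pieces.

    Returns one interval when there is no wrap, otherwise the two pieces
    ``[start, L)`` and ``[0, end)``.  A degenerate ``start == end`` interval
    is taken to mean the full circle only when it is the canonical
    ``[0, L)``; other zero-length intervals are returned unchanged.
    """
    if interval.start >= unit_length or interval.end > unit_length:
        raise ValueError(
            f"interval {interval} outside circle of length {unit_length}"
        )
    if not interval.wraps:
        return [interval]
    pieces = []
    if interval.start < unit_length:
        pieces.append(GenomeInterval(interval.start, unit_length, interval.strand))
    if interval.end > 0:
        pieces.append(GenomeInterval(0, interval.end, interval.strand))
    return pieces


@dataclass
class PhageGenome:
    """A phage chromosome sequence with explicit topology semantics.

    For ``CIRCULAR_ASSEMBLY`` the sequence length equals ``unit_length``.
    For ``LINEAR_PHYSICAL`` the sequence is ``unit_length + repeat_length``
    long and its first ``repeat_length`` bases equal its last
    ``repeat_length`` bases (the duplicated terminal repeat).
    """

    name: str
    sequence: str
    topology: Topology
    unit_length: int
    repeat_interval: Optional[GenomeInterval] = None
    packaging: Packaging = Packaging.UNKNOWN
    notes: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
        if self.topology is Topology.CIRCULAR_ASSEMBLY:
            if len(self.sequence) != self.unit_length:
                raise ValueError(
                    "circular assembly length "
                    f"{len(self.sequence)} != unit_length {self.unit_length}"
                )
        else:
            rlen = self.repeat_length
            if rlen is None:
                raise ValueError("linear physical genome requires repeat_interval")
            if len(self.sequence) != self.unit_length + rlen:
                raise ValueError(
                    f"physical genome length {len(self.sequence)} != "
                    f"unit_length + repeat_length {self.unit_length + rlen}"
                )
            if self.sequence[:rlen] != self.sequence[-rlen:]:
                raise ValueError("terminal repeat copies differ (prefix != suffix)")
        if self.repeat_interval is not None:
            ri = self.repeat_interval
            if ri.start >= self.unit_length or ri.end > self.unit_length:
                raise ValueError(
                    f"repeat interval {ri} outside unit genome [0, {self.unit_length})"
                )

    @property
    def repeat_length(self) -> Optional[int]:
        if self.repeat_interval is None:
            return None
        return self.repeat_interval.length(self.unit_length)

    def rotated(self, offset: int) -> str:
        """Sequence of the circle rotated so that ``offset`` becomes base 0."""
        if self.topology is not Topology.CIRCULAR_ASSEMBLY:
            raise ValueError("rotation is defined on circular assemblies only")
        offset %= self.unit_length
        return self.sequence[offset:] + self.sequence[:offset]


@dataclass
class GeneFeature:
    """A gene-level annotation record (CDS, tRNA or other).

    ``frame`` follows the GFF3 phase convention: number of bases to skip at
    the feature's 5' end to reach the first complete codon.  tRNA features
    must carry an ``anticodon`` attribute (a triplet over ACGTU).
    """

    interval: GenomeInterval
    kind: str = "CDS"
    frame: int = 0
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in {"CDS", "tRNA", "other"}:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {self.frame}")
        if self.kind == "CDS":
            if self.interval.wraps:
                raise ValueError("wrap-around CDS features are not supported")
            if (self.interval.length() - self.frame) % 3 != 0:
                raise ValueError(
                    f"CDS length {self.interval.length()} not divisible by 3 "
                    f"after frame adjustment ({self.frame})"
                )
        if self.kind == "tRNA":
            anticodon = self.attributes.get("anticodon", "")
            if len(anticodon) != 3 or set(anticodon.upper()) - set("ACGTU"):
                raise ValueError(
                    f"tRNA feature requires a valid anticodon triplet, got {anticodon!r}"
                )

    @property
    def gene_id(self) -> str:
        for key in ("ID", "gene", "locus_tag", "Name"):
            if key in self.attributes:
                return self.attributes[key]
        return f"{self.kind}:{self.interval.start}-{self.interval.end}"


def reading_frame_codon_at(gene: GeneFeature, genomic_pos: int) -> int:
    """1-based codon index of a genomic position within a CDS.

    The index counts from the annotated start codon, strand-aware: on the
    minus strand the start codon sits at the interval's right edge.  A
    terminus falling "within codon 652" of a terminase gene, for example,
    means this function returns 652 for that position.
    """
    if gene.kind != "CDS":
        raise ValueError(f"codon indexing requires a CDS feature, got {gene.kind}")
    iv = gene.interval
    if not (iv.start <= genomic_pos < iv.end):
        raise OutOfFeatureError(
            f"position {genomic_pos} outside CDS [{iv.start}, {iv.end})"
        )
    if iv.strand == "-":
        offset = (iv.end - 1 - gene.frame) - genomic_pos
    else:
        offset = genomic_pos - (iv.start + gene.frame)
    if offset < 0:
        raise OutOfFeatureError(
            f"position {genomic_pos} lies in the frame-skipped bases of the CDS"
        )
    return offset // 3 + 1


def gc_content(dna: str) -> float:
    """GC percentage over unambiguous bases (N excluded from the denominator)."""
    if not dna:
        raise ValueError("empty sequence")
    dna = dna.upper()
    counts = {b: dna.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    return 100.0 * (counts["G"] + counts["C"]) / denom
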