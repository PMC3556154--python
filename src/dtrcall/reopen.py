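"""Rewrite a collapsed circular assembly as the physical linear chromosome.

A confirmed terminal-repeat call implies the packaged molecule carries the
repeat at both ends.  Reopening rotates the circle so the left repeat
boundary (the packaging initiation site) becomes base 0 and appends one
extra repeat copy, yielding a physical genome of ``unit + repeat`` bases
whose terminal copies are bit-identical.  Collapsing (dropping one terminal
copy and re-circularizing) is the exact inverse up to the recorded
rotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .coverage import TerminalRepeatCall
from .genome import (
    GeneFeature,
    GenomeInterval,
    Packaging,
    PhageGenome,
    Topology,
    reading_frame_codon_at,
)

__all__ = [
    "reopen_genome",
    "collapse_genome",
    "TerminusLocation",
    "locate_terminus_in_annotation",
]


def reopen_genome(assembly: PhageGenome, call: TerminalRepeatCall) -> PhageGenome:
    """Produce the physical linear chromosome implied by a repeat call.

    The left boundary defines position 0 of the physical genome.  For a
    gradual right end the sequence is still cut at the called (midpoint)
    boundary, but the result is flagged approximate in ``notes``.
    """
    if assembly.topology is not Topology.CIRCULAR_ASSEMBLY:
        raise ValueError("can only reopen a circular assembly")
    L = assembly.unit_length
    r0 = call.left.position % L
    rlen = call.repeat_length
    if not 0 < rlen < L:
        raise ValueError(f"repeat length {rlen} outside (0, {L})")
    rotated = assembly.rotated(r0)
    physical_seq = rotated + rotated[:rlen]
    notes = {
        "rotation": r0,
        "source_assembly": assembly.name,
        "boundary_class": call.boundary_class,
    }
    if call.boundary_class == "gradual":
        notes["right_end_approximate"] = True
        notes["right_transition_width"] = call.right.transition_width
    return PhageGenome(
        name=f"{assembly.name}_physical",
        sequence=physical_seq,
        topology=Topology.LINEAR_PHYSICAL,
        unit_length=L,
        repeat_interval=GenomeInterval(0, rlen),
        packaging=(
            Packaging.NONPERMUTED_IMPRECISE
            if call.boundary_class == "gradual"
            else Packaging.NONPERMUTED_REPEAT
        ),
        notes=notes,
    )


def collapse_genome(physical: PhageGenome, rotation: Optional[int] = None) -> PhageGenome:
    """Inverse of :func:`reopen_genome`: drop one terminal copy, re-circularize.

    ``rotation`` restores the original assembly origin; when omitted it is
    taken from the genome's notes (0 if absent).
    """
    if physical.topology is not Topology.LINEAR_PHYSICAL:
        raise ValueError("can only collapse a linear physical genome")
    rlen = physical.repeat_length
    unit_seq = physical.sequence[:-rlen]
    if rotation is None:
        rotation = int(physical.notes.get("rotation", 0))
    L = len(unit_seq)
    back = (L - rotation) % L
    circ = unit_seq[back:] + unit_seq[:back]
    return PhageGenome(
        name=physical.notes.get("source_assembly", f"{physical.name}_collapsed"),
        sequence=circ,
        topology=Topology.CIRCULAR_ASSEMBLY,
        unit_length=L,
        repeat_interval=GenomeInterval(rotation % L, (rotation + rlen) % L),
        packaging=physical.packaging,
    )


@dataclass
class TerminusLocation:
    """Where a terminus falls relative to the gene annotation."""

    kind: str                       # 'CDS' | 'tRNA' | 'other' | 'intergenic'
    feature_id: Optional[str] = None
    codon_index: Optional[int] = None
    upstream_gene: Optional[str] = None
    downstream_gene: Optional[str] = None

    def describe(self) -> str:
        if self.kind == "intergenic":
            return (
                f"intergenic region between {self.upstream_gene or 'genome start'} "
                f"and {self.downstream_gene or 'genome end'}"
            )
        if self.kind == "CDS":
            return f"within codon {self.codon_index} of {self.feature_id}"
        return f"within {self.kind} feature {self.feature_id}"


def locate_terminus_in_annotation(
    pos: int,
    features: Sequence[GeneFeature],
) -> TerminusLocation:
    """Localize a terminus position against CDS/tRNA annotation records.

    Returns the containing feature (with a strand-aware codon index for
    CDS) or an intergenic record naming the flanking genes.  Overlapping
    features are allowed; the first containing feature in coordinate order
    wins.
    """
    ordered: List[GeneFeature] = sorted(
        features, key=lambda f: (f.interval.start, f.interval.end)
    )
    for feature in ordered:
        if feature.interval.start <= pos < feature.interval.end:
            codon = (
                reading_frame_codon_at(feature, pos)
                if feature.kind == "CDS"
                else None
            )
            return TerminusLocation(
                kind=feature.kind, feature_id=feature.gene_id, codon_index=codon
            )
    upstream = None
    downstream = None
    for feature in ordered:
        if feature.interval.end <= pos:
            upstream = feature.gene_id
        elif feature.interval.start > pos and downstream is None:
            downstream = feature.gene_id
    return TerminusLocation(
        kind="intergenic", upstream_gene=upstream, downstream_gene=downstream
    )
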