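"""Synthetic packaged-DNA molecules, shotgun reads and tag-ligated fragments.

The generator mirrors the data-generating process the detection pipeline
assumes.  Reads are sampled from *packaged molecules*, never from the
circular assembly, so repeat-coverage doubling and terminus effects emerge
mechanistically: a non-permuted molecule carries the terminal repeat twice,
hence mapping its reads back onto the collapsed circle doubles depth inside
the repeat and steps back down at its boundaries.

Read starts are uniform over ``[-(len-1), M-1]`` and truncated to the
molecule, so the physical ends receive the same expected depth as the
interior and the coverage step at a repeat boundary is single-base abrupt —
the pattern real libraries show for precise-cleavage packaging.

All randomness flows from one integer seed; pipeline stages derive child
seeds via ``numpy.random.SeedSequence`` spawning so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np

from .genome import (
    GenomeInterval,
    Packaging,
    PhageGenome,
    Topology,
    reverse_complement,
)

__all__ = [
    "DEFAULT_TAG",
    "PackagedMolecule",
    "ReadTruth",
    "SimulatedRead",
    "build_genome",
    "package_molecules",
    "shotgun_reads",
    "ligate_tags",
]

#: 49 bp dsDNA oligonucleotide ligated to free chromosome ends in the
#: terminal-labeling assay.
DEFAULT_TAG = "TTACTTACAATCCTTGGCGGTTTTGCTGCGCGCCCATGATGGACTGGAC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class PackagedMolecule:
    """One packaged linear chromosome cut from the circular unit genome."""

    name: str
    sequence: str
    origin_coords: tuple  # (packaging start, cleavage end) on the circle
    style: Packaging

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadTruth:
    """Ground-truth provenance of a simulated read (for oracle tests)."""

    molecule: str
    offset: int          # start position in molecule coordinates
    strand: str          # '+' read equals molecule subsequence, '-' its revcomp
    tagged: bool = False
    tag_end: Optional[str] = None   # left_terminus | right_terminus | random_break
    junction: Optional[int] = None  # circle coordinate of the base abutting the tag


@dataclass
class SimulatedRead:
    id: str
    sequence: str
    quality: str
    truth: ReadTruth

    def __len__(self) -> int:
        return len(self.sequence)


def build_genome(
    unit_length: int,
    repeat_length: int,
    gc_fraction: float = 0.662,
    seed: RngLike = 0,
    name: str = "sim_phage",
    repeat_start: Optional[int] = None,
) -> PhageGenome:
    """Build a random circular unit assembly with a declared repeat interval.

    Bases are i.i.d. with the requested GC fraction.  The repeat interval is
    a *declaration* of where the terminal repeat sits on the collapsed
    circle (its sequence occurs once in the assembly); by default it is
    placed one third of the way around so that neither boundary coincides
    with the arbitrary assembly origin.
    """
    if not 0 < repeat_length < unit_length:
        raise ValueError(
            f"repeat_length must satisfy 0 < repeat < unit_length, got "
            f"{repeat_length} vs {unit_length}"
        )
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = _rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    codes = rng.choice(_BASES, size=unit_length, p=[p_at, p_gc, p_gc, p_at])
    sequence = codes.tobytes().decode("ascii")
    if repeat_start is None:
        repeat_start = unit_length // 3
    repeat_start %= unit_length
    repeat_end = (repeat_start + repeat_length) % unit_length
    return PhageGenome(
        name=name,
        sequence=sequence,
        topology=Topology.CIRCULAR_ASSEMBLY,
        unit_length=unit_length,
        repeat_interval=GenomeInterval(repeat_start, repeat_end),
        packaging=Packaging.UNKNOWN,
    )


def _circle_walk(genome: PhageGenome, start: int, length: int) -> str:
    """Sequence obtained by walking ``length`` bases clockwise from ``start``."""
    L = genome.unit_length
    start %= L
    reps = (start + length) // L + 1
    return (genome.sequence * reps)[start:start + length]


def package_molecules(
    genome: PhageGenome,
    n: int,
    style: Packaging = Packaging.NONPERMUTED_REPEAT,
    imprecision_sd: float = 0.0,
    seed: RngLike = 0,
    headful_length: Optional[int] = None,
) -> List[PackagedMolecule]:
    """Cut ``n`` packaged linear molecules from the circular unit genome.

    * ``NONPERMUTED_REPEAT`` — every molecule starts at the repeat's left
      boundary and spans unit + repeat, so both repeat copies are intact and
      identical.
    * ``NONPERMUTED_IMPRECISE`` — same initiation, but the right-end
      cleavage deviates from the nominal boundary by a Gaussian draw with
      the given spread (Colossus-style imprecise termination).
    * ``HEADFUL_PERMUTED`` — uniform starts on the circle, fixed headful
      length (default 3% longer than the unit genome).
    """
    rng = _rng(seed)
    L = genome.unit_length
    if style in (Packaging.NONPERMUTED_REPEAT, Packaging.NONPERMUTED_IMPRECISE):
        if genome.repeat_interval is None:
            raise ValueError(f"{style.value} packaging requires a repeat interval")
        r0 = genome.repeat_interval.start
        rlen = genome.repeat_length
        base_len = L + rlen
        if style is Packaging.NONPERMUTED_REPEAT or imprecision_sd == 0:
            deltas = np.zeros(n, dtype=int)
        else:
            deltas = np.rint(rng.normal(0.0, imprecision_sd, size=n)).astype(int)
            deltas = np.clip(deltas, -(rlen - 1), L - rlen - 1)
        molecules = []
        for i, delta in enumerate(deltas):
            length = base_len + int(delta)
            end = (r0 + length) % L
            molecules.append(
                PackagedMolecule(
                    name=f"mol{i:05d}",
                    sequence=_circle_walk(genome, r0, length),
                    origin_coords=(r0, end),
                    style=style,
                )
            )
        return molecules
    if style is Packaging.HEADFUL_PERMUTED:
        if headful_length is None:
            headful_length = int(round(1.03 * L))
        starts = rng.integers(0, L, size=n)
        return [
            PackagedMolecule(
                name=f"mol{i:05d}",
                sequence=_circle_walk(genome, int(s), headful_length),
                origin_coords=(int(s), int((s + headful_length) % L)),
                style=style,
            )
            for i, s in enumerate(starts)
        ]
    raise ValueError(f"cannot simulate packaging style {style}")


def _draw_lengths(rng: np.random.Generator, n: int, mean: float, sd: float,
                  min_len: int) -> np.ndarray:
    lengths = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    return np.maximum(lengths, min_len)


def _apply_errors(seq: str, n_errors: int, rng: np.random.Generator) -> str:
    if n_errors == 0:
        return seq
    arr = bytearray(seq, "ascii")
    positions = rng.choice(len(arr), size=n_errors, replace=False)
    for p in positions:
        choices = [b for b in b"ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.decode("ascii")


def shotgun_reads(
    molecules: Sequence[PackagedMolecule],
    mean_len: float = 400.0,
    len_sd: float = 80.0,
    fold_coverage: float = 100.0,
    error_rate: float = 0.0,
    seed: RngLike = 0,
    unit_length: Optional[int] = None,
    min_len: int = 50,
    quality_char: str = "?",  # constant Q30 placeholder
) -> List[SimulatedRead]:
    """Sample 454-like shotgun reads uniformly from packaged molecules.

    ``fold_coverage`` is defined against the unit genome: reads are drawn
    until their total base count reaches ``fold_coverage * unit_length``
    (within one read).  Reads overhanging a molecule end are truncated at
    the physical terminus; truncated reads shorter than 20 bp are dropped.
    Substitution errors only, at ``error_rate`` per base.
    """
    if mean_len < 50:
        raise ValueError(f"mean_len must be >= 50, got {mean_len}")
    if fold_coverage <= 0:
        raise ValueError("fold_coverage must be positive")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    if not molecules:
        raise ValueError("no molecules to sample from")
    rng = _rng(seed)
    if unit_length is None:
        # collapsed-assembly length is molecule minus one repeat copy for
        # non-permuted styles; fall back to the shortest molecule length
        unit_length = min(len(m) for m in molecules)
    target_bases = fold_coverage * unit_length
    reads: List[SimulatedRead] = []
    total = 0
    batch = max(64, int(target_bases / mean_len * 1.1))
    counter = 0
    mol_lengths = np.array([len(m) for m in molecules])
    while total < target_bases:
        n = max(64, int((target_bases - total) / mean_len))
        mol_idx = rng.integers(0, len(molecules), size=n)
        lengths = _draw_lengths(rng, n, mean_len, len_sd, min_len)
        # start uniform over [-(len-1), M-1] then truncate: ends keep full depth
        starts = rng.integers(-(lengths - 1), mol_lengths[mol_idx])
        strands = rng.integers(0, 2, size=n)
        if error_rate > 0:
            n_errs = rng.binomial(lengths, error_rate)
        else:
            n_errs = np.zeros(n, dtype=int)
        for k in range(n):
            if total >= target_bases:
                break
            mol = molecules[int(mol_idx[k])]
            lo = max(0, int(starts[k]))
            hi = min(len(mol), int(starts[k]) + int(lengths[k]))
            if hi - lo < 20:  # unmappably short sliver at a terminus
                continue
            seq = mol.sequence[lo:hi]
            seq = _apply_errors(seq, min(int(n_errs[k]), hi - lo), rng)
            strand = "+" if strands[k] == 0 else "-"
            if strand == "-":
                seq = reverse_complement(seq)
            reads.append(
                SimulatedRead(
                    id=f"read{counter:07d}",
                    sequence=seq,
                    quality=quality_char * len(seq),
                    truth=ReadTruth(molecule=mol.name, offset=lo, strand=strand),
                )
            )
            total += hi - lo
            counter += 1
    return reads


def _molecule_circle_pos(mol: PackagedMolecule, offset: int, unit_length: int) -> int:
    """Circle coordinate of molecule position ``offset``."""
    return (mol.origin_coords[0] + offset) % unit_length


def ligate_tags(
    molecules: Sequence[PackagedMolecule],
    tag: str = DEFAULT_TAG,
    termini_fraction: float = 0.37,
    random_break_rate: Optional[float] = None,
    seed: RngLike = 0,
    n_tagged: Optional[int] = 52,
    unit_length: Optional[int] = None,
    mean_flank: float = 300.0,
    flank_sd: float = 60.0,
) -> List[SimulatedRead]:
    """Emit reads containing the full oligo tag abutting a DNA end.

    A fraction ``termini_fraction`` of tag-ligation events happen at true
    molecule termini (split evenly between left and right ends at random);
    the rest model blunt ligation to random double-stranded breaks
    introduced during DNA isolation, uniform over the molecule.  The truth
    record stores which, plus the circle coordinate of the junction base.

    The number of tagged reads is ``n_tagged``; alternatively, pass
    ``n_tagged=None`` with a per-bp ``random_break_rate`` to derive the
    count as ``rate * total molecule bases`` (plus the terminus events).
    """
    tag = tag.upper()
    if len(tag) < 20:
        raise ValueError(f"tag must be >= 20 bp, got {len(tag)}")
    if set(tag) - set("ACGT"):
        raise ValueError("tag must contain only A/C/G/T")
    if not 0.0 <= termini_fraction <= 1.0:
        raise ValueError("termini_fraction must be in [0, 1]")
    rng = _rng(seed)
    if unit_length is None:
        unit_length = min(len(m) for m in molecules)
    if n_tagged is None:
        if random_break_rate is None:
            raise ValueError("need n_tagged or random_break_rate")
        n_breaks = rng.poisson(random_break_rate * sum(len(m) for m in molecules))
        n_tagged = int(round(n_breaks / max(1e-12, 1.0 - termini_fraction)))
    reads: List[SimulatedRead] = []
    for i in range(n_tagged):
        mol = molecules[int(rng.integers(0, len(molecules)))]
        at_terminus = rng.random() < termini_fraction
        flank_len = int(max(25, round(rng.normal(mean_flank, flank_sd))))
        flank_len = min(flank_len, len(mol) - 1)
        if at_terminus:
            if rng.random() < 0.5:
                tag_end = "left_terminus"
                seq = tag + mol.sequence[:flank_len]
                junction = _molecule_circle_pos(mol, 0, unit_length)
            else:
                tag_end = "right_terminus"
                seq = mol.sequence[-flank_len:] + tag
                junction = _molecule_circle_pos(mol, len(mol) - 1, unit_length)
            offset = 0 if tag_end == "left_terminus" else len(mol) - flank_len
        else:
            tag_end = "random_break"
            p = int(rng.integers(1, len(mol)))
            if rng.random() < 0.5:
                # tag ligated to the rightward fragment's exposed 5' end
                hi = min(len(mol), p + flank_len)
                seq = tag + mol.sequence[p:hi]
                junction = _molecule_circle_pos(mol, p, unit_length)
                offset = p
            else:
                lo = max(0, p - flank_len)
                seq = mol.sequence[lo:p] + tag
                junction = _molecule_circle_pos(mol, p - 1, unit_length)
                offset = lo
        strand = "+"
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
            strand = "-"
        reads.append(
            SimulatedRead(
                id=f"tagread{i:05d}",
                sequence=seq,
                quality="?" * len(seq),
                truth=ReadTruth(
                    molecule=mol.name,
                    offset=offset,
                    strand=strand,
                    tagged=True,
                    tag_end=tag_end,
                    junction=junction,
                ),
            )
        )
    return reads
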