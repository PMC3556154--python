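"""Exact-seed-and-extend read placement on the doubled circular assembly.

The assembly is doubled so that placements crossing the arbitrary origin
stay contiguous; reported start coordinates are canonicalized modulo the
unit length.  Extension is ungapped with a small mismatch budget.  When
extension stops well before the read end (e.g. a chimeric or
junction-spanning read), the remaining tail is re-seeded and placed as a
separate segment, so per-base depth around sharp discontinuities is counted
exactly once per base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .genome import PhageGenome, Topology, reverse_complement

__all__ = ["Segment", "ReadPlacement", "SeedExtendMapper"]


@dataclass(frozen=True)
class Segment:
    """One contiguous placement of (part of) a read on the circle."""

    start: int          # canonical circle coordinate in [0, unit_length)
    length: int
    strand: str         # '+' or '-'
    mismatches: int
    read_offset: int    # offset of this segment within the (forward) read

    @property
    def end(self) -> int:
        """End on the *doubled* circle (may exceed unit_length)."""
        return self.start + self.length


@dataclass
class ReadPlacement:
    segments: List[Segment] = field(default_factory=list)

    @property
    def is_split(self) -> bool:
        return len(self.segments) > 1

    @property
    def mismatches(self) -> int:
        return sum(s.mismatches for s in self.segments)


class SeedExtendMapper:
    """31-mer exact seeding with ungapped mismatch-tolerant verification.

    Parameters
    ----------
    assembly:
        Circular assembly to index.
    seed_len:
        Exact seed k-mer length (default 31).
    max_mismatch:
        Substitution budget per contiguous segment (default 2).
    split_min_tail:
        Minimum unplaced tail length that triggers split placement.
    """

    def __init__(
        self,
        assembly: PhageGenome,
        seed_len: int = 31,
        max_mismatch: int = 2,
        split_min_tail: int = 20,
        min_read_len: int = 20,
    ) -> None:
        if assembly.topology is not Topology.CIRCULAR_ASSEMBLY:
            raise ValueError("mapper indexes circular assemblies only")
        self.assembly = assembly
        self.seed_len = seed_len
        self.max_mismatch = max_mismatch
        self.split_min_tail = split_min_tail
        self.min_read_len = min_read_len
        self.unit_length = assembly.unit_length
        if "N" * seed_len in assembly.sequence:
            warnings.warn(
                f"assembly contains an N-run of length >= seed ({seed_len}); "
                "reads over it will not seed",
                stacklevel=2,
            )
        self._doubled = (assembly.sequence + assembly.sequence).encode("ascii")
        self._doubled_arr = np.frombuffer(self._doubled, dtype=np.uint8)
        self._index = self._build_index()

    @property
    def params(self) -> Dict[str, int]:
        return {
            "seed_len": self.seed_len,
            "max_mismatch": self.max_mismatch,
            "split_min_tail": self.split_min_tail,
        }

    def _build_index(self) -> Dict[bytes, List[int]]:
        index: Dict[bytes, List[int]] = {}
        d, k = self._doubled, self.seed_len
        for pos in range(self.unit_length):
            index.setdefault(d[pos:pos + k], []).append(pos)
        return index

    # -- placement ---------------------------------------------------------

    def _count_mismatches(self, seq: bytes, start: int, limit: int) -> int:
        """Mismatches of ``seq`` against the doubled circle at ``start``."""
        window = self._doubled[start:start + len(seq)]
        if window == seq:
            return 0
        a = np.frombuffer(seq, dtype=np.uint8)
        b = self._doubled_arr[start:start + len(seq)]
        return int(np.count_nonzero(a != b))

    def _mismatch_positions(self, seq: bytes, start: int) -> np.ndarray:
        a = np.frombuffer(seq, dtype=np.uint8)
        b = self._doubled_arr[start:start + len(seq)]
        return np.flatnonzero(a != b)

    def _candidates(self, seq: bytes) -> List[int]:
        k, L = self.seed_len, self.unit_length
        hits: List[int] = []
        # try non-overlapping seed offsets until one lands on an error-free
        # stretch; the first productive seed is enough for verification
        for offset in range(0, min(len(seq) - k + 1, 8 * k), k):
            found = self._index.get(seq[offset:offset + k])
            if found:
                hits.extend((h - offset) % L for h in found)
                break
        return sorted(set(hits))

    def _best_single(self, seq: bytes) -> Optional[Segment]:
        best: Optional[Segment] = None
        for strand, s in (("+", seq), ("-", reverse_complement(seq.decode("ascii")).encode("ascii"))):
            for cand in self._candidates(s):
                mm = self._count_mismatches(s, cand, self.max_mismatch)
                seg = Segment(cand, len(s), strand, mm, 0)
                if best is None or (seg.mismatches, seg.start, seg.strand) < (
                    best.mismatches, best.start, best.strand
                ):
                    best = seg
        return best

    def _exhaustive(self, seq: bytes) -> Optional[Segment]:
        """Fallback for reads shorter than the seed: direct substring scan."""
        for strand, s in (("+", seq), ("-", reverse_complement(seq.decode("ascii")).encode("ascii"))):
            pos = self._doubled.find(s)
            if pos >= 0:
                return Segment(pos % self.unit_length, len(s), strand, 0, 0)
        return None

    def map_read(self, sequence: str, _depth: int = 0) -> Optional[ReadPlacement]:
        """Place a read; returns ``None`` when no placement passes the budget.

        The best (fewest-mismatch) contiguous placement wins; ties break
        deterministically toward the smaller coordinate and '+' strand.  If
        the best contiguous placement exceeds the mismatch budget, the read
        is split at the point where the budget is exhausted and the tail is
        mapped independently (at most one recursion level deep).
        """
        seq = sequence.upper().encode("ascii")
        if len(seq) < self.min_read_len:
            return None
        if len(seq) < self.seed_len:
            seg = self._exhaustive(seq)
            return ReadPlacement([seg]) if seg else None
        best = self._best_single(seq)
        if best is None:
            return None
        if best.mismatches <= self.max_mismatch:
            return ReadPlacement([best])
        if _depth >= 1:
            return None
        # split placement: keep the prefix up to the mismatch budget,
        # re-map the remainder as its own segment
        s = seq if best.strand == "+" else reverse_complement(seq.decode("ascii")).encode("ascii")
        mism = self._mismatch_positions(s, best.start)
        cut = int(mism[self.max_mismatch])  # first base beyond the budget
        if cut < self.seed_len:
            return None
        head = Segment(best.start, cut, best.strand,
                       int(np.count_nonzero(mism < cut)), 0)
        if len(seq) - cut < self.split_min_tail:
            # tail too short to place independently: soft-clip it
            return ReadPlacement([head])
        tail_seq = s[cut:].decode("ascii")
        tail_placement = self.map_read(tail_seq, _depth=_depth + 1)
        if tail_placement is None:
            return ReadPlacement([head])
        segments = [head]
        for t in tail_placement.segments:
            strand = t.strand if best.strand == "+" else ("-" if t.strand == "+" else "+")
            segments.append(Segment(t.start, t.length, strand, t.mismatches,
                                    cut + t.read_offset))
        return ReadPlacement(segments)

    def map_sequence(self, sequence: str) -> Optional[Segment]:
        """Single best contiguous placement (used for tag-flank mapping)."""
        placement = self.map_read(sequence)
        if placement is None or not placement.segments:
            return None
        return max(placement.segments, key=lambda s: s.length)
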