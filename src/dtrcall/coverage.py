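"""Per-base depth profiles and terminal-repeat breakpoint detection.

A non-permuted terminal repeat collapses to a single copy in the circular
assembly, so reads drawn from packaged molecules cover it twice: depth
inside the repeat sits near twice the background and steps back down at the
repeat boundaries.  Detection is a two-stage scan:

1. an adjacent-window mean-ratio sweep over the circle flags candidate
   discontinuities exceeding ``min_fold``;
2. each candidate is refined to single-base resolution by a two-plateau
   least-squares step fit, and the local transition shape is characterised
   by fitting a piecewise-linear ramp whose fitted span is reported as
   ``transition_width`` (0 for an ideal abrupt step; ~the cleavage spread
   for an imprecise right end).

All window arithmetic wraps: the assembly origin is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genome import PhageGenome, Topology
from .mapping import ReadPlacement, SeedExtendMapper

__all__ = [
    "CoverageProfile",
    "BreakpointCall",
    "TerminalRepeatCall",
    "NoRepeatCallError",
    "AmbiguousRepeatError",
    "map_reads",
    "profile_from_sam",
    "detect_breakpoints",
    "call_terminal_repeat",
]


class NoRepeatCallError(RuntimeError):
    """No acceptable terminal-repeat call could be made from the profile."""


class AmbiguousRepeatError(RuntimeError):
    """Several up/down breakpoint pairings are equally plausible."""

    def __init__(self, candidates: List["TerminalRepeatCall"]):
        self.candidates = candidates
        pretty = "; ".join(
            f"[{c.left.position}, {c.right.position}) len={c.repeat_length} "
            f"fold={c.mean_fold:.2f}" for c in candidates
        )
        super().__init__(f"ambiguous terminal-repeat pairings: {pretty}")


@dataclass
class CoverageProfile:
    """Per-base read depth over the circular assembly."""

    depths: np.ndarray
    total_reads: int
    mapper_params: Dict[str, int] = field(default_factory=dict)
    unmapped: int = 0
    name: str = "assembly"

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if (self.depths < 0).any():
            raise ValueError("negative depth")

    @property
    def unit_length(self) -> int:
        return len(self.depths)

    @property
    def total_mapped_bases(self) -> int:
        return int(self.depths.sum())


@dataclass
class BreakpointCall:
    """A single coverage discontinuity on the circle.

    ``position`` uses the half-open boundary convention: the first base
    *after* the depth change (for an up-step, the first high base; for a
    down-step, the first low base), so a repeat spans
    ``[left.position, right.position)`` on the circle.
    """

    position: int
    fold_change: float
    transition_width: int
    direction: str                  # 'up' | 'down'
    level_low: float = 0.0
    level_high: float = 0.0

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.transition_width < 0:
            raise ValueError("transition_width must be >= 0")
        if self.direction not in ("up", "down"):
            raise ValueError(f"invalid direction {self.direction!r}")

    def to_dict(self) -> Dict[str, object]:
        return {
            "position": int(self.position),
            "fold_change": round(float(self.fold_change), 4),
            "transition_width": int(self.transition_width),
            "direction": self.direction,
            "level_low": round(float(self.level_low), 3),
            "level_high": round(float(self.level_high), 3),
        }


@dataclass
class TerminalRepeatCall:
    left: BreakpointCall            # up-step: packaging initiation boundary
    right: BreakpointCall           # down-step: cleavage boundary
    repeat_length: int
    mean_fold: float
    boundary_class: str             # 'abrupt' | 'gradual'

    def to_dict(self) -> Dict[str, object]:
        return {
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
            "repeat_length": int(self.repeat_length),
            "mean_fold": round(float(self.mean_fold), 4),
            "boundary_class": self.boundary_class,
        }


# ---------------------------------------------------------------------------
# depth computation


def map_reads(
    reads: Iterable,
    assembly: PhageGenome,
    mapper: Optional[SeedExtendMapper] = None,
    seed_len: int = 31,
    max_mismatch: int = 2,
) -> CoverageProfile:
    """Place reads on the circular assembly and accumulate per-base depth.

    ``reads`` may be ``SimulatedRead`` objects, ``(id, seq, qual)`` tuples
    or plain sequences.  Unmapped reads are counted, not fatal.  Split
    placements contribute each segment exactly once per base.
    """
    if assembly.topology is not Topology.CIRCULAR_ASSEMBLY:
        raise ValueError("coverage is computed on circular assemblies")
    reads = list(reads)
    if not reads:
        raise ValueError("empty read set")
    if mapper is None:
        mapper = SeedExtendMapper(assembly, seed_len=seed_len, max_mismatch=max_mismatch)
    L = assembly.unit_length
    diff = np.zeros(2 * L + 1, dtype=np.int64)
    n_mapped = 0
    n_unmapped = 0
    for read in reads:
        seq = _read_sequence(read)
        placement = mapper.map_read(seq)
        if placement is None:
            n_unmapped += 1
            continue
        n_mapped += 1
        for seg in placement.segments:
            diff[seg.start] += 1
            diff[seg.end] -= 1
    depth2 = np.cumsum(diff[:-1])
    depths = depth2[:L] + depth2[L:]
    return CoverageProfile(
        depths=depths,
        total_reads=n_mapped,
        mapper_params=mapper.params,
        unmapped=n_unmapped,
        name=assembly.name,
    )


def _read_sequence(read) -> str:
    if hasattr(read, "sequence"):
        return read.sequence
    if isinstance(read, tuple):
        return read[1]
    return str(read)


def profile_from_sam(path: str, assembly: PhageGenome) -> CoverageProfile:
    """Build a depth profile from pre-computed placements in a SAM file.

    Stands in for any external placement engine honouring the split-read
    contract; aligned blocks are counted per base.  SAM coordinates are
    linear, so placements crossing the assembly origin must already be
    represented as split/supplementary alignments.
    """
    import pysam

    L = assembly.unit_length
    depths = np.zeros(L, dtype=np.int64)
    n_mapped = 0
    n_unmapped = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                n_unmapped += 1
                continue
            n_mapped += 1
            for start, end in aln.get_blocks():
                depths[start:end] += 1
    return CoverageProfile(
        depths=depths,
        total_reads=n_mapped,
        mapper_params={"source": "sam"},
        unmapped=n_unmapped,
        name=assembly.name,
    )


# ---------------------------------------------------------------------------
# breakpoint detection


def _circular_runs(indices: np.ndarray, L: int, gap: int) -> List[np.ndarray]:
    """Group sorted candidate indices into runs on the circle."""
    if indices.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > gap)
    runs = np.split(indices, breaks + 1)
    # merge a run touching the origin with one touching the end of the circle
    if len(runs) > 1 and (indices[0] <= gap) and (L - 1 - indices[-1] <= gap):
        runs[0] = np.concatenate([runs[-1] - L, runs[0]])
        runs.pop()
    return runs


def _refine_step(C: np.ndarray, L: int, i: int, w: int) -> int:
    """Single-base two-plateau least-squares step fit around coarse index i."""
    xs = np.arange(i - w + 1, i + w)
    left_sum = C[L + xs] - C[L + i - w]
    left_n = xs - (i - w)
    right_sum = C[L + i + w] - C[L + xs]
    right_n = (i + w) - xs
    score = left_sum**2 / left_n + right_sum**2 / right_n
    return int(xs[int(np.argmax(score))])


_WIDTH_GRID = (
    list(range(0, 21))
    + list(range(25, 101, 5))
    + list(range(110, 601, 10))
)


def _fit_transition(
    d3: np.ndarray,
    L: int,
    b: int,
    direction: str,
    tol_factor: float = 4.0,
) -> Tuple[int, float, float]:
    """Fit a plateau-ramp-plateau model around breakpoint ``b``.

    Returns ``(transition_width, level_low, level_high)``.  The width is the
    span of the best-fitting linear ramp between the two plateaus, with a
    parsimony rule: the smallest width whose fit is within ``tol_factor``
    plateau-noise variances of the optimum wins, so ideal steps report 0
    even under Poisson noise.
    """
    S = min(800, L // 4)
    guard = max(60, (3 * S) // 8)
    seg = d3[L + b - S: L + b + S].astype(float)
    if direction == "down":
        seg = seg[::-1]
    two_s = 2 * S
    low_med = float(np.median(seg[: S - guard]))
    high_med = float(np.median(seg[S + guard:]))
    if high_med <= low_med:
        return 0, min(low_med, high_med), max(low_med, high_med)
    sigma2 = 0.5 * (np.var(seg[: S - guard]) + np.var(seg[S + guard:]))
    P = np.concatenate([[0.0], np.cumsum(seg)])
    Q = np.concatenate([[0.0], np.cumsum(seg**2)])
    X = np.concatenate([[0.0], np.cumsum(seg * np.arange(two_s))])
    total_y = P[two_s]
    total_yy = Q[two_s]
    pad = 50
    # per-(a, W) closed-form least squares with both plateau levels free:
    # y = alpha + beta * r(x), where r is 0 left of the ramp, linear across
    # it, and 1 right of it
    best: Optional[Tuple[float, int, int, float, float]] = None
    chosen: List[Tuple[float, int, int, float, float]] = []
    w_max = min(600, S + guard - 10)
    for W in _WIDTH_GRID:
        if W > w_max:
            break
        a_lo = max(1, S - W - pad)
        a_hi = min(two_s - W - 1, S + pad)
        if a_hi < a_lo:
            continue
        a = np.arange(a_lo, a_hi + 1)
        c = a + W
        n_right = two_s - c
        if W > 0:
            dP = P[c] - P[a]
            dX = X[c] - X[a]
            ramp_yr = (dX - (a - 0.5) * dP) / W        # sum of y * r over the ramp
            s_r = W / 2.0 + n_right                     # sum of r
            s_rr = (W / 3.0 - 1.0 / (12.0 * W)) + n_right  # sum of r^2
        else:
            ramp_yr = np.zeros_like(a, dtype=float)
            s_r = n_right.astype(float)
            s_rr = n_right.astype(float)
        s_yr = ramp_yr + (total_y - P[c])
        denom = two_s * s_rr - s_r**2
        beta = (two_s * s_yr - s_r * total_y) / denom
        alpha = (total_y - beta * s_r) / two_s
        sse = total_yy - alpha * total_y - beta * s_yr
        sse = np.where(beta > 0, sse, np.inf)
        k = int(np.argmin(sse))
        if not np.isfinite(sse[k]):
            continue
        entry = (float(sse[k]), W, int(a[k]), float(alpha[k]), float(beta[k]))
        chosen.append(entry)
        if best is None or entry[0] < best[0]:
            best = entry
    if best is None:
        return 0, low_med, high_med
    tol = tol_factor * float(sigma2)
    admissible = min(
        (c for c in chosen if c[0] <= best[0] + tol), key=lambda c: c[1]
    )
    w_ls, alpha, beta = admissible[1], admissible[3], admissible[4]
    w_jump = _jump_walk_width(seg, S, beta)
    # The ramp fit can chase read-length-scale coverage drift; the local
    # jump statistic cancels it (adjacent windows share most reads).  Both
    # are exact on clean profiles; take the smaller.
    width = min(w_ls, w_jump)
    return int(width), alpha, alpha + beta


_JUMP_HALF_WIDTHS = (5, 10, 25, 50, 75, 100, 150, 200, 300)


def _jump_walk_width(seg: np.ndarray, center: int, delta: float) -> int:
    """Transition width from the two-window jump statistic.

    For an up-oriented transition of span W, the mean difference between
    windows of half-width m on either side of the boundary is
    ``delta * (1 - W / (4 m))`` once m >= W/2, so
    ``W_m = 4 m (1 - s(m) / delta)`` recovers W; the walk stops at the
    first window wide enough to contain the ramp (``W_m <= 2 m``).
    """
    if delta <= 0:
        return 0
    estimate = 0
    for m in _JUMP_HALF_WIDTHS:
        if center - m < 0 or center + m > len(seg):
            break
        s = float(seg[center:center + m].mean() - seg[center - m:center].mean())
        estimate = int(round(4 * m * max(0.0, 1.0 - s / delta)))
        if estimate <= 2 * m:
            return estimate
    return estimate


def detect_breakpoints(
    profile: CoverageProfile,
    min_fold: float = 1.5,
    window: int = 200,
) -> List[BreakpointCall]:
    """Scan the circular depth profile for fold-change discontinuities.

    Returns breakpoints where the ratio of adjacent ``window``-bp mean
    depths exceeds ``min_fold`` (up) or falls below its inverse (down),
    refined to single-base resolution.  An empty list is a valid outcome
    (flat profile: permuted/headful packaging).
    """
    depths = np.asarray(profile.depths, dtype=float)
    L = len(depths)
    if L < 4 * window:
        raise ValueError(f"profile length {L} < 4 * window ({window})")
    if not depths.any():
        raise ValueError("all-zero coverage profile")
    d3 = np.tile(depths, 3)
    C = np.concatenate([[0.0], np.cumsum(d3)])
    idx = np.arange(L)
    eps = 1e-9
    # multi-scale scan: the base window resolves closely spaced boundaries;
    # wider windows keep sensitivity when the transition is smeared over a
    # few hundred bp or the flanking coverage fluctuates at read-length
    # scale.  Extra candidates are harmless: refinement plus the fold
    # plausibility check downstream discard spurious ones.
    scales = [window]
    for factor in (2, 4):
        if L >= 4 * factor * window:
            scales.append(factor * window)
    calls: List[BreakpointCall] = []
    for w in scales:
        right = (C[L + idx + w] - C[L + idx]) / w
        left = (C[L + idx] - C[idx + (L - w)]) / w
        ratio = (right + eps) / (left + eps)
        for direction, mask in (("up", ratio >= min_fold), ("down", ratio <= 1.0 / min_fold)):
            runs = _circular_runs(np.flatnonzero(mask), L, gap=w)
            for run in runs:
                vals = ratio[run % L]
                coarse = int(run[int(np.argmax(vals) if direction == "up" else np.argmin(vals))])
                b = _refine_step(C, L, coarse, w) % L
                width, low, high = _fit_transition(d3, L, b, direction)
                if low <= 0 or high / max(low, eps) < min_fold:
                    continue
                calls.append(
                    BreakpointCall(
                        position=b,
                        fold_change=high / max(low, eps),
                        transition_width=width,
                        direction=direction,
                        level_low=low,
                        level_high=high,
                    )
                )
    # non-maximum suppression: same-direction refinements within one window
    # of a stronger call are echoes of the same discontinuity
    unique: List[BreakpointCall] = []
    for call in sorted(calls, key=lambda c: -c.fold_change):
        if any(
            u.direction == call.direction
            and min((u.position - call.position) % L,
                    (call.position - u.position) % L) <= window
            for u in unique
        ):
            continue
        unique.append(call)
    unique.sort(key=lambda c: (c.position, c.direction))
    return unique


def _circular_mean(depths: np.ndarray, start: int, end: int) -> float:
    """Mean depth over circular interval [start, end)."""
    L = len(depths)
    start %= L
    end %= L
    if start < end:
        return float(depths[start:end].mean())
    return float(np.concatenate([depths[start:], depths[:end]]).mean())


def call_terminal_repeat(
    breakpoints: Sequence[BreakpointCall],
    profile: CoverageProfile,
    plausibility_band: Tuple[float, float] = (1.6, 2.6),
    gradual_threshold: int = 50,
    ambiguity_margin: float = 0.05,
) -> TerminalRepeatCall:
    """Pair up/down breakpoints into a terminal-repeat call.

    The repeat is the circular span from the up-step to the down-step; a
    pairing is plausible when the in-repeat/out-of-repeat mean depth ratio
    lies in ``plausibility_band`` (packaging theory predicts 2.0: two repeat
    copies per molecule).  Among plausible pairings the one with mean fold
    closest to 2.0 wins; near-ties raise :class:`AmbiguousRepeatError`
    rather than silently choosing.
    """
    depths = np.asarray(profile.depths, dtype=float)
    L = len(depths)
    ups = [b for b in breakpoints if b.direction == "up"]
    downs = [b for b in breakpoints if b.direction == "down"]
    if not ups or not downs:
        raise NoRepeatCallError(
            f"need at least one up and one down breakpoint, got "
            f"{len(ups)} up / {len(downs)} down"
        )
    candidates: List[TerminalRepeatCall] = []
    for u in ups:
        for d in downs:
            rlen = (d.position - u.position) % L
            if rlen == 0 or rlen >= L - 1:
                continue
            inside = _circular_mean(depths, u.position, d.position)
            outside = _circular_mean(depths, d.position, u.position)
            if outside <= 0:
                continue
            fold = inside / outside
            if not plausibility_band[0] <= fold <= plausibility_band[1]:
                continue
            boundary_class = (
                "gradual"
                if max(u.transition_width, d.transition_width) > gradual_threshold
                else "abrupt"
            )
            candidates.append(
                TerminalRepeatCall(
                    left=u, right=d, repeat_length=rlen,
                    mean_fold=fold, boundary_class=boundary_class,
                )
            )
    if not candidates:
        raise NoRepeatCallError(
            "no up/down pairing with a plausible in-repeat coverage fold "
            f"(band {plausibility_band})"
        )
    candidates.sort(key=lambda c: (abs(c.mean_fold - 2.0), c.repeat_length))
    if len(candidates) > 1:
        best, runner = candidates[0], candidates[1]
        if (
            abs(abs(runner.mean_fold - 2.0) - abs(best.mean_fold - 2.0))
            < ambiguity_margin
        ):
            raise AmbiguousRepeatError(candidates[:5])
    return candidates[0]
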