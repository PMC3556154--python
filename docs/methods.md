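# Methods

## Model

A non-permuted phage chromosome is the unit genome plus one extra copy of
the terminal repeat: packaging initiates at a fixed position (the left
repeat boundary) and cleaves one unit length plus one repeat length
downstream. In a collapsed circular assembly of length *L* with repeat
interval `[r0, r1)`, shotgun reads drawn from such molecules cover the
repeat twice per molecule, so expected depth is `2u` inside `[r0, r1)` and
`u` outside, with single-base steps at the boundaries when cleavage is
precise. All positional arithmetic is circular and 0-based half-open; a
breakpoint's `position` is the first base *after* the depth change, so the
repeat is exactly `[left.position, right.position)` and the physical right
terminus base is `right.position - 1`.

Two packaging variants are modelled besides the precise one: imprecise
right-end cleavage (the cleavage point deviates from the nominal boundary
by a Gaussian draw, which smears the down-step into a gradual transition)
and circularly permuted headful packaging (uniform starts, fixed headful
length), which produces no coverage discontinuity and serves as the
negative control.

## Simulator

The generator is first-class, tested code; its defaults are the study
conditions used throughout the tests and the acceptance script.

* Genome: i.i.d. bases at the requested GC (default 66.2%), unit length
  205,423 bp, repeat 10,287 bp — the dimensions of a large prolate
  siphophage assembly. The repeat is placed one third of the way around
  the circle so neither boundary coincides with the arbitrary origin.
* Molecules: default 40 per run. Imprecise cleavage uses a Gaussian
  right-end deviation (sd 70 bp in the gradual-boundary tests, chosen so
  the 10–90% span of the smear is ≈180 bp, a few-hundred-bp transition).
  Headful length defaults to 1.03 × unit length.
* Reads: lengths are truncated normal (mean 400, sd 80, floor 50),
  approximating FLX-Titanium-era pyrosequencing. Read *starts* are uniform
  over `[-(len-1), M-1]` and truncated to the molecule, so every base of
  the molecule — including the physical termini — has the same expected
  depth, and the repeat-boundary step is single-base abrupt. This matters:
  a model whose reads start uniformly *inside* the molecule would ramp
  depth down over a read length at each terminus and smear the boundary.
  Truncated slivers shorter than 20 bp are discarded. Coverage is defined
  against the unit genome (total read bases ≈ fold × L within 5%).
* Errors: substitutions only, at a per-base rate (default 0). Quality
  strings are constant Q30 placeholders. Homopolymer indels, flowgram
  artifacts and paired ends are out of scope.
* Tag ligation: a 49 bp tag is attached to a true molecule end with
  probability `termini_fraction` (default 0.37, i.e. roughly one in three
  ligation events at a genuine terminus) and otherwise to a uniform random
  break; default 52 tagged reads per run. Blunt end-repair is treated as
  position-neutral; resection is not modelled.

What ideal simulations do **not** reproduce: real libraries show mild
coverage bias, so the observed in-repeat enrichment on real data can
exceed the theoretical 2.0 (values around 2.2 have been reported); the
plausibility band below is deliberately wider than the ideal expectation.
Passing tests therefore demonstrate correctness of the detection contracts
under the stated read model, not robustness to every library artifact.

All randomness flows from one integer seed; the pipeline derives per-stage
generators with `numpy.random.SeedSequence.spawn`, so each stage is
independently reproducible.

## Read placement

The internal mapper indexes every 31-mer of the doubled circle and places
reads by exact seeding plus ungapped verification with a 2-substitution
budget; ties break deterministically (fewest mismatches, then smaller
coordinate, then forward strand). Reads whose best contiguous placement
exceeds the budget are split at the base where the budget is exhausted and
the tail is re-seeded independently (one level deep); tails too short to
place are soft-clipped. Reads shorter than the seed fall back to a direct
substring scan (they arise only as terminal slivers). Any external
placement engine honouring the same split-read contract can substitute via
SAM ingestion (`profile_from_sam`), which counts aligned blocks per base.

## Breakpoint detection

1. **Scan.** The ratio of adjacent window means is computed at three
   scales (window, 2×, 4×; default base window 200 bp). Positions where
   the ratio exceeds `min_fold` (default 1.5) or falls below its inverse
   become candidate runs. The coarser scales keep sensitivity when the
   transition is smeared or the flanking coverage fluctuates at
   read-length scale; spurious candidates are cheap because refinement and
   the pairing plausibility check discard them.
2. **Refinement.** Each candidate is refined to single-base resolution by
   a two-plateau least-squares step fit over ±window. Same-direction
   refinements within one window of a stronger call are suppressed as
   echoes.
3. **Transition width.** Around each breakpoint a plateau–ramp–plateau
   model is fitted by closed-form least squares with both plateau levels
   free, over a grid of ramp widths (0–600 bp) and offsets. Among fits
   within `4 σ²` of the optimum (σ² = plateau residual variance), the
   smallest width wins, so ideal steps report 0 under Poisson noise.
   Because depth noise is autocorrelated over the read length, the ramp
   fit alone can chase coverage drift; a second, local estimator — the
   two-window jump statistic `W_m = 4m (1 − s(m)/Δ)`, evaluated at
   increasing half-widths *m* until the window contains the ramp — cancels
   shared-read noise, and the reported width is the smaller of the two.
   Both estimators are exact on noiseless profiles (an ideal step gives 0;
   a constructed 200 bp linear ramp gives 200; a Gaussian smear with
   sd 70 gives ≈210, the least-squares ramp equivalent of its ≈180 bp
   10–90% span).
4. **Pairing.** Up/down breakpoints are paired into a repeat call when the
   in-repeat/out-of-repeat mean depth ratio falls in the plausibility band
   (default [1.6, 2.6], configurable for biased libraries); among
   plausible pairings the mean fold closest to the theoretical 2.0 wins,
   and near-ties (within 0.05) raise an explicit ambiguity error listing
   the candidates rather than choosing silently. Boundaries are classified
   `gradual` when either transition width exceeds 50 bp — chosen so that
   precise-cleavage boundaries (≤ a few bp) and imprecise ones (≈200 bp)
   separate with wide margin.

## Tag-ligation statistics

Reads containing the complete tag (both orientations, default 0
mismatches, configurable to 2 for noisier chemistry) are trimmed and their
genomic flanks (≥25 nt) mapped with the same mapper; the junction is the
first genomic base adjacent to the tag. Junction positions closer than the
cluster window (default 5 bp, strict) merge into clusters; each cluster of
support ≥2 is tested with a binomial tail probability under uniform
breakage (success probability window/L over n junctions),
Bonferroni-corrected over the observed clusters. Under the uniform null
with n = 41 junctions on a 205 kb genome this procedure calls a false
hotspot in ≈4% of replicates at α = 0.05 — the chance of two independent
breaks landing within one cluster window; a full scan-statistic correction
would be more conservative but was not needed at these margins.

Reconciliation matches each repeat boundary to its nearest hotspot with a
5 bp default tolerance (left boundary base vs `left.position`, right
terminus base vs `right.position − 1`) and reports
confirmed / partial / coverage-only / tag-only / discordant.

## Reopening

The physical chromosome starts at the left (packaging-initiation) boundary:
the circle is rotated so that boundary becomes base 0 and one repeat copy
is appended, giving `L + R` bases with bit-identical terminal copies. The
rotation is recorded so collapsing (dropping one copy, re-rotating) is the
exact inverse. For gradual right ends the called boundary is the
transition midpoint; the result is flagged approximate and carries the
transition width. Terminus positions are localized against supplied
CDS/tRNA annotations (strand-aware 1-based codon index inside a CDS,
flanking gene names when intergenic); annotations are consumed, never
created.

## Sequence calculators

* Intein splicing: inclusive residue span; mature = precursor − span
  length; spans touching residue 1 or the terminus are rejected (inteins
  are internal).
* Tape measure: `round(length_aa × 0.15 nm)`.
* Fiber range: `(ceil(L/20), ceil(L/12)) nm`; ceilings reproduce the
  customary hand-rounded ranges, though published ranges for specific
  proteins are sometimes rounded more loosely than any fixed rule.
* Slippery sites: literal X XXY YYZ heptamers, or a generic scan for
  `N1=N2=N3, N4=N5=N6`.
* Codon/tRNA coverage: strict Watson–Crick reverse-complement decoding of
  anticodons (no wobble), duplicate anticodons collapsed; the fraction is
  weighted by codon instances over all CDSs, stops and N-containing codons
  excluded.
* Genome identity: length-weighted mean percent identity of segments ×
  fraction of the genome covered after merging overlaps on the chosen
  axis; segments shorter than 50 bp are ignored and segments overlapping a
  declared terminal-repeat interval can be excluded (repeats are
  duplicated sequence and inflate identity). The statistic is
  direction-dependent, so both directions and their mean are reported with
  an asymmetry flag at 2 percentage points.

## Problem sizes

The test suite runs unit fixtures at 3–50 kb and the end-to-end checks at
the full 205,423 bp dimensions: ten 50× replicates for repeat-length
recovery and coverage fold, one 100× replicate for tag confirmation,
boundary classification and reopening, and 1,000 seeded replicates for the
hotspot type-I rate. The acceptance script runs one 100× replicate
(~51,000 reads, a few seconds on one CPU). These sizes are the package's
standard verification conditions; all scale linearly if enlarged.

## Known limitations

* The mapper is ungapped; indel-containing reads are split or soft-clipped
  rather than gap-aligned. Fine for substitution-dominated simulations and
  for depth computation; use SAM ingestion for real indel-rich data.
* Short cohesive-end (cos) overhangs, Mu-style host-DNA termini and
  protein-capped termini produce no coverage fingerprint and are reported
  as no-call (packaging unknown), by design.
* Hotspot detection assumes a uniform breakage background; strongly biased
  fragmentation would need a different null.
* The identity statistic ingests alignments; it does not align. Its value
  depends on the aligner's segmenting behaviour, which is why the aligner
  table (BLAST outfmt 6) is part of the interface.
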