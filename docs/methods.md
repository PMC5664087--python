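# Methods

This note records the models, conventions and numerical choices behind
`mitocap`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the bundled simulations do and do not show.

## The analysis problem

Capture-based sequencing of the mitochondrial control region (CR) from
degraded material — old bone and teeth, rootless hair — produces short
reads (roughly 30–300 bp, run means near 96–171 bp) aligned against the
16,569 bp circular mitochondrial reference. The analysis must

1. discard unreliable alignments without discarding the
   origin-spanning fragments a circular genome legitimately produces,
2. collapse PCR duplicates so each template molecule is counted once,
3. call a consensus haplotype as a list of differences to the
   reference in forensic position-plus-base notation,
4. summarise each run with enrichment, coverage, strand-bias and
   read-length metrics, and
5. assess authenticity of degraded material through terminal
   deamination (C→T / G→A) misincorporation profiles.

## Coordinates and circular geometry

All coordinates are 1-based and inclusive. A region with `start > end`
wraps across the origin; the CR is `16024-576` and enumerates
(16569 − 16024 + 1) + 576 = 1122 positions. Alignments against the
*linearised* reference never wrap: a fragment crossing the origin
arrives as an aligned arm ending at position 16569 plus a soft-clipped
arm (or starts at position 1). Membership and interval-overlap tests
are O(1) arithmetic on the two arms.

## Read filtering

A read is kept iff it is aligned, its mapping quality is **strictly
above 30**, and its aligned-to-soft-clipped base ratio is **strictly
above 0.75** — unless its aligned interval covers position 1 or 16569,
in which case the ratio test is waived (the origin exemption). The
ratio is A/(A+S) with A the M/=/X/I read bases (insertions are placed
read bases, not clipping) and S the soft-clipped bases; hard clips
carry no bases and are ignored. The exemption deliberately does not
waive the mapping-quality test. Filtering precedes duplicate marking.

Duplicate marking groups reads by (unclipped 5′ reference coordinate,
strand): forward reads use `start − leading clip`, reverse reads
`alignment end + trailing clip`. Within a group the read with the
highest base-quality sum survives; ties break to the lexicographically
smallest name. This is a deterministic, reproducible reduction of the
usual duplicate-marking heuristics. Its known failure mode is the
coordinate coincidence: two independent template molecules that share
an endpoint and strand are indistinguishable from duplicates, which
matters at high template diversity but is rare for the sparse template
counts typical of these libraries.

## Base counting and consensus calling

The pileup is a position × strand × {A,C,G,T,N,DEL} integer tensor.
M/=/X bases increment their position and the read's alignment strand;
deletions are tallied in the DEL channel but excluded from depth, so
"coverage" always means observed sequenced bases. Soft clips and
insertions touch no reference position (insertions are therefore never
called — a documented limitation, acceptable because insertion-rich
poly-C tracts are excluded from calling anyway).

Consensus calling uses duplicate-removed counts (duplicates carry no
independent evidence; a switch allows all-read counts). At each region
position with total depth ≥ 2 (the same minimum as the coverage-breadth
convention) the majority channel among A/C/G/T/DEL is compared to the
reference:

- divergent majority with support ≥ 0.75 → variant;
- divergent majority below 0.75 → listed as uncalled
  (`below_threshold`) with its fraction — point heteroplasmy is
  disregarded, never asserted;
- ties prefer the reference, so fluctuation noise cannot produce a
  call;
- support is the fraction of *reads* covering the position. A stricter
  per-strand mode (threshold met on every covered strand) is available
  but not default: runs with extreme strand imbalance still yield
  valid haplotypes.

The C-tract 310–316 is excluded by default; further poly-C tracts
(16183–16194, 568–573) are offered in configuration because
homopolymer length artefacts concentrate there. Reference-N positions
are reported uncallable.

Haplotype comparison is restricted to the jointly callable region;
a conflict is any position where two confident calls differ (including
variant vs. confident reference call). Positions uncalled on either
side never count against concordance.

## Run metrics

Percentages of mitochondrial, human-genome and unaligned reads are
computed from per-read labels against total reads; the label channel
replaces a secondary nuclear-genome alignment. Gross enrichment is the
mitochondrial percentage with duplicates included. CR-read membership
is ≥ 1 bp interval intersection with the CR. Coverage breadth uses
depth ≥ 2; CR depth statistics are taken over all 1122 CR positions,
counting uncovered positions as depth 0. Read length is the full
molecule length including soft-clipped bases. Empty denominators yield
0 rather than an error, matching how empty runs are tabulated.

Strand bias is the **unweighted** per-position mean of
forward-depth/total-depth over covered positions (the pooled,
depth-weighted ratio is available as a switch). Within-run coverage
SDs use the population (n) convention; cross-run aggregation reports
the mean together with *both* SD conventions, because published
summary tables demonstrably mix them between columns — the bundled
published control-run values (see `mitocap.refdata`) reproduce their
summary row only when the between-run CR-coverage SD uses n−1 and
others use n. Reports label the convention explicitly; internal values
are never rounded (display rounding is decimal half-up).

The module also provides the small analytic utilities used alongside
such runs: Pearson correlation, dsDNA copy-number-from-mass conversion
(N = m·N_A/(L·660 g·mol⁻¹·bp⁻¹); note that one published figure for a
5 pg / 405 bp amplicon is not reproducible with any standard molar
mass and is therefore not asserted anywhere), and a k-mer
linguistic-complexity score — the product over k = 1..k_max of
distinct observed k-mers over min(4^k, |s|−k+1) — which separates
di-/trimeric repeat reads from alignable sequence.

## Damage profiling

For every aligned read the mismatch columns are mapped into the
molecule frame (reverse-strand alignments are flipped and
complemented, so offset 0 is the molecule's 5′ terminal base;
distances index the full read including soft-clipped bases, but only
aligned columns contribute). At distance i from the 5′ end a
reference-C column counts an opportunity, and a mismatch when read as
T; symmetrically G→A from the 3′ end. For reads shorter than two
windows, positions beyond the midpoint belong to the far end only, so
no base is double-counted. Distances with zero opportunities are
missing (NaN), never zero. The window default is 25 bp, past which
terminal damage has decayed to background.

The decay model is f(i) = amplitude · decay^i, fitted by least squares
weighted by opportunity counts (binomial-precision proxy) with
parameters clamped to [0,1] × (0,1). An all-zero profile returns
amplitude 0 with the decay flagged unidentifiable. The model has no
constant term, so a flat error baseline (sequencing error ≈ e/3 per
mismatch class) biases the fit slightly upward; parameter-recovery
claims are therefore stated for error-free simulation, and empirical
profiles from real data should be read as damage plus error. The full
Bayesian position-specific posterior machinery of dedicated
ancient-DNA damage tools is intentionally out of scope; the empirical
profile and the two fitted parameters are the authenticity readout.

## The simulator and what it emulates

`simreads` generates the statistical structure of a capture library
from a degraded sample, with full truth records. Per template
fragment: start uniform over the target region (wrap-aware) or the
whole genome; length from a truncated normal; strand uniform; planted
substitutions; damage applied in the molecule frame with probability
amplitude·decay^i from the relevant end (C→T from 5′, G→A from 3′);
independent uniform substitution errors; k ~ Poisson extra PCR copies
(by default byte-identical, i.e. errors drawn before duplication — the
conservative case for duplicate-marking tests; amplification-then-
error is a switch). Background reads are i.i.d. uniform-composition
sequences whose only role is to be unalignable, plus a label channel
marking the fraction that would have aligned to the nuclear genome.

Defaults are the observed positive-control conditions of the assay
this package models: fragment mean 147.08 bp, SD 50, minimum 30;
97% background (gross enrichment ≈ 3%); 56.5% of background labelled
human; 35% of mitochondrial fragments off-target (≈ 65% CR reads);
Poisson duplication rate 2 (≈ one third of mt reads unique);
unalignable-read length mean 52 bp (human-labelled background follows
the mt fragment-length distribution, as observed); per-base error 0.01;
constant Q30 qualities (qualities matter only to duplicate-survivor
selection).

Not emulated: indels and homopolymer-length artefacts, platform strand
preference, PCR chimeras, two-person mixtures, real nuclear or
microbial sequence content, base-quality variation. Passing the
simulation-based tests therefore demonstrates the pipeline's logic and
statistics, not robustness to those real-data phenomena.

Truth alignments are emitted directly as SAM (full-match CIGAR;
origin-spanning fragments as aligned arm + soft-clipped arm; background
unmapped), bypassing external aligners so the whole pipeline is
testable hermetically. The bundled reference is a synthetic 16,569 bp
sequence with mtDNA-like base composition generated from a fixed seed;
a real reference FASTA is accepted as input everywhere.

## Problem sizes and determinism

All simulation-backed tests and the acceptance script use fixed seeds
and moderate problem sizes chosen for statistical adequacy: consensus
recovery at ≥ 20× (clean) and ≥ 50× (1% error) CR depth; damage
parameter recovery at 50,000 fragments per condition, where the
terminal-frequency standard error is ≈ 0.4% absolute; duplicate
accounting at 50 templates over the whole genome, where coordinate
coincidences are improbable and the no-collision precondition is
asserted explicitly. Identical seeds give byte-identical simulator
output.

## Known limitations

- Insertions and homopolymer length variation are not called.
- The duplicate criterion conflates genuine duplicates with coordinate
  coincidences (see above).
- The decay fit has no error-baseline term.
- Strand bias, complexity and damage summaries are descriptive; no
  hypothesis tests are attached.
- Single-end reads only; mate information, if present, is ignored.
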