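# Methods

`ribodyn` models the computational workflow of a long-term evolution study
of the budding-yeast rDNA locus: a tandem array of ~9.1-kb repeat units on
chromosome XII whose copy number wanders under unequal recombination, is
actively recovered toward a setpoint when the replication-fork barrier
(RFB/Fob1) pathway is intact, and drifts downward when it is not. This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic data do and do not establish.

## The repeat unit and tandem arrays

A `ReferenceUnit` is a single repeat with named element intervals (35S and
5S rRNA genes, the rARS replication origin, the E-pro non-coding promoter,
and the RFB). The default sequence is uniform random ACGT: none of the
analyses in this package depend on real sequence content, only on
coordinates, and a real unit can be supplied via FASTA. The default layout
is schematic (35S occupying the first 6.6 kb, the spacer elements in the
remainder); intervals must be disjoint and inside the unit.

A `TandemArray` is `left_arm + n_c edited copies + right_arm`. Per-copy
edits are SNVs (position, alt base) and internal deletions (half-open
intervals; overlapping deletions within one copy are rejected so length
arithmetic stays exact: realized length = |arms| + n_c·L_unit − Σ deleted).
Arms are random flanks drawn from a stream decorrelated from the unit's,
so an arm never silently duplicates unit sequence.

Defaults of `L_unit = 9,100 bp` and a 150-copy setpoint are standard
wild-type yeast values; both are configuration, as is the 1,050-kb
non-rDNA "backbone" of chromosome XII used by the gel conversion.

## Read, pileup, gel, and flow-cytometry simulators

**Long reads** start uniformly on the array; lengths follow a truncated
log-normal (median ≈ 10 kb, range 1–50 kb) chosen to straddle the QC
length threshold so the filter is actually exercised; reads running off
the array end are truncated and logged. Substitution errors are uniform at
the given rate (no homopolymer or context structure — a deliberate
non-goal). Per-read mean Phred is Normal(22, 4) with per-base jitter,
clamped to [0, 60], again chosen to straddle the Q18 filter; FASTQ output
is Sanger-encoded (Phred+33). Each read records its true origin interval
and the planted deletion junctions it spans, which is what the SV
sensitivity tests score against.

**Pileups** collapse all copies onto unit coordinates analytically: at
each position the state probabilities over {A, C, G, T, deletion} mix the
n_c copies equally, substitution error moves mass uniformly to the other
three bases, and counts are one multinomial draw per position at exactly
the requested coverage. A variant in k of n copies therefore has expected
frequency k/n — the detection-limit geometry of population sequencing of
a tandem repeat.

**Gel lanes** are mixtures of Gaussian bands (SD `band_width`, default
0.6 mm) centered where the truth calibration places each copy number,
plus half-normal baseline noise; a wide copy-number distribution yields a
visibly broader band (a "smear") than a clonal sample. No mobility physics
is modelled — the calibration map *is* the gel model.

**DNA-content histograms** are two Gaussian peaks (G1 at `ploidy × u`,
G2/M at twice that, u = 100 arbitrary units) with coefficient of variation
`peak_cv`, binned over a fixed 256-bin range.

## Copy-number trajectory model

The trajectory generator is a biased, copy-count-scaled random walk — the
simplest generative structure consistent with the qualitative behavior the
analyses must detect; no mechanistic fidelity is claimed and absolute
calibration to any measured time course is deliberately not attempted.
Per generation and per chromosome:

- a recombination event fires with probability
  `recomb_rate × copies / setpoint` (default rate 0.02; more repeats,
  more substrate), changing copies by Normal(0, `step_sd` = 6) in WT mode
  or Normal(−`deletion_bias` = −3, 6) in fob1 mode (strictly negative mean,
  no recovery);
- in WT mode only, a recovery event fires with probability
  `recovery_rate × |total − ploidy·setpoint| / setpoint` (default rate
  0.05) and steps the *total* back toward the setpoint; the homolog that
  changes is drawn in proportion to its copy count, which is what makes
  the higher-copy homolog of a diploid the more variable one;
- copies are floored at `min_viable` (default 2).

Under these defaults, fob1-mode runs lose on the order of 30–60 copies
over 900 generations with ≥20/24 replicates showing negative OLS slopes,
while WT runs stay within a few copies of their start on average — the
directional structure the drift analysis is designed to read out.

## Gel quantification

Ladder calibration is piecewise-linear interpolation of log10(size)
against migration distance — the standard empirical treatment; evaluation
at a knot returns the marker size exactly, and queries outside the knot
range extrapolate the terminal segment with a warning. The map is
strictly monotone and therefore invertible, and the simulator uses the
inverse of the *same* calibration, making noiseless round trips exact up
to grid resolution.

Band detection subtracts a lower-envelope baseline (rolling minimum over a
10-mm window — kept much wider than a band, since a window comparable to
the band width demonstrably skews the apex) and runs standard peak finding
with a prominence floor expressed as a fraction of the corrected maximum.
A smeared band is summarized by its apex by default; the intensity
centroid is available as an option. When a lane shows several peaks
(e.g. two chromosome XII homologs in a diploid), the caller selects by
area or supplies an anchor; `copy_shift` anchors the time-point lane to
the generation-0 peak (tie broken toward larger area) and sizes both lanes
with the same calibration so ladder error largely cancels. Band
proportions integrate baseline-subtracted signal over user-supplied
disjoint windows; an all-zero lane is flagged undefined rather than
normalized. ERC quantification is the same operation with ERC-vs-genomic
windows — there is no ERC-specific code path.

## Bin-split SV calling

QC passes a read iff length > 8,000 nt AND mean Phred > 18, both strict
(a read of exactly 8,000 nt or mean exactly 18.0 fails). Mean quality is
the arithmetic mean of Phred scores, matching common basecaller
summaries; an error-probability-domain mean is available behind a flag.
Reads are cut into 300-nt bins, the sub-bin tail discarded.

The unit is treated as circular: the mapper indexes the unit extended by
one bin length and looks up exact 15-mers from the bin, verifying each
candidate offset by Hamming distance over the wrapped window
(≤ 60 mismatches, i.e. 20% of a bin). Fewest mismatches wins; ties break
to the lowest offset, then to the forward strand. Reverse-strand hits are
reported reflected (`L − bin_len − p mod L`) so that consecutive bins of a
reverse-strand read still advance by +300 along the unit and one deviation
rule covers both strands. The test suite holds this mapper to exact
agreement with an exhaustive Hamming scan over every offset and both
strands.

For consecutive mapped bins i < j (unmapped bins skipped; the expected
distance scales as (j − i) × 300, preserving sensitivity when one noisy
bin fails to map), the observed distance is the representative of
(pos_j − pos_i) mod L nearest the expected value. This makes
unit-junction crossings — the common case in a tandem array — deviation-
free by construction, while a deletion of d bp (d ≤ L/2) surfaces as
deviation +d and an insertion as −d. The unrestricted (signed) choice of
representative is deliberate: constraining it to non-negative multiples
would misreport every insertion as a large deletion. A call is emitted iff
|deviation| strictly exceeds 100 nt, typed deletion (+) or
insertion/duplication (−), size = |deviation|. Mixed-strand bin pairs are
inversion-like and excluded from the rule. Note the rule's intrinsic
blind spot: with the 100-nt tolerance, deletions of 51–100 nt can never
fire a call even though summaries nominally cover deletions ≥ 50 nt; the
implementation follows the literal rule and leaves the gap.

Sample summaries run QC → bins → map → call and tally a weakly decreasing
filter chain (input → QC pass → ≥ 2 mapped bins → reads with calls).
Headline rates count deletion calls of size ≥ 50 nt only; insertion calls
are reported but excluded, being harder to separate from sequencing error.
Pre-mapped bins can be supplied as SAM or PAF (query names
`<read>:bin<i>`); the import path feeds the identical calling code, and
round-trip tests require identical call sets. The SAM reference is
declared one bin longer than the unit so origin-wrapping bins fit a linear
coordinate; import folds positions modulo L.

## Variant spectra

Tallying counts {A, C, G, T, deletion} per unit position from SAM
alignments (via aligned pairs, CIGAR-aware for deletions) or from the
simulator's pileup table; an optional base-quality floor is off by
default. Frequencies are (coverage − ref count)/coverage, with
below-floor positions reported missing (NaN), never zero. Two spectra are
compared by paired per-position differences (b − a) over jointly covered
positions, summarized by the mean difference, a seeded position-bootstrap
percentile interval, and the positions whose |difference| exceeds a
reporting floor (default 0.05). The bootstrap is an artifact-level
summary choice — the underlying comparison in the motivating setting was
descriptive — and the comparison is antisymmetric by construction.

## Generation accounting, drift, ploidy

Doublings-as-generations assumes every viable cell divides until
saturation: log2(dilution) per liquid transfer (1,000-fold → 9.97,
reported as ≈10), log2(cells) per colony (1.165 × 10⁷ → 23.5). The known
tension between a 2^23.5-cell colony and the ~20 generations usually
quoted for colony growth is documented, not reconciled — death and
non-dividing cells make log2(N) an upper bound. Drift uses per-replicate
OLS slope of (total) copies on generation (all time points, ≥ 3 required)
rather than end-minus-start, which is available as an option; signs are
tallied with a ±0.005 copies/generation zero band. Ploidy is classified
by the ratio of dominant histogram modes (3-bin smoothing before the
argmax), "doubled"/"unchanged" within ±0.2 of 2 or 1, else "ambiguous".

## What the synthetic data do not show

Passing tests demonstrate that the analysis chains are internally correct
and invert the simulators at realistic signal-to-noise; they do not
validate against real gels, basecallers, or aligners. In particular the
read simulator has no context-dependent error structure, the gel model
assumes Gaussian bands and a perfectly known ladder, the trajectory model
encodes directionality but not the true event-size distribution of
unequal recombination, and the FACS model has no cell-cycle structure
beyond two peaks. Real-data entry points (FASTQ, SAM/PAF, lane-profile
and histogram TSVs) exist precisely so those assumptions can be bypassed.

## Problem sizes

Test and verification runs use 12–20-copy arrays, 25–60 reads per sample,
coverage 500–2,000, 50-seed Monte-Carlo loops for gel and bootstrap
properties, and 24 replicates × 900 generations for trajectories — sizes
at which every chain, including the exhaustive mapping oracle, runs in
seconds to a couple of minutes on one core while leaving the statistical
assertions well-powered.
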