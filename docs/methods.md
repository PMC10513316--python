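# Methods

This note documents the models, defaults and design choices behind each
stage of the pipeline, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Oligo thermodynamics

Duplex stability is computed with the Breslauer (1986) nearest-neighbor
stacking parameters: ΔH and ΔS are sums over the 16 dinucleotide stacks
plus an initiation entropy of −10.8 e.u. (the Breslauer set has no
enthalpic initiation term). The melting temperature is the two-state
expression

    Tm = ΔH / (ΔS + R ln(C/4)) − 273.15 + 16.6 log10([Na+]eq)

with C the oligo concentration (C/4 because a PCR primer is
non-self-complementary and in excess over template) and the
Schildkraut–Lifson salt term evaluated at the monovalent equivalent
[Na+]eq = monovalent + 120·√(divalent − dNTP) mM, free magnesium clamped
at zero when dNTPs exceed it. This combination is the documented
behaviour of the Primer3 lineage with the Breslauer table selected,
which is the convention the assay's oligo panel was designed under.
SantaLucia unified parameters, mismatch/dangling-end terms and
secondary-structure prediction are deliberately out of scope: the
package's Tm is used for *ordering and balancing* candidates, not as a
physical prediction, and no experimental Tm exists to validate absolute
values against. Defaults — 50 mM monovalent, 2 mM Mg²⁺, 0.2 mM dNTPs,
0.4 µM oligo — are the assay's stated buffer. Temperatures are reported
to 0.1 °C, matching the resolution at which melt windows are specified.

## Candidate design and scoring

The allele-specific primer is the flank sequence ending 3′ on the SNV
with the mutant base; the blocker is the wild-type window with the SNV
at position ⌈L/2⌉ of the oligo (exact center for odd lengths, one base
5′ of center for even lengths — the convention that reproduces the
published even-length blocker) and a 3′-phosphate. Both exist in two
orientations (forward/downstream and reverse-complement/upstream), and
`enumerate_candidates` forms the full Cartesian product with opposite
primers, exactly reproducing the published 27- and 45-combination
panels.

Scoring is an explicit heuristic, not a claim about the empirical
selection: score = −|Tm_blocker − Tm_allele − Δ*| minus a fixed penalty
(default 2 °C-equivalents) for the hottest member of the allele-primer
family and of the blocker family. The target gap Δ* defaults to 5 °C —
a documented guess, exposed as a parameter, chosen because the blocker
must out-compete the primer on wild-type template (so hotter than the
primer) without suppressing the mutant reaction (so not much hotter).
The family-maximum penalties encode the two observed failure modes: the
hottest allele primer amplifies wild-type template despite the blocker,
and the hottest blocker slows or kills the mutant reaction. The
heuristic's agreement with the bench choice (coolest blocker preferred,
hottest primer avoided) is treated as a regression check only.

## qPCR call logic and sensitivity model

A well is *specific* iff it has a Ct and a melt peak inside the closed
window [80, 81] °C; a Ct without a peak cannot be confirmed and counts
as non-specific. A sample is positive iff ≥1 replicate is specific at
Ct ≤ cutoff; the cutoff defaults to the run's cycle count and should be
set explicitly (e.g. 45) when calling 90-cycle screening runs, which
exist to surface non-specific amplification rather than to call
samples. No replicate-majority rule is applied (any specific replicate
is detection); this is configurable at the call site by the caller
filtering records.

The dilution model: Ct = intercept + slope·log₁₀(copies) + N(0, σ),
slope −3.32 cycles/log₁₀ (100% efficiency), intercept 43.13 so that
9000 copies give Ct ≈ 30, σ = 0.3 cycles. Specific products melt at
N(80.5, 0.12) °C, concentrated well inside the window. Wells without
mutant template do not amplify except for breakthrough events
(probability 0.02 per well by default), which are equally likely to be
*late* specific amplification (Ct uniform on [60, max]) or non-specific
product (peak uniform on [73, 79] °C) — both forms are rejected by the
call logic, which is why screening across many seeds yields no false
positives. Fitting uses ordinary least squares of Ct on log₁₀(copies)
(scipy), restricted to specific amplified wells.

## Read counting

Demultiplexing and allele assignment follow exact substring
co-occurrence: a read (or its reverse complement) must contain exactly
one panel barcode, and the oriented read exactly one of the two
SNV-spanning signatures. Reads matching two barcodes are discarded as
chimera candidates; reads containing both signatures are ambiguous;
barcode-only reads are counted but uninformative. The signature length
defaults to k = 11 centered on the SNV — unique within the 137-bp
amplicon, clear of the annealing and reverse-primer regions, and short
enough to survive read errors often. The per-barcode ratio is
100·n_mu/(n_wt+n_mu) rounded half-up to one decimal, reported only at
sufficient depth (≥1000 informative reads by default). The
positive/negative threshold on the ratio defaults to 0.0% — any
rounded-nonzero mutant fraction is positive — which is a documented
choice: observed true positives were ≥0.1% and true negatives exactly
0.0%, so no printed value constrains the threshold between them.

An optional edit-distance mode (`max_mismatch > 0`, via edlib) exists
for noisier reads. Because the two signatures differ at exactly one
position, presence/absence testing is meaningless at tolerance ≥1;
instead the read is assigned to the strictly nearer signature by best
infix edit distance, with ties ambiguous. At tolerance 0 this reduces
exactly to the substring semantics above. The mode is off by default:
exact matching is the fidelity baseline, and the bias properties of
distance-based assignment under asymmetric error are not characterised
here.

## Synthetic data

The fixture templates are *designed* sequences, not the genomic locus:
every published primer, blocker and annealing part occurs in them
character-exactly, in the correct order, orientation and spacing around
the T>A substitution (all of which is forced by the overlaps among the
published oligos), but the unpublished stretches between landmarks are
fixed arbitrary filler. Spacer lengths were chosen so the sequenced
region (annealing-part start through reverse-primer site) is exactly
137 bp; the individual detection amplicon lengths are then fixed by
geometry (67–102 bp) and are not claimed to match the bench amplicons.
Tests therefore exercise sequence *logic* (matching, counting,
geometry), not alignment to a real genome.

Read simulation assembles pad + barcode + template body, draws the
mutant allele with the configured probability, applies independent
per-base substitution / insertion / deletion errors, and
reverse-complements half the reads. Quality strings are placeholders;
classification is sequence-only. Default error rates are substitution
1×10⁻⁴, insertion 2×10⁻³, deletion 3×10⁻³ per base. The indel-dominated
profile mirrors current nanopore chemistry, and the substitution
component is deliberately the smallest because it is the only error
mode that can *fabricate* an allele: a substitution landing exactly on
the SNV converts a wild-type read into a perfect mutant signature,
whereas indels and off-SNV substitutions merely void the exact match.
The assay's observed behaviour — mutant-free samples measuring 0.0% at
≥1000 reads while true positives are resolved at 0.1% — bounds that
fabrication mode below ~10⁻³ per read, and the default is calibrated to
that observed floor. What the simulator does *not* model: quality
scores, homopolymer-length-dependent indels, context-dependent
substitution spectra, chimeric PCR products, barcode cross-talk from
index hopping, and coverage imbalance between pooled samples. Passing
tests therefore demonstrate the counting logic and its statistical
behaviour under a plausible error budget, not performance on a real
flow cell.

Standard samples are modelled as concentrations only (mutant copies,
wild-type copies, carrier ng/µL, all per µL) with exact linear volume
mixing; the equal Mu/WT mix reproduces the 9000 mutant copies/µL top of
the dilution series, and serial dilution uses round-half-away-from-zero
to integer copies (9000, 3000, 1000, 333, 111, 37).

## Determinism and numerics

All simulators take an explicit seed (numpy `default_rng`) and are
byte-reproducible. Ratios are rounded half-up via exact decimal
arithmetic to avoid float-representation artefacts at the x.x5
boundaries. Tm ties in ranking are broken by input order (stable sort).
Degenerate inputs are rejected with messages naming the offending
position/file/line rather than silently coerced; the one deliberate
clamp is negative free magnesium (excess dNTP) in the salt conversion.

## Problem sizes

The shipped test suite and acceptance script use 10⁵ reads for the
fraction-recovery checks, 2×10³ reads for the mutant-free pool, 10³
reads for the counting oracle, 10³ random oligos for the thermodynamic
properties, 10³ seeds for the screening false-positive property, and 20
random fractions at 10⁴ reads each for recovery across the range —
sizes at which the binomial tolerances quoted in the tests are
meaningful while the whole suite runs in well under a minute of compute
for the statistical parts.

## Known limitations

* Absolute Tm values are pinned only by an independent transcription of
  the published parameter table; no experimental melting data exists
  for these oligos.
* The candidate score is a two-parameter heuristic; it is not fitted to
  any quantitative outcome and should be re-examined before use on a
  different locus.
* The qPCR simulator's breakthrough model is phenomenological (late or
  non-specific), not mechanistic; it reproduces the *call-level*
  behaviour of negative controls, not fluorescence traces.
* Sanger interpretation, basecalling, and wet-lab protocol steps are
  out of scope; the pipeline starts at oligo sequences, well-level qPCR
  outcomes, and basecalled reads.
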