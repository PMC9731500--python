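# Methods

## Site-calling model

The caller detects m6A through the crosslink chemistry of antibody-based
eCLIP: reverse transcription through the antibody adduct on a methylated
adenosine induces a C→T conversion at the base immediately 3′ of the A.
Since m6A resides in the RAC motif (purine, methylated A, C), the
evidence for a site at adenosine position *a* is the T count among reads
covering the C at *a* + 1.

A candidate position is called when three filters pass simultaneously:

| filter | default | notes |
| --- | --- | --- |
| motif | R-A-C at *a* − 1 … *a* + 1 | R ∈ {A, G}; transcript-edge positions lack context and are never callable |
| event count | ≥ 3 C→T reads | lowered to 2 in reduced mode |
| frequency window | 2.5% ≤ *k*/*n* ≤ 50% | both bounds inclusive |

Confidence tiers: **high** = ≥ 3 events in ≥ 5% of reads, **low** =
≥ 3 events in 2.5–5%, **reduced** = exactly 2 events (only reachable in
reduced mode). The frequency window applies in reduced mode too; the
reduced threshold is understood as lowering only the event count.

The 50% ceiling is interpreted as variant exclusion: a position mutated
in most reads of a library behaves like a genetic variant, not like
sub-stoichiometric crosslink chemistry. This interpretation is the
package's own; it is also the reason input subtraction and the ceiling
overlap in what they remove (a heterozygous-like 40% signal is removed
by subtraction, a fixed 100% signal already fails the ceiling).

Input subtraction runs the same calling parameters on the input library
and removes IP calls whose exact (transcript, position) also appears
there; an override for separate input thresholds exists but is off by
default. Consensus requires exact coordinate identity in ≥ 2 replicates
— the method is single-nucleotide, so no fuzzy matching window is
applied — and does not require tiers to agree across replicates.

### Frequency denominator

The denominator of *k*/*n* is the total read depth at the C position,
all base columns included. N bases count toward depth; reference
positions deleted in a read are tallied in the N column, so a deletion
spanning the C contributes to depth but never to the C→T count. This
keeps the container invariant "depth = sum of base counts" exact.

### Strand handling

The pipeline operates in transcript space on stranded libraries.
Reverse-strand alignments are excluded and counted in the log rather
than complemented: silently complementing would risk double-counting
conventions, and the libraries this models are stranded. Secondary and
supplementary alignments are always excluded; a mapping-quality floor is
exposed but defaults to 0.

## Simulator

`simulate_library` emits sense-strand, ungapped, fixed-length alignments
tiling each transcript at a target mean coverage, written directly as
SAM (plus FASTQ) so no aligner is involved. The generative law at a
planted site is explicit: an IP read covering the +1 base carries a T
with probability stoichiometry × ip_enrichment × conversion_prob;
input libraries carry no conversion chemistry. Conversions are applied
before background noise and background substitutions never overwrite a
converted base, so with zero background error the conversion count at a
site is exactly Binomial(local depth, s·e·c) — the oracle the tests use.

Defaults: read length 50 nt, depth 200×, background substitution rate
10⁻³ per base, IP enrichment 1.0. Planted sites are kept ≥ 2 read
lengths apart (`min_spacing`, default 100 nt) so no read spans two
sites and the per-site binomial oracle stays exact. Site contexts are
created by editing at most 3 nt of the reference; the edited reference
is what gets written and simulated from, so reads and reference never
disagree. Per-site stoichiometry is a free parameter: the endogenous
regime in the motivating biology is ~25% methylation, and the
recovery-benchmark conditions use full stoichiometry with conversion
probability 0.15.

What the simulator does not model: UMIs and PCR duplicates, indels,
paired-end chemistry, position-dependent coverage bias, reverse-strand
reads, and multi-exon (genome-space) coordinates. Passing the recovery
benchmarks therefore demonstrates correctness of the counting and
thresholding logic under the stated generative law, not robustness to
alignment artifacts or library-prep biases of real data.

## Downstream operators

**Percent input.** recovery = input_fraction × 2^(Ct_input − Ct_ip),
with amplification efficiency fixed at 2.0 (no efficiency correction).
The exact dilution bookkeeping is this module's convention, exposed via
`input_fraction`; recoveries above 1 are returned but flagged. Region
profiles divide each region's recovery by that of an m6A-free reference
region, which maps to exactly 1.0.

**Chromatin association.** A ΔΔCt chain:
ratio = 2^−[(Ct_target,chr − Ct_target,input) − (Ct_norm,chr − Ct_norm,input)],
divided by the baseline condition's ratio, so the baseline is exactly
1.0. Whether the housekeeping normalizer is referenced to input or
total RNA is ambiguous in general; this chain (both target and
normalizer referenced to input) is the consistent reading implemented.

**Doubling time.** Ordinary least squares of log2(confluence) on time;
doubling time = 1/slope. This log-linear fit is the closed-form,
deterministic equivalent of least-squares exponential fitting up to the
noise model. Non-positive slopes are flagged non-growing with NaN
doubling time rather than raising. Exact recovery on noiseless
exponentials is a test invariant; with 1% multiplicative noise at a 2-h
cadence over 48 h the median absolute relative error stays well under
5%.

**Peak proximity.** A site is proximal when the nearest peak *edge*
lies within the window (inclusive), distance 0 inside a peak. Edge
rather than center, and boundary inclusivity, are the package's
conventions — the window size is the only externally fixed quantity.
Sites are taken in the same 0-based coordinate system as the BED peaks.

**Metaprofile.** Mean signal per offset bin over [−halfwidth,
+halfwidth] across sites; sites near sequence ends contribute only their
valid offsets, and empty bins report NaN rather than 0.

**Antimorph classification.** Among genes significant (adjusted
p < α = 0.1) in contrast A: same-direction if also significant in B
with matching fold-change sign, opposite (the antimorph class) with
opposing sign, A-only otherwise; genes significant only in B are
B-only. A zero log2 fold change has no direction and falls into A-only.
Adjusted p values are consumed as given — the expression pipeline that
produced them owns the multiple-testing correction; none is re-applied.
The fold-change correlation uses genes with linear |FC| > 1.15 in both
contrasts (i.e. |log2FC| > log2 1.15) and is reported on signed-linear
axes (a halving written as −2) by default, with the log2-axis variant
alongside, plus the least-squares trend line.

## Synthetic downstream tables

`tables.py` generates inputs with planted truth for each operator. The
qPCR generators invert the closed forms (a Ct pair encoding a chosen
recovery; Ct quartets encoding chosen fold differences), so recovery of
the encoded value checks the implementation against its own inverse.
The growth generator emits exponential confluence at a 2-h imaging
cadence, truncating once the well saturates (95% confluence), with
lognormal multiplicative noise. The proximity generator spaces sites
10 kb apart and plants a 20-nt peak uniformly inside the window for a
chosen subset.

The fold-change generator plants category membership exactly (signs and
significance labels) and draws magnitudes randomly: genes significant in
both contrasts draw |log2FC| pairs from a correlated bivariate normal
(mean 1.5, sd 0.6, correlation 0.9, values clipped above the 1.15
filter), and genes significant only in the first contrast carry small
sub-significant second-contrast changes (uniform between log2 1.15 and
1.0, sign opposing the first contrast with probability 0.85) —
reflecting that the antimorph trend extends weakly into genes that do
not reach significance in the mutant contrast. These magnitude
parameters were fixed once by matching the generator's filtered
fold-change correlation to the anticorrelation regime the classifier is
meant to detect (r ≈ −0.48); they are generator properties, not
classifier inputs.

## Problem sizes

The recovery benchmark simulates 20 planted sites at full stoichiometry
(conversion 0.15) across four 1.2-kb transcripts, three replicate
IP/input pairs at 200–500× depth, background error 10⁻³, repeated over
five seeds — about 10⁶ reads total, which keeps the full test suite in
the tens of seconds. The brute-force oracle check runs at ≤ 200 reads
where an exact text-level recount is feasible.

## Known limitations

* The caller is threshold-based by design; no statistical model of
  conversion counts (and hence no per-site p value) is provided.
* Transcript-space only: genome-space G→A mirrors on the minus strand
  and multi-exon liftover are out of scope.
* The simulator's uniform-coverage, error-free-alignment regime is
  favorable; sensitivity/precision figures from it are upper bounds on
  real-data performance.
* qPCR arithmetic assumes perfect primer efficiency throughout.
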