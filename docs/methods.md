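# Methods

## The measurement model

Non-denaturing bisulfite treatment converts a cytosine to uracil (sequenced
as T) only while that cytosine is in single-stranded form. On chromatinized,
double-stranded DNA the conversion frequency at a position is therefore the
product of two probabilities: the chance the position was transiently exposed
as ssDNA in a given molecule, and the chemical conversion efficiency given
exposure. Each strand reports its own cytosines: a top-strand conversion
appears as T at a reference C; a bottom-strand conversion appears — once
mapped into top-strand coordinates — as A at a reference G. The two
strand-specific rate formulas,

- top: `T / (C + T) × 100` at reference C positions,
- bottom: `A / (G + A) × 100` at reference G positions,

use only the concordant bases in the denominator, so sequencing errors to
other bases reduce depth rather than biasing the rate. Counting keeps the two
strand partitions separate (a bottom-strand read never contributes to a
top-strand denominator); a pooled per-position view is provided for the
boundary scan, because both strands show the same exposure transition.

## Synthetic data: what it emulates and what it does not

The generator is the package's test bed and defines the conditions every
downstream claim is verified under.

- **Reference**: iid background at a configurable GC content (default 0.40,
  approximately the yeast genome), with one planted inverted repeat —
  default arm 15 nt, loop 9 nt, left arm starting at position 1011 of a 2 kb
  element, mirroring the geometry of an IR at the 5' end of a ~1 kb silencing
  region. The generator verifies the planted IR is the unique detector hit
  and deterministically resamples otherwise.
- **Exposure**: a two-regime step function, default 0.20 per molecule per
  cytosine upstream of the boundary and 0.04 at/downstream of it. The
  defaults are the regimes the profile is expected to show (conversion
  reaching ~20% upstream, below 5% downstream) with conversion efficiency
  1.0. The default `per_base` mode draws exposure independently per cytosine
  per molecule (the simpler null); a `per_molecule_segment` mode draws
  contiguous exposed patches via a two-state Markov chain (persistence 0.98,
  mean patch ~50 nt) because real ssDNA exposure is correlated along a
  molecule. The real assay's spatial correlation is unknown, so neither mode
  is claimed to be realistic beyond its marginal rate.
- **Reads**: uniform start positions, strand of origin Bernoulli(0.5),
  default 250 nt single-end (the 250-cycle MiSeq setting is the template),
  constant FASTQ quality (quality modeling is irrelevant to the contracts),
  substitution sequencing errors only. Indel reads are a *filtered* class in
  this analysis, so they are produced by a dedicated corrupt-read injector
  rather than by the error model.
- **Not emulated**: PCR duplicates, adapter contamination, coverage bias,
  bisulfite degradation, repeat structure beyond the planted IR. Passing
  tests therefore demonstrate correctness of the estimators under the stated
  generative model, not robustness to every artifact of real libraries.

## Alignment

Reads are aligned under the standard three-letter reduction: top mode
collapses C→T in read and reference, bottom mode collapses G→A. Each read is
scored ungapped at every offset, in both orientations, under both modes; the
match count is computed for a whole batch at once as a one-hot matrix
product, so the exhaustive scan stays fast (20,000 × 250 nt reads against a
2 kb reference align in a few seconds on one core). Decisions:

- **Ambiguity**: a tie for best score at more than one (offset, orientation)
  placement flags the read, and the filter drops flagged reads. This is the
  semantic intent of removing low-MAPQ multi-mapping reads when the aligner
  is not a Bowtie2 stack.
- **Mode ties are not ambiguity**: a read with no conversion events scores
  identically under both collapse modes at its true locus. Dropping such
  reads would censor exactly the unconverted molecules and inflate every
  conversion rate, so a mode tie at a single placement resolves to the
  orientation-consistent mode of a directional protocol (forward → top,
  reverse-complemented → bottom), which is also how the simulator generates
  reads.
- **Mismatch budget**: default 10% of read length after collapse, the analog
  of a lenient local-alignment score floor over 250 nt reads; configurable.
- **Gapped mode** (optional): reads rejected by the ungapped scan are retried
  with banded edit-distance alignment (edlib) on the collapsed strings; indel
  edit ops are recorded and the standard filter then removes those reads, so
  gapped mode exists to *classify* indel reads, not to rescue them into the
  counts.
- `min_depth` for reporting a rate defaults to 10; positions below it are NA
  (never 0), and NA positions are skipped, not imputed.

## Boundary estimation

Candidates are the informative (depth > 0) positions with at least 10
informative positions on each side. The estimator is an exhaustive
single-changepoint scan of the two-regime binomial profile likelihood,
computed with cumulative sums (O(n) per scan); exactness and testability were
preferred over CUSUM-style approximations since profiles are a few kb. The
leftmost maximizer is reported, with a plateau flag when another candidate
lies within 1 log-likelihood unit.

Significance: the scan-max likelihood-ratio statistic is the maximum of many
correlated LR statistics and is not χ² distributed, so the default p-value is
a permutation test (jointly permuting the per-position (converted, depth)
pairs, 199 permutations, add-one rule). Under a single-regime null the
positions are exchangeable and the test is exact, which is what the
calibration test asserts (type-I error ≈ α over 500 replicates). A `chi2`
method (2·LLR against χ², df 2) is kept as a fast, conservative-in-intent
approximation for interactive use; its calibration is not guaranteed.

## IR detection, folding and MBN-PCR

- **IR definition**: arms of equal length a ≥ `min_arm` around a loop of
  3–`max_loop` nt; arm position t pairs left-arm base (inside-out) against
  right-arm base t; at most `max_mismatch` non-Watson-Crick pairs, and the
  innermost and outermost pairs must match (no terminal mismatches). An IR is
  reported only if *maximal*: neither the one-step outward extension (same
  loop) nor the inward extension (loop − 2) is itself valid. Implementation
  enumerates loop centers with bounded outward extension (early exit once the
  mismatch budget is spent); brute-force enumeration of every (start, arm,
  loop) placement is the test oracle. Ties sort by start, then longer arm.
- **Folding**: Nussinov base-pair maximization with `min_loop` 3,
  Watson-Crick pairs only by default (G·T wobble opt-in). The package needs
  only the qualitative ordering — a wild-type IR folds a strong stem, a
  stem-mutant does not — so a thermodynamic model would add parameters
  without changing any readout.
- **Stem mutant**: substitutes every right-arm base by a non-complementary
  one (A↔C, G↔T), breaking all stem pairs while keeping length; the builder
  verifies the fold score drops below the configured fraction of wild type.
  Loop mutants apply the named point substitutions (→C at element coordinates
  1027, or 1025/1027/1029) and leave arm pairing untouched.
- **MBN-PCR**: mung-bean nuclease cleaves the extruded ssDNA loop of a
  cruciform, so the predictor declares a product non-amplifiable iff a
  detected IR inside the amplicon folds at least `fold_threshold` (default
  12) base pairs. A single pairing-score threshold reproduces the binary gel
  readout without a thermodynamic parameter set. PCR itself is exact-match
  only (mismatch-tolerant binding is deliberately out of scope); more than
  one possible product raises an ambiguity error listing all.

## qPCR arithmetic

`Cq = intercept − log_E(quantity)`, default efficiency E = 2, intercept 20.
Percent-of-input recovery uses `2^(Cq_input + log2(d) − Cq_IP) × 100`, where
`d ∈ (0,1]` is the fraction of the sheared chromatin measured as input: the
input Cq is first projected onto the undiluted total (an input that is a
fraction d of the material runs −log2(d) cycles late), after which each cycle
of IP lag halves recovery. This reading is fixed by two identities that are
asserted in tests: noiseless simulated Cqs for a programmed IP fraction f
invert to exactly 100·f, and halving d halves recovery at fixed Cqs. The
no-antibody mock is subtracted to give actual recovery; negative values are
kept and flagged rather than clipped. Relative expression is plain ΔCq
against the ACT1 reference (`E^(Cq_ACT1 − Cq_target)`) — normalization is to
the reference transcript within condition only, so no second (ΔΔCq) baseline
is applied. Group contrasts are unpaired t tests, equal-variance by default
with a Welch option; one-tailed p-values halve the two-tailed value in the
observed direction.

## Metaprofiles

Occupancy tracks live on an anchored coordinate grid (element/GAG start = 0)
and aggregate positionwise as sum or mean over elements; both are provided
because it is not always knowable whether a published "summed" profile was
depth-normalized per element first. A track not covering the requested
window is an error naming the track.

## Pipeline and reproducibility

`run_pipeline` chains simulate → align → filter → count → profile →
changepoint → regime summary. One top-level seed fans out as seed + stage
index (reference 0, reads 1, boundary permutation 2); the manifest records
the config, derived seeds and planted-IR coordinates, and repeated runs with
one seed are byte-identical. The default configuration (2 kb element,
20,000 × 250 nt reads, regimes 0.20/0.04) is the condition the acceptance
checks run under; the calibration study uses 500 replicates of 120-position
profiles at depth 200, sizes chosen so the whole suite runs in well under a
minute per check on one core.

## Known limitations

- Single reference sequence, ungapped-by-default alignment, no quality-aware
  scoring: this is a targeted-amplicon analysis, not a genome-scale mapper.
- One changepoint only; a profile with several chromatin transitions needs
  segmentation the package deliberately does not attempt.
- The hairpin surrogate maximizes pairs; it says nothing about folding
  kinetics or in-vivo extrusion probability beyond the qualitative ordering.
- The χ² p-value option is approximate; use the permutation default whenever
  the decision matters.
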