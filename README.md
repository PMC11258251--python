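# bsfoot

ssDNA footprinting of chromatin boundaries by **non-denaturing bisulfite
sequencing**, with companion tools for inverted-repeat (IR) analysis and the
standard ChIP/qPCR arithmetic of a boundary study.

## The problem

Sodium bisulfite converts unmethylated cytosine to uracil (read as T) only on
*single-stranded* DNA. Applied to chromatinized, double-stranded DNA without a
denaturation step, conversion therefore marks cytosines that were transiently
exposed as ssDNA — a footprint of chromatin relaxation, not of methylation.
The per-base, strand-specific **CT conversion rate**

```
top strand:    rate(%) = T / (C + T) × 100   at reference C positions
bottom strand: rate(%) = A / (G + A) × 100   at reference G positions
```

reports ssDNA exposure along the element. In yeast Ty1-like LTR
retrotransposons, an inverted repeat near the 5' end of the GAG silencing
region acts as a chromatin boundary: exposure is high (~20%) on the
promoter-proximal side and drops below 5% on the gene-body side, with the IR
as the tipping point. `bsfoot` formalizes that tipping point as a
**single-changepoint estimator on binomial conversion profiles**: with
per-position counts (cᵢ converted out of dᵢ), the boundary k̂ maximizes the
two-regime binomial log likelihood

```
ℓ(k) = Σ_{i<k} log Bin(cᵢ; dᵢ, p̂_up) + Σ_{i≥k} log Bin(cᵢ; dᵢ, p̂_down)
```

over all candidate splits, with significance from a permutation test on the
scan-max log-likelihood ratio (a χ² approximation is available).

The package is aimed at people analyzing non-denaturing BS-seq footprints or
building simulations of them. It contains:

- `bsfoot.seqcore` — FASTA I/O, maximal inverted-repeat detection, Nussinov
  base-pair-maximization hairpin folding, IR mutation builders (stem/loop
  mutants), exact-match in-silico PCR and a mung-bean-nuclease PCR predictor.
- `bsfoot.synthetic` — seeded generators with ground truth: Ty1-like
  references with planted IRs, non-denaturing bisulfite reads (two-regime
  exposure, strand-of-origin sampling, conversion efficiency, sequencing
  error), ChIP occupancy tracks, qPCR Cq values.
- `bsfoot.bsmap` — bisulfite-aware aligner (three-letter reduction, both
  strands/orientations, ambiguity = tie-for-best), the multi-mapping and
  indel read filters, per-position base counting and conversion profiling.
- `bsfoot.boundary` — the changepoint estimator and regime summaries.
- `bsfoot.chromatin` — anchored ChIP metaprofiles; ChIP-qPCR percent-of-input
  recovery with no-antibody background subtraction; unpaired t contrasts.
- `bsfoot.assays` — transformation-efficiency and ACT1-relative expression
  calculators.
- `bsfoot.pipeline` / `bsfoot.cli` — an end-to-end, seed-reproducible
  pipeline with a `bsfoot` command-line interface.

## Worked example

Simulate a 2 kb Ty1-like element with an IR planted at position 1011,
exposure 0.20 upstream / 0.04 downstream, 20,000 × 250 nt bisulfite reads,
then align, profile and call the boundary:

```sh
$ bsfoot run-all --seed 11 --outdir out
boundary at 1011 (p_up_hat=0.1994, p_down_hat=0.0402, p=0.005)
```

The planted boundary (1011) is recovered exactly; the regime estimates are
the maximum-likelihood conversion proportions on each side (truth 0.20 and
0.04), and `p` is the permutation p-value of the two-regime model against a
single-regime null (0.005 is the smallest value attainable with the default
199 permutations). `out/` contains the reference FASTA, reads FASTQ, truth
tables, alignment/count/profile TSVs, a JSON boundary report and a manifest
with every parameter and per-stage seed.

The same steps are available individually (`bsfoot simulate`, `bsfoot bsmap
run`, `bsfoot boundary`, `bsfoot irscan`, `bsfoot fold`, `bsfoot mbn-pcr`,
`bsfoot metaprofile`, `bsfoot qpcr`, `bsfoot assay`) and as library calls.

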