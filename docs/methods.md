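# Methods

## The analysis problem

A pseudogene and its cognate protein-coding gene are near-identical
homologs. Three consequences drive the design of this package:

1. **Read assignment is the bottleneck.** Reads cross-map between the two
   loci; the pipeline therefore admits a read at a locus only when every
   mismatch lies on a known SNP position carrying the recorded alternate
   allele, and only when that placement is unique across all loci, offsets
   and strands. Ambiguous reads are discarded, never fractionally allocated.
   A lenient mode (≤ k mismatches anywhere, default k = 3) exists solely to
   quantify what the strict policy buys.
2. **m⁶A must be quantified at the gene level and localized at the site
   level.** LAIC-seq partitions full-length RNAs into an m⁶A-positive
   (eluate) and m⁶A-negative (supernatant) fraction; the gene-level level is
   the eluate share of the informative signal, so equal signals mean 50%.
   Localization uses RIP/input coverage peaks and the DRACH motif.
3. **Evolutionary claims need a neutral yardstick.** Point mutation pressure
   is strand-symmetric, so the antisense strand supplies the neutral
   background for motif gains; DRACH motifs outside m⁶A peaks supply the
   neutral control for site ages.

## Synthetic cohort: the generative model

`SimulationConfig` holds every knob; the defaults are the cohort conditions
used by the tests and the acceptance script.

**Pseudogene birth.** Each cognate transcript (random uniform sequence,
length U{600, …, 1500} nt) spawns a pseudogene by per-site substitution.
Sites propose a substitution with probability `rate` (per-pair rate =
`mutation_rate` × U(0.25, 2), default base 0.18, giving the cohort a spread
of divergences); proposals creating ≥ 1 new sense-strand DRACH are accepted
with probability min(1, (1+s)·p₀), all others with p₀. The default baseline
p₀ = 1/(1+s) keeps acceptance probabilities in [0, 1], makes motif-creating
proposals certain to fix, and reduces to accept-everything at s = 0, where
the process is exactly strand-symmetric — the property the type-I
calibration of the strand-bias test rests on. The default s = 2 produces a
realized sense/antisense gain ratio near 2.7.

**Substitution model.** Uniform single-nucleotide (Jukes–Cantor-like): the
replacement base is uniform over the three alternatives. This is the
simplest strand-symmetric neutral null. An AT/GC-biased variant is
deliberately out of scope of the defaults; the uniform choice is what the
strand-bias test's null requires.

**Ortholog evolution and site ages.** Species sequences are generated
outward along an ordered ladder (default chimp < gorilla < orangutan <
rhesus) by cumulative neutral substitution. Branch rates are expected
substitutions per site under the multi-hit uniform model (per-site change
probability ¾(1−e^{−4r/3}), saturating at identity ¼); defaults
(0.04, 0.09, 0.16, 0.28) are chosen so that DRACH survival spreads sites
across all five strata rather than piling them at the oldest stratum —
larger than literal primate divergences, because pattern-level conservation
(any DRACH counts, not the identical 5-mer) is forgiving. A site's true age
is the most distant stratum with an intact DRACH, exactly the statistic the
analysis estimates; on the simulator's gapless alignments the two agree
identically, which the tests assert.

**Methylation placement.** Which sense DRACH sites are truly methylated is
controlled by `site_choice`:
- `young_biased` (default): methylation probability `level·(0.90 −
  0.80·age/K)` — young motifs are preferentially methylated, so in-peak
  m⁶A sites are stochastically younger than the out-of-peak control, the
  positive-selection signature.
- `age_increasing`: `level·(0.15 + 0.75·age/K)` — the opposite gradient,
  used to produce the older-motifs-more-often-in-peaks pattern.
- `uniform`: age-blind.
Peaks in the coverage simulation are ±60 nt windows around methylated sites;
RIP coverage is Poisson with a 7× rate inside peaks over a depth-30 input.
The two modes cannot hold simultaneously in one cohort; they are distinct
study conditions.

**LAIC counts.** Informative reads per gene are Poisson with mean
`laic_depth` scaled by the gene's total (nucleus + cytosol) abundance, each
read assigned to the eluate with probability equal to the true level; input
is an independent Poisson draw at the same mean. A negative-binomial
dispersion switch exists for robustness checks and is off by default. Tying
depth to abundance makes m⁶A-driven decay visible in the input signal, as it
is in real libraries.

**Expression.** Nuclear abundance is log-normal (log-mean log 50, sd 0.8);
cytosolic abundance is nuclear × export factor (3) ×
exp(−`decay_coeff`·level) × log-normal noise (sd 0.3), with the decay term
applied to processed pseudogenes — the class the decay phenotype belongs
to; `decay_coeff = 0` is the methyltransferase-knockdown analogue and must
(and does, by calibration test) null every stratified comparison. The
population matrix (default 462 samples, the size of the reference
B-lymphoblastoid panel) gives each pair a shared latent factor with log-scale
correlation `ceRNA_coupling·(1 − coupling_attenuation·level)` for processed
pairs and unattenuated coupling for unprocessed pairs.

**True m⁶A levels.** Pseudogene level = clip(0.12 + 5.0·divergence +
N(0, 0.15)) — an increasing function of divergence, the generative form of
the divergence–level correlation — spanning all three categories under the
default mutation rates; cognate levels are Beta(1.3, 3.5) (low-mean).

**Determinism.** All draws descend from one seed through named substreams
(`sequences`, `orthologs`, `laic`, `coverage`, `expression`, `snps`,
`reads`); identical config ⇒ bit-identical bundle, asserted in the tests.

## Analysis-side choices

- **Level reliability**: genes with < 20 scaled informative reads are flagged
  undefined and excluded (the operational "reliable level" filter). Size
  factors default to 1 (the simulator's fractions are already on a common
  scale, as spike-in-normalized fractions would be); a library-size mode and
  an explicit-factor injection point exist for real data.
- **Peak caller**: windows of 100 nt, step 50, library-size-normalized
  RIP/input ratio ≥ 2 and RIP coverage ≥ 10; overlapping windows merge;
  intensity is the length-weighted mean ratio (ratio-based, not
  input-subtracted). Zero-input windows are skipped. All three parameters
  are exposed.
- **Alignment**: pairwise global Needleman–Wunsch with affine gaps stands in
  for a two-sequence ClustalW run (which is a pairwise global alignment);
  defaults match +2, mismatch −1, first gap residue −5, each further residue
  −1. Precomputed alignments are accepted via `alignment_from_gapped`. The
  simulator's pseudogenes are substitution-only, so equal-length pairs are
  used as-is (already optimally aligned column-for-column).
- **Motif bookkeeping**: the counted region is the union of both genes'
  peak projections onto alignment columns ("peaks of either"); a motif is in
  the region when its methylatable-A column is; motifs whose five columns
  are non-consecutive or face a gap are excluded from gained/lost/shared and
  tallied as `gap_spanning` (homology unassignable).
- **Strand-bias test unit**: the pseudogene (gaining ≥ 1 motif), not the
  motif. Yates continuity correction is the reported default — it reproduces
  the printed worked value on the reconstructed 223-pair table — and the
  uncorrected statistic is always emitted alongside. Type-I calibration is
  asserted on the uncorrected p, the asymptotically nominal one, over
  neutral cohorts with independent sense/antisense groups (the paired
  same-cohort design is conservative by construction).
- **Conservation mode**: pattern-level (the homologous 5-mer still matches
  DRACH) by default, identity-level behind a flag; a missing or unalignable
  species counts as not-conserved rather than dropping the site.
- **Wilcoxon**: normal approximation with tie correction at the cohort's
  sample sizes, exact enumeration below 20 per group. Expression
  correlations use Pearson on log2(x+1); BH FDR is applied across all
  testable pairs of a run, significance at q < 0.05.
- **Nuclear index**: (nucleus + 0.01)/(cytosol + 0.01) RPKM; the pseudocount
  guards zero cytosolic estimates and a zero-pseudocount mode errors
  instead.

## Problem sizes

The default cohort is 200 pairs (70% processed) — near the 223-pair scale of
the reference study — with a 462-sample expression panel. The test suite
runs the full pipeline once at 200 pairs / 200 samples and reuses it across
tests; calibration uses 1000 neutral replicate cohorts of 300 sequences ×
400 nt and power uses 60 replicate cohorts of 500 pseudogenes, sizes at
which the Monte-Carlo error of a rejection rate is under one percentage
point. The read-assignment stage runs on 25 pairs per report (the policy is
exhaustive per offset and quadratic in transcript length by design).

## What passing tests do and do not show

The cohort has the *statistical shape* of the real data — homology with
known divergence, fraction counts with the estimator's generative inverse,
coverage enrichment at true sites, compartment ratios and coupled
expression — but none of its biological texture: no splicing or isoforms, no
indel evolution on the pseudogene branch (gaps enter only through the
alignment handling), no sequencing error or base qualities, no batch
structure, no GC or mappability bias, uniform base composition, and
ceRNA coupling that is never negative (so the fraction of positive
significant correlations is 1 by construction, unlike real panels where
confounders produce negative pairs). Passing therefore demonstrates that the
estimators and tests recover what they claim from data satisfying their
assumptions — calibration, power, oracle equivalence and directional
fidelity — not that those assumptions hold in any particular cell line.

## Known limitations

Population-genetic selection inference (INSIGHT ρ), GERP-style constraint
scores, dN/dS and external motif predictors are consumed, if at all, as
annotation columns only. The peak caller is a transcript-coordinate
sliding-window method, not a spliced genome-scale caller. Paired-end
handling reduces to both mates unique to the same locus with consistent
orientation. The strict assignment scan has no index; it is exhaustive and
meant for transcript-scale loci.
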