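# pseudom6a

Analysis pipeline for the evolution of N6-methyladenosine (m⁶A) RNA
methylation on pseudogenes, paired with a ground-truth synthetic cohort
generator.

Transcribed pseudogenes — above all processed pseudogenes, the intronless
copies retrotransposed from mature mRNAs — escape splicing-dependent RNA
surveillance, yet their transcripts can interfere with the mRNAs of their
cognate protein-coding genes through shared miRNA/RBP pools (the ceRNA
effect). m⁶A, installed on DRACH motifs (D=[AGT], R=[AG], A, C, H=[ACT]),
promotes cytosolic RNA decay and offers a splicing-independent way to clear
such transcripts. This package implements the computational machinery needed
to study that hypothesis end to end:

- **`pseudom6a.simulate`** — a synthetic cohort whose generative model encodes
  the hypotheses: pseudogene birth by substitution with soft selection
  favouring mutations that create sense-strand DRACH motifs, neutral ortholog
  evolution along a primate-like species ladder, LAIC-seq-style fraction
  counts, RIP/input coverage around truly methylated sites, m⁶A-dependent
  cytosolic decay, and pseudogene–cognate expression coupling attenuated by
  m⁶A. Every downstream stage is testable against recorded truth.
- **`pseudom6a.assign`** — strict SNP-aware read assignment: a read is used
  only if it matches a unique locus perfectly except at known SNP positions
  carrying the recorded alternate (with a lenient k-mismatch mode for the
  conventional-mapping contrast).
- **`pseudom6a.quant`** — gene-level m⁶A stoichiometry from eluate/supernatant
  fraction counts (`level = eluate / (eluate + supernatant)` after size-factor
  scaling; equal signals ⇒ 50%), sliding-window RIP/input peak calling, and
  DRACH-in-peak single-nucleotide site calling, with the high (≥ 0.6) /
  medium ([0.3, 0.6)) / low (< 0.3) categories.
- **`pseudom6a.motifs`** — pairwise global alignment (affine gaps), DRACH
  gain/loss/shared classification within peak-covered aligned regions on both
  strands, the sense-vs-antisense strand-bias chi-square (antisense as the
  neutral background), and divergence–m⁶A-level Pearson correlation.
- **`pseudom6a.ages`** — phylostratigraphy: each site is dated by the most
  distantly related species with an intact DRACH at the orthologous position;
  m⁶A-site ages are compared against out-of-peak DRACH controls.
- **`pseudom6a.expression`** — RPKM, nuclear indexes, m⁶A-stratified
  two-tailed Wilcoxon comparisons with ECDF tables, and pseudogene–cognate
  Pearson correlations across samples under Benjamini–Hochberg FDR.
- **`pseudom6a.pipeline` / CLI** — end-to-end orchestration with one seed,
  plain-text outputs, and a machine-readable report.

## Worked example

```python
from pseudom6a import SimulationConfig, run_pipeline

report = run_pipeline(SimulationConfig(n_pairs=200, n_samples=200, seed=42),
                      "runs/demo")
sb = report.headline["motifs"]["strand_bias"]
print(sb["sense_gaining"], sb["antisense_gaining"], sb["p_yates"])
print(report.headline["expression"]["nuclear_index_processed_high_vs_low"])
print(report.recovery)
```

prints (seed 42):

```
142 94 1.7701075049622785e-06
{'p': 4.130269749872161e-11, 'median_shift': 0.7272486224790845}
{'n_genes_with_level': 400, 'level_bias': -0.0004943900954704862,
 'level_rmse': 0.01563593205269182}
```

With selection on (s = 2), 142 of 200 pseudogenes gain at least one
sense-strand DRACH versus 94 on the antisense background — the strand-bias
chi-square rejects decisively. Highly methylated processed pseudogenes show
a higher nucleus/cytosol expression ratio than lowly methylated ones
(cytosolic depletion), and the m⁶A levels estimated from the simulated
fraction counts recover the generating truth essentially without bias.

The same run is available from a shell:

```bash
pseudom6a run --config cohort.yaml --out runs/demo --seed 42
pseudom6a report --out runs/demo
```

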