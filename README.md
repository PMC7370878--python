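# regudyn

Regulatory dynamics of embryogenesis from time-series multi-omics.

Developmental studies that profile the same embryonic stages with
short-read RNA-seq (expression), long-read RNA-seq (gene models) and
ATAC-seq (chromatin accessibility) can ask not just *which* genes are
active, but *how* transcription and the regulatory genome move together
through development. `regudyn` implements that joint analysis as a tested,
reusable library:

- **Gene-model comparison** — intron-chain equivalence between transcript
  model sets (exact match / novel isoform / novel locus), splice-junction
  support binning (0, 1–500, >500 short reads), primary+supplement model
  merging, and the lncRNA retention filter (≥200 nt, no coding homology,
  low coding potential).
- **Expression dynamics** — genes expressed at ≥1 TPM in both replicates
  are z-scored per gene and clustered with fuzzy c-means into k=30 soft
  clusters (memberships `u_ij = 1 / Σ_l (‖x_j−c_i‖/‖x_j−c_l‖)^{2/(m−1)}`,
  fuzzifier m=1.25); a membership cutoff of 0.3 gives adjustable
  single/multi-cluster assignments, with clusters ordered by peak stage.
- **Isoform switching** — for multi-isoform genes (each isoform ≥1 TPM
  somewhere), the predominant isoform at a stage is the one carrying >60%
  of the gene's summed TPM; a change of predominant isoform across stages
  is a switch event.
- **Accessible-element atlas** — per-stage peaks filtered at
  −log10(q) > 7 and merged across stages into elements; nearest-gene
  assignment; promoter / gene-body / downstream / distal-intergenic
  categories; >2× and >5× accessibility variability; conservation by
  overlap with constrained regions, tested against 200 rounds of
  length-matched random intervals (two-sample KS).
- **Cis-regulatory logic** — element–gene relationships classified as
  synchronization (Spearman ρ > 0.8), repression (ρ < −0.8), enhancer
  switching (anti-correlated element pair whose joint OLS fit of the gene
  passes an overall F-test at p < 0.1), or early opening (element half-max
  stage strictly before the gene's, among genes passing a gradual-increase
  promoter filter: ρ > 0.7 and empirical p ≤ 0.1 against random
  promoter–gene pairings).
- **Trans-regulatory logic** — CIS-BP-style PWMs normalized with a 1e−6
  tolerance and 0.008 pseudocount; log-odds motif scanning; chromVAR-style
  accessibility deviation z-scores against matched background element
  sets; a chromatin opening index (log2 Tn5 cut-density enrichment
  flanking bound motifs); footprint aggregation; pioneer TFs called where
  opening > 2.5, deviation z > 10 and expression > 5 TPM jointly hold.
- **Synthetic data with planted truth** — a first-class generator that
  emulates the data shapes above (10 stages, 30 expression archetypes,
  planted switches, planted cis-logic couplings, conservation tracks,
  planted motif instances and footprints) and records every label, so
  every stage of the pipeline is validated by truth recovery.

## Worked example

```bash
python examples/05_cis_logic.py
```

prints (abbreviated):

```
call counts: {'early_opening': 52, 'enhancer_switching': 28, 'repression': 93, 'synchronization': 173}
confusion (planted rows x called columns):
 ... diagonal ...
off-diagonal entries: 0
```

meaning every planted regulatory relationship — synchronized enhancers,
repressive elements, anti-correlated enhancer pairs, early-opening
elements — was recovered exactly on noise-free data; under realistic
noise the recovery is measured instead of exact (`examples/02` prints
adjusted-Rand 0.976 for clustering at noise 0.3, `examples/03` prints
precision/recall 1.00 for switch detection at noise 0.1).

The `regudyn` CLI wraps the same pipeline for shell use:

```bash
regudyn simulate --out ds --n-genes 300 --seed 1
regudyn run-all --input-dir ds --output-dir out --seed 1
regudyn report --output-dir out
```

`run-all` is deterministic: identical config and seed give bit-identical
outputs.

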