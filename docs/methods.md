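# Methods

This note documents the models, parameters and design choices behind
`regudyn`: what each analysis stage computes, what the synthetic-data
generator plants and deliberately omits, and where the design was
genuinely open.

## Coordinates and containers

All genomic intervals are 0-based half-open internally; GFF3's 1-based
inclusive convention is converted at the parsing boundary and restored on
write. Expression and accessibility live in `StageMatrix` objects
(entities × ordered stages, non-negative), serialized as TSV with the
entity id in the first column and stage labels as header. Two replicates
are two matrices with identical shape; analyses operate on the replicate
mean unless noted.

## Expression dynamics

Genes are retained when both replicates reach ≥ 1 TPM at the same stage
(`min_tpm`, default 1). Profiles are standardized per gene across stages
with the sample standard deviation (ddof = 1); constant profiles cannot be
standardized and become all-zero rows with a warning.

Fuzzy c-means uses the classic alternating updates: memberships
`u_ij = 1 / Σ_l (‖x_j − c_i‖ / ‖x_j − c_l‖)^{2/(m−1)}`, centers
`c_i = Σ_j u_ij^m x_j / Σ_j u_ij^m`, objective
`J = Σ_ij u_ij^m ‖x_j − c_i‖²`. A point coinciding with a center receives
full membership there. Iteration stops when the relative change of `J`
falls below `tol` (1e−6) or after `max_iter` (1000) iterations; `J` is
recorded every iteration and is non-increasing by construction.

Parameters that matter:

- **k = 30 clusters** — the number of temporal archetypes the analysis
  resolves over ~10 stages.
- **fuzzifier m = 1.25** — membership softness; m → 1 recovers hard
  k-means. Time-course clustering tools estimate m in this range for
  well-structured data; it is a configurable knob, not a fitted value.
- **restarts = 20** — each restart is initialized from a converged hard
  k-means fit (greedy k-means++ seeding via scikit-learn), then softened
  by the fuzzy updates; the best restart by objective wins, ties by seed
  order. With k = 30 the objective landscape has many local optima:
  5 restarts routinely landed ~5% short in label agreement, and because
  the objective improvement tracks truth agreement this is an
  optimization fix, not threshold tuning.
- **membership cutoff 0.3** — an entity is assigned to every cluster with
  membership strictly above the cutoff, giving the
  none / one / several-cluster breakdown.

Cluster display order sorts clusters by the stage index of their center's
maximum, ties by cluster index.

## Isoform switching

Within genes having ≥ 2 isoforms each reaching ≥ 1 TPM at some stage
(threshold inclusive), stage-wise isoform fractions are isoform TPM over
summed gene TPM, undefined where the gene total is 0. The predominant
isoform at a stage must carry strictly more than 60% of the gene total,
and the gene must have ≥ 1 TPM at that stage (`gene_floor`, preventing
0/0 artifacts; with a threshold above 0.5 at most one isoform can
qualify). A switch event is a change of predominant isoform between
consecutive *defined* stages — undefined stages are bridged, so
A → none → B is one A→B event and A → none → A is no event, which
suppresses noise-driven flicker while still counting any genuine change
during development.

## Accessible-element atlas

Per-stage peak calls carry −log10(q) scores; peaks with score ≤ 7 are
dropped (strict inequality) and survivors are merged across all stages by
single-linkage ≥ 1 bp overlap (bookended peaks stay separate). Each
element records its contributing stages and maximum score.

Nearest-gene assignment measures the bp gap to the gene *span* (0 when
overlapping); ties go to the gene with the nearer strand-aware TSS, then
the lexicographically smaller id. Categories use precedence
promoter > gene_body > downstream > distal_intergenic, with the promoter
window (−1000, +500) around the TSS (strand-aware) and a 1 kb downstream
window. The promoter window is configurable and shifts the category
split; no universal convention exists, so the default is stated
prominently rather than hidden.

Variability is `(max + 1) / (min + 1)` over stages of the replicate-mean
accessibility, with strict >2× and >5× flags. A per-stage
equal-total normalization helper exists but is not applied before
correlation analyses, because column-wise rescaling distorts cross-stage
ranks.

Conservation: an element overlapping ≥ 1 bp of a constrained region is
conserved; its conserved ratio is overlapped bases over length and its RS
score the maximum over overlapped regions. The enrichment test samples,
200 times, as many random intervals as there are elements — lengths
resampled with replacement from the observed lengths, chromosomes chosen
by size, positions uniform, overruns rejected and redrawn — and compares
the observed conserved-ratio distribution to the pooled null ratios with
a two-sample two-sided asymptotic KS test. Under the null (elements drawn
by the sampler itself) the test rejects at α = 0.01 in ≈ 0–1% of seeds;
ties at ratio 0 make the KS test slightly conservative, which is the safe
direction.

## Cis-regulatory logic

Accessibility (9 stages) and expression (10 stages) are paired through an
injective stage map; correlation calls need ≥ 5 shared stages. Per
element: synchronization if Spearman ρ(accessibility, expression) > 0.8,
repression if ρ < −0.8 (average ranks for ties; zero-variance profiles
are flagged unclassified). Enhancer switching considers unordered pairs
of a gene's elements with ρ(e_i, e_j) < 0 (strictly negative preselection)
and keeps a pair when the OLS fit of expression on both accessibility
profiles plus intercept passes the overall-regression F-test at p < 0.1;
an exact fit yields p = 0, collinear pairs are skipped with a warning.

Early opening is evaluated only for genes passing the gradual-increase
filter: promoter–gene ρ > 0.7 **and** empirical p ≤ 0.1 where the null is
1000 random promoter–gene re-pairings and
p = (1 + #{null ρ ≥ observed}) / (1 + N) (the +1/+1 correction keeps p
positive). For retained genes an element is called early-opening when its
half-max stage — the first stage reaching ≥ 50% of the profile maximum
(inclusive) — strictly precedes the gene's. Early opening may co-occur
with a synchronization call on the same element (a gradually opening
promoter is both); when one label per element is needed (confusion
matrices) the precedence is
enhancer_switching > early_opening > synchronization > repression.

## Trans-regulatory logic

PWM normalization: entries below 1e−6 are clamped up to the tolerance and
each position rescaled to sum to 1; positions are renormalized; a 0.008
pseudocount is added and positions renormalized once more, leaving every
entry positive.

Scanning computes log2 odds against a uniform (or supplied) background on
both strands; a window is a hit at ≥ 80% of the maximum attainable score;
windows containing N are skipped.

The deviation score follows the background-corrected form: for motif m at
stage s, observed `o = Σ_i M_im X_is`, expected
`e = (Σ_i M_im a_i / Σ_i a_i) · Σ_i X_is` with `a_i` the element's mean
accessibility, raw deviation `y = (o − e)/e`, and
`z = (y − mean(y_bg)) / sd(y_bg)` over 50 background element sets matched
on mean-accessibility deciles. Background sets exclude the motif's own
elements: in a small element universe (hundreds, not the >10⁵ peaks of a
genome-wide atlas) a strongly enriched motif dominates its accessibility
decile, and sampling it into its own null halves the z-score for purely
mechanical reasons. With large element universes the exclusion is
immaterial.

The chromatin opening index is the package's scalar reading of "cut-site
enrichment around bound motifs": log2 of the mean Tn5 cut density within
±200 bp of hit centers (motif core excluded, densities pooled over hits
before the log) over the background density, defined as the mean cut
density across the accessible compartment (element-covered bases). Using
the whole genome length as denominator would only measure what fraction
of the genome is accessible and score every motif high. The index needs
≥ 10 hits and is undefined otherwise.

Footprints sum per-base cut counts over hits in a motif-centered window
(±100 bp), reversing minus-strand hits. Pioneer TFs are motifs whose
opening index > 2.5, deviation z > 10 and TF expression > 5 TPM all hold
at one stage (strict inequalities; an undefined score disqualifies).

## The synthetic-data generator

The generator is the package's test bed: it emulates the *shapes* of a
developmental multi-omics study and records every planted label.

- **Stages** — 10 RNA stages, the first 9 also covered by ATAC, an
  injective stage map between them.
- **Annotation** — non-overlapping loci round-robin across chromosomes,
  3–8 exons (10% single-exon among single-isoform genes), exons 80–400 bp,
  introns 0.2–1.5 kb, inter-locus gaps 8–14 kb (more than twice the
  maximal distal-element reach, so nearest-gene assignment is
  unambiguous by construction). Multi-isoform genes (rate 0.3) carry 2–4
  isoforms sharing first and last exons, differing by skipped internal
  exons.
- **Expression archetypes** — 30 smooth curves (bumps, valleys, ramps)
  chosen from a large candidate pool by deterministic greedy
  farthest-point selection *in the space the clustering operates in*
  (z-scored exponentiated profiles). This maximizes the minimal pairwise
  archetype distance; a naive grid of Gaussian bumps over 10 stages puts
  neighboring archetypes ~0.3 stages apart and is unrecoverable at
  realistic noise, which would test the data rather than the method.
  Ramp onsets stop early enough that every archetype still varies over
  the ATAC-covered stage prefix, and pool curves are quantized to 8
  decimals so tail values below numerical resolution become exact ties
  (rank structure then survives every later monotone transform).
- **TPM backtransform** — `TPM = exp(zscale·z + μ_g)` with
  `μ_g ~ LogNormal(log 3.4, 0.25)`; the multiplicative `exp(μ_g)` cancels
  exactly under per-gene z-scoring, so cluster geometry is controlled by
  the archetypes alone. Noise is Gaussian on the z-scale per transcript,
  stage and replicate (default sd 0.1; replicates differ only by noise,
  and the study's "high replicate correlation" has no printed magnitude,
  so the default is our choice of a realistic level).
- **Type-aware gene profiles** — each gene draws one cis-logic type
  (defaults: sync 0.25, repression 0.15, enhancer switching 0.15, early
  opening 0.15, null 0.30). Sync/repression/null genes follow an
  archetype (cluster label = archetype id). Enhancer-switching genes are
  bimodal — an early plus a late bump — so their two elements (one per
  bump) are anti-correlated and sum exactly to the gene. Early-opening
  genes are monotone ramps; their promoter tracks the gene exactly
  (labelled sync — the gradual-increase filter must retain these genes,
  and a promoter shifted like the enhancers cannot beat the synthetic
  null's heavy high-ρ tail, an artifact of drawing all profiles from 30
  archetypes that real transcriptomes do not share) while the remaining
  elements are the ramp shifted exactly `early_shift` (= 2) stages
  earlier, giving a half-max lead of exactly 2 stages under the shared
  backtransform. Bimodal and ramp genes carry cluster label −1 (not from
  an archetype). Null-gene elements are flat.
- **Switches** — among multi-isoform genes, a fraction 0.35 swaps its
  top-two isoform fractions (e.g. 0.8/0.2 → 0.2/0.8) from a recorded
  stage onward; switch genes get an expression floor (μ ≥ log 20) so
  predominance stays defined around the switch.
- **Peaks and decoys** — each element emits a peak (q-score uniform in
  8–60) at every stage where its noise-free accessibility is ≥ 50% of its
  maximum, plus sub-threshold decoy peaks (q in 1–6.5) placed away from
  elements; the merged, filtered peak set therefore reproduces the
  planted elements exactly.
- **Conservation** — a fraction `conserved_fraction_fg` (default 0.51) of
  elements receives a constrained region covering its middle half
  (ratio 0.5); background regions (300 bp) are scattered at a density
  chosen so a random element-length interval overlaps the track with
  probability ≈ `conserved_fraction_bg` (default 0.18), avoiding
  elements so the planted foreground rate stays exact.
- **Motifs and cut sites** — 12-bp consensus PWMs; instances are planted
  at motif-indexed offsets (so motifs sharing an element never overwrite
  each other). The pioneer motif is planted in up to 20 null-gene
  elements (600 bp, so ±200 bp flanks stay inside); those elements get a
  20× accessibility burst at the planted stage, and their cut-site
  profiles get 16× flank density with a 0.15× core depletion at that
  stage. Non-pioneer motifs get a mild (0.5×) core footprint at all
  stages and no flank boost. These plant strengths are the generator's
  calibration to the fixed pioneer thresholds (2.5 / 10 / 5): the planted
  effect clears them with a safety margin while unplanted motifs stay
  near opening 0 and |z| < 7.
- **Determinism** — one master seed spawns fixed per-submodule streams
  (annotation, types, expression, accessibility, conservation, motifs,
  cut sites, decoys), so adding a later stage never perturbs earlier
  draws; identical config + seed give byte-identical files.

What the generator does **not** emulate: read-level noise and mapping
artifacts, GC and mappability biases, overlapping or nested genes,
antisense transcription, inter-replicate batch structure, realistic motif
degeneracy, or distance-dependent enhancer–gene assignment errors.
Passing recovery tests here demonstrates that the pipeline's logic is
implemented correctly and is calibrated under its stated model — not that
the thresholds are optimal for any particular real dataset.

## Problem sizes

The validation suite uses 150–600 genes for pipeline-level checks, 3000
profiles for clustering recovery, and ~1900 elements with 200 null
repeats (plus a 100-seed calibration) for the conservation test — sizes
at which every planted structure is exercised with comfortable counting
statistics while the whole suite stays interactive.

## Known limitations

- The opening index is a deliberate scalar proxy for footprint-model
  scores produced by dedicated tools; it shares their monotone intent,
  not their numerical scale, and the 2.5 threshold is meaningful only
  relative to a matched background definition.
- The deviation score implements one canonical variant
  (background-corrected z of fractional deviations, accessibility-decile
  matching); GC matching is supported in spirit but not computed from
  sequence here.
- The empirical promoter null re-pairs promoters and genes within the
  analyzed set; on small or highly structured gene sets this null is
  conservative.
- `compare_model_sets` classifies single-exon transcripts by reciprocal
  overlap (≥ 0.8), a convention the intron-chain definition does not
  cover; the `other` class absorbs opposite-strand and otherwise
  ambiguous overlaps.
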