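# Methods

## Gene-to-CNV assignment

CNVs and gene models are held in 0-based half-open coordinates; input
tables declare their dialect (`bed` = already half-open, `one_based` =
1-based inclusive, converted on load).  Chromosome labels are normalized by
stripping a `chr` prefix; X/Y stay strings.  All overlap logic is
strand-agnostic, since CNVs are unstranded.

The two dosage rules are deliberately asymmetric:

- **Gains**: a gene is assigned only when its whole span — the union extent
  over all transcripts — is contained in the gain (`cnv.start ≤ span.start`
  and `span.end ≤ cnv.end`, same chromosome).  Containment of the span
  implies containment of every transcript, so the "most inclusive" and
  "per-transcript" readings coincide.  The rationale is that a duplicated
  gene only gains a functional copy if every expressed isoform is
  duplicated intact.
- **Losses**: a gene is assigned only when the loss overlaps (≥1 bp) at
  least one *coding* exon of *every* coding transcript.  Non-coding
  isoforms are excluded from the quantifier — a loss cannot disrupt a
  coding exon that does not exist — and genes with no coding transcript are
  never loss-genes.  The rule targets the protein product: no isoform may
  escape with an intact coding sequence.

The cohort size filter is strictly greater-than (a CNV of exactly the
cutoff length is excluded).  Control filtering removes a case gene only
when a control CNV changes it in the *same* direction, with control CNVs of
all lengths participating and assigned under exactly the same rules.  The
operation is a per-dosage set difference, hence idempotent and insensitive
to duplication or row order.

Interval queries go through per-chromosome interval trees; correctness is
checked in the tests against brute-force all-pairs containment/overlap
oracles.

## Annotation universe and enrichment

The phenotype ontology is a DAG of `is_a` relations (other relationship
types in an OBO file are ignored; obsolete terms are dropped; cycles are a
load-time error naming the cycle).  Orthology is strictly 1:1: any pair
whose human or mouse gene appears more than once is dropped with a logged
count rather than resolved heuristically.  A human gene enters the
annotated universe iff its 1:1 mouse orthologue carries at least one
phenotype annotation; it belongs to a term's gene set iff the orthologue is
annotated with the term or any descendant (ancestor closure).  Closure
makes child sets subsets of parent sets by construction, which the tests
assert edge by edge.

Enrichment of a query gene set is per term: with `n` distinct query genes
inside the universe (deduplicated across CNVs and subjects), `k` of them in
a term set of size `K`, and universe size `N`,

- fold enrichment = `(k/n) / (K/N)`; reported at 2 significant figures in
  the report layer only, full precision internally;
- p-value = exact upper tail `P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`,
  computed through the survival function (log-space pmf summation, stable
  for large `N`); `k = 0` returns exactly 1;
- the test is one-sided (enrichment only); depletion is reported through
  the fold but not tested, matching the directional claims the pipeline is
  meant to support.

FDR control defaults to Storey q-values with the π₀ smoother (cubic fit of
π₀(λ) on λ ∈ {0.05, …, 0.90}, evaluated at the largest λ, clipped to
(1/m, 1]); Benjamini–Hochberg is available, and a warning recommends it
below 100 tests where the smoother is unstable.  An empty query∩universe is
an explicit `NoAnalyzableGenesError`, not an empty result.

## Co-expression network

Expression matrices are pandas DataFrames of non-negative RPKM values,
genes × samples.  Construction:

1. keep genes with value ≥ `min_rpkm` (default 1.0) in at least
   `ceil(min_fraction × S)` samples (default 5%), both comparisons
   inclusive;
2. Pearson correlation of log2(x+1)-transformed profiles by default.  The
   transform is configurable (`none` for pre-transformed input) because the
   upstream convention is not fixed by the analysis being emulated; the
   log2 default reflects standard practice for RPKM.  Zero-variance genes
   get undefined correlations and can never form edges or nodes;
3. edge retention either at a fixed signed cutoff (`r ≥ 0.7` default —
   negative correlations are never edges) or as the strongest
   `floor(value × n_pairs)` pairs, extended through ties at the boundary
   value (deterministic, slightly more than the requested fraction, with
   the tie count recorded).  Both modes report the achieved fraction and
   the implied cutoff so they can be cross-checked against each other.

Soft-power adjacency and topological-overlap transforms are intentionally
omitted: the artifact implements the plain correlation-threshold network
that the downstream connectivity statistics consume.  Relaxing the cutoff
only ever adds edges (monotone nesting, asserted across 0.9 → 0.5).

## Connectivity permutation tests

The statistic is always a sum of retained edge weights: within one gene set
(cohesion) or between two disjoint sets.  Genes named in a set but absent
from the network are kept and contribute zero weight — an analysis may
legitimately test a candidate set of which only part participates in the
expressed network.  Disjointness between candidate and target sets is a
*precondition*, not an automatic fix: shared genes must be removed from
both sets and from the background explicitly, so the exclusion bookkeeping
stays visible in the caller and in logs.  The comparative test builds its
composite background as candidates ∪ competitor minus target-annotated
genes, deduplicated, and errors when the composite is not strictly larger
than the candidate set.

Null distributions redraw candidate-sized subsets uniformly without
replacement from the declared background, independently per permutation
(single seeded NumPy generator per test invocation, seed recorded in the
result).  The empirical p-value is `(k + 1)/(n_perm + 1)` with `k` counting
permutations whose statistic is ≥ the observed one — ties count toward
`k`, the value is never exactly zero, and at the default 100,000
permutations the attainable minimum is 1/100,001.  Permutations are
vectorized (random-key argpartition subset sampling, chunked fancy-indexed
submatrix sums), so 100,000 draws run in seconds on one CPU.

## Synthetic data: what is emulated, and how

The generator reproduces the *statistical shape* of the real study inputs,
not their content:

- **Toy genome** — 3,000 non-overlapping gene models on 1.2 Gb (one gene
  per 400 kb, the density that makes a ~2 Mb gain cover ~5 genes, matching
  the real cohort's ~5 genes per large gain), with 1–5 transcripts per
  gene, 1–6 exons, CDS sub-intervals, and non-coding isoforms at 10%.
- **Annotation universe** — gene-id pool of 26,000 with exactly 6,350
  annotated (≈24%, the fraction of human genes with informative mouse
  models) and exactly 439 in the focal behavioural term.  Focal genes are
  annotated only on the focal term's children, so every downstream count
  exercises ancestor closure; 157 sibling behavioural terms get independent
  gene sets with log-uniform sizes 10–600 — specific behavioural phenotypes
  are mostly small, and none should rival the ~2,000-gene category root.
- **CNV cohorts** — the case cohort's composition mirrors the emulated
  study's printed margins as fixed design constants: 52 large gains and 19
  large losses above the strict 500 kb cutoff, plus 50 small CNVs
  straddling it from below; lengths log-uniform.  The 1,200 control CNVs
  (86% losses, all lengths) remove roughly 8–10% of case genes, as in the
  real control cohort.
- **Planted enrichment** — case gains start uniform.  For
  `planted_fold > 1`, large gains that hit no focal gene are iteratively
  re-anchored onto unused modeled focal genes until the focal count among
  annotated gain-genes — counted after control filtering, the way the
  analysis counts it — reaches `round(planted_fold × (K/N) × A)`.  Anchors
  are spread evenly across the focal child terms (largest deficit first) so
  the planted signal is a parent-level property rather than a
  single-subtype artefact.  At `planted_fold ≤ 1` no re-anchoring occurs,
  keeping the null cohort an honest null (the calibration must not clamp
  the natural sampling variation of `k`).
- **Expression** — a latent-factor model: module genes share a standard
  normal factor plus independent noise with `sd = sqrt(1/r − 1)`, so the
  expected within-module Pearson correlation equals the configured
  `within_module_r` (0.8 default) analytically; profiles are exponentiated
  around per-gene log2 baselines to be RPKM-like, and 10% of background
  genes are planted at negligible expression to exercise the filter.

Everything is deterministic under one seed, and the writers emit the same
on-disk formats the loaders consume (TSV with a 1-based dialect, GFF3, OBO,
edge lists), so the format round trip is covered by the same tests.

What the generator does *not* emulate: real genomic coordinates and gene
clustering, linkage structure, region/age covariates of brain expression,
heavy-tailed RPKM distributions, or annotation biases (e.g. gene-length
effects).  Passing tests therefore demonstrate that the machinery is
correct and calibrated under the stated model — not that the biological
conclusions of any particular real cohort would replicate.

## Experiment scales

The bundled experiments are sized for a single CPU: planted-enrichment
recovery regenerates 100 full cohorts (~1 s each); null calibration uses a
2,000-gene network with 200 uniform candidate draws × 1,000 permutations;
cohesion power uses 15 cohorts at 10,000 permutations; the hypergeometric
oracle enumerates all ~19,000 instances with N ≤ 20 in exact rational
arithmetic.  The permutation default of 100,000 is retained for single
test invocations.

## Known limitations

- Genome-build conversion (liftOver) is out of scope; all inputs must share
  a build.
- The gene-length bias diagnostic of the emulated analysis is not
  implemented; the assignment rules themselves are the mitigation.
- CNV input is a headered TSV (with a coordinate-dialect switch) rather
  than headerless BED.
- Storey's π₀ estimate is noisy for small term families; the package warns
  and offers BH.
- Real-data figures of the motivating study (its 13,953-node BrainSpan
  network and the specific permutation p-values) depend on external
  downloads and are documented as the use case, not reproduced here.
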