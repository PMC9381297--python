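# Methods

## Problem and approach

The package asks a cross-comparative question: does a focal disease share
transcriptomic dysregulation with a set of candidate risk factors? Each
disease contributes one case/control expression cohort. The pipeline calls
differentially expressed genes (DEGs) per cohort, intersects the per-disease
DEG sets, scores every disease pair, ranks hub proteins on the PPI subgraph
induced by the shared DEGs, and tests the shared gene list for
over-representation in pathway, ontology and disease-gene benchmark
libraries.

## Preprocessing

Cohorts from different platforms arrive on different scales. Values are
moved to the log2 scale (`log2(x + pseudocount)`, pseudocount 1) and each
gene row is standardised across all samples of its cohort:

    z_ij = (x_ij - mean_i) / sd_i

Decisions made where the procedure was genuinely open:

- **Auto-log detection.** Under `log2_policy: auto` the transform is applied
  only when the 99th percentile of the matrix exceeds 50 and no value is
  negative — the heuristic public repositories use to separate raw
  intensities from already-logged data. Negative values always mean "already
  logged" and suppress the transform.
- **Standard deviation.** The Z-score uses the sample sd (ddof = 1) by
  default; configurable to ddof = 0. The t statistic is unaffected either
  way.
- **Zero-variance rows** cannot be standardised and are dropped with a
  logged count.
- **Order of operations.** Fold changes are computed on the log2 scale
  *before* Z-scoring. Row standardisation rescales every gene by its own sd,
  so a fixed cutoff like |logFC| >= 1 would mean something different for
  every gene after Z-scoring. The t statistic is invariant to per-row affine
  maps (a property the test suite checks), so p-values are identical on
  either scale and nothing is lost by this order.
- **Probe collapsing.** When a probe-to-symbol map is supplied, the probe
  with the largest |case mean − control mean| represents the gene
  (`max_abs_logfc`; `max_abs_t` and `mean` are available). Ties keep the
  lexicographically smallest probe ID so results are reproducible.

## DEG calling

Per gene, the unpaired two-sided Student's t-test (pooled variance,
n1 + n2 − 2 df; Welch available as an option) and
logFC = mean(case) − mean(control) on the log2 scale. P-values are
BH-adjusted across the genes of a cohort. Direction calls use inclusive
thresholds:

- up: p-criterion <= 0.05 and logFC >= 1
- down: p-criterion <= 0.05 and logFC <= −1

The p-criterion defaults to the **raw** p-value, with the adjusted p always
reported and selectable as the criterion. Degenerate genes (zero variance in
both groups) get t = 0, p = 1 when the means agree; equal variance with
unequal means is perfect separation and reported as p = 0 with a warning.

## Diseasome construction

For disease pair (i, j) with dysregulated sets G_i, G_j:

    n_ij = |G_i ∩ G_j|            shared-gene count
    E(i, j) = |G_i ∩ G_j| / |G_i ∪ G_j|   Jaccard edge-prediction score

Both are computed three ways — up-only, down-only and combined — because
cross-disease overlaps are conventionally reported split by direction. The
bipartite network links each disease to the genes it shares with the focal
disease, per direction; a disease pair enters the pair table only when it
shares at least one gene. The Jaccard of two empty sets is undefined and
reported as NaN with a warning.

When the focal disease has several cohorts they are combined by
per-direction union; a gene called up in one cohort and down in another has
no consistent direction, is excluded from both sets, and is listed as
direction-conflicted so the exclusion is auditable. Gene symbols are
uppercased on both sides of every comparison (HGNC symbols are uppercase;
datasets vary).

## Hub proteins

The user-supplied PPI edge list is read as an undirected simple graph
(self-loops and duplicate edges dropped, optional confidence-score filter),
restricted to the shared DEGs, and ranked by degree. The report returns the
top k (default 10) with deterministic lexicographic tie-breaking;
`include_ties` keeps every node tied with the k-th degree. Degree is the
only scorer implemented; the ranking interface accepts alternatives.

## Enrichment

One-sided hypergeometric tail (equivalently Fisher exact),
p = P(X >= overlap) with X ~ Hypergeom(|universe|, |term|, |query|). The
default universe is the union of all genes in the library — the convention
of web enrichment tools — and a measured-gene background can be substituted.
BH runs across the terms of a library (same implementation as the DEG
module; single source of truth); significance defaults to raw p <= 0.05 with
the adjusted p always reported. Benchmark validation runs the same test
against disease-gene libraries and reports, per target disease, whether it
is significant, with its overlap genes; targets absent from a library are
"not testable" rather than errors.

## Synthetic data

The generator emulates the statistical structure of a multi-disease
microarray compendium, not its artifacts:

- values Gaussian on the log2 scale, baseline mean 7, noise sd 0.5 —
  typical log2 intensity levels and the t-test's working assumptions;
- planted effects additive on the log2 scale (default ±2), so the expected
  logFC of a planted gene equals the effect size and recovery thresholds
  are analytic: with 15 + 15 samples the t statistic of a planted gene is
  ≈ 2 / (0.5·√(2/15)) ≈ 11, while a null gene needs a ≈ 5.5-sd excursion
  of its logFC to cross the |logFC| >= 1 cutoff;
- overlap structure planted explicitly: a shared core dysregulated in every
  disease plus private genes per disease, so pairwise shared counts and
  Jaccard scores are known exactly by construction;
- PPI graphs wire each planted hub to at least its requested degree and cap
  filler edges strictly below the smallest hub degree, so the top-k degree
  ranking recovers the planted set deterministically;
- GMT libraries contain one planted term holding ⌈fraction·|query|⌉ query
  genes plus random fillers among uniformly drawn terms.

A single root seed derives one substream per disease from (seed, index), so
adding a disease never reshuffles earlier cohorts. Not emulated: probe-level
artifacts, batch effects, platform differences, correlated genes,
heavy-tailed noise. Passing recovery tests therefore demonstrates the
pipeline's correctness under its own model assumptions, not performance on
real microarray data.

## Problem sizes

The recovery analyses use 5 diseases × 2,000 genes × 15 + 15 samples over
20 seeds for DEG/overlap recovery, 80-node/200-edge graphs for hub
recovery, and 200-term libraries on a 1,000-gene universe for enrichment
recovery; the packaged demo study uses 4 cohorts × 500 genes. These sizes
make every planted quantity statistically comfortable to recover while the
whole analysis completes in seconds.

## Known limitations

- Student's t with the raw-p criterion reproduces a common published
  selection rule but is anticonservative relative to moderated (limma-style)
  statistics on small cohorts; the adjusted-p criterion and Welch test are
  the stricter options.
- Enrichment p-values depend strongly on the background universe; with the
  library-union default, results are comparable across runs but not across
  libraries.
- The diseasome is a bipartite graph with pairwise scores; no higher-order
  network inference is attempted.
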