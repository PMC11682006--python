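# Methods

## Scope and data model

`methmark` operates on CpG-by-sample β-value matrices (β ∈ [0, 1], missing
allowed), per-sample group labels from a closed vocabulary (tumor, adjacent,
cirrhotic, healthy, blood, disease), a per-probe manifest (1-based
coordinates, CGI membership, gene/TSS assignment — one gene per probe;
multi-transcript resolution is upstream of this package) and, for the
expression stages, a raw RNA count matrix and a gene-by-tissue TPM table.
β values are consumed as given: probe-level normalization, IDAT parsing and
cell-type deconvolution are out of scope.

## Cohort assembly

Cohorts are merged on the probe universe present with a non-missing value in
every sample of every cohort (a `max_missing_frac` relaxation exists but
defaults to 0). How partially missing probes were handled upstream in real
exports varies by provider, so the strict rule is the default and the
relaxation is explicit. Sample ids are prefixed with their cohort id on
merge, which also makes the merge idempotent.

## Differential methylation

Per CpG, Δβ is the difference of group means; significance is a two-sided
equal-variance Student t-test (Welch available via `FilterConfig.equal_var`)
with Benjamini–Hochberg correction applied over all probes entering the test
— i.e. after the CGI restriction, matching the stage order of the workflow
(intersect → CGI filter → test). Calls use strict inequalities:
hyper iff Δβ > 0.2 and q < 0.05, hypo iff Δβ < −0.2 and q < 0.05.

Degenerate probes (both groups constant) get p = 1 when Δβ = 0 and p = 0
with a `zero_variance` flag otherwise; constancy is detected by per-group
range, not variance, to dodge floating-point cancellation. Records are
ranked by ascending q, then descending Δβ, then probe id, so reports are
deterministic.

Global hypermethylation enrichment is an exact two-sided binomial test of
significant hyper vs hypo counts against 0.5. No particular test is
canonical for this claim; the binomial test is the simplest test of the
direction imbalance and is documented as this package's choice.

Clustering QC uses Ward linkage on Euclidean distance (required by Ward's
criterion) over sample β profiles, cut at two clusters; agreement is the
best-matching fraction against tumor vs non-tumor status. Identical-profile
inputs return a single cluster and majority-class agreement.

## Panel selection

All β thresholds are strict, as printed in the defaults: unmethylated means
β < 0.2, methylated means β > 0.2, branch deltas > 0.3 / > 0.4, panel tumor
mean > 0.3. Design choices where the rules leave room:

- Branch B's "methylated in adjacent tissue and in tumors" is operationalized
  as group means > 0.2; the per-sample universal rule is stated only for the
  unmethylated side. `branch_b_adjacent_rule` exposes `mean` (default),
  `all` and `fraction` variants.
- Branch A's Δβ is computed against all non-tumoral samples pooled
  (healthy + cirrhotic + adjacent); branch B's against healthy + cirrhotic
  only ("livers not harboring a tumor"). Branch deltas are recomputed per
  branch rather than reusing the discovery-contrast means.
- The final panel is the branch union. The summary criterion (tumor mean
  β > 0.3; healthy and cirrhotic means < 0.2) is *verified* on every member
  and discrepancies flagged, never silently resolved: the branches define
  membership, the summary describes it.
- Branches are provably disjoint whenever `unmeth_thresh <= meth_thresh`:
  branch A requires every adjacent sample below `unmeth_thresh`, which
  forces the adjacent mean below `meth_thresh`, contradicting branch B.
- The disease-exclusion check flags (does not drop) probes with
  Δβ > 0.2 versus within-cohort controls in any benign-disease cohort.
- The validation tumor-fraction is descriptive; no threshold is applied.

## Pan-cancer specificity

A tumor-type cohort is control-bearing only when it has **more than**
`min_controls` (default 5) peritumoral samples. Control-bearing cohorts
support a hypermethylation call (mean Δβ > 0.2, no per-cohort significance
test — the mean-difference rule is the classification criterion); tumor-only
cohorts can only corroborate tumor methylation (mean β > 0.2) and never
enter specificity decisions. `index_exclusive` means the index tissue is the
only control-bearing cohort with a hyper call; `pan` means hyper calls in
≥ `pan_min` (default 10) tumor types. Baseline NT-methylation counts are
reported alongside the calls without feeding into them. Heatmap ordering is
deterministic: probes by descending hyper-tumor count, tissues by descending
probe count, ties lexicographic.

## Expression integration

The promoter window is TSS−1500 to TSS+300 on the gene's strand-oriented
axis, closed on both ends; a probe in both the window and the gene span is
promoter (the window overlaps first exons by construction). Expression uses
log2(CPM + 0.5). A gene is "not expressed" when median CPM < 1 in both
groups — the threshold is an explicit package choice, config-exposed, since
only the qualitative category is given upstream. Otherwise each group is
checked with the D'Agostino–Pearson normality test (α = 0.05, needs n ≥ 8;
smaller groups fall back to Mann–Whitney with a warning); both-normal pairs
use Student's t, otherwise Mann–Whitney U, two-sided, with significance at
α = 0.001 and no multiple-testing correction across the handful of panel
genes (per-gene reporting). Concordance: promoter + down or gene body + up;
intergenic probes and non-significant genes are not applicable.

Tissue repression calls on the TPM table: `broadly_silent` iff median TPM
over all tissues < 1; `repressed_in_index` iff index TPM < 1 and below 25 %
of the median of the other tissues; else `expressed_in_index`. The TPM < 1
and 25 % cut-offs quantify a qualitative pattern and are config-exposed
assumptions.

## Synthetic cohorts

The generator draws one β per probe per sample from Beta distributions:
baseline Beta(2, 38) (mean 0.05), methylated Beta(30, 10) (mean 0.75),
adjacent field effect Beta(14, 26) (mean 0.35). Bounded support matches β
semantics and makes group means analytic for tests; no probe-chemistry
(type I/II) or batch effects are simulated. Default cohort sizes: 100
tumors + 30 adjacent + 10 cirrhotic + 10 healthy (split over two discovery
cohorts so the merge is exercised), 200 blood (smaller than a real blood
reference panel, but the "at least one methylated sample" filter semantics
are size-independent), 30 disease + 10 controls, 500 validation tumors with
planted penetrance 0.7, and 14 paired (20 T / 8 NT) + 13 tumor-only (20 T)
tumor-type cohorts.

Planted classes (disjoint by construction): 30 branch-A and 12 branch-B
markers, 50 blood-methylated and 10 clock contaminants, 20 disease-only
probes, 100 tumor-hypomethylated probes, 5 pan-cancer (hyper in 11 paired
cohorts) and 10 index-exclusive probes. Planted effects are large
(Δβ ≈ 0.7) so recovery is near-deterministic; the generator accepts smaller
effects for power exploration. Panel-class probes are drawn from the
baseline Beta *truncated below 0.2* in blood and non-tumoral liver: being
unmethylated in every such sample is the class definition, and without
truncation the strict per-sample filters would eject planted markers at the
Beta(2, 38) tail rate (P(β > 0.2) ≈ 1.8 × 10⁻³ per draw, ≈ 30 % ejection
odds across 200 blood samples). Pan-cancer and index-exclusive classes
carry effects only in the tumor-type cohorts; panel probes additionally
carry the effect in the index paired cohort, so the end-to-end run
classifies them index-exclusive.

Expression: negative-binomial counts (dispersion 0.1, baseline mean 200)
for each panel gene plus 160 background genes; promoter-hyper genes are
halved in tumors, gene-body-hyper genes doubled, and 30 % of panel genes
are silent (mean 0.1, median CPM 0). The TPM table spans 20 tissues with
coupled panel genes repressed in the index tissue only and silent genes
broadly silent.

What passing on these data shows — and does not. The simulation reproduces
the *decision structure* of real cohorts (group contrasts, strict filters,
planted contaminant classes, location-coupled expression) with idealized
noise: independent probes, no batch effects, no cell-type mixture, large
effect sizes. Recovery of planted truth therefore validates the logic and
thresholds of the implementation, not its statistical power on real arrays,
where effects are smaller and probes correlated.

With the default planted classes, significant hyper (≈ 102) and hypo
(≈ 100) counts are nearly balanced, so the global-enrichment p on synthetic
data is non-significant by design; the enrichment test's behaviour under a
hyper-dominant regime is exercised separately in the unit tests.

## Problem sizes and determinism

Default synthetic runs use 20,000 probes (30 % in CGIs) across ~1,600
samples; a full generate-and-run cycle takes a few seconds on one CPU, and
the test suite and acceptance script run the five-seed default conditions
end to end. All randomness flows from a single integer seed through
`numpy.random.default_rng` seed sequences; repeated runs are byte-identical
apart from the report timestamp.
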