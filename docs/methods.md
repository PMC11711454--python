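# Methods

`netsig` implements, as a tested desk-scale pipeline, an analysis design
that derives gene signatures from transcriptomic-causal networks and uses them
to stratify metastatic colorectal-cancer patients treated with bevacizumab
or cetuximab by overall survival (OS). Because the patient-level genotype
and clinical data behind such analyses are not public, the package ships a
synthetic-cohort generator that reproduces the statistical structure every
stage relies on, together with the generating truth, so each stage can be
scored for recovery.

## The synthetic cohort

The generator (`netsig.synthcohort`) draws, in order:

* **A gene-gene causal graph.** Genes are split into `n_clusters` nearly
  equal clusters (default 4, mirroring the k-means-clustered analysis);
  each ordered within-cluster pair receives a directed edge with
  probability `edge_prob` (default 0.1) and a signed weight of magnitude
  drawn uniformly from 0.5–1.2. Acyclicity is guaranteed by drawing edges
  only forward along a random gene order.
* **cis instruments.** A subset of genes ("eGenes", default 8) each get
  `n_cis_variants` (default 3) independent biallelic variants placed
  uniformly within ±1 Mb of the gene's TSS, with MAF uniform on
  (0.05, 0.5] and dosages Binomial(2, MAF). One variant per eGene carries
  a causal effect (default 0.8) on the gene's latent expression.
* **Latent expression.** A linear structural-equation model evaluated in
  topological order: each gene is the weighted sum of its parents, plus
  its cis-dosage effect, plus a cell-type contamination term
  (loadings ~ N(0, 0.3) times Dirichlet cell fractions), plus N(0, 1)
  noise. Cell fractions use a symmetric Dirichlet with concentration 0.5
  over 9 cell types; this puts the marginal fraction SD at ~0.13, so the
  simulated scores behave like the *enriched* cell phenotypes the
  downstream 30%-zeros / SD > 0.1 rule is meant to select (a concentration
  of 1 would leave every simulated cell type's SD just below the 0.1
  threshold, silently disabling the adjustment stage).
* **Counts.** Poisson draws around `count_scale * exp(latent)` (default
  scale 30) with independent Bernoulli zero-inflation (default rate 0.1),
  which produces the zero fractions the preprocessing filters need to
  exercise. This distributional family is a pragmatic stand-in; nothing in
  the downstream method depends on it.
* **Survival.** Exponential baseline hazard (default rate 1/30 months)
  scaled by `exp(sum of arm-specific log-HRs x standardized gene latent +
  covariate effects)`; arms assigned by fair Bernoulli. By default two
  genes adjacent to eGenes carry a log-HR of ln 1.5, one per arm.
  Censoring is an independent exponential process whose rate gives the
  configured expected censored fraction (default 30%) under the baseline;
  an earlier informative-censoring scheme (censoring time as a fraction of
  the event time) was replaced because it violates the independent-
  censoring assumption of the Cox model.

What the generator does **not** emulate: linkage disequilibrium (variants
are independent), read-level sequencing artifacts, population structure,
batch effects beyond the cell-fraction channel, and the tens-of-thousands
gene panels of real RNA-seq. The last point matters: at desk-scale panels
(tens of genes) upper-quartile normalization couples all genes through the
per-sample quantile (measured mean |r| ≈ 0.05 against an unrelated gene's
latent at a 24-gene panel, vs ≈ 0.014 expected under independence), a
coupling that is negligible at realistic panel sizes. Passing tests on
synthetic cohorts therefore demonstrate the statistical machinery, not
robustness to the full messiness of FFPE tumor RNA-seq.

## Preprocessing

Stages and their defaults: exact-duplicate
samples reduced to one; samples with >50% zero genes dropped; genes
retained when the SD of upper-quartile-normalized counts is ≥ 0.5 and the
raw zero fraction is ≤ 30% (a gene constant in raw counts is dropped
regardless, since per-sample scaling can manufacture variance for it);
upper-quartile normalization to the mean of per-sample UQs of nonzero
counts; log2(x+1); cell types kept when ≤ 30% zeros and SD > 0.1;
expression residualized on the enriched cell fractions (with one fraction
dropped as reference when the enriched set spans the simplex). Quantiles
use the linear-interpolation convention throughout. The SD filter is
evaluated on normalized counts before the log transform; the order is
configurable; either convention is defensible.
Recorded sex is checked by k = 2 k-means on chromosome-Y genes, labeling
the higher-expression cluster male-like.

## cis-eQTL mapping

For every gene-variant pair within a closed ±1 Mb window of the TSS on the
same chromosome, expression is regressed on dosage with covariates
(clinical covariates, genotype PC1 when supplied). Gene-level significance
uses an adaptive permutation scheme: covariates are residualized out of
expression and dosages once, so every permutation reduces to a correlation
scan with the degrees of freedom reduced by the number of covariates; the
statistic is the minimum nominal p over the gene's cis variants; the
adjusted p is (r+1)/(n+1) with early stopping at 100 exceedances or
10,000 permutations. The beta-distribution tail refinement some eQTL
mappers add on top of the empirical p is deliberately not implemented —
the empirical estimate is exact to Monte-Carlo error and the adaptive rule
bounds that error. eGenes are genes with adjusted p < 0.05; each carries
its top variant as a candidate instrument. Enrichment of eQTL sets in
genomic annotations is scored as z = (observed − mean null)/SD(null)
against 1000 matched null sets drawn from equal-frequency covariate bins
(10 per covariate by default; bin definitions are a package choice).

## Network learning

Within each k-means gene cluster (k = 4, standardized per-gene profiles,
genes sorted before clustering so the partition is order-invariant), two
stability routes are run and their edge sets intersected:

* **FDR route** — full-order partial correlations (precision matrix of the
  cluster correlation matrix), Fisher-z p-values, Benjamini-Hochberg at
  q = 0.05. A shrinkage option handles genes ≥ samples.
* **Hamming-distance route** — PC-stable skeletons along
  α ∈ {10⁻³ … 10⁻²²}; consecutive skeletons compared by Hamming distance
  (symmetric difference of undirected edge sets; orientation ignored); a
  broken-stick regression HD = β₀ + β₁α + β₃(α − α_k)·1{α > α_k} fit at
  every interior grid candidate. Among candidates whose slope-change term
  is significant (t-test, p < 0.05) the **minimum-RSS** breakpoint is
  selected (ties toward larger α); if none is significant the global
  minimum-RSS candidate is used with a warning. A "largest significant α"
  rule was considered and rejected: on a convex single-kink HD curve
  essentially every candidate shows a significant slope change, so the
  maximal one systematically overshoots the kink, whereas only the true
  kink attains near-zero RSS. Note that on the raw α scale the decade grid
  collapses: every α below ~10⁻⁵ is numerically zero relative to 10⁻³, so
  only kinks in the top grid positions are identifiable; a log-scale
  regressor is available via `log_scale=True`.

The PC-stable skeleton freezes adjacency sets at each depth before any
removal, making the output invariant to gene order; conditioning sets are
drawn from both endpoints' frozen adjacencies; separating sets are
recorded. Conditional independence uses the Fisher z transform of the
partial correlation obtained by inverting the {i,j}∪S correlation
submatrix.

Orientation applies, in order: unshielded-collider (v-structure) detection
from separating sets, with conflicts left undirected; Mendelian
randomization on each undirected edge whose endpoint carries an
instrument (orient g1→g2 when the instrument of g1 associates with g2
marginally at p < 0.05 but not after conditioning on g1; contradictory
verdicts leave the edge undirected); and prior-knowledge orientations,
which win over earlier orientations but never add edges. Any orientation
that would close a directed cycle is refused and logged. Undirected edges
are first-class and are never dropped. Meek-rule CPDAG completion is
intentionally not applied.

Edges are validated on held-out samples: for each gene, least-squares
coefficients from its neighbors on the training samples predict its
held-out expression; the gene validates at Pearson r > 0.5, and an edge is
flagged validated when at least one endpoint validates (configurable to
both).

## Subnetworks, the network-adjusted Cox model, and stratification

A subnetwork is an eGene plus all genes within undirected-graph distance
two. Within a subnetwork and treatment arm, the hazard is

    h(t) = h0(t) exp( γ·G̃ + β·G + θ·Z + δ·T )

where G̃ stacks each member gene residualized on its direct (directed-
edge) upstream genes inside the subnetwork — the hat-matrix projection
with intercept — G stacks the raw upstream genes, Z the clinical
covariates, and T the enriched cell fractions. Residualization is computed
by least squares even when the upstream design is rank-deficient (the
projection is still unique; a warning names the collinear genes). Because
a raw upstream gene that is itself a member makes the printed design
exactly collinear (its raw column lies in the span of its residualized
column plus its own upstream raws), raw columns that are linearly
dependent on the retained design are pruned by an incremental rank check;
residualized columns are always kept, so every member gene receives a
hazard ratio exp(γ̂) and Wald p. Since pruning only removes columns
already in the span, the fitted linear predictor space is unchanged. The
partial likelihood is maximized by lifelines with Efron tie handling and a
tightened convergence precision (1e-9; the default tolerance leaves toy
problems several 1e-4 from the optimum).

A signature is the set of member genes with Wald p < 0.1 in an arm. Each
signature gene is dichotomized at its cohort-wide third quartile (all
arms, linear interpolation, strictly greater than); a patient is "high"
when every signature gene is high, "medium-to-low" when every gene is
below, otherwise mixed — mixed patients are reported but excluded from
the two-group Kaplan-Meier comparison. KM curves use the product-limit
estimator with Greenwood confidence bounds; the median is the first time
survival drops to ≤ 0.5; group comparison is the one-degree-of-freedom
log-rank test.

Interpretation caveat, quantified on synthetic cohorts: the model
estimates each gene's effect *given its identified parents*. Ancestors of
a survival-driving gene carry genuine indirect effects and legitimately
enter signatures; descendants of a driving gene are genuinely associated
with OS and are suppressed only where orientation succeeds in identifying
the upstream set. Since many edges are unorientable from observational
data (Markov equivalence) and instruments cover only eGene-adjacent
edges, descendant genes enter signatures at well above the nominal rate
(≈0.6 of tested descendants on default synthetic cohorts), and even
marginally independent genes reject at ≈0.10–0.13 rather than the nominal
0.0975, reflecting finite-sample Wald behavior with heavy-tailed
expression covariates (the robust sandwich variance does not change
this). The per-cluster network construction also loses every
cross-cluster edge; at desk-scale panels (15-gene clusters) this removes
roughly half of the planted-gene edges, capping end-to-end recovery near
0.5 under the default conditions, versus >0.9 when the panel is small
enough for partners to co-cluster.

## Immune signature scoring

A signature definition is a named gene list with an aggregation rule:
per-patient median of the member genes' (log2) values, or — for
cytotoxicity-style scores — the geometric mean on the linear scale,
computed as 2^mean(log2 values) (always positive because the upstream
log2 transform applies a pseudocount). Gene-signature correlation tables
flag |Pearson r| > 0.4 for display.

## Pipeline, reproducibility, numerics

`run_pipeline` chains simulate → preprocess → eQTL → network → survival →
immune, writing each stage's artifacts (TSV/VCF/JSON/SIF/GraphML) and a
manifest with the config hash and stage seed. One global seed fans out to
per-stage seeds by SHA-256 of "seed:stage", keeping every stage
bit-reproducible and independent of which other stages run. Genomic
coordinates are 1-based closed internally; BED input is converted at the
boundary. Degenerate inputs (monomorphic variants, constant genes,
zero-variance PCA columns, zero null-set variance in enrichment) warn and
are skipped or reported missing rather than raising, except where a
result would be silently wrong (all-zero samples, cyclic graphs,
rank-deficient adjustment covariates).

Problem sizes in the test suite are chosen to keep the full run under a
few minutes of one CPU: stage oracles run at n ≤ 2,000, calibration
checks at 2,000 replicates, and end-to-end recovery on 20 cohorts of
3,000 patients x 60 genes; `scripts/acceptance.py` re-runs the same
experiments at 10 seeds plus one full desk-scale pipeline (400 patients,
matching the few-hundred-sample scale typical of trial expression
subsets).
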