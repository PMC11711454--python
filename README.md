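# netsig

Transcriptomic-causal networks, cis-eQTL instruments, and
network-adjusted survival signatures for patient stratification.

## The problem

In trials comparing targeted therapies (e.g. bevacizumab vs. cetuximab
plus chemotherapy in metastatic colorectal cancer), pre-treatment tumor
gene expression can carry predictive signal: small sets of genes whose
expression separates patients who benefit from one therapy from those who
do not. Testing genes one at a time against overall survival (OS)
confounds direct effects with network effects — a gene can look
prognostic merely because an upstream regulator drives both it and
survival. `netsig` implements the opposite approach: first learn a
gene-gene causal network from expression and germline genetic
instruments, then estimate each gene's effect on OS *adjusted for its
upstream genes*, and finally turn the significant genes of each
eGene-anchored subnetwork into a dichotomized signature for Kaplan-Meier
stratification.

The pipeline, stage by stage:

1. **Preprocessing** — duplicate/degenerate sample removal, gene filters
   (SD of normalized counts ≥ 0.5, ≤ 30% zeros), upper-quartile
   normalization, log2, immune cell-fraction adjustment, chrY sex check.
2. **cis-eQTL mapping** — linear models for all gene-variant pairs within
   ±1 Mb of the TSS; gene-level adaptive permutation p (up to 10,000
   permutations); eGenes at adjusted p < 0.05; enrichment z-scores
   against covariate-matched null variant sets.
3. **Network learning** — per k-means gene cluster (k = 4), the
   intersection of two stability routes: Benjamini-Hochberg-selected
   full-order partial-correlation edges (FDR ≤ 0.05), and the PC-stable
   skeleton at the significance level α* found by a broken-stick
   regression of the Hamming distance between consecutive skeletons along
   α ∈ {10⁻³…10⁻²²}

       HD = β₀ + β₁·α + β₃·(α − α_k)·1{α > α_k}

   with the breakpoint α_k chosen among significant slope changes by
   minimum residual sum of squares. Edges are oriented by v-structures,
   by Mendelian randomization using each eGene's top cis variant as an
   instrument, and by prior knowledge; unidentified directions are kept
   undirected. Edges are validated by neighbor-based prediction on
   held-out samples (r > 0.5).
4. **Signatures and survival** — per eGene subnetwork (distance ≤ 2) and
   treatment arm, the network-adjusted Cox model

       h(t) = h₀(t) exp(γ·G̃ + β·G + θ·Z + δ·T)

   with G̃ the member genes residualized on their upstream genes, G the
   raw upstream genes, Z clinical covariates, T cell fractions. Genes
   with Wald p < 0.1 form the signature; patients are labeled high /
   medium-to-low by the cohort-wide third quartile of each signature
   gene, and the groups compared by Kaplan-Meier curves and the log-rank
   test.
5. **Immune scoring** — median (or, for cytotoxicity, linear-scale
   geometric mean) signature scores and gene-signature correlation
   tables (|r| > 0.4 display mask).

Because the patient-level data behind such a study are not public, the
package includes a first-class synthetic-cohort generator
(`netsig.synthcohort`) producing a sparse gene DAG realized as a linear
structural-equation model, cis instruments, cell-type contamination,
zero-inflated counts, and arm-specific survival effects — with the
generating truth retained, so every stage is testable for recovery
(`netsig.recovery`). See `docs/methods.md` for the model details and
known limitations.

## Worked example

```python
from netsig import recovery, signatures
from netsig.synthcohort import SimulationConfig, make_cohort

cfg = SimulationConfig(seed=7, n_samples=3000, n_genes=60, n_clusters=4)
cohort = make_cohort(cfg)
print(cohort.truth.signature_genes)
# {'G037': {'cetuximab': 0.405}, 'G050': {'bevacizumab': 0.405}}

expr, enriched, clinical = recovery.preprocess_cohort(cohort)
instruments = recovery.map_egenes(cohort, expr, clinical, seed=7)
graph = recovery.learn_network(expr, instruments, cohort.variants.dosages,
                               n_clusters=4, seed=7)
print(len(graph))                      # 16 stable edges, 4 directed
```

Fitting the network-adjusted Cox model in the cetuximab arm of the
subnetwork anchored at eGene `G000` and stratifying by the resulting
signature prints:

```
subnetwork G000 / cetuximab: gene G037 HR=1.12 p=2.59e-18
KM: high n=60 median=8.4 mo | medium-to-low n=713 median=23.2 mo | log-rank p=1.6e-12
```

The planted hazardous gene `G037` (true arm-specific log-HR ln 1.5 on its
standardized latent value; the printed HR is per unit of adjusted log2
expression) is recovered in the correct arm, and patients with high
expression of every signature gene show the shorter median OS — 8.4 vs
23.2 months — exactly the kind of treatment-specific stratification the
method is built to find.

The same stages are available from a thin CLI:

```bash
netsig run-all --seed 7 --outdir run7      # simulate + full pipeline
netsig report --outdir run7
```

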