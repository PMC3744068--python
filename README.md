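# anchorprio

Anchored gene prioritization for case/control expression studies.

Given an *anchor gene* (by default **FBN1**, the fibrillin-1 gene mutated in
Marfan syndrome), the package asks which genes related to the anchor are
dysregulated in a disease context such as trisomy 21 (Down Syndrome).
Candidate genes are gathered from three sources:

1. the anchor's **interaction neighborhood** — genes at shortest-path
   distance 1 ("direct") or 2 ("indirect") in a protein–protein
   interaction network;
2. **pathways** enriched in either study, found by preranked Gene Set
   Enrichment Analysis (GSEA) with a permutation null and FDR q-values;
3. **co-expression modules** containing the anchor, found by the
   Iterative Signature Algorithm (ISA) and merged when they share more
   than 80 % of their genes.

Candidates significant in at least one of two studies — a multi-study
meta-analysis (surrogate Stouffer score ≥ 3.4) or a case/control
expression study (shrinkage t-test, p < 0.1) — are then integrated by a
conjugate normal Bayesian update.  Per gene, the meta-analysis supplies
the prior θ ~ N(θ₀, σ₀²) (θ₀ = mean of per-study log2-ratio means over
studies with detection p < 0.1, σ₀ = their SD), and the case samples
supply the likelihood summary (x̄, σ, n).  The posterior is
N(θ₁, σ₁²) with

    1/σ₁² = 1/σ₀² + n/σ² ,   θ₁ = σ₁² (θ₀/σ₀² + n·x̄/σ²)

and each gene is scored by the **Typified Bayes Value** TBV = θ₁/σ₁,
called significant when |TBV| > 2.58 (the two-sided 99 % normal critical
value).  Downstream analyses cover hypergeometric overlap tests, disease
gene-list enrichment, anchor-gene Pearson correlation/concordance across
studies, Canberra/complete-linkage clustering with Newick dendrogram
export, and Cytoscape-compatible SIF network export.

A synthetic-data module generates all five inputs (study-level effect
table, case/control expression matrix, interaction network, pathway
collection, disease gene list) with planted ground truth, so the whole
pipeline is testable without any data download.

## Worked example

```python
import pandas as pd
from anchorprio import posterior_update

priors = pd.DataFrame({"gene": ["FBN1"], "theta0": [0.5], "sigma0": [0.2]})
lik = pd.DataFrame({"gene": ["FBN1"], "xbar": [0.8], "sigma": [0.5], "n": [10]})
post, _, _ = posterior_update(priors, lik)
print(post.round(5).to_string(index=False))
```

prints

```
gene  theta0  sigma0  xbar  sigma  n  theta1  sigma1     tbv  significant
FBN1     0.5     0.2   0.8    0.5 10 0.68462 0.12403 5.51955         True
```

The posterior mean 0.685 lies between the prior mean 0.5 and the data
mean 0.8 (precision-weighted), the posterior SD 0.124 is smaller than
either source alone, and TBV = 5.52 > 2.58 calls the gene significant.

A full synthetic run from the command line:

```
anchorprio run-all --config config.yaml
```

with `config.yaml`:

```yaml
seed: 1
output_dir: demo_run
simulate:
  n_genes: 2000
  rng_seed: 0
```

finishes in a few seconds and reports, among other counts:
2,000 genes in the meta universe and 1,806 on the synthetic heart
platform; a 96-gene anchor neighborhood; 63 meta-analysis and 203 heart
candidates; 67 assembled candidate genes of which 65 are TBV-significant
(63 outside HSA21, 2 on it).  Scored against the planted truth this run
attains sensitivity 1.0 at a false-positive rate of 0.002.  All stage
outputs (priors, t-statistics, GSEA/ISA tables, posterior, dendrograms,
SIF network, JSON report and manifest) are written under `demo_run/`.

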