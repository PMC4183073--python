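# adiponet

Weighted gene co-expression network analysis of RNA-Seq count data for
three-group (lean / intermediate / obese) study designs: normalization,
unsigned network construction with soft thresholding, topological-overlap
module detection, module–trait statistics, lean-vs-obese differential
connectivity, gene-length-bias-corrected enrichment, and module-network
regulator scoring — together with a synthetic-study generator that plants
known modules, trait correlations, condition-specific hub blocks and
regulator genes, so every stage can be validated against ground truth.

It is aimed at researchers analysing bulk RNA-Seq of phenotypically extreme
groups (the reference design is 36 adipose-tissue samples, 12 per group)
who want the complete count-matrix-to-regulators workflow as tested,
composable Python rather than a pile of R scripts.

## The analysis in brief

* **Normalization.** Genes with mean raw count ≤ 5 are removed; library
  size factors are estimated by the median-of-ratios method
  (s_j = median_i k_ij / (∏_v k_iv)^(1/m) over genes positive in all
  samples); expression is offset log2-CPM, residualized on gender.
* **Network.** Unsigned adjacency a_ij = |cor(x_i, x_j)|^β with β chosen by
  the scale-free topology criterion (smallest β with negative slope and
  R² ≥ 0.90 of the log p(k) vs log k regression; sample-size convention
  when no β reaches the target). The topological overlap
  t_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij), ℓ_ij = Σ_u a_iu a_uj,
  feeds average-linkage clustering of 1 − TOM; branches with ≥ 50 genes
  become modules.
* **Module statistics.** The module eigengene is the first principal
  component of the standardized module submatrix; module–trait
  relationships (MTR) are Pearson correlations of eigengenes with
  phenotypes; kME is the gene–eigengene correlation used to refine module
  membership (kME_own > 0.6, kME_other < 0.6).
* **Differential connectivity.** Lean-only and obese-only sub-networks at
  β = 9; per-gene connectivity normalized by the sub-network maximum;
  k_diff = k_obese − k_lean ∈ [−1, 1]; genes with |k_diff| > 0.6 and
  |t| > 1.96 (pooled two-sample t, obese vs lean) are called.
* **Enrichment.** A probability weighting function P(selected | length) is
  fitted by isotonic regression on length-binned selection rates and
  converted into per-term odds for Wallenius' noncentral hypergeometric
  test; Benjamini–Hochberg adjustment across terms.
* **Regulators.** Genes (centered/scaled, SD > 0.5) are clustered by a
  Dirichlet-process Gibbs sampler run 10 times and integrated into tight
  clusters; each cluster's samples are arranged in a hierarchical tree;
  candidate regulators are assigned to tree nodes by logistic regression
  and accumulate balance-weighted −log10 LR p-values over the ensemble
  into a global probabilistic score; the top 1% are reported and compared
  with randomly assigned genes by t-test.

## Worked example

```python
import adiponet as an
import pandas as pd
from sklearn.metrics import adjusted_rand_score

study = an.simulate_study(an.SimulationConfig(seed=0))   # 1,000 genes, 36 samples
counts = an.filter_low_expression(study.counts)          # mean count > 5
expr = an.normalize(counts, an.size_factors(counts), study.phenotypes)
expr = an.variance_filter(expr, 0.25)                    # SD > 0.25

genes = an.select_by_connectivity(expr, study.phenotypes["group"],
                                  top_n=min(1500, expr.shape[0]), beta=7)
net = an.WGCNA(beta="auto").fit(expr.loc[genes])
print("beta:", net.beta_)
print("modules:", net.modules_.value_counts().to_dict())

eig, ve = an.module_eigengenes(expr.loc[genes], net.modules_)
mtr = an.module_trait(eig, study.phenotypes.select_dtypes("number"))
print("strongest MTR:", mtr.r.abs().max().max().round(2))

truth = pd.Series(study.truth.module_of_gene).loc[genes]
print("recovery ARI:", round(adjusted_rand_score(truth, net.modules_), 2))
```

Output:

```
beta: 7
modules: {'grey': 448, 'turquoise': 163, 'blue': 99, 'brown': 90, 'yellow': 80, 'green': 70}
strongest MTR: 0.67
recovery ARI: 0.86
```

The five planted modules come back as the five colored branches (the
largest is "turquoise" by the conventional size-ranked naming; "grey"
collects unassigned genes), the chosen soft power is the one the reference
study design calls for at 36 samples, the strongest module–trait
correlation is close to the planted 0.7, and the adjusted Rand index
against the planted labels shows the partition is essentially recovered.

The same workflow is available end to end:

```bash
adiponet pipeline run --seed 5          # simulate -> ... -> regulators
```

which writes `report.json`, per-stage TSV tables and `run.log` into a
config-named directory, byte-identically for a fixed seed.

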