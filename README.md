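# sbmpheno

Network-based discovery of behavioral sub-populations in multi-site animal
cohorts, with fully Bayesian uncertainty quantification.

Preclinical addiction studies score each animal on several behavioral
assays — drug taking, refraining, relapse-like seeking — and ask whether the
cohort contains distinct vulnerability sub-populations.  Composite scores
flatten these traits into one axis; `sbmpheno` instead clusters animals on a
similarity *network* so that non-linear, multi-trait structure can surface,
and, because the clustering is a generative probability model, every
assignment comes with a posterior uncertainty.

The workflow:

1. **Within-site z-scoring** removes location-shift batch effects between
   study sites.
2. A **k-nearest-neighbor similarity network** joins each subject to its
   R = round(√n) most similar peers (Euclidean distance over standardized
   measures, union symmetrization).
3. A **Bayesian stochastic block model** is fit by Gibbs sampling:

   A_ij | z, Θ ~ Bernoulli(θ_{z_i z_j}) for i < j, with
   z_i ~ Categorical(π), π ~ Dirichlet(α), θ_rs ~ Beta(β₁, β₂);
   defaults α_k = 1, β₁ = β₂ = 1, 10,000 iterations, 1,000 burn-in.
   Label switching is handled by canonical (first-occurrence) relabeling of
   every stored sample; the partition estimate ẑ maximizes the collapsed
   posterior p(z | A); K is compared across fits by BIC.

4. **Phenotyping**: per subject, the assignment uncertainty
   u(i) = 1 − (1/S)Σ_s 1[z_i⁽ˢ⁾ = ẑ_i] and the continuous vulnerability
   score v(i) = (1/S)Σ_s 1[z_i⁽ˢ⁾ = k_v], where k_v is the cluster whose
   composite behavioral profile ranks most vulnerable.  Clusters are
   compared by per-measure one-way ANOVA and partitions by the adjusted
   Rand index.

See `docs/methods.md` for the model details, numerical choices and
limitations.

## Worked example

Real behavioral cohorts of this kind are rarely public, so the package
ships a generator whose default benchmark is shaped like a two-site,
451-rat heroin self-administration study (three latent clusters of
200/122/129 subjects, seven measures, a one-sd site offset on six of
them):

```python
import sbmpheno as sp

table, net, truth = sp.make_default_benchmark(seed=42)
model = sp.StochasticBlockModel(net, k=3)
res = model.fit(n_iter=10_000, n_burn=1_000, seed=42)
print(res.summary())
```

```
Bayesian stochastic block model (Gibbs)
==============================================
nodes: 451   edges: 6686   K: 3
iterations: 10000 (burn-in 1000, 9000 kept)   seed: 42
log-likelihood (MAP): -20688.73   BIC: 41469.67
cluster sizes: 1: 125, 2: 155, 3: 171

connectivity Theta (posterior mean [95% CI]):
  theta[1,1] = 0.1497 [0.1413, 0.1585]
  theta[1,2] = 0.0444 [0.0415, 0.0474]
  theta[1,3] = 0.0236 [0.0215, 0.0258]
  theta[2,2] = 0.1593 [0.1519, 0.1670]
  theta[2,3] = 0.0000 [0.0000, 0.0002]
  theta[3,3] = 0.1558 [0.1497, 0.1619]
```

Every within-cluster connectivity (diagonal) is several times larger than
every between-cluster one — assortative structure, i.e. genuine behavioral
sub-populations.  The two extreme clusters are almost never directly
linked (θ₂₃ ≈ 0.000): they are bridged only through the intermediate
cluster.

```python
report = sp.build_report(res, table)
report.annotations          # {2: 'vulnerable', 1: 'intermediate', 3: 'resilient'}
len(report.flagged_uncertain)   # 15 subjects with u > 0.10
sp.adjusted_rand_index(res.z_map, truth["z"])   # 0.476 vs generating labels
report.anova.head(2)
#             measure       F    p
#   total_consumption  180.03  0.0
#          escalation  139.20  0.0
```

Fifteen subjects spent more than 10% of the chain outside their assigned
cluster — border animals worth individual follow-up — and all seven
measures separate the clusters decisively (ANOVA F ≳ 100).  The moderate
ARI against the generating labels reflects the benchmark's deliberately
overlapping cluster profiles: neighbouring animals genuinely share
behavior, and the uncertainty scores say so.

The same pipeline runs from the shell:

```bash
sbmpheno simulate --out cohort.csv --truth truth.csv --seed 42
sbmpheno run cohort.csv --out results/
# or stage by stage:
sbmpheno standardize cohort.csv --out std.csv
sbmpheno network std.csv --out net.edgelist          # R = 21 at n = 451
sbmpheno select-k --network net.edgelist --kmin 2 --kmax 10
sbmpheno fit --network net.edgelist --k 3 --iter 10000 --burn 1000 --seed 42
```

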