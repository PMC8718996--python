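# Methods

## Problem and model

`sbmpheno` discovers latent sub-populations in a cohort of subjects measured
on a handful of continuous behavioral assays at more than one study site —
the motivating case is outbred rats scored on seven operant measures of drug
taking, refraining and seeking, collected in two laboratories.  The workflow
is:

1. **Batch correction.** Each measure is z-scored *within study site*
   (sample, n−1, standard deviation).  This removes location-scale site
   effects exactly; it deliberately does nothing more (no imputation, no
   quantile matching), because the observed between-site differences are
   location shifts.  Constant-within-site measures are a hard error rather
   than being dropped silently: removing a column would change the distance
   metric downstream without the user noticing.
2. **Similarity network.** Euclidean distances over the standardized
   measures; each subject is joined to its R nearest neighbors and the
   directed relation is symmetrized by **union** (an edge exists when either
   endpoint names the other).  Union is the minimal completion that keeps
   every stated neighbor edge; a consequence is that degrees are ≥ R, not
   exactly R.  Distance ties are broken by ascending node index so the graph
   is identical across runs and platforms.  The default neighbor count is
   the widely used heuristic R = round(√n) (21 at n = 451).
3. **Stochastic block model.**  With labels z_i ∈ {1..K},

       A_ij | z, Θ ~ Bernoulli(θ_{z_i z_j}),  i < j,

   under conjugate priors z_i ~ Categorical(π), π ~ Dirichlet(α₁..α_K),
   θ_rs ~ Beta(β₁, β₂) for r ≤ s.  Defaults are the weakly informative
   α_k = 1, β₁ = β₂ = 1.  No degree correction: kNN graphs have
   near-uniform degree, so the extra parameters buy nothing.
4. **Posterior inference.** Plain Gibbs sampling (10,000 iterations, 1,000
   burn-in by default, single chain, systematic 1..n sweep, uniform random
   initial labels).  Label switching is removed by projecting every stored
   sample onto the canonical subspace: community labels are renamed in order
   of first occurrence along z.  The partition estimate is the stored sample
   maximizing the **collapsed** posterior p(z | A) with π and Θ integrated
   out (Dirichlet-multinomial term plus a Beta-function ratio per block
   pair); ranking by the collapsed posterior is well defined independently
   of the accompanying continuous draws, and ties go to the earliest
   iteration.
5. **Model selection.** BIC = −2 log L(ẑ, Θ̄) + p log M with
   p = K(K+1)/2 + (K−1) free parameters and M = n(n−1)/2 dyads, compared
   across independent fits for a range of K (per-K seeds derived as
   seed + K).  The parameter count and sample size are this package's
   definition (recorded in every fit summary); BIC for SBMs has no single
   canonical form, and on kNN graphs it should be read as a guide to a
   *set* of comparably good K — see "Limitations".
6. **Phenotyping.** From the canonical samples: uncertainty
   u(i) = 1 − (1/S) Σ_s I(z_i^(s) = ẑ_i) and, once a cluster k_v is
   annotated as the vulnerable phenotype, the continuous vulnerability
   score v(i) = (1/S) Σ_s I(z_i^(s) = k_v).  Cluster annotation ranks
   clusters by the mean orientation-adjusted z-score over members and
   measures (orientation is a user-supplied ±1 per measure, default all +1);
   with K = 3 the ranks map to vulnerable / intermediate / resilient.  Flag
   lists use u > 0.10 (uncertain assignment) and u > 0.10 ∧ v < 0.90
   (uncertain and not already firmly vulnerable).  Descriptive statistics
   are one-way ANOVA F per measure (unadjusted p by default, Bonferroni
   optional) and the adjusted Rand index between partitions.

## Numerical and implementation choices

* The production sampler is a single numba-compiled kernel (`_engine.py`)
  covering all three conditional updates, canonical relabeling and the
  collapsed log posterior of each stored sample; Dirichlet and Beta draws
  are composed from gamma variates, the label conditional is evaluated in
  log space (per-node cost O(deg + K²) via neighbor lists).  Readable
  single-step NumPy implementations of every update live in `sbm.py` and
  are tested against conjugate closed forms; the fused kernel is tested
  against exact posterior enumeration on 6-node graphs (total variation
  < 0.05 required; < 0.01 observed).
* θ draws are clipped to [1e−12, 1 − 1e−12] before logs purely as an
  underflow guard; conjugate Beta draws have open-interval support so the
  clip is essentially never active.
* Credible intervals for Θ are equal-tailed 2.5%/97.5% sample quantiles
  with linear interpolation between order statistics; the rule is recorded
  in the JSON output because other conventions shift interval ends by
  O(1/S).
* Empty clusters are legal during sampling — K is an upper bound, and the
  Dirichlet prior keeps emptied clusters reachable.  Blocks with no
  possible dyads fall back to the Beta prior.
* Reproducibility: every stochastic entry point takes a seed; a fit is
  bit-reproducible for a given (network, config, seed), and the pipeline
  manifest records every derived seed.

## Synthetic data: what it emulates and what it does not

The cohort generator plants K clusters with ordered mean profiles on the
z-scale, adds per-site location offsets and i.i.d. Gaussian noise (a
lognormal option mimics the right skew of raw operant counts; the pipeline
operates on z-scores and the network on distance ranks, so the noise family
matters little).  The default benchmark is shaped like the motivating
study: 451 subjects in clusters of 200/122/129, seven measures with mean
profiles +0.9/0/−0.9, two sites (243/208 expected split), a one-sd site
offset on six of seven measures, and a mild female bias in the top cluster.

What passing tests on these data do **not** show: real behavioral measures
are correlated within subject, attrition is not random, cluster profiles
need not be parallel across measures, and real site effects may not be pure
location shifts.  The generator is a ground-truth harness for the
*inference machinery*, not a calibrated model of any cohort.

## Design choices where the design was open

* **Union vs intersection kNN symmetrization:** union (keeps every declared
  neighbor edge; intersection would drop edges and can disconnect sparse
  graphs).
* **MAP over samples vs joint MAP:** collapsed p(z|A) over stored samples;
  the joint density with sampled continuous parameters would make the
  ranking depend on Monte-Carlo noise in π and Θ.
* **√n rounding:** round-to-nearest (floor and round agree at n = 451).
* **Annotation rule:** composite orientation-adjusted mean rather than a
  single designated measure, since ordered cluster profiles are typically
  consistent across measures; ties beyond 1e−9 raise instead of guessing.
* **No spectral or greedy warm start:** uniform random initial labels keep
  the sampler's behavior interpretable; the cost is documented below.

## Limitations

* **Mode sticking.** A single Gibbs chain from random labels can lodge in a
  suboptimal partition mode on *strongly* separated sparse kNN graphs
  (e.g. merging two well-separated clusters and splitting a third); the
  collapsed posterior of the stuck mode is visibly worse, so comparing the
  reported `log_post` across seeds diagnoses it.  Re-running with a few
  seeds and keeping the best collapsed posterior is the practical remedy.
* **BIC on kNN graphs.** On networks *simulated from the SBM itself* the
  BIC sweep recovers the generating K reliably (tested: 10/10 at n = 300,
  K = 3).  On kNN graphs built from overlapping continuous profiles — the
  benchmark, and realistically any behavioral cohort — BIC keeps improving
  slowly past the generating K because local neighborhood structure always
  supports finer blocks; K = 2 is sharply worse, while K = 3..6 are close.
  The tool therefore reports the full BIC table and leaves the final choice
  of K to the analyst's domain knowledge, rather than auto-selecting the
  argmin blindly.
* **Anchor-node artifact.** Under canonical first-occurrence relabeling the
  first subject in row order always carries label 1, so its uncertainty is
  0 by construction, and u for other subjects is measured relative to that
  anchoring.  With well-separated communities this is immaterial; with very
  unstable partitions, u should be interpreted jointly with the occupancy
  matrix rather than alone.
* Dense adjacency storage bounds practical use to n of a few thousand,
  ample for behavioral cohorts.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use: 6-node graphs with full
2⁶ enumeration and 100,000 retained samples for sampler exactness; planted
three-block networks at n = 300 (θ_in = 0.30, θ_out = 0.03, 10 seeds,
10,000 iterations) for recovery and a K = 1..6 sweep at 4,000 iterations
for selection; a 180-subject two-site cohort for the batch-correction
contrast; and the 451-subject benchmark for the end-to-end run.  These
sizes match the scale of the motivating study while keeping a full run in
minutes on one CPU.
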