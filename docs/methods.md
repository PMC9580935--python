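# Methods

## The problem

Shotgun metagenomes mix reads from every strain of every species in a
community. For a single species, a *metagenotype* summarizes this
evidence as an N x G x 2 count array: for each of N samples and G
biallelic SNP sites, the number of reads carrying the reference and the
alternative allele. `straindecon` deconvolves a metagenotype into

* `Gamma` (S x G): latent strain genotypes, relaxed to *fuzzy* values in
  (0, 1) between fully reference (0) and fully alternative (1), and
* `Pi` (N x S): per-sample strain relative abundances (rows on the
  simplex),

so that the underlying alternative-allele frequency in sample i at site
g is `p_ig = sum_s pi_is * gamma_sg`, a structure closely related to
non-negative matrix factorization but with simplex and interval
constraints. The fuzzy relaxation makes the whole posterior
differentiable, so estimation is gradient-based and scales to hundreds
of strains and thousands of samples.

## Model

Measurement: reads carry the wrong allele at a per-sample rate
`eps_i`, giving `ptilde = p (1 - eps/2) + (1 - p) eps/2`; observed
alternative counts are Beta-Binomial,
`y_ig ~ BetaBinom(ptilde_ig, alpha* | m_ig)`, with concentration
`alpha*` absorbing overdispersion relative to Binomial sampling.

Priors use the shifted-scaled Dirichlet (SSD) family: a draw is
`closure(p_i * z_i^a)` with `z ~ Dirichlet(alpha)`; the reference
composition `p` shifts the distribution and the scale `a` powers it
toward the simplex vertices. The model places

* `(gamma, 1-gamma) ~ SSD(1, 1, 1/gamma*)` on every genotype entry
  (small `gamma*` favors near-discrete genotypes),
* `pi_i ~ SSD(1, rho, 1/pi*)` on each sample's composition, anchored to
  a metacommunity profile `rho`,
* `rho ~ SSD(1, 1, 1/rho*)` on the metacommunity,
* a Beta prior on each `eps_i`.

Hyperparameter defaults (used for every analysis here):
`gamma* = 1e-10`, `pi* = 0.3`, `rho* = 0.5`, `alpha* = 10`,
`eps_a* = 1.5`, `eps_b* = 0.01`. Decreasing `gamma*`/`pi*`/`rho*`
strengthens the respective regularization.

### The error-rate prior orientation

A Beta prior with shapes `(eps_a*, eps_a* eps_b*) = (1.5, 0.015)`
concentrates near 1 — implausible for a sequencing *error rate*, and in
simulation it biases fitted error rates upward, degrading composition
recovery. The default is therefore the orientation
`Beta(eps_a* eps_b*, eps_a*) = Beta(0.015, 1.5)`, whose mean
`eps_b*/(1 + eps_b*) ~ 0.0099` matches the error rates these data
actually exhibit; the reversed orientation remains available via
`Hyperparameters(epsilon_prior_orientation="reversed")` for comparison.

### Estimator: MAP in the unconstrained parameterization

Simplex rows are parameterized by anchored softmax, interval values by
log-odds, and the point estimate maximizes the log posterior *plus the
log-Jacobian of these transforms* — the convention of autodiff
probabilistic-programming stacks. This matters: the corner-seeking SSD
priors have unbounded density at the simplex boundary, so
constrained-space MAP is degenerate — its "mode" collapses every
composition onto a single strain regardless of the data (verified
empirically: with the literal density objective the optimizer abandons
the simulation ground truth it was started at and collapses, at any
realistic sample size). The Jacobian terms vanish at the boundary at
exactly the compensating rate, making the objective bounded. A
byproduct with a clean interpretation: during annealing the genotype
prior goes from center-seeking (`gamma* = 1`, keeping genotypes fuzzy
while the factorization organizes) to flat (`gamma* -> 0`, releasing
them to discretize under likelihood pressure).

Relatedly, the SSD density of `pi_i` given `rho` carries a
normalization factor `prod_s rho_s^(-pi*)` that depends on `rho` only.
Summed over N samples it rewards collapsing `rho` onto one strain by
`~ N * pi* * sum_s(-log rho_s)` — unbounded, and growing with N while
every counterweight is O(1). The objective therefore couples `pi` to
`rho` only through the scale-invariant alignment term
`-S log sum_s (pi_s/rho_s)^pi*`; as a function of `pi` the prior is
unchanged, while `rho` is informed by how well it explains the fitted
rows (plus its own prior).

## Fitting

* **Initialization.** `Pi` and `Gamma` come from scikit-learn NMF
  (random init, seed-determined) of the observed allele-frequency
  matrix; sample loadings are row-normalized (lightly smoothed toward
  uniform to stay interior), components rescaled to compensate and
  clipped to [0.01, 0.99]. `rho` starts uniform; `eps` at its prior
  mean.
* **Optimizer.** Adam (beta1 0.9, beta2 0.999) with learning rate 0.05
  on the unconstrained vector; gradients are analytic (digamma terms
  for the Beta-Binomial, closed forms for the SSD kernels) and verified
  against central finite differences in the test suite.
* **Prior annealing.** `gamma*` and `rho*` are held at 1.0 and 5 for
  the first 2,000 steps, then relaxed geometrically (log-linearly in
  the step index) to their final values over the next 8,000 steps.
* **Convergence.** After the annealing period, whenever the best-seen
  loss has not improved for 100 consecutive steps the learning rate is
  halved; the fit is declared converged when the rate falls below 1e-6.
  The maximum step count defaults to 20,000 (annealing plus headroom).
  The best-seen post-annealing parameters are returned. Loss
  comparisons across the annealing phase are not meaningful (the
  hyperparameters move the objective's normalization), which is why the
  patience counter only runs after it.
* **Precision.** Computations are 64-bit by default (`precision=32`
  available). Fits are bit-reproducible for a fixed seed, precision and
  platform.
* **Post-hoc genotype refit.** After fitting on a site subset, full-
  length genotypes are re-estimated chunk by chunk with `Pi` and `eps`
  fixed, using a fixed-length annealed schedule (default 500 hold +
  1,500 relax + 500 final steps). With `Pi` fixed the objective
  separates per site, and the fixed schedule makes the result exactly
  invariant to the chunking — chunk size only trades memory for
  vectorization.

## Filtering conventions

Sites are filtered on minor-allele occurrence: by default, per site,
the fraction of covered samples (total count > 0) whose within-sample
majority allele is the minor one, with ties counting toward the
alternative allele; sites below 5% are dropped. This majority-vote
statistic is robust to uneven depth; a pooled-read-frequency variant is
available (`mode="pooled"`). Samples with horizontal coverage (fraction
of sites with >= 1 read) below 5% are dropped after site filtering;
this order is fixed. Remaining sites are down-sampled without
replacement to at most 5,000. Site positions are 1-based at I/O
boundaries; arrays are 0-indexed internally.

## Simulation

The generator draws discrete genotypes as i.i.d. symmetric Bernoulli,
compositions from a symmetric Dirichlet with concentration 0.4, applies
error `eps = 0.01`, and draws Binomial counts at uniform depth m = 10 —
the benchmark conditions for all recovery experiments. What it does
*not* emulate: linkage between sites, phylogenetic correlation between
strain genotypes, reference bias, variable and correlated depth, and
multi-species contamination; passing recovery tests therefore bounds
algorithmic correctness, not real-data accuracy. Options off by
default: Beta-Binomial (overdispersed) counts; Poisson depth.

## Evaluation

Five indices, all invariant to strain relabeling and exactly zero when
the estimate equals the truth:

1. **UniFrac error** — mean per-sample normalized weighted UniFrac
   between true and inferred compositions, both placed on one
   average-linkage tree built from masked Hamming distances over the
   union of (discretized) true and inferred genotypes, with branch
   lengths the cophenetic increments. The tree construction is this
   package's convention (verified against scikit-bio's weighted UniFrac
   on the same tree).
2. **Bray-Curtis error** — mean absolute difference of all-by-all
   pairwise Bray-Curtis dissimilarities.
3. **Entropy error** — mean absolute difference of per-sample Shannon
   entropy, in bits.
4/5. **Abundance-weighted best-match Hamming** in both directions
   (truth to inferred and inferred to truth), using masked normalized
   Hamming distance after discretizing fuzzy genotypes at 0.5 (ties to
   the alternative allele).

At the benchmark regime (200 samples, 40 strains, 250 sites, depth 10)
the identifiability floor is substantial even for an oracle that knows
the true compositions, because each strain typically holds only a few
percent of any sample's mass at depth 10; composition indices carry an
additional penalty from the joint estimation.

## Downstream analyses

* **Dereplication**: average-linkage ("average-neighbor") clustering of
  discrete genotypes at 0.05 masked-Hamming distance; each cluster is
  replaced by its per-site majority genotype (ties to alternative) with
  summed abundances.
* **Co-clustering** with reference genotypes at 0.15; clusters are
  categorized shared / inferred-only / reference-only.
* **Permutation enrichment**: the strain-to-cluster assignment vector
  is shuffled (9,999 permutations), the shared-strain or inferred-only
  strain tally recomputed, and the one-sided p-value estimated with the
  add-one rule (1 + b)/(1 + n), which never returns 0.
* **LD**: r^2 across dereplicated strain genotypes (strains are the
  observations; missing alleles excluded pairwise; monomorphic sites
  undefined). Genome-wide LD90 is the 90th percentile over all pairs
  among up to 20,000 sampled positions. The decay profile bins pairs
  into windows `[floor(10^((i-1)/c)), floor(10^(i/c))]` with c = 30
  (120 windows spanning [1, 1e4)); where small-distance windows share
  boundary integers a pair goes to the first matching window, making
  the binning a partition. "Adjacent" SNPs are consecutive polymorphic
  positions. LD_1/2,90 is the smallest window midpoint whose LD90 falls
  below half the adjacent-SNP LD90.

## Numerical choices and degenerate inputs

* Simplex inputs are validated to 1e-6 and silently renormalized below
  that; genotype and error-rate values are kept in the open interval by
  clipping at 1e-15 during optimization; expected frequencies are
  floored at 1e-10 before digamma evaluation.
* Zero-depth cells contribute no likelihood; all-zero samples yield a
  missing (NaN) metagenotype entropy rather than an error.
* Genotype pairs with no co-observed site have undefined distance;
  for clustering they are treated as maximally distant (1.0).
* Ties: within-sample majority allele, per-site consensus majority, and
  fuzzy discretization at exactly 0.5 all resolve to the alternative
  allele; dominant-strain ties resolve to the lowest strain index.

## Known limitations

* Biallelic sites only; multiallelic variants and indels are upstream
  concerns.
* MAP point estimation: no posterior uncertainty on genotypes or
  abundances.
* The strain count S is fixed per fit (default 30% of the sample
  count); model selection relies on the sparsity priors zeroing unused
  strains rather than an explicit search.
* Joint recovery at shallow depth is limited by identifiability (see
  the floor noted above); composition accuracy degrades faster than
  genotype accuracy as per-sample strain heterogeneity rises.
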