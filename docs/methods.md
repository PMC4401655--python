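# Methods

## The Dirichlet-multinomial host-preference model

For each fungal OTU *i* the vector of association counts over the *J*
plant OTUs at one clustering level, `y_i` (`y_ij` = number of samples of
plant OTU *j* containing fungus *i*), is multinomial with total
`N_i = Σ_j y_ij` and composition `π_i`. The conjugate Dirichlet prior uses

    α_ij = T_j · N_i / Σ_j T_j,

where `T_j` is the number of samples of plant OTU *j*. Two properties fix
the interpretation: `Σ_j α_ij = N_i` (the prior carries as much weight as
the data), and the prior mean `α_ij / Σ_j α_ij = T_j / Σ_j T_j` is the
association share expected under random host selection proportional to
sampling effort, identical for every fungus. The posterior is
`Dirichlet(α_i + y_i)` exactly.

Preference is quantified per posterior draw by

    D̄_ij = (π_ij − E[π_ij]) / ‖π_i − E[π_i]‖₂,

with `E[π_ij] = T_j / Σ T_j`. We read the expectation as the *prior* mean
(the random-host-selection value) and the deviation as a per-draw
quantity: only this reading yields the advertised −1…1 range, a sum-zero
unit-norm deviation vector, and a draw-wise distribution from which
credible intervals can be taken. `D̂_ij` is the across-draw mean; 95 % and
99 % equal-tailed quantile intervals give the significance flags (`+` /
`*` when the interval excludes zero). Draws whose deviation vector has
numerically zero norm (π exactly at the prior mean) cannot be normalized;
they are dropped, and more than 1 % dropped draws for an OTU raises an
error rather than silently biasing the summary.

`D̂max_i = max_j D̂_ij` is the *signed* maximum, exactly as defined — not
`max |D̂|`. A row whose largest-magnitude deviation is negative therefore
has `D̂max < max |D̂|`; such rows are flagged (`abs_max_differs`) instead
of being reinterpreted. Comparing `D̂max` across the four host clustering
cutoffs (99.8/99/98/97 % sequence similarity) locates the host taxonomic
grain of the preference: a fungus preferring one whole coarse cluster
scores higher when hosts are clustered at that grain. Cross-level
comparisons use two-sided paired Wilcoxon signed-rank tests on the common
OTU set with Holm correction over the six level pairs, plus a compact
letter display. The exact signed-rank null is enumerated over all 2^n
sign assignments for n ≤ 16 non-zero differences (correct under tied
ranks, where the usual exact algorithms are not); larger n uses the
tie-corrected normal approximation.

### Samplers

The default `conjugate` mode draws i.i.d. samples from the exact
posterior (default 5 000 draws per OTU; OTUs are processed in chunks of
64 to bound memory). The `gibbs` mode is an independent route kept for
fidelity to MCMC-based fits and as a mutual oracle: each latent gamma
variable `g_ij` (with `π_i = g_i / Σ g_i`, `g_ij ~ Gamma(α_ij + y_ij)`)
is updated by random-walk Metropolis on `log g`, with step size
`2.4 / sqrt(max(a, 0.5))` (≈ the conditional posterior sd of `log g`).
Defaults are 100 000 iterations per chain, 40 000 burn-in counted in raw
iterations before thinning, thinning 20, three chains with overdispersed
starts — 9 000 retained draws. Convergence is monitored by the
Gelman–Rubin statistic `R̂ = sqrt(((n−1)/n · W + B/n) / W)` per π
parameter; note that with identical chains `B = 0` gives
`R̂ = sqrt((n−1)/n)`, marginally below 1. In validation runs the two
samplers agree on `D̂` to < 0.01 at 10⁵-draw resolution.

Fungal OTUs occurring in fewer than `min_occurrence` samples (default 5)
are not modelled; below that the deviation statistic is dominated by the
prior. A caveat worth knowing: for fungi so abundant that they occur in
essentially every sample, `y_ij ≈ T_j` and the deviation vector is a
normalized near-zero residual, so `D̄` is wide and weak — presence/absence
simply carries no information about their preferences.

## Pipeline steps

**Rarefaction** subsamples each sample's reads to a fixed depth (default
100) without replacement (multivariate hypergeometric); samples below the
depth are dropped and reported, samples at exactly the depth are kept.
Each sample uses an RNG stream derived from `(seed, row index)`, so any
single sample can be re-drawn in isolation and reproduced.

**Association matrices** count, per clustering level, the samples of each
plant OTU containing each fungal OTU; margins `T_j` and `N_i` are carried
along and validated (`Σ_j T_j` = retained samples, `y_ij ≤ T_j`).

**Accumulation curves** use the exact hypergeometric estimator
`E[S(t)] = Σ_k (1 − C(M−m_k, t)/C(M, t))` with the analytic standard
deviation from pairwise joint-absence probabilities (requiring the
co-occurrence matrix; O(K²) per *t*, so supply a `t_values` grid for
large OTU sets), or a random-permutation estimator. Both report
mean ± 1.96 sd as the 95 % band; the exact band shrinks to zero at
t = M, as it must.

**Frequency tables** report, per taxon, the percentage of dipterocarp /
non-dipterocarp / all samples containing at least one OTU of the taxon,
with a two-sided Fisher exact test on the present/absent × group 2×2
table per taxon (the "at most as probable" two-sided convention) and Holm
correction across all reported taxa — the tested set is every taxon in
the table, including the per-phylum totals and the ECM subtotal.
Percentages are rounded half away from zero to one decimal. The ECM flag
comes from an editable whitelist of ectomycorrhizal basidiomycete
families (shipped seeded with the standard review families:
Thelephoraceae, Russulaceae, Cortinariaceae, Tricholomataceae, …) and is
only applied to OTUs whose phylum is Basidiomycota.

## Community structure

**Raup–Crick** dissimilarity between community units (plant OTUs, pooling
their samples' occurrences) compares the observed number of shared OTUs
against `n_null` (default 999) pairs of null communities that preserve
each unit's richness and draw OTUs without replacement with probability
proportional to occurrence frequency across units (an explicit frequency
vector can be supplied, e.g. a uniform pool for calibration studies).
The score `[#{null > obs} + ½·#{null = obs}]/n_null` lies in [0, 1] and
centres at ½ for null-distributed pairs; sharing more than expected
scores below ½. Weighted sampling without replacement uses the Gumbel
top-k construction.

**Mantel tests** correlate the lower triangles of two distance matrices
by Spearman rank correlation; significance comes from simultaneous
row/column permutations of the second matrix with the add-one estimator
`p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm)` (default 9 999 permutations).
The test is one-sided (positive association) by default — the scientific
hypothesis is that community dissimilarity *increases* with host genetic
distance — with a two-sided alternative available. For small label sets
an exact variant enumerates all n! relabelings. The partial Mantel test
uses the first-order partial Spearman correlation
`r₁₂·₃ = (r₁₂ − r₁₃r₂₃)/√((1−r₁₃²)(1−r₂₃²))`, permuting the first
matrix's labels and recomputing the partial statistic.

**Moran's I** uses inverse-distance weights `w_ij = 1/|x_i − x_j|`
(configurable, no row standardization) on the transect coordinates, the
null expectation `−1/(n−1)`, and a two-sided p from the normal
approximation with the randomization variance.

The dipterocarp/non-dipterocarp split produces two disjoint sample sets
analysed separately, mirroring the contrast between ECM-forming hosts and
the rest.

## The synthetic-data generator

The generator emulates the *processed* data of a transect survey — not
reads or sequences (no PCR/chimera artefacts, no sequence evolution).
Defaults describe the emulated study: 600 samples at 1-m intervals along
a transect; host plants in chain-nested partitions of 150/100/60/30 OTUs
at the four cutoffs (each coarser level merges contiguous blocks of the
previous level, as similarity-threshold clustering does); geometric-series
host frequencies (decay 0.98, shuffled rank order) with family and
dipterocarp flags constant within each coarsest cluster; 1 700 fungal
OTUs with geometric-series base abundance (decay 0.995) giving a few
dominant and many rare OTUs; per-sample read depth lognormal
(`ln 250 ± 1.0`, floor 1), placing roughly a fifth of samples below the
100-read rarefaction threshold so the filtering branch is exercised.
Per sample, reads are allocated multinomially with weight
(base abundance × preference weight for the sample's host × spatial
kernel); the optional spatial kernel multiplies colonization odds by
`1 + A·exp(−d/range)` around a per-OTU random centre (A = 3), producing
the weak aggregation a Moran's-I screen detects. Host genetic distances
assign each pair of finest-level OTUs the tier value of the coarsest
level at which they first share a cluster (0.01/0.02/0.03, 0.05 if
never), which is an ultrametric by construction; optional jitter perturbs
within tiers. All outputs are bit-for-bit reproducible from `rng_seed`.

What passing tests on these data do *not* show: robustness to compositional
sequencing biases, chimeras/contamination, uneven primer affinity across
taxa, or non-ultrametric host phylogenies. The generator's preference
weights act on read allocation, so presence/absence preference strength
also depends on abundance and depth — as in real surveys.

The depth-law parameters are free knobs of the generator, not estimates
fitted to any dataset; they were chosen once to produce a realistic
below-threshold fraction and are not tuned thereafter.

## Replication scenarios and validation scale

`hostpref.scenarios` packages the four validation designs used by the
test-suite and `scripts/acceptance.py`:

* **Null calibration** — 200 preference-free OTUs, 4 balanced hosts
  (T = 50 each), N = 20: the rate of 95 % intervals excluding zero stays
  below 8 % (measured ≈ 0.5 %; the interval is conservative because the
  prior carries weight N).
* **Recovery** — 100 host-exclusive OTUs (all 20 occurrences on one
  host): the correct host is flagged significantly positive in ≥ 95 % of
  replicates (measured 100 %).
* **Scale detection** — 240 samples, 24/12/6/3 host partitions, 40 fungal
  OTUs of which 10 prefer one 98 %-level cluster (strength 8): mean
  `D̂max` is higher at the 98 % level than at 99.8 % (measured ≈ 0.19 vs
  0.07 over 50 replicates).
* **Dipterocarp contrast** — 300 samples, 30/15/8/4 partitions, 300
  fungal OTUs of which 60 (spread over abundance ranks) prefer one
  dipterocarp 98 %-cluster (strength 20): the ECM-subset Mantel r against
  host genetic distance is larger in the dipterocarp than the
  non-dipterocarp dataset in ≥ 90 % of replicates (measured 50/50).

These sizes are the package's chosen validation scale: large enough for
the effects to be unambiguous, small enough that the whole suite runs in
well under a minute per scenario on one CPU.

## Numerical choices and edge cases

* Percent rounding is half-away-from-zero (report-table convention).
* Preference is undefined for a single host taxon (J = 1 raises — the
  deviation vector is identically zero).
* Rarefaction depth ≤ 0, raw/rarefied state misuse, duplicate IDs,
  asymmetric distance matrices and nesting violations raise typed errors
  naming the offending record.
* Constant distance-matrix triangles make rank correlation undefined and
  raise, rather than returning NaN — degenerate community matrices (every
  unit containing the whole OTU pool) surface here.
* Mantel p-values can never be 0 (add-one estimator); exact enumeration
  includes the identity relabeling.
* Burn-in counts raw iterations before thinning; retained draws per chain
  are `(iterations − burn_in) // thin`.
* Seeds: every stochastic entry point takes an explicit seed; internal
  streams are spawned as `default_rng([seed, salt])` so subsystems are
  decorrelated but reproducible.

## Known limitations

* The Gibbs mode is a validation tool; it is two orders of magnitude
  slower than the conjugate sampler and adds nothing statistically (the
  model is fully conjugate).
* The exact accumulation-curve variance needs the OTU co-occurrence
  matrix (O(K²) memory); for very large OTU sets use the random method or
  a sparse `t_values` grid.
* The Raup–Crick implementation stores one boolean null block per unit
  (`n_null × K`); for thousands of units or OTUs this is memory-heavy.
* Geographic separation between plant-OTU units is summarized by mean
  transect position per unit — adequate for a linear transect, crude for
  2-D layouts.
* `D̂max` comparisons assume the same OTU set at every level; OTUs lost to
  the occurrence filter at some level must be dropped from the comparison
  by the caller.
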