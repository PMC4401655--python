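# hostpref

Bayesian host-preference statistics and community-structure analyses for
root-associated fungal OTU tables.

Surveys of root-associated fungi (ectomycorrhizal basidiomycetes, root
endophytes and other guilds) typically produce a sample × fungal-OTU read
count table, a host-plant assignment for each root sample at several
sequence-similarity cutoffs, and a host genetic distance matrix. The
scientific questions are: *does a fungus associate with particular hosts
more often than sampling effort alone predicts, at which host taxonomic
grain is that preference expressed, and does fungal community composition
track host genetic distance?* `hostpref` implements the full analysis
chain for these questions, plus a synthetic-data generator with known
ground truth so every estimator can be validated against the truth that
produced the data.

## The model

For fungal OTU *i*, let `y_ij` be the number of root samples of plant OTU
*j* in which it occurs, `N_i = Σ_j y_ij`, and `T_j` the number of samples
of plant OTU *j*. The counts are modelled as

    y_i ~ Multinomial(N_i, π_i),      π_i ~ Dirichlet(α_i),
    α_ij = T_j · N_i / Σ_j T_j ,

so the prior mean of `π_ij` is the sampling share `T_j / Σ T_j` — the
association frequency expected if fungi colonized hosts at random in
proportion to sampling effort. Host preference is measured per posterior
draw by the normalized deviation

    D̄_ij = (π_ij − E[π_ij]) / ‖π_i − E[π_i]‖₂ ∈ [−1, 1],

whose posterior mean is `D̂_ij`; positive values mean the fungus occurs on
host *j* more often than random host selection predicts. `D̂max_i =
max_j D̂_ij` summarizes how sharply OTU *i* prefers its best host, and
comparing `D̂max` across host clustering cutoffs (99.8 / 99 / 98 / 97 %
similarity) locates the taxonomic grain of the preference.

The model is conjugate, so the default fit samples the exact posterior
`Dirichlet(α_i + y_i)` directly; an independent Metropolis-within-Gibbs
MCMC mode with burn-in, thinning, multiple chains and Gelman–Rubin
diagnostics is provided as a cross-check.

Around the model, the package supplies the standard pipeline: rarefaction
to a fixed read depth, presence/absence conversion, plant × fungal
association matrices, sample-based OTU accumulation curves, taxonomy and
dipterocarp/non-dipterocarp frequency tables (Fisher exact + Holm),
Raup–Crick null-model β-diversity, Mantel and partial Mantel permutation
tests, and Moran's *I* spatial autocorrelation.

## Worked example

```python
import numpy as np
import hostpref as hp

cfg = hp.SimulationConfig(
    n_samples=300, n_plant_otus=(24, 12, 6, 3), n_fungal_otus=120,
    depth_distribution=(np.log(300.0), 0.7, 1), rng_seed=42,
)
hosts, coords = hp.generate_hosts(cfg)
# three mid-abundance fungi prefer one whole 98%-level host cluster
cfg.preference_matrix = hp.preference_for_level(
    cfg, hosts, otu_rows=[40, 41, 42], level="98", strength=25.0
)
counts, truth = hp.generate_counts(cfg, hosts, coords)
rarefied, dropped = hp.rarefy(counts, depth=100, seed=42)
occ = hp.to_presence_absence(rarefied)
print(f"{len(dropped)} of {cfg.n_samples} samples below 100 reads were dropped")

model = hp.HostPreferenceModel.from_occurrence(occ, hosts, level="98", min_occurrence=5)
res = model.fit(mode="conjugate", draws=5000, seed=42)
print(res.summary().query("otu == 'F0041'").round(3).to_string(index=False))
```

prints

```
21 of 300 samples below 100 reads were dropped
  otu    host  d_hat  ci95_lo  ci95_hi  ci99_lo  ci99_hi flag
F0041 P98_001 -0.010   -0.556    0.598   -0.699    0.743
F0041 P98_002 -0.035   -0.566    0.567   -0.703    0.703
F0041 P98_003  0.656    0.122    0.890   -0.197    0.904    +
F0041 P98_004 -0.191   -0.673    0.418   -0.785    0.616
F0041 P98_005 -0.181   -0.667    0.428   -0.782    0.610
F0041 P98_006 -0.240   -0.696    0.343   -0.795    0.527
```

`F0041` was simulated to prefer the hosts of cluster `P98_003`, and the
fit recovers exactly that: `D̂ = 0.656` there, with a 95 % credible
interval excluding zero (the `+` flag; `*` marks 99 %). Its `D̂max`
(`res.dmax()`) is 0.656, versus a mean of about 0.25 for the
preference-free background OTUs.

Community structure is tested the same way from the occurrence matrix:

```python
units = hp.group_by_plant_otu(occ, hosts, level="99.8")
cd = hp.raup_crick(units, n_null=999, seed=1)          # β-diversity
gd = hp.generate_host_distances(hosts, cfg).reindex(cd.labels)
print(hp.mantel(cd, gd, n_perm=9999, seed=1))          # r and permutation p
```

A thin CLI mirrors the library (`hostpref simulate | rarefy | assoc |
preference | summarize | community`, see `hostpref --help`).

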