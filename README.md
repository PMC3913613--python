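# oralclust

Analysis toolkit for 16S rRNA amplicon surveys of oral biofilm communities
sampled repeatedly from the same hosts — the study design where each
subject's biofilm is profiled at several maturation time points and the
questions are (i) does alpha diversity change with biofilm age, (ii) how
much community turnover is attributable to time versus host, and (iii) do
species organise into robust, mutually exclusive clusters with matching
host community types?

The package takes a mothur `shared`-format sample-by-OTU count table, a
mothur `cons.taxonomy` file and a sample metadata TSV (`sample`, `subject`,
`day`) and provides:

* **Alpha diversity over time.** Effective richness ^1D = exp(H), the Hill
  number of order 1, per sample; a linear mixed model of log ^1D on day
  (REML) with subject random intercepts or intercepts + slopes, compared by
  AIC, with a Wald test of the day trend.
* **Beta diversity / turnover.** Hellinger transform
  y'_ij = sqrt(y_ij / y_i+), then partial redundancy analysis
  `Y ~ Day + Condition(Subject)`: the total variance splits into a
  conditioned (between-host) fraction, a day-constrained fraction with
  Ezekiel-adjusted semipartial R², and a residual; significance by
  pseudo-F with permutations of day labels restricted to within-subject
  strata, plus a multivariate dispersion homogeneity test.
* **Consensus clustering.** Monti-style resampling consensus: H subsamples
  of the items at proportion p, a base clusterer per subsample (UPGMA
  average linkage on 1 − Spearman ρ for species; PAM, i.e. k-medoids with
  BUILD + SWAP, on PCA scores for subjects), consensus matrices
  M_K(i,j) = #co-clustered / #co-sampled, cluster number from the
  delta-area of the consensus CDF, and a robustness filter keeping items
  with item consensus ≥ 0.6 for their own cluster and ≤ 0.4 for every
  other.
* **Association statistics.** Escoufier RV coefficient between
  rank-transformed species-cluster blocks with a row-permutation test, and
  ANOSIM R = (r̄_between − r̄_within) / (n(n−1)/4) on Euclidean distances of
  Hellinger-transformed subject profiles.
* **A synthetic-community generator** (Dirichlet-multinomial with planted
  species clusters and subject community types) so that every stage is
  testable against known ground truth.

## Worked example

Simulate a 31-subject × 5-day community (three planted species clusters
mixed in host-type-specific proportions, 1,042 reads per sample) and run
the full pipeline at desk-scale resampling settings:

```python
from oralclust import PipelineConfig, SimulationDesign, run_pipeline

config = PipelineConfig(
    simulation=SimulationDesign(seed=11),
    species_h=200, subject_h=500,
    rda_permutations=199, anosim_permutations=999, rv_permutations=199,
    seed=11)
report = run_pipeline(config)
d = report.to_dict()
```

Printing the headline numbers of this run gives:

```
day slope (log 1D): -0.001  p = 0.671
RDA subject fraction: 0.582  day fraction: 0.0034  p = 0.47
species K*: 3  robust members: 26
subject K*: 4  ANOSIM R = 0.819  p = 0.001
recovered vs planted: species ARI = 1.0  subject ARI = 0.615
```

Read: alpha diversity shows no day trend (p = 0.67), almost 60% of
community variance is between hosts while the day term explains ~0.3%
(p = 0.47) — the simulated design has no temporal signal, and the pipeline
says so. The species consensus run selects K = 3 and recovers the three
planted clusters perfectly (ARI = 1.0) with 26/27 species passing the
item-consensus filter. Subject clustering at this seed over-splits one
community type (K* = 4, ARI = 0.6): host types overlap by design, so
subject recovery is noisier than species recovery. `report.composition`
holds the species-cluster × subject-cluster mixing fractions (rows sum
to 1).

The same analysis runs from the shell against real mothur outputs:

```sh
oralclust simulate --seed 11 --out sim/           # or your own files
oralclust run --config config.yaml --out results/
oralclust alpha --shared sim/counts.shared --metadata sim/metadata.tsv --out alpha.tsv
```

`oralclust run` writes `report.json` plus TSV sidecars (diversity table,
consensus matrices, composition). Subcommands `beta`, `cluster-species`,
`cluster-subjects`, `anosim` and `rv` expose the individual stages.

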