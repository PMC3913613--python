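# Methods

This note records the statistical models, the numerical conventions, and
the design choices made where more than one defensible option existed.

## Input handling and normalisation

The pipeline starts from a sample-by-OTU count table (mothur `shared`
dialect), an OTU taxonomy (`cons.taxonomy` dialect, confidence suffixes
stripped into a separate field) and per-sample `(subject, day)` metadata.
Counts are rarefied to a common depth (default 1,042 reads) by a
multivariate hypergeometric draw — subsampling reads without replacement,
the semantics of mothur's `sub.sample`. Samples below the target depth are
**kept unrarefied and flagged** rather than dropped (a `strict_depth`
option drops them); with per-sample relative abundances downstream, a
slightly shallower sample is still informative and discarding whole
subject-days costs more than it saves.

Collapsing to a taxonomic rank sums counts over OTUs sharing the
rank-level name and divides by the per-sample total **before** any feature
is dropped, so filtered tables keep their original denominators and remain
comparable across samples. OTUs whose lineage ends above the requested
rank are labelled `<deepest name> unclassified` (the mothur placeholder
convention). The species-name filter removes features whose name contains
"uncultured" or "unclassified" (case-insensitive substring — the filter is
given as terms, not a grammar), which covers both annotated junk names and
the placeholder labels. Surviving abundances are *not* renormalised by
default (`renormalize_after_filter` exposes the alternative); whether the
original analysis renormalised is not documented, and keeping the original
denominators preserves each species' actual relative abundance.

## Alpha diversity and the time model

Per sample we report observed richness and effective richness
^1D = exp(−Σ p_i ln p_i), the Hill number of order 1 ("effective number of
equally abundant OTUs"). ^1D is invariant to count rescaling, equals S for
a uniform community over S features and 1 for a point mass; these
identities are tested.

The day trend is modelled as a **Gaussian linear mixed model on log ^1D**
fitted by REML (statsmodels `MixedLM`):

    log(^1D)_sj = β0 + β1·day_j + u_s (+ v_s·day_j) + ε_sj

The log-normal response is a close working approximation to a gamma GLMM
with log link for this positive, right-skewed quantity, and admits an
exact REML criterion; the approximation is recorded on the fit object.
Day enters as a numeric covariate (a linear trend, matching the
random-slope formulation). Random-intercept and random-intercept+slope
structures are compared by AIC computed from the REML criterion
(−2·restricted log-likelihood + 2k, k counting fixed effects, variance
components and the residual variance) with identical fixed effects in
both candidates — AICs from REML fits are only comparable when the fixed
part is held constant. The day effect is reported with its Wald p-value;
simulation tests verify that the null p-value is approximately
Uniform(0,1) and that parameters are recovered without bias at the
31-subject × 5-day design size.

## Beta diversity: partial RDA

Abundances are Hellinger-transformed (square root of row-relative
abundances), after which Euclidean distance equals the Hellinger distance
between profiles — verified directly in the tests. Partial RDA partitions
the total variance (sum of column variances, divisor n−1) of the
transformed table:

1. conditioned fraction — projection of the centred table onto the span of
   the centred subject indicators (rank S−1);
2. constrained fraction — additional variance explained by day after
   residualising both the table and the day covariate on the subject span;
3. residual — the remainder; the three fractions sum to 1 exactly.

Day is numeric (1 df) by default, with a factor option (4 df for five
days). The adjusted R² of the day term applies the Ezekiel correction to
the semipartial R²: 1 − (1 − R²)(n − g − 1)/(n − g − 1 − m) with
g = S − 1 subject degrees of freedom and m day degrees of freedom.
Significance uses the pseudo-F

    F = (constrained/m) / (residual/(n − 1 − g − m))

with day labels permuted **only within each subject** (the exchangeable
units under the null of no time effect given host identity);
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm), so p is never 0. Homogeneity of
multivariate dispersion across days is checked by the distance-to-group-
centroid ANOVA F in the principal-coordinate embedding (tiny negative
eigenvalues clamped at zero at 1e−9 relative tolerance), permuted within
the same strata.

## Consensus clustering

For each of H subsamples, ⌈p·n⌉ items are drawn without replacement and
clustered into K groups for every K in the candidate range (default 2–6);
the same subsample stream is reused across K so a run is reproducible from
one seed. The species distance is 1 − Spearman ρ (midranks) between
species profiles across all samples; restricting this matrix to a
subsample equals recomputing it on the subsample, since dropping columns
does not change the remaining ranks — asserted in the tests. Base
clusterers:

* **UPGMA** (unweighted average linkage, scipy) for species; correctness
  is checked against a naive O(n³) agglomeration oracle.
* **PAM** (k-medoids) for subjects, on the scaling-1 PCA scores of the
  Hellinger-transformed subject-mean table: greedy BUILD initialisation,
  then steepest-descent single-medoid SWAP until no swap lowers the total
  distance-to-medoid cost, ties broken by lowest index (deterministic).
  PAM terminates at a 1-swap local optimum; on a small fraction (~5%) of
  tiny random instances this differs from exhaustive medoid search, a
  property shared by the reference R implementation of the algorithm. The
  tests assert the actual contract (cost never below the global optimum,
  1-swap local optimality).

The consensus matrix entry M_K(i,j) is the fraction of co-sampled runs in
which i and j co-clustered; pairs never co-sampled (negligible at the
default H and p, but the contract must be total) get 0 and are counted in
the run log, with a `strict` mode that errors instead. Per-K assignments
come from average-linkage clustering of 1 − M_K, the convention of the
consensus-clustering literature.

**Cluster number.** A(K) is the exact area under the empirical CDF of the
upper-triangular consensus entries, computed as the step integral over
[0, 1] (algebraically 1 − mean(M) — deterministic and oracle-checkable
against numeric integration, unlike a binned histogram). Δ(2) = A(2) and
Δ(K) = (A(K) − A(K−1))/A(K−1); K* is the largest K with Δ(K) > ε
(default ε = 0.1). ε is configurable and the full Δ table is always
emitted so a user can override K*: the delta-area elbow is a heuristic,
and genuinely weak species (see the generator section) can hold Δ above
any fixed cutoff past the planted K.

**Robustness filter.** Item consensus m_i(k) is the mean consensus of i
with the members of cluster k (excluding i from its own cluster; undefined
for singletons). An item is robust iff m_i(assigned) ≥ 0.6 and
m_i(k) ≤ 0.4 for every other k, both thresholds inclusive.

## Association statistics

The RV coefficient between two species-cluster blocks observed on the same
subjects is trace(XᵀY·YᵀX)/√(trace((XᵀX)²)·trace((YᵀY)²)) on column-centred,
column-wise midrank-transformed blocks ("RV" is read as the Escoufier
matrix correlation — the standard statistic matching the pairwise-block
usage). By default the blocks are subject-mean abundances. The permutation
test shuffles the rows of one block (default 999 permutations). RV is
symmetric, invariant to orthogonal rotations of either block, 1 for
identical blocks, and reduces to the squared rank correlation for single
columns — all tested.

ANOSIM ranks all n(n−1)/2 distances once with midranks;
R = (r̄_between − r̄_within)/(n(n−1)/4) ∈ [−1, 1], invariant under
monotone transforms of the distances. Labels are permuted freely (cluster
labels carry no strata). The implementation is cross-checked against
scikit-bio's ANOSIM. Note that testing cluster labels *derived from the
same distances* inflates R relative to pre-specified groups; the reported
R should be read as a separation descriptor, not an independent test.

## Synthetic communities

The generator emulates the target study shape: 31 subjects × days
(1, 3, 5, 9, 14), three species clusters of 12/10/8 species, three equally
likely subject community types with cluster-mixing rows
(0.60, 0.40, 0) / (0.32, 0.66, 0.02) / (0.54, 0.20, 0.27) (the third row,
taken from printed percentages, sums to 101% and is renormalised), 1,042
reads per sample. Hierarchy:

1. subject type t ~ Categorical(1/3, 1/3, 1/3);
2. each species cluster carries a **consortium profile**
   q_c ~ Dirichlet(1, …, 1) drawn once per dataset: a species cluster is a
   set of particular species in characteristic relative proportions shared
   across hosts — this is what makes cluster membership discoverable from
   between-host correlation. (Redrawing q per subject destroys the
   within-cluster correlation signal entirely and makes the planted
   structure unrecoverable by any correlation-based method.);
3. subject cluster weights w ~ Dirichlet(κ·mixing[t]) with κ = 30
   (structural zeros stay zero), giving the subject profile π = ⋃ w_c·q_c;
4. per sample: p ~ Dirichlet(τ·π) with τ = 50 (between-day wobble within a
   host; larger τ = more stable hosts, verified monotone in the tests),
   optionally tilted by exp(day_effect·day) on cluster-1 species, then
   counts ~ Multinomial(1042, p).

κ controls type overlap: at κ = 30 the types overlap enough that even
clustering the *true* weights w recovers them only at ARI ≈ 0.75–0.9, so
subject-cluster recovery is intrinsically noisier than species recovery.
A default 10% of species receive "uncultured" names to exercise the name
filter. Ground truth (species cluster, subject type, realised weights) is
returned for recovery scoring with the adjusted Rand index (contingency
formula, cross-checked against scikit-learn).

What the generator does **not** emulate: real taxonomic correlation
structure within clusters, sequencing error, compositional zeros beyond
multinomial sampling, subject covariates, or OTU-level within-species
variation (one OTU per species). Passing recovery tests therefore show the
machinery is correct under the planted model, not that three clusters
exist in any particular real dataset. A known consequence of the
Dirichlet(1) consortium profiles: most runs contain one to three species
with expected counts below ~20 of 1,042 reads; such species sit below the
detection limit of rank correlation, attach to clusters stably but
arbitrarily, and are the main source of over-splitting in delta-area K
selection.

## Pipeline orchestration

`run_pipeline` derives one seed per stochastic stage (rarefaction, RDA
permutations, dispersion test, species consensus, RV, subject consensus,
ANOSIM) from the master seed via `SeedSequence.spawn`, making the report a
pure function of (inputs, config, seed) and each stage independently
re-runnable; a rerun is byte-identical. Subject exclusion (e.g. an outlier
host) happens before rarefaction and is equivalent to pre-filtered inputs.
The subject-cluster composition table sums robust-species abundances per
species cluster within each subject, normalises over species clusters
(default basis: robust members only, with an all-species option) and
averages within subject clusters; rows sum to 1.

Problem sizes in the shipped experiments: the test suite runs consensus at
H = 200 subsamples and permutation tests at 49–199 permutations across
50-seed (cluster recovery), 200-replicate (null calibration) and
100-replicate (mixed-model recovery) designs; `scripts/acceptance.py` runs
the full design (H = 1,000 / 10,000; 1,000 / 100,000 / 999 permutations).
These sizes give stable Monte-Carlo estimates while keeping a full run in
well under a minute.
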