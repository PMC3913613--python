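"""End-to-end orchestration: OTU table to clusters, statistics and report.

Stages, in run order:

1. load (or simulate) counts + taxonomy + metadata; exclude subjects;
   rarefy to a common depth;
2. alpha diversity (^1D per sample) and the REML mixed model of log ^1D on
   day, comparing random-intercept vs random-intercept+slope by AIC;
3. beta diversity: Hellinger transform of the OTU table, partial RDA
   (day | subject) with a stratified permutation test and a dispersion
   homogeneity check across days;
4. species analysis: collapse to species relative abundances, drop
   unresolved/"uncultured"/"unclassified" names, consensus clustering of
   species on 1 - Spearman distances (average linkage), item-consensus
   robustness filter, pairwise RV between robust clusters on rank-
   transformed subject-mean abundances;
5. subject analysis: subject-mean species table, Hellinger + PCA,
   consensus PAM on the subjects' PCA scores, ANOSIM on Euclidean
   distances of the Hellinger-transformed subject-by-species table;
6. composition summary: mean share of each robust species cluster within
   each subject cluster.

Every random stage draws its own seed from the master seed via
``numpy.random.SeedSequence.spawn``, so the report is a pure function of
(inputs, config, master seed) and stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import pdist, squareform

from . import association, consensus, diversity, ordination, tables_io
from .synthetic import SimulationDesign, adjusted_rand_index, simulate_dataset

log = logging.getLogger("oralclust")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full analysis run."""

    shared: str | None = None
    constaxonomy: str | None = None
    metadata: str | None = None
    simulation: SimulationDesign | None = None
    rarefaction_depth: int = 1042
    strict_depth: bool = False
    exclude_subjects: tuple[str, ...] = ()
    renormalize_after_filter: bool = False
    day_as_factor: bool = False
    species_h: int = 1000
    species_p: float = 0.8
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    epsilon: float = 0.1
    item_consensus_hi: float = 0.6
    item_consensus_lo: float = 0.4
    subject_h: int = 10000
    subject_p: float = 0.8
    subject_method: str = "pam"
    subject_k: int | None = None  # None: delta-area selection
    n_axes: int | None = None  # PCA axes fed to subject clustering (None = all)
    rda_permutations: int = 1000
    anosim_permutations: int = 100000
    rv_permutations: int = 999
    composition_basis: str = "robust"  # or "all"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("species_h", "subject_h", "rda_permutations",
                     "anosim_permutations", "rv_permutations",
                     "rarefaction_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if sim is not None:
            cfg.simulation = SimulationDesign(
                **{k: tuple(tuple(r) if isinstance(r, list) else r
                            for r in v) if isinstance(v, list) else v
                   for k, v in sim.items()})
        return cfg


def _spawn_seeds(master: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(master).spawn(n)]


def composition_by_cluster(subject_means: tables_io.AbundanceTable,
                           species_clusters: consensus.RobustClusters,
                           subject_labels: pd.Series) -> pd.DataFrame:
    """Mean species-cluster composition inside each subject cluster.

    For every subject, robust-species abundances are summed per species
    cluster and normalised over the species clusters; the fractions are then
    averaged over the subjects of each subject cluster. Rows: subject
    clusters; columns: species clusters; rows sum to 1.
    """
    if not species_clusters.clusters:
        raise ValueError("no species clusters")
    ab = subject_means.abundances
    per_subject = pd.DataFrame({
        k: ab[[s for s in members if s in ab.columns]].sum(axis=1)
        for k, members in species_clusters.clusters.items()})
    totals = per_subject.sum(axis=1)
    zero = totals == 0
    if zero.any():
        import warnings
        warnings.warn(f"subjects with zero robust-species mass excluded: "
                      f"{list(per_subject.index[zero])}", stacklevel=2)
        per_subject = per_subject[~zero]
        totals = totals[~zero]
    fracs = per_subject.div(totals, axis=0)
    out = fracs.groupby(subject_labels.loc[fracs.index].to_numpy()).mean()
    out.index.name = "subject_cluster"
    out.columns.name = "species_cluster"
    return out


@dataclass
class PipelineReport:
    diversity_table: pd.DataFrame
    mixed_models: dict
    rda: ordination.RdaPartition
    dispersion: dict
    species_run: consensus.ConsensusRun
    robust: consensus.RobustClusters
    rv_pairs: dict[tuple[int, int], association.RvResult]
    subject_run: consensus.ConsensusRun
    anosim: association.AnosimResult
    composition: pd.DataFrame
    recovery: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    runtime_s: float = 0.0  # not serialized: the report JSON is a pure
    # function of (inputs, config, seed)

    def to_dict(self) -> dict:
        """JSON-serialisable summary of every stage."""
        best = self.mixed_models["best"]
        return {
            "provenance": self.provenance,
            "alpha": {
                "n_samples": int(len(self.diversity_table)),
                "mean_effective_richness":
                    float(self.diversity_table["effective_richness"].mean()),
                "best_model": "random_intercept_slope" if best.random_slope
                              else "random_intercept",
                "day_slope": best.day_slope,
                "day_pvalue": best.day_pvalue,
                "aic": {k: v.aic for k, v in self.mixed_models.items()
                        if k != "best"},
            },
            "beta": {
                "total_inertia": self.rda.total_inertia,
                "conditioned_fraction": self.rda.conditioned_fraction,
                "constrained_fraction": self.rda.constrained_fraction,
                "residual_fraction": self.rda.residual_fraction,
                "adjusted_r2": self.rda.adjusted_r2,
                "pseudo_f": self.rda.pseudo_f,
                "permutation_p": self.rda.permutation_p,
                "dispersion": self.dispersion,
            },
            "species_clusters": {
                "selected_k": self.species_run.selected_k,
                "areas": {str(k): v for k, v in self.species_run.areas.items()},
                "deltas": {str(k): v for k, v in self.species_run.deltas.items()},
                "robust": {str(k): sorted(v) for k, v in
                           self.robust.clusters.items()},
                "excluded": self.robust.excluded,
                "rv": {f"{a}-{b}": dataclasses.asdict(r)
                       for (a, b), r in self.rv_pairs.items()},
            },
            "subject_clusters": {
                "selected_k": self.subject_run.selected_k,
                "assignment": {str(i): int(v) for i, v in
                               self.subject_run.selected_assignment.items()},
                "anosim_r": self.anosim.r,
                "anosim_p": self.anosim.p,
            },
            "composition": {str(i): {str(c): float(v) for c, v in row.items()}
                            for i, row in self.composition.iterrows()},
            "recovery": self.recovery,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        table, tax, truth = simulate_dataset(config.simulation)
        return table, tax, truth
    if not (config.shared and config.constaxonomy and config.metadata):
        raise ValueError("config needs either input paths or a simulation design")
    table = tables_io.read_shared(config.shared)
    md = tables_io.read_metadata(config.metadata)
    table = tables_io.attach_metadata(table, md)
    tax = tables_io.read_constaxonomy(config.constaxonomy)
    return table, tax, None


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis; see the module docstring for the stages."""
    t0 = time.time()
    seeds = _spawn_seeds(config.seed, 7)
    table, tax, truth = _load_inputs(config)
    if config.exclude_subjects:
        table = table.drop_subjects(list(config.exclude_subjects))
    log.info("load: %d samples x %d features", *table.counts.shape)

    table = tables_io.rarefy(table, config.rarefaction_depth, seeds[0],
                             strict_depth=config.strict_depth)

    # (a) alpha diversity + mixed model
    records = diversity.diversity_records(table)
    models = diversity.compare_random_structures(records)

    # (b) partial RDA on Hellinger-transformed OTU counts
    hel = ordination.hellinger(table.counts)
    day = table.metadata["day"].to_numpy()
    subject = table.metadata["subject"].to_numpy()
    rda = ordination.stratified_permutation_test(
        hel, day, subject, n_perm=config.rda_permutations, seed=seeds[1],
        day_as_factor=config.day_as_factor)
    dist_all = pd.DataFrame(squareform(pdist(hel.to_numpy())),
                            index=hel.index, columns=hel.index)
    disp = ordination.dispersion_test(dist_all, day,
                                      n_perm=min(config.rda_permutations, 999),
                                      seed=seeds[2], strata=subject)
    log.info("beta: conditioned=%.3f constrained=%.4f p=%s",
             rda.conditioned_fraction, rda.constrained_fraction,
             rda.permutation_p)

    # (c) species consensus clustering
    species = tables_io.collapse_by_rank(table, tax, "species")
    species = tables_io.filter_species_names(
        species, renormalize_after_filter=config.renormalize_after_filter)
    sp_dist = association.spearman_distance(species.abundances)
    sp_run = consensus.consensus_cluster(
        sp_dist, method="average_linkage", k_range=config.k_range,
        h=config.species_h, p=config.species_p, seed=seeds[3],
        epsilon=config.epsilon)
    robust = consensus.robust_members(
        sp_run.item_consensus_scores[sp_run.selected_k],
        sp_run.assignments[sp_run.selected_k],
        hi=config.item_consensus_hi, lo=config.item_consensus_lo)
    log.info("species: K*=%d, %d robust members, %d excluded",
             sp_run.selected_k, sum(map(len, robust.clusters.values())),
             len(robust.excluded))

    # pairwise RV between robust clusters on subject-mean abundances
    subject_means = tables_io.mean_by_subject(species)
    rv_pairs: dict[tuple[int, int], association.RvResult] = {}
    ks = sorted(robust.clusters)
    for i, a in enumerate(ks):
        for b in ks[i + 1:]:
            rv_pairs[(a, b)] = association.rv_permutation_test(
                subject_means.abundances[robust.clusters[a]],
                subject_means.abundances[robust.clusters[b]],
                n_perm=config.rv_permutations, seed=seeds[4])

    # (d) subject consensus clustering on PCA scores of the Hellinger table
    hel_subj = ordination.hellinger(subject_means.abundances)
    ordn = ordination.pca(hel_subj, n_axes=config.n_axes)
    subj_scores = ordn.sample_scores
    subj_dist = pd.DataFrame(squareform(pdist(subj_scores.to_numpy())),
                             index=subj_scores.index, columns=subj_scores.index)
    k_range = config.k_range
    if config.subject_k is not None and config.subject_k not in k_range:
        k_range = tuple(sorted({*k_range, config.subject_k}))
    subj_run = consensus.consensus_cluster(
        subj_dist, method=config.subject_method, k_range=k_range,
        h=config.subject_h, p=config.subject_p, seed=seeds[5],
        epsilon=config.epsilon)
    subj_labels = (subj_run.assignments[config.subject_k]
                   if config.subject_k is not None
                   else subj_run.selected_assignment)
    hel_dist = pd.DataFrame(squareform(pdist(hel_subj.to_numpy())),
                            index=hel_subj.index, columns=hel_subj.index)
    # ANOSIM needs >=2 members per group: subjects in singleton clusters
    # carry no within-group information and are set aside
    sizes = subj_labels.value_counts()
    multi = subj_labels[subj_labels.isin(sizes[sizes >= 2].index)]
    if len(multi) < len(subj_labels):
        import warnings as _warnings
        _warnings.warn(
            f"excluding {len(subj_labels) - len(multi)} singleton-cluster "
            "subject(s) from ANOSIM", stacklevel=2)
    if multi.nunique() >= 2:
        keep = list(multi.index)
        ano = association.anosim(hel_dist.loc[keep, keep], multi,
                                 n_perm=config.anosim_permutations,
                                 seed=seeds[6])
    else:
        ano = association.AnosimResult(float("nan"), None, 0,
                                       sizes.to_dict())
    log.info("subjects: K*=%d, ANOSIM R=%.3f p=%s",
             subj_run.selected_k, ano.r, ano.p)

    basis = robust if config.composition_basis == "robust" else \
        consensus.RobustClusters({k: [s for s in species.feature_ids
                                      if sp_run.selected_assignment[s] == k]
                                  for k in sorted(set(
                                      sp_run.selected_assignment))})
    comp = composition_by_cluster(subject_means, basis, subj_labels)

    recovery = {}
    if truth is not None:
        sp_truth = {s: truth.species_cluster[s] for s in robust.labels}
        recovery["species_ari"] = adjusted_rand_index(sp_truth, robust.labels)
        subj_truth = {s: truth.subject_type[s] for s in subj_labels.index}
        recovery["subject_ari"] = adjusted_rand_index(
            subj_truth, subj_labels.to_dict())
        recovery["selected_k_species"] = sp_run.selected_k
        recovery["selected_k_subjects"] = subj_run.selected_k

    report = PipelineReport(
        diversity_table=records, mixed_models=models, rda=rda,
        dispersion=disp, species_run=sp_run, robust=robust,
        rv_pairs=rv_pairs, subject_run=subj_run, anosim=ano,
        composition=comp, recovery=recovery,
        provenance={
            "seed": config.seed, "stage_seeds": seeds,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(config).items()
                       if k != "simulation"},
            "simulated": config.simulation is not None,
        },
        runtime_s=round(time.time() - t0, 2))
    return report
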