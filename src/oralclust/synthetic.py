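"""Synthetic oral-biofilm communities with planted cluster structure.

Emulates the study design the analysis pipeline targets: ~31 subjects
sampled over 5 biofilm-maturation days, species organised into a few
mutually exclusive clusters, and subjects falling into community types that
mix those clusters in different proportions. Counts follow a hierarchical
Dirichlet-multinomial:

1. subject type ``t ~ Categorical(subject_type_probs)``;
2. each species cluster carries a characteristic composition
   ``q_c ~ Dirichlet(within_cluster_dirichlet)`` drawn once per dataset (a
   cluster is a consortium of particular species in particular relative
   proportions, shared across hosts); each subject mixes the clusters with
   weights ``w ~ Dirichlet(kappa * mixing[t])`` (zero mixing entries stay
   exactly zero), giving a subject profile ``pi = concat(w_c * q_c)``;
3. per sample (subject, day): proportions ``p ~ Dirichlet(tau * pi)``,
   optionally tilted by ``exp(day_effect * day)`` on cluster-1 species,
   then ``counts ~ Multinomial(depth, p)``.

The default mixing matrix encodes the subject-cluster compositions reported
for the three oral community types (Prevotella- / Streptococcus- /
Proteobacteria-dominated mixes). A taxonomy with synthetic binomials is
emitted so the real collapse/filter path is exercised; a configurable
fraction of species receive "uncultured" names to feed the name filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import RANKS, CountTable, TaxonomyMap

DEFAULT_MIXING = (
    (0.60, 0.40, 0.00),
    (0.32, 0.66, 0.02),
    (0.54, 0.20, 0.27),
)


@dataclass
class SimulationDesign:
    """Parameters of the community simulator (defaults match the target study)."""

    n_subjects: int = 31
    days: tuple[int, ...] = (1, 3, 5, 9, 14)
    n_clusters: int = 3
    species_per_cluster: tuple[int, ...] = (12, 10, 8)
    subject_type_probs: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    mixing_matrix: tuple[tuple[float, ...], ...] = DEFAULT_MIXING
    within_cluster_dirichlet: float = 1.0
    between_subject_kappa: float = 30.0
    overdispersion: float = 50.0  # tau: per-sample Dirichlet concentration
    depth: int = 1042
    day_effect: float = 0.0  # log-fold change per day on cluster-1 species
    uncultured_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.mixing_matrix, dtype=float)
        if mix.shape != (len(self.subject_type_probs), self.n_clusters):
            raise ValueError("mixing_matrix shape must be (n_types, n_clusters)")
        # tolerate percentage-rounding (e.g. 54/20/27 sums to 101%) and
        # renormalize rows exactly
        if not np.allclose(mix.sum(axis=1), 1.0, atol=0.02):
            raise ValueError("rows of mixing_matrix must sum to 1")
        self.mixing_matrix = tuple(
            tuple(row / row.sum()) for row in mix)
        if len(self.species_per_cluster) != self.n_clusters:
            raise ValueError("species_per_cluster must have n_clusters entries")
        if min(self.within_cluster_dirichlet, self.between_subject_kappa,
               self.overdispersion) <= 0:
            raise ValueError("concentration parameters must be > 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery scoring."""

    species_cluster: dict[str, int]  # species binomial -> cluster id (0-based)
    subject_type: dict[str, int]  # subject id -> type (0-based)
    realized_weights: pd.DataFrame = field(repr=False)  # subjects x clusters


def _dirichlet_with_zeros(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw treating zero concentrations as structural zeros."""
    out = np.zeros_like(alpha, dtype=float)
    pos = alpha > 0
    g = rng.gamma(alpha[pos], 1.0)
    if not g.sum() > 0:  # all-zero gamma draw is measure-zero but guard anyway
        g = np.full(pos.sum(), 1.0)
    out[pos] = g / g.sum()
    return out


def _species_names(design: SimulationDesign, rng: np.random.Generator
                   ) -> tuple[list[str], list[int]]:
    names, clusters = [], []
    j = 0
    for c, n_sp in enumerate(design.species_per_cluster):
        for _ in range(n_sp):
            names.append(f"Genus{j + 1:02d} species{j + 1:02d}")
            clusters.append(c)
            j += 1
    n_unc = int(round(design.uncultured_fraction * len(names)))
    if n_unc:
        idx = rng.choice(len(names), size=n_unc, replace=False)
        for i in idx:
            names[i] = f"Genus{i + 1:02d} uncultured organism {i + 1}"
    return names, clusters


def _taxonomy_for(names: list[str]) -> TaxonomyMap:
    lineages = {}
    for j, name in enumerate(names):
        genus = name.split(" ")[0]
        lineages[f"Otu{j + 1:04d}"] = list(zip(RANKS, (
            "Bacteria", f"Phylum{j % 4 + 1}", f"Class{j % 4 + 1}",
            f"Order{j % 4 + 1}", f"Family{j % 4 + 1}", genus, name)))
    return TaxonomyMap(lineages)


def simulate_dataset(design: SimulationDesign
                     ) -> tuple[CountTable, TaxonomyMap, SyntheticTruth]:
    """Draw one synthetic dataset; deterministic for a fixed design+seed."""
    rng = np.random.default_rng(design.seed)
    mix = np.asarray(design.mixing_matrix, dtype=float)
    names, sp_cluster = _species_names(design, rng)
    n_species = len(names)
    cluster_of = np.asarray(sp_cluster)

    subjects = [f"p{i + 1:02d}" for i in range(design.n_subjects)]
    types = rng.choice(len(design.subject_type_probs), size=design.n_subjects,
                       p=np.asarray(design.subject_type_probs))

    # cluster-level consortium compositions, shared across subjects
    cluster_profiles = {
        c: rng.dirichlet(np.full((cluster_of == c).sum(),
                                 design.within_cluster_dirichlet))
        for c in range(design.n_clusters)}

    rows, sample_ids, md_rows = [], [], []
    realized = np.zeros((design.n_subjects, design.n_clusters))
    for s, subj in enumerate(subjects):
        w = _dirichlet_with_zeros(rng, design.between_subject_kappa * mix[types[s]])
        realized[s] = w
        profile = np.zeros(n_species)
        for c in range(design.n_clusters):
            members = cluster_of == c
            profile[members] = w[c] * cluster_profiles[c]
        for day in design.days:
            p = _dirichlet_with_zeros(rng, design.overdispersion * profile)
            if design.day_effect != 0.0:
                tilt = np.where(cluster_of == 0,
                                np.exp(design.day_effect * day), 1.0)
                p = p * tilt
                p = p / p.sum()
            rows.append(rng.multinomial(design.depth, p))
            sample_ids.append(f"{subj}d{day:02d}")
            md_rows.append((subj, day))

    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64), index=sample_ids,
        columns=[f"Otu{j + 1:04d}" for j in range(n_species)])
    metadata = pd.DataFrame(md_rows, index=sample_ids, columns=["subject", "day"])
    truth = SyntheticTruth(
        species_cluster=dict(zip(names, sp_cluster)),
        subject_type=dict(zip(subjects, types.tolist())),
        realized_weights=pd.DataFrame(realized, index=subjects,
                                      columns=range(design.n_clusters)))
    return CountTable(counts, metadata), _taxonomy_for(names), truth


def adjusted_rand_index(labels_a: dict | pd.Series, labels_b: dict | pd.Series) -> float:
    """Chance-corrected agreement between two partitions of the same items.

    Computed from the contingency table:
    ``ARI = (sum_ij C(n_ij,2) - E) / (max - E)`` with
    ``E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2)`` and
    ``max = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2``.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if set(a.index) != set(b.index):
        raise ValueError("partitions cover different item sets")
    b = b.loc[a.index]
    ct = pd.crosstab(a.to_numpy(), b.to_numpy()).to_numpy()

    def comb2(x: np.ndarray) -> float:
        return float((x * (x - 1) / 2).sum())

    n = ct.sum()
    sum_ij = comb2(ct)
    sum_a = comb2(ct.sum(axis=1))
    sum_b = comb2(ct.sum(axis=0))
    expected = sum_a * sum_b / (n * (n - 1) / 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:  # both partitions trivial
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
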