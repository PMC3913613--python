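"""Reading, writing and reshaping sample-by-OTU count tables.

The pipeline starts from three plain-text inputs:

* a mothur ``shared``-format sample-by-OTU count table,
* a mothur ``cons.taxonomy`` (constaxonomy) OTU-to-lineage table,
* a sample metadata TSV with columns ``sample``, ``subject``, ``day``.

This module parses those into :class:`CountTable` / :class:`TaxonomyMap`,
rarefies counts to a common depth (multivariate hypergeometric, i.e.
subsampling reads without replacement), collapses OTUs to a taxonomic rank
as relative abundances, and applies the species-name filters used before
correlation clustering (removal of "uncultured"/"unclassified" taxa and of
OTUs unresolved at species level).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class FormatError(ValueError):
    """A malformed input file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Integer sample-by-feature count matrix with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, rows indexed by sample id,
        columns by OTU/taxon id.
    metadata
        DataFrame indexed by sample id with columns ``subject`` and ``day``;
        may be None until joined via :func:`attach_metadata`.
    under_depth
        Sample ids that were below the rarefaction depth and kept unchanged.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None
    under_depth: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.metadata is not None:
            self._check_metadata()

    def _check_metadata(self) -> None:
        md = self.metadata
        missing = [s for s in self.counts.index if s not in md.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        md = md.loc[self.counts.index]
        pairs = list(zip(md["subject"], md["day"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("(subject, day) pairs are not unique")
        self.metadata = md

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, keep: list[str]) -> "CountTable":
        md = self.metadata.loc[keep] if self.metadata is not None else None
        return CountTable(self.counts.loc[keep].copy(), md,
                          tuple(s for s in self.under_depth if s in keep))

    def drop_subjects(self, subjects: list[str]) -> "CountTable":
        if self.metadata is None:
            raise ValueError("metadata required to drop subjects")
        unknown = set(subjects) - set(self.metadata["subject"])
        if unknown:
            raise ValueError(f"unknown subjects: {sorted(unknown)}")
        keep = [s for s in self.counts.index
                if self.metadata.loc[s, "subject"] not in set(subjects)]
        return self.subset_samples(keep)


@dataclass
class AbundanceTable:
    """Per-sample relative abundances (fractions of the sample total).

    ``complete`` is True while every row still sums to 1; dropping features
    after normalization (see :func:`filter_species_names`) sets it to False
    and records the dropped feature names.
    """

    abundances: pd.DataFrame
    metadata: pd.DataFrame | None = None
    complete: bool = True
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        sums = self.abundances.sum(axis=1).to_numpy()
        if self.complete and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("rows of a complete AbundanceTable must sum to 1")
        if (sums > 1 + 1e-9).any():
            raise ValueError("row sums exceed 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.abundances.columns)


@dataclass
class TaxonomyMap:
    """OTU id -> ordered lineage of (rank, name), kingdom downwards."""

    lineages: dict[str, list[tuple[str, str]]]
    confidences: dict[str, list[float | None]] = field(default_factory=dict)
    sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for otu, lin in self.lineages.items():
            ranks = [r for r, _ in lin]
            order = [RANKS.index(r) for r in ranks]
            if order != sorted(order) or len(set(order)) != len(order):
                raise ValueError(f"lineage ranks not strictly ordered for {otu}")
            if any(not n for _, n in lin):
                raise ValueError(f"empty lineage name for {otu}")

    def __contains__(self, otu: str) -> bool:
        return otu in self.lineages

    def name_at_rank(self, otu: str, rank: str) -> str:
        """Taxon label of ``otu`` at ``rank``.

        OTUs whose lineage ends above the requested rank are labelled with
        their deepest resolved name suffixed ``_unclassified`` (the mothur
        placeholder convention), which the species-name filter later removes.
        Underscores in names become spaces; a species epithet lacking its
        genus is prefixed with the genus name to form a binomial.
        """
        lin = self.lineages[otu]
        names = dict(lin)
        if rank not in names:
            deepest = lin[-1][1]
            return f"{deepest}_unclassified".replace("_", " ")
        name = names[rank].replace("_", " ")
        if rank == "species" and " " not in name and "genus" in names:
            name = f"{names['genus'].replace('_', ' ')} {name}"
        return name


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_shared(path: str) -> CountTable:
    """Parse a mothur shared file (``label Group numOtus Otu0001 ...``)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty shared file")
    header = lines[0].split("\t")
    if len(header) < 3 or header[1].lower() != "group":
        raise FormatError(f"{path}: not a shared file (header {header[:3]})")
    otu_ids = header[3:]
    rows, samples = [], []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise FormatError(f"{path}:{i}: expected {len(header)} columns, got {len(parts)}")
        try:
            numotus = int(parts[2])
            counts = [int(x) for x in parts[3:]]
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: non-integer cell ({exc})") from None
        if numotus != len(otu_ids):
            raise FormatError(
                f"{path}:{i}: numOtus={numotus} disagrees with {len(otu_ids)} OTU columns")
        samples.append(parts[1])
        rows.append(counts)
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate sample ids")
    counts = pd.DataFrame(rows, index=samples, columns=otu_ids, dtype=np.int64)
    return CountTable(counts)


def write_shared(table: CountTable, path: str, label: str = "0.03") -> None:
    """Write counts in mothur shared format (inverse of :func:`read_shared`)."""
    with open(path, "w") as fh:
        fh.write("\t".join(["label", "Group", "numOtus", *table.feature_ids]) + "\n")
        n = len(table.feature_ids)
        for sample, row in table.counts.iterrows():
            fh.write("\t".join([label, str(sample), str(n),
                                *map(str, row.to_numpy())]) + "\n")


def _parse_lineage(tax: str) -> tuple[list[tuple[str, str]], list[float | None]]:
    parts = [p for p in tax.strip().split(";") if p]
    lineage, conf = [], []
    for rank, part in zip(RANKS, parts):
        name, c = part, None
        if part.endswith(")") and "(" in part:
            name, rest = part.rsplit("(", 1)
            try:
                c = float(rest[:-1])
            except ValueError:
                name = part
        lineage.append((rank, name.strip()))
        conf.append(c)
    return lineage, conf


def read_constaxonomy(path: str) -> TaxonomyMap:
    """Parse a mothur constaxonomy file (``OTU Size Taxonomy``)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if "taxonomy" not in header:
        raise FormatError(f"{path}: missing Taxonomy column")
    i_otu = header.index("otu")
    i_tax = header.index("taxonomy")
    i_size = header.index("size") if "size" in header else None
    lineages: dict[str, list[tuple[str, str]]] = {}
    confidences: dict[str, list[float | None]] = {}
    sizes: dict[str, int] = {}
    for n, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        otu = parts[i_otu]
        if otu in lineages:
            raise FormatError(f"{path}:{n}: duplicate OTU id {otu}")
        lineages[otu], confidences[otu] = _parse_lineage(parts[i_tax])
        if i_size is not None:
            sizes[otu] = int(parts[i_size])
    return TaxonomyMap(lineages, confidences, sizes)


def write_constaxonomy(tax: TaxonomyMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("OTU\tSize\tTaxonomy\n")
        for otu, lin in tax.lineages.items():
            conf = tax.confidences.get(otu, [None] * len(lin))
            parts = [f"{name}({c:g})" if c is not None else name
                     for (_, name), c in zip(lin, conf)]
            fh.write(f"{otu}\t{tax.sizes.get(otu, 1)}\t" + ";".join(parts) + ";\n")


def read_metadata(path: str) -> pd.DataFrame:
    """Read the sample metadata TSV (columns sample, subject, day)."""
    md = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str, "subject": str})
    required = {"sample", "subject", "day"}
    if not required.issubset(md.columns):
        raise FormatError(f"{path}: metadata needs columns {sorted(required)}")
    if md["sample"].duplicated().any():
        dups = md.loc[md["sample"].duplicated(), "sample"].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    md["day"] = md["day"].astype(int)
    if (md["day"] < 1).any():
        raise FormatError(f"{path}: day must be a positive integer")
    unusual = sorted(set(md["day"]) - {1, 3, 5, 9, 14})
    if unusual:
        warnings.warn(f"unusual day values {unusual} accepted", stacklevel=2)
    return md.set_index("sample")[["subject", "day"]]


def attach_metadata(table: CountTable, metadata: pd.DataFrame) -> CountTable:
    """Join per-sample (subject, day) onto a count table."""
    return CountTable(table.counts, metadata, table.under_depth)


# ---------------------------------------------------------------------------
# Count-table operations
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: int,
           strict_depth: bool = False) -> CountTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Each sample whose total is at least ``depth`` is replaced by a
    multivariate-hypergeometric draw of exactly ``depth`` reads (the
    semantics of mothur's ``sub.sample``). Samples below depth are kept
    unchanged and flagged in ``under_depth`` — or dropped when
    ``strict_depth`` is set.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    out = table.counts.copy()
    under = []
    for sample, row in table.counts.iterrows():
        total = int(row.sum())
        if total < depth:
            under.append(sample)
            continue
        if total == depth:
            continue
        out.loc[sample] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    if under:
        warnings.warn(
            f"{len(under)} sample(s) below depth {depth} "
            + ("dropped" if strict_depth else "kept unchanged")
            + f": {under}", stacklevel=2)
    md = table.metadata
    if strict_depth and under:
        keep = [s for s in out.index if s not in set(under)]
        out = out.loc[keep]
        md = md.loc[keep] if md is not None else None
        under = []
    return CountTable(out, md, tuple(under))


def collapse_by_rank(table: CountTable, tax: TaxonomyMap, rank: str) -> AbundanceTable:
    """Sum counts over features sharing a rank-level name and normalize.

    Normalization divides by the per-sample total *before* any feature is
    dropped, so rows sum to 1 here and later filters only lower the sums.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    missing = [f for f in table.feature_ids if f not in tax]
    if missing:
        raise ValueError(f"features missing from taxonomy: {missing[:5]}")
    labels = [tax.name_at_rank(f, rank) for f in table.feature_ids]
    totals = table.counts.sum(axis=1).to_numpy().astype(float)
    if (totals == 0).any():
        zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"zero-total samples cannot be normalized: {zero}")
    grouped = table.counts.T.groupby(pd.Index(labels, name=rank), sort=False).sum().T
    rel = grouped.div(totals, axis=0)
    return AbundanceTable(rel, table.metadata)


_FILTER_TERMS = ("uncultured", "unclassified")


def filter_species_names(table: AbundanceTable,
                         renormalize_after_filter: bool = False) -> AbundanceTable:
    """Drop species-level taxa that are not resolved, clean binomials.

    Removes features whose name contains "uncultured" or "unclassified"
    (case-insensitive substring match; OTUs unresolved at species level
    carry an "unclassified" placeholder from :meth:`TaxonomyMap.name_at_rank`
    and are removed by the same rule). By default the surviving abundances
    keep their original per-sample denominators; ``renormalize_after_filter``
    rescales rows to sum to 1 instead.
    """
    bad = [f for f in table.feature_ids
           if any(t in f.lower() for t in _FILTER_TERMS)]
    keep = [f for f in table.feature_ids if f not in set(bad)]
    if not keep:
        raise ValueError("no species-level taxa survive filtering")
    if not bad:
        return table
    sub = table.abundances[keep].copy()
    if renormalize_after_filter:
        sums = sub.sum(axis=1)
        if (sums == 0).any():
            raise ValueError("cannot renormalize rows with zero surviving mass")
        return AbundanceTable(sub.div(sums, axis=0), table.metadata,
                              complete=True, dropped=tuple(bad))
    return AbundanceTable(sub, table.metadata, complete=False, dropped=tuple(bad))


def mean_by_subject(table: AbundanceTable) -> AbundanceTable:
    """Average relative abundances over each subject's time points."""
    if table.metadata is None:
        raise ValueError("metadata required")
    subj = table.metadata.loc[table.sample_ids, "subject"]
    means = table.abundances.groupby(subj.to_numpy(), sort=True).mean()
    means.index.name = "subject"
    md = pd.DataFrame({"subject": means.index, "day": 0}, index=means.index)
    return AbundanceTable(means, md, complete=table.complete, dropped=table.dropped)


def abundant_taxa_summary(table: AbundanceTable, threshold: float) -> pd.DataFrame:
    """Taxa whose mean relative abundance across subjects is >= threshold.

    Returns per-subject mean abundances (taxa as rows, subjects as columns)
    plus a ``mean`` column, sorted by descending mean. The threshold is
    inclusive.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    per_subject = mean_by_subject(table).abundances  # subjects x taxa
    means = per_subject.mean(axis=0)
    keep = means[means >= threshold].sort_values(ascending=False)
    out = per_subject.T.loc[keep.index]
    out.insert(0, "mean", keep)
    return out


def write_tsv(df: pd.DataFrame, path: str, provenance: str = "") -> None:
    """Write a TSV with a one-line '#' provenance header."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t")
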