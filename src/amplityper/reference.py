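"""Construction, naming, versioning and serialization of the reference index.

The reference index is a versioned collection of labelled haplotypes against
which query specimens are assigned.  Its samples are grouped at three nested
levels mirroring the taxonomy of the genus:

- **fine** — species-like clusters from single-linkage clustering of the
  pairwise sample k-mer distance matrix at a threshold of 0.1;
- **intermediate** — complex/group-like clusters at a threshold of 0.3;
- **coarse** — taxonomic series (or subgenus for the species-poor subgenera),
  taken from a taxonomy table rather than from a distance threshold, because
  no single threshold separates all series.

Single-linkage (connected components of the sub-threshold distance graph) is
the one clustering scheme for which a pure distance threshold defines the
partition and for which the fine partition is guaranteed to nest inside the
intermediate one.

Group naming follows a fixed convention: a fine group matching exactly one
species takes the species name with no suffix; groups spanning several
species are named after the lowest shared taxon with a ``§`` mark; groups
representing distinct clades of one base name carry ``_cl1``, ``_cl2``, …;
``_f``/``_i`` mark the level (omitted for one-to-one fine groups and
unflagged single-species intermediate pass-throughs); ``*`` marks a conflict
between clustering and taxonomic placement, ``^`` an unnamed species and
``†`` strong geographic structure.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .kmer import extract_kmers, haplotype_distance, sample_distance
from .samples import Sample

__all__ = [
    "CONFLICT",
    "MULTI_SPECIES",
    "UNNAMED",
    "GEO_STRUCTURE",
    "SpeciesGroupLabel",
    "TaxonomyRecord",
    "load_taxonomy",
    "IndexEntry",
    "ReferenceIndex",
    "BuildReport",
    "select_candidates",
    "pairwise_distance_matrix",
    "ThresholdClusterer",
    "cluster_at_threshold",
    "name_group",
    "build_index",
    "serialize_index",
    "load_index",
]

# Confidence flags and their rendered symbols, in rendering order.
CONFLICT = "CONFLICT"
MULTI_SPECIES = "MULTI_SPECIES"
UNNAMED = "UNNAMED"
GEO_STRUCTURE = "GEO_STRUCTURE"
FLAG_SYMBOLS = {CONFLICT: "*", MULTI_SPECIES: "§", UNNAMED: "^", GEO_STRUCTURE: "†"}
FLAG_ORDER = (CONFLICT, MULTI_SPECIES, UNNAMED, GEO_STRUCTURE)

LEVELS = ("fine", "intermediate", "coarse")


def normalise_name(name: str) -> str:
    """Canonical underscored form of a taxon name (``An. foo bar`` → ``An_foo_bar``)."""
    return name.replace(".", "").strip().replace(" ", "_")


@dataclass(frozen=True)
class SpeciesGroupLabel:
    """A structured species-group name at one hierarchy level.

    ``render()`` concatenates base name, optional clade suffix ``_clN``,
    optional level suffix ``_f``/``_i``, then flag symbols in the order
    ``* § ^ †``.
    """

    base_name: str
    level: str
    clade_number: int | None = None
    level_suffix: str | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        unknown = set(self.flags) - set(FLAG_SYMBOLS)
        if unknown:
            raise ValueError(f"unknown flags {sorted(unknown)}")
        if self.level_suffix not in (None, "_f", "_i"):
            raise ValueError(f"invalid level suffix {self.level_suffix!r}")
        if self.level == "coarse" and (self.level_suffix or self.clade_number):
            raise ValueError("coarse labels carry no level or clade suffix")
        if self.level == "fine":
            expect_f = MULTI_SPECIES in self.flags or self.clade_number is not None
            if expect_f != (self.level_suffix == "_f"):
                raise ValueError(
                    "fine labels take '_f' exactly when they span several "
                    "species or carry a clade suffix"
                )

    def render(self) -> str:
        parts = [self.base_name]
        if self.clade_number is not None:
            parts.append(f"_cl{self.clade_number}")
        if self.level_suffix:
            parts.append(self.level_suffix)
        parts.extend(FLAG_SYMBOLS[f] for f in FLAG_ORDER if f in self.flags)
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class TaxonomyRecord:
    """Taxonomic placement of one species.

    ``series_or_subgenus`` is the coarse unit: the taxonomic series for the
    two species-rich subgenera and the subgenus itself otherwise.
    """

    species: str
    complex_or_group: str
    series_or_subgenus: str
    subgenus: str = ""


def load_taxonomy(source) -> dict[str, TaxonomyRecord]:
    """Load a taxonomy table (species → complex/group → series/subgenus).

    ``source`` may be a path to a TSV with columns ``species``,
    ``complex_or_group``, ``series_or_subgenus`` and optionally ``subgenus``,
    a ``pandas.DataFrame`` with those columns, or a mapping of species name
    to :class:`TaxonomyRecord` (returned unchanged).
    """
    if isinstance(source, Mapping):
        return dict(source)
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    required = {"species", "complex_or_group", "series_or_subgenus"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table is missing columns {sorted(missing)}")
    records = {}
    for row in df.itertuples(index=False):
        rec = TaxonomyRecord(
            species=row.species,
            complex_or_group=row.complex_or_group,
            series_or_subgenus=row.series_or_subgenus,
            subgenus=getattr(row, "subgenus", ""),
        )
        records[rec.species] = rec
    return records


@dataclass(frozen=True)
class IndexEntry:
    """One reference individual: haplotypes plus its three-level labels."""

    sample_id: str
    country: str
    haplotypes: tuple[tuple[str, tuple[str, ...]], ...]  # (target, alleles) sorted
    fine: str
    intermediate: str
    coarse: str

    @classmethod
    def from_sample(cls, sample: Sample, fine: str, intermediate: str, coarse: str) -> "IndexEntry":
        haps = tuple((t, sample.alleles(t)) for t in sample.targets)
        return cls(sample.sample_id, sample.country, haps, fine, intermediate, coarse)


@dataclass
class ReferenceIndex:
    """Versioned, labelled haplotype collection used for species assignment."""

    version: str
    k: int
    metric: str
    entries: tuple[IndexEntry, ...]
    group_metadata: dict[str, dict] = field(default_factory=dict)
    fine_threshold: float = 0.1
    intermediate_threshold: float = 0.3

    def __post_init__(self) -> None:
        self.entries = tuple(sorted(self.entries, key=lambda e: e.sample_id))
        self._validate_hierarchy()
        self._by_target: dict[str, list[tuple[str, str]]] | None = None

    def _validate_hierarchy(self) -> None:
        fine_to_upper: dict[str, tuple[str, str]] = {}
        for e in self.entries:
            upper = (e.intermediate, e.coarse)
            prev = fine_to_upper.setdefault(e.fine, upper)
            if prev != upper:
                raise ValueError(
                    f"fine group {e.fine!r} maps to both {prev} and {upper}: "
                    "the fine → intermediate → coarse mapping must be functional"
                )
            for label in (e.fine, e.intermediate, e.coarse):
                if self.group_metadata and label not in self.group_metadata:
                    raise ValueError(f"label {label!r} missing from group_metadata")

    # -- lookups -----------------------------------------------------------
    @property
    def fine_labels(self) -> tuple[str, ...]:
        return tuple(sorted({e.fine for e in self.entries}))

    @property
    def intermediate_labels(self) -> tuple[str, ...]:
        return tuple(sorted({e.intermediate for e in self.entries}))

    @property
    def coarse_labels(self) -> tuple[str, ...]:
        return tuple(sorted({e.coarse for e in self.entries}))

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(sorted({t for e in self.entries for t, _ in e.haplotypes}))

    def fine_to_intermediate(self) -> dict[str, str]:
        return {e.fine: e.intermediate for e in self.entries}

    def fine_to_coarse(self) -> dict[str, str]:
        return {e.fine: e.coarse for e in self.entries}

    def haplotypes_by_target(self) -> dict[str, list[tuple[str, str]]]:
        """Deduplicated ``target → [(sequence, fine label), ...]`` lookup."""
        if self._by_target is None:
            seen: set[tuple[str, str, str]] = set()
            by_target: dict[str, list[tuple[str, str]]] = defaultdict(list)
            for e in self.entries:
                for target, alleles in e.haplotypes:
                    for seq in alleles:
                        key = (target, seq, e.fine)
                        if key not in seen:
                            seen.add(key)
                            by_target[target].append((seq, e.fine))
            self._by_target = dict(by_target)
        return self._by_target

    def members(self, label: str) -> tuple[str, ...]:
        """Species represented by a group label, from group metadata."""
        return tuple(self.group_metadata.get(label, {}).get("members", ()))


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------

def select_candidates(
    pool: Iterable[tuple[str, str, str]],
    max_per_species: int = 10,
    max_per_country: int = 5,
) -> list[tuple[str, str, str]]:
    """Select reference candidates per species with a country-spread cap.

    Per species, at most ``max_per_species`` individuals are kept with no
    more than ``max_per_country`` from any one country.  Countries are filled
    round-robin — one individual per country per pass — so the selection
    spans as many countries as possible; within a country, candidates are
    taken in sample-id order.  ``pool`` rows are ``(sample_id, species,
    country)`` tuples.
    """
    per_species: dict[str, dict[str, list[tuple[str, str, str]]]] = defaultdict(lambda: defaultdict(list))
    for sample_id, species, country in pool:
        if not species or not country:
            raise ValueError(
                f"pool entry {sample_id!r} has empty species or country"
            )
        per_species[species][country].append((sample_id, species, country))

    selected: list[tuple[str, str, str]] = []
    for species in sorted(per_species):
        queues = {
            c: sorted(rows) for c, rows in per_species[species].items()
        }
        taken: list[tuple[str, str, str]] = []
        per_country_count: Counter[str] = Counter()
        while len(taken) < max_per_species:
            progressed = False
            for country in sorted(queues):
                if len(taken) >= max_per_species:
                    break
                if queues[country] and per_country_count[country] < max_per_country:
                    taken.append(queues[country].pop(0))
                    per_country_count[country] += 1
                    progressed = True
            if not progressed:
                break
        selected.extend(sorted(taken))
    return selected


# ---------------------------------------------------------------------------
# Threshold clustering
# ---------------------------------------------------------------------------

def pairwise_distance_matrix(
    samples: Sequence[Sample], k: int = 8, metric: str = "min"
) -> tuple[list[str], np.ndarray]:
    """Symmetric pairwise sample k-mer distance matrix, in sample-id order."""
    ordered = sorted(samples, key=lambda s: s.sample_id)
    ids = [s.sample_id for s in ordered]
    n = len(ordered)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = sample_distance(ordered[i], ordered[j], k=k, metric=metric)
    return ids, D


def _validate_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {D.shape}")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if D.min() < -1e-12 or D.max() > 1 + 1e-12:
        raise ValueError("distances must lie in [0, 1]")
    return D


class ThresholdClusterer(BaseEstimator, ClusterMixin):
    """Single-linkage clustering by a hard distance threshold.

    Two samples belong to the same cluster when they are connected by a path
    of pairwise distances strictly below ``threshold`` (connected components
    of the sub-threshold graph).  Boundary pairs at exactly the threshold
    are split; set ``strict=False`` to include them.

    Parameters
    ----------
    threshold : float, default 0.1
        Distance threshold defining graph edges.
    strict : bool, default True
        Use ``D < threshold`` for edges; ``D <= threshold`` otherwise.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster label per sample.  Components are numbered in order of their
        smallest member index, so labelling is deterministic.
    n_clusters_ : int
    """

    def __init__(self, threshold: float = 0.1, strict: bool = True):
        self.threshold = threshold
        self.strict = strict

    def fit(self, X, y=None):
        D = _validate_distance_matrix(X)
        if self.strict:
            adj = D < self.threshold
        else:
            adj = D <= self.threshold
        np.fill_diagonal(adj, False)
        n_comp, raw = connected_components(csr_matrix(adj), directed=False)
        # renumber components by smallest member index for determinism
        order: dict[int, int] = {}
        for idx in range(len(raw)):
            order.setdefault(raw[idx], len(order))
        self.labels_ = np.array([order[c] for c in raw])
        self.n_clusters_ = n_comp
        return self


def cluster_at_threshold(
    D: np.ndarray, t: float, ids: Sequence[str] | None = None, strict: bool = True
) -> list[list[str]]:
    """Partition samples by single-linkage at distance threshold ``t``.

    Returns clusters as lists of sample ids, each sorted, ordered by their
    smallest member.  With ``ids`` omitted, stringified indices are used.
    """
    D = _validate_distance_matrix(D)
    if ids is None:
        ids = [str(i) for i in range(D.shape[0])]
    if len(ids) != D.shape[0]:
        raise ValueError("ids length must match the distance matrix")
    labels = ThresholdClusterer(threshold=t, strict=strict).fit(D).labels_
    clusters: dict[int, list[str]] = defaultdict(list)
    for sid, lab in zip(ids, labels):
        clusters[lab].append(sid)
    out = [sorted(members) for members in clusters.values()]
    return sorted(out, key=lambda c: c[0])


# ---------------------------------------------------------------------------
# Naming
# ---------------------------------------------------------------------------

def _shared_taxon(
    members: Sequence[str], taxonomy: Mapping[str, TaxonomyRecord]
) -> str:
    """Lowest taxon shared by all member species: complex/group if unanimous,
    else series/subgenus if unanimous, else raises."""
    missing = [m for m in members if m not in taxonomy]
    if missing:
        raise KeyError(f"species missing from taxonomy table: {sorted(missing)}")
    complexes = {taxonomy[m].complex_or_group for m in members}
    if len(complexes) == 1:
        return complexes.pop()
    series = {taxonomy[m].series_or_subgenus for m in members}
    if len(series) == 1:
        return series.pop()
    raise ValueError(
        f"species {sorted(members)} share no taxon at any level below genus; "
        "the taxonomy table needs repair before this group can be named"
    )


def name_group(
    members: Sequence[str],
    level: str,
    taxonomy: Mapping[str, TaxonomyRecord],
    flags: Iterable[str] = (),
    clade_number: int | None = None,
    host_taxon: str | None = None,
    single_fine: bool = True,
) -> SpeciesGroupLabel:
    """Deterministically name a species-group per the naming convention.

    - a single named species keeps its own (underscored) name; at the fine
      level the ``_f`` suffix is then omitted, and an unflagged intermediate
      pass-through (a single species forming a single fine group, signalled
      by ``single_fine``) omits ``_i``;
    - several species are named after the lowest taxon they share; the ``§``
      flag (``MULTI_SPECIES``) marks a fine group spanning several species
      and an intermediate group spanning several complexes;
    - unnamed species (``UNNAMED`` flag) are named after ``host_taxon``, the
      taxon they most likely belong to, and always carry a clade suffix;
    - ``clade_number`` renders as ``_clN`` before the level suffix.
    """
    flags = frozenset(flags)
    members = sorted(set(members))
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    if UNNAMED in flags:
        if not host_taxon:
            raise ValueError("UNNAMED groups require a host_taxon base name")
        if clade_number is None:
            clade_number = 1
        base = normalise_name(host_taxon)
    elif not members:
        raise ValueError("members must be non-empty unless the group is UNNAMED")
    elif len(members) == 1:
        base = normalise_name(members[0])
    else:
        base = normalise_name(_shared_taxon(members, taxonomy))
        if level == "fine":
            flags = flags | {MULTI_SPECIES}
        else:
            complexes = {
                taxonomy[m].complex_or_group for m in members if m in taxonomy
            }
            if len(complexes) > 1:
                flags = flags | {MULTI_SPECIES}

    if level == "fine":
        suffix = "_f" if (MULTI_SPECIES in flags or clade_number is not None) else None
    elif level == "intermediate":
        passthrough = (
            len(members) == 1 and not flags and clade_number is None and single_fine
        )
        suffix = None if passthrough else "_i"
    else:
        suffix = None
    return SpeciesGroupLabel(
        base_name=base,
        level=level,
        clade_number=clade_number,
        level_suffix=suffix,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Index construction
# ---------------------------------------------------------------------------

@dataclass
class BuildReport:
    """Everything surfaced (never silently fixed) during an index build."""

    dropped_candidates: list[tuple[str, str]] = field(default_factory=list)
    excluded_low_targets: list[tuple[str, int]] = field(default_factory=list)
    multi_species_groups: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    split_species: list[dict] = field(default_factory=list)
    taxonomy_conflicts: list[dict] = field(default_factory=list)
    missing_taxonomy: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


def _majority(values: Iterable[str]) -> str:
    counts = Counter(values)
    top = max(counts.values())
    return sorted(v for v, c in counts.items() if c == top)[0]


def _within_species_cluster_support(
    samples_by_id: Mapping[str, Sample],
    clusters: Sequence[Sequence[str]],
    k: int,
    metric: str,
) -> dict[str, float]:
    """Per member, the proportion of its alleles whose nearest neighbour
    among the species' *other* members lies in the member's own cluster."""
    cluster_of = {sid: ci for ci, cl in enumerate(clusters) for sid in cl}
    all_ids = sorted(cluster_of)
    support: dict[str, float] = {}
    for sid in all_ids:
        sample = samples_by_id[sid]
        others = [samples_by_id[o] for o in all_ids if o != sid]
        own, total = 0.0, 0.0
        for target in sample.targets:
            for allele in sample.alleles(target):
                prof = extract_kmers(allele, k)
                best, best_ids = None, []
                for other in others:
                    for seq in other.alleles(target):
                        d = haplotype_distance(prof, extract_kmers(seq, k), metric)
                        if best is None or d < best - 1e-15:
                            best, best_ids = d, [other.sample_id]
                        elif abs(d - best) <= 1e-15:
                            best_ids.append(other.sample_id)
                if best is None:
                    continue
                hit_clusters = {cluster_of[o] for o in best_ids}
                own += (cluster_of[sid] in hit_clusters) / len(hit_clusters)
                total += 1.0
        support[sid] = own / total if total else 0.0
    return support


def _prefilter_mislabelled(
    samples: list[Sample],
    taxonomy: Mapping[str, TaxonomyRecord],
    k: int,
    metric: str,
    threshold: float,
    min_targets: int,
    report: BuildReport,
) -> list[Sample]:
    """Drop candidates whose NN assignment under a provisional index
    (every other candidate labelled by its claimed species) contradicts
    their claimed coarse-level taxon.  Applied only to species with at
    least two candidates, since a sole representative has no peers to
    contradict it."""
    from .assign import assign_sample  # local import to avoid a cycle

    by_species: Counter[str] = Counter(s.species_label for s in samples)
    kept: list[Sample] = []
    for sample in samples:
        species = sample.species_label
        if species not in taxonomy or by_species[species] < 2:
            kept.append(sample)
            continue
        claimed_coarse = normalise_name(taxonomy[species].series_or_subgenus)
        provisional = _provisional_index(
            [s for s in samples if s.sample_id != sample.sample_id], taxonomy, k, metric
        )
        result = assign_sample(
            sample, provisional, threshold=threshold, min_targets=min_targets, k=k
        )
        if not result.proportions_coarse:
            kept.append(sample)
            continue
        top_coarse = max(
            sorted(result.proportions_coarse), key=lambda l: result.proportions_coarse[l]
        )
        if top_coarse != claimed_coarse:
            report.dropped_candidates.append(
                (
                    sample.sample_id,
                    f"provisional NN coarse assignment {top_coarse!r} contradicts "
                    f"claimed taxon {claimed_coarse!r} for species {species!r}",
                )
            )
        else:
            kept.append(sample)
    return kept


def _provisional_index(
    samples: Sequence[Sample],
    taxonomy: Mapping[str, TaxonomyRecord],
    k: int,
    metric: str,
) -> "ReferenceIndex":
    """Index labelled directly by claimed species labels (no clustering)."""
    entries = []
    for s in samples:
        species = s.species_label or "unknown"
        rec = taxonomy.get(species)
        fine = normalise_name(species)
        inter = normalise_name(rec.complex_or_group) if rec else fine
        coarse = normalise_name(rec.series_or_subgenus) if rec else fine
        entries.append(IndexEntry.from_sample(s, fine, inter, coarse))
    return ReferenceIndex(
        version="provisional", k=k, metric=metric, entries=tuple(entries)
    )


def build_index(
    samples: Sequence[Sample],
    taxonomy,
    fine_t: float = 0.1,
    intermediate_t: float = 0.3,
    k: int = 8,
    metric: str = "min",
    version: str = "v1",
    min_targets: int = 10,
    prefilter: bool = True,
    assignment_threshold: float = 0.7,
    split_support: float = 0.9,
    geo_structure_species: Iterable[str] = (),
) -> tuple[ReferenceIndex, BuildReport]:
    """Build a three-level reference index from labelled candidate samples.

    Fine and intermediate groups come from single-linkage clustering of the
    pairwise sample distance matrix at ``fine_t`` and ``intermediate_t``;
    coarse groups come from the taxonomy table.  Thresholds rarely partition
    candidates perfectly, so every irregularity — clusters mixing species
    (``§``), species split over several clusters (``_clN`` or a merge),
    clustering/taxonomy conflicts (``*``), dropped candidates — is surfaced
    in the returned :class:`BuildReport`.

    A species split over several single-species clusters is kept split only
    when every member's alleles support its own cluster with proportion at
    least ``split_support`` (and the clusters sit in one intermediate
    group); otherwise the clusters are merged into one fine group.  Species
    listed in ``geo_structure_species`` get the ``†`` flag — geographic
    structure evidence is metadata passed through, not computed here.

    Returns the index together with the build report.
    """
    if fine_t >= intermediate_t:
        raise ValueError(
            f"fine threshold ({fine_t}) must be below the intermediate "
            f"threshold ({intermediate_t})"
        )
    taxonomy = load_taxonomy(taxonomy)
    geo_structure_species = set(geo_structure_species)
    report = BuildReport()

    usable: list[Sample] = []
    for s in samples:
        if s.n_targets < min_targets:
            report.excluded_low_targets.append((s.sample_id, s.n_targets))
        else:
            usable.append(s)
    for s in usable:
        if s.species_label and s.species_label not in taxonomy:
            if s.species_label not in report.missing_taxonomy:
                report.missing_taxonomy.append(s.species_label)
    if not usable:
        raise ValueError("no candidate sample has enough recovered targets")

    if prefilter:
        usable = _prefilter_mislabelled(
            usable, taxonomy, k, metric, assignment_threshold, min_targets, report
        )

    samples_by_id = {s.sample_id: s for s in usable}
    ids, D = pairwise_distance_matrix(usable, k=k, metric=metric)
    fine_clusters = cluster_at_threshold(D, fine_t, ids)
    inter_clusters = cluster_at_threshold(D, intermediate_t, ids)
    inter_of = {sid: ci for ci, cl in enumerate(inter_clusters) for sid in cl}

    species_of = {s.sample_id: s.species_label for s in usable}

    # --- merge pass: species split over several single-species clusters ----
    def named_species(cluster: Sequence[str]) -> set[str]:
        return {species_of[sid] for sid in cluster if species_of[sid]}

    clusters_of_species: dict[str, list[int]] = defaultdict(list)
    for ci, cluster in enumerate(fine_clusters):
        sp = named_species(cluster)
        if len(sp) == 1:
            clusters_of_species[next(iter(sp))].append(ci)
    mixed_species = {
        sp
        for cluster in fine_clusters
        if len(named_species(cluster)) > 1
        for sp in named_species(cluster)
    }

    merged: list[list[str]] = []
    consumed: set[int] = set()
    for species, cluster_ids in sorted(clusters_of_species.items()):
        if len(cluster_ids) < 2 or species in mixed_species:
            continue
        members = [fine_clusters[ci] for ci in cluster_ids]
        inters = {inter_of[cl[0]] for cl in members}
        if len(inters) > 1:
            report.messages.append(
                f"species {species!r} splits across intermediate groups; "
                "clusters kept separate to preserve nesting"
            )
            continue
        support = _within_species_cluster_support(samples_by_id, members, k, metric)
        clean = all(v >= split_support for v in support.values())
        report.split_species.append(
            {
                "species": species,
                "n_clusters": len(members),
                "min_support": min(support.values()),
                "action": "split" if clean else "merge",
            }
        )
        if not clean:
            consumed.update(cluster_ids)
            merged.append(sorted(sid for cl in members for sid in cl))
    fine_groups = [
        cl for ci, cl in enumerate(fine_clusters) if ci not in consumed
    ] + merged
    fine_groups = sorted((sorted(g) for g in fine_groups), key=lambda g: g[0])

    # --- naming -------------------------------------------------------------
    inter_majority_series: dict[int, str] = {}
    for ci, cluster in enumerate(inter_clusters):
        series = [
            taxonomy[species_of[sid]].series_or_subgenus
            for sid in cluster
            if species_of[sid] in taxonomy
        ]
        inter_majority_series[ci] = _majority(series) if series else ""

    complex_to_series = {
        rec.complex_or_group: rec.series_or_subgenus for rec in taxonomy.values()
    }

    def group_descriptor(cluster, level):
        """(base key, members, flags, host) for one cluster, before clade numbering."""
        sp = sorted(named_species(cluster))
        flags: set[str] = set()
        host = None
        ici = inter_of[cluster[0]]
        majority_series = inter_majority_series[ici]
        member_series = sorted(
            {
                taxonomy[s].series_or_subgenus
                for s in sp
                if s in taxonomy
            }
        )
        if not sp:  # unnamed species
            flags.add(UNNAMED)
            inter_named = sorted(
                named_species([sid for sid in inter_clusters[ici]])
            )
            if inter_named:
                try:
                    host = _shared_taxon(inter_named, taxonomy)
                except (ValueError, KeyError):
                    host = majority_series
            else:
                host = _nearest_series(cluster, usable, taxonomy, species_of, D, ids)
            base_key = normalise_name(host)
        elif len(sp) == 1:
            base_key = normalise_name(sp[0])
            rec = taxonomy.get(sp[0])
            if rec and majority_series and rec.series_or_subgenus != majority_series:
                flags.add(CONFLICT)
                report.taxonomy_conflicts.append(
                    {
                        "group_members": sp,
                        "taxonomy_series": rec.series_or_subgenus,
                        "cluster_majority_series": majority_series,
                    }
                )
        else:
            member_complexes = sorted(
                {taxonomy[s].complex_or_group for s in sp if s in taxonomy}
            )
            if level == "fine" or len(member_complexes) > 1:
                flags.add(MULTI_SPECIES)
            if len(member_series) > 1:
                flags.add(CONFLICT)
                report.taxonomy_conflicts.append(
                    {
                        "group_members": sp,
                        "taxonomy_series": member_series,
                        "cluster_majority_series": majority_series,
                    }
                )
                base_key = normalise_name(majority_series)
            else:
                try:
                    base_key = normalise_name(_shared_taxon(sp, taxonomy))
                except KeyError:
                    base_key = normalise_name(majority_series)
            if level == "fine":
                report.multi_species_groups.append((base_key, tuple(sp)))
        if level == "fine" and geo_structure_species & set(sp):
            flags.add(GEO_STRUCTURE)
        return base_key, sp, flags, host

    def assign_labels(groups, level, single_fine_of=None):
        descriptors = [group_descriptor(g, level) for g in groups]
        by_base: Counter[str] = Counter(d[0] for d in descriptors)
        # clade numbers: groups sharing a base name (or any UNNAMED group)
        # ordered by descending size then smallest member id
        clade_number: dict[int, int | None] = {}
        for base in sorted(by_base):
            idxs = [i for i, d in enumerate(descriptors) if d[0] == base]
            needs_clades = len(idxs) > 1 or any(
                UNNAMED in descriptors[i][2] for i in idxs
            )
            if not needs_clades:
                clade_number[idxs[0]] = None
                continue
            ordered = sorted(idxs, key=lambda i: (-len(groups[i]), groups[i][0]))
            for n, i in enumerate(ordered, start=1):
                clade_number[i] = n
        labels = []
        for i, (base, sp, flags, host) in enumerate(descriptors):
            single_fine = True if single_fine_of is None else single_fine_of[i]
            if UNNAMED in flags:
                label = name_group(
                    [], level, taxonomy, flags=flags, clade_number=clade_number[i],
                    host_taxon=base,
                )
            elif CONFLICT in flags and len(sp) > 1:
                # no shared taxon: fall back to the majority series as base
                label = SpeciesGroupLabel(
                    base_name=base,
                    level=level,
                    clade_number=clade_number[i],
                    level_suffix="_f" if level == "fine" else "_i",
                    flags=frozenset(flags),
                )
            else:
                label = name_group(
                    sp, level, taxonomy, flags=flags, clade_number=clade_number[i],
                    single_fine=single_fine,
                )
            labels.append(label)
        return descriptors, labels

    fine_desc, fine_labels = assign_labels(fine_groups, "fine")
    inter_groups = [sorted(c) for c in inter_clusters]
    n_fine_in_inter = Counter(inter_of[g[0]] for g in fine_groups)
    inter_desc, inter_labels = assign_labels(
        inter_groups,
        "intermediate",
        single_fine_of={ci: n_fine_in_inter[ci] == 1 for ci in range(len(inter_groups))},
    )

    # --- coarse labels from taxonomy (majority series per fine group) ------
    fine_of = {sid: gi for gi, g in enumerate(fine_groups) for sid in g}
    coarse_of_fine: dict[int, str] = {}
    for gi, (base, sp, flags, host) in enumerate(fine_desc):
        series = [taxonomy[s].series_or_subgenus for s in sp if s in taxonomy]
        if series:
            coarse = _majority(series)
        elif host and host in complex_to_series:
            coarse = complex_to_series[host]
        elif host:
            coarse = host
        else:
            coarse = inter_majority_series[inter_of[fine_groups[gi][0]]]
        coarse_of_fine[gi] = coarse

    # nesting can be broken by taxonomy-derived coarse labels when an
    # intermediate cluster mixes series; force the majority series per
    # intermediate cluster so fine → intermediate → coarse stays functional
    coarse_of_inter = {
        ci: inter_majority_series[ci] or "unplaced" for ci in range(len(inter_clusters))
    }
    for gi in coarse_of_fine:
        ci = inter_of[fine_groups[gi][0]]
        if coarse_of_fine[gi] != coarse_of_inter[ci]:
            coarse_of_fine[gi] = coarse_of_inter[ci]

    coarse_labels = {
        gi: SpeciesGroupLabel(base_name=normalise_name(c), level="coarse")
        for gi, c in coarse_of_fine.items()
    }

    # --- assemble -----------------------------------------------------------
    group_metadata: dict[str, dict] = {}
    entries: list[IndexEntry] = []
    inter_label_of_cluster = {ci: inter_labels[ci].render() for ci in range(len(inter_groups))}
    for gi, group in enumerate(fine_groups):
        fine_str = fine_labels[gi].render()
        ci = inter_of[group[0]]
        inter_str = inter_label_of_cluster[ci]
        coarse_str = coarse_labels[gi].render()
        group_metadata.setdefault(
            fine_str,
            {
                "level": "fine",
                "members": fine_desc[gi][1],
                "flags": sorted(fine_labels[gi].flags),
                "notes": "",
            },
        )
        group_metadata.setdefault(
            inter_str,
            {
                "level": "intermediate",
                "members": inter_desc[ci][1],
                "flags": sorted(inter_labels[ci].flags),
                "notes": "",
            },
        )
        group_metadata.setdefault(
            coarse_str,
            {"level": "coarse", "members": [], "flags": [], "notes": ""},
        )
        for sid in group:
            entries.append(
                IndexEntry.from_sample(samples_by_id[sid], fine_str, inter_str, coarse_str)
            )
    # coarse member lists: union of constituent species
    for e in entries:
        sp = species_of[e.sample_id]
        if sp and sp not in group_metadata[e.coarse]["members"]:
            group_metadata[e.coarse]["members"].append(sp)
    for meta in group_metadata.values():
        meta["members"] = sorted(meta["members"])

    index = ReferenceIndex(
        version=version,
        k=k,
        metric=metric,
        entries=tuple(entries),
        group_metadata=group_metadata,
        fine_threshold=fine_t,
        intermediate_threshold=intermediate_t,
    )
    return index, report


def _nearest_series(cluster, usable, taxonomy, species_of, D, ids):
    """Series of the taxonomically placed sample nearest to an unnamed cluster."""
    idx = {sid: i for i, sid in enumerate(ids)}
    best, best_series = None, "unplaced"
    for sid in cluster:
        for other in ids:
            sp = species_of[other]
            if other in cluster or sp not in taxonomy:
                continue
            d = D[idx[sid], idx[other]]
            if best is None or d < best:
                best, best_series = d, taxonomy[sp].series_or_subgenus
    return best_series


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FASTA_NAME = "haplotypes.fasta"
_LABELS_NAME = "labels.tsv"
_META_NAME = "meta.json"


class IndexBundleError(ValueError):
    """Malformed or incomplete reference-index bundle on disk."""


def serialize_index(index: ReferenceIndex, path) -> Path:
    """Write an index bundle: FASTA + labels TSV + JSON metadata.

    FASTA record ids are ``sample_id.target_id.allele_index``, so those
    identifiers must not contain ``.``.  Output is fully sorted; two
    serializations of equal indexes are byte-identical.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if not index.version:
        raise ValueError("index version string is required for serialization")

    fasta_lines = []
    label_rows = []
    for e in index.entries:
        if "." in e.sample_id:
            raise ValueError(f"sample id {e.sample_id!r} must not contain '.'")
        label_rows.append(
            f"{e.sample_id}\t{e.country}\t{e.fine}\t{e.intermediate}\t{e.coarse}"
        )
        for target, alleles in e.haplotypes:
            if "." in target:
                raise ValueError(f"target id {target!r} must not contain '.'")
            for ai, seq in enumerate(alleles):
                fasta_lines.append(f">{e.sample_id}.{target}.{ai}\n{seq}")
    (path / _FASTA_NAME).write_text("\n".join(fasta_lines) + "\n")
    header = "sample_id\tcountry\tfine\tintermediate\tcoarse"
    (path / _LABELS_NAME).write_text("\n".join([header, *label_rows]) + "\n")
    meta = {
        "version": index.version,
        "k": index.k,
        "metric": index.metric,
        "fine_threshold": index.fine_threshold,
        "intermediate_threshold": index.intermediate_threshold,
        "group_metadata": index.group_metadata,
    }
    (path / _META_NAME).write_text(
        json.dumps(meta, sort_keys=True, indent=2, ensure_ascii=False) + "\n"
    )
    return path


def load_index(path, expected_version: str | None = None) -> ReferenceIndex:
    """Load an index bundle written by :func:`serialize_index`.

    Warns when ``expected_version`` is given and does not match the bundle.
    Raises :class:`IndexBundleError` naming any missing or malformed file.
    """
    path = Path(path)
    for name in (_FASTA_NAME, _LABELS_NAME, _META_NAME):
        if not (path / name).exists():
            raise IndexBundleError(
                f"index bundle at {path} is missing required file {name!r}"
            )
    try:
        meta = json.loads((path / _META_NAME).read_text())
    except json.JSONDecodeError as exc:
        raise IndexBundleError(f"malformed {_META_NAME} in {path}: {exc}") from exc
    labels = pd.read_csv(path / _LABELS_NAME, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "country", "fine", "intermediate", "coarse"}
    if not required <= set(labels.columns):
        raise IndexBundleError(
            f"{_LABELS_NAME} is missing columns "
            f"{sorted(required - set(labels.columns))}"
        )

    from Bio import SeqIO

    haps: dict[str, dict[str, dict[int, str]]] = defaultdict(lambda: defaultdict(dict))
    for record in SeqIO.parse(str(path / _FASTA_NAME), "fasta"):
        try:
            sample_id, target, allele = record.id.rsplit(".", 2)
            allele_i = int(allele)
        except ValueError as exc:
            raise IndexBundleError(
                f"FASTA record id {record.id!r} does not parse as "
                "sample_id.target_id.allele_index"
            ) from exc
        haps[sample_id][target][allele_i] = str(record.seq).upper()

    entries = []
    for row in labels.itertuples(index=False):
        sample_haps = haps.get(row.sample_id, {})
        hap_tuple = tuple(
            (t, tuple(sample_haps[t][i] for i in sorted(sample_haps[t])))
            for t in sorted(sample_haps)
        )
        entries.append(
            IndexEntry(
                sample_id=row.sample_id,
                country=row.country,
                haplotypes=hap_tuple,
                fine=row.fine,
                intermediate=row.intermediate,
                coarse=row.coarse,
            )
        )
    version = meta.get("version", "")
    if expected_version is not None and version != expected_version:
        warnings.warn(
            f"index bundle version {version!r} does not match expected "
            f"{expected_version!r}",
            stacklevel=2,
        )
    return ReferenceIndex(
        version=version,
        k=int(meta.get("k", 8)),
        metric=meta.get("metric", "min"),
        entries=tuple(entries),
        group_metadata=meta.get("group_metadata", {}),
        fine_threshold=float(meta.get("fine_threshold", 0.1)),
        intermediate_threshold=float(meta.get("intermediate_threshold", 0.3)),
    )
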