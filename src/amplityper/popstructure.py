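"""Within-group population structure from amplicon k-mer content.

Three complementary views of structure below the species-group level:

- :func:`variable_kmer_pca` — PCA of per-sample k-mer counts (k = 8 by
  default) summed over all targets and alleles, restricted to the
  "variable" k-mers whose counts differ between samples;
- :func:`haplotype_sharing` — for each allele of a focal cohort, the set of
  populations carrying an identical sequence at the same target (exact
  match only; a private allele has an empty sharing set);
- :func:`distance_heatmap_matrix` — the pairwise distance matrix ordered by
  (coarse, intermediate, fine, sample id) with group boundary indices, the
  computational contract behind the usual annotated heatmap.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .samples import Sample

__all__ = [
    "KmerCountMatrix",
    "SharingPattern",
    "VariableKmerPCA",
    "variable_kmer_pca",
    "kmer_count_matrix",
    "haplotype_sharing",
    "distance_heatmap_matrix",
    "HeatmapMatrix",
]


@dataclass
class KmerCountMatrix:
    """Per-sample k-mer counts summed over all targets and alleles."""

    sample_ids: list[str]
    kmers: list[str]
    counts: np.ndarray  # shape (n_samples, n_kmers), non-negative ints


@dataclass(frozen=True)
class SharingPattern:
    """One focal allele and the populations carrying an identical sequence."""

    sample_id: str
    target_id: str
    allele_index: int
    sharing_set: frozenset[str]


def kmer_count_matrix(
    samples: Sequence[Sample], k: int = 8, binary: bool = False, variable_only: bool = True
) -> KmerCountMatrix:
    """Build the samples × k-mers count matrix.

    Counts are occurrences of each k-mer summed over every allele of every
    target (``binary=True`` records presence/absence instead).  With
    ``variable_only`` (the default) only columns with at least two distinct
    values across samples are retained.
    """
    ordered = sorted(samples, key=lambda s: s.sample_id)
    per_sample: list[Counter[str]] = []
    for s in ordered:
        counts: Counter[str] = Counter()
        # every allele entry counts, so a homozygous diploid target
        # contributes its k-mers twice, exactly like a heterozygous one
        for hap in s.iter_haplotypes():
            seq = hap.sequence.upper()
            for i in range(len(seq) - k + 1):
                window = seq[i : i + k]
                if "N" not in window:
                    counts[window] += 1
        per_sample.append(counts)
    kmers = sorted(set().union(*per_sample)) if per_sample else []
    X = np.zeros((len(ordered), len(kmers)), dtype=np.int64)
    pos = {km: j for j, km in enumerate(kmers)}
    for i, counts in enumerate(per_sample):
        for km, c in counts.items():
            X[i, pos[km]] = c
    if binary:
        X = (X > 0).astype(np.int64)
    if variable_only and len(kmers):
        variable = np.array([len(np.unique(X[:, j])) > 1 for j in range(X.shape[1])])
        X = X[:, variable]
        kmers = [km for km, keep in zip(kmers, variable) if keep]
    return KmerCountMatrix([s.sample_id for s in ordered], kmers, X)


class VariableKmerPCA(BaseEstimator, TransformerMixin):
    """PCA of per-sample variable k-mer counts.

    Centred (unscaled by default) principal components of the variable
    k-mer count matrix.  Component signs are fixed by making each
    component's largest-magnitude loading positive, so projections are
    deterministic.

    Parameters
    ----------
    k : int, default 8
    n_components : int, default 2
    binary : bool, default False
        Use presence/absence instead of counts.
    scale : bool, default False
        Standardise columns to unit variance before the decomposition.

    Attributes
    ----------
    kmers_ : list of retained variable k-mers
    components_, explained_variance_ratio_, mean_ : as in sklearn PCA
    sample_ids_ : sample order of the fitted matrix
    """

    def __init__(self, k: int = 8, n_components: int = 2, binary: bool = False, scale: bool = False):
        self.k = k
        self.n_components = n_components
        self.binary = binary
        self.scale = scale

    def fit(self, samples: Sequence[Sample], y=None):
        matrix = kmer_count_matrix(samples, k=self.k, binary=self.binary)
        if len(matrix.sample_ids) < 3:
            raise ValueError("PCA needs at least 3 samples")
        if not matrix.kmers:
            raise ValueError(
                "no variable k-mers: the samples are k-mer identical"
            )
        X = matrix.counts.astype(float)
        self.scale_ = X.std(axis=0, ddof=0) if self.scale else None
        if self.scale_ is not None:
            X = X / self.scale_
        n_comp = min(self.n_components, X.shape[0] - 1, X.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full")
        pca.fit(X)
        # deterministic sign: largest-magnitude loading positive per component
        signs = np.array(
            [np.sign(c[np.argmax(np.abs(c))]) or 1.0 for c in pca.components_]
        )
        self.components_ = pca.components_ * signs[:, None]
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.mean_ = pca.mean_
        self.kmers_ = matrix.kmers
        self.sample_ids_ = matrix.sample_ids
        return self

    def transform(self, samples: Sequence[Sample]) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise ValueError("VariableKmerPCA is not fitted")
        matrix = kmer_count_matrix(samples, k=self.k, binary=self.binary, variable_only=False)
        pos = {km: j for j, km in enumerate(matrix.kmers)}
        X = np.zeros((len(matrix.sample_ids), len(self.kmers_)))
        for jj, km in enumerate(self.kmers_):
            if km in pos:
                X[:, jj] = matrix.counts[:, pos[km]]
        if self.scale_ is not None:
            X = X / self.scale_
        return (X - self.mean_) @ self.components_.T


@dataclass
class PCAResult:
    sample_ids: list[str]
    coordinates: np.ndarray
    explained_variance_pct: np.ndarray
    kmers: list[str]


def variable_kmer_pca(
    samples: Sequence[Sample], k: int = 8, n_components: int = 2, binary: bool = False
) -> PCAResult:
    """Project samples along principal components of variable k-mer counts.

    Returns per-sample coordinates (in sorted sample-id order) and the
    percentage of variance explained per component.
    """
    est = VariableKmerPCA(k=k, n_components=n_components, binary=binary).fit(samples)
    ordered = sorted(samples, key=lambda s: s.sample_id)
    coords = est.transform(ordered)
    return PCAResult(
        sample_ids=est.sample_ids_,
        coordinates=coords,
        explained_variance_pct=est.explained_variance_ratio_ * 100.0,
        kmers=est.kmers_,
    )


def haplotype_sharing(
    focal: Sequence[Sample], populations: Mapping[str, Sequence[Sample]]
) -> tuple[list[SharingPattern], dict[frozenset, int]]:
    """Exact-sequence sharing of focal alleles with labelled populations.

    Each distinct target sequence carried by a focal sample is one
    haplotype; its sharing set is the set of population labels containing an
    identical sequence at the same target.  Focal samples must not appear in
    ``populations``.  Returns per-allele patterns plus bar-plot-ready counts
    of alleles per unique sharing set (the empty set counts private
    alleles).
    """
    focal_ids = {s.sample_id for s in focal}
    for label, members in populations.items():
        clash = focal_ids & {s.sample_id for s in members}
        if clash:
            raise ValueError(
                f"population {label!r} overlaps the focal cohort: {sorted(clash)}"
            )
    pop_sequences: dict[str, dict[str, set[str]]] = {}
    for label, members in populations.items():
        per_target: dict[str, set[str]] = {}
        for s in members:
            for target in s.targets:
                per_target.setdefault(target, set()).update(s.alleles(target))
        pop_sequences[label] = per_target

    patterns: list[SharingPattern] = []
    counts: dict[frozenset, int] = {}
    # per allele entry (two per diploid individual), not per distinct sequence
    for s in sorted(focal, key=lambda x: x.sample_id):
        for hap in s.iter_haplotypes():
            sharing = frozenset(
                label
                for label, per_target in sorted(pop_sequences.items())
                if hap.sequence in per_target.get(hap.target_id, ())
            )
            patterns.append(
                SharingPattern(s.sample_id, hap.target_id, hap.allele_index, sharing)
            )
            counts[sharing] = counts.get(sharing, 0) + 1
    return patterns, counts


@dataclass
class HeatmapMatrix:
    """Ordered pairwise distance matrix with nested group boundaries."""

    sample_ids: list[str]
    matrix: np.ndarray
    boundaries: dict[str, list[int]] = field(default_factory=dict)
    unlabelled: list[str] = field(default_factory=list)


def distance_heatmap_matrix(
    samples: Sequence[Sample],
    labels: Mapping[str, tuple[str, str, str]],
    k: int = 8,
    metric: str = "min",
    D: np.ndarray | None = None,
    ids: Sequence[str] | None = None,
) -> HeatmapMatrix:
    """Pairwise distance matrix ordered by (coarse, intermediate, fine, id).

    ``labels`` maps sample id to its ``(fine, intermediate, coarse)`` label
    triple; unlabelled samples are ordered last and flagged.  ``boundaries``
    gives, per level, the index after each group's last sample — the
    positions where annotation lines would be drawn.  A precomputed matrix
    can be supplied via ``D``/``ids``.
    """
    from .reference import pairwise_distance_matrix

    if len(samples) < 1:
        raise ValueError("at least one sample is required")
    if D is None:
        ids, D = pairwise_distance_matrix(samples, k=k, metric=metric)
    elif ids is None:
        raise ValueError("ids must accompany a precomputed distance matrix")

    def sort_key(sid: str):
        if sid in labels:
            fine, inter, coarse = labels[sid]
            return (0, coarse, inter, fine, sid)
        return (1, "", "", "", sid)

    order = sorted(range(len(ids)), key=lambda i: sort_key(ids[i]))
    ordered_ids = [ids[i] for i in order]
    M = np.asarray(D)[np.ix_(order, order)]

    boundaries: dict[str, list[int]] = {"fine": [], "intermediate": [], "coarse": []}
    for level, pos in (("fine", 0), ("intermediate", 1), ("coarse", 2)):
        prev = None
        for i, sid in enumerate(ordered_ids):
            cur = labels.get(sid, (None, None, None))[pos]
            if i > 0 and cur != prev:
                boundaries[level].append(i)
            prev = cur
    unlabelled = [sid for sid in ordered_ids if sid not in labels]
    return HeatmapMatrix(ordered_ids, M, boundaries, unlabelled)
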