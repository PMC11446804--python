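"""k-mer set extraction and normalised k-mer distances.

The distance kernel underlying both reference-index construction and species
assignment.  A haplotype is represented by its set of distinct k-mers
(default k = 8, forward strand, since panel primers fix amplicon
orientation).  The default distance between two haplotypes is the
min-normalised set overlap

    d(A, B) = 1 - |A ∩ B| / min(|A|, |B|)

which maps a short haplotype fully contained in a longer one to 0, making it
robust to amplicon length variation.  Jaccard and Sørensen–Dice
normalisations are available as alternatives.

Sample-to-sample distance averages the haplotype distance over all allele
pairs at each shared target and then over shared targets, i.e. it is
normalised over alleles and targets; targets recovered in only one of the
two samples are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

from .samples import Sample

__all__ = [
    "KmerProfile",
    "extract_kmers",
    "haplotype_distance",
    "sequence_distance",
    "sample_distance",
    "DISTANCE_METRICS",
]

DISTANCE_METRICS = ("min", "jaccard", "dice")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class KmerProfile:
    """The set of distinct k-mers of one haplotype sequence.

    Invariants: every element has length ``k`` over {A,C,G,T}; the set is
    non-empty whenever ``source_length >= k`` and the sequence is not
    saturated with N; ``len(kmers) <= source_length - k + 1``.
    """

    k: int
    kmers: frozenset[str]
    source_length: int


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=1 << 18)
def _kmer_set(sequence: str, k: int, canonical: bool) -> frozenset[str]:
    kmers: set[str] = set()
    for i in range(len(sequence) - k + 1):
        window = sequence[i : i + k]
        if "N" in window:
            continue
        if canonical:
            window = min(window, _revcomp(window))
        kmers.add(window)
    return frozenset(kmers)


def extract_kmers(sequence: str, k: int = 8, canonical: bool = False) -> KmerProfile:
    """Extract the set of distinct k-mers of a DNA sequence.

    Windows containing ``N`` are skipped (ambiguous consensus bases must not
    fabricate spurious k-mers).  With ``canonical=True`` each k-mer is folded
    with its reverse complement; the default keeps the forward strand only.

    Raises
    ------
    ValueError
        If ``k < 1`` or the sequence is shorter than ``k``.
    """
    if k < 1:
        raise ValueError(f"k must be a positive integer, got {k}")
    sequence = sequence.upper()
    if len(sequence) < k:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than k={k}: "
            f"{sequence!r}"
        )
    return KmerProfile(k=k, kmers=_kmer_set(sequence, k, canonical), source_length=len(sequence))


def haplotype_distance(a: KmerProfile, b: KmerProfile, metric: str = "min") -> float:
    """Normalised k-mer distance between two haplotype profiles, in [0, 1].

    ``metric`` selects the overlap normalisation:

    - ``"min"`` (default): ``1 - |A∩B| / min(|A|, |B|)``
    - ``"jaccard"``: ``1 - |A∩B| / |A∪B|``
    - ``"dice"``: ``1 - 2|A∩B| / (|A| + |B|)``
    """
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} != {b.k}")
    if not a.kmers or not b.kmers:
        raise ValueError("cannot compute a k-mer distance for an empty profile")
    shared = len(a.kmers & b.kmers)
    if metric == "min":
        denom = min(len(a.kmers), len(b.kmers))
    elif metric == "jaccard":
        denom = len(a.kmers) + len(b.kmers) - shared
    elif metric == "dice":
        return 1.0 - 2.0 * shared / (len(a.kmers) + len(b.kmers))
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {DISTANCE_METRICS}")
    return 1.0 - shared / denom


def sequence_distance(a: str, b: str, k: int = 8, metric: str = "min", canonical: bool = False) -> float:
    """Convenience wrapper: k-mer distance between two raw sequences."""
    return haplotype_distance(
        extract_kmers(a, k, canonical), extract_kmers(b, k, canonical), metric=metric
    )


def sample_distance(
    x: Sample,
    y: Sample,
    k: int = 8,
    metric: str = "min",
    canonical: bool = False,
) -> float:
    """Normalised k-mer distance between two samples, in [0, 1].

    For each target recovered in both samples, the mean haplotype distance
    over all allele pairs (one allele from ``x`` crossed with one from ``y``)
    is taken; the sample distance is the mean of these per-target values.
    Targets recovered in only one sample do not contribute.

    Raises
    ------
    ValueError
        If the two samples share no recovered target, which makes them
        incomparable (as opposed to maximally distant).
    """
    shared_targets = sorted(set(x.haplotypes) & set(y.haplotypes))
    if not shared_targets:
        raise ValueError(
            f"samples {x.sample_id!r} and {y.sample_id!r} share no recovered "
            "target: distance is undefined (not comparable), not 1.0"
        )
    per_target = []
    for target in shared_targets:
        pairs = [
            haplotype_distance(
                extract_kmers(sa, k, canonical), extract_kmers(sb, k, canonical), metric
            )
            for sa, sb in product(x.alleles(target), y.alleles(target))
        ]
        per_target.append(sum(pairs) / len(pairs))
    return sum(per_target) / len(per_target)
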