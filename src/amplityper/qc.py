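"""Contamination-risk categorisation and basic sample QC.

A diploid specimen carries at most two alleles per target, so a target with
more than two distinct haplotype sequences ("multiallelic") signals
cross-sample contamination.  Risk categories combine the multiallelic count
with total read support:

- ``low``: >= 1,000 reads and 0 multiallelic targets
- ``medium``: < 1,000 reads, or 1–2 multiallelic targets
- ``high``: 3–4 multiallelic targets
- ``very_high``: more than 4 multiallelic targets

Where rules overlap (e.g. 800 reads and 4 multiallelic targets), the
highest-risk applicable category wins — the conservative reading.
"""

from __future__ import annotations

from dataclasses import dataclass

from .samples import Sample

__all__ = [
    "ContaminationCategory",
    "CATEGORIES",
    "count_multiallelic",
    "contamination_category",
    "sample_contamination",
]

CATEGORIES = ("low", "medium", "high", "very_high")


@dataclass(frozen=True)
class ContaminationCategory:
    """Contamination risk category with the inputs that determined it."""

    category: str
    total_reads: int
    n_multiallelic: int


def count_multiallelic(sample: Sample, max_alleles: int = 2) -> int:
    """Number of targets with more than ``max_alleles`` distinct sequences.

    The default of 2 reflects diploidy; pass ``max_alleles=1`` for haploid
    panels.
    """
    return sum(
        1 for target in sample.haplotypes if len(sample.alleles(target)) > max_alleles
    )


def contamination_category(total_reads: int, n_multiallelic: int) -> ContaminationCategory:
    """Map (total reads, multiallelic-target count) to a risk category."""
    if total_reads < 0 or n_multiallelic < 0:
        raise ValueError(
            f"reads and multiallelic counts must be non-negative, got "
            f"({total_reads}, {n_multiallelic})"
        )
    if n_multiallelic > 4:
        category = "very_high"
    elif n_multiallelic >= 3:
        category = "high"
    elif total_reads < 1000 or n_multiallelic >= 1:
        category = "medium"
    else:
        category = "low"
    return ContaminationCategory(category, total_reads, n_multiallelic)


def sample_contamination(sample: Sample, max_alleles: int = 2) -> ContaminationCategory:
    """Contamination risk of a sample from its reads and allele counts."""
    return contamination_category(sample.total_reads, count_multiallelic(sample, max_alleles))
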