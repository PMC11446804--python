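"""In-memory containers for per-sample amplicon haplotype data.

A specimen sequenced on a multi-locus amplicon panel yields, per target
locus, up to two haplotype sequences (the diploid alleles), each with read
support.  ``Sample`` holds the recovered haplotypes of one specimen keyed by
target identifier, together with collection metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["TargetHaplotype", "Sample"]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True, order=True)
class TargetHaplotype:
    """One amplicon sequence at one panel target in one sample."""

    target_id: str
    allele_index: int
    sequence: str
    read_count: int = 0

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"haplotype {self.target_id}.{self.allele_index} contains "
                f"invalid characters {sorted(bad)}; allowed: A, C, G, T, N"
            )
        if self.allele_index < 0:
            raise ValueError("allele_index must be non-negative")
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")


@dataclass
class Sample:
    """A specimen's recovered haplotypes across panel targets plus metadata."""

    sample_id: str
    haplotypes: dict[str, tuple[TargetHaplotype, ...]] = field(default_factory=dict)
    country: str = ""
    species_label: str | None = None
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_haplotypes(
        cls,
        sample_id: str,
        haplotypes: Iterable[TargetHaplotype],
        country: str = "",
        species_label: str | None = None,
        metadata: Mapping | None = None,
    ) -> "Sample":
        """Build a sample from a flat haplotype iterable, grouping by target.

        Raises ``ValueError`` on duplicate ``(target_id, allele_index)`` keys.
        """
        by_target: dict[str, list[TargetHaplotype]] = {}
        seen: set[tuple[str, int]] = set()
        for hap in haplotypes:
            key = (hap.target_id, hap.allele_index)
            if key in seen:
                raise ValueError(
                    f"duplicate haplotype key ({sample_id}, {hap.target_id}, "
                    f"{hap.allele_index})"
                )
            seen.add(key)
            by_target.setdefault(hap.target_id, []).append(hap)
        grouped = {
            t: tuple(sorted(haps, key=lambda h: h.allele_index))
            for t, haps in sorted(by_target.items())
        }
        return cls(
            sample_id=sample_id,
            haplotypes=grouped,
            country=country,
            species_label=species_label,
            metadata=dict(metadata or {}),
        )

    @property
    def targets(self) -> tuple[str, ...]:
        """Sorted identifiers of targets with at least one recovered haplotype."""
        return tuple(sorted(self.haplotypes))

    @property
    def n_targets(self) -> int:
        return len(self.haplotypes)

    @property
    def total_reads(self) -> int:
        return sum(h.read_count for haps in self.haplotypes.values() for h in haps)

    def alleles(self, target_id: str) -> tuple[str, ...]:
        """Distinct haplotype sequences recovered at ``target_id`` (sorted)."""
        return tuple(sorted({h.sequence for h in self.haplotypes.get(target_id, ())}))

    def iter_haplotypes(self) -> Iterable[TargetHaplotype]:
        for target in self.targets:
            yield from self.haplotypes[target]
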