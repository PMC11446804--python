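"""Synthetic amplicon panels and cohorts with known truth.

Generates a multi-locus panel (62 targets by default, lengths 150–300 bp)
for a hierarchically structured set of synthetic species — series → group/
complex → species → optional clades — by substitution-only evolution down
the species tree, then samples diploid specimens with within-species
polymorphism, target dropout, skewed read counts and optional cross-sample
contamination.  Every downstream module (index construction, assignment,
QC, population structure) is testable against the retained truth labels.

The default branch rates are calibrated to the clustering regimes the
reference-index thresholds carve out for the min-normalised 8-mer distance:

- alleles of one species/clade: expected sample distance ≈ 0.03 (< 0.1, one
  fine cluster);
- clades of a split species: ≈ 0.15, and sibling "close pair" species:
  ≈ 0.08 (below 0.1, merging into a multi-species fine group);
- species within a group: ≈ 0.22–0.27 (between 0.1 and 0.3, one
  intermediate cluster, separate fine clusters);
- groups within a series: ≈ 0.66 and different series ≈ 0.97 (> 0.3).

These are expectations over the 62 targets; per-panel realisations vary
slightly, so calibration tests assert them statistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .reference import TaxonomyRecord
from .samples import Sample, TargetHaplotype

__all__ = [
    "BranchRates",
    "SpeciesSpec",
    "SimulatedPanel",
    "SimulatedSample",
    "default_species_specs",
    "simulate_panel",
    "simulate_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Default country pool used to spread species and clades geographically.
COUNTRIES = ("Gabon", "Ghana", "Kenya", "Madagascar", "Senegal", "Tanzania", "Uganda")


@dataclass(frozen=True)
class BranchRates:
    """Per-site substitution probabilities for each branch class of the tree."""

    series: float = 0.12
    group: float = 0.05
    species: float = 0.013
    clade: float = 0.008
    sibling: float = 0.003
    polymorphism: float = 0.002

    def validate(self) -> None:
        for name in ("series", "group", "species", "clade", "sibling", "polymorphism"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"rate {name}={v} must lie in [0, 1)")


@dataclass(frozen=True)
class SpeciesSpec:
    """Placement of one synthetic species in the simulated tree.

    ``n_clades > 1`` models a species split into diverged populations;
    ``close_pair`` names a partner species sharing a recent ancestor, so
    the two fall below the fine clustering threshold.
    """

    species: str
    group: str
    series: str
    n_clades: int = 1
    close_pair: str | None = None


def default_species_specs() -> tuple[SpeciesSpec, ...]:
    """A calibrated 10-species panel exercising every clustering regime.

    Synthetic species names over four series and seven groups/complexes:
    one close sibling pair below the fine threshold (An_albus/An_alcis),
    one species with two sympatric clades (An_bifidus), one with two
    geographically separated clades (An_geminus), a three-group series
    (Gamma) and an isolated single-species series (Delta).
    """
    return (
        SpeciesSpec("An_albus", "Alphafirst complex", "Alpha series", close_pair="An_alcis"),
        SpeciesSpec("An_alcis", "Alphafirst complex", "Alpha series", close_pair="An_albus"),
        SpeciesSpec("An_brevis", "Betafirst complex", "Beta series"),
        SpeciesSpec("An_bucolicus", "Betafirst complex", "Beta series"),
        SpeciesSpec("An_bifidus", "Betasecond group", "Beta series", n_clades=2),
        SpeciesSpec("An_caelum", "Gammafirst group", "Gamma series"),
        SpeciesSpec("An_cinereus", "Gammasecond complex", "Gamma series"),
        SpeciesSpec("An_geminus", "Gammasecond complex", "Gamma series", n_clades=2),
        SpeciesSpec("An_cursor", "Gammathird group", "Gamma series"),
        SpeciesSpec("An_dorsalis", "Deltafirst group", "Delta series"),
    )


@dataclass(frozen=True)
class SimulatedPanel:
    """Per-species (and per-clade) reference sequences for every target."""

    n_targets: int
    target_ids: tuple[str, ...]
    target_lengths: tuple[int, ...]
    specs: tuple[SpeciesSpec, ...]
    rates: BranchRates
    seed: int
    # (species, clade) -> tuple of per-target sequences
    sequences: Mapping[tuple[str, int], tuple[str, ...]] = field(default_factory=dict)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s.species for s in self.specs)

    def taxonomy(self) -> dict[str, TaxonomyRecord]:
        return {
            s.species: TaxonomyRecord(
                species=s.species,
                complex_or_group=s.group,
                series_or_subgenus=s.series,
            )
            for s in self.specs
        }

    def clades(self, species: str) -> tuple[int, ...]:
        spec = next(s for s in self.specs if s.species == species)
        return tuple(range(spec.n_clades))


@dataclass
class SimulatedSample(Sample):
    """A simulated specimen with its generating truth retained."""

    true_species: str = ""
    true_clade: int = 0
    contaminant_species: str | None = None
    n_contaminant_targets: int = 0
    dropout_targets: tuple[str, ...] = ()


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hits = rng.random(len(seq)) < rate
    n = int(hits.sum())
    if n:
        # shift by 1..3 mod 4 guarantees a different base
        out[hits] = (out[hits] + rng.integers(1, 4, size=n)) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def simulate_panel(
    specs: Sequence[SpeciesSpec] | None = None,
    n_targets: int = 62,
    seed: int = 0,
    rates: BranchRates | None = None,
    length_range: tuple[int, int] = (150, 300),
) -> SimulatedPanel:
    """Evolve per-species reference sequences down the synthetic tree.

    Deterministic given ``seed``.  Raises on fewer than two species or on an
    inconsistent tree (close pairs must be mutual and share a group).
    """
    specs = tuple(specs) if specs is not None else default_species_specs()
    rates = rates or BranchRates()
    rates.validate()
    if len(specs) < 2:
        raise ValueError("at least two species are required")
    by_name = {s.species: s for s in specs}
    if len(by_name) != len(specs):
        raise ValueError("duplicate species names in the tree specification")
    for s in specs:
        if s.n_clades < 1:
            raise ValueError(f"{s.species}: n_clades must be >= 1")
        if s.close_pair is not None:
            partner = by_name.get(s.close_pair)
            if partner is None or partner.close_pair != s.species:
                raise ValueError(
                    f"close pair {s.species}/{s.close_pair} must be mutual"
                )
            if partner.group != s.group:
                raise ValueError(
                    f"close pair {s.species}/{s.close_pair} must share a group"
                )

    rng = np.random.default_rng(seed)
    lengths = tuple(int(x) for x in rng.integers(length_range[0], length_range[1] + 1, size=n_targets))
    target_ids = tuple(f"t{i + 1}" for i in range(n_targets))

    series_names = sorted({s.series for s in specs})
    groups = sorted({(s.series, s.group) for s in specs})
    pairs = sorted({tuple(sorted((s.species, s.close_pair))) for s in specs if s.close_pair})

    sequences: dict[tuple[str, int], list[str]] = {
        (s.species, c): [] for s in specs for c in range(s.n_clades)
    }
    for L in lengths:
        root = _random_sequence(rng, L)
        series_seq = {name: _mutate(rng, root, rates.series) for name in series_names}
        group_seq = {
            (ser, grp): _mutate(rng, series_seq[ser], rates.group) for ser, grp in groups
        }
        pair_seq = {
            pair: _mutate(rng, group_seq[(by_name[pair[0]].series, by_name[pair[0]].group)], rates.species)
            for pair in pairs
        }
        for s in specs:
            if s.close_pair:
                pair = tuple(sorted((s.species, s.close_pair)))
                tip = _mutate(rng, pair_seq[pair], rates.sibling)
            else:
                tip = _mutate(rng, group_seq[(s.series, s.group)], rates.species)
            for c in range(s.n_clades):
                clade_tip = _mutate(rng, tip, rates.clade) if s.n_clades > 1 else tip
                sequences[(s.species, c)].append(_to_str(clade_tip))
    return SimulatedPanel(
        n_targets=n_targets,
        target_ids=target_ids,
        target_lengths=lengths,
        specs=specs,
        rates=rates,
        seed=seed,
        sequences={k: tuple(v) for k, v in sequences.items()},
    )


def _sample_countries(panel: SimulatedPanel) -> dict[tuple[str, int], str]:
    """Deterministic country per (species, clade); clades of a split species
    are placed in different countries (geographic structure)."""
    out: dict[tuple[str, int], str] = {}
    i = 0
    for s in panel.specs:
        for c in range(s.n_clades):
            out[(s.species, c)] = COUNTRIES[i % len(COUNTRIES)]
            i += 1
    return out


def simulate_cohort(
    panel: SimulatedPanel,
    n_per_species: int = 5,
    dropout_rate: float = 0.0,
    contamination_rate: float = 0.0,
    n_contaminant_targets: int = 8,
    mean_total_reads: float = 1500.0,
    read_depth_sigma: float = 0.5,
    seed: int = 0,
    species: Iterable[str] | None = None,
    id_prefix: str = "sim",
) -> list[SimulatedSample]:
    """Draw diploid specimens from a simulated panel.

    Each specimen carries two alleles per target, independently mutated from
    its species (or clade) sequence at the polymorphism rate; each target is
    dropped with probability ``dropout_rate``.  With probability
    ``contamination_rate`` a specimen receives one extra allele from a
    random other species at ``n_contaminant_targets`` of its recovered
    targets.  Per-target read counts follow a negative-binomial model scaled
    by a log-normal per-sample depth factor, so total reads straddle the
    1,000-read QC boundary.  Deterministic given ``seed``.
    """
    for name, value in (
        ("dropout_rate", dropout_rate),
        ("contamination_rate", contamination_rate),
    ):
        if not 0 <= value <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {value}")
    rng = np.random.default_rng(seed)
    countries = _sample_countries(panel)
    wanted = tuple(species) if species is not None else panel.species
    unknown = set(wanted) - set(panel.species)
    if unknown:
        raise ValueError(f"species not in the panel: {sorted(unknown)}")

    poly = panel.rates.polymorphism
    samples: list[SimulatedSample] = []
    counter = 0
    for sp_name in wanted:
        spec = next(s for s in panel.specs if s.species == sp_name)
        for i in range(n_per_species):
            clade = i % spec.n_clades
            counter += 1
            sample_id = f"{id_prefix}{counter:04d}_{sp_name}"
            tip_seqs = panel.sequences[(sp_name, clade)]
            depth = float(np.exp(rng.normal(0.0, read_depth_sigma)))
            mean_per_target = mean_total_reads * depth / (2 * panel.n_targets)

            dropped = []
            haplotypes: list[TargetHaplotype] = []
            own_alleles: dict[str, list[str]] = {}
            for target_id, tip in zip(panel.target_ids, tip_seqs):
                if rng.random() < dropout_rate:
                    dropped.append(target_id)
                    continue
                tip_num = np.searchsorted(_BASES, np.frombuffer(tip.encode(), dtype="S1"))
                own_alleles[target_id] = [
                    _to_str(_mutate(rng, tip_num, poly)) for _ in range(2)
                ]
                for allele, seq in enumerate(own_alleles[target_id]):
                    reads = 1 + int(rng.negative_binomial(2, 2 / (2 + mean_per_target)))
                    haplotypes.append(TargetHaplotype(target_id, allele, seq, reads))

            # a contaminated target must become multiallelic (>2 distinct
            # sequences), so injection prefers targets whose two host
            # alleles already differ; the foreign allele is then a third
            # distinct sequence since the contaminant species is diverged
            contaminant: str | None = None
            contaminated_at: set[str] = set()
            if own_alleles and rng.random() < contamination_rate:
                others = [s for s in panel.species if s != sp_name]
                contaminant = others[int(rng.integers(len(others)))]
                het = sorted(t for t, al in own_alleles.items() if al[0] != al[1])
                hom = sorted(t for t in own_alleles if t not in het)
                pool = het + hom
                contaminated_at = set(pool[: min(n_contaminant_targets, len(pool))])
                for target_id in sorted(contaminated_at):
                    cont_tip = panel.sequences[(contaminant, 0)][
                        panel.target_ids.index(target_id)
                    ]
                    cont_arr = np.searchsorted(
                        _BASES, np.frombuffer(cont_tip.encode(), dtype="S1")
                    )
                    seq = _to_str(_mutate(rng, cont_arr, poly))
                    reads = 1 + int(rng.negative_binomial(2, 2 / (2 + mean_per_target / 4)))
                    haplotypes.append(TargetHaplotype(target_id, 2, seq, reads))

            base = Sample.from_haplotypes(
                sample_id,
                haplotypes,
                country=countries[(sp_name, clade)],
                species_label=sp_name,
            )
            samples.append(
                SimulatedSample(
                    sample_id=base.sample_id,
                    haplotypes=base.haplotypes,
                    country=base.country,
                    species_label=base.species_label,
                    metadata=base.metadata,
                    true_species=sp_name,
                    true_clade=clade,
                    contaminant_species=contaminant if contaminated_at else None,
                    n_contaminant_targets=len(contaminated_at),
                    dropout_targets=tuple(dropped),
                )
            )
    return samples
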