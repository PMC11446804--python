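"""Reference index: candidate selection, clustering, naming, serialization."""

import re

import numpy as np
import pytest

from amplityper import (
    build_index,
    cluster_at_threshold,
    load_index,
    name_group,
    select_candidates,
    serialize_index,
    simulate_cohort,
    simulate_panel,
)
from amplityper.reference import (
    CONFLICT,
    GEO_STRUCTURE,
    MULTI_SPECIES,
    UNNAMED,
    IndexBundleError,
    SpeciesGroupLabel,
    TaxonomyRecord,
)
from amplityper.simulate import SpeciesSpec

TAX = {
    "An. pretoriensis": TaxonomyRecord("An. pretoriensis", "Pretoriensis group", "Myzomyia series"),
    "An. sundaicus": TaxonomyRecord("An. sundaicus", "Sundaicus complex", "Pyretophorus series"),
    "An. epiroticus": TaxonomyRecord("An. epiroticus", "Sundaicus complex", "Pyretophorus series"),
    "An. pharoensis": TaxonomyRecord("An. pharoensis", "Cellia group", "Cellia series"),
}


# --- candidate selection ----------------------------------------------------

def test_selection_caps_single_country_at_five():
    pool = [(f"s{i:02d}", "An. pauliani", "Madagascar") for i in range(12)]
    picked = select_candidates(pool)
    assert len(picked) == 5
    assert [p[0] for p in picked] == [f"s{i:02d}" for i in range(5)]


def test_selection_spreads_over_countries_round_robin():
    countries = [f"C{j}" for j in range(7)]
    pool = [
        (f"s_{c}_{i}", "An. arabiensis", c) for c in countries for i in range(3)
    ]
    picked = select_candidates(pool)
    assert len(picked) == 10
    per_country = {c: sum(1 for p in picked if p[2] == c) for c in countries}
    assert set(per_country.values()) <= {1, 2}  # one or two per country
    assert len([c for c in per_country.values() if c > 0]) == 7


def test_selection_keeps_small_pools_whole():
    pool = [(f"s{i}", "An. pauliani", "Madagascar") for i in range(5)]
    assert len(select_candidates(pool)) == 5
    assert select_candidates([]) == []


def test_selection_caps_hold_on_random_pools(rng):
    species = [f"sp{i}" for i in range(6)]
    countries = [f"C{i}" for i in range(4)]
    pool = [
        (f"s{i:03d}", rng.choice(species), rng.choice(countries))
        for i in range(300)
    ]
    picked = select_candidates(pool)
    from collections import Counter

    by_species = Counter(p[1] for p in picked)
    by_pair = Counter((p[1], p[2]) for p in picked)
    assert all(v <= 10 for v in by_species.values())
    assert all(v <= 5 for v in by_pair.values())
    assert picked == select_candidates(pool)  # deterministic


# --- threshold clustering ---------------------------------------------------

def test_threshold_zero_isolates_and_large_threshold_merges():
    D = np.array([[0, 0.2, 0.4], [0.2, 0, 0.3], [0.4, 0.3, 0]])
    assert cluster_at_threshold(D, 0.0, list("abc")) == [["a"], ["b"], ["c"]]
    assert cluster_at_threshold(D, 0.9, list("abc")) == [["a", "b", "c"]]


def test_single_linkage_chains_through_intermediates():
    D = np.array([[0, 0.05, 0.2], [0.05, 0, 0.05], [0.2, 0.05, 0]])
    assert cluster_at_threshold(D, 0.1, list("ABC")) == [["A", "B", "C"]]


def test_boundary_pairs_split_under_strict_inequality():
    D = np.array([[0, 0.1], [0.1, 0]])
    assert cluster_at_threshold(D, 0.1, list("ab")) == [["a"], ["b"]]
    assert cluster_at_threshold(D, 0.1, list("ab"), strict=False) == [["a", "b"]]


def test_invalid_matrices_are_rejected():
    with pytest.raises(ValueError, match="symmetric"):
        cluster_at_threshold(np.array([[0, 0.1], [0.3, 0]]), 0.2)
    with pytest.raises(ValueError, match="diagonal"):
        cluster_at_threshold(np.array([[0.5, 0.1], [0.1, 0]]), 0.2)
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        cluster_at_threshold(np.array([[0, 1.7], [1.7, 0]]), 0.2)


def test_fine_partition_refines_intermediate_on_random_matrices(rng):
    """Single-linkage monotonicity: clusters at a lower threshold nest
    inside the clusters at any higher threshold."""
    for _ in range(20):
        n = int(rng.integers(4, 12))
        M = rng.random((n, n))
        D = np.triu(M, 1)
        D = D + D.T
        fine = cluster_at_threshold(D, 0.1)
        inter = cluster_at_threshold(D, 0.3)
        parent = {sid: i for i, cl in enumerate(inter) for sid in cl}
        for cl in fine:
            assert len({parent[sid] for sid in cl}) == 1


# --- naming -----------------------------------------------------------------

def test_single_species_fine_group_keeps_species_name():
    label = name_group(["An. pretoriensis"], "fine", TAX)
    assert label.render() == "An_pretoriensis"


def test_multi_species_fine_group_named_from_shared_complex():
    label = name_group(["An. sundaicus", "An. epiroticus"], "fine", TAX)
    assert label.render() == "Sundaicus_complex_f§"
    assert MULTI_SPECIES in label.flags


def test_unnamed_group_named_from_host_taxon():
    label = name_group(
        [], "fine", TAX, flags={UNNAMED}, clade_number=1, host_taxon="Myzomyia series"
    )
    assert label.render() == "Myzomyia_series_cl1_f^"


def test_flag_symbols_render_in_canonical_order():
    label = name_group(
        ["An. pharoensis"],
        "fine",
        TAX,
        flags={GEO_STRUCTURE, CONFLICT},
        clade_number=2,
    )
    assert label.render() == "An_pharoensis_cl2_f*†"


def test_intermediate_passthrough_omits_suffix_but_flagged_does_not():
    assert name_group(["An. pretoriensis"], "intermediate", TAX).render() == "An_pretoriensis"
    assert (
        name_group(["An. pretoriensis"], "intermediate", TAX, flags={CONFLICT}).render()
        == "An_pretoriensis_i*"
    )
    # a species split into clades is no longer a pass-through
    assert (
        name_group(["An. pretoriensis"], "intermediate", TAX, single_fine=False).render()
        == "An_pretoriensis_i"
    )


def test_name_group_demands_taxonomy_repair_without_shared_taxon():
    with pytest.raises(ValueError, match="taxonomy"):
        name_group(["An. sundaicus", "An. pharoensis"], "fine", TAX)


LABEL_GRAMMAR = re.compile(
    r"^[A-Za-z][A-Za-z0-9_]*?(_cl[1-9][0-9]*)?(_[fi])?[*§^†]*$"
)


def test_rendered_labels_match_convention_grammar(index):
    for label in (
        index.fine_labels + index.intermediate_labels + index.coarse_labels
    ):
        assert LABEL_GRAMMAR.match(label), label


def test_fine_label_suffix_invariant_is_enforced():
    with pytest.raises(ValueError, match="_f"):
        SpeciesGroupLabel("An_x", "fine", level_suffix="_f")  # no § and no clade
    with pytest.raises(ValueError, match="_f"):
        SpeciesGroupLabel("An_x", "fine", clade_number=1)  # clade requires _f


# --- index construction -----------------------------------------------------

def _mini_panel(specs, seed=7, n_targets=15):
    return simulate_panel(specs, n_targets=n_targets, seed=seed)


def test_separable_species_build_clean_index():
    specs = (
        SpeciesSpec("An_xa", "Xfirst group", "X series"),
        SpeciesSpec("An_xb", "Xsecond group", "X series"),
        SpeciesSpec("An_xc", "Yfirst group", "Y series"),
    )
    panel = _mini_panel(specs)
    cohort = simulate_cohort(panel, n_per_species=3, seed=8)
    index, report = build_index(cohort, panel.taxonomy(), prefilter=False)
    assert index.fine_labels == ("An_xa", "An_xb", "An_xc")
    assert index.intermediate_labels == ("An_xa", "An_xb", "An_xc")
    assert index.coarse_labels == ("X_series", "Y_series")
    assert not report.multi_species_groups
    assert not report.taxonomy_conflicts


def test_close_sibling_pair_collapses_to_multi_species_group():
    specs = (
        SpeciesSpec("An_pa", "Pair complex", "X series", close_pair="An_pb"),
        SpeciesSpec("An_pb", "Pair complex", "X series", close_pair="An_pa"),
        SpeciesSpec("An_far", "Far group", "X series"),
    )
    panel = _mini_panel(specs)
    cohort = simulate_cohort(panel, n_per_species=3, seed=9)
    index, report = build_index(cohort, panel.taxonomy(), prefilter=False)
    assert "Pair_complex_f§" in index.fine_labels
    assert index.group_metadata["Pair_complex_f§"]["members"] == ["An_pa", "An_pb"]
    assert ("Pair_complex", ("An_pa", "An_pb")) in report.multi_species_groups


def test_diverged_populations_become_numbered_clades_in_one_intermediate():
    specs = (
        SpeciesSpec("An_split", "Split group", "X series", n_clades=2),
        SpeciesSpec("An_other", "Other group", "X series"),
    )
    panel = _mini_panel(specs)
    cohort = simulate_cohort(panel, n_per_species=4, seed=10)
    index, report = build_index(cohort, panel.taxonomy(), prefilter=False)
    clades = [l for l in index.fine_labels if l.startswith("An_split_cl")]
    assert sorted(clades) == ["An_split_cl1_f", "An_split_cl2_f"]
    f2i = index.fine_to_intermediate()
    assert f2i["An_split_cl1_f"] == f2i["An_split_cl2_f"] == "An_split_i"
    assert any(s["species"] == "An_split" and s["action"] == "split" for s in report.split_species)


def test_thresholds_must_be_ordered(ref_cohort, taxonomy):
    with pytest.raises(ValueError, match="below"):
        build_index(ref_cohort[:6], taxonomy, fine_t=0.3, intermediate_t=0.1)


def test_hierarchy_is_functional_and_caps_hold(index, ref_cohort):
    f2i = {}
    f2c = {}
    for e in index.entries:
        assert f2i.setdefault(e.fine, e.intermediate) == e.intermediate
        assert f2c.setdefault(e.fine, e.coarse) == e.coarse
        assert e.fine in index.group_metadata
        assert e.intermediate in index.group_metadata
        assert e.coarse in index.group_metadata


def test_geo_structure_flag_is_passed_through(index):
    geminus = [l for l in index.fine_labels if l.startswith("An_geminus")]
    assert geminus and all(l.endswith("†") for l in geminus)


# --- serialization ----------------------------------------------------------

def test_bundle_round_trip_preserves_index(index, tmp_path):
    out = tmp_path / "bundle"
    serialize_index(index, out)
    loaded = load_index(out)
    assert loaded == index


def test_serialization_is_byte_deterministic(index, tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    serialize_index(index, a)
    serialize_index(index, b)
    for name in ("haplotypes.fasta", "labels.tsv", "meta.json"):
        assert (a / name).read_bytes() == (b / name).read_bytes()


def test_missing_bundle_file_is_named(index, tmp_path):
    out = tmp_path / "bundle"
    serialize_index(index, out)
    (out / "labels.tsv").unlink()
    with pytest.raises(IndexBundleError, match="labels.tsv"):
        load_index(out)


def test_version_mismatch_warns(index, tmp_path):
    out = tmp_path / "bundle"
    serialize_index(index, out)
    with pytest.warns(UserWarning, match="version"):
        load_index(out, expected_version="NNv999")
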