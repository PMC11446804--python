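"""Population structure: k-mer PCA, haplotype sharing, distance ordering."""

import numpy as np
import pytest

from amplityper import (
    Sample,
    TargetHaplotype,
    VariableKmerPCA,
    distance_heatmap_matrix,
    haplotype_sharing,
    kmer_count_matrix,
    simulate_cohort,
    simulate_panel,
    variable_kmer_pca,
)


def _sample(sample_id, seqs):
    return Sample.from_haplotypes(
        sample_id, [TargetHaplotype(f"t{i}", 0, s, 5) for i, s in enumerate(seqs)]
    )


def test_identical_samples_have_no_variable_kmers():
    samples = [_sample(f"s{i}", ["ACGTACGTACGT"]) for i in range(3)]
    with pytest.raises(ValueError, match="k-mer identical"):
        variable_kmer_pca(samples, k=4)


def test_counts_sum_over_targets_and_alleles():
    s = Sample.from_haplotypes(
        "s",
        [
            TargetHaplotype("t0", 0, "AAAAA", 1),  # AAAA twice
            TargetHaplotype("t0", 1, "AAAA", 1),  # AAAA once
            TargetHaplotype("t1", 0, "AAAAAA", 1),  # AAAA three times
        ],
    )
    other = Sample.from_haplotypes("z", [TargetHaplotype("t0", 0, "CCCC", 1)])
    m = kmer_count_matrix([s, other], k=4, variable_only=False)
    j = m.kmers.index("AAAA")
    assert m.counts[m.sample_ids.index("s"), j] == 6
    binary = kmer_count_matrix([s, other], k=4, binary=True, variable_only=False)
    assert binary.counts.max() == 1


def test_two_cluster_simulation_separates_on_pc1():
    """Two diverged populations of one species project apart along PC1 with
    a dominant explained-variance share, and the ordered distance matrix is
    block structured — the geographic-structure signature."""
    from amplityper.simulate import BranchRates, SpeciesSpec

    # tight clusters: low within-population polymorphism relative to the
    # between-population divergence
    panel = simulate_panel(
        (
            SpeciesSpec("An_geo", "Geo group", "G series", n_clades=2),
            SpeciesSpec("An_out", "Out group", "G series"),
        ),
        n_targets=25,
        seed=11,
        rates=BranchRates(polymorphism=0.0005),
    )
    cohort = [
        s
        for s in simulate_cohort(panel, n_per_species=8, seed=12)
        if s.true_species == "An_geo"
    ]
    clade_of = {s.sample_id: s.true_clade for s in cohort}
    result = variable_kmer_pca(cohort, k=8)
    assert result.explained_variance_pct[0] > 50.0
    pc1 = {sid: x for sid, x in zip(result.sample_ids, result.coordinates[:, 0])}
    a = [pc1[sid] for sid in pc1 if clade_of[sid] == 0]
    b = [pc1[sid] for sid in pc1 if clade_of[sid] == 1]
    assert max(a) < min(b) or max(b) < min(a)

    # distance blocks: within-clade mean < between-clade mean
    from amplityper import pairwise_distance_matrix

    ids, D = pairwise_distance_matrix(cohort)
    same = [
        D[i, j]
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if clade_of[ids[i]] == clade_of[ids[j]]
    ]
    diff = [
        D[i, j]
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if clade_of[ids[i]] != clade_of[ids[j]]
    ]
    assert np.mean(same) < np.mean(diff)


def test_hand_built_two_column_pca_matches_eigendecomposition():
    """4 samples over 2 variable k-mers: compare against the closed-form
    eigendecomposition of the 2x2 covariance matrix."""
    seqs = {
        "s1": "AAAA",  # AAAA x1
        "s2": "AAAAA",  # AAAA x2
        "s3": "CCCC",  # CCCC x1
        "s4": "CCCCC",  # CCCC x2
    }
    samples = [_sample(k, [v]) for k, v in seqs.items()]
    est = VariableKmerPCA(k=4, n_components=2).fit(samples)
    m = kmer_count_matrix(samples, k=4)
    X = m.counts.astype(float)
    C = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    np.testing.assert_allclose(
        est.explained_variance_ratio_, evals / evals.sum(), atol=1e-12
    )
    for comp, vec in zip(est.components_, evecs.T):
        vec = vec * np.sign(vec[np.argmax(np.abs(vec))])
        np.testing.assert_allclose(np.abs(comp), np.abs(vec), atol=1e-12)
    ratios = est.explained_variance_ratio_
    assert ratios.sum() <= 1.0 + 1e-12
    assert all(r1 >= r2 for r1, r2 in zip(ratios, ratios[1:]))


def test_sharing_patterns_exact_match_only():
    focal = [_sample("f1", ["ACGTACGTAC", "TTTTGGGGCC"])]
    pop_p = [_sample("p1", ["ACGTACGTAC"])]
    pop_q = [_sample("q1", ["ACGTACGTAC", "TTTTGGGGCA"])]  # second differs by 1 bp
    patterns, counts = haplotype_sharing(focal, {"P": pop_p, "Q": pop_q})
    by_target = {p.target_id: p.sharing_set for p in patterns}
    assert by_target["t0"] == {"P", "Q"}
    assert by_target["t1"] == frozenset()  # private: near-identical is not shared
    assert counts[frozenset({"P", "Q"})] == 1
    assert counts[frozenset()] == 1


def test_sharing_rejects_overlapping_cohorts():
    s = _sample("dup", ["ACGTACGTAC"])
    with pytest.raises(ValueError, match="overlap"):
        haplotype_sharing([s], {"P": [s]})


def test_sharing_fraction_tracks_known_private_mutation_rate(rng):
    """Focal alleles copy a population haplotype except for a 10% chance of
    carrying a private mutation: ~90% of alleles share with that population
    (binomial tolerance)."""
    pop_haps = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(40)]
    population = [
        Sample.from_haplotypes(
            f"p{i}",
            [TargetHaplotype(f"t{t}", 0, pop_haps[t], 5) for t in range(40)],
        )
        for i in range(2)
    ]
    n_private = 0
    focal_haps = []
    for t in range(40):
        seq = pop_haps[t]
        if rng.random() < 0.10:
            n_private += 1
            pos = int(rng.integers(len(seq)))
            seq = seq[:pos] + {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]] + seq[pos + 1 :]
        focal_haps.append(TargetHaplotype(f"t{t}", 0, seq, 5))
    focal = [Sample.from_haplotypes("f", focal_haps)]
    patterns, counts = haplotype_sharing(focal, {"P": population})
    shared = sum(1 for p in patterns if "P" in p.sharing_set)
    assert shared == len(patterns) - n_private
    assert counts.get(frozenset(), 0) == n_private
    assert shared / len(patterns) == pytest.approx(0.9, abs=0.12)


def test_sharing_separates_own_population_from_distant_one(panel):
    """A cohort shares far more alleles with its own population than with a
    distant species, which shares essentially nothing."""
    focal = simulate_cohort(panel, n_per_species=4, seed=21, species=["An_caelum"], id_prefix="f")
    same_pop = simulate_cohort(panel, n_per_species=8, seed=22, species=["An_caelum"], id_prefix="p")
    far_pop = simulate_cohort(panel, n_per_species=8, seed=23, species=["An_dorsalis"], id_prefix="d")
    patterns, _ = haplotype_sharing(focal, {"same": same_pop, "far": far_pop})
    n = len(patterns)
    shared_same = sum(1 for p in patterns if "same" in p.sharing_set) / n
    shared_far = sum(1 for p in patterns if "far" in p.sharing_set) / n
    assert shared_same > 0.4
    assert shared_far < 0.05
    assert shared_same > 10 * shared_far


def test_heatmap_matrix_ordering_and_boundaries():
    seqs = ["ACGTACGTACGTACGTACGT", "TTTTCCCCGGGGAAAATTTT"]
    samples = [
        _sample("a1", [seqs[0]]),
        _sample("a2", [seqs[0]]),
        _sample("b1", [seqs[1]]),
        _sample("b2", [seqs[1]]),
    ]
    labels = {
        "a1": ("fA", "iA", "cA"),
        "a2": ("fA", "iA", "cA"),
        "b1": ("fB", "iB", "cB"),
        "b2": ("fB", "iB", "cB"),
    }
    hm = distance_heatmap_matrix(samples, labels, k=8)
    assert hm.sample_ids == ["a1", "a2", "b1", "b2"]
    assert hm.boundaries["fine"] == [2]
    assert hm.boundaries["coarse"] == [2]
    assert hm.matrix.shape == (4, 4)
    assert hm.matrix[0, 1] == pytest.approx(0.0)
    assert hm.matrix[0, 2] == pytest.approx(1.0)


def test_heatmap_single_sample_and_unlabelled_flagging():
    s = _sample("only", ["ACGTACGTACGT"])
    hm = distance_heatmap_matrix([s], {"only": ("f", "i", "c")})
    assert hm.matrix.shape == (1, 1) and hm.matrix[0, 0] == 0.0

    extra = _sample("zz_unknown", ["ACGTACGTACGT"])
    hm = distance_heatmap_matrix([extra, s], {"only": ("f", "i", "c")})
    assert hm.sample_ids[-1] == "zz_unknown"
    assert hm.unlabelled == ["zz_unknown"]


def test_index_distances_are_block_diagonal(index, ref_cohort):
    """Mean within-fine-group distance is below mean between-group distance."""
    from amplityper import pairwise_distance_matrix

    labels = {e.sample_id: (e.fine, e.intermediate, e.coarse) for e in index.entries}
    samples = [s for s in ref_cohort if s.sample_id in labels]
    ids, D = pairwise_distance_matrix(samples)
    fine = {sid: labels[sid][0] for sid in ids}
    within, between = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            (within if fine[ids[i]] == fine[ids[j]] else between).append(D[i, j])
    assert np.mean(within) < 0.1 < 0.3 < np.mean(between)
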