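# Methods

## Distance kernel

A haplotype is reduced to its set of distinct k-mers (k = 8 by default,
matching the resolution used throughout; configurable). Windows containing
`N` are skipped rather than rejected, since amplicon consensus sequences can
carry ambiguous bases, and only the forward strand is used because panel
primers fix amplicon orientation (a `canonical` flag folds reverse
complements for unoriented input). The default haplotype distance is the
min-normalised overlap d(A,B) = 1 − |A∩B| / min(|A|,|B|), chosen so that a
short haplotype fully contained in a longer one scores 0 — robust to the
amplicon length variation that Jaccard or Sørensen–Dice normalisations
would penalise; both alternatives are exposed via `metric=`. Sample-level
distance is the mean of haplotype distances over all allele pairs at each
shared target, then the mean over shared targets; targets recovered in only
one sample are ignored rather than penalised, so partial dropout does not
inflate distances. Samples sharing no target raise an error ("not
comparable") instead of returning a maximal distance.

## Reference-index construction

Candidates are selected per species with caps of 10 per species and 5 per
(species, country), filling countries round-robin to maximise geographic
spread; within a country, sample-id order makes selection deterministic. A
pre-filter drops candidates whose nearest-neighbour assignment against a
provisional index (all other candidates labelled by their claimed species)
contradicts their claimed coarse taxon — modelling the removal of clearly
mislabelled specimens — and is applied only when the species has at least
two candidates, since a sole representative has no peers to contradict it.

Clustering is single-linkage: connected components of the graph with edges
where D < t. It is the only scheme for which a pure distance threshold
defines the partition, and it guarantees that the fine partition (t = 0.1)
nests inside the intermediate partition (t = 0.3). Edges use strict
inequality; boundary pairs at exactly t split (configurable via
`strict=False`). Coarse groups come solely from the taxonomy table because
no single distance threshold separates the series and subgenera.

A species whose samples form several fine clusters is kept split (as
`_cl1`, `_cl2`, … groups, numbered by descending cluster size then smallest
member id — a package convention) only when every member's alleles support
its own cluster with proportion ≥ 0.9 under within-species nearest-
neighbour comparison and the clusters share one intermediate group;
otherwise the clusters are merged into a single fine group. Evidence of
geographic structure (`†`) and barcode support are treated as metadata
passed in by the analyst, not computed. All irregularities — multi-species
clusters, split species, clustering/taxonomy conflicts, dropped candidates,
missing taxonomy rows — are surfaced in a build report.

Naming is a pure function of (members, level, taxonomy, flags): single
species keep their name (no `_f` for one-to-one fine groups; no `_i` for
unflagged single-fine-group intermediate pass-throughs); multi-species
groups take the lowest shared taxon with `§` (at the intermediate level `§`
marks groups spanning several complexes, and the shared series is used as
the base when complexes differ); unnamed species take their host taxon with
`^` and always a clade suffix; `*` marks conflict with taxonomy and `†`
geographic structure; symbols render in the fixed order `* § ^ †`.

Serialization writes a fully sorted bundle (`haplotypes.fasta` with
`sample.target.allele` record ids, `labels.tsv`, `meta.json` with version
and group metadata), so two serializations of equal indexes are
byte-identical and version drift is detectable on load.

## Assignment

Per allele, all reference haplotypes at the same target minimising the
distance are found; the allele's unit weight is split equally over their
*distinct fine labels* (not over neighbours), so a species with ten
reference haplotypes carries no more weight than one with a single
haplotype. Allele vectors are averaged per target and per-target vectors
over recovered targets; intermediate and coarse proportions are sums of
constituent fine proportions, so the aggregation identities hold exactly.
Targets are weighted uniformly (not by read depth). The call is the
deepest level whose maximum reaches the threshold; exact argmax ties fall
through to the next level rather than being broken arbitrarily. The
min-targets gate (default 10) is applied before any proportion is computed;
gated samples report `not_run`. Lowering the threshold can only turn
unassigned samples into assigned ones — it never changes which label an
assigned sample receives.

One consequence of label-split tie handling: when two fine groups contain
an identical haplotype at some target — which happens routinely between
`_clN` clade groups of one species at conserved targets — a reference
individual re-assigned against its own index receives slightly less than
proportion 1.0 for its own label (the shared target's weight is split).
Groups that share no exact haplotype self-assign at exactly 1.0.

Rainbow grouping clusters coarse-level/unassigned samples by single linkage
on the cosine distance between fine proportion vectors. The default
threshold 0.2 lies in the wide gap observed in calibration simulations
between same-species patterns (≲ 0.01) and patterns of distinct
unrepresented species (≳ 0.35).

## Contamination QC

A target is multiallelic when it carries more than two distinct sequences
(diploid expectation; `max_alleles=1` for haploid panels). Categories:
`very_high` (> 4 multiallelic targets), `high` (3–4), `medium` (< 1,000
total reads or 1–2 multiallelic), `low` (≥ 1,000 reads and none). Where
rules overlap, the highest risk wins — the conservative reading.

## Population structure

The k-mer count matrix counts occurrences per sample summed over every
allele entry of every target (a homozygous diploid target contributes its
k-mers twice, like a heterozygous one, avoiding a spurious
heterozygosity axis); only variable columns (≥ 2 distinct values) are kept,
and a binary presence/absence option is exposed. PCA is centred and
unscaled by default; component signs are fixed by making each component's
largest-magnitude loading positive, so projections are deterministic.
Haplotype sharing is exact-sequence, per allele entry (two per diploid
individual), with the focal cohort required to be disjoint from the
populations; the empty sharing set counts private alleles. The heatmap
contract is the distance matrix ordered by (coarse, intermediate, fine,
sample id) plus boundary indices per level; rendering is optional,
unlabelled samples sort last and are flagged.

## Synthetic data

The generator emulates the study conditions: a 62-target panel (lengths
uniform in 150–300 bp), a four-level species tree (series → group/complex →
species → optional clades) over ten synthetic species, substitution-only
evolution (an indel-free simplification; amplicon length variation is
instead covered by the min-normalisation), diploid individuals with
within-species polymorphism, Bernoulli target dropout, negative-binomial
read counts scaled by a log-normal per-sample depth factor (so totals
straddle the 1,000-read QC boundary in both directions), and contamination
modelled as one foreign allele injected at a fixed number of targets,
preferring targets whose host alleles already differ so that an injected
target is detectably multiallelic.

Default per-site branch rates (series 0.12, group 0.05, species 0.013,
clade 0.008, close-sibling 0.003, polymorphism 0.002) are calibrated so
each relatedness tier lands in its intended regime of the min-normalised
8-mer distance: within species/clade ≈ 0.03 (< 0.1), close sibling pair
≈ 0.08 (< 0.1, merging into a `§` group), clades of a split species ≈ 0.15
and congeners ≈ 0.22–0.27 (between 0.1 and 0.3), other groups ≈ 0.66 and
other series ≈ 0.97 (> 0.3). These are expectations over the 62 targets,
asserted statistically in the tests. The default tree contains one close
pair, one sympatric two-clade species, one geographically structured
two-clade species (clades placed in different countries), a three-group
series and an isolated single-species series, so that index ablations
reproduce all four unrepresented-species behaviours (fine mis-assignment to
a close congener, intermediate fallback, coarse fallback, unassigned
rainbow).

What passing tests do not show: real amplicon data carry indels, sequencing
error, primer artefacts, uneven taxon sampling and much deeper coalescent
structure than this tree-plus-Bernoulli model; results on synthetic data
validate the machinery and its thresholds, not field performance.

## Numerical choices and limitations

Distance ties use an absolute tolerance of 1e-12; distance matrices are
validated for symmetry, zero diagonal and range before clustering. Problem
sizes in the test-suite and summary script (≤ 80 reference individuals,
50-sample query cohorts) were chosen as the smallest panels at which every
clustering regime and ablation scenario is stable across seeds. Known
limitations: no minimizer/sketching approximation for very large indexes;
no read-depth weighting; clade ordering and the rainbow threshold are
package conventions, not field standards; the merge/split decision for
multi-cluster species implements only the assignment-support criterion —
sympatry and barcode evidence remain analyst decisions.
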