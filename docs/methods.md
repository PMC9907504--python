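# Methods

This note documents the models behind each module, the parameters that
matter, the numerical conventions, and what the synthetic-data generators do
and do not emulate.

## Synthetic metagenomes (`simdata.simulate_metagenome`)

Each organism is described by an `OrganismSpec`: genome size, mean and
spread of GC content, mean read depth with a lognormal spread, a phylum
label, the probability that a contig is missing from the taxonomy table
("no hit"), and a compositional seed.

*Sequence model.* Contig sequences come from an order-2 Markov chain. A
seeded per-organism bias tensor fixes how GC splits into G vs C (and AT into
A vs T) per dinucleotide context, plus small per-context GC offsets; for
each contig a target GC is drawn from N(gc_mean, gc_sd) and the per-context
GC shares are shifted globally so that the chain's *stationary* GC equals
the target (bisection over the 16-state context chain, 50 iterations). Two
organisms with the same GC but different seeds therefore have
distinguishable tetranucleotide signatures — the property contig binning
relies on, and the reason a plain i.i.d. model would make the binning tests
vacuous. Realized contig GC fluctuates around the target by O(1/√L).

*Lengths and depth.* Contig lengths are geometric with default mean 20 kbp
floored at 5 kbp (producing both sub-fragment-size and multi-fragment
contigs); per-contig depth is lognormal around the organism mean (strictly
positive and heavy-tailed, like real mapping depth). Contigs are emitted
until the genome size is covered.

*Taxonomy table.* With probability 1 − label_miss_prob a contig receives a
protein-tier hit row (bitscore U(150, 450), e-value 10^U(−60,−30)) and, half
the time, a second nucleotide-tier row for the same phylum; otherwise it is
absent from the table entirely. The generator does not emulate *wrong*
phylum labels, chimeric contigs, read-level errors, or assembly artifacts —
recovery scores on it are upper bounds on real-data performance in those
respects.

*Default community.* One mycobiont core (5 Mbp, GC 0.50, depth 30×,
Ascomycota, 30% no-hit), an AT-rich mycobiont tail carrying 20% of the
mycobiont bases (1.25 Mbp, GC 0.33, same depth, 80% no-hit — the tail size
and GC are simulator defaults, not literature values), a photobiont (3 Mbp,
GC 0.60, 90×, Chlorophyta), and two bacteria separated in GC and depth
(0.42/150× and 0.66/7×). This reproduces the diagnostic "linear cloud with
an AT-rich, database-dark tail" situation the binning pipeline targets.

## Mycobiont isolation (`binning`)

Features are computed per 10 kbp fragment (terminal remainders are appended
to the previous window so no fragment is shorter than the window;
coordinates are 0-based half-open). The 136 canonical 4-mer frequencies
(+1 pseudocount) concatenated with standardized log10(depth+1) are reduced
by PCA retaining ≥ 90% variance and clustered with full-covariance Gaussian
mixtures, k = 1..max_bins (default 10) selected by BIC. Fragments are sorted
by id before fitting, so results are invariant to input order; the model
seed fixes initialization. A contig joins the bin owning most of its
fragment bases (ties to the lower label).

Taxonomy calls use best-sum aggregation: hits above the e-value cutoff
(default 1e-25) are dropped, the rest summed per phylum across both hit
tiers, top score wins, ties break lexicographically.

The anchor bin maximizes target-taxon bases. Tail merging uses three
explicit thresholds, each configurable and reported per decision: coverage
within 2-fold of the anchor median, median GC at most 0.02 above the
anchor's (one-sided — the tail is AT-rich, never GC-rich), and at most 20%
of bin bases labelled with a foreign taxon. These thresholds are this
package's operationalization of a qualitative criterion ("consistent
coverage, lower GC, few contaminants"); they are deliberately surfaced in
the run report rather than silently applied. Bins are evaluated against the
anchor independently — no transitive chaining. The final filter keeps only
contigs called target-taxon or NO_HIT, which is what rescues the
database-dark AT tail: its contigs enter through the merge rule and survive
the filter as no-hits, so tail recovery does not depend on taxonomy labels
at all (verified by the test that sets the tail's miss probability to 1).

## BGC panels and family recovery (`simdata.simulate_bgc_panel`, `bgcnet`)

Archetypes define families; each genome derives its instance by dropping
each gene with probability `gene_loss_prob`, transposing each domain with
its neighbour with probability `domain_swap_prob` (domain *shuffling*:
order, not content, is perturbed — content changes are what family
membership is defined by, so they are not a within-family process), and
substituting each residue with probability `residue_sub_prob`. Reference
archetypes additionally emit one unmutated, compound-annotated cluster.
Random archetypes draw 4–7 genes with 2–4 domains each from a 6-label
family-specific sub-lexicon (real clusters reuse a handful of domain types)
and 100–200 aa sequences.

Distances: identity is global alignment (match +1, mismatch −1, linear gap
−2; arguments canonically ordered, so it is exactly symmetric), identity =
matches/columns. DSS pairs shared domain copies greedily by descending
parent-gene identity and divides the summed identities by pairs + unpaired
copies on both sides; AI compares unordered adjacent domain pairs of the
linearized cluster (inherently orientation-insensitive); J compares pooled
domain-label sets. The composite uses weights (0.2, 0.7, 0.1); this is one
global triple rather than class-specific weight sets, and DSS matches whole
parent-gene sequences rather than HMM-extracted domain subsequences — a
deliberate simplification that preserves the ingredients (domain content,
sequence identity, order, copy number) while staying fully self-contained.

Networking links same-class pairs at d ≤ cutoff (inclusive, so cutoff
selection on a 0.01 grid is well defined), except pairs with no similarity
at all (d = 1), which are never linked. RiPP and saccharide classes are
excluded. Components of size ≥ 3 are refined by affinity propagation on
s = 1 − d with damping 0.9, ≤ 1000 iterations, and exemplar preference 0.3.
The preference is a fixed scalar rather than the median similarity because
a median preference sits at the typical within-family similarity and
shatters homogeneous families into arbitrary exemplars (observed directly:
a 10-member family at s ≈ 0.85 splits three ways); 0.3 sits below
within-family similarity and above between-family similarity, which is the
regime in which affinity propagation acts as intended here. Non-convergence
keeps the component whole. Family ids are the smallest member cluster id,
making the partition invariant to input order.

## Diversity statistics (`divstat`)

Beta diversity uses the Sorensen family: pairwise
βsor = (b+c)/(2a+b+c), βsim = min(b,c)/(a+min(b,c)), βsne = βsor − βsim,
and the multiple-site generalization built from Σ min(b_ij, b_ji),
Σ max(b_ij, b_ji), and the richness excess Σ S_i − S_T. The identity
βSOR = βSIM + βSNE holds to 1e-12 by construction and is property-tested
against an independently coded brute force.

PCoA Gower-centers −d²/2, eigendecomposes, scales eigenvectors by √λ for
positive eigenvalues, reports negative eigenvalues unaltered, and fixes axis
signs by making the first nonzero loading positive. The Mantel test is
one-tailed for positive association with 999 default permutations and the
add-one p-value rule (so the smallest attainable p is 1/1000); an `exact`
mode enumerates all permutations for small n. PERMANOVA computes sequential
(Type-I) sums of squares from nested hat matrices applied to the
Gower-centered matrix, with unrestricted joint row/column permutations of
the distance matrix; on Euclidean distances of univariate data it reproduces
the classical regression F exactly. Phylogenetic PCs treat
distance-matrix rows as raw feature vectors (column-centered SVD), keeping
the smallest k with ≥ 80% cumulative variance; a `double_center` switch
provides the PCoA-equivalent geometry instead, since either reading of
"PCA of phylogenetic distances" is defensible. No multiple-testing
correction is applied anywhere.

Tree simulation is pure-birth with unit speciation rate (tip count set by
the user, depth ~ ln n emerging from the process; no rescaling). Presence
columns evolve by a two-state Markov chain with gain g and loss l, root
states drawn from the stationary distribution. Note that with pendant
branches ~ 1/n, even g = l = 5 does not fully decorrelate sister tips —
"fast evolution" suppresses but does not erase the Mantel correlation at
moderate tip counts; tests assert the computed behaviour, not an idealized
zero.

## Anthraquinone screen (`aqscreen`)

A gene counts as the NR-PKS on KS + AT co-occurrence (so degraded
annotations still screen); the full SAT-KS-AT-ACP order-preserving
subsequence check is reported separately, with PT optional because domain
annotation tools routinely miss it in these clusters. The four-gene order
(ABC, MβL-TE, PKS, EthD) is accepted in either orientation and tolerates
intervening genes; both tolerances are defaults and the per-cluster report
carries the raw flags so stricter readings can be applied downstream.
Endocrocin and clavorubin are listed as separate compounds in the reference
set even though they are produced by one reference cluster.

## Problem sizes and determinism

The test suite and the acceptance script use desk-scale sizes chosen for
fast, stable statistics: ~13 Mbp communities (~650 contigs), 20-family ×
10-genome panels (200 clusters), 20–45-tip trees with 300–500 families, 500
replicates × 199 permutations for calibration checks. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; identical
seeds give identical outputs, including byte-identical simulated sequences.

## Known limitations

- The simulators do not model read errors, chimeras, strain mixtures,
  misassigned taxonomy labels, or assembly fragmentation bias.
- DSS operates on parent-gene sequences, not extracted domain subsequences;
  clusters whose genes share domains but differ radically elsewhere in the
  protein are scored more harshly than an HMM-based pipeline would.
- The merge thresholds (2-fold coverage, 0.02 GC slack, 20% foreign bases)
  are engineering defaults; real communities with contaminants that mimic
  the tail's GC/coverage profile would require tightening them.
- Affinity propagation granularity depends on the preference scalar; very
  heterogeneous families near the cutoff may still split.
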