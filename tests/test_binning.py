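"""Contig features, taxonomy calls, fragmentation, and the isolation pipeline."""

import numpy as np
import pandas as pd
import pytest

from lichenbgc import binning, simdata
from lichenbgc.binning import (
    NO_HIT,
    Bin,
    BinningConfig,
    TaxonomyConfig,
    assign_taxonomy,
    compute_contig_features,
    filter_contaminants,
    fragment_contigs,
    merge_tail_bins,
    select_anchor_bin,
)


def cov_frame(contigs, depth=10.0):
    return pd.DataFrame(
        {"contig_id": list(contigs), "mean_depth": [depth] * len(contigs)}
    )


class TestFeatures:
    def test_gc_extremes(self):
        contigs = {"a": "GGCC", "b": "ATAT" * 5}
        recs = compute_contig_features(contigs, cov_frame(contigs))
        assert recs["a"].gc == 1.0
        assert recs["b"].gc == 0.0

    def test_kmer_profile_normalized(self):
        contigs = {"a": "ACGTACGTACGTNNACGT"}
        recs = compute_contig_features(contigs, cov_frame(contigs))
        assert recs["a"].kmer_profile.sum() == pytest.approx(1.0, abs=1e-9)
        assert recs["a"].kmer_profile.shape == (binning.N_CANONICAL_KMERS,)

    def test_missing_coverage_listed(self):
        contigs = {"a": "ACGT", "b": "ACGT"}
        with pytest.raises(ValueError, match="b"):
            compute_contig_features(contigs, cov_frame({"a": None}))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_contig_features({"a": ""}, cov_frame({"a": None}))


class TestTaxonomy:
    def make_hits(self, rows):
        return pd.DataFrame(
            rows, columns=["contig_id", "taxon", "rank", "bitscore", "evalue", "tier"]
        )

    def test_best_sum_across_tiers(self):
        hits = self.make_hits(
            [
                ("c1", "Ascomycota", "phylum", 100, 1e-40, "protein"),
                ("c1", "Ascomycota", "phylum", 50, 1e-30, "nucleotide"),
                ("c1", "Chlorophyta", "phylum", 120, 1e-50, "protein"),
            ]
        )
        assert assign_taxonomy(hits) == {"c1": "Ascomycota"}  # 150 > 120

    def test_evalue_cutoff_enforced(self):
        hits = self.make_hits([("c1", "Ascomycota", "phylum", 500, 1e-10, "protein")])
        assert assign_taxonomy(hits) == {}

    def test_tie_breaks_lexicographic(self):
        hits = self.make_hits(
            [
                ("c1", "Basidiomycota", "phylum", 100, 1e-40, "protein"),
                ("c1", "Ascomycota", "phylum", 100, 1e-40, "protein"),
            ]
        )
        assert assign_taxonomy(hits) == {"c1": "Ascomycota"}

    def test_negative_bitscore_rejected(self):
        hits = self.make_hits([("c1", "Ascomycota", "phylum", -5, 1e-40, "protein")])
        with pytest.raises(ValueError):
            assign_taxonomy(hits)


class TestFragmentation:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (25_000, [(0, 10_000), (10_000, 25_000)]),  # remainder appended
            (9_999, [(0, 9_999)]),
            (20_000, [(0, 10_000), (10_000, 20_000)]),
            (10_000, [(0, 10_000)]),
        ],
    )
    def test_window_boundaries(self, length, expected):
        frags = fragment_contigs({"c": "A" * length}, 10_000)
        assert list(zip(frags.start, frags.end)) == expected

    def test_parent_map_covers_sequence(self):
        frags = fragment_contigs({"c": "A" * 43_210}, 10_000)
        assert frags.start.iloc[0] == 0 and frags.end.iloc[-1] == 43_210
        assert (frags.start.iloc[1:].to_numpy() == frags.end.iloc[:-1].to_numpy()).all()


class TestClustering:
    def test_single_organism_selects_one_bin(self):
        # BIC should pick k = 1 for a homogeneous fragment pool
        ones = 0
        n_runs = 20
        for seed in range(n_runs):
            contigs, coverage, _, _ = simdata.simulate_metagenome(
                [
                    simdata.OrganismSpec(
                        "m", "mycobiont_core", 250_000, 0.5, 0.02, 30, 0.25,
                        "Ascomycota", 0.3, markov_seed=5,
                    )
                ],
                contig_length_dist=(8000, 12_000),
                seed=seed,
            )
            recs = compute_contig_features(contigs, coverage)
            frags = fragment_contigs(contigs, 10_000)
            _, _, report = binning.cluster_fragments(
                contigs, recs, frags, BinningConfig(max_bins=5, seed=seed)
            )
            ones += report["k"] == 1
        assert ones >= 0.9 * n_runs

    def test_two_organisms_separate_accurately(self):
        specs = [
            simdata.OrganismSpec("a", "mycobiont_core", 400_000, 0.50, 0.015, 40,
                                 0.2, "Ascomycota", 0.3, markov_seed=1),
            simdata.OrganismSpec("b", "bacterium", 400_000, 0.65, 0.015, 10,
                                 0.2, "Proteobacteria", 0.3, markov_seed=2),
        ]
        contigs, coverage, _, truth = simdata.simulate_metagenome(specs, seed=4)
        recs = compute_contig_features(contigs, coverage)
        frags = fragment_contigs(contigs, 10_000)
        _, contig_labels, _ = binning.cluster_fragments(
            contigs, recs, frags, BinningConfig(seed=0)
        )
        lab = pd.Series(contig_labels)
        org = truth.set_index("contig_id").organism
        # majority label per organism; accuracy vs that mapping
        correct = 0
        for o in ("a", "b"):
            members = org[org == o].index
            majority = lab[members].mode()[0]
            correct += (lab[members] == majority).sum()
        assert correct / len(lab) >= 0.95


def toy_bins():
    return {
        0: Bin(0, ["a"], 5_000_000, 0.50, 30.0, {"Ascomycota": 0.6, NO_HIT: 0.4}),
        1: Bin(1, ["b"], 1_000_000, 0.33, 28.0, {NO_HIT: 1.0}),
        2: Bin(2, ["c"], 2_000_000, 0.60, 240.0, {"Chlorophyta": 0.9, NO_HIT: 0.1}),
        3: Bin(3, ["d"], 1_000_000, 0.45, 29.0, {"Chlorophyta": 0.4, NO_HIT: 0.6}),
    }


class TestAnchorAndMerge:
    def test_anchor_maximizes_target_bp(self):
        bins = toy_bins()
        calls = {"a": "Ascomycota", "b": NO_HIT, "c": "Chlorophyta", "d": NO_HIT}
        recs = {
            k: binning.ContigRecord(k, bp, 0.5, 30, np.ones(136) / 136, calls[k])
            for k, bp in zip("abcd", (5_000_000, 1_000_000, 2_000_000, 1_000_000))
        }
        assert select_anchor_bin(bins, calls, recs) == 0

    def test_no_target_anywhere_is_error(self):
        bins = toy_bins()
        calls = {"a": NO_HIT, "b": NO_HIT, "c": "Chlorophyta", "d": NO_HIT}
        recs = {
            k: binning.ContigRecord(k, 1000, 0.5, 30, np.ones(136) / 136, calls[k])
            for k in "abcd"
        }
        with pytest.raises(ValueError, match="anchor"):
            select_anchor_bin(bins, calls, recs)

    def test_merge_rules(self):
        merged, decisions = merge_tail_bins(toy_bins(), anchor=0)
        by_bin = {d["bin_id"]: d["merged"] for d in decisions}
        assert by_bin[1] is True  # AT-rich tail: low GC, same coverage, no hits
        assert by_bin[2] is False  # photobiont: 8-fold coverage, higher GC
        assert by_bin[3] is False  # 40% foreign bp exceeds 20% limit
        assert merged == {"a", "b"}

    def test_widening_coverage_tol_never_shrinks_merge(self):
        sizes = []
        for tol in (1.5, 2.0, 4.0, 16.0):
            merged, _ = merge_tail_bins(
                toy_bins(), 0, BinningConfig(coverage_ratio_tol=tol)
            )
            sizes.append(len(merged))
        assert sizes == sorted(sizes)


class TestFilterAndPipeline:
    def test_filter_keeps_target_and_nohit(self):
        calls = {"a": "Ascomycota", "b": NO_HIT, "c": "Chlorophyta"}
        assert filter_contaminants({"a", "b", "c"}, calls) == {"a", "b"}

    def test_all_contaminant_result_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            filter_contaminants({"c"}, {"c": "Chlorophyta"})

    def test_mycobiont_only_perfect_recovery(self):
        contigs, coverage, hits, truth = simdata.simulate_metagenome(
            [
                simdata.OrganismSpec(
                    "m", "mycobiont_core", 400_000, 0.5, 0.02, 30, 0.25,
                    "Ascomycota", 0.3, markov_seed=3,
                )
            ],
            seed=6,
        )
        final, _ = binning.run_binning(contigs, coverage, hits)
        assert final == set(truth.contig_id)  # recall = precision = 1

    def test_empty_taxonomy_fails_at_anchor(self):
        contigs, coverage, _, _ = simdata.simulate_metagenome(
            [
                simdata.OrganismSpec(
                    "m", "mycobiont_core", 150_000, 0.5, 0.02, 30, 0.25,
                    "Ascomycota", 1.0, markov_seed=3,
                )
            ],
            seed=6,
        )
        empty = pd.DataFrame(
            columns=["contig_id", "taxon", "rank", "bitscore", "evalue", "tier"]
        )
        with pytest.raises(ValueError, match="anchor"):
            binning.run_binning(contigs, coverage, empty)

    def test_output_subset_and_input_order_invariance(self, community_sim):
        contigs, coverage, hits, _ = community_sim
        final1, _ = binning.run_binning(contigs, coverage, hits)
        assert final1 <= set(contigs)
        reordered = dict(sorted(contigs.items(), reverse=True))
        final2, _ = binning.run_binning(reordered, coverage, hits)
        assert final1 == final2

    def test_report_documents_decisions(self, community_sim):
        contigs, coverage, hits, _ = community_sim
        final, report = binning.run_binning(contigs, coverage, hits)
        assert report["n_final"] == len(final)
        assert report["anchor_bin"] in report["bins"]
        assert {d["bin_id"] for d in report["merge_decisions"]} == (
            set(report["bins"]) - {report["anchor_bin"]}
        )
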