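"""Generator correctness: determinism, guarantees, sampling moments."""

import numpy as np
import pandas as pd
import pytest

import phagescreen as ps
from phagescreen.simulate import (
    even_abundance,
    fragments_to_reads,
    make_ag_library,
    make_screen_truth,
    make_tn5_reference,
    make_tnseq_truth,
    make_barseq_library,
    random_barcode_set,
    reads_from_counts,
    simulate_apms,
    simulate_moi_assay,
    simulate_refmap_fragments,
    simulate_screen_counts,
    SimTruth,
)


def brute_min_pairwise_hamming(barcodes):
    return min(
        sum(x != y for x, y in zip(a, b))
        for i, a in enumerate(barcodes)
        for b in barcodes[i + 1 :]
    )


class TestBarcodeLibraries:
    def test_single_member_library(self):
        lib = make_ag_library(1, seed=7)
        assert len(lib) == 1
        assert len(lib.barcodes[0]) == 10

    def test_pairwise_distance_exhaustive(self):
        lib = make_ag_library(200, seed=1)
        assert len(lib) == 200
        assert brute_min_pairwise_hamming(lib.barcodes) >= 3

    def test_deterministic_given_seed(self):
        assert make_ag_library(2, seed=3).members == make_ag_library(2, seed=3).members

    def test_infeasible_set_raises(self):
        with pytest.raises(RuntimeError):
            random_barcode_set(30, length=3, min_dist=3, max_attempts_per_barcode=50)

    def test_library_invariants_enforced(self):
        with pytest.raises(ValueError):
            ps.BarcodeLibrary(members=[("a", "ACGTACGTAC"), ("b", "ACGTACGTAC")])
        with pytest.raises(ValueError):
            ps.BarcodeLibrary(members=[("a", "ACGTT")])  # wrong length for AG


class TestScreenCounts:
    def test_neutral_effects_match_proportions(self, small_library):
        truth = make_screen_truth(small_library, seed=5)
        sc = simulate_screen_counts(small_library, truth, depth=10**6, n_reps=1, seed=5)
        p = np.array([truth.abundance[m] for m in small_library.member_ids])
        for tab in (sc.uninfected, sc.infected):
            obs = tab.counts.iloc[:, 0].to_numpy() / 10**6
            sd = np.sqrt(p * (1 - p) / 10**6)
            assert (np.abs(obs - p) < 4 * sd + 1e-9).all()

    def test_depletion_ratio_matches_effect(self, small_library):
        member = small_library.member_ids[0]
        truth = make_screen_truth(small_library, {member: -4.0}, seed=6)
        sc = simulate_screen_counts(small_library, truth, depth=10**6, n_reps=1, seed=6)
        n_inf = sc.infected.counts.loc[member].iloc[0]
        n_un = sc.uninfected.counts.loc[member].iloc[0]
        p = truth.abundance[member]
        # renormalization slightly lifts the infected proportions
        z = sum(truth.abundance[m] * 2 ** truth.depletion_effect[m] for m in truth.abundance)
        expected = 10**6 * p * 2.0**-4 / z
        sd = np.sqrt(expected)
        assert abs(n_inf - expected) < 3 * sd
        assert n_un / n_inf > 8  # 16-fold depletion, generous sampling margin

    def test_totals_equal_depth_exactly(self, small_library):
        truth = make_screen_truth(small_library, seed=2)
        sc = simulate_screen_counts(small_library, truth, depth=12345, n_reps=3, seed=2)
        assert (sc.combined().counts.sum(axis=0) == 12345).all()

    def test_depth_zero_rejected(self, small_library):
        truth = make_screen_truth(small_library, seed=2)
        with pytest.raises(ValueError):
            simulate_screen_counts(small_library, truth, depth=0, n_reps=1, seed=2)

    def test_truth_key_mismatch_rejected(self, small_library):
        truth = make_screen_truth(small_library, seed=2)
        del truth.abundance[small_library.member_ids[0]]
        truth.abundance[small_library.member_ids[1]] += 0  # keep sum valid enough
        with pytest.raises(KeyError):
            simulate_screen_counts(small_library, truth, depth=10, n_reps=1, seed=2)


class TestReadsFromCounts:
    def test_error_free_round_trip(self, small_library):
        counts = pd.Series(
            np.arange(1, len(small_library) + 1), index=small_library.member_ids
        )
        reads = reads_from_counts(counts, small_library, substitution_rate=0.0, seed=3)
        assert len(reads) == counts.sum()
        table = ps.count_barcodes(reads, small_library, "s")
        assert (table.counts["s"] == counts).all()
        assert table.audit.loc["s", "assigned"] == counts.sum()

    def test_read_count_conservation(self, small_library):
        reads = reads_from_counts({small_library.member_ids[0]: 3}, small_library, seed=0)
        assert len(reads) == 3

    def test_unknown_member_rejected(self, small_library):
        with pytest.raises(KeyError):
            reads_from_counts({"nope": 1}, small_library, seed=0)

    def test_bad_rate_rejected(self, small_library):
        with pytest.raises(ValueError):
            reads_from_counts({small_library.member_ids[0]: 1}, small_library, 0.5, seed=0)

    def test_prefix_lengths_within_layout_range(self, small_library):
        reads = reads_from_counts({small_library.member_ids[0]: 200}, small_library, seed=8)
        core = len(small_library.layout.up_flank) + 10 + len(small_library.layout.down_flank)
        lens = {len(r) - core for r in reads}
        assert lens <= {5, 6, 7}


class TestTn5Reference:
    def test_downstream_50mers_unique_brute_force(self, tn5_reference):
        genome = tn5_reference.genome
        for pos in tn5_reference.insertions["position"]:
            probe = genome[pos - 1 : pos - 1 + 50]
            assert genome.count(probe) == 1

    def test_gene_free_genome_is_all_intergenic(self):
        ref = make_tn5_reference(5_000, n_genes=0, n_insertions=20, seed=4)
        assert len(ref.annotation) == 0
        assert (ref.insertions["gene_id"] == "INTERGENIC").all()

    def test_deterministic(self):
        a = make_tn5_reference(5_000, 4, 10, seed=9)
        b = make_tn5_reference(5_000, 4, 10, seed=9)
        assert a.genome == b.genome
        assert a.insertions.equals(b.insertions)

    def test_genes_do_not_overlap(self, tn5_reference):
        ann = tn5_reference.annotation.sort_values("start")
        assert (ann["start"].iloc[1:].to_numpy() > ann["end"].iloc[:-1].to_numpy()).all()

    def test_overfull_genome_rejected(self):
        with pytest.raises(ValueError):
            make_tn5_reference(900, n_genes=1, n_insertions=1, seed=0, gene_len=1000)


class TestRefmapFragments:
    def test_clean_simulation_fragments_unique(self, tn5_reference):
        frags, truth = simulate_refmap_fragments(tn5_reference, 5, seed=1)
        assert len(frags) == len(set(frags)) == 500
        assert not truth["chimeric"].any() and not truth["duplicate"].any()

    def test_duplicates_are_verbatim_copies(self, tn5_reference):
        frags, truth = simulate_refmap_fragments(tn5_reference, 10, dup_rate=0.5, seed=2)
        genuine = (~truth["duplicate"]).sum()
        assert genuine == 1000
        assert len(ps.dedupe(frags)) == genuine

    def test_invalid_rates_rejected(self, tn5_reference):
        with pytest.raises(ValueError):
            simulate_refmap_fragments(tn5_reference, 2, dup_rate=1.0)
        with pytest.raises(ValueError):
            simulate_refmap_fragments(tn5_reference, 2, chimera_rate=-0.1)

    def test_reads_round_trip(self, tn5_reference):
        frags, _ = simulate_refmap_fragments(tn5_reference, 3, seed=5)
        reads = fragments_to_reads(frags, seed=5)
        parsed, audit = ps.parse_fragments(reads)
        assert audit["assigned"] == len(reads)
        assert parsed == frags


class TestApmsSimulation:
    def test_noiseless_unspiked_is_null(self):
        df, _ = simulate_apms(50, ["h1"], cv=0.0, seed=1)
        result = ps.run_apms(df, control_bait="orf74")
        enr = result.enrichment[("h1", "bait")]
        assert np.allclose(enr["log2fc"], 0.0)

    def test_spike_recorded_in_truth(self):
        _, truth = simulate_apms(50, ["h1", "h2"], spiked={"P0003"}, seed=1)
        assert truth.spiked_interactors[("h1", "bait")] == {"P0003"}

    def test_unknown_spike_rejected(self):
        with pytest.raises(KeyError):
            simulate_apms(10, ["h1"], spiked={"P9999"}, seed=1)


class TestMoiSimulation:
    def test_zero_moi_full_survival(self):
        df = simulate_moi_assay(1.0, [0.0], n_cells=100, seed=0)
        assert df.loc[0, "survival_fraction"] == 1.0

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            simulate_moi_assay(1.0, [1.0], n_cells=0)

    def test_negative_moi_rejected(self):
        with pytest.raises(ValueError):
            simulate_moi_assay(1.0, [-1.0], n_cells=10)


class TestSimTruth:
    def test_abundances_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimTruth(abundance={"a": 0.5, "b": 0.4})

    def test_json_round_trip(self, tmp_path):
        truth = SimTruth(
            depletion_effect={"a": -4.0},
            abundance={"a": 0.25, "b": 0.75},
            spiked_interactors={("h1", "bait"): {"P0001"}},
            adsorption_factor=26.0,
            seed=3,
        )
        truth.to_json(tmp_path / "t.json")
        back = SimTruth.from_json(tmp_path / "t.json")
        assert back.abundance == truth.abundance
        assert back.spiked_interactors == truth.spiked_interactors

    def test_even_abundance_bounded_spread(self):
        ab = even_abundance([f"m{i}" for i in range(100)], seed=0, log2_spread=1.0)
        v = np.array(list(ab.values()))
        assert v.max() / v.min() <= 4.0 + 1e-9
        assert np.isclose(v.sum(), 1.0)


def test_tnseq_truth_targets_one_gene(tn5_reference):
    truth = make_tnseq_truth(tn5_reference, "gene001", effect=-4.0, seed=1)
    b2g = tn5_reference.true_barcode_to_gene()
    for bc, eff in truth.depletion_effect.items():
        assert (eff == -4.0) == (b2g[bc] == "gene001")
    lib = make_barseq_library(tn5_reference)
    assert set(lib.member_ids) == set(truth.abundance)
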