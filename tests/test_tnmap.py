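"""Tn5 mapping: fragment parsing, dedupe, localization, dominance, genes."""

import numpy as np
import pandas as pd
import pytest

import phagescreen as ps
from phagescreen import Fragment, TN5_REFMAP_LAYOUT, INTERGENIC, UNLOCATED, VECTOR
from phagescreen.tables import CountTable


def make_read(frag, layout=TN5_REFMAP_LAYOUT):
    return layout.up_flank + frag.barcode + layout.down_flank + frag.tag + frag.is_seq


@pytest.fixture
def annotation():
    return pd.DataFrame(
        [("geneA", 1000, 2000), ("geneB", 3000, 4000)],
        columns=["gene_id", "start", "end"],
    )


class TestParseFragments:
    def test_round_trip(self, tn5_reference):
        frags, _ = ps.simulate.simulate_refmap_fragments(tn5_reference, 4, seed=2)
        reads = ps.simulate.fragments_to_reads(frags, seed=2)
        parsed, audit = ps.parse_fragments(reads)
        assert parsed == frags
        assert audit["assigned"] == len(reads)

    @pytest.mark.parametrize("n_mm,ok", [(6, True), (7, False)])
    def test_down_flank_budget_boundary(self, n_mm, ok, rng):
        frag = Fragment("A" * 20, "ACGT", "T" * 30)
        read = list(make_read(frag))
        start = 23 + 20  # downstream 50-mer window
        for i in range(n_mm):
            pos = start + i
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        parsed, audit = ps.parse_fragments(["".join(read)])
        assert (len(parsed) == 1) == ok
        if not ok:
            assert audit["rejected_flank"] == 1

    def test_short_read_rejected(self):
        parsed, audit = ps.parse_fragments(["ACGT"])
        assert parsed == [] and audit["rejected_other"] == 1

    def test_is_shorter_than_minimum_rejected(self):
        frag = Fragment("A" * 20, "ACGT", "T" * 10)  # IS below the 16 nt floor
        parsed, audit = ps.parse_fragments([make_read(frag)])
        assert parsed == [] and audit["rejected_other"] == 1

    def test_is_clipped_to_layout_maximum(self):
        frag = Fragment("A" * 20, "ACGT", "T" * 50)
        parsed, _ = ps.parse_fragments([make_read(frag) + "C" * 20])
        assert parsed[0].is_seq == "T" * 50


class TestDedupe:
    def test_triplicated_input_collapses(self):
        frags = [Fragment("A" * 20, "ACGT", "T" * 20)] * 3 + [
            Fragment("C" * 20, "ACGT", "T" * 20)
        ] * 3
        assert len(ps.dedupe(frags)) == 2

    def test_tag_distinguishes_fragments(self):
        a = Fragment("A" * 20, "AAAA", "T" * 20)
        b = Fragment("A" * 20, "CCCC", "T" * 20)
        assert ps.dedupe([a, b]) == [a, b]

    def test_empty_input(self):
        assert ps.dedupe([]) == []


class TestLocate:
    def test_unique_genome_hit_is_one_based(self, tn5_reference):
        genome = tn5_reference.genome
        assert ps.locate(genome[1233:1283], genome) == 1234

    def test_vector_match_flagged(self, tn5_reference):
        seg = tn5_reference.vector[10:40]
        assert ps.locate(seg, tn5_reference.genome, tn5_reference.vector) == VECTOR

    def test_multimapping_segment_unlocated(self):
        seg = "ACGTACGTACGTACGA"  # 16-mer planted twice
        genome = "T" * 40 + seg + "G" * 40 + seg + "C" * 40
        assert genome.count(seg) == 2
        assert ps.locate(seg, genome) == UNLOCATED

    def test_absent_segment_unlocated(self):
        assert ps.locate("A" * 16, "C" * 1000) == UNLOCATED


class TestBuildMap:
    def seg(self, genome, pos, length=30):
        return genome[pos - 1 : pos - 1 + length]

    @pytest.fixture
    def genome(self, rng):
        return "".join(rng.choice(list("ACGT"), 6000))

    def test_unanimous_barcode_retained(self, genome, annotation):
        frags = [Fragment("A" * 20, tag, self.seg(genome, 1500))
                 for tag in ("AAAA", "AAAC", "AAAG", "AAAT", "AACA", "AACC", "AACG",
                             "AACT", "AAGA", "AAGC")]
        imap = ps.build_map(frags, genome, "", annotation)
        entry = imap.entries.iloc[0]
        assert entry["dominant_fraction"] == 1.0
        assert entry["support"] == 10
        assert entry["gene_id"] == "geneA"

    @pytest.mark.parametrize("n_major,retained", [(91, True), (90, False)])
    def test_dominance_boundary_over_90_percent(self, genome, annotation, n_major, retained, rng):
        tags = ["".join(rng.choice(list("ACGT"), 4)) for _ in range(200)]
        tags = list(dict.fromkeys(tags))[:100]
        major = self.seg(genome, 1500)
        minor = self.seg(genome, 3500)
        frags = [Fragment("G" * 20, tags[i], major) for i in range(n_major)]
        frags += [Fragment("G" * 20, tags[n_major + i], minor) for i in range(100 - n_major)]
        imap = ps.build_map(frags, genome, "", annotation)
        if retained:
            assert list(imap.entries["barcode"]) == ["G" * 20]
            assert imap.entries.iloc[0]["position"] == 1500
        else:
            assert list(imap.discarded["reason"]) == ["AMBIGUOUS_DOMINANCE"]

    def test_vector_fragments_count_in_denominator_but_never_win(self, genome, annotation):
        vector = "TTTTGGGGCCCCAAAA" * 10
        vseg = vector[:30]
        frags = [Fragment("C" * 20, f"AAA{b}", self.seg(genome, 1200)) for b in "ACGT"]
        frags += [Fragment("C" * 20, f"CCC{b}", vseg) for b in "ACGT"]
        imap = ps.build_map(frags, genome, vector, annotation)
        # 4/8 genomic share: below dominance, discarded
        assert list(imap.discarded["reason"]) == ["AMBIGUOUS_DOMINANCE"]
        imap2 = ps.build_map(
            frags, genome, vector, annotation, include_vector_in_denominator=False
        )
        assert list(imap2.entries["barcode"]) == ["C" * 20]

    def test_all_vector_barcode_discarded_as_vector(self, genome, annotation):
        vector = "TTTTGGGGCCCCAAAA" * 10
        frags = [Fragment("T" * 20, f"AAA{b}", vector[:30]) for b in "ACGT"]
        imap = ps.build_map(frags, genome, vector, annotation)
        assert list(imap.discarded["reason"]) == [VECTOR]

    def test_gene_containment_boundaries(self, genome, annotation):
        from phagescreen.tnmap import assign_gene

        assert assign_gene(1000, annotation) == "geneA"
        assert assign_gene(2000, annotation) == "geneA"
        assert assign_gene(2500, annotation) == INTERGENIC

    def test_clean_simulation_reproduces_truth_exactly(self, tn5_reference):
        frags, _ = ps.simulate.simulate_refmap_fragments(tn5_reference, 5, seed=3)
        imap = ps.build_map(
            ps.dedupe(frags),
            tn5_reference.genome,
            tn5_reference.vector,
            tn5_reference.annotation,
        )
        assert len(imap.discarded) == 0
        assert imap.barcode_to_gene() == tn5_reference.true_barcode_to_gene()
        truth_pos = dict(
            zip(tn5_reference.insertions["barcode"], tn5_reference.insertions["position"])
        )
        assert dict(zip(imap.entries["barcode"], imap.entries["position"])) == truth_pos

    def test_map_tsv_round_trip(self, tn5_reference, tmp_path):
        frags, _ = ps.simulate.simulate_refmap_fragments(tn5_reference, 3, seed=4)
        imap = ps.build_map(
            ps.dedupe(frags), tn5_reference.genome, tn5_reference.vector,
            tn5_reference.annotation,
        )
        imap.to_tsv(tmp_path / "map.tsv")
        back = ps.InsertionMap.from_tsv(tmp_path / "map.tsv")
        assert back.barcode_to_gene() == imap.barcode_to_gene()


class TestGeneCounts:
    def make_map(self):
        entries = pd.DataFrame(
            {
                "barcode": ["A" * 20, "C" * 20, "G" * 20],
                "position": [1500, 1600, 2500],
                "gene_id": ["geneA", "geneA", INTERGENIC],
                "support": [5, 5, 5],
                "dominant_fraction": [1.0, 1.0, 1.0],
            }
        )
        discarded = pd.DataFrame({"barcode": ["T" * 20], "reason": ["AMBIGUOUS_DOMINANCE"]})
        return ps.InsertionMap(entries=entries, discarded=discarded)

    def test_additivity_within_gene(self):
        imap = self.make_map()
        counts = pd.DataFrame(
            {"s1": [5, 7, 2, 100, 3]},
            index=["A" * 20, "C" * 20, "G" * 20, "T" * 20, "N" * 20],
        )
        genes, audit = ps.gene_counts(imap, counts)
        assert genes.loc["geneA", "s1"] == 12
        assert genes.loc[INTERGENIC, "s1"] == 2
        assert audit.loc["s1", "discarded"] == 100  # dominance-discarded barcode
        assert audit.loc["s1", "unknown"] == 3
        # conservation
        assert audit.loc["s1"].sum() == counts["s1"].sum()

    def test_empty_map_all_unknown(self):
        imap = ps.InsertionMap(
            entries=pd.DataFrame(
                columns=["barcode", "position", "gene_id", "support", "dominant_fraction"]
            ),
            discarded=pd.DataFrame(columns=["barcode", "reason"]),
        )
        counts = pd.DataFrame({"s1": [5, 7]}, index=["A" * 20, "C" * 20])
        genes, audit = ps.gene_counts(imap, counts)
        assert len(genes) == 0
        assert audit.loc["s1", "unknown"] == 12

    def test_accepts_count_table(self, tn5_reference):
        frags, _ = ps.simulate.simulate_refmap_fragments(tn5_reference, 5, seed=6)
        imap = ps.build_map(
            ps.dedupe(frags), tn5_reference.genome, tn5_reference.vector,
            tn5_reference.annotation,
        )
        lib = ps.simulate.make_barseq_library(tn5_reference)
        truth = ps.simulate.make_tnseq_truth(tn5_reference, "gene001", seed=6)
        sc = ps.simulate.simulate_screen_counts(lib, truth, depth=10**5, n_reps=2, seed=6)
        genes, audit = ps.gene_counts(imap, sc.uninfected)
        assert (audit.sum(axis=1) == 10**5).all()
        assert (genes.sum(axis=0) == audit["mapped"]).all()
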