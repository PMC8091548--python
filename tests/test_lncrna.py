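"""ORF scanning, hexamer scoring, the coding-potential vote, candidate
filtering and positional classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cernanet.io import TranscriptModel
from cernanet.lncrna import (
    classify_lncrna_position,
    coding_potential_vote,
    filter_lncrna_candidates,
    find_longest_orf,
    index_by_contig,
    train_hexamer_model,
)
from cernanet.simulate import SimulationConfig, generate_annotation
from tests.conftest import make_counts

STOPS = ("TAA", "TAG", "TGA")


def brute_force_longest_orf(seq: str):
    """Independent oracle: enumerate every AUG/stop pair in every frame."""
    s = seq.upper().replace("U", "T")
    best_len, best_start = 0, -1
    for start in range(len(s) - 2):
        if s[start : start + 3] != "ATG":
            continue
        for stop in range(start + 3, len(s) - 2, 3):
            if s[stop : stop + 3] in STOPS:
                length = stop + 3 - start
                if length > best_len or (length == best_len and start < best_start):
                    best_len, best_start = length, start
                break
    return best_len, best_start


class TestFindLongestOrf:
    @pytest.mark.parametrize(
        "seq,length,start",
        [
            ("AUGAAAUAA", 9, 0),
            ("CCCCCCCC", 0, -1),
            ("AAAUGGCCUGAUUU", 9, 2),  # AUG GCC UGA in frame 2
        ],
    )
    def test_examples(self, seq, length, start):
        res = find_longest_orf(seq)
        assert (res.length, res.start) == (length, start)

    def test_orf_requires_stop_codon(self):
        assert find_longest_orf("ATGAAAAAA").length == 0

    def test_alphabet_error(self):
        with pytest.raises(ValueError, match="characters"):
            find_longest_orf("ATGXXXTAA")

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            res = find_longest_orf(seq)
            assert (res.length, res.start) == brute_force_longest_orf(seq)


class TestHexamerModel:
    def test_identical_training_sets_score_zero(self):
        seqs = ["ACGTACGTACGTACGT", "TTTTGGGGCCCCAAAA"] * 5
        table = train_hexamer_model(seqs, list(seqs))
        assert all(v == 0.0 for v in table.log_ratios.values())
        assert table.score("ACGTACGTACGT") == 0.0

    def test_single_window_equals_table_entry(self):
        coding = ["AUGAUG" * 20] * 10
        noncoding = ["CCCCCC" * 20] * 10
        table = train_hexamer_model(coding, noncoding)
        assert table.score("AUGAUG") == pytest.approx(table.log_ratios["ATGATG"])

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            train_hexamer_model(["ACGTACG"], ["ACGTACG"] * 10)

    def test_generator_coding_sequences_score_positive(self):
        train_ann = generate_annotation(
            SimulationConfig(seed=21, n_mrna=100, n_lncrna=100, n_mirna=8, n_triplets=0)
        )
        test_ann = generate_annotation(
            SimulationConfig(seed=22, n_mrna=100, n_lncrna=100, n_mirna=8, n_triplets=0)
        )
        table = train_hexamer_model(
            [t.sequence for t in train_ann.mrnas],
            [t.sequence for t in train_ann.lncrnas],
        )
        scores = [table.score(t.sequence) for t in test_ann.mrnas]
        assert np.mean([s > 0 for s in scores]) >= 0.9


class TestCodingPotentialVote:
    @pytest.fixture(scope="class")
    @staticmethod
    def table():
        ann = generate_annotation(
            SimulationConfig(seed=23, n_mrna=60, n_lncrna=60, n_mirna=8, n_triplets=0)
        )
        return train_hexamer_model(
            [t.sequence for t in ann.mrnas], [t.sequence for t in ann.lncrnas]
        )

    def test_no_orf_neutral_composition_gives_three_votes(self, table):
        # uniform random sequence with every ATG start removed: no reading
        # frame at all and no codon bias for the hexamer scorer to reward
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        while "ATG" in seq:
            seq = seq.replace("ATG", "TTG")
        res = coding_potential_vote("t", seq, table)
        assert res.orf_length == 0
        assert res.votes_noncoding == 3 and res.label == "noncoding"

    def test_two_votes_is_noncoding_boundary(self, table):
        # long ORF with full coverage but seen through a table trained the
        # other way round is not constructible deterministically; assert the
        # rule directly instead on a crafted result
        seq = "ATG" + "AAA" * 120 + "TAA"  # ORF 366 nt, coverage 1.0
        res = coding_potential_vote("t", seq, table, hexamer_threshold=1e9)
        # hexamer scorer forced to vote noncoding; orf and coverage vote coding
        assert res.votes_noncoding == 1 and res.label == "coding"
        res2 = coding_potential_vote(
            "t", seq, table, coverage_min=1.1, hexamer_threshold=1e9
        )
        assert res2.votes_noncoding == 2 and res2.label == "noncoding"

    def test_generator_vote_accuracy(self, table):
        ann = generate_annotation(
            SimulationConfig(seed=24, n_mrna=100, n_lncrna=100, n_mirna=8, n_triplets=0)
        )
        correct = 0
        for t in ann.transcripts:
            res = coding_potential_vote(t.transcript_id, t.sequence, table)
            truth = ann.coding_labels[t.transcript_id]
            correct += res.label == truth
        assert correct / len(ann.transcripts) >= 0.9


class TestCandidateFilter:
    def make_tx(self, tid, length, n_exons):
        exon_len = length // n_exons
        exons = []
        pos = 0
        for i in range(n_exons):
            el = exon_len if i < n_exons - 1 else length - exon_len * (n_exons - 1)
            exons.append((pos, pos + el))
            pos += el + 100
        return TranscriptModel(tid, f"gene_{tid}", "c1", "+", exons, "lncRNA-candidate")

    def fake_vote(self, tid, label="noncoding"):
        from cernanet.lncrna import CodingPotentialResult

        return CodingPotentialResult(tid, 0, 0.0, -1.0, 3, label)

    def test_threshold_composition(self):
        txs = [
            self.make_tx("short", 150, 2),
            self.make_tx("ok", 250, 2),
            self.make_tx("mono", 250, 1),
            self.make_tx("low_fpkm", 250, 2),
            self.make_tx("coding", 250, 2),
        ]
        fpkm = make_counts(
            [[0.2, 0.0]] * 4 + [[5.0, 5.0]],
            features=[t.transcript_id for t in txs],
            layer="FPKM",
        )
        fpkm.values.loc["low_fpkm"] = [0.05, 0.02]
        votes = {t.transcript_id: self.fake_vote(t.transcript_id) for t in txs}
        votes["coding"] = self.fake_vote("coding", "coding")
        kept = filter_lncrna_candidates(txs, fpkm, votes)
        assert [t.transcript_id for t in kept] == ["ok"]

    def test_missing_fpkm_keyed_error(self):
        tx = self.make_tx("t1", 250, 2)
        fpkm = make_counts([[1.0]], features=["other"], layer="FPKM")
        with pytest.raises(KeyError, match="t1"):
            filter_lncrna_candidates([tx], fpkm, {"t1": self.fake_vote("t1")})


class TestPositionalClassification:
    def coding_tx(self, exons, strand="+"):
        return TranscriptModel("cod", "gene_cod", "c1", strand, exons, "mRNA")

    def lnc(self, exons, strand="+", contig="c1"):
        return TranscriptModel("lnc", "gene_lnc", contig, strand, exons, "lncRNA-candidate")

    def test_no_overlap_is_lincrna(self):
        index = index_by_contig([self.coding_tx([(0, 1000)])], contigs=["c1"])
        assert classify_lncrna_position(self.lnc([(5000, 5200), (5400, 5600)]), index) == "lincRNA"

    def test_opposite_strand_exon_overlap_is_antisense(self):
        index = index_by_contig([self.coding_tx([(0, 1000)], "+")], contigs=["c1"])
        assert classify_lncrna_position(self.lnc([(500, 700), (800, 900)], "-"), index) == "antisense"

    def test_same_strand_exon_overlap_is_sense(self):
        index = index_by_contig([self.coding_tx([(0, 1000)], "+")], contigs=["c1"])
        assert classify_lncrna_position(self.lnc([(500, 700), (800, 900)], "+"), index) == "sense"

    def test_fully_intronic_same_strand(self):
        coding = self.coding_tx([(0, 500), (10_000, 11_000)], "+")
        index = index_by_contig([coding], contigs=["c1"])
        assert classify_lncrna_position(self.lnc([(2000, 2200), (2500, 2700)], "+"), index) == "intronic"

    def test_exon_overlap_precedes_intronic(self):
        coding = self.coding_tx([(0, 500), (10_000, 11_000)], "+")
        # lncRNA straddles: one exon inside the intron, one overlapping a coding exon
        lnc = self.lnc([(400, 600), (2000, 2200)], "-")
        index = index_by_contig([coding], contigs=["c1"])
        assert classify_lncrna_position(lnc, index) == "antisense"

    def test_unknown_contig_keyed_error(self):
        index = index_by_contig([self.coding_tx([(0, 100)])], contigs=["c1"])
        with pytest.raises(KeyError, match="c9"):
            classify_lncrna_position(self.lnc([(0, 100), (200, 300)], contig="c9"), index)

    @given(st.data())
    def test_classification_total_and_single(self, data):
        """Random interval fuzz: every lncRNA gets exactly one of the four classes."""
        rng_ints = st.integers(min_value=0, max_value=5000)
        a = data.draw(rng_ints)
        b = a + data.draw(st.integers(min_value=50, max_value=2000))
        c = b + data.draw(st.integers(min_value=50, max_value=3000))
        d = c + data.draw(st.integers(min_value=50, max_value=2000))
        coding = self.coding_tx([(a, b), (c, d)], data.draw(st.sampled_from("+-")))
        l0 = data.draw(rng_ints)
        l1 = l0 + data.draw(st.integers(min_value=10, max_value=1000))
        l2 = l1 + data.draw(st.integers(min_value=10, max_value=1000))
        l3 = l2 + data.draw(st.integers(min_value=10, max_value=1000))
        lnc = self.lnc([(l0, l1), (l2, l3)], data.draw(st.sampled_from("+-")))
        index = index_by_contig([coding], contigs=["c1"])
        result = classify_lncrna_position(lnc, index)
        assert result in ("lincRNA", "intronic", "antisense", "sense")
        assert classify_lncrna_position(lnc, index) == result  # deterministic
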