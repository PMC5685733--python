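"""Trimming, collapsing, calibrator matching and alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sermir import read_processing as rp
from sermir import synthetic_data as sd
from sermir._seq import random_seq, revcomp
from sermir.synthetic_data import DEFAULT_ADAPTER

from oracles import collapse_oracle, trim_oracle

INSERT = "ACGTTGCAGGCATTACGATCGA"  # 22 nt


class TestTrimAdapter:
    def test_full_adapter_removed(self):
        read = (INSERT + DEFAULT_ADAPTER + "AAAAAAA")[:50]
        assert rp.trim_adapter(read, DEFAULT_ADAPTER) == (INSERT, rp.TRIMMED)

    def test_no_adapter_left_untrimmed(self):
        read = random_seq(np.random.default_rng(0), 50)
        ins, status = rp.trim_adapter(read, "GGGGGGGGGGGGGGG")
        assert (ins, status) == (read, rp.UNTRIMMED)

    def test_short_insert_flagged_too_short(self):
        read = ("ACGTACGT" + DEFAULT_ADAPTER)[:50]
        ins, status = rp.trim_adapter(read, DEFAULT_ADAPTER, min_insert=10)
        assert status == rp.TOO_SHORT
        assert ins == "ACGTACGT"

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            rp.trim_adapter("ACGT", "")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_suffix_scan(self, seed):
        rng = np.random.default_rng(seed)
        ins = random_seq(rng, int(rng.integers(5, 35)))
        read = (ins + DEFAULT_ADAPTER + "ATCTCGTATGCC")[: int(rng.integers(30, 51))]
        assert rp.trim_adapter(read, DEFAULT_ADAPTER) == trim_oracle(read, DEFAULT_ADAPTER)


class TestCollapse:
    def test_identical_reads_collapse_to_one_row(self):
        reads = {"A": [("r1", INSERT + DEFAULT_ADAPTER), ("r2", INSERT + DEFAULT_ADAPTER),
                       ("r3", INSERT + DEFAULT_ADAPTER)]}
        mat, stats = rp.collapse_reads(reads, DEFAULT_ADAPTER)
        assert mat.shape == (1, 1)
        assert mat.loc[INSERT, "A"] == 3
        assert stats.loc["A", "trimmed"] == 3

    def test_per_sample_counts(self):
        s1, s2 = "ACGTACGTACGTACGTACGTAC", "TTTTGGGGCCCCAAAATTTTGG"
        reads = {
            "A": [("a1", s1 + DEFAULT_ADAPTER), ("a2", s1 + DEFAULT_ADAPTER),
                  ("a3", s2 + DEFAULT_ADAPTER)],
            "B": [("b1", s1 + DEFAULT_ADAPTER)],
        }
        mat, _ = rp.collapse_reads(reads, DEFAULT_ADAPTER)
        assert mat.loc[s1].tolist() == [2, 1]
        assert mat.loc[s2].tolist() == [1, 0]

    def test_matches_hash_count_oracle(self):
        rng = np.random.default_rng(3)
        pool = [random_seq(rng, 22) for _ in range(50)]
        reads = {
            sid: [(f"{sid}r{i}", pool[rng.integers(0, 50)] + DEFAULT_ADAPTER)
                  for i in range(5000)]
            for sid in ("A", "B")
        }
        mat, _ = rp.collapse_reads(reads, DEFAULT_ADAPTER)
        oracle = collapse_oracle(
            {sid: [seq[: len(seq) - len(DEFAULT_ADAPTER)] for _, seq in rs]
             for sid, rs in reads.items()}
        )
        assert mat.sum().sum() == 10000
        for seq, per_sample in oracle.items():
            for sid, cnt in per_sample.items():
                assert mat.loc[seq, sid] == cnt


class TestCalibratorMatching:
    def test_exact_match_claimed_and_removed(self, toy_ref):
        cal = toy_ref.calibrators[2]
        other = "ACGTACGTACGTACGTACGTAC"
        mat = pd.DataFrame({"A": [5, 7]}, index=[cal.sequence, other])
        counts, variants, rest = rp.match_calibrators(mat, toy_ref.calibrators)
        assert counts.loc[cal.name, "A"] == 5
        assert variants.empty
        assert list(rest.index) == [other]

    def test_terminal_deletion_counts_as_variant(self, toy_ref):
        cal = toy_ref.calibrators[0]
        mat = pd.DataFrame({"A": [4]}, index=[cal.sequence[:-1]])
        counts, variants, rest = rp.match_calibrators(mat, toy_ref.calibrators)
        assert counts.loc[cal.name, "A"] == 4
        assert variants.iloc[0]["calibrator"] == cal.name
        assert variants.iloc[0]["distance"] == 1
        assert rest.empty

    def test_distant_sequence_passes_through(self, toy_ref):
        mature = next(iter(toy_ref.mature_seqs.values()))
        mat = pd.DataFrame({"A": [9]}, index=[mature])
        counts, variants, rest = rp.match_calibrators(mat, toy_ref.calibrators)
        assert counts.to_numpy().sum() == 0
        assert list(rest.index) == [mature]

    def test_equidistant_tie_goes_to_lowest_index(self):
        cal1 = sd.Calibrator("cal-01", "A" * 22)
        cal2 = sd.Calibrator("cal-02", "A" * 21 + "T")
        seq = "A" * 21 + "G"  # distance 1 from both
        mat = pd.DataFrame({"A": [2]}, index=[seq])
        counts, variants, _ = rp.match_calibrators(mat, [cal1, cal2])
        assert counts.loc["cal-01", "A"] == 2
        assert counts.loc["cal-02", "A"] == 0
        assert variants.iloc[0]["calibrator"] == "cal-01"


class TestAlignment:
    GENOME = {"c1": random_seq(np.random.default_rng(42), 4000)}

    def test_unique_sequence_single_hit_no_tail(self):
        seq = self.GENOME["c1"][100:122]
        df = rp.align_unique_sequences([seq], self.GENOME)
        assert len(df) == 1
        r = df.iloc[0]
        assert (r["start"], r["end"], r["strand"], r["clipped_tail"]) == (100, 122, "+", "")

    def test_nontemplated_tail_clipped(self):
        core = self.GENOME["c1"][200:220]
        nxt = self.GENOME["c1"][220]
        tail = "AA" if nxt != "A" else "TT"
        df = rp.align_unique_sequences([core + tail], self.GENOME)
        assert len(df) == 1
        assert df.iloc[0]["clipped_tail"] == tail
        assert df.iloc[0]["end"] == 220

    def test_multi_locus_saturation_at_max_hits(self):
        seq = "ACGGATTACAGGCATGAGCCAC"
        genome = {"c1": ("TTTTTTTTTT" + seq) * 12 + "TTTTTTTTTT"}
        df = rp.align_unique_sequences([seq], genome, max_hits=10)
        assert len(df) == 10
        assert df["saturated"].all()
        # leftmost placements kept
        assert df["start"].tolist() == sorted(df["start"].tolist())[:10]

    def test_minus_strand_found(self):
        seq = revcomp(self.GENOME["c1"][300:322])
        df = rp.align_unique_sequences([seq], self.GENOME)
        plus_hits = df[df["strand"] == "-"]
        assert len(plus_hits) == 1
        assert plus_hits.iloc[0]["start"] == 300

    def test_unmapped_reported(self):
        df = rp.align_unique_sequences(["A" * 22], self.GENOME)
        assert df.iloc[0]["status"] == "unmapped"

    def test_retained_alignments_have_no_internal_mismatches(self, large_library):
        ref = large_library["ref"]
        aln = large_library["alignments"]
        ok = aln[aln["status"] == "aligned"].sample(n=300, random_state=0)
        for _, r in ok.iterrows():
            g = ref.contigs[r["contig"]][r["start"]:r["end"]]
            core = r["sequence"][: len(r["sequence"]) - len(r["clipped_tail"])]
            assert core == (g if r["strand"] == "+" else revcomp(g))

    def test_strand_symmetry_of_classification(self):
        # same mature planted on + and -; both reads align and overlap
        mature = "ACGGATTACAGGCATGAGCCAC"
        spacer = random_seq(np.random.default_rng(9), 50)
        genome = {"c1": spacer + mature + "C" + spacer + "G" + revcomp(mature) + spacer}
        df = rp.align_unique_sequences([mature], genome)
        strands = set(df["strand"])
        assert strands == {"+", "-"}
        assert (df["clipped_tail"] == "").all()

    def test_mirna_reads_recover_true_locus(self, large_library):
        truth = large_library["truth"]
        asn = large_library["assignments"]
        mirna_truth = truth[truth["rna_class"] == "miRNA"]
        assigned = asn[asn["kind"] == "miRNA"].groupby("sequence")["feature"].agg(set)
        hits = [
            row["feature"] in assigned.get(row["insert"], set())
            for _, row in mirna_truth.drop_duplicates(subset=["insert", "feature"]).iterrows()
        ]
        assert np.mean(hits) >= 0.99


class TestLengthDistribution:
    def test_totals_conserved_and_modes(self, large_library):
        remainder = large_library["remainder"]
        asn = large_library["assignments"]
        cls = {
            s: k.split(":", 1)[-1]
            for s, k in zip(asn["sequence"], asn["kind"])
        }
        hist = rp.length_distribution(remainder, cls)
        assert hist["reads"].sum() == remainder.sum().sum()
        mirna = hist[hist["rna_class"] == "miRNA"].set_index("length")["reads"]
        assert 21 <= mirna.idxmax() <= 23
        scrna = hist[hist["rna_class"] == "scRNA"].set_index("length")["reads"]
        assert 29 <= scrna.idxmax() <= 33
        # degradation-fragment mode around 13 nt
        pooled = hist.groupby("length")["reads"].sum()
        short = pooled[(pooled.index >= 10) & (pooled.index <= 16)]
        assert short.sum() / pooled.sum() > 0.15
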