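"""Context calling, depth filter, labels, splits, D_max."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methynet import preprocess as pp
from methynet.io import GenomeSequence


def brute_force_context(seq: str, pos: int, strand: str):
    """Independent triplet scanner (string slicing, no shared code)."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
    if strand == "+":
        triplet = seq[pos - 1 : pos + 2]
    else:
        triplet = "".join(comp[b] for b in reversed(seq[max(pos - 3, 0) : pos]))
        if pos - 3 < 0:
            triplet = triplet + ""   # short at chromosome start
    if not triplet or triplet[0] != "C":
        return None
    if len(triplet) >= 2 and triplet[1] == "G":
        return "CpG"
    if len(triplet) < 3 or "N" in triplet[1:3]:
        return pp.INDETERMINATE
    if triplet[2] == "G":
        return "CHG"
    return "CHH"


class TestCallContext:
    @pytest.mark.parametrize("seq,pos,strand,expected", [
        ("ACGT", 2, "+", "CpG"),
        ("ACAGT", 2, "+", "CHG"),
        ("ACAAT", 2, "+", "CHH"),
        ("ACGT", 3, "-", "CpG"),          # G on + strand is C on -
        ("ACN", 2, "+", pp.INDETERMINATE),
        ("AC", 2, "+", pp.INDETERMINATE),  # runs off the end
        ("AAGT", 2, "+", None),            # not a cytosine
    ])
    def test_examples(self, seq, pos, strand, expected):
        assert pp.call_context(GenomeSequence("t", seq), pos, strand) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match="outside"):
            pp.call_context(GenomeSequence("t", "ACGT"), 5, "+")

    def test_all_short_genomes_match_brute_force(self):
        """Exhaustive: every <=6-mer over ACGT, every position, both strands."""
        for n in (1, 2, 3, 4):
            for tup in itertools.product("ACGT", repeat=n):
                seq = "".join(tup)
                g = GenomeSequence("t", seq)
                for pos in range(1, n + 1):
                    for strand in "+-":
                        assert (pp.call_context(g, pos, strand)
                                == brute_force_context(seq, pos, strand)), \
                            (seq, pos, strand)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=50, max_size=1000))
    def test_genome_cytosines_matches_brute_force(self, seq):
        g = GenomeSequence("t", seq)
        df = pp.genome_cytosines(g)
        # completeness: one row per C (plus) and G (minus)
        n_c = seq.count("C") + seq.count("G")
        assert len(df) == n_c
        for _, row in df.iloc[:: max(len(df) // 20, 1)].iterrows():
            assert row["context"] == brute_force_context(
                seq, int(row["pos"]), row["strand"])


class TestLabelSite:
    @pytest.mark.parametrize("n_meth,n_unmeth,expected", [
        (2, 1, None),      # depth 3 < 4 -> NA
        (4, 0, 1.0),
        (0, 4, 0.0),
        (2, 2, 1.0),       # exact 0.5 rounds up on the input side
        (3, 4, 0.0),       # rate 3/7 < 0.5
    ])
    def test_examples(self, n_meth, n_unmeth, expected):
        rec = pp.label_site({"chrom": "c", "pos": 1, "strand": "+",
                             "context": "CpG", "n_meth": n_meth,
                             "n_unmeth": n_unmeth})
        assert rec.label == expected

    def test_min_depth_is_configurable(self):
        rec = pp.label_site({"chrom": "c", "pos": 1, "strand": "+",
                             "context": "CpG", "n_meth": 2, "n_unmeth": 1},
                            min_depth=3)
        assert rec.label == 1.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 30), st.integers(0, 30))
    def test_na_iff_depth_below_threshold(self, n_meth, n_unmeth):
        df = pd.DataFrame({"chrom": ["c"], "pos": [1], "strand": ["+"],
                           "n_meth": [n_meth], "n_unmeth": [n_unmeth]})
        out = pp.label_sites(df)
        assert np.isnan(out["label"][0]) == (n_meth + n_unmeth < 4)
        if n_meth + n_unmeth >= 4:
            assert out["label"][0] == (1.0 if n_meth / (n_meth + n_unmeth) >= 0.5
                                       else 0.0)

    def test_idempotent_and_deterministic(self):
        df = pd.DataFrame({"chrom": "c", "pos": range(1, 11), "strand": "+",
                           "n_meth": range(10), "n_unmeth": 5})
        once = pp.label_sites(df)
        twice = pp.label_sites(once)
        pd.testing.assert_series_equal(once["label"], twice["label"])


class TestPrepareSites:
    def test_context_recomputed_with_mismatch_warning(self, toy_genome):
        report = pd.DataFrame({"chrom": ["toy"], "pos": [2], "strand": ["+"],
                               "n_meth": [5], "n_unmeth": [0],
                               "context": ["CHH"]})   # genome says CpG
        with pytest.warns(UserWarning, match="disagreed"):
            out = pp.prepare_sites(report, {"toy": toy_genome})
        assert out["context"][0] == "CpG"
        assert out.attrs["context_mismatches"] == 1

    def test_non_cytosine_row_flagged_na(self, toy_genome):
        report = pd.DataFrame({"chrom": ["toy"], "pos": [1], "strand": ["+"],
                               "n_meth": [9], "n_unmeth": [0],
                               "context": [None]})    # 'A' on + strand
        out = pp.prepare_sites(report, {"toy": toy_genome})
        assert out["context"][0] == pp.INDETERMINATE
        assert np.isnan(out["label"][0])

    def test_unknown_chromosome_raises(self, toy_genome):
        report = pd.DataFrame({"chrom": ["nope"], "pos": [1], "strand": ["+"],
                               "n_meth": [9], "n_unmeth": [0], "context": [None]})
        with pytest.raises(KeyError, match="nope"):
            pp.prepare_sites(report, {"toy": toy_genome})


class TestSplitSites:
    def _sites(self, chroms=("c1", "c2", "c3"), n=20):
        rows = []
        for c in chroms:
            for p in range(1, n + 1):
                rows.append({"chrom": c, "pos": p, "strand": "+",
                             "context": "CHH",
                             "label": np.nan if p % 5 == 0 else float(p % 2)})
        return pd.DataFrame(rows)

    def test_partition_complete_and_disjoint(self):
        sites = self._sites()
        spec = pp.SplitSpec({"c1"}, {"c2"}, {"c3"})
        s = pp.split_sites(sites, spec)
        n_labeled = sites["label"].notna().sum()
        assert len(s.train) + len(s.val) + len(s.test) == n_labeled
        assert len(s.universe) == len(sites)
        keys = [set(zip(d["chrom"], d["pos"])) for d in (s.train, s.val, s.test)]
        assert not (keys[0] & keys[1] or keys[0] & keys[2] or keys[1] & keys[2])

    def test_na_records_excluded_from_subsets(self):
        s = pp.split_sites(self._sites(), pp.SplitSpec({"c1"}, {"c2"}, {"c3"}))
        for d in (s.train, s.val, s.test):
            assert d["label"].notna().all()

    def test_overlapping_spec_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pp.SplitSpec({"c1"}, {"c1"}, {"c3"})

    def test_chrom_outside_spec_excluded(self):
        s = pp.split_sites(self._sites(("c1", "c2", "c3", "c4")),
                           pp.SplitSpec({"c1"}, {"c2"}, {"c3"}))
        for d in (s.train, s.val, s.test):
            assert "c4" not in set(d["chrom"])

    def test_empty_val_warns(self):
        sites = self._sites(("c1", "c3"))
        with pytest.warns(UserWarning, match="val split is empty"):
            pp.split_sites(sites, pp.SplitSpec({"c1"}, set(), {"c3"}))


class TestMaxNeighborGap:
    def brute(self, frame):
        best = 0
        for _, g in frame.groupby("chrom"):
            pos = sorted(set(g["pos"]))
            for a, b in zip(pos, pos[1:]):
                best = max(best, b - a)
        return best

    def test_single_chromosome_example(self):
        df = pd.DataFrame({"chrom": "c", "pos": [10, 12, 100]})
        assert pp.max_neighbor_gap(df) == 88

    def test_equally_spaced(self):
        df = pd.DataFrame({"chrom": "c", "pos": range(5, 100, 7)})
        assert pp.max_neighbor_gap(df) == 7

    def test_across_chromosomes(self):
        df = pd.DataFrame({"chrom": ["a", "a", "b", "b"],
                           "pos": [1, 6, 10, 60]})
        assert pp.max_neighbor_gap(df) == 50

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from("ab"), st.integers(1, 10_000)),
                    min_size=2, max_size=60))
    def test_matches_brute_force(self, pairs):
        df = pd.DataFrame(pairs, columns=["chrom", "pos"])
        expected = self.brute(df)
        if expected == 0:
            with pytest.raises(ValueError):
                pp.max_neighbor_gap(df)
        else:
            assert pp.max_neighbor_gap(df) == expected

    def test_too_few_sites_raises(self):
        with pytest.raises(ValueError, match="two cytosines"):
            pp.max_neighbor_gap(pd.DataFrame({"chrom": ["a"], "pos": [5]}))
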