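"""Pairwise alignment, variant inventories and region decomposition."""

import edlib
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igcall import (
    VariantPlacementSpec,
    align_pair,
    build_allele_panel,
    compare_references,
    decompose_regions,
    enumerate_variants,
)
from igcall.divergence import _ambiguous_offsets


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestAlignPair:
    def test_identical_sequences_zero_cost(self):
        aln = align_pair("ACGTACGT", "ACGTACGT")
        assert aln.cost == 0 and not aln.has_gaps

    def test_single_mismatch_forced(self):
        aln = align_pair("ACGT", "AGGT")
        assert aln.cost == 1
        cols = aln.columns()
        assert [a != b for a, b in cols] == [False, True, False, False]

    def test_cost_matches_edlib_oracle(self, rng):
        for _ in range(10):
            a = random_seq(rng, 200)
            b = list(a)
            # random substitutions and indels
            for pos in rng.choice(200, 8, replace=False):
                b[pos] = rng.choice(list("ACGT"))
            b = "".join(b)
            if rng.random() < 0.5:
                b = b[:50] + b[55:]
            expected = edlib.align(a, b, mode="NW")["editDistance"]
            assert align_pair(a, b).cost == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")


class TestEnumerateVariants:
    def test_identical_inputs(self):
        assert enumerate_variants("ACGTACGT", "ACGTACGT").total_variants == 0

    def test_nine_placed_substitutions(self, rng):
        a = random_seq(rng, 200)
        positions = sorted(rng.choice(200, 9, replace=False))
        b = list(a)
        for p in positions:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[a[p]]
        table = enumerate_variants(a, "".join(b))
        assert table.total_variants == 9
        assert list(table.rows["position"]) == [p + 1 for p in positions]

    def test_coding_utr_compartment_counts(self, rng):
        """Five coding + eight UTR placed substitutions attribute (5, 8)."""
        a = random_seq(rng, 300)
        coding = sorted(rng.choice(150, 5, replace=False))
        utr = sorted(150 + rng.choice(150, 8, replace=False))
        b = list(a)
        for p in coding + utr:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[a[p]]
        table = enumerate_variants(a, "".join(b), coding_end=150)
        assert table.total_variants == 13
        assert table.compartment_counts() == (5, 8)

    def test_symmetry(self, rng):
        """Swapping the inputs swaps the base columns but keeps positions
        (paralog-like pairs: same length, substitution divergence)."""
        a = random_seq(rng, 150)
        b = list(a)
        for p in rng.choice(150, 12, replace=False):
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[a[p]]
        b = "".join(b)
        ta = enumerate_variants(a, b)
        tb = enumerate_variants(b, a)
        assert list(ta.rows["position"]) == list(tb.rows["position"])
        assert list(ta.rows["base_left"]) == list(tb.rows["base_right"])
        assert list(ta.rows["base_right"]) == list(tb.rows["base_left"])

    def test_indels_inventoried_separately(self):
        table = enumerate_variants("AAAACCCC", "AAAACCC")
        assert table.n_indel_columns == 1
        assert table.frame == "alignment_columns"


class TestDecomposeRegions:
    def build(self, pair_variants, L=120):
        spec = VariantPlacementSpec("p", "gA", "gB", pair_variants=pair_variants)
        return build_allele_panel([spec], base_exon_length=L, seed=3)

    def test_no_variants_all_ambiguous_in_both(self):
        pa, pb = self.build({})
        deco = decompose_regions(pa, pb, ("gA", "gB"), 20)
        assert deco.class_lengths()["ambiguous_in_both"] == deco.n_offsets

    def test_single_variant_in_b_covers_expected_window(self):
        p = 57
        pa, pb = self.build({"refB": [(p, None, "T")]})
        deco = decompose_regions(pa, pb, ("gA", "gB"), 10)
        expect = np.zeros(deco.n_offsets, dtype=bool)
        expect[p - 9 : p + 1] = True  # offsets whose window covers position p
        got = deco.labels == "ambiguous_in_a_only"
        assert np.array_equal(got, expect)
        assert ((deco.labels == "ambiguous_in_a_only") | (deco.labels == "ambiguous_in_both")).all()

    def test_matches_brute_force_window_scan(self, panels):
        pa, pb = panels
        for pair in [("IGHG1", "IGHG2"), ("IGHA1", "IGHA2"), ("IGHG1", "IGHG3")]:
            deco = decompose_regions(pa, pb, pair, 90)
            for o in range(deco.n_offsets):
                wa1 = pa.terminal_seq(pair[0])[o : o + 90]
                wa2 = pa.terminal_seq(pair[1])[o : o + 90]
                wb1 = pb.terminal_seq(pair[0])[o : o + 90]
                wb2 = pb.terminal_seq(pair[1])[o : o + 90]
                amb_a, amb_b = wa1 == wa2, wb1 == wb2
                expected = {
                    (True, True): "ambiguous_in_both",
                    (True, False): "ambiguous_in_a_only",
                    (False, True): "ambiguous_in_b_only",
                    (False, False): "distinguishable_in_both",
                }[(amb_a, amb_b)]
                assert deco.class_of(o) == expected

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        r=st.integers(min_value=5, max_value=60),
        positions=st.lists(st.integers(min_value=0, max_value=119), min_size=0, max_size=6, unique=True),
    )
    def test_monotonicity_in_read_length(self, r, positions):
        """Longer windows never lose distinguishable offsets (per reference)."""
        pa, pb = self.build({"refA": [(p, None, "T") for p in positions]})
        a1, a2 = pa.terminal_seq("gA"), pa.terminal_seq("gB")
        amb_r = _ambiguous_offsets(a1, a2, r)
        amb_r2 = _ambiguous_offsets(a1, a2, min(r + 10, 120))
        n = amb_r2.size
        # every offset distinguishable at R stays distinguishable at R+10
        assert not np.any(~amb_r[:n] & amb_r2)

    def test_intervals_partition_offsets(self, panels):
        pa, pb = panels
        deco = decompose_regions(pa, pb, ("IGHA1", "IGHA2"), 90)
        deco.validate()
        frame = deco.to_frame()
        assert frame["start"].iloc[0] == 0
        assert frame["end"].iloc[-1] == deco.n_offsets


class TestCompareReferences:
    def test_same_allele_zero_variants(self):
        spec = VariantPlacementSpec("p", "gA", "gB")
        pa, pb = build_allele_panel([spec], seed=4)
        comps = compare_references(pa, pb, "gA")
        assert len(comps) == 1 and comps[0].table.total_variants == 0
        assert not comps[0].duplicated

    def test_single_placed_cross_variant(self):
        spec = VariantPlacementSpec(
            "p", "gA", "gB", cross_variants={"gA": [(33, "A", "G")]}
        )
        pa, pb = build_allele_panel([spec], seed=4)
        table = compare_references(pa, pb, "gA")[0].table
        assert table.total_variants == 1
        assert table.rows.iloc[0]["position"] == 34  # 1-based

    def test_duplicated_gene_compared_per_copy(self, panels):
        pa, pb = panels
        comps = compare_references(pa, pb, "IGHG4")
        assert len(comps) == 2
        assert all(c.duplicated for c in comps)
        by_copy = {c.gene_id_b: c.table.compartment_counts() for c in comps}
        assert by_copy["IGHG4"] == (2, 0)
        assert by_copy["IGHG4B"] == (1, 6)

    def test_missing_gene_raises(self, panels):
        with pytest.raises(KeyError):
            compare_references(*panels, "IGHZ")
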