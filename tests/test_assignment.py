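"""Read assignment model: alignment, unique-best-gene decision, dedup, counts."""

import numpy as np
import pytest

from igcall import (
    AssignmentPolicy,
    Region,
    align_read,
    assign_read,
    assign_reads,
    class_tallies,
    dedup_umis,
    panel_regions,
    quantify,
    simulate_cells,
    simulate_reads,
)
from igcall.assignment import CLASSES, DISCARDED_MULTIMAP, EFFECTIVE, PCR_DUPLICATE


def mk_region(gene, seq, region_id=None, segments=None):
    return Region(region_id or f"{gene}:x", gene, seq, segments)


class TestAlignRead:
    def test_exact_substring_single_region(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        read = seq[40:130]
        cands = align_read(read, [mk_region("g", seq)])
        assert cands[0].mismatches == 0 and cands[0].offset == 40
        assert cands[0].score == 90

    def test_one_covered_difference_ranks_genes(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 150))
        other = seq[:75] + ("A" if seq[75] != "A" else "C") + seq[76:]
        read = seq[30:120]
        cands = align_read(read, [mk_region("gX", seq), mk_region("gY", other)])
        best = {c.gene_id: c.mismatches for c in cands if c.offset == 30}
        assert best == {"gX": 0, "gY": 1}
        res = assign_read(cands)
        assert res.read_class == "effective" and res.assigned_gene == "gX"

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError):
            align_read("ACGT", [])


class TestAssignRead:
    def test_cross_gene_tie_discarded(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 120))
        read = seq[10:100]
        cands = align_read(read, [mk_region("IGHA1", seq), mk_region("IGHA2", seq)])
        res = assign_read(cands)
        assert res.read_class == "discarded_multimap" and res.assigned_gene is None

    def test_same_gene_tie_rescued_when_enabled(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 120))
        read = seq[10:100]
        regions = [
            mk_region("IGHA", seq, "IGHA1:x"),
            mk_region("IGHA", seq, "IGHA2:x"),
        ]
        on = assign_read(align_read(read, regions), AssignmentPolicy(gene_level_rescue=True))
        off_pol = AssignmentPolicy(gene_level_rescue=False)
        off = assign_read(align_read(read, regions, off_pol), off_pol)
        assert on.read_class == "effective" and on.assigned_gene == "IGHA"
        assert off.read_class == "discarded_multimap"

    def test_unique_best_by_mismatch(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 120))

        def mutate(s, k):
            s = list(s)
            for p in range(0, 3 * k, 3):
                s[20 + p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[20 + p]]
            return "".join(s)

        read = seq[0:90]
        cands = align_read(read, [mk_region("gX", mutate(seq, 1)), mk_region("gY", mutate(seq, 2))])
        res = assign_read(cands)
        assert res.assigned_gene == "gX" and res.mismatches == 1

    def test_no_alignment_is_unmapped(self, rng):
        read = "".join(rng.choice(list("ACGT"), 90))
        seq = "".join(rng.choice(list("ACGT"), 120))
        res = assign_read(align_read(read, [mk_region("g", seq)]))
        assert res.read_class == "unmapped"


class TestBulkOracle:
    def test_bulk_equals_brute_force_on_random_reads(self, panels, brute_assign, rng):
        """1000 random reads: the vectorised bulk path reproduces an
        independent exhaustive scan read by read."""
        _, pb = panels
        regions = panel_regions(pb)
        policy = AssignmentPolicy()
        cells = simulate_cells(30, {"IGHG1": 0.3, "IGHG2": 0.3, "IGHA1": 0.2, "IGHA2": 0.2},
                               libsize_log_mean=3.5, seed=31)
        reads = simulate_reads(pb, cells, error_rate=0.03, seed=32)
        idx = rng.choice(reads.n_reads, min(1000, reads.n_reads), replace=False)
        idx.sort()
        sub = reads.subset(idx)
        table = assign_reads(sub, pb, policy)
        seqs = sub.sequences()
        for i in range(sub.n_reads):
            cls, gene, mm = brute_assign(seqs[i], regions, policy.max_mismatch)
            assert CLASSES[table.read_class[i]] == cls
            if cls == "effective":
                assert table.gene_ids[table.gene_code[i]] == gene
                assert table.mismatches[i] == mm

    def test_bulk_matches_per_read_ops(self, panels, small_reads):
        _, pb = panels
        regions = panel_regions(pb)
        table = assign_reads(small_reads, pb)
        seqs = small_reads.sequences()
        rng = np.random.default_rng(5)
        for i in rng.choice(small_reads.n_reads, 40, replace=False):
            res = assign_read(align_read(seqs[i], regions))
            assert CLASSES[table.read_class[i]] == res.read_class


class TestDedup:
    def test_unique_umis_no_duplicates(self, panels, small_cells):
        _, pb = panels
        reads = simulate_reads(pb, small_cells, pcr_duplication_mean=1.0, seed=41)
        table = dedup_umis(assign_reads(reads, pb))
        assert table.class_counts()["pcr_duplicate"] <= 2  # rare UMI collisions only

    def test_k_copies_one_effective(self, panels, small_cells):
        _, pb = panels
        reads = simulate_reads(pb, small_cells, pcr_duplication_mean=3.0, seed=42)
        table = dedup_umis(assign_reads(reads, pb))
        eff = table.read_class == EFFECTIVE
        dup = table.read_class == PCR_DUPLICATE
        # per assigned molecule exactly one effective survivor
        assigned = eff | dup
        mols = reads.molecule_id[assigned]
        n_mols_assigned = np.unique(mols).size
        assert eff.sum() <= n_mols_assigned  # UMI collisions can merge molecules
        assert eff.sum() >= 0.99 * n_mols_assigned

    def test_duplicate_fraction_matches_shifted_poisson(self, panels):
        _, pb = panels
        cells = simulate_cells(40, {"IGHG1": 1.0}, libsize_log_mean=5.5, seed=43)
        mean = 2.0
        reads = simulate_reads(pb, cells, pcr_duplication_mean=mean, seed=44)
        table = dedup_umis(assign_reads(reads, pb))
        counts = table.class_counts()
        frac = counts["pcr_duplicate"] / (counts["effective"] + counts["pcr_duplicate"])
        # shifted Poisson: E[copies] = mean, so duplicate fraction -> 1 - 1/mean
        assert frac == pytest.approx(1 - 1 / mean, abs=0.02)


class TestQuantify:
    def test_zero_effective_reads_gives_zero_matrix(self, panels, small_cells):
        _, pb = panels
        reads = simulate_reads(pb, small_cells, seed=45).subset(np.arange(10))
        table = assign_reads(reads, pb)
        table.read_class[:] = DISCARDED_MULTIMAP
        m = quantify(table, small_cells["barcode"].to_numpy(), small_cells["barcode"].to_numpy())
        assert m.counts.sum() == 0
        assert m.n_cells == len(small_cells)

    def test_class_tallies_conserve_reads(self, panels, small_reads):
        _, pb = panels
        table = dedup_umis(assign_reads(small_reads, pb))
        tall = class_tallies(table, {"IGHG": ["IGHG1", "IGHG2"]})
        assert tall.loc["all", "total"] == small_reads.n_reads
        assert sum(table.class_counts().values()) == small_reads.n_reads

    def test_non_whitelist_barcodes_tallied_separately(self, panels, small_cells):
        _, pb = panels
        reads = simulate_reads(pb, small_cells, seed=46)
        table = assign_reads(reads, pb)
        wl = small_cells["barcode"].to_numpy()[:30]
        m = quantify(table, wl, small_cells["barcode"].to_numpy())
        t = m.tallies.iloc[0]
        assert t["effective_other_barcode"] > 0
        assert t["effective_whitelisted"] + t["effective_other_barcode"] == t["effective"]
        assert m.counts.sum() == t["effective_whitelisted"]


class TestReferenceMismatchProperties:
    def test_matched_reference_correct_or_discarded(self, panels, small_reads):
        """Error-free reads mapped against their donor panel are never
        assigned to a gene other than their truth."""
        _, pb = panels
        table = assign_reads(small_reads, pb)
        eff = table.read_class == EFFECTIVE
        assert (table.assigned_gene_names()[eff] == small_reads.true_gene_names()[eff]).all()

    def test_swapped_reference_reproduces_misassignment(self, panels):
        """Donor IGHG2 reads from the designated 3' window map to IGHG1
        under the mismatched reference."""
        pa, pb = panels
        cells = simulate_cells(30, {"IGHG2": 1.0}, libsize_log_mean=4.5, seed=51)
        reads = simulate_reads(pb, cells, seed=52)
        table = assign_reads(reads, pa)
        eff = table.read_class == EFFECTIVE
        names = table.assigned_gene_names()
        to_g1 = eff & (names == "IGHG1")
        assert to_g1.sum() > 0
        # misassigned reads cluster in the 3' window region
        assert reads.offsets[to_g1].min() >= 160
        # and under the matched reference those same reads are IGHG2 or discarded
        tb = assign_reads(reads, pb)
        nb = tb.assigned_gene_names()
        assert set(nb[to_g1 & (tb.read_class == EFFECTIVE)]) <= {"IGHG2"}

    def test_swapped_reference_loses_igha_reads(self, panels):
        """Fewer effective IGHA reads under the reference whose IGHA pair is
        identical over the 3' block, with classes still conserving."""
        pa, pb = panels
        cells = simulate_cells(40, {"IGHA1": 0.5, "IGHA2": 0.5}, libsize_log_mean=4.5, seed=53)
        reads = simulate_reads(pb, cells, seed=54)
        eff_a = assign_reads(reads, pa).class_counts()
        eff_b = assign_reads(reads, pb).class_counts()
        assert eff_b["effective"] < eff_a["effective"]
        assert sum(eff_a.values()) == sum(eff_b.values()) == reads.n_reads
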